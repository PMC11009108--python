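"""Dual-spacer CasRx gRNA array design.

CasRx (Cas13d) matures its own CRISPR array, so each library vector
encodes a pair of 30-nt spacers ("gRNA array") targeting the same lncRNA
gene; cleavage at two sites leaves fragments lacking either the cap or the
poly-A tail. Design proceeds per gene on the spliced gene sequence:

* enumerate all 23-nt spacer windows, extend each 3' along the target to
  30 nt, score with a pluggable on-target efficiency model (SGS in [0,1]),
  and drop windows on low-expressed exons, windows too close to the 3' end
  to extend, and spacers carrying a BsmBI site (CGTCTC, either
  orientation) that would break Golden-Gate cloning;
* remove spacers whose exact 23-mer occurs in any other transcript
  (off-target filter);
* assign each gene a 2-7 array quota by sextile of the library-wide
  structural complexity distribution;
* pick spacers greedily over four rounds of decreasing stringency, each
  round constraining the minimum score, the intra-array spacer distance
  (MLD) and the distance between any two spacers of the gene (MGD), both
  as fractions of the spliced gene length.

Non-targeting (NT) control arrays are random 23-mers with no genomic match
within three mismatches; blacklist matching flags spacers resembling
essential-gene sequence (23-nt window, up to two mismatches).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .seq import GenomeMismatchIndex, encode, hamming_hits, revcomp

SPACER_LEN = 23
EXTENDED_LEN = 30
BSMBI_SITE = "CGTCTC"
_BSMBI_RE = re.compile("|".join((BSMBI_SITE, revcomp(BSMBI_SITE))))


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class SpacerCandidate:
    """One candidate spacer: a 23-nt window and its 30-nt extension."""

    gene_id: str
    position: int  # 0-based offset into the gene's spliced sequence
    seq23: str
    seq30: str
    score: float

    def __post_init__(self):
        if len(self.seq23) != SPACER_LEN or len(self.seq30) != EXTENDED_LEN:
            raise DesignError("spacer lengths must be 23 and 30 nt")
        if not self.seq30.startswith(self.seq23):
            raise DesignError("seq23 must be a prefix of seq30")
        if not 0.0 <= self.score <= 1.0:
            raise DesignError(f"score {self.score} outside [0, 1]")


@dataclass(frozen=True)
class GuideArray:
    """One library element: two spacers on one vector."""

    array_id: str
    gene_id: str
    spacer_pos1: SpacerCandidate
    spacer_pos2: SpacerCandidate
    design_round: int = 0
    role: str = "lncRNA"  # lncRNA | AE | NE | NT


@dataclass(frozen=True)
class DesignRoundConfig:
    round_number: int
    sgs_rule: str  # "min" | "top_quartile" | "any"
    min_sgs: float = 0.0
    mld_fraction: float = 0.0
    mgd_fraction: float = 0.0
    overlap_only: bool = False  # MGD = positional non-overlap instead of a fraction


#: The published four rounds of decreasing stringency.
DEFAULT_ROUNDS = (
    DesignRoundConfig(1, "min", min_sgs=0.75, mld_fraction=0.30, mgd_fraction=0.10),
    DesignRoundConfig(2, "top_quartile", mld_fraction=0.25, mgd_fraction=0.05),
    DesignRoundConfig(3, "top_quartile", mld_fraction=0.10, mgd_fraction=0.01),
    DesignRoundConfig(4, "any", mld_fraction=0.10, overlap_only=True),
)


def surrogate_guide_score(seq23: str) -> float:
    """Deterministic stand-in on-target score in (0, 1).

    A logistic of GC-content deviation from 0.5 and longest homopolymer
    run: balanced-GC, run-free spacers score high, skewed or repetitive
    ones low. Any external efficiency model mapping a 23-mer to [0,1] can
    be plugged in instead wherever a scorer is accepted.
    """
    s = seq23.upper()
    gc = (s.count("G") + s.count("C")) / len(s)
    run = max(len(m.group(0)) for m in re.finditer(r"(.)\1*", s))
    penalty = 8.0 * abs(gc - 0.5) + 0.5 * max(0, run - 3)
    return 1.0 / (1.0 + math.exp(penalty - 2.0))


def enumerate_spacer_candidates(
    gene_id: str,
    gene_sequence: str,
    scorer: Callable[[str], float] = surrogate_guide_score,
    excluded_regions: Sequence[tuple[int, int]] = (),
    max_non_acgt_fraction: float = 0.1,
) -> list[SpacerCandidate]:
    """All valid spacer windows of a spliced gene sequence.

    ``excluded_regions`` are half-open spliced-coordinate intervals
    (typically low-expressed exons); a window is dropped when its 23-mer
    overlaps one. Windows within 7 nt of the 3' end cannot be extended to
    30 nt and are dropped, as are windows containing a BsmBI site in
    either orientation or any non-ACGT base.
    """
    seq = gene_sequence.upper()
    n_bad = sum(1 for c in seq if c not in "ACGT")
    if len(seq) and n_bad / len(seq) > max_non_acgt_fraction:
        raise DesignError(
            f"{gene_id}: {n_bad}/{len(seq)} non-ACGT bases exceeds "
            f"{max_non_acgt_fraction:.0%}"
        )
    out: list[SpacerCandidate] = []
    for pos in range(0, len(seq) - EXTENDED_LEN + 1):
        seq30 = seq[pos : pos + EXTENDED_LEN]
        if any(c not in "ACGT" for c in seq30):
            continue
        if any(
            pos < r_end and r_start < pos + SPACER_LEN
            for r_start, r_end in excluded_regions
        ):
            continue
        if _BSMBI_RE.search(seq30):
            continue
        seq23 = seq30[:SPACER_LEN]
        out.append(SpacerCandidate(gene_id, pos, seq23, seq30, float(scorer(seq23))))
    return out


def filter_offtarget_spacers(
    candidates: Sequence[SpacerCandidate],
    transcriptome: Mapping[str, str],
) -> list[SpacerCandidate]:
    """Remove spacers with an exact 23-mer occurrence outside their gene.

    ``transcriptome`` maps sequence ids (lncRNA genes plus protein-coding
    transcripts) to spliced sequences; both strands are indexed. A spacer
    survives only when every occurrence of its 23-mer lies in its own gene.
    """
    index: dict[str, set[str]] = {}
    for name, seq in transcriptome.items():
        s = seq.upper()
        for strand_seq in (s, revcomp(s)):
            for i in range(len(strand_seq) - SPACER_LEN + 1):
                index.setdefault(strand_seq[i : i + SPACER_LEN], set()).add(name)
    kept = []
    for cand in candidates:
        owners = index.get(cand.seq23, set())
        if owners - {cand.gene_id}:
            continue
        kept.append(cand)
    return kept


def arrays_quota(complexity: float, complexity_distribution: Sequence[float]) -> int:
    """Array quota (2-7) from the gene's complexity sextile.

    The six bins are the equal-probability sextiles of the library-wide
    complexity distribution; a complexity equal to a bin boundary falls in
    the upper bin, so the distribution median maps to quota 5.
    """
    dist = np.asarray(complexity_distribution, dtype=float)
    if dist.size == 0:
        raise DesignError("empty complexity distribution")
    boundaries = np.quantile(dist, np.arange(1, 6) / 6.0)
    return 2 + int(np.searchsorted(boundaries, complexity, side="right"))


def _sgs_threshold(round_config: DesignRoundConfig, scores: np.ndarray) -> float:
    if round_config.sgs_rule == "min":
        return round_config.min_sgs
    if round_config.sgs_rule == "top_quartile":
        return float(np.quantile(scores, 0.75))
    return -np.inf


def _greedy_round(
    candidates: list[SpacerCandidate],
    quota: int,
    gene_length: int,
    cfg: DesignRoundConfig,
) -> list[tuple[SpacerCandidate, SpacerCandidate]] | None:
    scores = np.array([c.score for c in candidates])
    threshold = _sgs_threshold(cfg, scores)
    eligible = [c for c in candidates if c.score >= threshold]
    # deterministic greedy order: best score first, then leftmost position
    eligible.sort(key=lambda c: (-c.score, c.position))
    mld = cfg.mld_fraction * gene_length
    mgd = float(SPACER_LEN) if cfg.overlap_only else cfg.mgd_fraction * gene_length
    mgd = max(mgd, 1.0)  # never reuse a position

    chosen: list[SpacerCandidate] = []

    def pick(extra_constraint=None) -> SpacerCandidate | None:
        for c in eligible:
            if any(c is p for p in chosen):
                continue
            if any(abs(c.position - p.position) < mgd for p in chosen):
                continue
            if extra_constraint is not None and not extra_constraint(c):
                continue
            return c
        return None

    firsts: list[SpacerCandidate] = []
    for _ in range(quota):
        c = pick()
        if c is None:
            return None
        chosen.append(c)
        firsts.append(c)
    pairs: list[tuple[SpacerCandidate, SpacerCandidate]] = []
    for first in firsts:
        second = pick(lambda c: abs(c.position - first.position) >= mld)
        if second is None:
            return None
        chosen.append(second)
        pairs.append((first, second))
    return pairs


def design_gene_arrays(
    gene_id: str,
    gene_length: int,
    candidates: Sequence[SpacerCandidate],
    quota: int,
    round_configs: Sequence[DesignRoundConfig] = DEFAULT_ROUNDS,
    role: str = "lncRNA",
) -> list[GuideArray]:
    """Design ``quota`` arrays for one gene, trying rounds in order.

    Within a round, position-1 spacers of all arrays are picked first (best
    score subject to MGD against everything already chosen), then each
    array's position-2 spacer (additionally subject to MLD against its own
    position-1 spacer). Any impossible pick restarts the gene at the next,
    less stringent round; a gene failing round 4 is undesignable and an
    empty list is returned.
    """
    if not 2 <= quota <= 7:
        raise DesignError(f"{gene_id}: quota {quota} outside [2, 7]")
    cands = list(candidates)
    if not cands:
        return []
    for cfg in round_configs:
        pairs = _greedy_round(cands, quota, gene_length, cfg)
        if pairs is not None:
            return [
                GuideArray(
                    f"{gene_id}_a{i + 1}", gene_id, p1, p2, cfg.round_number, role
                )
                for i, (p1, p2) in enumerate(pairs)
            ]
    return []


def design_nt_arrays(
    n_arrays: int,
    genome_sequences: Mapping[str, str],
    pool_size: int = 10_000,
    rng_seed: int = 0,
    max_mismatches: int = 3,
) -> list[GuideArray]:
    """Non-targeting control arrays from genome-free random spacers.

    ``pool_size`` random 23-mers are drawn; any with a genomic match (either
    strand) within ``max_mismatches`` substitutions is discarded. The first
    ``2 * n_arrays`` survivors are extended to 30 nt with random 7-mers and
    paired consecutively. Fully reproducible per seed.
    """
    if n_arrays == 0:
        return []
    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    pool = ["".join(bases[rng.integers(0, 4, SPACER_LEN)]) for _ in range(pool_size)]
    index = GenomeMismatchIndex(dict(genome_sequences), k=SPACER_LEN, max_mismatches=max_mismatches)
    survivors = [kmer for kmer in pool if not index.has_match(kmer)]
    needed = 2 * n_arrays
    if len(survivors) < needed:
        raise DesignError(
            f"only {len(survivors)} of {pool_size} random spacers survive the genome "
            f"filter but {needed} are needed; increase pool_size"
        )
    selected = survivors[:needed]
    spacers = []
    for i, seq23 in enumerate(selected):
        tail = "".join(bases[rng.integers(0, 4, EXTENDED_LEN - SPACER_LEN)])
        spacers.append(
            SpacerCandidate("NT", i, seq23, seq23 + tail, 0.0)
        )
    return [
        GuideArray(f"NT_a{i + 1}", "NT", spacers[2 * i], spacers[2 * i + 1], 0, "NT")
        for i in range(n_arrays)
    ]


def match_blacklist(
    spacer_seq: str,
    essential_sequences: Mapping[str, str],
    k: int = SPACER_LEN,
    max_mismatches: int = 2,
) -> tuple[bool, list[tuple[str, str, int, int]]]:
    """Does a spacer resemble essential coding-gene sequence?

    Returns ``(matched, hits)`` with hits as ``(sequence id, strand,
    position, mismatches)``; a hit is any length-``k`` window of an
    essential sequence (exon or intron, either strand) matching the first
    ``k`` nt of the spacer with at most ``max_mismatches`` substitutions.
    """
    if len(spacer_seq) < k:
        raise DesignError(f"spacer shorter than {k} nt")
    query = spacer_seq[:k].upper()
    hits: list[tuple[str, str, int, int]] = []
    for name, seq in essential_sequences.items():
        for strand, strand_seq in (("+", seq), ("-", revcomp(seq))):
            for pos, mm in hamming_hits(query, strand_seq.upper(), max_mismatches):
                hits.append((name, strand, pos, mm))
    return bool(hits), hits


def cells_required(n_arrays: int, coverage: float, moi: float) -> float:
    """Cells to transduce for a pooled screen.

    At multiplicity of infection ``moi`` only that fraction of cells
    receives a construct, so maintaining ``coverage`` cells per array needs
    ``n_arrays * coverage / moi`` cells (78,125 arrays at 300x and MOI 0.25
    -> 93.75 million).
    """
    if moi <= 0 or coverage <= 0:
        raise ValueError("coverage and MOI must be positive")
    return n_arrays * coverage / moi


@dataclass
class LibraryDesignResult:
    arrays: list[GuideArray] = field(default_factory=list)
    undesignable: list[str] = field(default_factory=list)


def design_library(
    gene_sequences: Mapping[str, str],
    complexities: Mapping[str, float],
    transcriptome: Mapping[str, str] | None = None,
    scorer: Callable[[str], float] = surrogate_guide_score,
    excluded_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    round_configs: Sequence[DesignRoundConfig] = DEFAULT_ROUNDS,
    roles: Mapping[str, str] | None = None,
) -> LibraryDesignResult:
    """Design arrays for a whole target set.

    Quotas are sextiles of the complexity values supplied for all genes;
    per-gene candidate enumeration, off-target filtering and the four-round
    greedy selection are as in the single-gene functions.
    """
    dist = list(complexities.values())
    result = LibraryDesignResult()
    for gene_id, sequence in gene_sequences.items():
        cands = enumerate_spacer_candidates(
            gene_id,
            sequence,
            scorer,
            () if excluded_regions is None else excluded_regions.get(gene_id, ()),
        )
        if transcriptome is not None:
            cands = filter_offtarget_spacers(cands, transcriptome)
        quota = arrays_quota(complexities[gene_id], dist)
        arrays = design_gene_arrays(
            gene_id,
            len(sequence),
            cands,
            quota,
            round_configs,
            role=(roles or {}).get(gene_id, "lncRNA"),
        )
        if arrays:
            result.arrays.extend(arrays)
        else:
            result.undesignable.append(gene_id)
    return result
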