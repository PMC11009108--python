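"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure the pipeline consumes in
practice, at desk scale and fully seeded:

* isoform families on a toy genome with controlled body/exon overlap
  fractions placed on both sides of the clustering thresholds, plus
  coding-gene overlaps bracketing the 70% loss cutoff;
* tissue-structured lncRNA expression (log-normal baselines, designated
  tissue-specific genes, valid TPM columns);
* negative-binomial screen counts with a spiked set of depleted genes,
  null no-CasRx controls and a plasmid baseline;
* paired FASTQ encoding arrays in the screen's read architecture, with
  optional substitution errors.

Each generator returns the emitted files/objects together with the ground
truth needed to score the corresponding pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import CodingAnnotation, TranscriptRecord
from .design import EXTENDED_LEN
from .screen import KEY1_LEN, READ2_VECTOR_TRIM
from .seq import revcomp

_BASES = np.array(list("ACGT"))

#: Vector sequence crossed by read 2 before it reaches spacer 1.
VECTOR_PREFIX = "GTGGAAAGGACGAAACACCGACTGG"[:READ2_VECTOR_TRIM].ljust(
    READ2_VECTOR_TRIM, "A"
)


@dataclass
class SimulationConfig:
    """Knobs for all generators; seeds are mandatory, defaults are the
    study conditions the test-suite runs under."""

    seed: int = 0
    # locus structure
    n_loci: int = 20
    isoforms_per_locus: tuple[int, int] = (2, 5)
    exons_per_transcript: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 1500)
    locus_gap: int = 10_000
    split_locus_fraction: float = 0.2
    split_body_overlap: float = 0.55  # below the 0.60 grouping threshold
    coding_overlap_fraction: float = 0.2
    # expression
    n_tissues: int = 20
    n_samples_per_tissue: int = 5
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    tissue_effect_sd: float = 1.0
    tissue_specific_fraction: float = 0.2
    conserved_fraction: float = 0.2
    # screen counts
    mean_plasmid_count: float = 300.0
    nb_dispersion: float = 0.1
    library_skew_sd: float = 0.4
    depletion_fold: float = 4.0
    depleted_fraction: float = 0.05
    ae_fold: float = 6.0
    array_noise_sd: float = 0.1
    n_screen_replicates: int = 2
    n_control_replicates: int = 2
    # fastq
    read_error_rate: float = 0.0

    def __post_init__(self):
        for name in ("split_locus_fraction", "coding_overlap_fraction",
                     "tissue_specific_fraction", "conserved_fraction",
                     "depleted_fraction", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GroundTruth:
    """What the generators actually emitted, for scoring pipeline stages."""

    transcript_partition: dict[str, str] = field(default_factory=dict)
    depleted_genes: list[str] = field(default_factory=list)
    true_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


# ---------------------------------------------------------------------------
# locus / annotation simulation


def _base_exons(rng: np.random.Generator, cfg: SimulationConfig, start: int):
    n_exons = int(rng.integers(*cfg.exons_per_transcript, endpoint=True))
    exons = []
    pos = start
    for _ in range(n_exons):
        length = int(rng.integers(*cfg.exon_length, endpoint=True))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(*cfg.intron_length, endpoint=True))
    return exons


def simulate_locus_set(config: SimulationConfig):
    """Toy genome, lncRNA transcripts, coding annotation and true partition.

    Most loci are isoform families built to satisfy the pass-1 grouping
    rule against a shared base isoform (one true gene per locus); a
    configured fraction are "split" loci whose two transcripts overlap
    below the body threshold (two true genes); a further fraction carry a
    coding gene overlapping the locus with ~75% of its exonic bases (so
    the overlapping transcript is dropped by the 70% loss rule).

    Returns ``(genome, transcripts, coding, truth)`` where genome maps
    chromosome name to sequence and ``truth.transcript_partition`` maps
    every emitted transcript to its intended gene label.
    """
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptRecord] = []
    coding_transcripts: list[TranscriptRecord] = []
    truth = GroundTruth()
    cursor = 1000
    n_split = int(round(config.n_loci * config.split_locus_fraction))
    n_coding = int(round(config.n_loci * config.coding_overlap_fraction))
    for locus in range(config.n_loci):
        label = f"locus{locus:03d}"
        kind = "split" if locus < n_split else "family"
        base = _base_exons(rng, config, cursor)
        if kind == "split":
            # two monoexonic-free transcripts, body overlap below threshold
            length = base[-1][1] - base[0][0]
            shift = int(round(length * (1.0 - config.split_body_overlap)))
            t1 = TranscriptRecord(f"{label}_t0", "chrS", "+", tuple(base), "sim")
            moved = tuple((s + shift, e + shift) for s, e in base)
            t2 = TranscriptRecord(f"{label}_t1", "chrS", "+", moved, "sim")
            transcripts += [t1, t2]
            truth.transcript_partition[t1.transcript_id] = f"{label}_A"
            truth.transcript_partition[t2.transcript_id] = f"{label}_B"
            cursor = moved[-1][1] + config.locus_gap
            continue
        n_iso = int(rng.integers(*config.isoforms_per_locus, endpoint=True))
        anchor = base[len(base) // 2]  # exon shared exactly by every isoform
        members = []
        for i in range(n_iso):
            if i == 0:
                exons = list(base)
            else:
                # jitter non-anchor exon edges; keep the anchor identical so
                # the exon-sharing condition holds and the body overlap stays
                # far above threshold
                exons = []
                for exon in base:
                    if exon == anchor:
                        exons.append(exon)
                        continue
                    s, e = exon
                    js = int(rng.integers(-30, 31))
                    je = int(rng.integers(-30, 31))
                    s2, e2 = s + js, max(s + js + 40, e + je)
                    exons.append((s2, e2))
                exons = sorted(exons)
                exons = [
                    (s, e) for s, e in exons
                ]
                # drop overlaps introduced by jitter
                pruned = []
                for s, e in exons:
                    if pruned and s < pruned[-1][1]:
                        s = pruned[-1][1] + 1
                        if s >= e:
                            continue
                    pruned.append((s, e))
                exons = pruned
            t = TranscriptRecord(f"{label}_t{i}", "chrS", "+", tuple(exons), "sim")
            members.append(t)
            truth.transcript_partition[t.transcript_id] = label
        transcripts += members
        locus_end = max(t.end for t in members)
        if locus - n_split < n_coding:
            # coding gene overlapping ~75% of the first member's exonic bases
            t0 = members[0]
            need = int(0.75 * t0.exonic_bp)
            covered = 0
            cexons = []
            for s, e in t0.exons:
                take = min(e - s, need - covered)
                if take <= 0:
                    break
                cexons.append((s, s + take))
                covered += take
            coding_transcripts.append(
                TranscriptRecord(f"{label}_cod", "chrS", "+", tuple(cexons), "sim")
            )
        cursor = locus_end + config.locus_gap
    genome = {"chrS": _random_seq(rng, cursor + 1000)}
    coding = CodingAnnotation.from_transcripts(coding_transcripts)
    return genome, transcripts, coding, truth


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(config: SimulationConfig, gene_ids: Sequence[str]):
    """Tissue-structured TPM matrix plus sample sheet and conserved ids.

    Gene baselines are log-normal; a configured fraction of genes is
    tissue-specific, receiving a positive log-scale boost in one designated
    tissue. Columns are valid TPM (non-negative, sum 1e6).

    Returns ``(tpm, sample_sheet, conserved_ids, tissue_specific)`` where
    ``tissue_specific`` maps each designated gene to its boosted tissue.
    """
    if config.n_tissues < 2:
        raise ValueError("need at least two tissues")
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = list(gene_ids)
    n_genes = len(gene_ids)
    tissues = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    samples = [
        f"{t}_s{i}" for t in tissues for i in range(config.n_samples_per_tissue)
    ]
    sample_tissue = pd.Series(
        [s.rsplit("_s", 1)[0] for s in samples], index=samples, name="tissue"
    )

    log_base = rng.normal(config.baseline_log_mean, config.baseline_log_sd, n_genes)
    n_specific = int(round(n_genes * config.tissue_specific_fraction))
    specific_idx = rng.choice(n_genes, n_specific, replace=False)
    specific_tissue = rng.integers(0, config.n_tissues, n_specific)
    boost = np.zeros((n_genes, config.n_tissues))
    if n_specific:
        boost[specific_idx, specific_tissue] = np.abs(
            rng.normal(0.0, config.tissue_effect_sd, n_specific)
        ) + 2.0 * config.tissue_effect_sd

    tissue_of_sample = np.repeat(
        np.arange(config.n_tissues), config.n_samples_per_tissue
    )
    noise = rng.normal(0.0, 0.2, (n_genes, len(samples)))
    log_expr = log_base[:, None] + boost[:, tissue_of_sample] + noise
    values = np.exp(log_expr)
    tpm = pd.DataFrame(
        values / values.sum(axis=0) * 1e6, index=gene_ids, columns=samples
    )
    n_conserved = int(round(n_genes * config.conserved_fraction))
    conserved = sorted(
        np.asarray(gene_ids, dtype=object)[
            rng.choice(n_genes, n_conserved, replace=False)
        ]
    )
    tissue_specific = {
        gene_ids[g]: tissues[t] for g, t in zip(specific_idx, specific_tissue)
    }
    return tpm, sample_tissue, conserved, tissue_specific


# ---------------------------------------------------------------------------
# library and screen-count simulation


def simulate_library(
    config: SimulationConfig,
    n_lnc_genes: int = 500,
    arrays_per_gene: int | None = None,
    n_ae_genes: int = 30,
    n_ne_genes: int = 30,
    arrays_per_control_gene: int = 4,
    n_nt_arrays: int = 50,
) -> pd.DataFrame:
    """A synthetic array library table with lncRNA targets and controls.

    By default each lncRNA gene receives 2-7 arrays, cycling through the
    quota range so the library mirrors the complexity-sextile rule's
    output (one sixth of genes per quota); pass ``arrays_per_gene`` for a
    flat design. Spacer sequences are random but unique per array,
    adequate for the read-architecture round trip; sequence-level design
    is exercised by :mod:`lncscreen.design` on simulated loci instead.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []

    def add_gene(gene_id: str, role: str, n_arrays: int):
        for a in range(n_arrays):
            rows.append(
                {
                    "array_id": f"{gene_id}_a{a + 1}",
                    "gene_id": gene_id,
                    "role": role,
                    "seq30_1": _random_seq(rng, EXTENDED_LEN),
                    "seq30_2": _random_seq(rng, EXTENDED_LEN),
                }
            )

    for i in range(n_lnc_genes):
        quota = arrays_per_gene if arrays_per_gene is not None else 2 + i % 6
        add_gene(f"LNC{i:04d}", "lncRNA", quota)
    for i in range(n_ae_genes):
        add_gene(f"AE{i:03d}", "AE", arrays_per_control_gene)
    for i in range(n_ne_genes):
        add_gene(f"NE{i:03d}", "NE", arrays_per_control_gene)
    for i in range(n_nt_arrays):
        rows.append(
            {
                "array_id": f"NT_a{i + 1}",
                "gene_id": "NT",
                "role": "NT",
                "seq30_1": _random_seq(rng, EXTENDED_LEN),
                "seq30_2": _random_seq(rng, EXTENDED_LEN),
            }
        )
    return pd.DataFrame(rows).set_index("array_id")


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial by mean and dispersion (var = mu + disp * mu^2)."""
    mean = np.clip(mean, 1e-9, None)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_screen_counts(config: SimulationConfig, library: pd.DataFrame):
    """NB count matrix for plasmid, screen replicates and no-CasRx controls.

    A configured fraction of lncRNA genes is spiked as depleted: all their
    arrays share the gene's fold change (1 / depletion_fold) times
    per-array log-normal noise. AE genes deplete by 1 / ae_fold; NE, NT
    and the no-CasRx controls are null.

    Returns ``(counts, sample_roles, truth)``.
    """
    rng = np.random.default_rng(config.seed + 3)
    lnc_genes = sorted(set(library.loc[library["role"] == "lncRNA", "gene_id"]))
    n_dep = int(round(len(lnc_genes) * config.depleted_fraction))
    depleted = sorted(
        np.asarray(lnc_genes, dtype=object)[
            rng.choice(len(lnc_genes), n_dep, replace=False)
        ]
    )
    dep_set = set(depleted)

    abundance = config.mean_plasmid_count * np.exp(
        rng.normal(0.0, config.library_skew_sd, len(library))
    )
    gene_fold = np.ones(len(library))
    for i, (aid, row) in enumerate(library.iterrows()):
        if row["role"] == "AE":
            gene_fold[i] = 1.0 / config.ae_fold
        elif row["gene_id"] in dep_set:
            gene_fold[i] = 1.0 / config.depletion_fold
    array_fold = gene_fold * np.exp(
        rng.normal(0.0, config.array_noise_sd, len(library))
    )

    columns: dict[str, np.ndarray] = {
        "plasmid": _nb(rng, abundance, config.nb_dispersion)
    }
    roles = {"plasmid": "plasmid"}
    for r in range(config.n_screen_replicates):
        name = f"screen_rep{r + 1}"
        columns[name] = _nb(rng, abundance * array_fold, config.nb_dispersion)
        roles[name] = "screen"
    for r in range(config.n_control_replicates):
        name = f"nocasrx_rep{r + 1}"
        columns[name] = _nb(rng, abundance, config.nb_dispersion)
        roles[name] = "no_casrx_control"
    counts = pd.DataFrame(columns, index=library.index)
    truth = GroundTruth(depleted_genes=list(depleted))
    return counts, roles, truth


# ---------------------------------------------------------------------------
# FASTQ simulation


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


def simulate_screen_fastq(
    count_column: Mapping[str, int] | pd.Series,
    library: pd.DataFrame,
    path_r1,
    path_r2,
    config: SimulationConfig | None = None,
    rng_seed: int | None = None,
):
    """Write the paired FASTQ a sample with the given counts would yield.

    Read 1 is the reverse complement of spacer 2 (30 nt); read 2 is 29 nt
    of vector followed by the first 27 nt of spacer 1. Substitution errors
    are injected at ``config.read_error_rate``; at rate zero, re-counting
    the emitted files reproduces ``count_column`` exactly. Headers carry
    the array id for debugging only.

    Returns the ground-truth counts written.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed + 4 if rng_seed is None else rng_seed)
    counts = pd.Series(count_column).astype(int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    truth: dict[str, int] = {}
    qual30 = "I" * 30
    qual56 = "I" * (READ2_VECTOR_TRIM + KEY1_LEN)
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        serial = 0
        for aid, n in counts.items():
            if n == 0:
                continue
            row = library.loc[aid]
            r1_base = revcomp(row["seq30_2"])
            r2_base = VECTOR_PREFIX + row["seq30_1"][:KEY1_LEN]
            truth[aid] = int(n)
            for _ in range(int(n)):
                serial += 1
                r1 = _inject_errors(rng, r1_base, config.read_error_rate)
                r2 = _inject_errors(rng, r2_base, config.read_error_rate)
                header = f"pair{serial}:{aid}"
                f1.write(f"@{header}/1\n{r1}\n+\n{qual30}\n")
                f2.write(f"@{header}/2\n{r2}\n+\n{qual56}\n")
    return truth
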