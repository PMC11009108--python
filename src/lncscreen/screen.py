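"""Pooled CasRx screen analysis: from paired-end reads to gene-level hits.

The sequencing protocol reads each integrated array twice: read 1 starts
directly at spacer 2 and reports it reverse-complemented (30 cycles);
read 2 crosses 29 nt of vector before covering the first 27 nt of
spacer 1. A pair is counted for an array only when both mates resolve
uniquely (up to two mismatches) to the same array.

Downstream, per-array log2 fold changes against the plasmid baseline are
computed on CPM-normalized counts, noisy and under-represented arrays are
filtered, counts are re-normalized by the median-of-ratios method, and
gene significance is assessed with permutation alpha-RRA (see
:mod:`lncscreen.rra`) followed by Benjamini-Hochberg FDR. Arrays
resembling essential coding-gene sequence that also deplete reproducibly
are blacklisted before gene aggregation; a gene is a hit when its FDR
falls below 0.25.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from scipy import stats

from .rra import rra_gene_test
from .seq import encode, revcomp

READ2_VECTOR_TRIM = 29  # vector bases crossed by read 2 before spacer 1
KEY1_LEN = 27  # spacer-1 bases covered by the sequencing layout
KEY2_LEN = 30  # spacer 2 is read in full


class ScreenError(ValueError):
    pass


# ---------------------------------------------------------------------------
# read-pair counting


class ArrayIndex:
    """Lookup structure for the two spacer keys of every array.

    Position 1 is keyed by the first 27 nt of its 30-nt spacer (the part
    the layout covers); position 2 by the full 30 nt. Duplicate keys are
    tolerated but reported, and reads hitting them are ambiguous.
    """

    def __init__(self, library: Mapping[str, tuple[str, str]]):
        """``library`` maps array_id -> (seq30 position 1, seq30 position 2)."""
        self.array_ids = sorted(library)
        self.key1 = {}
        self.key2 = {}
        k1_rows, k2_rows = [], []
        for i, aid in enumerate(self.array_ids):
            s1, s2 = library[aid]
            if len(s1) < KEY1_LEN or len(s2) < KEY2_LEN:
                raise ScreenError(f"{aid}: spacers shorter than index keys")
            k1 = s1[:KEY1_LEN].upper()
            k2 = s2[:KEY2_LEN].upper()
            self.key1.setdefault(k1, []).append(i)
            self.key2.setdefault(k2, []).append(i)
            k1_rows.append(encode(k1))
            k2_rows.append(encode(k2))
        self._mat1 = np.vstack(k1_rows)
        self._mat2 = np.vstack(k2_rows)
        self.collisions = sorted(
            [k for k, v in self.key1.items() if len(v) > 1]
            + [k for k, v in self.key2.items() if len(v) > 1]
        )

    def __len__(self) -> int:
        return len(self.array_ids)

    def _resolve(self, query: str, exact: dict, matrix: np.ndarray, max_mm: int):
        hits = exact.get(query)
        if hits is not None:
            return hits[0] if len(hits) == 1 else None
        if max_mm == 0:
            return -1
        mism = (matrix != encode(query)).sum(axis=1)
        best = int(mism.min())
        if best > max_mm:
            return -1  # no match
        idx = np.flatnonzero(mism == best)
        return int(idx[0]) if idx.size == 1 else None  # None = ambiguous

    def resolve_pos1(self, query27: str, max_mm: int = 2):
        return self._resolve(query27.upper(), self.key1, self._mat1, max_mm)

    def resolve_pos2(self, query30: str, max_mm: int = 2):
        return self._resolve(query30.upper(), self.key2, self._mat2, max_mm)


def count_read_pairs(
    fastq_r1,
    fastq_r2,
    index: ArrayIndex,
    max_mismatches: int = 2,
) -> tuple[pd.Series, dict]:
    """Count array-assignable read pairs from one sample's FASTQ pair.

    Read 1 is reverse-complemented and matched against the position-2
    keys; read 2 is trimmed by 29 nt and its next 27 nt matched against
    the position-1 keys. A pair increments an array's count only when both
    mates resolve uniquely to that same array; ambiguous and discordant
    pairs are discarded and tallied in the report.
    """
    counts = np.zeros(len(index), dtype=np.int64)
    report = {"pairs": 0, "counted": 0, "unmatched": 0, "ambiguous": 0,
              "discordant": 0, "short": 0}
    with open(fastq_r1) as fh1, open(fastq_r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ScreenError("read 1 and read 2 files differ in read count") from None
            report["pairs"] += 1
            seq1, seq2 = rec1[1], rec2[1]
            if len(seq1) < KEY2_LEN or len(seq2) < READ2_VECTOR_TRIM + KEY1_LEN:
                report["short"] += 1
                continue
            query2 = revcomp(seq1[:KEY2_LEN])
            query1 = seq2[READ2_VECTOR_TRIM : READ2_VECTOR_TRIM + KEY1_LEN]
            a2 = index.resolve_pos2(query2, max_mismatches)
            a1 = index.resolve_pos1(query1, max_mismatches)
            if a1 is None or a2 is None:
                report["ambiguous"] += 1
            elif a1 == -1 or a2 == -1:
                report["unmatched"] += 1
            elif a1 != a2:
                report["discordant"] += 1
            else:
                counts[a1] += 1
                report["counted"] += 1
        if next(it2, None) is not None:
            raise ScreenError("read 1 and read 2 files differ in read count")
    return pd.Series(counts, index=index.array_ids), report


# ---------------------------------------------------------------------------
# normalization and fold changes


def normalize_counts(matrix: pd.DataFrame, method: str = "cpm"):
    """Normalize an arrays x samples count matrix.

    ``cpm`` scales every column to one million; ``median_of_ratios``
    returns counts divided by per-sample size factors (the median across
    arrays of the ratio to the row geometric mean, rows containing any
    zero excluded). Returns ``(normalized, size_factors)``; size factors
    are None for CPM.
    """
    if (matrix < 0).to_numpy().any():
        raise ScreenError("negative counts")
    if method == "cpm":
        totals = matrix.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ScreenError(f"all-zero sample column(s): {bad}")
        return matrix / totals * 1e6, None
    if method == "median_of_ratios":
        values = matrix.to_numpy(dtype=float)
        nonzero = (values > 0).all(axis=1)
        if not nonzero.any():
            raise ScreenError("no array has nonzero counts in every sample")
        ref = np.exp(np.log(values[nonzero]).mean(axis=1))
        factors = np.median(values[nonzero] / ref[:, None], axis=0)
        size_factors = pd.Series(factors, index=matrix.columns)
        return matrix / size_factors, size_factors
    raise ValueError(f"unknown normalization method {method!r}")


def compute_array_lfc(
    matrix_norm: pd.DataFrame, baseline_sample: str, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-array log2 fold change of every sample against the baseline."""
    if baseline_sample not in matrix_norm.columns:
        raise ScreenError(f"baseline sample {baseline_sample!r} not in matrix")
    base = matrix_norm[baseline_sample] + pseudocount
    others = [c for c in matrix_norm.columns if c != baseline_sample]
    return np.log2(matrix_norm[others].add(pseudocount, axis=0).div(base, axis=0))


def filter_arrays(
    lfc_table: pd.DataFrame,
    counts: pd.DataFrame,
    plasmid_sample: str,
    screen_samples: Sequence[str],
    control_samples: Sequence[str],
    min_plasmid_count: int = 30,
    noise_quantile: float = 0.99,
) -> tuple[pd.Index, dict]:
    """Remove under-represented and noisy arrays.

    An array is removed when its plasmid count is below
    ``min_plasmid_count``, or when its absolute LFC lies in the top
    ``1 - noise_quantile`` tail in at least two no-CasRx control screens
    and at least one sample screen (the noise rule is skipped when fewer
    than two control screens exist).
    """
    low = counts[plasmid_sample] < min_plasmid_count
    noisy = pd.Series(False, index=lfc_table.index)
    if len(control_samples) >= 2:
        abs_lfc = lfc_table.abs()
        extreme = abs_lfc >= abs_lfc.quantile(noise_quantile, axis=0)
        noisy = (extreme[list(control_samples)].sum(axis=1) >= 2) & (
            extreme[list(screen_samples)].sum(axis=1) >= 1
        )
    keep = lfc_table.index[~(low | noisy)]
    report = {
        "low_plasmid": list(lfc_table.index[low]),
        "noisy": list(lfc_table.index[noisy]),
    }
    return keep, report


# ---------------------------------------------------------------------------
# blacklisting and hit calling


def array_depletion_pvalues(lfc_table: pd.DataFrame) -> pd.DataFrame:
    """One-sided per-array depletion p-values per screen.

    The normalized ascending rank of an array's LFC (most depleted rank 1)
    is uniform on (0, 1] under the null and serves as the array's p-value.
    """
    n = len(lfc_table)
    return lfc_table.rank(axis=0, method="average") / n


def blacklist_arrays(
    array_pvalues: pd.DataFrame,
    essential_match: Mapping[str, bool],
    p_threshold: float = 0.05,
    min_screens: int = 2,
) -> list[str]:
    """Arrays significant in >= ``min_screens`` screens that also match
    essential coding-gene sequence (see :func:`lncscreen.design.match_blacklist`)."""
    significant = (array_pvalues < p_threshold).sum(axis=1) >= min_screens
    return [
        aid
        for aid in array_pvalues.index[significant]
        if essential_match.get(aid, False)
    ]


def call_hits(gene_results: pd.DataFrame, fdr_threshold: float = 0.25) -> list[str]:
    """Gene ids with FDR strictly below the threshold, blacklisted genes excluded."""
    mask = gene_results["fdr"] < fdr_threshold
    if "blacklisted" in gene_results:
        mask &= ~gene_results["blacklisted"]
    return sorted(gene_results.index[mask])


def empirical_fdr(n_false_positive_hits: int, n_total_hits: int) -> float:
    """FP / (TP + FP), with FP estimated from nuclease-free control screens."""
    if n_false_positive_hits < 0 or n_total_hits < 0:
        raise ValueError("hit counts must be non-negative")
    if n_false_positive_hits > n_total_hits:
        raise ValueError("FP hits cannot exceed total hits")
    return 0.0 if n_total_hits == 0 else n_false_positive_hits / n_total_hits


def gene_unified_lfc(pvalues: Sequence[float], lfcs: Sequence[float]) -> float:
    """Mean LFC of a gene's two most significant arrays.

    Ties in p are broken toward the more negative LFC, so the unified
    value reflects the strongest consistent depletion.
    """
    if len(pvalues) != len(lfcs) or len(pvalues) < 2:
        raise ValueError("need matched p-values and LFCs for at least two arrays")
    order = sorted(range(len(pvalues)), key=lambda i: (pvalues[i], lfcs[i]))
    top = order[:2]
    return float(np.mean([lfcs[i] for i in top]))


# ---------------------------------------------------------------------------
# QC metrics


def control_auc(
    lfc_positive_controls: Sequence[float], lfc_negative_controls: Sequence[float]
) -> float:
    """ROC AUC separating depleted positive controls from negatives.

    Positives are arrays targeting always-essential genes, expected to
    deplete; the score is the probability that a random positive shows a
    lower LFC than a random negative (ties count one half).
    """
    pos = np.asarray(lfc_positive_controls, dtype=float)
    neg = np.asarray(lfc_negative_controls, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both control groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([-pos, -neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def lorenz_representation(array_counts: Sequence[float], read_fraction: float = 0.90) -> float:
    """Library evenness: percent of arrays holding ``read_fraction`` of reads.

    Arrays are sorted by descending abundance; the result is 100 times the
    minimal number of arrays whose cumulative reads reach
    ``read_fraction`` of the total, over the number of arrays. A perfectly
    even library returns ``100 * read_fraction``; skewed libraries return
    less.
    """
    counts = np.sort(np.asarray(array_counts, dtype=float))[::-1]
    if counts.size == 0:
        raise ValueError("empty count vector")
    total = counts.sum()
    if total == 0:
        return 100.0
    cum = np.cumsum(counts)
    n_needed = int(np.searchsorted(cum, read_fraction * total - 1e-9) + 1)
    return 100.0 * n_needed / counts.size


def classify_localization(
    cyt_cpm: float,
    nuc_cpm: float,
    pseudocount: float = 0.5,
    threshold: float = 0.75,
    log2_ratio: bool = True,
) -> tuple[str, float]:
    """Nuclear versus cytoplasmic enrichment from fractionation CPMs.

    The LFC is ``log2((cyt + pc) / (nuc + pc))``; genes at or below the
    threshold are nuclear-enriched, above it cytoplasm-enriched. Set
    ``log2_ratio=False`` to classify on the raw pseudocounted ratio.
    """
    ratio = (cyt_cpm + pseudocount) / (nuc_cpm + pseudocount)
    lfc = float(np.log2(ratio)) if log2_ratio else float(ratio)
    label = "nuclear-enriched" if lfc <= threshold else "cytoplasm-enriched"
    return label, lfc


def casrx_activity(gfp_target_mean: float, gfp_nt_mean: float) -> float:
    """CasRx knockdown activity: 1 - GFP(gGFP) / GFP(gNT), clipped to [0, 1]."""
    if gfp_nt_mean <= 0:
        raise ValueError("non-targeting GFP mean must be positive")
    activity = 1.0 - gfp_target_mean / gfp_nt_mean
    if not 0.0 <= activity <= 1.0:
        warnings.warn(f"activity {activity:.3f} outside [0, 1]; clipping", stacklevel=2)
    return float(np.clip(activity, 0.0, 1.0))


def insertion_normalized_coverage(
    insertion_counts: Sequence[float],
    total_sample_count: float,
    min_norm_cov: float = 2.0,
    artifact_flags: Sequence[bool] | None = None,
) -> pd.DataFrame:
    """Transposon-insertion reliability from normalized coverage.

    Normalized coverage is ``100 * count / total``; an insertion is
    reliable when it exceeds ``min_norm_cov`` strictly and is not flagged
    as an artifact.
    """
    counts = np.asarray(insertion_counts, dtype=float)
    if total_sample_count <= 0:
        raise ValueError("total sample count must be positive")
    norm = 100.0 * counts / total_sample_count
    artifacts = (
        np.zeros(counts.size, dtype=bool)
        if artifact_flags is None
        else np.asarray(artifact_flags, dtype=bool)
    )
    return pd.DataFrame(
        {"normalized_coverage": norm, "reliable": (norm > min_norm_cov) & ~artifacts}
    )


# ---------------------------------------------------------------------------
# end-to-end analysis


@dataclass
class ScreenAnalysis:
    gene_table: pd.DataFrame
    array_table: pd.DataFrame
    filter_report: dict = field(default_factory=dict)
    blacklisted_arrays: list[str] = field(default_factory=list)
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def hits(self) -> list[str]:
        return call_hits(self.gene_table)


def analyze_screen(
    counts: pd.DataFrame,
    sample_roles: Mapping[str, str],
    array_genes: Mapping[str, str],
    array_roles: Mapping[str, str] | None = None,
    essential_match: Mapping[str, bool] | None = None,
    fdr_threshold: float = 0.25,
    alpha: float = 0.25,
    n_permutations: int = 100_000,
    rng_seed: int = 0,
    pseudocount: float = 0.5,
    min_plasmid_count: int = 30,
) -> ScreenAnalysis:
    """Full per-cell-line analysis from a count matrix to gene hit calls.

    ``sample_roles`` maps each sample column to ``plasmid`` (exactly one),
    ``screen`` or ``no_casrx_control``. ``array_genes`` maps array ids to
    gene ids; NT arrays map to ``"NT"`` and are excluded from gene
    aggregation while still contributing to the rank pool. Screen
    replicates are averaged on the LFC scale before ranking.
    """
    roles = dict(sample_roles)
    plasmid = [s for s, r in roles.items() if r == "plasmid"]
    screens = [s for s, r in roles.items() if r == "screen"]
    controls = [s for s, r in roles.items() if r == "no_casrx_control"]
    if len(plasmid) != 1:
        raise ScreenError(f"need exactly one plasmid baseline, got {len(plasmid)}")
    if not screens:
        raise ScreenError("no screen samples")
    plasmid = plasmid[0]

    cpm, _ = normalize_counts(counts, "cpm")
    lfc_cpm = compute_array_lfc(cpm, plasmid, pseudocount)
    keep, filter_report = filter_arrays(
        lfc_cpm, counts, plasmid, screens, controls, min_plasmid_count
    )

    blacklisted: list[str] = []
    if essential_match is not None:
        pvals = array_depletion_pvalues(lfc_cpm.loc[keep, screens])
        blacklisted = blacklist_arrays(pvals, essential_match)
        keep = keep.difference(blacklisted)

    mor, size_factors = normalize_counts(counts.loc[keep], "median_of_ratios")
    lfc = compute_array_lfc(mor, plasmid, pseudocount)
    score = lfc[screens].mean(axis=1)

    # deterministic depletion ranks: most negative mean LFC gets rank 1
    aids = score.index.to_numpy(dtype=object)
    order = np.lexsort((aids, score.to_numpy()))
    ranks = np.empty(len(aids), dtype=int)
    ranks[order] = np.arange(1, len(aids) + 1)
    rank_series = pd.Series(ranks, index=score.index)
    array_p = pd.Series(ranks / len(aids), index=score.index)

    ranks_by_gene: dict[str, list[int]] = {}
    for aid in score.index:
        gene = array_genes.get(aid)
        if gene is None or gene == "NT":
            continue
        ranks_by_gene.setdefault(gene, []).append(int(rank_series[aid]))

    excluded = sorted(
        set(array_genes.values())
        - set(ranks_by_gene)
        - {"NT"}
    )
    if excluded:
        warnings.warn(
            f"{len(excluded)} gene(s) excluded: no arrays survived filtering",
            stacklevel=2,
        )

    rra = rra_gene_test(ranks_by_gene, len(aids), alpha, n_permutations, rng_seed)
    rows = []
    for gene, res in rra.items():
        gene_arrays = [a for a in score.index if array_genes.get(a) == gene]
        if len(gene_arrays) >= 2:
            unified = gene_unified_lfc(
                [array_p[a] for a in gene_arrays], [score[a] for a in gene_arrays]
            )
        else:
            unified = float(score[gene_arrays[0]])
        rows.append(
            {
                "gene_id": gene,
                "rho": res["rho"],
                "p": res["p"],
                "fdr": res["fdr"],
                "unified_lfc": unified,
                "n_arrays": len(gene_arrays),
                "blacklisted": False,
            }
        )
    gene_table = pd.DataFrame(rows).set_index("gene_id").sort_index()
    gene_table["hit"] = gene_table["fdr"] < fdr_threshold

    array_table = pd.DataFrame(
        {
            "gene_id": [array_genes.get(a) for a in score.index],
            "role": [
                (array_roles or {}).get(a, "lncRNA") for a in score.index
            ],
            "mean_lfc": score,
            "rank": rank_series,
            "p": array_p,
        }
    )
    return ScreenAnalysis(gene_table, array_table, filter_report, blacklisted, excluded)
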