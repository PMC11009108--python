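"""Quantitative target prioritization for a pan-cancer lncRNA library.

A screening library cannot target every annotated lncRNA gene, so targets
are prioritized from a gene x sample TPM matrix with tissue labels using a
four-step quota scheme:

1. top genes by mean TPM across all samples;
2. round-robin over tissues, each tissue contributing its next-best gene
   by tissue-mean TPM, until the step quota is filled;
3. round-robin over individual samples by per-sample TPM;
4. evolutionarily conserved genes only: top by global mean, then top by
   maximal tissue-mean TPM, with separate sub-quotas.

Steps are sequential and disjoint: a gene already selected never counts
against a later quota, so the final target set size equals the quota sum
whenever the candidate pool suffices. With the quotas used for the
published library (9,300 / 9,306 / 8,892 / 2,000 + 1,012) this yields
30,510 targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SelectionQuotas:
    """Per-step gene quotas. Defaults are the published library's."""

    n_global_avg: int = 9300
    n_per_tissue_total: int = 9306
    n_per_cell_line_total: int = 8892
    n_conserved_avg: int = 2000
    n_conserved_tissue: int = 1012

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"quota {name} must be a non-negative integer, got {value!r}")

    @property
    def total(self) -> int:
        return (
            self.n_global_avg
            + self.n_per_tissue_total
            + self.n_per_cell_line_total
            + self.n_conserved_avg
            + self.n_conserved_tissue
        )


def tpm_normalize(raw_counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from raw counts and effective gene lengths.

    Per sample: ``rate_g = count_g / length_g``; ``TPM_g = 1e6 * rate_g /
    sum(rate)``. Columns with at least one nonzero count sum to 1e6;
    all-zero columns stay zero.
    """
    lengths = effective_lengths.reindex(raw_counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing effective lengths for genes: {missing[:5]}")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive effective length for genes: {bad[:5]}")
    rates = raw_counts.div(lengths, axis=0)
    totals = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rates.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def flag_low_expressed_exons(
    exon_expression_by_gene: Mapping[str, Sequence[float]],
) -> dict[str, np.ndarray]:
    """Flag exons expressed anomalously low within their gene.

    An exon is flagged when its length-normalized expression is strictly
    below ``mean - 2 * sd`` of all exons of the same gene (population sd;
    values at the threshold are not flagged). Flagged exons are avoided
    during guide design so guides concentrate on well-expressed isoforms.
    """
    flags: dict[str, np.ndarray] = {}
    for gene, values in exon_expression_by_gene.items():
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            raise ValueError(f"gene {gene} has no exons")
        threshold = arr.mean() - 2.0 * arr.std()
        flags[gene] = arr < threshold
    return flags


def _ranked_order(values: np.ndarray, gene_ids: np.ndarray) -> np.ndarray:
    """Indices sorted by descending value, ties broken by gene id."""
    return np.lexsort((gene_ids, -values))


def _round_robin(
    orders: list[np.ndarray],
    unit_names: Sequence[str],
    selected: np.ndarray,
    quota: int,
) -> list[int]:
    """Cycle units in sorted-name order, taking each unit's next-best
    unselected gene, until ``quota`` genes are gathered or the pool is dry."""
    unit_order = np.argsort(np.asarray(unit_names, dtype=object))
    pointers = [0] * len(orders)
    picked: list[int] = []
    active = list(unit_order)
    while len(picked) < quota and active:
        still_active = []
        for u in active:
            order = orders[u]
            p = pointers[u]
            while p < order.size and selected[order[p]]:
                p += 1
            if p < order.size:
                g = order[p]
                selected[g] = True
                picked.append(int(g))
                pointers[u] = p + 1
                still_active.append(u)
                if len(picked) == quota:
                    break
            else:
                pointers[u] = p
        active = still_active
    return picked


def select_targets(
    tpm: pd.DataFrame,
    sample_tissues: Mapping[str, str] | pd.Series,
    conserved_ids: Iterable[str],
    quotas: SelectionQuotas = SelectionQuotas(),
) -> pd.DataFrame:
    """Run the four-step selection; returns a gene_id/step table.

    ``tpm`` is genes x samples; ``sample_tissues`` maps each sample to its
    tissue label. Ties in TPM are broken by lexicographic gene id. If a
    step's pool is exhausted the selection is partial and a warning is
    emitted.
    """
    tissues = pd.Series(sample_tissues).reindex(tpm.columns)
    if tissues.isna().any():
        raise ValueError("every sample column needs a tissue label")
    gene_ids = tpm.index.to_numpy(dtype=object)
    values = tpm.to_numpy(dtype=float)
    n_genes = values.shape[0]
    if (values < 0).any():
        raise ValueError("TPM matrix contains negative values")

    conserved = pd.Index(dict.fromkeys(conserved_ids))
    unknown = conserved.difference(tpm.index)
    if len(unknown):
        warnings.warn(f"{len(unknown)} conserved ids absent from the matrix", stacklevel=2)
    conserved_mask = np.zeros(n_genes, dtype=bool)
    conserved_mask[tpm.index.get_indexer(conserved.intersection(tpm.index))] = True

    selected = np.zeros(n_genes, dtype=bool)
    steps = np.zeros(n_genes, dtype=int)

    # step 1: global average
    global_mean = values.mean(axis=1)
    order = _ranked_order(global_mean, gene_ids)
    step1 = order[: quotas.n_global_avg]
    selected[step1] = True
    steps[step1] = 1

    # step 2: round-robin over tissue means
    tissue_names = sorted(set(tissues))
    tissue_means = [
        values[:, (tissues == t).to_numpy()].mean(axis=1) for t in tissue_names
    ]
    orders = [_ranked_order(m, gene_ids) for m in tissue_means]
    step2 = _round_robin(orders, tissue_names, selected, quotas.n_per_tissue_total)
    steps[step2] = 2

    # step 3: round-robin over individual samples
    sample_names = list(tpm.columns)
    sample_orders = [
        _ranked_order(values[:, i], gene_ids) for i in range(len(sample_names))
    ]
    step3 = _round_robin(sample_orders, sample_names, selected, quotas.n_per_cell_line_total)
    steps[step3] = 3

    # step 4: conserved genes only
    max_tissue_mean = np.max(np.column_stack(tissue_means), axis=1) if tissue_means else global_mean
    step4: list[int] = []
    for metric, quota in (
        (global_mean, quotas.n_conserved_avg),
        (max_tissue_mean, quotas.n_conserved_tissue),
    ):
        pool = np.flatnonzero(conserved_mask & ~selected)
        ranked = pool[_ranked_order(metric[pool], gene_ids[pool])]
        take = ranked[:quota]
        selected[take] = True
        step4.extend(int(i) for i in take)
    steps[step4] = 4

    total = int(selected.sum())
    if total < quotas.total:
        warnings.warn(
            f"candidate pool exhausted: selected {total} of {quotas.total} requested genes",
            stacklevel=2,
        )
    chosen = np.flatnonzero(selected)
    result = pd.DataFrame(
        {"gene_id": gene_ids[chosen], "step": steps[chosen]}
    ).sort_values(["step", "gene_id"], kind="stable", ignore_index=True)
    return result


def count_expressed_targets(
    tpm: pd.DataFrame,
    target_ids: Iterable[str],
    tpm_threshold: float = 0.01,
) -> pd.Series:
    """Per-sample count of target genes expressed strictly above threshold."""
    if tpm_threshold < 0:
        raise ValueError("threshold must be non-negative")
    ids = pd.Index(dict.fromkeys(target_ids)).intersection(tpm.index)
    return (tpm.loc[ids] > tpm_threshold).sum(axis=0)
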