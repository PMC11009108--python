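"""Modified robust rank aggregation (alpha-RRA) for pooled screens.

Arrays are ranked library-wide by log fold change, most depleted first.
For a gene with m arrays at normalized ranks r_(1) <= ... <= r_(m)
(rank / N), only ranks inside the top alpha fraction (r_(k) <= alpha) are
informative; the rho score is

    rho = min_{k : r_(k) <= alpha}  P(Beta(k, m - k + 1) <= r_(k)),

the probability that the k-th order statistic of m uniforms falls at or
below the observed k-th rank, minimized over the alpha-selected ranks.
This makes the score sensitive both to a few very strongly depleted
arrays and to many moderately depleted ones, while ignoring a gene's
weakest arrays. When no rank falls inside the alpha fraction, the score
falls back to k = 1 (the gene's best rank), which keeps the null
distribution of rho continuous and the permutation p-values uniform.

Significance is assessed against a permutation null in which m ranks are
re-drawn from the pooled rank list; an exact enumeration over all C(N, m)
assignments is available for small instances.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


def rho_score(normalized_ranks: Sequence[float], alpha: float = 0.25) -> float:
    """Alpha-restricted RRA rho for one gene's normalized ranks."""
    r = np.sort(np.asarray(normalized_ranks, dtype=float))
    m = r.size
    if m == 0:
        raise ValueError("gene without arrays")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    k_max = max(1, int(np.searchsorted(r, alpha, side="right")))
    ks = np.arange(1, k_max + 1)
    probs = stats.beta.cdf(r[:k_max], ks, m - ks + 1)
    return float(probs.min())


def _null_rhos(
    pool: np.ndarray, m: int, alpha: float, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Null rho distribution for genes of size m.

    Small pools are sampled without replacement (a true random assignment
    of m of the N ranks); for large pools the draws use replacement, which
    is indistinguishable from assignment permutation when m << N.
    """
    if pool.size <= 256:
        subset = rng.random((n_permutations, pool.size)).argsort(axis=1)[:, :m]
        draws = pool[subset]
    else:
        draws = rng.choice(pool, size=(n_permutations, m), replace=True)
    draws.sort(axis=1)
    ks = np.arange(1, m + 1)
    probs = stats.beta.cdf(draws, ks, m - ks + 1)
    # only alpha-selected ranks count; k = 1 as fallback when none qualify
    probs[:, 1:][draws[:, 1:] > alpha] = np.inf
    return probs.min(axis=1)


def exact_permutation_pvalue(
    gene_ranks: Sequence[float], all_ranks: Sequence[float], alpha: float = 0.25
) -> float:
    """Exact p-value by enumerating every size-m rank assignment.

    Feasible only for small C(N, m); used as the reference the sampled
    permutation test is checked against.
    """
    m = len(gene_ranks)
    obs = rho_score(gene_ranks, alpha)
    count = total = 0
    for combo in combinations(all_ranks, m):
        total += 1
        if rho_score(combo, alpha) <= obs + 1e-12:
            count += 1
    return count / total


def rra_gene_test(
    ranks_by_gene: Mapping[str, Sequence[int]],
    n_arrays_total: int,
    alpha: float = 0.25,
    n_permutations: int = 100_000,
    rng_seed: int = 0,
) -> dict[str, dict[str, float]]:
    """Permutation alpha-RRA over all genes.

    ``ranks_by_gene`` maps each gene to the 1-based depletion ranks of its
    surviving arrays among all ``n_arrays_total`` ranked arrays. Returns
    per-gene ``rho``, permutation ``p`` and Benjamini-Hochberg ``fdr``.
    """
    rng = np.random.default_rng(rng_seed)
    pool = np.arange(1, n_arrays_total + 1, dtype=float) / n_arrays_total
    genes = sorted(ranks_by_gene)
    sizes = sorted({len(ranks_by_gene[g]) for g in genes})
    nulls = {m: np.sort(_null_rhos(pool, m, alpha, n_permutations, rng)) for m in sizes}
    out: dict[str, dict[str, float]] = {}
    pvals = []
    for g in genes:
        ranks = np.asarray(ranks_by_gene[g], dtype=float)
        if ranks.size == 0 or (ranks < 1).any() or (ranks > n_arrays_total).any():
            raise ValueError(f"gene {g}: invalid ranks")
        rho = rho_score(ranks / n_arrays_total, alpha)
        null = nulls[ranks.size]
        p = (1 + np.searchsorted(null, rho, side="right")) / (n_permutations + 1)
        out[g] = {"rho": rho, "p": float(p)}
        pvals.append(p)
    fdr = stats.false_discovery_control(np.asarray(pvals), method="bh")
    for g, q in zip(genes, fdr):
        out[g]["fdr"] = float(min(1.0, q))
    return out
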