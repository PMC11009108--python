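"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by naive enumeration
(pairwise loops, quadratic scans, exhaustive rank assignment) so the
package's accelerated implementations are checked against a second,
independent route.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from lncscreen.annotation import TranscriptRecord


def make_transcript(tid, exons, chrom="chr1", strand="+", source="test"):
    return TranscriptRecord(tid, chrom, strand, tuple(sorted(exons)), source)


# ---------------------------------------------------------------------------
# brute-force clustering oracle


def _naive_overlap(a, b):
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _naive_merge(ivals):
    out = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _naive_pair_rule(a: TranscriptRecord, b: TranscriptRecord) -> bool:
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    body = _naive_overlap((a.start, a.end), (b.start, b.end))
    shorter = min(a.end - a.start, b.end - b.start)
    if body < 0.60 * shorter:
        return False
    for ea in a.exons:
        for eb in b.exons:
            longest = max(ea[1] - ea[0], eb[1] - eb[0])
            if _naive_overlap(ea, eb) >= 0.60 * longest:
                return True
    return False


def brute_force_cluster(transcripts):
    """Reference partition: enumerate all pairs, close transitively, then
    attach leftover monoexonic (>=30% span) and multiexonic (>=90% exonic
    bases) transcripts to multi-member groups, largest overlap first."""
    n = len(transcripts)
    groups = [{i} for i in range(n)]
    changed = True
    while changed:  # transitive closure by repeated merging
        changed = False
        for gi, gj in itertools.combinations(range(len(groups)), 2):
            if any(
                _naive_pair_rule(transcripts[i], transcripts[j])
                for i in groups[gi]
                for j in groups[gj]
            ):
                groups[gi] |= groups[gj]
                del groups[gj]
                changed = True
                break
    multi = [g for g in groups if len(g) > 1]
    single = sorted(i for g in groups if len(g) == 1 for i in g)

    def geometry(group):
        exons = _naive_merge([e for i in group for e in transcripts[i].exons])
        return (exons[0][0], exons[-1][1]), exons

    def attach(cands, mono):
        snapshot = [geometry(g) for g in multi]
        leftover = []
        pending = []
        for i in cands:
            t = transcripts[i]
            best = None
            for gi, (gspan, gexons) in enumerate(snapshot):
                member = next(iter(multi[gi]))
                ref = transcripts[member]
                if ref.chrom != t.chrom or ref.strand != t.strand:
                    continue
                if mono:
                    ov = _naive_overlap((t.start, t.end), gspan)
                    ok = ov >= 0.30 * (t.end - t.start)
                else:
                    ov = sum(
                        _naive_overlap(e, ge) for e in t.exons for ge in gexons
                    )
                    exonic = sum(e - s for s, e in t.exons)
                    ok = ov >= 0.90 * exonic
                if ok and (best is None or (-ov, gspan[0]) < best[:2]):
                    best = (-ov, gspan[0], gi)
            if best is None:
                leftover.append(i)
            else:
                pending.append((i, best[2]))
        for i, gi in pending:
            multi[gi].add(i)
        return leftover

    mono = [i for i in single if len(transcripts[i].exons) == 1]
    multiex = [i for i in single if len(transcripts[i].exons) > 1]
    left = attach(mono, True) + attach(multiex, False)
    final = multi + [{i} for i in left]
    return {
        frozenset(transcripts[i].transcript_id for i in g) for g in final
    }


@pytest.fixture
def cluster_oracle():
    return brute_force_cluster


def random_transcript_instance(rng: np.random.Generator, n: int):
    """A dense random instance: n transcripts crowded into a small window
    so every clustering pass is exercised."""
    transcripts = []
    for i in range(n):
        strand = "+" if rng.random() < 0.7 else "-"
        start = int(rng.integers(0, 2500))
        n_exons = int(rng.integers(1, 5))
        exons = []
        pos = start
        for _ in range(n_exons):
            length = int(rng.integers(50, 220))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(40, 320))
        transcripts.append(make_transcript(f"t{i}", exons, strand=strand))
    return transcripts


@pytest.fixture
def make_random_instance():
    return random_transcript_instance


# ---------------------------------------------------------------------------
# quadratic sequence-matching oracle


def naive_min_hamming_anywhere(kmer: str, sequences: dict[str, str]) -> int:
    """Minimal Hamming distance of kmer to any window on either strand."""
    comp = str.maketrans("ACGT", "TGCA")
    best = len(kmer)
    for seq in sequences.values():
        for s in (seq, seq.translate(comp)[::-1]):
            for i in range(len(s) - len(kmer) + 1):
                d = sum(a != b for a, b in zip(kmer, s[i : i + len(kmer)]))
                best = min(best, d)
    return best


@pytest.fixture
def hamming_oracle():
    return naive_min_hamming_anywhere


# ---------------------------------------------------------------------------
# order-statistic / RRA oracles


def binomial_tail_order_stat(r: float, k: int, m: int) -> float:
    """P(k-th smallest of m uniforms <= r) by the binomial-sum identity,
    independent of scipy's beta distribution."""
    from math import comb

    return sum(comb(m, j) * r**j * (1 - r) ** (m - j) for j in range(k, m + 1))


def naive_rho(normalized_ranks, alpha=0.25):
    r = sorted(normalized_ranks)
    m = len(r)
    ks = [k for k in range(1, m + 1) if r[k - 1] <= alpha] or [1]
    return min(binomial_tail_order_stat(r[k - 1], k, m) for k in ks)


def exhaustive_rra_pvalue(gene_ranks, n_total, alpha=0.25):
    """Exact permutation p by enumerating every assignment of m ranks."""
    m = len(gene_ranks)
    obs = naive_rho([r / n_total for r in gene_ranks], alpha)
    hits = total = 0
    for combo in itertools.combinations(range(1, n_total + 1), m):
        total += 1
        if naive_rho([r / n_total for r in combo], alpha) <= obs + 1e-12:
            hits += 1
    return hits / total


@pytest.fixture
def rra_oracles():
    return naive_rho, exhaustive_rra_pvalue
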