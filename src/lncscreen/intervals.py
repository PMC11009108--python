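"""Arithmetic on half-open, 0-based genomic intervals.

Intervals are plain ``(start, end)`` tuples with ``start < end``. Lists of
intervals handled here are assumed (and produced) sorted and pairwise
disjoint unless noted otherwise.
"""

from __future__ import annotations

from typing import Iterable, Sequence

Interval = tuple[int, int]


def validate(intervals: Sequence[Interval]) -> None:
    """Raise ``ValueError`` unless intervals are valid, sorted, disjoint."""
    prev_end = None
    for start, end in intervals:
        if end <= start:
            raise ValueError(f"invalid interval ({start}, {end}): end <= start")
        if prev_end is not None and start < prev_end:
            raise ValueError("intervals not sorted/disjoint")
        prev_end = end


def merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; overlapping or book-ended intervals are fused."""
    ivals = sorted(intervals)
    out: list[Interval] = []
    for start, end in ivals:
        if out and start <= out[-1][1]:
            if end > out[-1][1]:
                out[-1] = (out[-1][0], end)
        else:
            out.append((start, end))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(end - start for start, end in intervals)


def span(intervals: Sequence[Interval]) -> Interval:
    """Smallest single interval covering all intervals."""
    if not intervals:
        raise ValueError("span of empty interval list")
    return (min(s for s, _ in intervals), max(e for _, e in intervals))


def overlap_length(a: Interval, b: Interval) -> int:
    """Overlap in bp between two single intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total overlap in bp between two sorted disjoint interval lists."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        total += overlap_length(a[i], b[j])
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Bases of ``a`` not covered by ``b``; both sorted disjoint lists."""
    b = list(b)
    out: list[Interval] = []
    j = 0
    for start, end in a:
        cur = start
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < end:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= end:
                break
            k += 1
        if cur < end:
            out.append((cur, end))
    return out
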