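"""Nucleotide-sequence helpers: reverse complement, mismatch scans and a
pigeonhole index for approximate k-mer lookup against a genome.

Matching here is always plain Hamming matching (substitutions only); gapped
alignment is out of scope for spacer-length queries.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorized comparison."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def hamming_hits(query: str, target: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All ``(position, mismatches)`` where ``query`` matches a window of
    ``target`` with at most ``max_mismatches`` substitutions (one strand)."""
    q = encode(query)
    t = encode(target)
    k = len(q)
    if len(t) < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, k)
    mism = (windows != q).sum(axis=1)
    hits = np.flatnonzero(mism <= max_mismatches)
    return [(int(p), int(mism[p])) for p in hits]


def min_hamming(query: str, target: str) -> int:
    """Smallest window Hamming distance of ``query`` against ``target``."""
    q = encode(query)
    t = encode(target)
    k = len(q)
    if len(t) < k:
        return k
    windows = np.lib.stride_tricks.sliding_window_view(t, k)
    return int((windows != q).sum(axis=1).min())


def _chunk_bounds(k: int, n_chunks: int) -> list[tuple[int, int]]:
    base, extra = divmod(k, n_chunks)
    bounds = []
    pos = 0
    for i in range(n_chunks):
        size = base + (1 if i < extra else 0)
        bounds.append((pos, pos + size))
        pos += size
    return bounds


class GenomeMismatchIndex:
    """Approximate k-mer membership against a set of sequences.

    Answers "does this k-mer occur anywhere (either strand) with at most
    ``max_mismatches`` substitutions?" via seed-and-verify: the k-mer is
    split into ``max_mismatches + 1`` chunks, one of which must match
    exactly in any qualifying window (pigeonhole), so only exact chunk hits
    need Hamming verification.
    """

    def __init__(self, sequences: dict[str, str], k: int = 23, max_mismatches: int = 3):
        self.k = k
        self.max_mismatches = max_mismatches
        self._bounds = _chunk_bounds(k, max_mismatches + 1)
        self._arrays: list[np.ndarray] = []
        self._windows: list[np.ndarray] = []
        # chunk index -> {chunk bytes -> list of (seq idx, window start)}
        self._lookup: list[dict[bytes, list[tuple[int, int]]]] = [
            {} for _ in self._bounds
        ]
        for name, seq in sequences.items():
            for strand_seq in (seq, revcomp(seq)):
                arr = encode(strand_seq)
                if arr.size < k:
                    continue
                idx = len(self._arrays)
                self._arrays.append(arr)
                self._windows.append(np.lib.stride_tricks.sliding_window_view(arr, k))
                raw = arr.tobytes()
                n_windows = arr.size - k + 1
                for ci, (lo, hi) in enumerate(self._bounds):
                    table = self._lookup[ci]
                    for pos in range(n_windows):
                        key = raw[pos + lo : pos + hi]
                        table.setdefault(key, []).append((idx, pos))

    def has_match(self, kmer: str) -> bool:
        if len(kmer) != self.k:
            raise ValueError(f"expected {self.k}-mer, got length {len(kmer)}")
        q = encode(kmer)
        raw = q.tobytes()
        seen: set[tuple[int, int]] = set()
        for ci, (lo, hi) in enumerate(self._bounds):
            for hit in self._lookup[ci].get(raw[lo:hi], ()):
                seen.add(hit)
        if not seen:
            return False
        by_seq: dict[int, list[int]] = {}
        for idx, pos in seen:
            by_seq.setdefault(idx, []).append(pos)
        for idx, positions in by_seq.items():
            wins = self._windows[idx][np.asarray(positions)]
            if ((wins != q).sum(axis=1) <= self.max_mismatches).any():
                return True
        return False
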