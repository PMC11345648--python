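"""Half-open genomic interval arithmetic.

All coordinates in this package are 0-based half-open ``[start, end)``
(BED convention). Two intervals overlap iff their intersection length is
at least 1 bp, so ``[0, 10)`` and ``[10, 20)`` do *not* overlap.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "overlaps",
    "intersection_length",
    "merge_intervals",
    "IntervalIndex",
    "strand_window",
    "clamp",
]


def overlaps(a: Sequence[int], b: Sequence[int]) -> bool:
    """True iff half-open intervals ``a=(start, end)`` and ``b`` share >= 1 bp."""
    return a[0] < b[1] and b[0] < a[1]


def intersection_length(a: Sequence[int], b: Sequence[int]) -> int:
    """Length in bp of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def merge_intervals(intervals: Iterable[Sequence[int]]) -> list[tuple[int, int]]:
    """Merge overlapping or bookended half-open intervals into a sorted minimal set.

    Bookended intervals ([0,10) and [10,20)) are merged into one, matching
    ``bedtools merge`` default behaviour.
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def strand_window(anchor: int, strand: str, up: int, down: int) -> tuple[int, int]:
    """Strand-aware half-open window around a single-base anchor.

    Covers ``up`` bp upstream of the anchor and ``down`` bp downstream,
    *including* the anchor base in the downstream span when ``down >= 1``.
    For a plus-strand anchor ``t`` this is ``[t - up, t + down)``; on the
    minus strand upstream means larger coordinates: ``[t + 1 - down, t + 1 + up)``.
    """
    if strand == "+":
        return anchor - up, anchor + down
    return anchor + 1 - down, anchor + 1 + up


def clamp(start: int, end: int, size: int) -> tuple[int, int]:
    """Clamp a window to chromosome bounds ``[0, size)``."""
    return max(0, start), min(end, size)


class IntervalIndex:
    """Overlap queries against a static set of intervals on one chromosome.

    Uses start-sorted arrays with a running maximum of ends: an interval in
    the set overlaps query ``[qs, qe)`` iff some set interval has
    ``start < qe`` and ``end > qs``; the prefix-maximum of ends makes the
    any-overlap test O(log n).
    """

    def __init__(self, intervals: Iterable[Sequence[int]]):
        ivs = sorted((int(s), int(e)) for s, e in intervals)
        self.starts = np.array([s for s, _ in ivs], dtype=np.int64)
        self.ends = np.array([e for _, e in ivs], dtype=np.int64)
        self._ends_cummax = (
            np.maximum.accumulate(self.ends) if len(self.ends) else self.ends
        )

    def __len__(self) -> int:
        return len(self.starts)

    def any_overlap(self, qs: int, qe: int) -> bool:
        """True iff any indexed interval overlaps ``[qs, qe)``."""
        hi = int(np.searchsorted(self.starts, qe, side="left"))
        if hi == 0:
            return False
        return bool(self._ends_cummax[hi - 1] > qs)

    def any_overlap_many(self, qs: np.ndarray, qe: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`any_overlap` over parallel query arrays."""
        qs = np.asarray(qs, dtype=np.int64)
        qe = np.asarray(qe, dtype=np.int64)
        hi = np.searchsorted(self.starts, qe, side="left")
        out = np.zeros(len(qs), dtype=bool)
        nz = hi > 0
        if len(self._ends_cummax):
            out[nz] = self._ends_cummax[hi[nz] - 1] > qs[nz]
        return out

    def overlapping(self, qs: int, qe: int) -> np.ndarray:
        """Indices (in start-sorted order) of all intervals overlapping ``[qs, qe)``."""
        hi = int(np.searchsorted(self.starts, qe, side="left"))
        cand = np.arange(hi)
        return cand[self.ends[:hi] > qs]
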