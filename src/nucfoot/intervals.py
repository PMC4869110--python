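"""Genomic intervals and base-pair-exact interval arithmetic.

All coordinates are 0-based half-open throughout the package; 1-based
formats are converted at the I/O boundary.  Interval sets are held as
plain lists of :class:`GenomicInterval` at the API surface and converted
to per-chromosome sorted ``numpy`` start/end arrays internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

VALID_STRANDS = {"+", "-", "."}


@dataclass
class GenomicInterval:
    """One genomic interval, 0-based half-open.

    Strand is ``+``, ``-`` or ``.`` (unstranded).  ``name`` and ``score``
    are optional BED-style annotations.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


def by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, np.ndarray]:
    """Group intervals into per-chromosome sorted (n, 2) start/end arrays."""
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return {
        c: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        for c, pairs in out.items()
    }


def merge_arrays(arr: np.ndarray) -> np.ndarray:
    """Union overlapping/adjacent-sorted (n, 2) intervals into disjoint ones."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    merged = [list(arr[0])]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.array(merged, dtype=np.int64)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge an interval set into disjoint intervals (strand ignored)."""
    out: list[GenomicInterval] = []
    grouped = by_chrom(intervals)
    for chrom in sorted(grouped):
        for s, e in merge_arrays(grouped[chrom]):
            out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total bp covered by an interval set (after internal merging)."""
    grouped = by_chrom(intervals)
    return int(
        sum((m[:, 1] - m[:, 0]).sum() for m in map(merge_arrays, grouped.values()))
    )


def _intersect_merged(a: np.ndarray, b: np.ndarray) -> int:
    """Intersection length in bp of two disjoint sorted (n, 2) arrays."""
    i = j = 0
    inter = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if hi > lo:
            inter += hi - lo
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return int(inter)


def intersection_length(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Total bp in the intersection of two interval sets."""
    ga = {c: merge_arrays(v) for c, v in by_chrom(a).items()}
    gb = {c: merge_arrays(v) for c, v in by_chrom(b).items()}
    return sum(_intersect_merged(ga[c], gb[c]) for c in ga.keys() & gb.keys())


class IntervalIndex:
    """Overlap queries against a fixed interval set (>= 1 bp intersection)."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._merged = {c: merge_arrays(v) for c, v in by_chrom(intervals).items()}

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        arr = self._merged.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        # first merged interval whose end > start
        i = int(np.searchsorted(arr[:, 1], start, side="right"))
        return i < len(arr) and arr[i, 0] < end

    def overlaps_many(self, intervals: Iterable[GenomicInterval]) -> np.ndarray:
        return np.array(
            [self.overlaps(iv.chrom, iv.start, iv.end) for iv in intervals], dtype=bool
        )
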