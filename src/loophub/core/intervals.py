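"""Genomic intervals (0-based half-open) and interval algebra."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A located feature on a chromosome.

    ``start`` is 0-based inclusive, ``end`` exclusive.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Genome:
    """Ordered chromosome names with lengths in bp."""

    lengths: Dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has length {length}")

    @property
    def chroms(self) -> List[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def n_bins(self, chrom: str, bin_size: int) -> int:
        return -(-self.lengths[chrom] // bin_size)  # ceil division

    def contains_interval(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.lengths and iv.end <= self.lengths[iv.chrom]


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff same chromosome and >= 1 bp shared under half-open semantics."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class IntervalIndex:
    """Per-chromosome sorted index for overlap and proximity queries.

    Stores positions of the input sequence; ``query`` returns indices into
    the original list.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._by_chrom: Dict[str, tuple] = {}
        by_chrom: Dict[str, List[int]] = {}
        for i, iv in enumerate(self.intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            idx_arr = np.asarray(idx, dtype=np.intp)
            starts = np.asarray([self.intervals[i].start for i in idx])
            ends = np.asarray([self.intervals[i].end for i in idx])
            order = np.argsort(starts, kind="stable")
            self._by_chrom[chrom] = (starts[order], ends[order], idx_arr[order])

    def query(self, chrom: str, start: int, end: int) -> List[int]:
        """Indices of stored intervals overlapping [start, end) on chrom."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, idx = entry
        hi = np.searchsorted(starts, end, side="left")
        cand = ends[:hi] > start
        return list(idx[:hi][cand])

    def any_overlap(self, iv: GenomicInterval) -> bool:
        return bool(self.query(iv.chrom, iv.start, iv.end))


def closest_distance(
    queries: Sequence[GenomicInterval],
    targets: Sequence[GenomicInterval],
) -> np.ndarray:
    """Minimal gap in bp from each query to any same-chromosome target.

    Overlapping features have distance 0.  Queries with no target on their
    chromosome get NaN.
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    sorted_targets = {}
    for chrom, tl in by_chrom.items():
        starts = np.asarray(sorted(t.start for t in tl))
        ends = np.asarray(sorted(t.end for t in tl))
        sorted_targets[chrom] = (starts, ends)

    out = np.full(len(queries), np.nan)
    for qi, q in enumerate(queries):
        entry = sorted_targets.get(q.chrom)
        if entry is None:
            continue
        starts, ends = entry
        # gap to the left: query.start - target.end for nearest end <= start
        d = np.inf
        pos = np.searchsorted(ends, q.start, side="right")
        if pos > 0:
            d = min(d, q.start - ends[pos - 1])
        pos = np.searchsorted(starts, q.end, side="left")
        if pos < len(starts):
            d = min(d, starts[pos] - q.end)
        # any target overlapping -> 0
        hi = np.searchsorted(starts, q.end, side="left")
        lo = np.searchsorted(ends, q.start, side="right")
        if hi > lo:
            d = 0
        out[qi] = max(d, 0)
    return out
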