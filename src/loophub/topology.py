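"""Per-peak loop statistics and the highly-looping caller.

A peak's loop count is the number of distinct loop ids with at least 1 bp
of overlap between the peak and either anchor.  Highly-looping peaks are
called from the ascending rank curve of loop counts scaled to the unit
square: the cutoff sits at the point where the curve's slope reaches 1,
implemented as the argmin of (scaled count - scaled rank); everything
strictly above the cutoff count is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core.intervals import GenomicInterval, IntervalIndex, closest_distance
from .core.loops import Loop


def filter_loops(
    loops: Sequence[Loop],
    condition: Optional[str] = None,
    fdr_max: float = 0.01,
    min_pets: int = 5,
) -> List[Loop]:
    """Keep loops with FDR < fdr_max and summed PETs >= min_pets.

    PETs are summed over the given condition's samples (all samples if
    ``condition`` is None).  The defaults implement the "FDR below 1% and
    more than 4 PETs" rule.
    """
    out = []
    for lp in loops:
        samples = lp.condition_samples(condition) if condition else None
        if lp.fdr < fdr_max and lp.total_pets(samples) >= min_pets:
            out.append(lp)
    return out


def count_distinct_loops(
    peaks: Sequence[GenomicInterval],
    loops: Sequence[Loop],
    count_anchor_hits: bool = False,
) -> pd.DataFrame:
    """Distinct loops per peak and the looping flag.

    A loop overlapping both anchors of the same peak counts once unless
    ``count_anchor_hits`` is set (then each anchor hit counts).
    """
    index = IntervalIndex(peaks)
    counts = np.zeros(len(peaks), dtype=int)
    for lp in loops:
        hits1 = index.query(lp.anchor1.chrom, lp.anchor1.start, lp.anchor1.end)
        hits2 = index.query(lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.end)
        if count_anchor_hits:
            for i in hits1:
                counts[i] += 1
            for i in hits2:
                counts[i] += 1
        else:
            for i in set(hits1) | set(hits2):
                counts[i] += 1
    return pd.DataFrame(
        {
            "id": [iv.name or str(i) for i, iv in enumerate(peaks)],
            "n_distinct_loops": counts,
            "looping": counts >= 1,
        }
    )


def max_partner_loops(
    peaks: Sequence[GenomicInterval],
    loops: Sequence[Loop],
    stats: pd.DataFrame,
) -> pd.Series:
    """Largest loop count among partner-anchor peaks, per peak.

    For each loop touching a peak through one anchor, the peaks overlapping
    the *other* anchor contribute their distinct-loop counts; the maximum
    over all such partners is returned (NaN when no partner anchor contains
    a peak).
    """
    index = IntervalIndex(peaks)
    counts = stats["n_distinct_loops"].to_numpy()
    best = np.full(len(peaks), np.nan)
    for lp in loops:
        hits1 = index.query(lp.anchor1.chrom, lp.anchor1.start, lp.anchor1.end)
        hits2 = index.query(lp.anchor2.chrom, lp.anchor2.start, lp.anchor2.end)
        for here, there in ((hits1, hits2), (hits2, hits1)):
            if not there:
                continue
            partner_max = max(counts[j] for j in there)
            for i in here:
                if np.isnan(best[i]) or partner_max > best[i]:
                    best[i] = partner_max
    return pd.Series(best, name="max_partner_loops")


@dataclass
class ElbowResult:
    n: int
    x: np.ndarray  # scaled rank in [0, 1], ascending count order
    y: np.ndarray  # scaled count in [0, 1]
    cutoff_rank: int
    cutoff_count: float


def call_highly_looping(counts: pd.Series) -> tuple:
    """Rank-curve tangent cutoff; returns (ElbowResult | None, flags).

    Counts are sorted ascending (ties broken by index), rank and count are
    scaled to [0, 1], and the cutoff is the argmin of (scaled count -
    scaled rank), taking the last index on ties.  Peaks with count strictly
    greater than the cutoff count are highly looping.  Fewer than 3 peaks
    or constant counts yield an empty call with a warning.
    """
    values = counts.to_numpy(dtype=float)
    flags = pd.Series(False, index=counts.index, name="highly_looping")
    if len(values) < 3 or np.all(values == values[0]):
        warnings.warn("degenerate loop-count distribution; no highly-looping call")
        return None, flags
    order = np.lexsort((np.arange(len(values)), values))
    sorted_counts = values[order]
    n = len(values)
    x = np.arange(n) / (n - 1)
    y = sorted_counts / sorted_counts.max()
    diff = y - x
    # argmin with last-index tie-breaking
    cutoff_rank = int(n - 1 - np.argmin(diff[::-1]))
    cutoff_count = float(sorted_counts[cutoff_rank])
    flags[:] = values > cutoff_count
    return ElbowResult(n, x, y, cutoff_rank, cutoff_count), flags


def distance_to_anchors(
    peaks: Sequence[GenomicInterval],
    anchors: Sequence[GenomicInterval],
) -> np.ndarray:
    """Distance in bp from each peak to the nearest anchor (NaN if none)."""
    if not anchors:
        return np.full(len(peaks), np.nan)
    return closest_distance(peaks, anchors)


def peak_loop_stats(
    peaks: Sequence[GenomicInterval],
    loops: Sequence[Loop],
    condition: Optional[str] = None,
    fdr_max: float = 0.01,
    min_pets: int = 5,
) -> tuple:
    """Full per-peak topology table for one condition's filtered loop set."""
    kept = filter_loops(loops, condition, fdr_max, min_pets)
    stats = count_distinct_loops(peaks, kept)
    stats["max_partner_loops"] = max_partner_loops(peaks, kept, stats)
    elbow, flags = call_highly_looping(stats["n_distinct_loops"])
    stats["highly_looping"] = flags
    return stats, elbow
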