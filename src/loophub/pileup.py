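"""Observed/expected aggregate contact pileups centered on peak sets.

Expected values are per-chromosome means at each bin separation; windows of
the O/E matrix around each center bin are averaged cellwise (missing cells
excluded) and the mean is log2-transformed.  Minus-strand centers are
reflected across the diagonal.  Centers are filtered against a blacklist
and deduplicated per matrix bin keeping the strongest signal, in that
order, before edge filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core.intervals import GenomicInterval, closest_distance
from .core.matrix import ContactMatrix


def expected_by_distance(matrix: ContactMatrix) -> np.ndarray:
    """Mean of present entries at each separation s = |i - j|."""
    n = matrix.n_bins
    out = np.full(n, np.nan)
    for s in range(n):
        diag = np.diagonal(matrix.data, offset=s)
        finite = np.isfinite(diag)
        if finite.any():
            out[s] = diag[finite].mean()
    return out


def observed_over_expected(matrix: ContactMatrix) -> np.ndarray:
    from scipy.linalg import toeplitz

    expected = expected_by_distance(matrix)
    exp_mat = toeplitz(expected)
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = matrix.data / exp_mat
    oe[~np.isfinite(oe)] = np.nan
    return oe


@dataclass
class CenterSet:
    centers: List[GenomicInterval]  # carry strand; bin = center // bin_size
    n_input: int
    n_blacklisted: int
    n_deduplicated: int


def prepare_centers(
    peaks: pd.DataFrame,
    bin_size: int,
    blacklist: Sequence[GenomicInterval] = (),
    blacklist_distance: int = 1000,
) -> CenterSet:
    """Blacklist-filter then per-bin deduplicate peak centers.

    ``peaks`` needs columns chrom/start/end/strand/signal (id optional).
    Peaks within ``blacklist_distance`` bp of a blacklist interval are
    dropped; among peaks sharing a matrix bin the one with the strongest
    signal is kept.
    """
    ivs = [
        GenomicInterval(r.chrom, r.start, r.end, r.strand,
                        getattr(r, "id", ""), r.signal)
        for r in peaks.itertuples()
    ]
    n_input = len(ivs)
    if blacklist:
        dist = closest_distance(ivs, list(blacklist))
        keep = [iv for iv, d in zip(ivs, dist) if not (np.isfinite(d) and d <= blacklist_distance)]
    else:
        keep = ivs
    n_blacklisted = n_input - len(keep)

    best: Dict[Tuple[str, int], GenomicInterval] = {}
    for iv in keep:
        key = (iv.chrom, iv.center // bin_size)
        if key not in best or iv.score > best[key].score:
            best[key] = iv
    centers = sorted(best.values(), key=lambda iv: (iv.chrom, iv.start))
    n_dedup = len(keep) - len(centers)
    return CenterSet(centers, n_input, n_blacklisted, n_dedup)


@dataclass
class PileupResult:
    half_width: int
    mean_oe: np.ndarray  # (2W+1) x (2W+1) cellwise mean O/E
    log2_mean_oe: np.ndarray
    n_used: int
    n_dropped_edge: int
    n_blacklisted: int = 0
    n_deduplicated: int = 0


def pileup(
    matrices: Dict[str, ContactMatrix],
    centers: CenterSet,
    half_width: int = 10,
) -> PileupResult:
    """Cellwise mean O/E window around each center bin, log2-transformed.

    Minus-strand windows are transposed (reflection across the diagonal);
    centers within ``half_width`` bins of a chromosome edge are dropped and
    counted.
    """
    w = half_width
    size = 2 * w + 1
    total = np.zeros((size, size))
    count = np.zeros((size, size), dtype=int)
    oe_cache = {chrom: observed_over_expected(m) for chrom, m in matrices.items()}
    used = 0
    dropped = 0
    for iv in centers.centers:
        mat = matrices.get(iv.chrom)
        if mat is None:
            dropped += 1
            continue
        b = iv.center // mat.bin_size
        if b - w < 0 or b + w >= mat.n_bins:
            dropped += 1
            continue
        window = oe_cache[iv.chrom][b - w : b + w + 1, b - w : b + w + 1]
        if iv.strand == "-":
            window = window.T
        finite = np.isfinite(window)
        total[finite] += window[finite]
        count += finite
        used += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_oe = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        log2 = np.log2(mean_oe)
    return PileupResult(
        half_width=w,
        mean_oe=mean_oe,
        log2_mean_oe=log2,
        n_used=used,
        n_dropped_edge=dropped,
        n_blacklisted=centers.n_blacklisted,
        n_deduplicated=centers.n_deduplicated,
    )
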