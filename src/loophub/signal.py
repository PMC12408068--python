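"""Speckle-signal covariates: deciles, the 90th-percentile association rule,
correlations, and aggregate signal profiles."""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core.intervals import GenomicInterval
from .core.loops import Loop
from .core.tracks import SignalTrack, map_binned_signal


def loop_signal(loops: Sequence[Loop], track: SignalTrack) -> np.ndarray:
    """Per loop, unweighted mean over the distinct bins overlapping either
    anchor; NaN when no data bin is touched."""
    out = np.full(len(loops), np.nan)
    for i, lp in enumerate(loops):
        chrom = lp.chrom
        if chrom not in track.values:
            continue
        bins = set(track.bin_range(chrom, lp.anchor1.start, lp.anchor1.end))
        bins |= set(track.bin_range(chrom, lp.anchor2.start, lp.anchor2.end))
        idx = sorted(bins)
        vals = track.values[chrom][idx]
        mask = track.mask[chrom][idx]
        if mask.any():
            out[i] = float(vals[mask].mean())
    return out


def assign_deciles(values: Sequence[float], n_bins: int = 10) -> pd.Series:
    """Equal-count quantile binning; label ``n_bins`` is the highest signal.

    Duplicate quantile edges are collapsed and labels renumbered from 1.
    Missing values get label 0 (excluded).  All-identical values yield a
    single bin labelled 1 with a warning.
    """
    s = pd.Series(values, dtype=float)
    labels = pd.Series(0, index=s.index, dtype=int)
    present = s.dropna()
    if present.empty:
        return labels
    if present.nunique() == 1:
        warnings.warn("all covariate values identical; single decile")
        labels[present.index] = 1
        return labels
    binned = pd.qcut(present, q=n_bins, labels=False, duplicates="drop")
    labels[present.index] = binned.astype(int) + 1
    return labels


def speckle_associated_peaks(
    peaks: Sequence[GenomicInterval],
    track: SignalTrack,
    percentile: float = 90.0,
    interpolation: str = "linear",
) -> Tuple[np.ndarray, float]:
    """Flag peaks whose mapped signal is >= the genome-wide bin percentile.

    The threshold is the ``percentile`` of all data-carrying 20 kb bin
    values (linear interpolation between order statistics by default).
    """
    genome_vals = track.genome_values()
    threshold = float(np.percentile(genome_vals, percentile, method=interpolation))
    mapped = map_binned_signal(track, peaks)
    flags = np.zeros(len(peaks), dtype=bool)
    ok = np.isfinite(mapped)
    flags[ok] = mapped[ok] >= threshold
    return flags, threshold


def correlate_looping_with_signal(
    looping: Sequence[float],
    covariate: Sequence[float],
    n_deciles: int = 10,
) -> Tuple[float, pd.DataFrame]:
    """Pearson r between a per-item looping quantity and a covariate, plus
    per-decile medians of the looping quantity (NaN r when n < 3)."""
    x = np.asarray(looping, dtype=float)
    y = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return np.nan, pd.DataFrame(columns=["decile", "median", "n"])
    r = float(sps.pearsonr(x[ok], y[ok]).statistic)
    deciles = assign_deciles(np.where(ok, y, np.nan), n_deciles)
    rows = []
    for d in sorted(set(deciles) - {0}):
        sel = (deciles == d).to_numpy()
        rows.append(
            dict(decile=int(d), median=float(np.median(x[sel])), n=int(sel.sum()))
        )
    return r, pd.DataFrame.from_records(rows)


def aggregate_profile(
    track: SignalTrack,
    centers: Sequence[GenomicInterval],
    flank: int = 1000,
    bin: int = 50,
) -> Tuple[np.ndarray, np.ndarray, int, int]:
    """Mean signal vs offset around feature midpoints, strand-aware.

    Returns (offsets, mean profile, n centers used, n dropped).  Signal is
    sampled from the track bin containing each offset position; profiles of
    minus-strand centers are reversed.  Centers whose window leaves the
    chromosome are dropped.
    """
    offsets = np.arange(-flank, flank, bin) + bin // 2
    rows = []
    dropped = 0
    for iv in centers:
        if iv.chrom not in track.values:
            dropped += 1
            continue
        mid = iv.center
        length = track.genome.length(iv.chrom)
        if mid - flank < 0 or mid + flank > length:
            dropped += 1
            continue
        vals = np.array([track.value_at(iv.chrom, mid + off) for off in offsets])
        if iv.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    if not rows:
        return offsets, np.full(len(offsets), np.nan), 0, dropped
    profile = np.nanmean(np.vstack(rows), axis=0)
    return offsets, profile, len(rows), dropped
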