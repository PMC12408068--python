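"""Fixed-width binned genome-wide signal tracks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence

import numpy as np

from .intervals import Genome, GenomicInterval


@dataclass
class SignalTrack:
    """One value per fixed-width bin per chromosome (RPKM-like units).

    ``mask`` flags bins that carry data; zero-filled gap bins are flagged
    False and skipped by aggregators.
    """

    genome: Genome
    bin_size: int
    values: Dict[str, np.ndarray]
    mask: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in self.values:
            expected = self.genome.n_bins(chrom, self.bin_size)
            if len(self.values[chrom]) != expected:
                raise ValueError(
                    f"{chrom}: {len(self.values[chrom])} bins, expected {expected}"
                )
            if chrom not in self.mask:
                self.mask[chrom] = np.ones(expected, dtype=bool)

    @classmethod
    def zeros(cls, genome: Genome, bin_size: int, with_data: bool = True) -> "SignalTrack":
        values = {c: np.zeros(genome.n_bins(c, bin_size)) for c in genome.chroms}
        mask = {
            c: np.full(genome.n_bins(c, bin_size), with_data, dtype=bool)
            for c in genome.chroms
        }
        return cls(genome, bin_size, values, mask)

    def copy(self) -> "SignalTrack":
        return SignalTrack(
            self.genome,
            self.bin_size,
            {c: v.copy() for c, v in self.values.items()},
            {c: m.copy() for c, m in self.mask.items()},
        )

    def bin_range(self, chrom: str, start: int, end: int) -> range:
        """Indices of bins overlapping [start, end) on chrom."""
        first = start // self.bin_size
        last = -(-end // self.bin_size)  # ceil
        n = len(self.values[chrom])
        return range(max(first, 0), min(last, n))

    def feature_values(self, iv: GenomicInterval) -> np.ndarray:
        """Values of data-carrying bins overlapping the feature."""
        if iv.chrom not in self.values:
            return np.empty(0)
        idx = self.bin_range(iv.chrom, iv.start, iv.end)
        v = self.values[iv.chrom][idx.start : idx.stop]
        m = self.mask[iv.chrom][idx.start : idx.stop]
        return v[m]

    def value_at(self, chrom: str, pos: int) -> float:
        """Value of the bin containing ``pos``; NaN outside or masked."""
        if chrom not in self.values:
            return np.nan
        b = pos // self.bin_size
        if pos < 0 or b >= len(self.values[chrom]):
            return np.nan
        if not self.mask[chrom][b]:
            return np.nan
        return float(self.values[chrom][b])

    def genome_values(self) -> np.ndarray:
        """All data-carrying bin values, concatenated in chromosome order."""
        parts = [self.values[c][self.mask[c]] for c in self.genome.chroms if c in self.values]
        return np.concatenate(parts) if parts else np.empty(0)


def map_binned_signal(
    track: SignalTrack,
    features: Sequence[GenomicInterval],
    aggregator: Callable[[np.ndarray], float] = np.mean,
) -> np.ndarray:
    """Per feature, the unweighted aggregate over bins overlapping it.

    Bins without data are skipped; a feature overlapping no data bin (or on
    a chromosome absent from the track) yields NaN.
    """
    out = np.full(len(features), np.nan)
    for i, iv in enumerate(features):
        vals = track.feature_values(iv)
        if vals.size:
            out[i] = aggregator(vals)
    return out
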