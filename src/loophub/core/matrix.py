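"""Dense per-chromosome balanced contact matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ContactMatrix:
    """Symmetric balanced interaction-frequency matrix for one chromosome.

    Missing entries (diagonal, unbalanced bins) are NaN.
    """

    chrom: str
    bin_size: int
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != self.data.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(self.data, self.data.T, equal_nan=True):
            raise ValueError(f"{self.chrom}: contact matrix is not symmetric")
        finite = self.data[np.isfinite(self.data)]
        if finite.size and finite.min() < 0:
            raise ValueError(f"{self.chrom}: negative interaction frequencies")

    @property
    def n_bins(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.bin_size, self.data.copy())
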