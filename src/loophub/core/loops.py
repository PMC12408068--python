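"""Chromatin loops: ordered anchor pairs with per-sample PET counts."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .intervals import GenomicInterval


@dataclass
class Loop:
    """A pair of same-chromosome anchors with PET support and an FDR.

    ``pets`` maps sample names of the form ``"<condition>:<replicate>"``
    (e.g. ``"B:1"``) to non-negative integer PET counts.  Anchors are
    canonicalized so anchor1 is leftmost.
    """

    id: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pets: Dict[str, int] = field(default_factory=dict)
    fdr: float = 0.0

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError(f"loop {self.id}: inter-chromosomal anchors")
        if self.anchor1.start > self.anchor2.start:
            self.anchor1, self.anchor2 = self.anchor2, self.anchor1
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"loop {self.id}: FDR {self.fdr} outside [0, 1]")
        for sample, n in self.pets.items():
            if n < 0:
                raise ValueError(f"loop {self.id}: negative PETs in {sample}")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    def total_pets(self, samples=None) -> int:
        if samples is None:
            samples = self.pets.keys()
        return sum(self.pets[s] for s in samples)

    def condition_samples(self, condition: str):
        return [s for s in self.pets if s.split(":")[0] == condition]


def loop_distance(loop: Loop) -> int:
    """Separation between anchor midpoints in bp."""
    return abs(loop.anchor2.center - loop.anchor1.center)
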