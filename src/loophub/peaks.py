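"""Condition-specific peak sets and genomic annotation.

The differential peak caller itself is external; this module applies the
set restriction (called in B, zero overlap with any A peak) and annotates
peaks by the position of their midpoint with a fixed priority order:
promoter > TTS > exon > intron > intergenic.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .core.genes import GeneModel
from .core.intervals import GenomicInterval, IntervalIndex

CATEGORIES = ("promoter", "exon", "TTS", "intron", "intergenic")


def condition_specific_peaks(
    peaks_a: Sequence[GenomicInterval],
    peaks_b: Sequence[GenomicInterval],
) -> List[GenomicInterval]:
    """Peaks called in B with zero overlap with any A peak.

    A single bp of overlap disqualifies (any-overlap semantics).  Pass the
    union of replicate call sets for each condition.
    """
    index = IntervalIndex(peaks_a)
    return [iv for iv in peaks_b if not index.any_overlap(iv)]


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    model: GeneModel,
    promoter_upstream: int = 1000,
    promoter_downstream: int = 100,
    tts_upstream: int = 100,
    tts_downstream: int = 1000,
) -> List[str]:
    """One category per peak, by peak-center position.

    Priority promoter > TTS > exon > intron > intergenic; promoter and TTS
    windows are strand-aware.
    """
    promoters = IntervalIndex(
        [g.promoter(promoter_upstream, promoter_downstream) for g in model.genes]
    )
    tts = IntervalIndex(
        [g.tts_window(tts_upstream, tts_downstream) for g in model.genes]
    )
    exons = IntervalIndex([e for g in model.genes for e in g.exons])
    genes = IntervalIndex([g.interval for g in model.genes])

    out = []
    for iv in peaks:
        c = iv.center
        if promoters.query(iv.chrom, c, c + 1):
            out.append("promoter")
        elif tts.query(iv.chrom, c, c + 1):
            out.append("TTS")
        elif exons.query(iv.chrom, c, c + 1):
            out.append("exon")
        elif genes.query(iv.chrom, c, c + 1):
            out.append("intron")
        else:
            out.append("intergenic")
    return out


def annotation_proportions(
    peaks: pd.DataFrame,
    group_cols: Sequence[str],
    category_col: str = "category",
) -> pd.DataFrame:
    """Per-group category fractions (rows sum to 1; empty groups omitted)."""
    rows = []
    for key, grp in peaks.groupby(list(group_cols)):
        if not isinstance(key, tuple):
            key = (key,)
        counts = grp[category_col].value_counts()
        total = counts.sum()
        row = dict(zip(group_cols, key))
        for cat in CATEGORIES:
            row[cat] = counts.get(cat, 0) / total
        row["n"] = int(total)
        rows.append(row)
    return pd.DataFrame.from_records(rows)
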