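"""Minimal gene model: genes with exons, derived promoter/TTS windows.

GFF3 input (genes/exons only) is converted to 0-based half-open on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .intervals import GenomicInterval


def _merge(intervals: List[tuple]) -> List[tuple]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


@dataclass
class Gene:
    interval: GenomicInterval  # carries strand and gene id as name
    exons: List[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"exon off-chromosome in gene {self.interval.name}")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon outside gene {self.interval.name}")
        merged = _merge([(e.start, e.end) for e in self.exons])
        self.exons = [
            GenomicInterval(self.interval.chrom, s, e, self.interval.strand)
            for s, e in merged
        ]

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware)."""
        return self.interval.start if self.strand != "-" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end position (strand-aware)."""
        return self.interval.end - 1 if self.strand != "-" else self.interval.start

    def promoter(self, upstream: int = 1000, downstream: int = 100) -> GenomicInterval:
        if self.strand != "-":
            s, e = self.tss - upstream, self.tss + downstream
        else:
            s, e = self.tss - downstream + 1, self.tss + upstream + 1
        return GenomicInterval(self.interval.chrom, max(s, 0), max(e, 1), self.strand)

    def tts_window(self, upstream: int = 100, downstream: int = 1000) -> GenomicInterval:
        if self.strand != "-":
            s, e = self.tes - upstream, self.tes + downstream
        else:
            s, e = self.tes - downstream + 1, self.tes + upstream + 1
        return GenomicInterval(self.interval.chrom, max(s, 0), max(e, 1), self.strand)


@dataclass
class GeneModel:
    genes: List[Gene]

    def __post_init__(self) -> None:
        seen: Dict[str, bool] = {}
        for g in self.genes:
            if g.interval.name in seen:
                raise ValueError(f"duplicate gene id {g.interval.name!r}")
            seen[g.interval.name] = True

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> Dict[str, Gene]:
        return {g.interval.name: g for g in self.genes}


def write_gff3(path, model: GeneModel) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in model.genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tloophub\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={iv.name}\n"
            )
            for k, ex in enumerate(g.exons):
                fh.write(
                    f"{ex.chrom}\tloophub\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{iv.strand}\t.\tID={iv.name}.exon{k + 1};Parent={iv.name}\n"
                )


def _attr(field8: str, key: str) -> str:
    for part in field8.split(";"):
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return ""


def read_gff3(path) -> GeneModel:
    """Read genes/exons from a GFF3 file (1-based closed -> half-open)."""
    genes: Dict[str, dict] = {}
    exons: Dict[str, List[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in ("gene", "exon"):
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if ftype == "gene":
                gid = _attr(attrs, "ID")
                genes[gid] = dict(chrom=chrom, start=s, end=e, strand=strand)
            else:
                parent = _attr(attrs, "Parent")
                exons.setdefault(parent, []).append(
                    GenomicInterval(chrom, s, e, strand)
                )
    out = []
    for gid, rec in genes.items():
        iv = GenomicInterval(rec["chrom"], rec["start"], rec["end"], rec["strand"], gid)
        out.append(Gene(iv, exons.get(gid, [])))
    return GeneModel(out)
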