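"""Readers/writers for BED, BEDPE, bedGraph and the dense matrix container.

Errors name the offending file and line.  All writers emit the canonical
dialects the readers accept, so write -> read is the identity on canonical
records.
"""

from __future__ import annotations

import gzip
import warnings
from typing import Dict, List, Optional, Sequence

import numpy as np

from .intervals import Genome, GenomicInterval
from .loops import Loop
from .matrix import ContactMatrix
from .tracks import SignalTrack


class FormatError(ValueError):
    """A malformed record in an on-disk file."""


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _check_bounds(iv: GenomicInterval, genome: Optional[Genome], path, lineno: int):
    if genome is None:
        return
    if iv.chrom not in genome:
        raise FormatError(f"{path}:{lineno}: unknown chromosome {iv.chrom!r}")
    if iv.end > genome.length(iv.chrom):
        raise FormatError(
            f"{path}:{lineno}: interval end {iv.end} beyond {iv.chrom} "
            f"length {genome.length(iv.chrom)}"
        )


# ---------------------------------------------------------------------------
# BED

def read_bed(path, genome: Optional[Genome] = None) -> List[GenomicInterval]:
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else ""
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
                strand = fields[5] if len(fields) > 5 else "."
                iv = GenomicInterval(chrom, start, end, strand, name, score)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            _check_bounds(iv, genome, path, lineno)
            out.append(iv)
    return out


def write_bed(path, intervals: Sequence[GenomicInterval]) -> None:
    with _open(path, "wt") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{iv.score:g}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# BEDPE

_BEDPE_FIXED = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
]


def read_bedpe(path, genome: Optional[Genome] = None) -> List[Loop]:
    """Read loops from BEDPE with per-sample PET columns and a final fdr.

    The header line declares the sample columns (``pet:<cond>:<rep>``).
    Anchors are re-ordered so anchor1 is leftmost; inter-chromosomal rows
    are rejected with a warning.
    """
    loops: List[Loop] = []
    sample_cols: List[str] = []
    with _open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#"):
            raise FormatError(f"{path}:1: missing BEDPE header line")
        cols = header.lstrip("#").split("\t")
        if cols[: len(_BEDPE_FIXED)] != _BEDPE_FIXED or cols[-1] != "fdr":
            raise FormatError(f"{path}:1: unexpected BEDPE header layout")
        sample_cols = [c for c in cols[len(_BEDPE_FIXED):-1]]
        for c in sample_cols:
            if not c.startswith("pet:"):
                raise FormatError(f"{path}:1: bad sample column {c!r}")
        samples = [c[4:] for c in sample_cols]
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: {len(fields)} columns, expected {len(cols)}"
                )
            try:
                a1 = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[8]
                )
                a2 = GenomicInterval(
                    fields[3], int(fields[4]), int(fields[5]), fields[9]
                )
                pets = {
                    s: int(v)
                    for s, v in zip(samples, fields[len(_BEDPE_FIXED):-1])
                }
                fdr = float(fields[-1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if a1.chrom != a2.chrom:
                warnings.warn(
                    f"{path}:{lineno}: inter-chromosomal loop "
                    f"{fields[6]!r} skipped"
                )
                continue
            _check_bounds(a1, genome, path, lineno)
            _check_bounds(a2, genome, path, lineno)
            loops.append(Loop(fields[6], a1, a2, pets, fdr))
    return loops


def write_bedpe(path, loops: Sequence[Loop]) -> None:
    samples: List[str] = []
    for lp in loops:
        for s in lp.pets:
            if s not in samples:
                samples.append(s)
    with _open(path, "wt") as fh:
        fh.write(
            "#" + "\t".join(_BEDPE_FIXED + [f"pet:{s}" for s in samples] + ["fdr"])
            + "\n"
        )
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            row = [
                a1.chrom, str(a1.start), str(a1.end),
                a2.chrom, str(a2.start), str(a2.end),
                lp.id or ".", "0", a1.strand, a2.strand,
            ]
            row += [str(lp.pets.get(s, 0)) for s in samples]
            row.append(f"{lp.fdr:.6g}")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path, genome: Genome, bin_size: int) -> SignalTrack:
    """Read a binned bedGraph into a SignalTrack.

    Gaps (bins with no record) are zero-filled and flagged as missing so
    aggregators skip them.
    """
    track = SignalTrack.zeros(genome, bin_size, with_data=False)
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if chrom not in genome:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > genome.length(chrom) or start < 0 or end <= start:
                raise FormatError(f"{path}:{lineno}: interval outside chromosome")
            for b in track.bin_range(chrom, start, end):
                track.values[chrom][b] = value
                track.mask[chrom][b] = True
    return track


def write_bedgraph(path, track: SignalTrack) -> None:
    """Write data-carrying bins only (gaps are implicit)."""
    with _open(path, "wt") as fh:
        for chrom in track.genome.chroms:
            if chrom not in track.values:
                continue
            vals, mask = track.values[chrom], track.mask[chrom]
            length = track.genome.length(chrom)
            for b in np.flatnonzero(mask):
                start = int(b) * track.bin_size
                end = min(start + track.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[b]:.6g}\n")


# ---------------------------------------------------------------------------
# Contact matrix container

def read_matrix(path) -> ContactMatrix:
    with _open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("#contactmatrix"):
            raise FormatError(f"{path}:1: missing contact-matrix header")
        meta = dict(
            part.split("=", 1) for part in header.split("\t")[1:] if "=" in part
        )
        try:
            chrom = meta["chrom"]
            bin_size = int(meta["bin_size"])
            n_bins = int(meta["n_bins"])
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}:1: bad matrix header: {header!r}") from exc
        rows = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            vals = line.split("\t")
            if len(vals) != n_bins:
                raise FormatError(
                    f"{path}:{lineno}: {len(vals)} values, expected {n_bins}"
                )
            rows.append(np.array(vals, dtype=float))
        if len(rows) != n_bins:
            raise FormatError(f"{path}: {len(rows)} rows, expected {n_bins}")
    return ContactMatrix(chrom, bin_size, np.vstack(rows))


def write_matrix(path, matrix: ContactMatrix) -> None:
    with _open(path, "wt") as fh:
        fh.write(
            f"#contactmatrix\tchrom={matrix.chrom}\tbin_size={matrix.bin_size}"
            f"\tn_bins={matrix.n_bins}\n"
        )
        for row in matrix.data:
            fh.write("\t".join("nan" if not np.isfinite(v) else f"{v:.8g}" for v in row))
            fh.write("\n")
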