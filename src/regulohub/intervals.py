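"""Genome-interval algebra, promoter construction, and BED-family I/O.

All coordinates are 0-based half-open throughout the package; BED is the
native convention and any 1-based input must be converted at the boundary.

Three promoter definitions coexist in the pipeline, reflecting the three
stages that use them:

* ``atac_promoter`` — 2000 bp, from 1500 bp upstream to 500 bp downstream of
  the TSS (strand-aware); used for promoter-accessibility bookkeeping.
* ``loop_promoter`` — 2200 bp; used when annotating CORE-promoter loops.
  Realized as the atac window widened ~10% on each side ([tss-1650, tss+550)
  on the + strand); the offset is configurable because only the width is a
  fixed convention.
* ``das_promoter`` — 6000 bp, +/-3000 bp around the TSS, strand-free; used to
  attach differentially accessible peaks to genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "overlaps",
    "contains",
    "overlap_length",
    "promoter_from_tss",
    "PROMOTER_WINDOWS",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``.

    ``strand`` is '+', '-' or '.' (unstranded). ``name`` is an optional
    identifier carried through I/O.
    """

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)
    name: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.chrom, self.start + offset, self.end + offset, self.strand, self.name
        )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 bp under half-open coordinates.

    Adjacent intervals ([0,10) vs [10,20)) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared base pairs (0 if disjoint or different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def contains(outer: GenomicInterval, inner: GenomicInterval) -> bool:
    """True iff inner lies entirely within outer (same chromosome)."""
    return (
        outer.chrom == inner.chrom
        and outer.start <= inner.start
        and inner.end <= outer.end
    )


#: (upstream, downstream) extents in bp relative to the TSS for each promoter kind.
PROMOTER_WINDOWS: dict[str, tuple[int, int]] = {
    "atac_promoter": (1500, 500),
    "loop_promoter": (1650, 550),
    "das_promoter": (3000, 3000),
}


def promoter_from_tss(
    chrom: str,
    tss: int,
    strand: str,
    kind: str = "atac_promoter",
    name: str = ".",
    chrom_length: int | None = None,
) -> GenomicInterval:
    """Build a promoter window around a TSS.

    On the + strand the window is [tss - upstream, tss + downstream); on the
    - strand it is mirrored so that "upstream" lies at larger coordinates.
    The window is truncated at 0 and, when ``chrom_length`` is given, at the
    chromosome end.
    """
    if tss < 0:
        raise ValueError("tss must be >= 0")
    try:
        up, down = PROMOTER_WINDOWS[kind]
    except KeyError:
        raise ValueError(
            f"unknown promoter kind {kind!r}; expected one of {sorted(PROMOTER_WINDOWS)}"
        ) from None
    if strand == "-":
        start, end = tss - down, tss + up
    else:
        start, end = tss - up, tss + down
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(chrom, start, end, strand, name)


# ---------------------------------------------------------------------------
# BED-family I/O


def _parse_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicInterval records (0-based half-open)."""
    out: list[GenomicInterval] = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 3:
            raise ValueError(f"{path}: line {lineno}: expected >= 3 BED columns")
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
        name = fields[3] if len(fields) > 3 else "."
        strand = fields[5] if len(fields) > 5 else "."
        out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    extra_columns: Sequence[Sequence] | None = None,
) -> None:
    """Write BED6 (score column '0'); optional extra columns appended per record."""
    intervals = list(intervals)
    with open(path, "w") as fh:
        for idx, iv in enumerate(intervals):
            row = [iv.chrom, str(iv.start), str(iv.end), iv.name, "0", iv.strand]
            if extra_columns is not None:
                row.extend(str(v) for v in extra_columns[idx])
            fh.write("\t".join(row) + "\n")


def read_narrowpeak(path: str | Path) -> pd.DataFrame:
    """Read ENCODE narrowPeak (BED6+4) into a DataFrame.

    Columns: chrom, start, end, name, score, strand, signalValue, pValue,
    qValue, summit (summit is the offset from start; -1 if not called).
    """
    rows = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 10:
            raise ValueError(f"{path}: line {lineno}: narrowPeak needs 10 columns")
        try:
            rows.append(
                (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(float(fields[4])),
                    fields[5],
                    float(fields[6]),
                    float(fields[7]),
                    float(fields[8]),
                    int(fields[9]),
                )
            )
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: malformed narrowPeak fields") from None
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "name",
            "score",
            "strand",
            "signalValue",
            "pValue",
            "qValue",
            "summit",
        ],
    )


def write_narrowpeak(peaks: pd.DataFrame, path: str | Path) -> None:
    cols = [
        "chrom",
        "start",
        "end",
        "name",
        "score",
        "strand",
        "signalValue",
        "pValue",
        "qValue",
        "summit",
    ]
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read bedGraph (chrom, start, end, value) into a DataFrame."""
    rows = []
    for lineno, fields in _parse_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}: line {lineno}: bedGraph needs 4 columns")
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: malformed bedGraph fields") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(track: pd.DataFrame, path: str | Path) -> None:
    track[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def peaks_to_intervals(peaks: pd.DataFrame) -> list[GenomicInterval]:
    """Convert a peak DataFrame (chrom/start/end[/name]) to intervals."""
    names = peaks["name"] if "name" in peaks.columns else ["."] * len(peaks)
    return [
        GenomicInterval(c, s, e, ".", n)
        for c, s, e, n in zip(peaks["chrom"], peaks["start"], peaks["end"], names)
    ]
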