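"""Per-base signal tracks (ATAC insertion counts, Tn5 bias, corrected signal)."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = ["SignalTrack", "write_bedgraph_tracks", "tracks_from_bedgraph"]


@dataclass
class SignalTrack:
    """A contiguous per-base signal over [start, start + len(values)) on chrom."""

    chrom: str
    start: int
    values: np.ndarray
    name: str = "."

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Values over genomic [start, end); raises if outside coverage."""
        if start < self.start or end > self.end or start >= end:
            raise IndexError(
                f"[{start}, {end}) outside track coverage [{self.start}, {self.end})"
            )
        off = start - self.start
        return self.values[off : off + (end - start)]

    def covers(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end and start < end


def write_bedgraph_tracks(tracks: Iterable[SignalTrack], path: str | Path) -> None:
    """Write tracks as bedGraph, run-length-encoding constant stretches."""
    with open(path, "w") as fh:
        for t in tracks:
            vals = t.values
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                v = vals[s]
                out = int(v) if float(v).is_integer() else v
                fh.write(f"{t.chrom}\t{t.start + s}\t{t.start + e}\t{out}\n")


def tracks_from_bedgraph(df: pd.DataFrame) -> list[SignalTrack]:
    """Reassemble contiguous SignalTracks from a bedGraph DataFrame."""
    tracks: list[SignalTrack] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_start: int | None = None
        buf: list[np.ndarray] = []
        prev_end = None
        for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
            if cur_start is None:
                cur_start, prev_end = int(s), int(e)
                buf = [np.full(e - s, v)]
            elif s == prev_end:
                buf.append(np.full(e - s, v))
                prev_end = int(e)
            else:
                tracks.append(SignalTrack(chrom, cur_start, np.concatenate(buf)))
                cur_start, prev_end = int(s), int(e)
                buf = [np.full(e - s, v)]
        if cur_start is not None:
            tracks.append(SignalTrack(chrom, cur_start, np.concatenate(buf)))
    return tracks
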