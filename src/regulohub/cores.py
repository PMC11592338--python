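"""Clusters of cis-regulatory elements (COREs) and CORE-promoter loops.

A CORE is a chain of >= 2 ATAC peaks in which consecutive peaks are less
than 20 Kb apart and the whole cluster spans at least 1 Kb — a
super-enhancer-like accessible hub. CORE-promoter loops are significant
Hi-C loops with one 10 Kb anchor overlapping (>= 1 bp) a promoter and the
other overlapping a CORE; a subset overlaps "completely": an entire
promoter or CORE fits inside the anchor, or (for COREs wider than the bin)
the anchor fits inside the CORE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from regulohub.intervals import GenomicInterval, contains, overlaps

__all__ = [
    "CORE",
    "COREPromoterLoop",
    "detect_cores",
    "annotate_core_promoter_loops",
    "intersect_differential_loops_with_cores",
]


@dataclass
class CORE:
    interval: GenomicInterval
    n_peaks: int
    member_peak_ids: list
    footprint_count: int = 0


@dataclass
class COREPromoterLoop:
    chrom: str
    bin_i: int
    bin_j: int
    category: str
    core_ids: list
    promoter_gene_ids: list
    complete_overlap: bool
    orientation: str  # 'i_promoter', 'j_promoter' or 'both'


def detect_cores(
    peaks: Sequence[GenomicInterval],
    max_gap_bp: int = 20_000,
    min_length_bp: int = 1_000,
    min_peaks: int = 2,
) -> list[CORE]:
    """Chain-link clustering of peaks into COREs.

    Consecutive peaks (per chromosome, sorted by start) join a chain while
    the gap from the end of one peak to the start of the next is strictly
    below ``max_gap_bp``; chains are kept when they span at least
    ``min_length_bp`` and contain at least ``min_peaks`` peaks. The CORE
    interval runs from the first peak's start to the last peak's end.
    Output is independent of input order.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for pk in peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    cores: list[CORE] = []
    for chrom in sorted(by_chrom):
        chain: list[GenomicInterval] = []
        sorted_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))

        def flush() -> None:
            if len(chain) >= min_peaks:
                start = chain[0].start
                end = max(p.end for p in chain)
                if end - start >= min_length_bp:
                    cores.append(
                        CORE(
                            GenomicInterval(
                                chrom, start, end, name=f"core_{len(cores):03d}"
                            ),
                            n_peaks=len(chain),
                            member_peak_ids=[p.name for p in chain],
                        )
                    )

        for pk in sorted_peaks:
            if chain and pk.start - max(p.end for p in chain) < max_gap_bp:
                chain.append(pk)
            else:
                flush()
                chain = [pk]
        flush()
    return cores


def annotate_core_promoter_loops(
    loops: pd.DataFrame,
    cores: Sequence[CORE],
    promoters: Sequence[GenomicInterval],
    bin_size_bp: int,
) -> list[COREPromoterLoop]:
    """Find significant loops linking a promoter anchor to a CORE anchor.

    ``loops`` is a loop table (chrom/bin_i/bin_j, plus significant and
    category columns when present); ``promoters`` are 2200 bp loop-promoter
    windows whose name is the gene id. Each qualifying loop is reported
    once; if both anchors qualify in both roles the orientation is 'both'.
    The complete_overlap flag marks loops where an entire promoter or CORE
    is contained in the 10 Kb anchor or the anchor is contained in a CORE
    wider than the bin.
    """
    if "significant" in loops.columns:
        loops = loops.loc[loops["significant"]]
    out: list[COREPromoterLoop] = []
    for row in loops.itertuples():
        a1 = GenomicInterval(row.chrom, row.bin_i * bin_size_bp, (row.bin_i + 1) * bin_size_bp)
        a2 = GenomicInterval(row.chrom, row.bin_j * bin_size_bp, (row.bin_j + 1) * bin_size_bp)

        def hits(anchor):
            proms = [p for p in promoters if overlaps(anchor, p)]
            crs = [c for c in cores if overlaps(anchor, c.interval)]
            return proms, crs

        p1, c1 = hits(a1)
        p2, c2 = hits(a2)
        fwd = bool(p1) and bool(c2)  # promoter at anchor i, CORE at anchor j
        rev = bool(p2) and bool(c1)
        if not (fwd or rev):
            continue
        proms = (p1 if fwd else []) + (p2 if rev else [])
        crs = (c2 if fwd else []) + (c1 if rev else [])
        complete = False
        for anchor, ps, cs in ((a1, p1, c1), (a2, p2, c2)):
            complete |= any(contains(anchor, p) for p in ps)
            complete |= any(contains(anchor, c.interval) for c in cs)
            complete |= any(
                len(c.interval) > bin_size_bp and contains(c.interval, anchor)
                for c in cs
            )
        out.append(
            COREPromoterLoop(
                chrom=row.chrom,
                bin_i=row.bin_i,
                bin_j=row.bin_j,
                category=getattr(row, "category", ""),
                core_ids=sorted({c.interval.name for c in crs}),
                promoter_gene_ids=sorted({p.name for p in proms}),
                complete_overlap=complete,
                orientation="both" if (fwd and rev) else ("i_promoter" if fwd else "j_promoter"),
            )
        )
    return out


def intersect_differential_loops_with_cores(
    loops: pd.DataFrame, cores: Sequence[CORE], bin_size_bp: int
) -> pd.DataFrame:
    """Per category, the unique differential loops touching >= 1 CORE.

    Returns one row per dynamic category with the loop count and the set of
    unique COREs involved.
    """
    rows = []
    if "significant" in loops.columns:
        loops = loops.loc[loops["significant"]]
    for category in ("gained", "lost"):
        sub = loops.loc[loops.get("category", "") == category]
        loop_keys = set()
        involved: set[str] = set()
        for row in sub.itertuples():
            a1 = GenomicInterval(row.chrom, row.bin_i * bin_size_bp, (row.bin_i + 1) * bin_size_bp)
            a2 = GenomicInterval(row.chrom, row.bin_j * bin_size_bp, (row.bin_j + 1) * bin_size_bp)
            touched = {
                c.interval.name
                for c in cores
                if overlaps(a1, c.interval) or overlaps(a2, c.interval)
            }
            if touched:
                loop_keys.add((row.chrom, row.bin_i, row.bin_j))
                involved |= touched
        rows.append(
            {
                "category": category,
                "n_loops_with_core": len(loop_keys),
                "n_cores_involved": len(involved),
                "core_ids": ",".join(sorted(involved)),
            }
        )
    return pd.DataFrame(rows)
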