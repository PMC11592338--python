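"""Bias-corrected TF footprint scoring and differential binding statistics.

A footprint is a local depletion of Tn5 insertions at a bound motif inside
otherwise accessible chromatin. The workflow mirrors footprinting practice:

1. :func:`correct_bias` removes a known multiplicative insertion bias from a
   per-base cut track by local-mean scaling; corrected values can be
   negative (the depletion signal).
2. :func:`scan_motifs` finds motif occurrences in peak-window sequences by
   log-odds scanning of both strands against JASPAR-style PFMs.
3. :func:`footprint_score` scores each occurrence as mean flank signal minus
   mean center signal: a bound site shows accessible flanks and a protected
   (depleted) center, hence a high score.
4. :func:`restrict_to_anchors` keeps only sites inside Hi-C loop anchors.
5. :func:`differential_binding` compares AS vs GFP score vectors per anchor
   (optionally grouped by TF class) with a Wilcoxon rank-sum test. The test
   is self-contained: exact null enumeration for small groups, normal
   approximation with tie and continuity correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.stats import norm, rankdata

from regulohub.intervals import GenomicInterval, overlaps
from regulohub.signal import SignalTrack

__all__ = [
    "MotifModel",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "correct_bias",
    "footprint_score",
    "scan_motifs",
    "restrict_to_anchors",
    "wilcoxon_rank_sum",
    "differential_binding",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MotifModel:
    """A position frequency matrix with JASPAR-style metadata.

    ``pfm`` is a 4 x width count matrix (rows A, C, G, T). The log-odds
    matrix uses pseudocount 1 and a uniform background.
    """

    motif_id: str
    name: str
    class_label: str
    family_label: str
    pfm: np.ndarray

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        if self.pfm.shape[1] < 4:
            raise ValueError("motif width must be >= 4")
        sums = self.pfm.sum(axis=0)
        if not np.allclose(sums, sums[0]):
            raise ValueError("PFM columns must sum to a constant")

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        counts = self.pfm + 1.0
        probs = counts / counts.sum(axis=0, keepdims=True)
        return np.log2(probs / 0.25)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))


def write_jaspar_pfm(motifs: Sequence[MotifModel], path: str | Path) -> None:
    """Write JASPAR-format PFMs; class/family ride as key=value header tokens."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(
                f">{m.motif_id}\t{m.name}\tclass={m.class_label}\tfamily={m.family_label}\n"
            )
            for base in "ACGT":
                row = " ".join(
                    str(int(v)) if float(v).is_integer() else str(v)
                    for v in m.pfm[_BASE_INDEX[base]]
                )
                fh.write(f"{base}  [ {row} ]\n")


def read_jaspar_pfm(path: str | Path) -> list[MotifModel]:
    """Read JASPAR-format PFM text (4 bracketed count rows per motif)."""
    motifs: list[MotifModel] = []
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if set(rows) != set("ACGT"):
            raise ValueError(f"motif {header[0]}: missing base rows")
        meta = {"class": "", "family": ""}
        for token in header[2:]:
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
        motifs.append(
            MotifModel(
                header[0],
                header[1] if len(header) > 1 else header[0],
                meta["class"],
                meta["family"],
                np.array([rows[b] for b in "ACGT"]),
            )
        )
        header, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split("\t")
                if len(header) == 1:  # plain JASPAR uses '>ID NAME'
                    header = line[1:].split(None, 1)
            else:
                base = line[0].upper()
                nums = line[1:].strip().strip("[]").split()
                rows[base] = [float(v) for v in nums]
    flush()
    return motifs


# ---------------------------------------------------------------------------
# bias correction and scoring


def correct_bias(
    cuts: SignalTrack, bias: SignalTrack, window_bp: int = 200
) -> SignalTrack:
    """Remove multiplicative insertion bias by local-mean scaling.

    corrected(x) = cuts(x) - local_mean(cuts)(x) * bias(x) / local_mean(bias)(x)

    with local means over a centered ``window_bp`` sliding window. If the
    cuts are exactly proportional to the bias the correction cancels to
    zero; depleted centers come out negative.
    """
    if not bias.covers(cuts.start, cuts.end):
        raise ValueError("bias track does not cover the cut track")
    b = bias.slice(cuts.start, cuts.end)
    if np.any((b <= 0) & (cuts.values > 0)):
        raise ValueError("bias must be strictly positive where cuts > 0")
    local_cuts = uniform_filter1d(cuts.values, size=window_bp, mode="nearest")
    local_bias = uniform_filter1d(b, size=window_bp, mode="nearest")
    corrected = cuts.values - local_cuts * b / local_bias
    return SignalTrack(cuts.chrom, cuts.start, corrected, name=cuts.name)


def footprint_score(
    signal: SignalTrack, site: GenomicInterval, flank_bp: int = 60
) -> float | None:
    """Flank-minus-center binding score; None if coverage is insufficient."""
    lo, hi = site.start - flank_bp, site.end + flank_bp
    if site.chrom != signal.chrom or not signal.covers(lo, hi):
        return None
    left = signal.slice(lo, site.start)
    right = signal.slice(site.end, hi)
    center = signal.slice(site.start, site.end)
    flank_mean = np.concatenate([left, right]).mean()
    return float(flank_mean - center.mean())


# ---------------------------------------------------------------------------
# motif scanning


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(len(codes), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[codes == ord(base)] = idx
    return out


def scan_motifs(
    regions: Iterable[tuple[str, int, str]],
    motifs: Sequence[MotifModel],
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Scan region sequences for motif occurrences on both strands.

    ``regions`` yields (chrom, genomic_start, sequence). A window is a hit
    when its log-odds score >= threshold * max achievable score. Windows
    containing non-ACGT bases are skipped. Overlapping hits of the same
    motif are merged, keeping the best-scoring window.

    Returns a DataFrame: chrom, start, end, motif_id, strand, score.
    """
    hits: list[tuple[str, int, int, str, str, float]] = []
    for chrom, g_start, seq in regions:
        codes = _encode(seq)
        n = len(codes)
        for m in motifs:
            w = m.width
            if n < w:
                continue
            lo = m.log_odds
            lo_rc = lo[::-1, ::-1]  # reverse complement scan matrix
            windows = np.lib.stride_tricks.sliding_window_view(codes, w)
            valid = (windows >= 0).all(axis=1)
            pos = np.arange(w)
            cut = threshold * m.max_score
            for strand, mat in (("+", lo), ("-", lo_rc)):
                safe = np.where(windows >= 0, windows, 0)
                scores = mat[safe, pos].sum(axis=1)
                for off in np.flatnonzero(valid & (scores >= cut)):
                    hits.append(
                        (
                            chrom,
                            g_start + int(off),
                            g_start + int(off) + w,
                            m.motif_id,
                            strand,
                            float(scores[off]),
                        )
                    )
    df = pd.DataFrame(
        hits, columns=["chrom", "start", "end", "motif_id", "strand", "score"]
    )
    return _merge_same_motif(df)


def _merge_same_motif(df: pd.DataFrame) -> pd.DataFrame:
    """Greedily keep the best-scoring hit among overlapping same-motif hits."""
    kept_rows = []
    for (chrom, motif_id), sub in df.groupby(["chrom", "motif_id"], sort=False):
        sub = sub.sort_values("score", ascending=False)
        taken: list[tuple[int, int]] = []
        for row in sub.itertuples():
            if all(not (row.start < e and s < row.end) for s, e in taken):
                taken.append((row.start, row.end))
                kept_rows.append(row)
    out = pd.DataFrame(kept_rows)
    if out.empty:
        return df.iloc[0:0]
    out = out[["chrom", "start", "end", "motif_id", "strand", "score"]]
    return out.sort_values(["chrom", "start", "motif_id"]).reset_index(drop=True)


def restrict_to_anchors(
    sites: pd.DataFrame, anchors: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Keep sites overlapping (>= 1 bp) any anchor; annotate anchor_id.

    A site overlapping two anchors appears once per anchor.
    """
    rows = []
    for _, site in sites.iterrows():
        iv = GenomicInterval(site["chrom"], int(site["start"]), int(site["end"]))
        for anchor in anchors:
            if overlaps(iv, anchor):
                row = site.to_dict()
                row["anchor_id"] = anchor.name
                rows.append(row)
    if not rows:
        out = sites.iloc[0:0].copy()
        out["anchor_id"] = pd.Series(dtype=str)
        return out
    return pd.DataFrame(rows).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 8
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of x vs y.

    Returns (W, p) where W is the rank sum of x (midranks for ties). Exact
    null enumeration of all C(n, m) rank assignments when both samples have
    <= ``exact_limit`` observations; otherwise the normal approximation with
    tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, k = len(x), len(y)
    if m == 0 or k == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    w_obs = float(ranks[:m].sum())
    n = m + k
    expected = m * (n + 1) / 2

    if m <= exact_limit and k <= exact_limit:
        dev = abs(w_obs - expected)
        total = math.comb(n, m)
        hits = 0
        for subset in itertools.combinations(range(n), m):
            w = ranks[list(subset)].sum()
            if abs(w - expected) >= dev - 1e-9:
                hits += 1
        return w_obs, hits / total

    _, counts = np.unique(combined, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    sigma2 = m * k / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return w_obs, 1.0
    z = (abs(w_obs - expected) - 0.5) / math.sqrt(sigma2)
    return w_obs, float(min(1.0, 2 * norm.sf(max(z, 0.0))))


def differential_binding(
    sites: pd.DataFrame,
    grouping: str = "all",
    min_group: int = 3,
    exact_limit: int = 8,
) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of AS vs GFP footprint scores per anchor.

    ``sites`` needs columns anchor_id, score_AS, score_GFP and, for
    ``grouping='by_class'``, class_label. Groups smaller than ``min_group``
    are reported untested (NaN p).

    Returns one row per (anchor_id[, class]): n_sites, statistic, p_value,
    median score difference (AS - GFP).
    """
    if grouping not in ("all", "by_class"):
        raise ValueError("grouping must be 'all' or 'by_class'")
    keys = ["anchor_id"] if grouping == "all" else ["anchor_id", "class_label"]
    rows = []
    for key, sub in sites.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        x = sub["score_AS"].to_numpy(dtype=float)
        y = sub["score_GFP"].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        rec = dict(zip(keys, key))
        rec["n_sites"] = len(x)
        rec["median_diff"] = float(np.median(x - y)) if len(x) else np.nan
        if len(x) >= min_group:
            w, p = wilcoxon_rank_sum(x, y, exact_limit=exact_limit)
            rec["statistic"], rec["p_value"], rec["tested"] = w, p, True
        else:
            rec["statistic"], rec["p_value"], rec["tested"] = np.nan, np.nan, False
        rows.append(rec)
    return pd.DataFrame(rows)
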