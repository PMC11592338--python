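"""Contact-matrix data model: binning, ICE balancing, merging, O/E, Pearson.

A :class:`SparseContactMatrix` holds one chromosome's cis contacts at a fixed
bin size, storing only the upper triangle (bin_i <= bin_j). Raw matrices hold
integer counts; ICE normalization produces real-valued matrices plus a
per-bin bias vector. Text I/O follows the HiC-Pro convention: a bin BED file
(chrom, start, end, 1-based bin id) and a sparse triplet file
(``binA  binB  count``).

Resolutions used by the pipeline are 10 Kb (loops, TADs) and 100 Kb
(compartments); :func:`coarsen` rebins 10 Kb counts to coarser grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SparseContactMatrix",
    "ExpectedProfile",
    "ice_normalize",
    "merge_replicates",
    "coarsen",
    "observed_expected",
    "pearson_matrix",
    "read_triplet",
    "write_triplet",
]


@dataclass
class SparseContactMatrix:
    """Symmetric per-chromosome binned contact matrix (upper triangle stored).

    Attributes
    ----------
    chrom : chromosome name
    bin_size_bp : bin width in bp
    n_bins : number of bins on the chromosome
    bin_i, bin_j : parallel arrays with bin_i <= bin_j
    values : counts (raw) or normalized contact values
    bias : per-bin ICE bias vector (NaN for masked bins), or None if raw
    """

    chrom: str
    bin_size_bp: int
    n_bins: int
    bin_i: np.ndarray
    bin_j: np.ndarray
    values: np.ndarray
    bias: np.ndarray | None = None
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        self.bin_i = np.asarray(self.bin_i, dtype=np.int64)
        self.bin_j = np.asarray(self.bin_j, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if not (len(self.bin_i) == len(self.bin_j) == len(self.values)):
            raise ValueError("bin_i, bin_j, values must have equal length")
        if np.any(self.bin_i > self.bin_j):
            raise ValueError("upper-triangle storage requires bin_i <= bin_j")
        if len(self.bin_j) and (self.bin_j.max() >= self.n_bins or self.bin_i.min() < 0):
            raise ValueError("bin indices outside chromosome")
        if np.any(self.values < 0):
            raise ValueError("contact values must be non-negative")

    @property
    def is_normalized(self) -> bool:
        return self.bias is not None

    def total(self) -> float:
        return float(self.values.sum())

    def toarray(self) -> np.ndarray:
        """Dense symmetric matrix (diagonal counted once)."""
        m = np.zeros((self.n_bins, self.n_bins))
        m[self.bin_i, self.bin_j] = self.values
        off = self.bin_i != self.bin_j
        m[self.bin_j[off], self.bin_i[off]] = self.values[off]
        return m

    @classmethod
    def from_dense(
        cls,
        dense: np.ndarray,
        chrom: str = "chr1",
        bin_size_bp: int = 10000,
        bias: np.ndarray | None = None,
        chrom_length: int | None = None,
    ) -> "SparseContactMatrix":
        dense = np.asarray(dense, dtype=float)
        if dense.ndim != 2 or dense.shape[0] != dense.shape[1]:
            raise ValueError("dense matrix must be square")
        iu, ju = np.triu_indices(dense.shape[0])
        vals = dense[iu, ju]
        keep = vals != 0
        return cls(
            chrom,
            bin_size_bp,
            dense.shape[0],
            iu[keep],
            ju[keep],
            vals[keep],
            bias=bias,
            chrom_length=chrom_length,
        )

    def bin_interval(self, b: int):
        from regulohub.intervals import GenomicInterval

        start = b * self.bin_size_bp
        end = start + self.bin_size_bp
        if self.chrom_length is not None:
            end = min(end, self.chrom_length)
        return GenomicInterval(self.chrom, start, end, name=f"bin{b}")


@dataclass
class ExpectedProfile:
    """Mean contact value per bin-distance d (NaN where no pair exists)."""

    bin_size_bp: int
    values: np.ndarray  # index = distance in bins

    def at(self, d: int) -> float:
        return float(self.values[d])


def _check_compatible(ms: Sequence[SparseContactMatrix]) -> None:
    first = ms[0]
    for m in ms[1:]:
        if m.chrom != first.chrom:
            raise ValueError(f"chromosome mismatch: {m.chrom} vs {first.chrom}")
        if m.bin_size_bp != first.bin_size_bp:
            raise ValueError(
                f"bin size mismatch: {m.bin_size_bp} vs {first.bin_size_bp}"
            )
        if m.n_bins != first.n_bins:
            raise ValueError("bin count mismatch")


def merge_replicates(ms: Sequence[SparseContactMatrix]) -> SparseContactMatrix:
    """Entrywise sum of raw replicate matrices.

    Merging precedes ICE when building condition-level matrices.
    """
    if not ms:
        raise ValueError("no matrices to merge")
    _check_compatible(ms)
    dense = ms[0].toarray()
    for m in ms[1:]:
        dense += m.toarray()
    return SparseContactMatrix.from_dense(
        dense, ms[0].chrom, ms[0].bin_size_bp, chrom_length=ms[0].chrom_length
    )


def coarsen(m: SparseContactMatrix, factor: int) -> SparseContactMatrix:
    """Aggregate counts into bins ``factor`` times wider (e.g. 10 Kb -> 100 Kb)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    ci = m.bin_i // factor
    cj = m.bin_j // factor
    n_coarse = int(np.ceil(m.n_bins / factor))
    dense = np.zeros((n_coarse, n_coarse))
    np.add.at(dense, (ci, cj), m.values)
    dense = np.triu(dense) + np.triu(dense, 1).T
    return SparseContactMatrix.from_dense(
        dense, m.chrom, m.bin_size_bp * factor, chrom_length=m.chrom_length
    )


def ice_normalize(
    m: SparseContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-6,
    mask_low_marginal_pct: float = 0.0,
) -> SparseContactMatrix:
    """Iterative correction (ICE) equalizing bin marginals.

    Repeats: compute row sums s of the current matrix over non-masked bins,
    update biases b_i <- b_i * s_i / mean(s), renormalize entries to
    raw_ij / (b_i b_j); stops when max |s_i/mean(s) - 1| < tol. Bins with a
    zero raw marginal (or below the ``mask_low_marginal_pct`` percentile of
    positive marginals) are masked: their bias is NaN and their rows are
    dropped. The total matrix sum is rescaled to the raw total afterwards.
    """
    if m.total() == 0:
        raise ValueError("empty matrix")
    dense = m.toarray()
    marginal = dense.sum(axis=1)
    masked = marginal == 0
    if mask_low_marginal_pct > 0:
        cutoff = np.percentile(marginal[~masked], mask_low_marginal_pct)
        masked |= marginal < cutoff
    active = ~masked
    if active.sum() < 2:
        raise ValueError("fewer than 2 non-empty bins")

    sub = dense[np.ix_(active, active)]
    b = np.ones(active.sum())
    for _ in range(max_iter):
        cur = sub / np.outer(b, b)
        s = cur.sum(axis=1)
        rel = s / s.mean()
        if np.abs(rel - 1).max() < tol:
            break
        b *= rel

    normalized = sub / np.outer(b, b)
    # restore to full size; masked rows/cols stay zero
    out = np.zeros_like(dense)
    out[np.ix_(active, active)] = normalized
    # recompute scale on the stored triangle so total() matches the raw total
    scm = SparseContactMatrix.from_dense(
        out, m.chrom, m.bin_size_bp, chrom_length=m.chrom_length
    )
    scm.values *= m.total() / scm.total()
    bias = np.full(m.n_bins, np.nan)
    bias[active] = b
    scm.bias = bias
    return scm


def observed_expected(
    m: SparseContactMatrix,
) -> tuple[np.ndarray, ExpectedProfile]:
    """Observed/expected transform of a normalized matrix.

    expected(d) = mean contact value over all non-masked bin pairs at
    bin-distance d (zero entries included); the O/E matrix divides each entry
    by its distance's expected value. Entries involving masked bins, or at
    distances whose expected value is 0, are NaN.
    """
    dense = m.toarray()
    masked = (
        np.isnan(m.bias) if m.bias is not None else dense.sum(axis=1) == 0
    )
    n = m.n_bins
    active = ~masked
    exp = np.full(n, np.nan)
    for d in range(n):
        i = np.arange(0, n - d)
        j = i + d
        ok = active[i] & active[j]
        if ok.any():
            exp[d] = dense[i[ok], j[ok]].mean()
    oe = np.full_like(dense, np.nan)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.abs(i - j)
    ed = exp[d]
    ok = np.outer(active, active) & (ed > 0)
    oe[ok] = dense[ok] / ed[ok]
    return oe, ExpectedProfile(m.bin_size_bp, exp)


def pearson_matrix(oe: np.ndarray) -> np.ndarray:
    """Pearson correlation of O/E rows over mutually non-masked columns.

    Entry (i, j) correlates rows i and j; diagonal is set to 1. Rows that are
    entirely NaN (masked bins) stay NaN. Requires >= 3 usable bins.
    """
    n = oe.shape[0]
    usable = ~np.all(np.isnan(oe), axis=1)
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable bins")
    sub = oe[np.ix_(usable, usable)]
    # O/E of a balanced matrix has no NaN inside the active block; guard anyway
    sub = np.where(np.isnan(sub), np.nanmean(sub, axis=0, keepdims=True), sub)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    np.fill_diagonal(corr, 1.0)
    out = np.full((n, n), np.nan)
    out[np.ix_(usable, usable)] = corr
    return out


# ---------------------------------------------------------------------------
# HiC-Pro-style text I/O


def write_triplet(
    m: SparseContactMatrix, matrix_path: str | Path, bed_path: str | Path | None = None
) -> None:
    """Write sparse triplets (1-based bin ids) and, optionally, the bin BED."""
    order = np.lexsort((m.bin_j, m.bin_i))
    with open(matrix_path, "w") as fh:
        for i, j, v in zip(m.bin_i[order], m.bin_j[order], m.values[order]):
            val = int(v) if float(v).is_integer() else v
            fh.write(f"{i + 1}\t{j + 1}\t{val}\n")
    if bed_path is not None:
        length = m.chrom_length or m.n_bins * m.bin_size_bp
        with open(bed_path, "w") as fh:
            for b in range(m.n_bins):
                start = b * m.bin_size_bp
                end = min(start + m.bin_size_bp, length)
                fh.write(f"{m.chrom}\t{start}\t{end}\t{b + 1}\n")


def read_triplet(
    matrix_path: str | Path, bed_path: str | Path
) -> SparseContactMatrix:
    """Read a HiC-Pro-style bin BED + sparse triplet pair (single chromosome)."""
    chroms, starts, ends, ids = [], [], [], []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise ValueError(f"{bed_path}: line {lineno}: need 4 columns")
            chroms.append(fields[0])
            starts.append(int(fields[1]))
            ends.append(int(fields[2]))
            ids.append(int(fields[3]))
    if len(set(chroms)) != 1:
        raise ValueError("bin BED must describe a single chromosome")
    bin_size = max(e - s for s, e in zip(starts, ends))
    id_to_bin = {bid: s // bin_size for bid, s in zip(ids, starts)}
    n_bins = len(ids)
    bi, bj, vals = [], [], []
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if len(fields) != 3:
                raise ValueError(f"{matrix_path}: line {lineno}: need 3 columns")
            a, b = id_to_bin[int(fields[0])], id_to_bin[int(fields[1])]
            if a > b:
                a, b = b, a
            bi.append(a)
            bj.append(b)
            vals.append(float(fields[2]))
    return SparseContactMatrix(
        chroms[0],
        bin_size,
        n_bins,
        np.array(bi, dtype=np.int64),
        np.array(bj, dtype=np.int64),
        np.array(vals),
        chrom_length=max(ends),
    )
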