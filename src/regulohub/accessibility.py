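"""Simplified differential chromatin accessibility at ATAC peaks.

A deliberately lightweight stand-in for consensus-peak differential testing
(DESeq2/limma class machinery): per peak, the same two-group negative-
binomial Wald test used for differential loops, with library-size offsets
and a pooled dispersion. A peak is differentially accessible when its
absolute linear fold change exceeds 1.5 and p < 0.05. Peaks are attached to
genes when they overlap the +/-3000 bp window around a TSS.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from regulohub.intervals import GenomicInterval, overlaps, promoter_from_tss
from regulohub.loops import estimate_pooled_dispersion, nb_two_group_wald

__all__ = ["differential_accessibility", "map_peaks_to_promoters"]


def differential_accessibility(
    counts: pd.DataFrame,
    conditions: tuple[str, str] = ("AS", "GFP"),
    fc_cut: float = 1.5,
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """NB Wald test per peak; significant iff |linear FC| > fc_cut and p < p_cut.

    ``counts`` needs chrom/start/end[/name] plus ``<cond>_rep<k>`` columns
    with >= 2 replicates per condition. Adds log2fc (positive = more
    accessible in the first condition), linear_fc = 2^|log2fc| as a
    fold-factor, p, and the significance flag. All-zero peaks are
    untestable (NaN statistics, not significant).
    """
    cond_a, cond_b = conditions
    cols_a = [c for c in counts.columns if c.startswith(f"{cond_a}_rep")]
    cols_b = [c for c in counts.columns if c.startswith(f"{cond_b}_rep")]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    mat = counts[cols_a + cols_b].to_numpy(dtype=float)
    libs = mat.sum(axis=0)
    libs = libs / libs.mean()
    groups = np.array([0] * len(cols_a) + [1] * len(cols_b))
    theta = estimate_pooled_dispersion(mat, libs, groups)

    n_a = len(cols_a)
    log2fc = np.full(len(counts), np.nan)
    pvals = np.full(len(counts), np.nan)
    for k in range(len(counts)):
        log2fc[k], pvals[k] = nb_two_group_wald(
            mat[k, :n_a], mat[k, n_a:], libs[:n_a], libs[n_a:], theta
        )
    out = counts.copy()
    out["log2fc"] = log2fc
    out["linear_fc"] = 2.0 ** np.abs(log2fc)
    out["p"] = pvals
    with np.errstate(invalid="ignore"):
        out["significant"] = (out["linear_fc"] > fc_cut) & (pvals < p_cut)
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out


def map_peaks_to_promoters(
    records: pd.DataFrame, tss_list: Sequence[GenomicInterval]
) -> pd.DataFrame:
    """Attach gene ids to peaks overlapping +/-3000 bp around a TSS.

    ``tss_list`` holds 1 bp TSS intervals whose name is the gene id and
    whose strand is the gene strand. A peak may map to several genes
    (comma-joined in ``promoter_gene_ids``).
    """
    windows = [
        promoter_from_tss(t.chrom, t.start, t.strand, "das_promoter", name=t.name)
        for t in tss_list
    ]
    ids = []
    for row in records.itertuples():
        peak = GenomicInterval(row.chrom, int(row.start), int(row.end))
        genes = sorted({w.name for w in windows if overlaps(peak, w)})
        ids.append(",".join(genes))
    out = records.copy()
    out["promoter_gene_ids"] = ids
    return out
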