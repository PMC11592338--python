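"""Significant chromatin-loop calling and differential classification.

The background model is a negative-binomial regression of bin-pair counts on
genomic distance, log mu = beta0 + beta1 * log(d); a bin pair is a
significant loop when its observed count is in the extreme right tail of
NB(mu(d), theta) after Benjamini-Hochberg control (q <= 0.05). Because the
dispersion theta is estimated from the same data, structural variation that
is not a loop (domain and compartment enrichment) widens the fitted NB and
is absorbed by the background rather than called.

Only cis pairs with 50 Kb <= distance <= 2 Mb enter testing: closer pairs
are dominated by proximity biases and farther ones by sparsity.

Differential testing compares the two conditions per significant loop with a
two-group NB Wald test on replicate counts with log library-size offsets
(positive log2FC = higher in AS). Significant loops are then partitioned:

* gained -- log2FC > 1 and p < 0.05
* lost   -- log2FC < -1 and p < 0.05
* static -- everything else (including untestable loops)

The thresholds are strict inequalities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.stats import nbinom, norm
from statsmodels.stats.multitest import multipletests

from regulohub.hic import SparseContactMatrix

__all__ = [
    "DEFAULT_MIN_DISTANCE_BP",
    "DEFAULT_MAX_DISTANCE_BP",
    "BackgroundFit",
    "build_pair_table",
    "fit_background",
    "loop_significance",
    "estimate_pooled_dispersion",
    "nb_two_group_wald",
    "differential_loops",
    "classify_loops",
    "call_loops",
    "write_bedpe",
]

DEFAULT_MIN_DISTANCE_BP = 50_000
DEFAULT_MAX_DISTANCE_BP = 2_000_000

_THETA_MAX = 1e6


@dataclass
class BackgroundFit:
    """Fitted NB distance background for one condition.

    mu(d) = exp(beta0 + beta1 * log(d_bins)); variance mu + mu^2/theta.
    """

    condition: str
    beta0: float
    beta1: float
    theta: float
    n_pairs: int

    def mu(self, distance_bins: np.ndarray) -> np.ndarray:
        return np.exp(self.beta0 + self.beta1 * np.log(distance_bins))


def build_pair_table(
    matrices: Mapping[tuple[str, int], SparseContactMatrix],
    min_distance_bp: int = DEFAULT_MIN_DISTANCE_BP,
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
) -> pd.DataFrame:
    """Tabulate every cis bin pair in the distance window, zeros included.

    ``matrices`` maps (condition, replicate) -> raw matrix (same chromosome
    and binning). Columns: chrom, bin_i, bin_j, distance_bp, and one
    ``count_<cond>_rep<k>`` per input matrix.
    """
    mats = list(matrices.values())
    if not mats:
        raise ValueError("no matrices given")
    first = mats[0]
    n, bs = first.n_bins, first.bin_size_bp
    for m in mats[1:]:
        if (m.n_bins, m.bin_size_bp, m.chrom) != (n, bs, first.chrom):
            raise ValueError("matrices must share chromosome and binning")

    dmin = max(1, -(-min_distance_bp // bs))
    dmax = max_distance_bp // bs
    ii, jj = [], []
    for d in range(dmin, dmax + 1):
        i = np.arange(0, n - d)
        ii.append(i)
        jj.append(i + d)
    bin_i = np.concatenate(ii)
    bin_j = np.concatenate(jj)
    table = pd.DataFrame(
        {
            "chrom": first.chrom,
            "bin_i": bin_i,
            "bin_j": bin_j,
            "distance_bp": (bin_j - bin_i) * bs,
        }
    )
    for (cond, rep), m in matrices.items():
        dense_lookup = np.zeros((n, n))
        dense_lookup[m.bin_i, m.bin_j] = m.values
        table[f"count_{cond}_rep{rep}"] = dense_lookup[bin_i, bin_j].astype(np.int64)
    return table


def _condition_columns(table: pd.DataFrame, condition: str) -> list[str]:
    cols = [c for c in table.columns if c.startswith(f"count_{condition}_rep")]
    if not cols:
        raise ValueError(f"no count columns for condition {condition!r}")
    return cols


def _theta_mom(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Method-of-moments dispersion from squared Pearson-style residuals."""
    excess = float((((y - mu) ** 2 - mu) / mu**2).sum())
    if excess <= 0:
        return _THETA_MAX
    return min(_THETA_MAX, max(1e-3, (len(y) - n_params) / excess))


def _theta_ml(y: np.ndarray, mu: np.ndarray, theta0: float) -> float:
    """One ML refinement of theta holding mu fixed."""

    def negll(log_theta: float) -> float:
        t = math.exp(log_theta)
        return -float(nbinom.logpmf(y, t, t / (t + mu)).sum())

    res = minimize_scalar(
        negll,
        bracket=(math.log(theta0) - 1.0, math.log(theta0) + 1.0),
        method="brent",
        options={"maxiter": 50},
    )
    theta = math.exp(res.x) if res.success or np.isfinite(res.fun) else theta0
    return float(min(_THETA_MAX, max(1e-3, theta)))


def fit_background(
    table: pd.DataFrame,
    condition: str,
    extra_covariates: Sequence[str] = (),
    max_iter: int = 50,
) -> BackgroundFit:
    """Fit the NB distance background to replicate-summed counts.

    A Poisson GLM seeds the mean model, theta comes from method of moments
    on its residuals, the mean model is refit as an NB GLM at that theta,
    and theta is refined by maximum likelihood at the final means.
    ``extra_covariates`` names additional columns to include in the design.
    """
    bs = int(table["distance_bp"].iloc[0] // (table["bin_j"] - table["bin_i"]).iloc[0])
    d_bins = (table["distance_bp"] / bs).to_numpy(dtype=float)
    y = table[_condition_columns(table, condition)].sum(axis=1).to_numpy(dtype=float)
    if len(y) < 100 or len(np.unique(d_bins)) < 10:
        raise ValueError("need >= 100 bin pairs spanning >= 10 distinct distances")

    X = np.column_stack(
        [np.ones_like(d_bins), np.log(d_bins)]
        + [table[c].to_numpy(dtype=float) for c in extra_covariates]
    )
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=max_iter)
        mu0 = np.clip(pois.fittedvalues, 1e-8, None)
        theta = _theta_mom(y, mu0, X.shape[1])
        nb = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta)
        ).fit(maxiter=max_iter)
        params = nb.params
        mu = np.clip(nb.fittedvalues, 1e-8, None)
    except Exception as err:  # statsmodels raises on IRLS breakdown
        raise RuntimeError(
            f"NB background fit failed for condition {condition!r}: {err}"
        ) from err
    theta = _theta_ml(y.astype(np.int64), mu, theta)
    if not np.all(np.isfinite(params)):
        raise RuntimeError(
            f"non-finite background parameters for condition {condition!r}: {params}"
        )
    return BackgroundFit(condition, float(params[0]), float(params[1]), theta, len(y))


def loop_significance(
    table: pd.DataFrame, fit: BackgroundFit, condition: str | None = None
) -> pd.DataFrame:
    """Right-tail NB p-values and BH q-values for every tabulated pair.

    p = P(Y >= y_obs) under NB(mu(d), theta); the table must already be
    restricted to the tested distance window (build_pair_table does this).
    """
    condition = condition or fit.condition
    out = table.copy()
    bs = int(table["distance_bp"].iloc[0] // (table["bin_j"] - table["bin_i"]).iloc[0])
    d_bins = (out["distance_bp"] / bs).to_numpy(dtype=float)
    y = out[_condition_columns(out, condition)].sum(axis=1).to_numpy(dtype=np.int64)
    mu = fit.mu(d_bins)
    p_nb = fit.theta / (fit.theta + mu)
    pvals = nbinom.sf(y - 1, fit.theta, p_nb)
    out[f"mu_{condition}"] = mu
    out[f"p_{condition}"] = pvals
    out[f"q_{condition}"] = multipletests(pvals, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# differential testing


def estimate_pooled_dispersion(
    counts: np.ndarray, libsizes: np.ndarray, groups: np.ndarray
) -> float:
    """Pooled MoM dispersion across loops given per-group rate estimates.

    ``counts`` is loops x samples, ``libsizes`` per sample, ``groups`` a
    label per sample; each loop contributes residuals around its per-group
    rate * libsize means.
    """
    mus = np.empty_like(counts, dtype=float)
    for g in np.unique(groups):
        sel = groups == g
        rate = counts[:, sel].sum(axis=1) / libsizes[sel].sum()
        mus[:, sel] = rate[:, None] * libsizes[sel][None, :]
    ok = mus > 0
    excess = float((((counts - mus) ** 2 - mus)[ok] / mus[ok] ** 2).sum())
    df = int(ok.sum()) - 2 * counts.shape[0]
    if excess <= 0 or df <= 0:
        return _THETA_MAX
    return min(_THETA_MAX, max(1e-3, df / excess))


def nb_two_group_wald(
    y_a: np.ndarray,
    y_b: np.ndarray,
    s_a: np.ndarray,
    s_b: np.ndarray,
    theta: float,
) -> tuple[float, float]:
    """Closed-form NB Wald test of group A vs group B rates with offsets.

    The two-group NB GLM with log link and log-libsize offsets has MLE
    rate_g = sum(y_g) / sum(s_g); the test statistic uses the Fisher
    information I_g = sum_i mu_gi * theta / (theta + mu_gi). Returns
    (log2 fold change A/B, two-sided Wald p). When one group is all zero a
    half-count is added to both group totals so the estimate stays finite.
    """
    tot_a, tot_b = float(y_a.sum()), float(y_b.sum())
    S_a, S_b = float(s_a.sum()), float(s_b.sum())
    if tot_a + tot_b == 0:
        return np.nan, np.nan
    if tot_a == 0 or tot_b == 0:
        tot_a += 0.5
        tot_b += 0.5
    rate_a, rate_b = tot_a / S_a, tot_b / S_b
    beta = math.log(rate_a / rate_b)
    mu_a = rate_a * s_a
    mu_b = rate_b * s_b
    info_a = float((mu_a * theta / (theta + mu_a)).sum())
    info_b = float((mu_b * theta / (theta + mu_b)).sum())
    se = math.sqrt(1.0 / info_a + 1.0 / info_b)
    z = beta / se
    p = float(min(1.0, 2 * norm.sf(abs(z))))
    return beta / math.log(2), p


def differential_loops(
    table: pd.DataFrame,
    conditions: tuple[str, str] = ("AS", "GFP"),
    libsizes: Mapping[str, float] | None = None,
    theta: float | None = None,
) -> pd.DataFrame:
    """Per-loop differential test between conditions on replicate counts.

    Adds log2fc (positive = higher in the first condition) and diff_p.
    Library sizes default to each replicate column's total over the table;
    the NB dispersion defaults to a pooled MoM estimate across loops. Loops
    with zero counts in every replicate of both conditions are untestable
    (NaN log2fc and diff_p, ``testable`` False).
    """
    cond_a, cond_b = conditions
    cols_a = _condition_columns(table, cond_a)
    cols_b = _condition_columns(table, cond_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per condition")
    counts = table[cols_a + cols_b].to_numpy(dtype=float)
    if libsizes is None:
        libs = counts.sum(axis=0)
    else:
        libs = np.array([libsizes[c] for c in cols_a + cols_b], dtype=float)
    libs = libs / libs.mean()  # relative library sizes
    groups = np.array([0] * len(cols_a) + [1] * len(cols_b))
    if theta is None:
        theta = estimate_pooled_dispersion(counts, libs, groups)

    n_a = len(cols_a)
    out = table.copy()
    log2fc = np.full(len(table), np.nan)
    diff_p = np.full(len(table), np.nan)
    for k in range(len(table)):
        fc, p = nb_two_group_wald(
            counts[k, :n_a], counts[k, n_a:], libs[:n_a], libs[n_a:], theta
        )
        log2fc[k], diff_p[k] = fc, p
    out["log2fc"] = log2fc
    out["diff_p"] = diff_p
    out["testable"] = ~np.isnan(diff_p)
    return out


def classify_loops(
    table: pd.DataFrame, log2fc_cut: float = 1.0, p_cut: float = 0.05
) -> pd.DataFrame:
    """Partition significant loops into static / gained / lost.

    gained: log2fc > cut and diff_p < p_cut; lost: log2fc < -cut and
    diff_p < p_cut; static otherwise (untestable loops are static). Strict
    inequalities throughout.
    """
    out = table.copy()
    lfc = out["log2fc"].to_numpy(dtype=float)
    p = out["diff_p"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        gained = (lfc > log2fc_cut) & (p < p_cut)
        lost = (lfc < -log2fc_cut) & (p < p_cut)
    category = np.where(gained, "gained", np.where(lost, "lost", "static"))
    out["category"] = category
    return out


def call_loops(
    matrices: Mapping[tuple[str, int], SparseContactMatrix],
    conditions: tuple[str, str] = ("AS", "GFP"),
    q_cut: float = 0.05,
    min_distance_bp: int = DEFAULT_MIN_DISTANCE_BP,
    max_distance_bp: int = DEFAULT_MAX_DISTANCE_BP,
    mode: str = "per_condition",
) -> pd.DataFrame:
    """End-to-end loop calling: background fits, significance, differential.

    ``mode='per_condition'`` (default) calls significance on each
    condition's replicate-summed counts and takes the union of loops with
    q <= q_cut in either condition; ``mode='pooled'`` sums all replicates
    of both conditions into one test. Differential classification then runs
    on the significant set.

    Returns the full pair table with per-condition p/q columns, a
    ``significant`` flag, and (on significant rows) log2fc/diff_p/category.
    """
    table = build_pair_table(matrices, min_distance_bp, max_distance_bp)
    if mode == "per_condition":
        sig = np.zeros(len(table), dtype=bool)
        for cond in conditions:
            fit = fit_background(table, cond)
            table = loop_significance(table, fit, cond)
            sig |= table[f"q_{cond}"].to_numpy() <= q_cut
    elif mode == "pooled":
        pooled = table.copy()
        pooled["count_pooled_rep1"] = table[
            [c for c in table.columns if c.startswith("count_")]
        ].sum(axis=1)
        fit = fit_background(pooled, "pooled")
        scored = loop_significance(pooled, fit, "pooled")
        for col in ("mu_pooled", "p_pooled", "q_pooled"):
            table[col] = scored[col]
        sig = table["q_pooled"].to_numpy() <= q_cut
    else:
        raise ValueError("mode must be 'per_condition' or 'pooled'")
    table["significant"] = sig

    sig_table = table.loc[sig].copy()
    if len(sig_table):
        libs = {
            c: float(table[c].sum())
            for c in table.columns
            if c.startswith("count_")
        }
        sig_table = differential_loops(sig_table, conditions, libsizes=libs)
        sig_table = classify_loops(sig_table)
        table["log2fc"] = np.nan
        table["diff_p"] = np.nan
        table["testable"] = False
        table["category"] = ""
        for col in ("log2fc", "diff_p", "testable", "category"):
            table.loc[sig_table.index, col] = sig_table[col].to_numpy()
    else:
        table["log2fc"] = np.nan
        table["diff_p"] = np.nan
        table["testable"] = False
        table["category"] = ""
    return table


def write_bedpe(loops: pd.DataFrame, path: str | Path, bin_size_bp: int) -> None:
    """Write significant loops as BEDPE with statistics columns."""
    sig = loops.loc[loops["significant"]].copy()
    sig["start1"] = sig["bin_i"] * bin_size_bp
    sig["end1"] = sig["start1"] + bin_size_bp
    sig["start2"] = sig["bin_j"] * bin_size_bp
    sig["end2"] = sig["start2"] + bin_size_bp
    stat_cols = [
        c
        for c in sig.columns
        if c.startswith(("count_", "p_", "q_", "mu_")) or c in ("log2fc", "diff_p", "category")
    ]
    header = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"] + stat_cols
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(header) + "\n")
        for _, row in sig.iterrows():
            fields = [
                row["chrom"],
                row["start1"],
                row["end1"],
                row["chrom"],
                row["start2"],
                row["end2"],
            ] + [row[c] for c in stat_cols]
            fh.write("\t".join(str(f) for f in fields) + "\n")
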