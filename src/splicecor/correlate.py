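"""Correlate exon inclusion and gene expression with pathway activity per cohort.

One record is produced per (target, cohort): Pearson r, a two-sided
p-value from the t distribution with n-2 degrees of freedom, and a
Benjamini-Hochberg adjusted p computed within each cohort. Missing PSI
is handled by pairwise deletion, never imputation. Records with fewer
than ``min_n`` pairs (default 10) or zero variance keep their r (when
computable) but have p and p_adj withheld and are flagged unevaluable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    ActivityScoreVector,
    NormalizedExpression,
    PsiMatrix,
    SampleMetadata,
    SpliceCorError,
)

__all__ = [
    "pearson_r_p",
    "bh_adjust",
    "correlate_psi_with_activity",
    "correlate_expression_with_activity",
    "permutation_pvalue",
    "plot_correlation",
]

#: minimum paired observations for an evaluable p-value
MIN_N_DEFAULT = 10


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson r and two-sided p; (nan, nan) when either vector is constant.

    Pairs with a missing value in either vector are deleted. Requires at
    least 3 complete pairs. |r| = 1 gives p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise SpliceCorError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise SpliceCorError(f"need >= 3 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise SpliceCorError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _correlate_matrix(
    ids,
    values: np.ndarray,
    scores: ActivityScoreVector,
    meta: SampleMetadata,
    value_samples,
    min_n: int,
) -> pd.DataFrame:
    score_s = scores.to_series()
    shared = [s for s in value_samples if s in score_s.index and s in meta.table.index]
    if not shared:
        raise SpliceCorError("no shared samples between values and activity scores")
    col_idx = [list(value_samples).index(s) for s in shared]
    vals = values[:, col_idx]
    sc = score_s.loc[shared].to_numpy()
    cohorts = meta.table.loc[shared, "cohort"].to_numpy()

    rows = []
    for cohort in pd.unique(cohorts):
        cmask = cohorts == cohort
        v_c = vals[:, cmask]
        s_c = sc[cmask]
        for i, tid in enumerate(ids):
            xi = v_c[i]
            ok = np.isfinite(xi) & np.isfinite(s_c)
            n = int(ok.sum())
            r = p = np.nan
            evaluable = n >= max(min_n, 3)
            if n >= 3 and np.ptp(xi[ok]) > 0 and np.ptp(s_c[ok]) > 0:
                res = stats.pearsonr(xi[ok], s_c[ok])
                r, p = float(res.statistic), float(res.pvalue)
            else:
                evaluable = False
            if not evaluable:
                p = np.nan
            rows.append((tid, cohort, n, r, p, evaluable))

    df = pd.DataFrame(rows, columns=["target_id", "cohort", "n", "r", "p_value", "evaluable"])
    df["p_adj"] = np.nan
    for cohort in df["cohort"].unique():
        m = (df["cohort"] == cohort) & df["evaluable"]
        if m.any():
            df.loc[m, "p_adj"] = bh_adjust(df.loc[m, "p_value"].to_numpy())
    df["direction"] = np.sign(df["r"]).fillna(0).astype(int)
    return df


def correlate_psi_with_activity(
    psi: PsiMatrix,
    scores: ActivityScoreVector,
    meta: SampleMetadata,
    min_n: int = MIN_N_DEFAULT,
) -> pd.DataFrame:
    """Per-cohort Pearson correlation of each event's PSI with the activity score.

    BH adjustment is applied independently within each cohort across its
    evaluable events (the cohort is the multiple-testing family).
    """
    return _correlate_matrix(psi.event_ids, psi.psi, scores, meta, psi.sample_ids, min_n)


def correlate_expression_with_activity(
    expr: NormalizedExpression,
    gene_list,
    scores: ActivityScoreVector,
    meta: SampleMetadata,
    min_n: int = MIN_N_DEFAULT,
) -> pd.DataFrame:
    """Per-cohort correlation of normalized gene expression with the activity score."""
    gene_list = list(gene_list)
    missing = [g for g in gene_list if g not in expr.gene_ids]
    if missing:
        raise SpliceCorError(f"genes absent from expression matrix: {missing[:5]}")
    idx = [expr.gene_ids.index(g) for g in gene_list]
    return _correlate_matrix(gene_list, expr.values[idx], scores, meta, expr.sample_ids, min_n)


def permutation_pvalue(x, y, B: int = 1000, seed: int = 0) -> float:
    """Empirical two-sided p for Pearson r by permuting y.

    p = (1 + #{|r_perm| >= |r_obs|}) / (B + 1), the standard add-one
    estimator that never returns zero.
    """
    if B < 100:
        raise SpliceCorError("B must be >= 100")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    r_obs, _ = pearson_r_p(x, y)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    n = x.size
    hits = 0
    for _ in range(B):
        perm = rng.permutation(yc)
        r = float(xc @ perm) / n
        if abs(r) >= abs(r_obs) - 1e-12:
            hits += 1
    return (1 + hits) / (B + 1)


def plot_correlation(x, y, ax=None, xlabel="activity score", ylabel="PSI"):
    """Basic scatter of a target against the activity score with the fit line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    ax.scatter(x[ok], y[ok], s=8, alpha=0.6)
    if ok.sum() >= 3 and np.ptp(x[ok]) > 0:
        b, a = np.polyfit(x[ok], y[ok], 1)
        xs = np.linspace(x[ok].min(), x[ok].max(), 10)
        ax.plot(xs, a + b * xs, color="C3")
        r, p = pearson_r_p(x, y)
        ax.set_title(f"r = {r:.3f}, p = {p:.2e}", fontsize=9)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    return ax
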