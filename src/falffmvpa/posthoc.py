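"""Post-hoc statistics: pre/post change, partial correlation, demographics.

After the prediction model is chosen, its clusters are examined
classically: a paired t-test on the treated subjects' mean z-fALFF before
and after treatment in each cluster, and a partial correlation between the
fALFF change and the clinical outcome (attack-frequency reduction)
controlling for age, sex and the anxiety/depression/quality-of-life scores,
FDR-corrected across clusters.  Demographic group comparisons are available
from summary statistics alone (two-sample t from mean/SD/n; 2x2 chi-square
for sex counts), which is how cohort characteristic tables are checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .screening import bh_fdr

__all__ = [
    "RegionChange",
    "paired_t",
    "partial_correlation",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "region_change_table",
]


@dataclass
class RegionChange:
    region: str
    paired_t: float
    p: float
    partial_r: float
    partial_p: float
    p_fdr_selected: bool = False


def paired_t(pre, post):
    """Classical paired t-test on post - pre differences (df = n - 1)."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be 1D arrays of equal length")
    if pre.size < 3:
        raise ValueError("need >= 3 pairs")
    d = post - pre
    if np.allclose(d, d[0]) and d.std(ddof=1) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        raise ValueError("zero-variance differences; paired t undefined")
    res = stats.ttest_rel(post, pre)
    return float(res.statistic), float(res.pvalue)


def partial_correlation(x, y, covariates=None):
    """Pearson correlation of x and y after removing covariate effects.

    Both variables are residualised on [intercept, covariates] by least
    squares; the p-value uses t = r * sqrt(df / (1 - r^2)) with
    df = n - 2 - #covariates (scipy's plain Pearson p would overstate the
    degrees of freedom).  With no covariates this is the ordinary Pearson
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValueError("covariates must have one row per observation")
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > #covariates + 2 (n={n}, covariates={k})")
    D = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("collinear covariates")
    proj = D @ np.linalg.lstsq(D, np.column_stack([x, y]), rcond=None)[0]
    rx, ry = x - proj[:, 0], y - proj[:, 1]
    # a variable fully explained by the covariates has no partial association
    tol_x = 1e-10 * max(x.std(), 1e-300)
    tol_y = 1e-10 * max(y.std(), 1e-300)
    if rx.std() <= tol_x or ry.std() <= tol_y:
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_c = min(max(r, -1.0), 1.0)
    if abs(r_c) >= 1.0:
        return r_c, 0.0
    t = r_c * np.sqrt(df / (1.0 - r_c**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def two_sample_t_from_summary(mean1, sd1, n1, mean2, sd2, n2, equal_var: bool = True):
    """Two-sample t-test from group summaries (pooled by default)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(a, b, c, d):
    """Pearson chi-square (no continuity correction, df = 1) for a 2x2 table.

    Rows are groups, columns the two category levels, e.g. male/female
    counts per group.
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def region_change_table(region_pre, region_post, outcome, covariates, q: float = 0.05):
    """Paired change + partial-correlation summary per region, FDR across regions.

    ``region_pre`` / ``region_post`` map region name -> per-subject mean
    z-fALFF arrays (same treated subjects, same order); ``outcome`` is the
    attack-frequency reduction; ``covariates`` the nuisance matrix (age,
    sex, SAS, SDS, MSQ).  FDR is applied to the partial-correlation
    p-values across regions.
    """
    names = list(region_pre)
    if set(names) != set(region_post):
        raise ValueError("pre and post must cover the same regions")
    rows = []
    pvals = []
    for name in names:
        t, p = paired_t(region_pre[name], region_post[name])
        change = np.asarray(region_post[name], float) - np.asarray(region_pre[name], float)
        r, pp = partial_correlation(change, outcome, covariates)
        rows.append(RegionChange(region=name, paired_t=t, p=p, partial_r=r, partial_p=pp))
        pvals.append(pp)
    _, selected = bh_fdr(pvals, q)
    for row, sel in zip(rows, selected):
        row.p_fdr_selected = bool(sel)
    return rows
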