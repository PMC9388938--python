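"""Voxelwise covariate-adjusted group comparison with FDR control.

Candidate features for the classifier are voxels whose z-fALFF differs
between patients and controls in a two-sample comparison adjusted for age,
sex and head motion.  The adjustment is a per-voxel linear model

    z-fALFF = intercept + b * group + c' * covariates + error

whose group-coefficient t statistic (df = n - 2 - #covariates) reduces to
the classical pooled two-sample t when no covariates are given.  Multiple
testing across voxels is controlled with the Benjamini-Hochberg step-up
rule at q = 0.05.

Two screening modes exist: ``whole_sample`` screens once on all subjects
(the procedure the original workflow describes) and ``per_fold`` recomputes
the screen inside every training fold of the cross-validation so that the
held-out subject never influences feature selection.  ``per_fold`` is the
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import FeatureMatrix

__all__ = ["ScreeningResult", "build_feature_matrix", "voxelwise_group_test", "bh_fdr"]


@dataclass
class ScreeningResult:
    """Per-voxel statistics of the adjusted group comparison."""

    t_stat: np.ndarray
    p_raw: np.ndarray
    p_fdr_threshold: float
    selected: np.ndarray  # boolean per voxel
    mode: str = "whole_sample"

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def build_feature_matrix(falff_maps, phenotype) -> FeatureMatrix:
    """Stack per-subject z-fALFF maps into a subjects x voxels matrix.

    All maps must share one mask; column order follows ``np.argwhere`` of
    the mask so it is reproducible and matches ``voxel_index``.
    """
    if len(falff_maps) != len(phenotype):
        raise ValueError("number of maps must match phenotype rows")
    mask = falff_maps[0].mask
    for m in falff_maps[1:]:
        if not np.array_equal(m.mask, mask):
            raise ValueError("all fALFF maps must share the same mask")
    X = np.vstack([m.masked_z for m in falff_maps])
    return FeatureMatrix(
        X=X, voxel_index=np.argwhere(mask), phenotype=phenotype.reset_index(drop=True)
    )


def group_t_matrix(
    X: np.ndarray, labels: np.ndarray, covariates: np.ndarray | None = None
):
    """Vectorised group-coefficient t statistic for every column of X.

    ``labels`` are binary (1 = patient).  Returns ``(t, p)`` arrays.  A
    column with zero residual variance gets t = 0, p = 1 by convention.
    """
    labels = np.asarray(labels, dtype=float)
    n = X.shape[0]
    if covariates is None or covariates.size == 0:
        covariates = np.empty((n, 0))
    if len(np.unique(labels)) < 2:
        raise ValueError("both groups must be present")
    D = np.column_stack([np.ones(n), labels, covariates])
    p_reg = D.shape[1]
    if np.linalg.matrix_rank(D) < p_reg:
        raise ValueError("collinear covariates in the screening design")
    if n < p_reg + 1:
        raise ValueError(f"need more subjects than regressors ({n} <= {p_reg})")
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ (D.T @ X)  # (p_reg, n_vox)
    resid = X - D @ beta
    df = n - p_reg
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 0.0))
    t = np.zeros(X.shape[1])
    nz = se > 0
    t[nz] = beta[1, nz] / se[nz]
    p = np.ones(X.shape[1])
    p[nz] = 2.0 * stats.t.sf(np.abs(t[nz]), df)
    return t, p


def voxelwise_group_test(
    features: FeatureMatrix,
    covariates=("age", "sex", "head_motion"),
    q: float = 0.05,
    mode: str = "whole_sample",
) -> ScreeningResult:
    """Adjusted two-sample comparison of every voxel, BH-corrected at ``q``.

    ``covariates`` names phenotype columns (empty tuple/None for the plain
    two-sample t).  Each group needs at least 3 subjects.
    """
    labels = features.group_labels()
    if min(labels.sum(), (1 - labels).sum()) < 3:
        raise ValueError("each group needs >= 3 subjects")
    C = features.covariate_matrix(covariates) if covariates else None
    t, p = group_t_matrix(features.X, labels, C)
    threshold, selected = bh_fdr(p, q)
    return ScreeningResult(
        t_stat=t, p_raw=p, p_fdr_threshold=threshold, selected=selected, mode=mode
    )


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up selection.

    Returns ``(threshold, selected)``: the largest p(i) with
    p(i) <= i*q/m (0.0 if none), and the boolean selection mask
    (p <= threshold).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    m = p.size
    order = np.sort(p)
    crit = np.arange(1, m + 1) * q / m
    ok = order <= crit
    if not ok.any():
        return 0.0, np.zeros(m, dtype=bool)
    threshold = float(order[np.nonzero(ok)[0].max()])
    return threshold, p <= threshold
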