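"""Study 2: SVR prediction of treatment response from discriminative voxels.

The treated patients' reduction in monthly attack frequency is predicted
from their baseline z-fALFF restricted to the discriminative voxel set
found in Study 1 (chain integrity is asserted: no column outside that mask
may enter).  Within each leave-one-out fold the nuisance covariates (age,
sex, head motion) are regressed out of the features — coefficients fitted
on the training fold and applied to the held-out subject — then a linear
support vector regression (C = 1, epsilon = 0.1) is fitted on all mask
features, the features are ranked by absolute SVR weight, and the model is
refitted on the top k for each k in the grid.  Performance is the Pearson
correlation between out-of-fold predictions and actual reductions, as a
curve over k; the best model maximises that curve.  Significance comes from
re-running the whole procedure under outcome permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVR

from .classify import PermutationNull, permutation_test
from .types import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["SVRConfig", "PredictionResult", "loocv_predict", "predict_permutation"]


@dataclass
class SVRConfig:
    C: float = 1.0
    epsilon: float = 0.1
    covariates: tuple = ("age", "sex", "head_motion")


@dataclass
class PredictionResult:
    k_grid: np.ndarray
    r_curve: np.ndarray
    best_k: int
    oof_predicted: np.ndarray  # (n_subjects, n_k)
    actual: np.ndarray
    weight_map: np.ndarray  # over the columns of the input FeatureMatrix

    @property
    def best_r(self) -> float:
        return float(np.nanmax(self.r_curve))

    @property
    def best_predictions(self) -> np.ndarray:
        return self.oof_predicted[:, int(np.nanargmax(self.r_curve))]


def _safe_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _residualize(train_F, test_f, train_C, test_c):
    """Remove covariate effects fitted on the training fold only."""
    D_tr = np.column_stack([np.ones(len(train_C)), train_C])
    beta, *_ = np.linalg.lstsq(D_tr, train_F, rcond=None)
    d_te = np.concatenate([[1.0], test_c])
    return train_F - D_tr @ beta, test_f - d_te @ beta


def loocv_predict(
    features: FeatureMatrix,
    outcome: np.ndarray,
    mask: np.ndarray | None = None,
    k_grid=None,
    config: SVRConfig | None = None,
) -> PredictionResult:
    """LOOCV weight-ranked SVR search over feature counts.

    ``features`` rows are the treated subjects; ``outcome`` their actual
    attack-frequency reductions.  ``mask`` is the boolean discriminative
    voxel mask from Study 1 over the columns of ``features`` (None = all
    columns, for standalone use).  Returns the r-over-k curve and the mean
    fold weight map at the best k, expanded over the input columns.
    """
    cfg = config or SVRConfig()
    outcome = np.asarray(outcome, dtype=float)
    n = features.n_subjects
    if len(outcome) != n:
        raise ValueError("outcome length must match number of subjects")
    if n < 6:
        raise ValueError("need >= 6 treated subjects for LOOCV")
    if outcome.std() == 0:
        raise ValueError("outcome has zero variance")

    if mask is None:
        cols_mask = np.ones(features.n_voxels, dtype=bool)
    else:
        cols_mask = np.asarray(mask, dtype=bool)
        if cols_mask.shape != (features.n_voxels,):
            raise ValueError("mask must be boolean over feature columns")
    mask_cols = np.flatnonzero(cols_mask)
    if mask_cols.size == 0:
        raise ValueError("discriminative mask is empty")
    X = features.X[:, mask_cols]
    # chain integrity: everything the SVR sees comes from the Study-1 mask
    assert X.shape[1] == int(cols_mask.sum())

    Cv = features.covariate_matrix(cfg.covariates) if cfg.covariates else np.empty((n, 0))
    n_feat = X.shape[1]
    if k_grid is None:
        step = 10 if n_feat > 100 else 1
        k_grid = np.unique(np.r_[np.arange(step, n_feat + 1, step), n_feat])
    k_grid = np.asarray(k_grid, dtype=int)
    k_grid = k_grid[(k_grid >= 1) & (k_grid <= n_feat)]
    if k_grid.size == 0:
        raise ValueError("k_grid has no feasible feature counts")
    n_k = len(k_grid)

    oof = np.zeros((n, n_k))
    fold_weights: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for i in range(n):
        tr = np.arange(n) != i
        F_tr, f_te = X[tr], X[i]
        if Cv.shape[1]:
            F_tr, f_te = _residualize(F_tr, f_te, Cv[tr], Cv[i])
        mu, sd = F_tr.mean(axis=0), F_tr.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        F_std = (F_tr - mu) / sd
        f_std = (f_te - mu) / sd
        y_tr = outcome[tr]
        full = SVR(kernel="linear", C=cfg.C, epsilon=cfg.epsilon)
        full.fit(F_std, y_tr)
        rank = np.argsort(-np.abs(full.coef_.ravel()), kind="stable")
        per_k = []
        for j, k in enumerate(k_grid):
            top = rank[:k]
            mdl = SVR(kernel="linear", C=cfg.C, epsilon=cfg.epsilon)
            mdl.fit(F_std[:, top], y_tr)
            oof[i, j] = float(mdl.predict(f_std[top][None, :])[0])
            per_k.append((mask_cols[top], mdl.coef_.ravel() / sd[top]))
        fold_weights.append(per_k)

    r_curve = np.array([_safe_pearson(oof[:, j], outcome) for j in range(n_k)])
    best_j = int(np.flatnonzero(r_curve == r_curve.max())[0])

    weight_map = np.zeros(features.n_voxels)
    for per_k in fold_weights:
        cols_j, w_j = per_k[best_j]
        weight_map[cols_j] += w_j
    weight_map /= n

    return PredictionResult(
        k_grid=k_grid,
        r_curve=r_curve,
        best_k=int(k_grid[best_j]),
        oof_predicted=oof,
        actual=outcome,
        weight_map=weight_map,
    )


def predict_permutation(
    features: FeatureMatrix,
    outcome: np.ndarray,
    mask: np.ndarray | None = None,
    k_grid=None,
    config: SVRConfig | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    observed: float | None = None,
) -> PermutationNull:
    """Outcome-permutation null for the best out-of-fold correlation.

    Each permutation re-runs the full LOOCV weight-ranking search on the
    shuffled outcome and records its best r.
    """

    def stat(y):
        return loocv_predict(features, y, mask=mask, k_grid=k_grid, config=config).best_r

    return permutation_test(
        stat,
        np.asarray(outcome, dtype=float),
        n_perm=n_perm,
        seed=seed,
        statistic_name="oof_pearson_r",
        observed=observed,
    )
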