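"""Study 1: LOOCV linear-SVM discrimination of patients from controls.

Each subject is held out once.  Inside every training fold the candidate
voxels are screened (covariate-adjusted group t + FDR; per-fold by default
so the held-out subject never touches feature selection), the survivors are
ranked by F-score, and for an increasing number of top-ranked features k a
linear soft-margin SVM (C = 1 by default) is trained on the standardised
training fold and applied to the held-out subject.  Aggregating the
out-of-fold predictions gives an accuracy / sensitivity / specificity curve
over k; the best classifier is the smallest k attaining maximal accuracy,
with AUC computed from the out-of-fold decision values at that k.

Significance is assessed non-parametrically: the entire cross-validated
procedure (including per-fold screening and ranking) is re-run under random
label permutations, and the empirical p-value uses the add-one rule
p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .types import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SVMConfig",
    "CVResult",
    "PermutationNull",
    "f_score",
    "f_score_matrix",
    "loocv_classify",
    "permutation_test",
    "classification_metrics",
    "default_k_grid",
]


@dataclass
class SVMConfig:
    C: float = 1.0
    screening_mode: str = "per_fold"  # or "whole_sample"
    covariates: tuple = ("age", "sex", "head_motion")
    q: float = 0.05


@dataclass
class PermutationNull:
    """Null distribution of a statistic under label permutation."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_perm: int
    p_value: float


@dataclass
class CVResult:
    """Outcome of the LOOCV feature-count search."""

    k_grid: np.ndarray
    accuracy_curve: np.ndarray
    sensitivity_curve: np.ndarray
    specificity_curve: np.ndarray
    auc: float
    best_k: int
    oof_labels: np.ndarray  # true labels (1 = patient)
    oof_predictions: np.ndarray  # (n_subjects, n_k) predicted labels
    oof_decision: np.ndarray  # (n_subjects, n_k) decision values
    weight_map: np.ndarray  # per-voxel mean fold weight at best_k

    @property
    def best_accuracy(self) -> float:
        return float(self.accuracy_curve[int(np.argmax(self.accuracy_curve))])

    @property
    def discriminative_mask(self) -> np.ndarray:
        """Voxels carrying nonzero mean weight at best_k (the Study-1 mask)."""
        return self.weight_map != 0


def f_score_matrix(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher-style F-score of every column for a binary split.

    F = [(mean+ - mean)^2 + (mean- - mean)^2] / (var+ + var-) with unbiased
    within-class variances.  Constant features score 0; zero within-class
    variance with distinct means scores +inf.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("need both classes to compute an F-score")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each class needs >= 2 subjects")
    Xp, Xm = X[labels], X[~labels]
    grand = X.mean(axis=0)
    num = (Xp.mean(axis=0) - grand) ** 2 + (Xm.mean(axis=0) - grand) ** 2
    denom = Xp.var(axis=0, ddof=1) + Xm.var(axis=0, ddof=1)
    out = np.zeros(X.shape[1])
    nz = denom > 0
    out[nz] = num[nz] / denom[nz]
    degen = (~nz) & (num > 0)
    out[degen] = np.inf
    return out


def f_score(x, labels) -> float:
    """F-score of one feature (see :func:`f_score_matrix`)."""
    return float(f_score_matrix(np.asarray(x, dtype=float)[:, None], labels)[0])


def default_k_grid(n_features: int, step: int | None = None) -> np.ndarray:
    """Feature counts to evaluate: ``step`` apart up to all features."""
    if n_features < 1:
        raise ValueError("no features to search over")
    if step is None:
        step = 50 if n_features > 200 else 1
    grid = list(range(step, n_features + 1, step))
    if not grid or grid[-1] != n_features:
        grid.append(n_features)
    return np.array(grid)


@lru_cache(maxsize=64)
def _t_cutoffs(m: int, df: int, q: float):
    """|t| cutoffs equivalent to BH on two-sided p over m tests, plus raw 0.05."""
    ranks = np.arange(1, m + 1)
    bh = stats.t.isf(ranks * q / m / 2.0, df)
    raw = float(stats.t.isf(0.025, df))
    return bh, raw


def _group_t_only(X, labels, covariates):
    """Group-coefficient t per column (same model as group_t_matrix, no p)."""
    n = X.shape[0]
    if covariates is None or covariates.size == 0:
        D = np.column_stack([np.ones(n), labels.astype(float)])
    else:
        D = np.column_stack([np.ones(n), labels.astype(float), covariates])
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ (D.T @ X)
    resid = X - D @ beta
    df = n - D.shape[1]
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * DtD_inv[1, 1], 0.0))
    t = np.zeros(X.shape[1])
    nz = se > 0
    t[nz] = beta[1, nz] / se[nz]
    return t, df


def _screen_columns(X, labels, covariates, q):
    """Candidate columns after FDR screening, with a documented fallback.

    Selection operates on |t| with cutoffs precomputed per (m, df, q),
    which is identical to Benjamini-Hochberg on the two-sided p-values.
    If no voxel survives BH (common under the null) fall back to raw
    p < 0.05, and failing that to all columns, so the CV stays total.
    """
    t, df = _group_t_only(X, labels, covariates)
    abs_t = np.abs(t)
    bh_cut, raw_cut = _t_cutoffs(X.shape[1], df, q)
    order = np.sort(abs_t)[::-1]
    ok = order >= bh_cut
    if ok.any():
        thr = order[np.nonzero(ok)[0].max()]
        selected = abs_t >= thr
    else:
        selected = abs_t >= raw_cut
    if not selected.any():
        selected = np.ones(X.shape[1], dtype=bool)
    return np.flatnonzero(selected), t


def loocv_classify(
    features: FeatureMatrix,
    k_grid=None,
    config: SVMConfig | None = None,
    labels: np.ndarray | None = None,
    candidate_columns: np.ndarray | None = None,
) -> CVResult:
    """Run the full LOOCV feature-count search and return its curves.

    ``labels`` overrides the phenotype group labels (used by the
    permutation test, which re-runs this whole procedure under permuted
    labels).  ``candidate_columns`` bypasses screening with a fixed
    candidate set; the whole-sample permutation test uses this so that the
    screen — computed once on the real labels, as in the original workflow
    — stays fixed while labels are permuted.  ``k_grid`` values exceeding a
    fold's surviving feature count are capped to that count for the fold.
    """
    cfg = config or SVMConfig()
    y = features.group_labels() if labels is None else np.asarray(labels, dtype=int)
    n = features.n_subjects
    if n < 6:
        raise ValueError("need >= 6 subjects for LOOCV")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = features.X
    C_cov = features.covariate_matrix(cfg.covariates) if cfg.covariates else None
    k_grid = default_k_grid(features.n_voxels) if k_grid is None else np.asarray(k_grid, int)
    n_k = len(k_grid)

    whole_cols = None
    if candidate_columns is not None:
        whole_cols = np.asarray(candidate_columns, dtype=int)
    elif cfg.screening_mode == "whole_sample":
        whole_cols, _ = _screen_columns(X, y, C_cov, cfg.q)
    elif cfg.screening_mode != "per_fold":
        raise ValueError(f"unknown screening_mode {cfg.screening_mode!r}")

    preds = np.zeros((n, n_k), dtype=int)
    decisions = np.zeros((n, n_k))
    fold_weights: list[list[tuple[np.ndarray, np.ndarray]]] = []  # [fold][k] -> (cols, w)
    capped = False
    for i in range(n):
        tr = np.arange(n) != i
        X_tr, y_tr = X[tr], y[tr]
        if whole_cols is None:
            cols, _ = _screen_columns(
                X_tr, y_tr, None if C_cov is None else C_cov[tr], cfg.q
            )
        else:
            cols = whole_cols
        Xs = X_tr[:, cols]
        fs = f_score_matrix(Xs, y_tr)
        order = np.argsort(-fs, kind="stable")
        mu, sd = Xs.mean(axis=0), Xs.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs_std = (Xs - mu) / sd
        x_te = (X[i, cols] - mu) / sd
        per_k = []
        for j, k in enumerate(k_grid):
            kk = min(int(k), len(cols))
            if kk < int(k):
                capped = True
            top = order[:kk]
            clf = SVC(kernel="linear", C=cfg.C)
            clf.fit(Xs_std[:, top], y_tr)
            # decision value > 0 means the higher class (classes_ sorted); one
            # call instead of predict + decision_function
            d = float(clf.decision_function(x_te[top][None, :])[0])
            decisions[i, j] = d
            preds[i, j] = int(clf.classes_[1] if d > 0 else clf.classes_[0])
            per_k.append((cols[top], clf.coef_.ravel() / sd[top]))
        fold_weights.append(per_k)
    if capped:
        logger.warning("some k in k_grid exceeded the surviving feature count; capped per fold")

    acc = (preds == y[:, None]).mean(axis=0)
    pos, neg = y == 1, y == 0
    sens = (preds[pos] == 1).mean(axis=0) if pos.any() else np.full(n_k, np.nan)
    spec = (preds[neg] == 0).mean(axis=0) if neg.any() else np.full(n_k, np.nan)
    best_j = int(np.flatnonzero(acc == acc.max())[0])  # smallest k wins ties
    auc = float(roc_auc_score(y, decisions[:, best_j]))

    weight_map = np.zeros(features.n_voxels)
    for per_k in fold_weights:
        cols_j, w_j = per_k[best_j]
        weight_map[cols_j] += w_j
    weight_map /= n

    return CVResult(
        k_grid=k_grid,
        accuracy_curve=acc,
        sensitivity_curve=sens,
        specificity_curve=spec,
        auc=auc,
        best_k=int(k_grid[best_j]),
        oof_labels=y,
        oof_predictions=preds,
        oof_decision=decisions,
        weight_map=weight_map,
    )


def permutation_test(
    statistic_fn,
    labels: np.ndarray,
    n_perm: int,
    seed: int | np.random.Generator = 0,
    statistic_name: str = "statistic",
    observed: float | None = None,
) -> PermutationNull:
    """Label-permutation null for any statistic of the labels.

    ``statistic_fn(labels) -> float`` must re-run the full procedure (for
    CV statistics that includes per-fold feature selection).  The p-value
    uses the add-one rule and therefore lies in (0, 1].
    """
    labels = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are constant; nothing to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = float(statistic_fn(labels)) if observed is None else float(observed)
    null = np.array([float(statistic_fn(rng.permutation(labels))) for _ in range(n_perm)])
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return PermutationNull(
        statistic_name=statistic_name,
        observed=obs,
        null_values=null,
        n_perm=n_perm,
        p_value=float(p),
    )


def classification_metrics(y_true, y_pred, decision_values=None, positive=1):
    """(accuracy, sensitivity, specificity, auc) with patients positive.

    AUC is the rank statistic of the decision values (ties averaged);
    ``None`` when no decision values are given.  Raises if either class is
    absent (sensitivity/specificity undefined).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    if not pos.any() or pos.all():
        raise ValueError("both classes must be present in y_true")
    tp = np.sum(pos & (y_pred == positive))
    tn = np.sum(~pos & (y_pred != positive))
    accuracy = (tp + tn) / len(y_true)
    sensitivity = tp / pos.sum()
    specificity = tn / (~pos).sum()
    auc = None
    if decision_values is not None:
        auc = float(roc_auc_score(pos.astype(int), np.asarray(decision_values, dtype=float)))
    return float(accuracy), float(sensitivity), float(specificity), auc
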