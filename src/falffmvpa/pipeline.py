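"""End-to-end orchestration of the two-study workflow.

Study 1: confound regression -> fALFF z-maps -> feature matrix -> LOOCV
linear-SVM feature-count search with permutation inference -> weight-map
clusters.  Study 2: restrict the treated patients' features to the Study-1
discriminative mask and run the LOOCV SVR treatment-response prediction
with its own permutation test.  Both stages write JSON reports plus
tab-separated voxel/cluster tables and echo the fully-resolved
configuration, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import SVMConfig, classification_metrics, loocv_classify, permutation_test
from .falff import FALFFConfig, falff_map, regress_confounds
from .predict import SVRConfig, loocv_predict, predict_permutation
from .regions import threshold_weights, weight_volume
from .screening import build_feature_matrix
from .types import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "cohort_to_features", "run_study1", "run_study2"]

CONFOUND_COLUMNS = [f"motion_{i}" for i in range(1, 7)] + ["trend", "wm", "csf"]


@dataclass
class RunConfig:
    """Fully-defaulted settings for a pipeline run."""

    manifest: str | None = None
    out_dir: str = "results"
    band_low: tuple[float, float] = (0.01, 0.08)
    band_full: tuple[float, float] = (0.0, 0.25)
    prefilter: tuple[float, float] | None = None
    confound_columns: list[str] = field(default_factory=lambda: list(CONFOUND_COLUMNS))
    screening_mode: str = "per_fold"
    screening_q: float = 0.05
    covariates: tuple = ("age", "sex", "head_motion")
    k_step: int | None = None
    k_grid: list[int] | None = None
    svm_C: float = 1.0
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    n_perm_study1: int = 100
    n_perm_study2: int = 100
    threshold_fraction: float = 0.3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band_low", "band_full", "prefilter", "covariates"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def echo(self, out_dir) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(out_dir, "config_resolved.yaml").write_text(yaml.safe_dump(d, sort_keys=True))


def cohort_to_features(
    scans, phenotype, config: RunConfig | None = None, regress: bool = True
) -> FeatureMatrix:
    """Confound-regress each scan, compute z-fALFF maps, stack features."""
    cfg = config or RunConfig()
    fcfg = FALFFConfig(band_low=cfg.band_low, band_full=cfg.band_full, prefilter=cfg.prefilter)
    maps = []
    for scan in scans:
        if regress:
            cols = [c for c in cfg.confound_columns if c in scan.confounds.columns]
            scan = regress_confounds(scan, cols)
        maps.append(falff_map(scan, fcfg))
    return build_feature_matrix(maps, phenotype)


def _clusters_to_frame(clusters) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sign": c.sign,
                "voxel_count": c.voxel_count,
                "peak_weight": c.peak_weight,
                "peak_x": c.peak_coordinate[0],
                "peak_y": c.peak_coordinate[1],
                "peak_z": c.peak_coordinate[2],
            }
            for c in clusters
        ]
    )


def run_study1(
    features: FeatureMatrix,
    config: RunConfig | None = None,
    out_dir=None,
    grid_shape=None,
):
    """Classification study on a prepared feature matrix.

    Returns ``(cv_result, permutation_null, clusters)`` and, when
    ``out_dir`` is given, writes study1.json, the weight/cluster tables and
    the echoed config there.
    """
    cfg = config or RunConfig()
    t0 = time.time()
    svm_cfg = SVMConfig(
        C=cfg.svm_C,
        screening_mode=cfg.screening_mode,
        covariates=cfg.covariates,
        q=cfg.screening_q,
    )
    if cfg.k_grid is not None:
        k_grid = np.asarray(cfg.k_grid, int)
    else:
        from .classify import default_k_grid

        k_grid = default_k_grid(features.n_voxels, cfg.k_step)
    cv = loocv_classify(features, k_grid=k_grid, config=svm_cfg)
    best_j = int(np.flatnonzero(cv.k_grid == cv.best_k)[0])
    acc, sens, spec, auc = classification_metrics(
        cv.oof_labels, cv.oof_predictions[:, best_j], cv.oof_decision[:, best_j]
    )

    perm = None
    if cfg.n_perm_study1 > 0:
        # in whole-sample mode the screen computed on the real labels stays
        # fixed under permutation, as in the original workflow; in per-fold
        # mode the entire procedure (including screening) is re-run
        fixed_cols = None
        if cfg.screening_mode == "whole_sample":
            from .classify import _screen_columns

            fixed_cols, _ = _screen_columns(
                features.X,
                cv.oof_labels,
                features.covariate_matrix(cfg.covariates) if cfg.covariates else None,
                cfg.screening_q,
            )

        def stat(labels):
            r = loocv_classify(
                features,
                k_grid=k_grid,
                config=svm_cfg,
                labels=labels,
                candidate_columns=fixed_cols,
            )
            return r.best_accuracy

        perm = permutation_test(
            stat,
            cv.oof_labels,
            n_perm=cfg.n_perm_study1,
            seed=np.random.default_rng(cfg.seed),
            statistic_name="loocv_accuracy",
            observed=cv.best_accuracy,
        )

    shape = grid_shape or tuple(features.voxel_index.max(axis=0) + 1)
    wvol = weight_volume(cv.weight_map, features.voxel_index, shape)
    clusters = threshold_weights(wvol, fraction=cfg.threshold_fraction)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.echo(out)
        report = {
            "k_grid": cv.k_grid.tolist(),
            "accuracy_curve": cv.accuracy_curve.tolist(),
            "sensitivity_curve": cv.sensitivity_curve.tolist(),
            "specificity_curve": cv.specificity_curve.tolist(),
            "best_k": cv.best_k,
            "accuracy": acc,
            "sensitivity": sens,
            "specificity": spec,
            "auc": auc,
            "permutation_p": None if perm is None else perm.p_value,
            "n_perm": 0 if perm is None else perm.n_perm,
            "seed": cfg.seed,
            "elapsed_seconds": time.time() - t0,
        }
        (out / "study1.json").write_text(json.dumps(report, indent=2))
        wdf = pd.DataFrame(features.voxel_index, columns=["x", "y", "z"])
        wdf["weight"] = cv.weight_map
        wdf["discriminative"] = cv.discriminative_mask
        wdf.to_csv(out / "study1_weights.tsv", sep="\t", index=False)
        _clusters_to_frame(clusters).to_csv(out / "study1_clusters.tsv", sep="\t", index=False)
        logger.info("study 1 written to %s (%.1fs)", out, report["elapsed_seconds"])
    return cv, perm, clusters


def run_study2(
    features: FeatureMatrix,
    discriminative_mask: np.ndarray,
    config: RunConfig | None = None,
    out_dir=None,
    grid_shape=None,
):
    """Treatment-response prediction on the treated patients.

    ``features`` must contain all subjects; the treated patients and their
    reductions are taken from the phenotype table.  Requires the Study-1
    ``discriminative_mask`` over feature columns.  Returns
    ``(prediction_result, permutation_null, clusters)``.
    """
    cfg = config or RunConfig()
    t0 = time.time()
    if discriminative_mask is None or not np.asarray(discriminative_mask).any():
        raise ValueError("study 2 needs a non-empty Study-1 discriminative mask; run study 1")
    pheno = features.phenotype
    treated = pheno["treated"].to_numpy(bool)
    sub = features.subset_subjects(np.flatnonzero(treated))
    reduction = (
        sub.phenotype["freq_pre"].to_numpy(float) - sub.phenotype["freq_post"].to_numpy(float)
    )
    if np.any(~np.isfinite(reduction)):
        raise ValueError("treated subjects must have both pre and post attack frequencies")

    svr_cfg = SVRConfig(C=cfg.svr_C, epsilon=cfg.svr_epsilon, covariates=cfg.covariates)
    k_grid = None if cfg.k_grid is None else np.asarray(cfg.k_grid, int)
    pred = loocv_predict(
        sub, reduction, mask=discriminative_mask, k_grid=k_grid, config=svr_cfg
    )
    perm = None
    if cfg.n_perm_study2 > 0:
        perm = predict_permutation(
            sub,
            reduction,
            mask=discriminative_mask,
            k_grid=k_grid,
            config=svr_cfg,
            n_perm=cfg.n_perm_study2,
            seed=np.random.default_rng(cfg.seed + 1),
            observed=pred.best_r,
        )

    shape = grid_shape or tuple(features.voxel_index.max(axis=0) + 1)
    wvol = weight_volume(pred.weight_map, features.voxel_index, shape)
    clusters = threshold_weights(wvol, fraction=cfg.threshold_fraction)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cfg.echo(out)
        report = {
            "k_grid": pred.k_grid.tolist(),
            "r_curve": pred.r_curve.tolist(),
            "best_k": pred.best_k,
            "r": pred.best_r,
            "permutation_p": None if perm is None else perm.p_value,
            "n_perm": 0 if perm is None else perm.n_perm,
            "n_treated": int(treated.sum()),
            "seed": cfg.seed,
            "elapsed_seconds": time.time() - t0,
        }
        (out / "study2.json").write_text(json.dumps(report, indent=2))
        _clusters_to_frame(clusters).to_csv(out / "study2_clusters.tsv", sep="\t", index=False)
        logger.info("study 2 written to %s (%.1fs)", out, report["elapsed_seconds"])
    return pred, perm, clusters
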