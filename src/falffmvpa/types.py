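"""Shared container types for the fALFF MVPA pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SubjectScan", "FeatureMatrix", "PHENOTYPE_COLUMNS"]

#: Columns every phenotype table carries.  ``group`` is "patient" or
#: "control"; ``treated`` flags the patients who received real stimulation
#: and therefore have a defined attack-frequency reduction
#: (``freq_pre - freq_post``, positive = improvement).
PHENOTYPE_COLUMNS = [
    "subject_id",
    "group",
    "treated",
    "age",
    "sex",
    "head_motion",
    "SAS",
    "SDS",
    "MSQ",
    "freq_pre",
    "freq_post",
]


@dataclass
class SubjectScan:
    """One subject's 4D voxel time series plus mask, TR and confounds.

    ``series`` is (x, y, z, t); ``confounds`` has one row per time point
    with nuisance-regressor columns (motion parameters, trend, white-matter
    and CSF signals).
    """

    series: np.ndarray
    mask: np.ndarray
    tr_seconds: float
    confounds: pd.DataFrame

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.series.ndim != 4:
            raise ValueError(f"series must be 4D (x,y,z,t), got shape {self.series.shape}")
        if self.mask.shape != self.series.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match series grid {self.series.shape[:3]}"
            )
        if self.mask.sum() < 1:
            raise ValueError("mask is empty")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if len(self.confounds) != self.series.shape[-1]:
            raise ValueError(
                f"confounds have {len(self.confounds)} rows but series has "
                f"{self.series.shape[-1]} time points"
            )
        if not np.all(np.isfinite(self.series[self.mask])):
            raise ValueError("non-finite values inside the mask")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[-1]


@dataclass
class FeatureMatrix:
    """Subjects x in-mask voxels matrix of z-fALFF with aligned phenotypes.

    ``X[i, j]`` is subject i's z-fALFF at the voxel whose 3D grid coordinate
    is ``voxel_index[j]``.  ``phenotype`` rows align with rows of ``X``.
    """

    X: np.ndarray  # (n_subjects, n_voxels)
    voxel_index: np.ndarray  # (n_voxels, 3) int grid coordinates
    phenotype: pd.DataFrame

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2D (subjects x voxels)")
        if self.voxel_index.shape != (self.X.shape[1], 3):
            raise ValueError("voxel_index must be (n_voxels, 3)")
        if len(self.phenotype) != self.X.shape[0]:
            raise ValueError("phenotype rows must align with X rows")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing/non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def group_labels(self, positive: str = "patient") -> np.ndarray:
        """Binary labels: 1 for ``positive`` group, 0 otherwise."""
        return (self.phenotype["group"].to_numpy() == positive).astype(int)

    def covariate_matrix(self, names=("age", "sex", "head_motion")) -> np.ndarray:
        """Numeric covariate columns; sex coded 0 (F) / 1 (M)."""
        cols = []
        for name in names:
            col = self.phenotype[name]
            if name == "sex":
                cols.append((col.to_numpy() == "M").astype(float))
            else:
                cols.append(col.to_numpy(float))
        return np.column_stack(cols) if cols else np.empty((self.n_subjects, 0))

    def subset_subjects(self, rows) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            X=self.X[rows],
            voxel_index=self.voxel_index,
            phenotype=self.phenotype.iloc[rows].reset_index(drop=True),
        )

    def subset_voxels(self, cols) -> "FeatureMatrix":
        cols = np.asarray(cols)
        return FeatureMatrix(
            X=self.X[:, cols],
            voxel_index=self.voxel_index[cols],
            phenotype=self.phenotype,
        )
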