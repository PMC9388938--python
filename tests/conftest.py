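import numpy as np
import pandas as pd
import pytest

import falffmvpa as fm


@pytest.fixture(scope="session")
def small_spec():
    return fm.SyntheticSpec(
        n_patients=10,
        n_controls=10,
        n_treated=8,
        grid_shape=(6, 6, 5),
        mask_fraction=1.0,
        n_effect_voxels=20,
        effect_size=0.8,
        outcome_snr=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return fm.generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    scans, phenotype = small_cohort
    return fm.cohort_to_features(scans, phenotype)


def make_phenotype(labels, rng=None):
    """Minimal phenotype table for hand-built feature matrices."""
    rng = rng or np.random.default_rng(0)
    labels = np.asarray(labels)
    n = len(labels)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "group": np.where(labels == 1, "patient", "control"),
            "treated": labels == 1,
            "age": rng.normal(30, 5, n),
            "sex": rng.choice(["M", "F"], n),
            "head_motion": rng.uniform(0.05, 0.2, n),
            "SAS": rng.normal(40, 5, n),
            "SDS": rng.normal(40, 5, n),
            "MSQ": rng.normal(60, 8, n),
            "freq_pre": rng.uniform(1, 8, n),
            "freq_post": rng.uniform(0, 6, n),
        }
    )


@pytest.fixture
def feature_matrix_factory():
    def make(X, labels, rng=None):
        X = np.asarray(X, dtype=float)
        coords = np.argwhere(np.ones((X.shape[1], 1, 1), dtype=bool))
        return fm.FeatureMatrix(X=X, voxel_index=coords, phenotype=make_phenotype(labels, rng))

    return make
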