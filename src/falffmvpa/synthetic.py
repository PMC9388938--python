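"""Synthetic resting-state cohorts with planted spectral group effects.

The downstream analysis detects purely spectral structure (fALFF is a
band-amplitude ratio), so the generative model plants the minimal structure
that statistic can see: every voxel's series is

    broadband (white) noise
    + a band-limited (0.01-0.08 Hz) oscillatory component
    + a linear drift
    + small loadings on shared nuisance signals (motion, WM, CSF, trend).

At *effect voxels* the oscillatory amplitude of the patient group is scaled
by ``1 + effect_size`` relative to controls, which raises fALFF there.  A
subset of the effect voxels (the *predictive voxels*) additionally drives a
treatment outcome: for the treated patients, the reduction in monthly attack
frequency is a linear function of baseline z-fALFF at those voxels plus
Gaussian noise.  With ``effect_size = 0`` and zero outcome weights the two
groups are exchangeable and the outcome is pure noise — the null world used
for calibration checks.

Covariate distributions (age, sex, anxiety/depression/quality-of-life
scores, baseline attack frequency) default to the patient/control summary
statistics of the study this design emulates: two groups of 70 with a
treated subgroup of 33, scans of 230 retained time points at TR = 2 s on a
small 3D lattice standing in for the 3-mm MNI grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .falff import falff_matrix
from .types import SubjectScan

__all__ = ["CovariateModel", "SyntheticSpec", "generate_cohort", "make_signal", "build_mask"]


@dataclass
class CovariateModel:
    """Per-group covariate distributions (mean, SD) and sex proportions."""

    age_patient: tuple[float, float] = (30.34, 7.20)
    age_control: tuple[float, float] = (28.07, 6.71)
    p_male_patient: float = 16 / 70
    p_male_control: float = 25 / 70
    sas_patient: tuple[float, float] = (43.39, 5.64)
    sds_patient: tuple[float, float] = (44.88, 5.97)
    msq_patient: tuple[float, float] = (57.23, 9.94)
    sas_control: tuple[float, float] = (35.0, 5.0)
    sds_control: tuple[float, float] = (35.0, 5.0)
    msq_control: tuple[float, float] = (85.0, 8.0)
    freq_pre_patient: tuple[float, float] = (3.81, 2.39)
    head_motion: tuple[float, float] = (0.12, 0.04)  # mean FD-like, mm


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    ``effect_voxels`` / ``predictive_voxels`` are (m, 3) integer grid
    coordinates; when None they are planted automatically as compact
    clusters inside the mask (``n_effect_voxels`` / ``n_predictive_voxels``
    of them).  ``outcome_snr``, when set, chooses the outcome noise SD so
    that the planted linear signal and the noise have the stated
    variance ratio within the cohort; otherwise ``outcome_noise_sd`` is
    used directly.
    """

    n_patients: int = 70
    n_controls: int = 70
    n_treated: int = 33
    grid_shape: tuple[int, int, int] = (12, 12, 10)
    mask_fraction: float = 0.7
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    effect_voxels: np.ndarray | None = None
    n_effect_voxels: int = 50
    effect_size: float = 0.35
    predictive_voxels: np.ndarray | None = None
    n_predictive_voxels: int = 5
    outcome_beta: float | np.ndarray = 1.0
    outcome_noise_sd: float = 1.0
    outcome_snr: float | None = None
    # clinical calibration: the planted reduction (linear in z-fALFF, in
    # arbitrary units) is affinely mapped to attacks/month with this mean
    # and SD; Pearson correlations with features are unaffected
    outcome_mean: float = 1.45
    outcome_sd: float = 2.5
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    # signal model
    noise_sd: float = 1.0
    osc_amp: float = 1.0
    amp_jitter_sd: float = 0.2
    cluster_jitter_sd: float = 0.3
    drift_sd: float = 0.05
    confound_loading_sd: float = 0.05
    band_low: tuple[float, float] = (0.01, 0.08)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        if not 0 <= self.n_treated <= self.n_patients:
            raise ValueError("n_treated must be between 0 and n_patients")
        if self.n_timepoints < 32:
            raise ValueError("n_timepoints must be >= 32 (enough FFT bins in both bands)")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 < self.mask_fraction <= 1:
            raise ValueError("mask_fraction must be in (0, 1]")
        if self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be non-negative")


def build_mask(grid_shape: tuple[int, int, int], mask_fraction: float) -> np.ndarray:
    """Centred-ellipsoid brain mask covering ~mask_fraction of the lattice."""
    if mask_fraction >= 1.0:
        return np.ones(grid_shape, dtype=bool)
    axes = [np.linspace(-1, 1, n) if n > 1 else np.zeros(1) for n in grid_shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    r2 = gx**2 + gy**2 + gz**2
    n_keep = max(1, int(round(mask_fraction * r2.size)))
    cutoff = np.partition(r2.ravel(), n_keep - 1)[n_keep - 1]
    return r2 <= cutoff


def _plant_clusters(mask: np.ndarray, n_voxels: int) -> np.ndarray:
    """Compact 6-connected clusters (~10 voxels each) at reproducible spots.

    Cluster seed points are chosen by farthest-point sampling over the mask
    (maximally spread), then grown breadth-first in round robin.  Fully
    deterministic given the mask and voxel count, so the planted "anatomy"
    is identical across cohort seeds.
    """
    coords = np.argwhere(mask)
    if n_voxels > len(coords):
        raise ValueError(f"cannot plant {n_voxels} voxels in a mask of {len(coords)}")
    in_mask = set(map(tuple, coords))
    n_clusters = max(1, n_voxels // 10)
    centroid = coords.mean(axis=0)
    d2 = ((coords - centroid) ** 2).sum(axis=1)
    seeds = [int(np.argmin(d2))]
    min_d = ((coords - coords[seeds[0]]) ** 2).sum(axis=1).astype(float)
    for _ in range(n_clusters - 1):
        nxt = int(np.argmax(min_d))
        seeds.append(nxt)
        min_d = np.minimum(min_d, ((coords - coords[nxt]) ** 2).sum(axis=1))
    sizes = [n_voxels // n_clusters] * n_clusters
    for i in range(n_voxels - sum(sizes)):
        sizes[i] += 1
    chosen: list[tuple[int, int, int]] = []
    chosen_set: set = set()
    neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for s, size in zip(seeds, sizes):
        queue = [tuple(coords[s])]
        seen = set(queue)
        grown = 0
        while queue and grown < size:
            v = queue.pop(0)  # FIFO -> breadth-first, compact balls
            if v in chosen_set:
                continue
            chosen.append(v)
            chosen_set.add(v)
            grown += 1
            for d in neigh:
                nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if nb in in_mask and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
    if len(chosen) < n_voxels:  # mask too fragmented for BFS growth
        for c in map(tuple, coords):
            if len(chosen) >= n_voxels:
                break
            if c not in chosen_set:
                chosen.append(c)
                chosen_set.add(c)
    return np.array(chosen[:n_voxels], dtype=int)


def _connected_components(voxels: np.ndarray) -> list[np.ndarray]:
    """Split a set of (m, 3) voxel coordinates into 6-connected components."""
    remaining = set(map(tuple, np.atleast_2d(voxels)))
    neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    comps = []
    while remaining:
        stack = [min(remaining)]
        remaining.discard(stack[0])
        comp = []
        while stack:
            v = stack.pop()
            comp.append(v)
            for d in neigh:
                nb = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if nb in remaining:
                    remaining.discard(nb)
                    stack.append(nb)
        comps.append(np.array(sorted(comp), dtype=int))
    return comps


def _validate_voxels(voxels: np.ndarray, mask: np.ndarray, what: str) -> np.ndarray:
    voxels = np.atleast_2d(np.asarray(voxels, dtype=int))
    if voxels.shape[1] != 3:
        raise ValueError(f"{what} must be (m, 3) grid coordinates")
    for v in voxels:
        if np.any(v < 0) or np.any(v >= np.array(mask.shape)) or not mask[tuple(v)]:
            raise ValueError(f"{what} voxel {tuple(int(x) for x in v)} lies outside the mask")
    return voxels


def _band_limited_unit(rng, n_series, n_t, tr, band) -> np.ndarray:
    """Gaussian series supported on the given band, unit RMS per row."""
    freqs = np.fft.rfftfreq(n_t, d=tr)
    keep = (freqs >= band[0] - 1e-12) & (freqs <= band[1] + 1e-12) & (freqs > 1e-12)
    spec = np.zeros((n_series, freqs.size), dtype=complex)
    k = int(keep.sum())
    spec[:, keep] = rng.standard_normal((n_series, k)) + 1j * rng.standard_normal((n_series, k))
    x = np.fft.irfft(spec, n=n_t, axis=-1)
    rms = x.std(axis=-1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def _make_confounds(rng, n_t: int) -> pd.DataFrame:
    """Motion random walks, linear trend and slow WM/CSF signals."""
    motion = np.cumsum(rng.normal(0.0, 0.01, size=(n_t, 6)), axis=0)
    trend = np.linspace(0.0, 1.0, n_t)
    slow = _band_limited_unit(rng, 2, n_t, 1.0, (0.0, 0.02))  # 0-0.02 cycles/sample
    cols = {f"motion_{i + 1}": motion[:, i] for i in range(6)}
    cols["trend"] = trend
    cols["wm"] = 0.5 * slow[0]
    cols["csf"] = 0.5 * slow[1]
    return pd.DataFrame(cols)


def _subject_series(
    rng,
    spec: SyntheticSpec,
    n_vox: int,
    effect_flat: np.ndarray,
    is_patient: bool,
    confounds: pd.DataFrame,
    effect_components: list[np.ndarray] | None = None,
) -> np.ndarray:
    """(n_vox, T) series matrix for one subject.

    ``effect_components`` groups the effect voxels into contiguous clusters
    that share a per-subject amplitude factor — the regional covariance of
    spontaneous activity that makes voxels of one functional cluster rise
    and fall together across subjects.
    """
    T = spec.n_timepoints
    amp = spec.osc_amp * np.exp(rng.normal(0.0, spec.amp_jitter_sd, size=n_vox))
    if effect_components is None and effect_flat.size:
        effect_components = [effect_flat]
    if effect_components and spec.cluster_jitter_sd > 0:
        for comp in effect_components:
            amp[comp] *= np.exp(rng.normal(0.0, spec.cluster_jitter_sd))
    if is_patient and effect_flat.size:
        amp[effect_flat] *= 1.0 + spec.effect_size
    osc = amp[:, None] * _band_limited_unit(rng, n_vox, T, spec.tr_seconds, spec.band_low)
    noise = rng.normal(0.0, spec.noise_sd, size=(n_vox, T)) if spec.noise_sd > 0 else 0.0
    t_norm = np.linspace(-0.5, 0.5, T)
    drift = rng.normal(0.0, spec.drift_sd, size=(n_vox, 1)) * t_norm[None, :]
    C = confounds.to_numpy(float)
    loadings = rng.normal(0.0, spec.confound_loading_sd, size=(C.shape[1], n_vox))
    return osc + noise + drift + (C @ loadings).T


def make_signal(
    voxel_kind: str,
    group: str,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    confounds: pd.DataFrame | None = None,
) -> np.ndarray:
    """One voxel's time series under the generative model.

    ``voxel_kind`` is "background" or "effect"; ``group`` is "patient" or
    "control".  Only a patient-group effect voxel receives the amplitude
    boost.  Passing ``confounds`` shares nuisance signals across calls.
    """
    if voxel_kind not in ("background", "effect"):
        raise ValueError(f"unknown voxel_kind {voxel_kind!r}")
    if group not in ("patient", "control"):
        raise ValueError(f"unknown group {group!r}")
    if confounds is None:
        confounds = _make_confounds(rng, spec.n_timepoints)
    effect_flat = np.array([0]) if voxel_kind == "effect" else np.array([], dtype=int)
    return _subject_series(rng, spec, 1, effect_flat, group == "patient", confounds)[0]


def _subject_zfalff(series: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    vals = falff_matrix(series, spec.tr_seconds)
    sd = vals.std()
    return (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)


def generate_cohort(spec: SyntheticSpec):
    """Generate one cohort: a list of :class:`SubjectScan` and a phenotype table.

    Deterministic for a fixed ``spec.seed``.  Patients come first in the
    returned lists, then controls; the first ``n_treated`` patients are the
    treated subgroup whose attack-frequency reduction is planted as
    ``sum(outcome_beta * z-fALFF at predictive voxels) + noise``.
    """
    rng = np.random.default_rng(spec.seed)
    mask = build_mask(spec.grid_shape, spec.mask_fraction)
    coords = np.argwhere(mask)
    n_vox = len(coords)
    flat_of_coord = {tuple(c): i for i, c in enumerate(coords)}

    if spec.effect_voxels is not None:
        effect = _validate_voxels(spec.effect_voxels, mask, "effect_voxels")
    elif spec.n_effect_voxels > 0:
        effect = _plant_clusters(mask, spec.n_effect_voxels)
    else:
        effect = np.empty((0, 3), dtype=int)

    if spec.predictive_voxels is not None:
        predictive = _validate_voxels(spec.predictive_voxels, mask, "predictive_voxels")
        eff_set = set(map(tuple, effect))
        for v in predictive:
            if tuple(v) not in eff_set:
                raise ValueError(
                    f"predictive voxel {tuple(int(x) for x in v)} is not an effect voxel"
                )
    else:
        # spread the predictive voxels across the planted clusters
        n_pred = min(spec.n_predictive_voxels, len(effect))
        stride = max(1, len(effect) // n_pred) if n_pred else 1
        predictive = effect[::stride][:n_pred]

    effect_flat = np.array([flat_of_coord[tuple(v)] for v in effect], dtype=int)
    predictive_flat = np.array([flat_of_coord[tuple(v)] for v in predictive], dtype=int)
    components = [
        np.array([flat_of_coord[tuple(v)] for v in comp], dtype=int)
        for comp in _connected_components(effect)
    ]

    cm = spec.covariate_model
    n_p, n_c = spec.n_patients, spec.n_controls
    groups = ["patient"] * n_p + ["control"] * n_c
    treated = [i < spec.n_treated for i in range(n_p)] + [False] * n_c

    scans: list[SubjectScan] = []
    rows = []
    z_predictive = np.zeros((n_p + n_c, len(predictive_flat)))
    for i, group in enumerate(groups):
        confounds = _make_confounds(rng, spec.n_timepoints)
        series_mat = _subject_series(
            rng, spec, n_vox, effect_flat, group == "patient", confounds, components
        )
        vol = np.zeros(spec.grid_shape + (spec.n_timepoints,))
        vol[mask] = series_mat
        scans.append(
            SubjectScan(series=vol, mask=mask, tr_seconds=spec.tr_seconds, confounds=confounds)
        )
        if len(predictive_flat) and treated[i]:
            z_predictive[i] = _subject_zfalff(series_mat, spec)[predictive_flat]

        is_p = group == "patient"
        age_m, age_s = cm.age_patient if is_p else cm.age_control
        sas = cm.sas_patient if is_p else cm.sas_control
        sds = cm.sds_patient if is_p else cm.sds_control
        msq = cm.msq_patient if is_p else cm.msq_control
        fd = np.abs(np.diff(confounds[[f"motion_{j + 1}" for j in range(6)]].to_numpy(), axis=0))
        rows.append(
            {
                "subject_id": f"sub-{i + 1:03d}",
                "group": group,
                "treated": treated[i],
                "age": float(np.clip(rng.normal(age_m, age_s), 18, 65)),
                "sex": "M"
                if rng.random() < (cm.p_male_patient if is_p else cm.p_male_control)
                else "F",
                "head_motion": float(
                    cm.head_motion[0]
                    + cm.head_motion[1] * (fd.sum(axis=1).mean() / 0.06 - 1.0)
                ),
                "SAS": float(rng.normal(*sas)),
                "SDS": float(rng.normal(*sds)),
                "MSQ": float(rng.normal(*msq)),
                "freq_pre": float(max(0.5, rng.normal(*cm.freq_pre_patient))) if is_p else 0.0,
                "freq_post": np.nan,
            }
        )
    phenotype = pd.DataFrame(rows)

    # planted treatment outcome for the treated subgroup
    beta = np.broadcast_to(
        np.atleast_1d(np.asarray(spec.outcome_beta, dtype=float)), (len(predictive_flat),)
    )
    treated_idx = np.flatnonzero(np.array(treated))
    if len(treated_idx):
        lp = z_predictive[treated_idx] @ beta if len(predictive_flat) else np.zeros(
            len(treated_idx)
        )
        if spec.outcome_snr is not None and lp.std() > 0:
            noise_sd = lp.std() / spec.outcome_snr
        else:
            noise_sd = spec.outcome_noise_sd
        reduction = lp + rng.normal(0.0, noise_sd, size=len(treated_idx))
        if reduction.std() > 0:
            reduction = (
                spec.outcome_mean
                + spec.outcome_sd * (reduction - reduction.mean()) / reduction.std()
            )
        for j, i in enumerate(treated_idx):
            pre = phenotype.at[i, "freq_pre"]
            if pre - reduction[j] < 0:
                pre = reduction[j]  # keep the planted reduction exact, freq_post >= 0
                phenotype.at[i, "freq_pre"] = pre
            phenotype.at[i, "freq_post"] = pre - reduction[j]
    phenotype.loc[phenotype["group"] == "control", "freq_post"] = 0.0

    phenotype.attrs["effect_voxels"] = effect
    phenotype.attrs["predictive_voxels"] = predictive
    return scans, phenotype
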