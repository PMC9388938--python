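"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF summarises the spectral content of a voxel's BOLD time series as the
fraction of its amplitude spectrum (square root of the power spectrum) that
falls in a low-frequency band, by default 0.01-0.08 Hz, relative to the
amplitude summed over the full band 0-0.25 Hz.  Because it is a ratio it is
insensitive to overall signal scale and is the standard normalised variant
of ALFF used in resting-state fMRI.

The module provides:

* :func:`regress_confounds` -- OLS removal of nuisance regressors (motion,
  trend, white-matter / CSF signals) from every voxel's series;
* :func:`amplitude_spectrum` -- one-sided DFT amplitude spectrum;
* :func:`falff` -- the band-amplitude ratio for a single series;
* :func:`falff_map` -- per-voxel fALFF and its z-standardised map over a
  brain mask (mean 0, SD 1 within the mask).

Conventions: the series is linearly detrended before the FFT; the DC bin is
excluded from both band sums (it carries the mean, not fluctuation); bands
are closed intervals on bin-centre frequencies and are unions of whole bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .types import SubjectScan

DEFAULT_BAND_LOW = (0.01, 0.08)
DEFAULT_BAND_FULL = (0.0, 0.25)

__all__ = [
    "FALFFMap",
    "FALFFConfig",
    "regress_confounds",
    "amplitude_spectrum",
    "falff",
    "falff_matrix",
    "falff_map",
    "band_mask",
]


@dataclass
class FALFFConfig:
    """Settings for the fALFF computation.

    band_low / band_full are (low, high) closed frequency intervals in Hz.
    ``prefilter`` optionally band-passes the series before the spectrum is
    taken (a sensitivity-analysis mode; the default pipeline computes fALFF
    on the unfiltered, confound-regressed series because the ratio's
    denominator spans frequencies a narrow band-pass would remove).
    ``detrend`` removes a linear trend before the FFT.
    """

    band_low: tuple[float, float] = DEFAULT_BAND_LOW
    band_full: tuple[float, float] = DEFAULT_BAND_FULL
    prefilter: tuple[float, float] | None = None
    detrend: bool = True


@dataclass
class FALFFMap:
    """Per-voxel fALFF values and their z-map over a brain mask."""

    values: np.ndarray  # 3D, NaN outside mask
    zmap: np.ndarray  # 3D, NaN outside mask
    mask: np.ndarray  # 3D bool
    band_low: tuple[float, float] = DEFAULT_BAND_LOW
    band_full: tuple[float, float] = DEFAULT_BAND_FULL
    prefilter: tuple[float, float] | None = None

    @property
    def masked_values(self) -> np.ndarray:
        return self.values[self.mask]

    @property
    def masked_z(self) -> np.ndarray:
        return self.zmap[self.mask]


def _design_matrix(confounds, columns):
    import pandas as pd

    if columns is None:
        cols = list(confounds.columns)
    else:
        missing = [c for c in columns if c not in confounds.columns]
        if missing:
            raise ValueError(f"confound columns not found: {missing}")
        cols = list(columns)
    X = np.column_stack([np.ones(len(confounds))] + [confounds[c].to_numpy(float) for c in cols])
    return X, cols


def _check_design_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which columns are linearly dependent on the preceding ones
        bad = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                bad.append(names[j - 1])
        raise ValueError(f"rank-deficient confound design; collinear columns: {bad}")


def regress_confounds(scan: SubjectScan, columns=None) -> SubjectScan:
    """Residualise every in-mask voxel series on [intercept, confounds].

    Ordinary least squares per voxel, vectorised across voxels; residuals
    are orthogonal to the design.  Requires at least two more time points
    than regressors; a rank-deficient design raises and names the collinear
    columns.
    """
    X, cols = _design_matrix(scan.confounds, columns)
    n_t, n_reg = X.shape
    if scan.series.shape[-1] != n_t:
        raise ValueError(
            f"series has {scan.series.shape[-1]} time points but confounds have {n_t} rows"
        )
    if n_t < n_reg + 2:
        raise ValueError(f"need >= {n_reg + 2} time points for {n_reg} regressors, have {n_t}")
    _check_design_rank(X, cols)

    Y = scan.series[scan.mask]  # (n_vox, T)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta  # (T, n_vox)
    out = np.zeros_like(scan.series)
    out[scan.mask] = resid.T
    return SubjectScan(
        series=out, mask=scan.mask, tr_seconds=scan.tr_seconds, confounds=scan.confounds
    )


def amplitude_spectrum(series: np.ndarray, tr_seconds: float):
    """One-sided DFT amplitude spectrum of a (detrended) series.

    Returns ``(freqs, amplitude)`` where ``amplitude = sqrt(power)`` and
    power is the squared modulus of the discrete Fourier transform.  The DC
    bin is included in the output but excluded from band sums downstream.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1D")
    if series.size < 8:
        raise ValueError("series too short (need >= 8 samples)")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite samples")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    detrended = sp_signal.detrend(series, type="linear")
    amp = np.abs(np.fft.rfft(detrended))
    freqs = np.fft.rfftfreq(series.size, d=tr_seconds)
    return freqs, amp


def band_mask(freqs: np.ndarray, band: tuple[float, float], include_dc: bool = False) -> np.ndarray:
    """Boolean bin-membership for a closed frequency interval."""
    lo, hi = band
    m = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if not include_dc:
        m &= freqs > 1e-12
    return m


def _check_bands(band_low, band_full, nyquist):
    lo_l, hi_l = band_low
    lo_f, hi_f = band_full
    if not (0 <= lo_l < hi_l and 0 <= lo_f < hi_f):
        raise ValueError(f"invalid bands {band_low}, {band_full}")
    if lo_l < lo_f - 1e-12 or hi_l > hi_f + 1e-12:
        raise ValueError(f"low band {band_low} must lie within full band {band_full}")
    if hi_f > nyquist + 1e-9:
        raise ValueError(
            f"full band upper edge {hi_f} Hz exceeds the Nyquist frequency "
            f"{nyquist:.6g} Hz achievable at this TR"
        )


def falff(
    series: np.ndarray,
    tr_seconds: float,
    band_low: tuple[float, float] = DEFAULT_BAND_LOW,
    band_full: tuple[float, float] = DEFAULT_BAND_FULL,
) -> float:
    """fALFF ratio of one series: low-band amplitude over full-band amplitude.

    Returns 0.0 when the full-band amplitude sum is zero (constant series).
    Scale invariant: ``falff(c * x) == falff(x)`` for any nonzero ``c``.
    """
    freqs, amp = amplitude_spectrum(series, tr_seconds)
    _check_bands(band_low, band_full, nyquist=1.0 / (2.0 * tr_seconds))
    denom = amp[band_mask(freqs, band_full)].sum()
    # a numerically constant series leaves only float-eps residue after
    # detrending; treat that as zero fluctuation
    tol = 100 * np.finfo(float).eps * series.size * (1.0 + np.abs(series).max())
    if denom <= tol:
        return 0.0
    return float(amp[band_mask(freqs, band_low)].sum() / denom)


def _bandpass(series_2d: np.ndarray, tr_seconds: float, band: tuple[float, float]) -> np.ndarray:
    """Ideal (frequency-domain) band-pass along the last axis."""
    n = series_2d.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = band_mask(freqs, band, include_dc=False)
    spec = np.fft.rfft(series_2d, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def falff_matrix(
    series_2d: np.ndarray,
    tr_seconds: float,
    band_low: tuple[float, float] = DEFAULT_BAND_LOW,
    band_full: tuple[float, float] = DEFAULT_BAND_FULL,
    prefilter: tuple[float, float] | None = None,
    detrend: bool = True,
) -> np.ndarray:
    """Vectorised fALFF over rows of a (n_series, T) matrix."""
    series_2d = np.asarray(series_2d, dtype=float)
    if series_2d.ndim == 1:
        series_2d = series_2d[None, :]
    n = series_2d.shape[-1]
    _check_bands(band_low, band_full, nyquist=1.0 / (2.0 * tr_seconds))
    if detrend:
        series_2d = sp_signal.detrend(series_2d, axis=-1, type="linear")
    if prefilter is not None:
        series_2d = _bandpass(series_2d, tr_seconds, prefilter)
    amp = np.abs(np.fft.rfft(series_2d, axis=-1))
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    num = amp[:, band_mask(freqs, band_low)].sum(axis=-1)
    denom = amp[:, band_mask(freqs, band_full)].sum(axis=-1)
    out = np.zeros(series_2d.shape[0])
    tol = 100 * np.finfo(float).eps * n * (1.0 + np.abs(series_2d).max(axis=-1, initial=0.0))
    nz = denom > tol
    out[nz] = num[nz] / denom[nz]
    return out


def falff_map(scan: SubjectScan, config: FALFFConfig | None = None) -> FALFFMap:
    """Compute the fALFF map and its within-mask z-map for one subject.

    The z-map standardises fALFF to mean 0 / SD 1 across in-mask voxels,
    the conventional step before group statistics.  Raises on an all-constant
    volume (zero variance leaves the z-map undefined).
    """
    cfg = config or FALFFConfig()
    Y = scan.series[scan.mask]  # (n_vox, T)
    vals = falff_matrix(
        Y,
        scan.tr_seconds,
        band_low=cfg.band_low,
        band_full=cfg.band_full,
        prefilter=cfg.prefilter,
        detrend=cfg.detrend,
    )
    sd = vals.std()
    if vals.size >= 2 and sd == 0:
        raise ValueError("fALFF constant over the mask (zero variance); cannot z-standardise")
    z = (vals - vals.mean()) / sd if vals.size >= 2 else np.zeros_like(vals)

    values = np.full(scan.mask.shape, np.nan)
    zmap = np.full(scan.mask.shape, np.nan)
    values[scan.mask] = vals
    zmap[scan.mask] = z
    return FALFFMap(
        values=values,
        zmap=zmap,
        mask=scan.mask,
        band_low=cfg.band_low,
        band_full=cfg.band_full,
        prefilter=cfg.prefilter,
    )
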