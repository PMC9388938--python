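"""Spectral core: amplitude spectra, fALFF ratios, confound regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

import falffmvpa as fm
from falffmvpa.falff import FALFFConfig, band_mask, falff_matrix
from falffmvpa.types import SubjectScan


def naive_dft_amplitude(series, tr):
    """O(N^2) DFT oracle: sqrt of the power spectrum, one-sided."""
    x = sp_signal.detrend(np.asarray(series, float), type="linear")
    n = len(x)
    n_bins = n // 2 + 1
    amp = np.empty(n_bins)
    for k in range(n_bins):
        re = np.sum(x * np.cos(-2 * np.pi * k * np.arange(n) / n))
        im = np.sum(x * np.sin(-2 * np.pi * k * np.arange(n) / n))
        amp[k] = np.hypot(re, im)
    freqs = np.arange(n_bins) / (n * tr)
    return freqs, amp


def naive_falff(series, tr, band_low=(0.01, 0.08), band_full=(0.0, 0.25)):
    freqs, amp = naive_dft_amplitude(series, tr)
    num = amp[band_mask(freqs, band_low)].sum()
    den = amp[band_mask(freqs, band_full)].sum()
    return 0.0 if den == 0 else num / den


class TestAmplitudeSpectrum:
    def test_matches_naive_dft_on_short_series(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=16)
        freqs, amp = fm.amplitude_spectrum(x, tr_seconds=2.0)
        f2, a2 = naive_dft_amplitude(x, 2.0)
        np.testing.assert_allclose(freqs, f2, atol=1e-12)
        np.testing.assert_allclose(amp, a2, atol=1e-10)

    def test_pure_tone_concentrates_at_its_bin(self):
        # tone at the bin centre nearest 0.04 Hz (18/460); an off-grid tone
        # would leak amplitude across the whole spectrum
        t = np.arange(230) * 2.0
        x = np.cos(2 * np.pi * (18 / 460) * t)
        freqs, amp = fm.amplitude_spectrum(x, 2.0)
        near = np.abs(freqs - 18 / 460) <= (freqs[1] - freqs[0]) * 1.5
        assert amp[near].sum() / amp[freqs > 0].sum() > 0.95

    def test_constant_series_has_zero_fluctuation(self):
        freqs, amp = fm.amplitude_spectrum(np.full(64, 3.7), 2.0)
        np.testing.assert_allclose(amp[freqs > 0], 0.0, atol=1e-9)

    def test_rejects_nonfinite_and_short_input(self):
        with pytest.raises(ValueError):
            fm.amplitude_spectrum(np.array([1.0, np.nan] * 8), 2.0)
        with pytest.raises(ValueError):
            fm.amplitude_spectrum(np.ones(4), 2.0)


class TestFalff:
    def test_low_band_tone_gives_ratio_near_one(self):
        t = np.arange(230) * 2.0
        assert fm.falff(np.cos(2 * np.pi * (18 / 460) * t), 2.0) >= 0.95

    def test_high_band_tone_gives_ratio_near_zero(self):
        t = np.arange(230) * 2.0
        assert fm.falff(np.cos(2 * np.pi * (92 / 460) * t), 2.0) <= 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64)
        assert fm.falff(x, 2.0) == pytest.approx(naive_falff(x, 2.0), abs=1e-10)

    @pytest.mark.parametrize("c", [3.0, -2.5, 1e-6, 1e6])
    def test_scale_invariance(self, c):
        x = np.random.default_rng(7).normal(size=100)
        assert fm.falff(c * x, 2.0) == pytest.approx(fm.falff(x, 2.0), abs=1e-12)

    def test_white_noise_mean_ratio_equals_bin_count_ratio(self):
        # with iid spectra every bin has the same expected amplitude, so the
        # expected ratio is the ratio of bin counts in the two bands
        rng = np.random.default_rng(10)
        n, tr = 64, 2.0
        freqs = np.fft.rfftfreq(n, tr)
        expected = band_mask(freqs, (0.01, 0.08)).sum() / band_mask(freqs, (0.0, 0.25)).sum()
        vals = falff_matrix(rng.normal(size=(4000, n)), tr)
        assert vals.mean() == pytest.approx(expected, abs=0.02)

    def test_constant_series_returns_zero(self):
        assert fm.falff(np.full(64, 2.0), 2.0) == 0.0

    def test_band_exceeding_nyquist_names_the_limit(self):
        x = np.random.default_rng(0).normal(size=64)
        with pytest.raises(ValueError, match="0.25"):
            fm.falff(x, 2.0, band_full=(0.0, 0.3))

    def test_band_additivity(self):
        x = np.random.default_rng(3).normal(size=230)
        freqs, amp = fm.amplitude_spectrum(x, 2.0)
        full = amp[band_mask(freqs, (0.0, 0.25))].sum()
        split = sum(
            amp[band_mask(freqs, b)].sum()
            for b in [(0.0, 0.0805), (0.0806, 0.152), (0.1521, 0.25)]
        )
        assert split == pytest.approx(full, abs=1e-10)


class TestRegressConfounds:
    def _scan(self, series_matrix, confounds):
        n_vox, T = series_matrix.shape
        series = series_matrix.reshape(n_vox, 1, 1, T)
        mask = np.ones((n_vox, 1, 1), dtype=bool)
        return SubjectScan(series=series, mask=mask, tr_seconds=2.0, confounds=confounds)

    def test_series_equal_to_confound_is_annihilated(self):
        T = 50
        conf = pd.DataFrame({"trend": np.linspace(0, 1, T), "wm": np.sin(np.arange(T))})
        scan = self._scan(np.vstack([conf["wm"].to_numpy()]), conf)
        out = fm.regress_confounds(scan, ["trend", "wm"])
        np.testing.assert_allclose(out.series[out.mask], 0.0, atol=1e-10)

    def test_zero_column_design_raises_naming_column(self):
        T = 30
        conf = pd.DataFrame({"trend": np.linspace(0, 1, T), "dead": np.zeros(T)})
        scan = self._scan(np.random.default_rng(0).normal(size=(2, T)), conf)
        with pytest.raises(ValueError, match="dead"):
            fm.regress_confounds(scan, ["trend", "dead"])

    def test_matches_pseudo_inverse_oracle(self):
        rng = np.random.default_rng(5)
        T, q, n_vox = 60, 4, 7
        conf = pd.DataFrame(rng.normal(size=(T, q)), columns=[f"c{i}" for i in range(q)])
        Y = rng.normal(size=(n_vox, T))
        scan = self._scan(Y, conf)
        out = fm.regress_confounds(scan)
        D = np.column_stack([np.ones(T), conf.to_numpy()])
        expected = Y.T - D @ (np.linalg.pinv(D) @ Y.T)
        np.testing.assert_allclose(out.series[out.mask].T, expected, atol=1e-8)
        # residuals orthogonal to the design
        assert np.abs(D.T @ out.series[out.mask].T).max() <= 1e-6 * np.abs(Y).max() * T


class TestFalffMap:
    def _scan_from_matrix(self, M, shape, mask=None):
        n_vox = M.shape[0]
        series = np.zeros(shape + (M.shape[1],))
        mask = np.ones(shape, dtype=bool) if mask is None else mask
        series[mask] = M
        conf = pd.DataFrame({"trend": np.linspace(0, 1, M.shape[1])})
        return SubjectScan(series=series, mask=mask, tr_seconds=2.0, confounds=conf)

    def test_identical_voxels_give_symmetric_z(self):
        x = np.random.default_rng(1).normal(size=64)
        y = np.random.default_rng(2).normal(size=64)
        mask = np.zeros((2, 1, 1), dtype=bool)
        mask[:, 0, 0] = True
        scan = self._scan_from_matrix(np.vstack([x, y]), (2, 1, 1), mask)
        m = fm.falff_map(scan)
        np.testing.assert_allclose(m.masked_z.sum(), 0.0, atol=1e-10)
        np.testing.assert_allclose(np.abs(m.masked_z), np.abs(m.masked_z)[::-1], atol=1e-10)

    def test_voxel_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(12, 64))
        scan = self._scan_from_matrix(M, (12, 1, 1))
        vals = fm.falff_map(scan).masked_values
        perm = rng.permutation(12)
        vals_p = fm.falff_map(self._scan_from_matrix(M[perm], (12, 1, 1))).masked_values
        np.testing.assert_allclose(vals_p, vals[perm], atol=1e-12)

    def test_equals_per_voxel_scalar_loop(self, small_cohort):
        scans, _ = small_cohort
        scan = scans[0]
        m = fm.falff_map(scan)
        Y = scan.series[scan.mask]
        looped = np.array([fm.falff(Y[i], scan.tr_seconds) for i in range(min(25, len(Y)))])
        np.testing.assert_allclose(m.masked_values[:25], looped, atol=1e-10)

    def test_zmap_standardised_over_mask(self, small_cohort):
        scans, _ = small_cohort
        m = fm.falff_map(scans[0])
        assert m.masked_z.mean() == pytest.approx(0.0, abs=1e-8)
        assert m.masked_z.std() == pytest.approx(1.0, abs=1e-8)
        assert np.all((m.masked_values >= 0) & (m.masked_values <= 1))

    def test_constant_volume_raises(self):
        scan = self._scan_from_matrix(np.ones((4, 64)), (4, 1, 1))
        with pytest.raises(ValueError, match="variance"):
            fm.falff_map(scan)

    def test_prefilter_mode_runs_and_stays_in_unit_interval(self, small_cohort):
        scans, _ = small_cohort
        m = fm.falff_map(scans[0], FALFFConfig(prefilter=(0.01, 0.10)))
        assert np.all((m.masked_values >= 0) & (m.masked_values <= 1))
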