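import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diatom_sync.errors import AnalysisError, ValidationError
from diatom_sync.ld_forward import RatioSeries
from diatom_sync.spectra import (
    PowerSpectrum,
    characterize_peak,
    entrainment_index,
    peak_prominences,
    power_spectrum,
    preprocess,
)

FWHM_FACTOR = 2 * math.sqrt(2 * math.log(2))


def brute_force_dft_power(x, dt):
    """O(N²) direct discrete transform with the package's normalization."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    ks = np.arange(n // 2 + 1)
    power = np.empty(len(ks))
    for i, k in enumerate(ks):
        coeff = np.sum(x * np.exp(-2j * math.pi * k * np.arange(n) / n))
        power[i] = abs(coeff) ** 2 / n**2
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = ks / (n * dt)
    return freqs[1:], power[1:]


def brute_force_prominences(y):
    """Exhaustive topographic prominence by contour search."""
    y = np.asarray(y, dtype=float)
    out = []
    for i in range(1, len(y) - 1):
        if y[i] > y[i - 1] and y[i] > y[i + 1]:
            # walk left until a higher point; the key saddle is the min
            left_min = y[i]
            j = i - 1
            left_bound = None
            while j >= 0:
                if y[j] > y[i]:
                    left_bound = j
                    break
                left_min = min(left_min, y[j])
                j -= 1
            if left_bound is None:
                left_min = np.min(y[: i + 1])
            right_min = y[i]
            j = i + 1
            right_bound = None
            while j < len(y):
                if y[j] > y[i]:
                    right_bound = j
                    break
                right_min = min(right_min, y[j])
                j += 1
            if right_bound is None:
                right_min = np.min(y[i:])
            out.append((i, y[i] - max(left_min, right_min)))
    return out


def make_ratio(times, values, valid=None):
    valid = np.ones(len(times), dtype=bool) if valid is None else valid
    return RatioSeries(times=np.asarray(times, float), ratio=np.asarray(values, float), valid=valid)


class TestPreprocess:
    def test_constant_series_maps_to_zeros(self):
        t = np.arange(128.0)
        sig, dt, _ = preprocess(make_ratio(t, np.full(128, 3.3)))
        assert np.allclose(sig, 0.0, atol=1e-12)
        assert dt == 1.0

    def test_linear_ramp_removed(self):
        t = np.arange(128.0)
        sig, _, _ = preprocess(make_ratio(t, 0.5 + 0.01 * t))
        assert np.allclose(sig, 0.0, atol=1e-10)

    def test_sinusoid_plus_ramp_recovered(self):
        # closed-form oracle: the result must equal the OLS line-fit residual
        t = np.arange(1024.0)
        wave = np.sin(2 * math.pi * t * 8 / 1024)
        data = wave + 0.3 + 0.002 * t
        slope, intercept = np.polyfit(t, data, 1)
        expected = data - (slope * t + intercept)
        sig, _, _ = preprocess(make_ratio(t, data))
        assert np.sqrt(np.mean((sig - expected) ** 2)) < 1e-9
        # and the line removal leaves the oscillation essentially intact
        assert np.sqrt(np.mean((sig - wave) ** 2)) < 0.1

    def test_too_few_samples_rejected(self):
        t = np.arange(32.0)
        with pytest.raises(AnalysisError):
            preprocess(make_ratio(t, np.sin(t)))

    def test_non_uniform_sampling_rejected(self):
        t = np.arange(128.0)
        t[64] += 0.5
        with pytest.raises(AnalysisError):
            preprocess(make_ratio(t, np.sin(t)))

    def test_invalid_points_reported(self):
        t = np.arange(130.0)
        valid = np.ones(130, dtype=bool)
        valid[:2] = False  # leading gap only → grid stays uniform
        sig, _, report = preprocess(make_ratio(t, np.sin(t / 5), valid))
        assert report["n_dropped"] == 2
        assert report["n_samples"] == 128

    def test_interior_gap_breaks_uniformity(self):
        t = np.arange(130.0)
        valid = np.ones(130, dtype=bool)
        valid[60] = False
        with pytest.raises(AnalysisError):
            preprocess(make_ratio(t, np.sin(t / 5), valid))

    def test_zscore_option(self):
        t = np.arange(128.0)
        sig, _, _ = preprocess(make_ratio(t, np.sin(2 * math.pi * t / 16)), zscore=True)
        assert np.std(sig) == pytest.approx(1.0)


class TestPowerSpectrum:
    def test_bin_centered_sinusoid_parseval(self):
        n, dt = 512, 1.0
        t = np.arange(n) * dt
        x = np.sin(2 * math.pi * 10 * t / n)  # exactly bin 10
        ps = power_spectrum(x, dt)
        k = np.argmax(ps.power)
        assert ps.frequencies[k] == pytest.approx(10 / n)
        assert ps.power[k] == pytest.approx(0.5, rel=1e-9)
        assert ps.power.sum() == pytest.approx(np.var(x), rel=1e-9)

    def test_matches_brute_force_dft(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(128)
        x -= x.mean()
        ps = power_spectrum(x, 0.5)
        freqs, power = brute_force_dft_power(x, 0.5)
        assert np.allclose(ps.frequencies, freqs, rtol=1e-12)
        assert np.allclose(ps.power, power, rtol=1e-9, atol=1e-15)

    def test_white_noise_spectrum_is_flat_on_average(self):
        rng = np.random.default_rng(1)
        n, reps = 256, 400
        acc = np.zeros(n // 2)
        for _ in range(reps):
            x = rng.standard_normal(n)
            x -= x.mean()
            acc += power_spectrum(x, 1.0).power
        # the folded one-sided Nyquist bin legitimately carries half power
        mean_bins = (acc / reps)[:-1]
        assert mean_bins.max() / mean_bins.min() < 1.5

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=25, deadline=None)
    def test_parseval_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(64, 300))
        x = rng.standard_normal(n)
        x -= x.mean()
        ps = power_spectrum(x, 2.0)
        assert ps.power.sum() == pytest.approx(np.var(x), rel=1e-9)

    def test_short_signal_rejected(self):
        with pytest.raises(AnalysisError):
            power_spectrum(np.zeros(63), 1.0)

    def test_odd_length_parseval(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(129)
        x -= x.mean()
        ps = power_spectrum(x, 1.0)
        assert ps.power.sum() == pytest.approx(np.var(x), rel=1e-9)


class TestPeakProminences:
    def spectrum_from(self, power):
        power = np.asarray(power, dtype=float)
        return PowerSpectrum(frequencies=np.arange(1, len(power) + 1) * 0.01, power=power)

    def test_single_triangular_peak_median_power_mode(self):
        power = np.array([0.1, 0.1, 0.1, 5.0, 0.1, 0.1, 0.1])
        pro, locs = peak_prominences(self.spectrum_from(power), normalization="median_power")
        assert locs == [3]
        assert pro[0] == pytest.approx(4.9 / np.median(power))

    def test_monotone_spectrum_has_no_peaks(self):
        pro, locs = peak_prominences(self.spectrum_from(np.arange(10.0)))
        assert pro == [] and locs == []

    def test_two_equal_peaks_valley_depth(self):
        power = np.array([0.0, 3.0, 1.0, 3.0, 0.0])
        pro, locs = peak_prominences(self.spectrum_from(power), normalization="median_power")
        oracle = dict(brute_force_prominences(power))
        assert set(locs) == set(oracle)
        med = np.median(power)
        for p, i in zip(pro, locs):
            assert p == pytest.approx(oracle[i] / med)
        assert locs[0] == 1  # tie broken toward lower frequency

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_exhaustive_contour_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 64))
        power = rng.exponential(1.0, n)
        pro, locs = peak_prominences(self.spectrum_from(power), normalization="median_power")
        oracle = dict(brute_force_prominences(power))
        med = np.median(power)
        assert set(locs) == set(oracle)
        for p, i in zip(pro, locs):
            assert p == pytest.approx(oracle[i] / med, rel=1e-9)
        assert all(pro[i] >= pro[i + 1] - 1e-12 for i in range(len(pro) - 1))

    def test_top_mean_mode_is_scale_invariant(self):
        rng = np.random.default_rng(9)
        power = rng.exponential(1.0, 200)
        a, _ = peak_prominences(self.spectrum_from(power))
        b, _ = peak_prominences(self.spectrum_from(power * 1e6))
        assert np.allclose(a, b, rtol=1e-12)

    def test_unknown_normalization_rejected(self):
        with pytest.raises(ValidationError):
            peak_prominences(self.spectrum_from(np.ones(5)), normalization="nope")


class TestCharacterizePeak:
    def gaussian_spectrum(self, pk=2.0, f0=1.0 / 140.0, sigma=1e-3, df=1e-4, fmax=0.05):
        freqs = np.arange(df, fmax, df)
        power = pk * np.exp(-((freqs - f0) ** 2) / (2 * sigma**2))
        return PowerSpectrum(frequencies=freqs, power=power)

    def test_gaussian_parameter_recovery(self):
        ps = self.gaussian_spectrum()
        summary = characterize_peak(ps)
        assert summary.pk == pytest.approx(2.0, rel=0.01)
        assert summary.f0_hz == pytest.approx(1.0 / 140.0, rel=0.01)
        assert summary.fwhm_hz == pytest.approx(FWHM_FACTOR * 1e-3, rel=0.01)
        assert summary.normalized_amplitude == pytest.approx(summary.pk / summary.fwhm_hz)
        assert summary.mean_period_s * summary.f0_hz == pytest.approx(1.0)

    def test_flat_spectrum_with_jitter_uses_full_spectrum_mode(self):
        rng = np.random.default_rng(5)
        freqs = np.arange(1, 201) * 1e-4
        power = 1.0 + 1e-3 * rng.standard_normal(200)
        summary = characterize_peak(PowerSpectrum(frequencies=freqs, power=np.abs(power)))
        assert summary.fit_mode == "full_spectrum"

    def test_isolated_peak_uses_main_peak_mode(self):
        rng = np.random.default_rng(6)
        freqs = np.arange(1, 501) * 1e-4
        power = np.abs(0.01 * rng.standard_normal(500)) + 1e-4
        power[200:203] += [2.0, 5.0, 2.0]
        summary = characterize_peak(PowerSpectrum(frequencies=freqs, power=power))
        assert summary.fit_mode == "main_peak"
        assert summary.f0_hz == pytest.approx(freqs[201], rel=0.02)

    def test_fit_mode_is_reproducible(self):
        ps = self.gaussian_spectrum()
        assert characterize_peak(ps).fit_mode == characterize_peak(ps).fit_mode

    @pytest.mark.parametrize("cycles", [20.3, 33.7, 47.5])
    def test_f0_within_one_bin_for_off_grid_sinusoids(self, cycles):
        n, dt = 2048, 1.0
        t = np.arange(n) * dt
        true_f = cycles / (n * dt)
        x = np.sin(2 * math.pi * true_f * t)
        sig, _, _ = preprocess(make_ratio(t, x + 0.5))
        ps = power_spectrum(sig, dt)
        summary = characterize_peak(ps)
        assert abs(summary.f0_hz - true_f) <= ps.df


class TestEntrainmentIndex:
    def summary(self, pk=1.0, na=10.0):
        from diatom_sync.spectra import SpectralPeakSummary

        return SpectralPeakSummary(
            pro=[3.0, 1.0],
            fit_mode="main_peak",
            pk=pk,
            f0_hz=1 / 140,
            fwhm_hz=pk / na,
            normalized_amplitude=na,
            mean_period_s=140.0,
        )

    def test_identical_inputs_give_unity(self):
        s = self.summary()
        idx = entrainment_index(s, s)
        assert idx.pk_ratio == pytest.approx(1.0)
        assert idx.normalized_amplitude_ratio == pytest.approx(1.0)
        assert idx.defined

    def test_zero_constant_peak_flagged_undefined(self):
        idx = entrainment_index(self.summary(), self.summary(pk=0.0))
        assert not idx.defined
        assert math.isnan(idx.pk_ratio)

    def test_ratio_scales_with_pulsed_peak(self):
        idx = entrainment_index(self.summary(pk=6.0), self.summary(pk=2.0))
        assert idx.pk_ratio == pytest.approx(3.0)
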