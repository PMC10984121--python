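"""Tests for the nine-statistic characterization ledger."""

import numpy as np
import pytest

from conftest import brute_force_apen
from electrome import (DegenerateInputError, ElectromeSeries, FeatureConfig,
                       ParameterError, approximate_entropy,
                       autocorrelation_summary, feature_ledger, fft_spectrum,
                       fit_pdf_exponent, fit_psd_exponent,
                       generate_colored_noise, mean_voltage_variation,
                       moments, multiscale_apen)
from electrome.features import coarse_grain
from electrome.synthetic import truncated_power_law


class TestMeanVoltageVariation:
    def test_hand_computed_absolute_mean(self):
        assert mean_voltage_variation([0.001, -0.001, 0.002, -0.002]) \
            == pytest.approx(0.0015)

    def test_zero_and_constant(self):
        assert mean_voltage_variation(np.zeros(10)) == 0.0
        assert mean_voltage_variation(np.full(10, 0.3)) == pytest.approx(0.3)

    def test_signed_option(self):
        assert mean_voltage_variation([1.0, -1.0], signed=True) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            mean_voltage_variation([])


class TestMoments:
    def test_symmetric_skew_zero(self):
        skew, _ = moments([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_normal_excess_kurtosis(self, rng):
        _, kurt = moments(rng.standard_normal(1_000_000))
        assert abs(kurt) < 0.05

    def test_exponential_skewness(self, rng):
        skew, _ = moments(rng.exponential(size=1_000_000))
        assert abs(skew - 2.0) < 0.05  # closed form for the exponential

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            moments(np.full(100, 2.0))


class TestPdfExponent:
    @pytest.mark.parametrize("mu", [1.5, 2.5])
    def test_recovery_on_known_generator(self, mu):
        x = truncated_power_law(mu, 0.05, 10.0, 100_000, seed=11)
        fit = fit_pdf_exponent(x, fit_range=(0.05, 10.0))
        assert fit.ok
        assert abs(fit.value - mu) < 0.2

    def test_gaussian_fits_worse_than_power_law(self, rng):
        pl = truncated_power_law(2.5, 0.05, 10.0, 100_000, seed=1)
        gauss = np.abs(rng.normal(0, 1.0, 100_000))
        fit_pl = fit_pdf_exponent(pl, fit_range=(0.05, 10.0))
        fit_g = fit_pdf_exponent(gauss, fit_range=(0.05, 4.0))
        assert fit_g.r_squared < fit_pl.r_squared

    def test_too_few_tail_points_flags_not_raises(self):
        fit = fit_pdf_exponent(np.array([0.1, 0.2, 0.3]))
        assert not fit.ok
        assert np.isnan(fit.value)


class TestAutocorrelation:
    def test_white_noise_decorrelates_immediately(self, rng):
        res = autocorrelation_summary(rng.normal(size=10_000), rate=62.5)
        assert res.lag_samples <= 2
        assert res.lag_seconds <= 2 / 62.5

    def test_ar1_closed_form_lag(self):
        # ACF of AR(1) is phi^k; first crossing of 1/e at -1/ln(0.9) ~ 9.5
        lags = []
        for s in range(20):
            rng = np.random.default_rng(s)
            x = np.empty(20_000)
            x[0] = rng.normal()
            eps = rng.normal(size=20_000)
            for i in range(1, x.size):
                x[i] = 0.9 * x[i - 1] + eps[i]
            lags.append(autocorrelation_summary(x, rate=1.0).lag_samples)
        assert abs(np.mean(lags) - 9.5) < 2.0

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            autocorrelation_summary(np.ones(1000), rate=62.5)

    def test_censoring_reported(self):
        t = np.arange(2000)
        slow = np.sin(2 * np.pi * t / 100_000)  # never decorrelates
        res = autocorrelation_summary(slow, rate=1.0, max_lag=50)
        assert res.censored
        assert res.lag_samples == 50


class TestPsdExponent:
    def test_white_noise_flat(self):
        est = [fit_psd_exponent(np.random.default_rng(s).normal(size=16384),
                                rate=62.5).value for s in range(10)]
        assert abs(np.mean(est)) < 0.1

    def test_too_narrow_band_flags(self, rng):
        fit = fit_psd_exponent(rng.normal(size=8192), rate=62.5,
                               fit_band_hz=(0.05, 0.06))
        assert not fit.ok

    def test_short_series_rejected(self, rng):
        with pytest.raises(DegenerateInputError):
            fit_psd_exponent(rng.normal(size=100), rate=62.5)


class TestFftSpectrum:
    def test_pure_sine_peaks_at_its_frequency(self):
        t = np.arange(6250) / 62.5
        freqs, mags = fft_spectrum(np.sin(2 * np.pi * 5.0 * t), rate=62.5)
        assert freqs[np.argmax(mags)] == pytest.approx(5.0, abs=0.02)
        assert freqs[-1] == pytest.approx(31.25)

    def test_parseval_consistency(self, rng):
        x = rng.normal(size=1024)
        spec = np.fft.rfft(x)
        power = np.abs(spec) ** 2
        # double the interior one-sided bins for the discrete relation
        power[1:-1] *= 2
        assert np.sum(power) / x.size == pytest.approx(np.sum(x ** 2),
                                                       rel=1e-9)

    def test_linearity(self, rng):
        t = np.arange(2048) / 62.5
        a = np.sin(2 * np.pi * 3.0 * t)
        b = np.sin(2 * np.pi * 11.0 * t)
        _, m_sum = fft_spectrum(a + b, rate=62.5)
        spec_sum = np.fft.rfft(a) + np.fft.rfft(b)
        mags = np.abs(spec_sum) * 2 / t.size
        mags[0] /= 2
        mags[-1] /= 2
        assert np.allclose(m_sum, mags, atol=1e-12)

    def test_wiener_khinchin_consistency(self, rng):
        # periodogram == FFT of the circular sample autocovariance
        x = rng.normal(size=1024)
        periodogram = np.abs(np.fft.rfft(x)) ** 2 / x.size
        acv = np.array([np.mean(x * np.roll(x, -k)) for k in range(x.size)])
        assert np.allclose(np.fft.rfft(acv).real, periodogram, atol=1e-8)


class TestApproximateEntropy:
    def test_constant_series_is_zero(self):
        assert approximate_entropy(np.full(100, 2.0)) == 0.0

    def test_matches_brute_force_definition(self, rng):
        for _ in range(10):
            n = int(rng.integers(30, 500))
            x = rng.normal(size=n)
            r = 0.2 * np.std(x)
            assert approximate_entropy(x, m=2, r=r) == pytest.approx(
                brute_force_apen(x, 2, r), abs=1e-9)

    def test_periodic_below_shuffled(self):
        # a periodic square wave is more regular than its random shuffle
        base = np.tile([0.0] * 5 + [1.0] * 5, 30)
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            shuffled = rng.permutation(base)
            r = 0.2 * np.std(base)
            if approximate_entropy(base, r=r) \
                    < approximate_entropy(shuffled, r=r):
                wins += 1
        assert wins == 20

    def test_invalid_parameters(self):
        with pytest.raises(ParameterError):
            approximate_entropy(np.arange(3), m=2)
        with pytest.raises(ParameterError):
            approximate_entropy(np.arange(100, dtype=float), r=-1.0)


class TestMultiscaleApen:
    def test_scale_one_equals_apen(self, rng):
        x = rng.normal(size=600)
        ms = multiscale_apen(x, max_scale=5)
        assert ms[0] == approximate_entropy(x)

    def test_coarse_grained_lengths(self, rng):
        x = rng.normal(size=1000)
        for s in (1, 3, 7, 50):
            assert coarse_grain(x, s).size == 1000 // s

    def test_white_noise_decreases_across_scales(self):
        # the expected multiscale curve of white noise decreases; average
        # over seeds to suppress single-series estimator noise
        curves = [multiscale_apen(np.random.default_rng(s).normal(size=3000),
                                  max_scale=20) for s in range(5)]
        diffs = np.diff(np.mean(curves, axis=0))
        assert np.sum(diffs >= 0) <= 1  # 5% of the 19 scale transitions

    def test_too_short_for_scale_names_feasible(self, rng):
        with pytest.raises(ParameterError, match="at most scale"):
            multiscale_apen(rng.normal(size=100), max_scale=50)


class TestFeatureLedger:
    def test_constant_series_flags_moments(self):
        series = ElectromeSeries(np.zeros(5000), rate=62.5)
        led = feature_ledger(series, FeatureConfig(compute_msapen=False))
        assert led.mean_dv == 0.0
        assert led.apen == 0.0
        assert "moments" in led.errors
        assert "acf" in led.errors

    def test_deterministic(self, rng):
        series = ElectromeSeries(rng.normal(size=6000) * 0.02, rate=62.5)
        cfg = FeatureConfig(apen_max_points=500, max_scale=5)
        a = feature_ledger(series, cfg)
        b = feature_ledger(series, cfg)
        assert a.to_row() == b.to_row()
        assert np.array_equal(a.msapen, b.msapen)

    def test_msapen_scale1_consistent_with_apen(self, rng):
        series = ElectromeSeries(rng.normal(size=2000), rate=62.5)
        cfg = FeatureConfig(apen_max_points=400, max_scale=4)
        led = feature_ledger(series, cfg)
        assert led.msapen[0] == led.apen

    def test_pink_noise_ledger_beta_near_one(self):
        x = generate_colored_noise(65536, 62.5, 1.0, 0.02, seed=5)
        series = ElectromeSeries(x, rate=62.5)
        led = feature_ledger(series, FeatureConfig(apen_max_points=300,
                                                   compute_msapen=False))
        assert led.psd_beta.ok
        assert abs(led.psd_beta.value - 1.0) < 0.15
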