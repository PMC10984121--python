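"""Tests for the synthetic electrophytogram generators."""

import numpy as np
import pytest

from electrome import (ElectromeSeries, ParameterError, SpikeProfile,
                       fit_pdf_exponent, fit_psd_exponent,
                       generate_colored_noise, generate_manifest,
                       generate_spike_train, default_session_manifest,
                       synthesize_electrome)
from electrome.errors import ConfigError
from electrome.synthetic import (fit_profile_to_duration, poisson_event_times,
                                 spike_waveform, truncated_power_law)
from electrome.types import ExperimentDesign, SessionManifest


class TestColoredNoise:
    def test_mean_zero_and_target_sd(self):
        x = generate_colored_noise(4096, 62.5, 1.3, 0.02, seed=0)
        assert x.size == 4096
        assert abs(x.mean()) < 1e-12
        assert abs(x.std() - 0.02) / 0.02 < 0.01

    def test_deterministic_given_seed(self):
        a = generate_colored_noise(1024, 62.5, 1.0, 1.0, seed=42)
        b = generate_colored_noise(1024, 62.5, 1.0, 1.0, seed=42)
        assert np.array_equal(a, b)

    @pytest.mark.parametrize("beta,tol", [(0.0, 0.1), (1.0, 0.15), (2.0, 0.15)])
    def test_spectral_exponent_recovery(self, beta, tol):
        # white noise must be flat; pink/brown must fit back to 1 and 2
        est = [fit_psd_exponent(
            generate_colored_noise(16384, 62.5, beta, 1.0, seed=s),
            rate=62.5).value for s in range(10)]
        assert abs(np.mean(est) - beta) < tol

    @pytest.mark.parametrize("bad", [dict(n=1), dict(sigma=0.0),
                                     dict(sigma=-1.0), dict(beta=-0.5)])
    def test_invalid_parameters(self, bad):
        kwargs = dict(n=256, rate=62.5, beta=1.0, sigma=1.0)
        kwargs.update(bad)
        with pytest.raises(ParameterError):
            generate_colored_noise(**kwargs, seed=0)


class TestSpikeTrain:
    def test_zero_rate_gives_silence(self):
        x = generate_spike_train(600, 0.0, SpikeProfile(), 62.5, seed=0)
        assert np.all(x == 0)

    def test_poisson_event_counts(self):
        # 60 events/h over 2 h -> mean 120, Poisson SE sqrt(120/50)
        counts = [poisson_event_times(7200, 60, seed=s).size
                  for s in range(50)]
        se = np.sqrt(120 / 50)
        assert abs(np.mean(counts) - 120) < 3 * se

    def test_amplitude_power_law_recovery(self):
        amps = truncated_power_law(2.5, 0.05, 10.0, 10_000, seed=7)
        fit = fit_pdf_exponent(amps, fit_range=(0.05, 10.0))
        assert fit.ok
        assert abs(fit.value - 2.5) < 0.2

    def test_waveform_shapes(self):
        ap = spike_waveform("ap_like", 4.0, 62.5)
        vp = spike_waveform("vp_like", 60.0, 62.5)
        assert np.max(np.abs(ap)) == pytest.approx(1.0)
        assert ap.min() < -0.5 < 0.5 < ap.max()     # biphasic
        assert vp.min() >= 0.0                       # monophasic
        with pytest.raises(ConfigError):
            spike_waveform("square", 1.0, 62.5)

    def test_waveform_longer_than_series_rejected(self):
        profile = SpikeProfile(duration_s=100.0)
        with pytest.raises(ParameterError):
            generate_spike_train(10.0, 60, profile, 62.5, seed=0)


class TestSynthesize:
    def test_canonical_length(self, profiles):
        series = synthesize_electrome(profiles["water"], "before", seed=1)
        assert len(series) == 450_000
        assert series.rate == 62.5

    def test_resting_baseline_amplitude(self, profiles):
        # resting electromes oscillate within +-0.05 mV
        series = synthesize_electrome(profiles["water"], "before", seed=1,
                                      duration_s=1800.0)
        assert np.mean(np.abs(series.samples) <= 0.05) >= 0.95

    def test_deterministic(self, profiles):
        a = synthesize_electrome(profiles["peg"], "after", seed=9,
                                 duration_s=120.0)
        b = synthesize_electrome(profiles["peg"], "after", seed=9,
                                 duration_s=120.0)
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_phase_rejected(self, profiles):
        with pytest.raises(ConfigError):
            synthesize_electrome(profiles["water"], "during", seed=0)

    def test_nacl_burst_density(self, profiles):
        # burst multiplies the Poisson rate in the configured early window;
        # compare early/late event densities against the configured ratio
        prof = profiles["nacl"]
        mult = prof.burst.rate_multiplier
        burst_end_min = prof.burst.end_s / 60
        early, late, expected_events = [], [], 0.0
        for s in range(20):
            series = synthesize_electrome(prof, "after", seed=s)
            ev = np.asarray(series.meta["spike_times_s"]) / 60.0
            early.append(np.sum(ev < 30) / 30)
            late.append(np.sum(ev >= 60) / 60)
        # expected early density per min: burst portion at mult x base rate
        base = prof.post_spikes.events_per_hour / 60
        exp_early = base * (burst_end_min * mult + (30 - burst_end_min)) / 30
        n_early = np.sum(early) * 30
        se = np.sqrt(n_early) / (20 * 30)
        assert abs(np.mean(early) - exp_early) < 3 * se
        assert np.mean(early) > mult / 2 * np.mean(late)

    def test_slow_waves_present_after_nacl(self, profiles):
        after = synthesize_electrome(profiles["nacl"], "after", seed=3)
        before = synthesize_electrome(profiles["nacl"], "before", seed=3)
        assert after.samples.std() > 3 * before.samples.std()


class TestManifest:
    def test_default_session_design(self):
        m = default_session_manifest()
        assert m.samples_per_series == 450_000
        assert m.n_electrome_series == 288
        per_exp = {e.name: e.n_plants * len(e.phases) for e in m.experiments}
        assert per_exp == {"water": 60, "nutrient": 42, "peg": 108,
                           "nacl": 78}
        assert m.n_reference_series == 96
        assert m.total_points == 172_800_000

    def test_empty_design(self):
        m = SessionManifest(experiments=[])
        assert m.n_electrome_series == 0
        assert m.total_points == 0
        entries, _ = generate_manifest(m, seed=0)
        assert entries == []

    def test_entries_enumeration_and_determinism(self, profiles):
        m = SessionManifest(
            experiments=[ExperimentDesign("water", n_plants=2,
                                          n_reference=1)],
            duration_s=60.0)
        entries, make = generate_manifest(m, profiles=profiles, seed=5)
        assert len(entries) == 5  # 2 plants x 2 phases + 1 reference
        a = make(entries[0])
        b = make(entries[0])
        assert np.array_equal(a.samples, b.samples)
        assert len(a) == m.samples_per_series

    def test_profile_rescaling_for_short_recordings(self, profiles):
        prof = fit_profile_to_duration(profiles["nacl"], 720.0)
        assert prof.burst.end_s <= 720.0
        assert prof.burst.rate_multiplier == profiles["nacl"].burst.rate_multiplier
        # canonical duration: untouched
        assert fit_profile_to_duration(profiles["nacl"], 7200.0) \
            is profiles["nacl"]
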