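"""Synthetic electrophytogram generation.

No raw plant recordings are publicly available for this experimental design,
so every downstream stage is exercised on synthetic series that reproduce the
*statistical* structure reported for real electromes:

* colored-noise baseline with power spectral density ~ 1/f^beta and
  oscillations confined to a few hundredths of a millivolt at rest;
* rare spike events (AP-like biphasic or VP-like slow monophasic waves) whose
  absolute amplitudes follow a truncated power law (the larger the peak, the
  less frequent it is), below +-0.5 mV at rest and reaching +-5-10 mV after
  osmotic stimulation;
* a salt-specific surge of activity in the first tens of minutes after NaCl,
  plus long-period waves carrying embedded spikes.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .errors import ConfigError, ParameterError
from .types import (DEFAULT_DURATION_S, DEFAULT_RATE_HZ, BurstWindow,
                    ElectromeSeries, ExperimentDesign, Phase, SessionManifest,
                    SlowWaves, SpikeProfile, TreatmentProfile)

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator, None]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# colored noise

def generate_colored_noise(n: int, rate: float, beta: float, sigma: float,
                           seed: SeedLike = None) -> np.ndarray:
    """Spectrally synthesized colored noise with PSD ~ 1/f^beta.

    Fourier amplitudes are shaped as f^(-beta/2) with i.i.d. uniform random
    phases; the DC component is zeroed and the result is rescaled so the
    sample mean is exactly 0 and the sample standard deviation exactly
    ``sigma``. beta=0 gives white, beta=1 pink, beta=2 brown noise.

    Parameters
    ----------
    n : int
        Number of samples (>= 2).
    rate : float
        Sampling frequency in Hz.
    beta : float
        Spectral exponent (>= 0).
    sigma : float
        Target sample standard deviation in mV (> 0).
    """
    if not isinstance(n, (int, np.integer)) or n < 2:
        raise ParameterError(f"n must be an integer >= 2, got {n!r}")
    if not rate > 0:
        raise ParameterError("rate must be > 0")
    if beta < 0:
        raise ParameterError("beta must be >= 0")
    if not sigma > 0:
        raise ParameterError("sigma must be > 0")

    rng = _rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amplitude = np.zeros_like(freqs)
    amplitude[1:] = freqs[1:] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    spectrum = amplitude * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        # Nyquist bin must be real for a real-valued signal
        spectrum[-1] = amplitude[-1] * np.cos(phases[-1])
    x = np.fft.irfft(spectrum, n=n)
    x -= x.mean()
    sd = x.std()
    if sd == 0.0:  # pragma: no cover - cannot happen for n >= 2 random phases
        raise ParameterError("degenerate noise draw with zero variance")
    return x * (sigma / sd)


# ---------------------------------------------------------------------------
# spike trains

def truncated_power_law(mu: float, lo: float, hi: float, size: int,
                        seed: SeedLike = None) -> np.ndarray:
    """Draw from the density p(x) ~ x^-mu on [lo, hi] by inverse CDF."""
    if not mu > 1:
        raise ParameterError("mu must be > 1")
    if not 0 < lo < hi:
        raise ParameterError("require 0 < lo < hi")
    rng = _rng(seed)
    u = rng.uniform(0.0, 1.0, size)
    a = lo ** (1.0 - mu)
    b = hi ** (1.0 - mu)
    return (a - u * (a - b)) ** (1.0 / (1.0 - mu))


def poisson_event_times(duration_s: float, rate_per_hour: float,
                        burst: Optional[BurstWindow] = None,
                        seed: SeedLike = None) -> np.ndarray:
    """Event times (s) of a piecewise-homogeneous Poisson process.

    The base rate applies everywhere except inside the optional burst
    window, where it is multiplied by ``burst.rate_multiplier``.
    """
    if not duration_s > 0:
        raise ParameterError("duration_s must be > 0")
    if rate_per_hour < 0:
        raise ParameterError("rate_per_hour must be >= 0")
    rng = _rng(seed)
    lam = rate_per_hour / 3600.0  # events per second
    segments = [(0.0, duration_s, lam)]
    if burst is not None and lam > 0:
        if burst.end_s > duration_s:
            raise ParameterError("burst window exceeds series duration")
        segments = [(0.0, burst.start_s, lam),
                    (burst.start_s, burst.end_s, lam * burst.rate_multiplier),
                    (burst.end_s, duration_s, lam)]
    times = []
    for t0, t1, seg_rate in segments:
        span = t1 - t0
        if span <= 0 or seg_rate <= 0:
            continue
        count = rng.poisson(seg_rate * span)
        times.append(t0 + rng.uniform(0.0, span, count))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def spike_waveform(kind: str, duration_s: float, rate: float) -> np.ndarray:
    """Unit-peak spike template sampled at ``rate``.

    ``ap_like``: biphasic (depolarization followed by repolarization
    overshoot), a Hann-windowed single sine cycle lasting a few seconds.
    ``vp_like``: slow monophasic bump (raised cosine) lasting tens of seconds.
    """
    n = max(3, int(round(duration_s * rate)))
    t = np.arange(n) / n
    if kind == "ap_like":
        w = np.sin(2.0 * np.pi * t) * np.hanning(n)
    elif kind == "vp_like":
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    else:
        raise ConfigError(f"unknown waveform kind {kind!r}")
    return w / np.max(np.abs(w))


def generate_spike_train(duration_s: float, rate_per_hour: float,
                         profile: SpikeProfile, sampling_rate: float,
                         seed: SeedLike = None,
                         burst: Optional[BurstWindow] = None,
                         return_events: bool = False):
    """Superpose spike templates at Poisson event times.

    Absolute amplitudes are truncated-power-law distributed with exponent
    ``profile.amplitude_exponent`` on
    [``amplitude_min``, ``amplitude_max``]; each spike is positive-going
    with probability ``profile.sign_probability``.

    Returns the sample array, or ``(samples, event_times_s)`` when
    ``return_events`` is true.
    """
    if not duration_s > 0:
        raise ParameterError("duration_s must be > 0")
    if not sampling_rate > 0:
        raise ParameterError("sampling_rate must be > 0")
    n = int(round(duration_s * sampling_rate))
    template = spike_waveform(profile.waveform, profile.duration_s,
                              sampling_rate)
    if template.size > n:
        raise ParameterError(
            f"waveform of {template.size} samples does not fit a series of "
            f"{n} samples")
    rng = _rng(seed)
    times = poisson_event_times(duration_s, rate_per_hour, burst=burst,
                                seed=rng)
    out = np.zeros(n)
    if times.size:
        amps = truncated_power_law(profile.amplitude_exponent,
                                   profile.amplitude_min,
                                   profile.amplitude_max, times.size, rng)
        signs = np.where(rng.uniform(size=times.size)
                         < profile.sign_probability, 1.0, -1.0)
        starts = np.minimum((times * sampling_rate).astype(int), n - 1)
        for start, amp, sign in zip(starts, amps, signs):
            stop = min(start + template.size, n)
            out[start:stop] += sign * amp * template[:stop - start]
    if return_events:
        return out, times
    return out


# ---------------------------------------------------------------------------
# full series

def _slow_wave_component(slow: SlowWaves, n: int, rate: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Sum of ``count`` single-cycle slow waves at random onsets."""
    out = np.zeros(n)
    wave_n = max(3, int(round(slow.period_s * rate)))
    t = np.arange(wave_n) / wave_n
    wave = slow.amplitude_mV * np.sin(2.0 * np.pi * t) * np.hanning(wave_n)
    for _ in range(slow.count):
        start = rng.integers(0, max(1, n - wave_n + 1))
        stop = min(start + wave_n, n)
        out[start:stop] += wave[:stop - start]
    return out


def synthesize_electrome(treatment: TreatmentProfile, phase: Phase,
                         plant_id: int = 0, seed: SeedLike = None,
                         rate: float = DEFAULT_RATE_HZ,
                         duration_s: float = DEFAULT_DURATION_S,
                         apply_filter: bool = False,
                         instrument_tones: bool = False) -> ElectromeSeries:
    """Generate one electrophytogram for a treatment and phase.

    Composition: colored-noise baseline + spike train (+ burst-elevated
    rate and slow waves after stimulation, when the profile configures
    them) + optional instrument tones at 2.5/5/7.5 Hz. When
    ``apply_filter`` is true the emulated acquisition high-pass
    (:func:`electrome.signal_io.apply_acquisition_filter`) is applied;
    the default leaves the sub-0.5 Hz structure in place since it is the
    carrier of the 1/f^beta and slow-wave phenomenology being emulated.

    Deterministic given ``seed``.
    """
    if phase not in ("before", "after"):
        raise ConfigError(f"unknown phase {phase!r}")
    treatment.validate_timing(duration_s)
    rng = _rng(seed)
    n = int(round(rate * duration_s))

    baseline = generate_colored_noise(n, rate, treatment.beta_for(phase),
                                      treatment.sigma_for(phase), rng)
    spikes_profile = treatment.spikes_for(phase)
    burst = treatment.burst if phase == "after" else None
    spikes, events = generate_spike_train(
        duration_s, spikes_profile.events_per_hour, spikes_profile, rate,
        seed=rng, burst=burst, return_events=True)
    x = baseline + spikes
    if phase == "after" and treatment.slow_waves is not None:
        x = x + _slow_wave_component(treatment.slow_waves, n, rate, rng)
    if instrument_tones:
        t = np.arange(n) / rate
        tone_amp = treatment.sigma_for(phase) / 5.0
        for f in (2.5, 5.0, 7.5):
            x = x + tone_amp * np.sin(2.0 * np.pi * f * t
                                      + rng.uniform(0, 2 * np.pi))
    meta = {"experiment": treatment.name, "plant_id": plant_id,
            "phase": phase, "is_reference": False,
            "spike_times_s": events.tolist()}
    series = ElectromeSeries(samples=x, rate=rate, meta=meta)
    if apply_filter:
        from .signal_io import apply_acquisition_filter
        series = apply_acquisition_filter(series)
    return series


def fit_profile_to_duration(profile: TreatmentProfile, duration_s: float,
                            reference_s: float = DEFAULT_DURATION_S
                            ) -> TreatmentProfile:
    """Rescale a profile's timed components for a non-canonical duration.

    Profiles describe a 2 h recording (burst in the first ~25 min,
    10-min slow waves). For shorter recordings the burst window and slow
    wave period are scaled by ``duration_s / reference_s`` so the same
    phenomenology occupies the same *fraction* of the recording. Rates
    (events per hour) are left untouched. Returns the profile unchanged
    when everything already fits.
    """
    import dataclasses

    factor = duration_s / reference_s
    changes = {}
    if profile.burst is not None and profile.burst.end_s > duration_s:
        changes["burst"] = BurstWindow(
            start_s=profile.burst.start_s * factor,
            end_s=profile.burst.end_s * factor,
            rate_multiplier=profile.burst.rate_multiplier)
    if profile.slow_waves is not None \
            and profile.slow_waves.period_s > duration_s / 2:
        changes["slow_waves"] = SlowWaves(
            period_s=profile.slow_waves.period_s * factor,
            amplitude_mV=profile.slow_waves.amplitude_mV,
            count=profile.slow_waves.count)
    if not changes:
        return profile
    return dataclasses.replace(profile, **changes)


# ---------------------------------------------------------------------------
# manifests

def default_session_manifest(rate: float = DEFAULT_RATE_HZ,
                           duration_s: float = DEFAULT_DURATION_S
                           ) -> SessionManifest:
    """The four-experiment design: 30/21/54/39 plants recorded before and
    after stimulation (60+42+108+78 = 288 electrophytograms) plus
    20/14/36/26 reference-electrode series."""
    return SessionManifest(
        experiments=[
            ExperimentDesign("water", n_plants=30, n_reference=20),
            ExperimentDesign("nutrient", n_plants=21, n_reference=14),
            ExperimentDesign("peg", n_plants=54, n_reference=36),
            ExperimentDesign("nacl", n_plants=39, n_reference=26),
        ],
        rate=rate, duration_s=duration_s)


def generate_manifest(manifest: SessionManifest,
                      profiles: Optional[dict] = None,
                      seed: SeedLike = None):
    """Enumerate a design and attach a deterministic per-series generator.

    Returns ``(entries, make_series)`` where ``entries`` is the list of
    series descriptors (experiment, plant, phase, reference flag) and
    ``make_series(entry)`` synthesizes the corresponding series on demand.
    Reference series are pure low-amplitude white-ish noise (an electrode
    pair in dead, dry stem tissue records only ambient pickup).
    """
    if profiles is None:
        from .config import default_profiles
        profiles = default_profiles()
    base = np.random.SeedSequence(seed if seed is not None else 0)
    entries = manifest.entries()

    exp_names = [e.name for e in manifest.experiments]

    def make_series(entry: dict) -> ElectromeSeries:
        exp = entry["experiment"]
        if exp not in exp_names:
            raise ConfigError(f"experiment {exp!r} not in manifest")
        phase_code = {"before": 0, "after": 1, "reference": 2}[entry["phase"]]
        child = np.random.SeedSequence(
            entropy=base.entropy,
            spawn_key=(exp_names.index(exp), entry["plant_id"], phase_code))
        rng = np.random.default_rng(child)
        if entry["is_reference"]:
            n = manifest.samples_per_series
            x = generate_colored_noise(n, manifest.rate, beta=0.2,
                                       sigma=0.005, seed=rng)
            return ElectromeSeries(x, manifest.rate,
                                   meta={**entry, "spike_times_s": []})
        if exp not in profiles:
            raise ConfigError(f"no treatment profile named {exp!r}")
        profile = fit_profile_to_duration(profiles[exp], manifest.duration_s)
        return synthesize_electrome(profile, entry["phase"],
                                    plant_id=entry["plant_id"], seed=rng,
                                    rate=manifest.rate,
                                    duration_s=manifest.duration_s)

    return entries, make_series
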