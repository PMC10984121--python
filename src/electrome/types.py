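"""Domain containers for electrophytogram recordings and experimental designs.

An electrophytogram is a voltage-variation time series dV(t), in millivolts,
recorded between a pair of electrodes inserted in a plant stem. A recording
session produces one series per plant per phase (before / after an osmotic
stimulus) plus reference-electrode series that monitor ambient noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import ConfigError, ParameterError

Phase = Literal["before", "after"]

#: Sampling rate (Hz) of the emulated acquisition system.
DEFAULT_RATE_HZ = 62.5
#: Recording duration (s): 2 h per phase.
DEFAULT_DURATION_S = 7200.0


@dataclass
class ElectromeSeries:
    """One voltage-variation recording.

    Parameters
    ----------
    samples : ndarray
        Voltage variation dV_i in mV, one value per sampling interval.
    rate : float
        Sampling frequency in Hz (> 0).
    meta : dict
        Provenance: ``experiment`` (water | nutrient | peg | nacl),
        ``plant_id``, ``phase`` (before | after), ``is_reference`` flag,
        plus any generator bookkeeping (e.g. spike event times).
    """

    samples: np.ndarray
    rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if not self.rate > 0:
            raise ParameterError(f"sampling rate must be > 0, got {self.rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples must all be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.rate

    def with_samples(self, samples: np.ndarray) -> "ElectromeSeries":
        """Copy of this series with the sample array replaced."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       meta=dict(self.meta))


@dataclass
class SpikeProfile:
    """Statistical description of a spike (transient peak) population.

    Spikes emulate the action-potential-like and variation-potential-like
    waves seen riding on the baseline: event times are Poisson, absolute
    amplitudes follow a truncated power law |A| ~ A^-mu on
    [amplitude_min, amplitude_max] (larger peaks are rarer), and the sign
    of each peak is positive with probability ``sign_probability``.
    """

    events_per_hour: float = 6.0
    amplitude_exponent: float = 2.5      # mu of the |amplitude| power law
    amplitude_min: float = 0.05          # mV
    amplitude_max: float = 0.5           # mV
    waveform: Literal["ap_like", "vp_like"] = "ap_like"
    duration_s: float = 4.0              # template support in seconds
    sign_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.events_per_hour < 0:
            raise ParameterError("events_per_hour must be >= 0")
        if not self.amplitude_exponent > 1:
            raise ParameterError("amplitude_exponent must be > 1")
        if not 0 < self.amplitude_min < self.amplitude_max:
            raise ParameterError(
                "require 0 < amplitude_min < amplitude_max, got "
                f"[{self.amplitude_min}, {self.amplitude_max}]")
        if self.waveform not in ("ap_like", "vp_like"):
            raise ConfigError(f"unknown waveform {self.waveform!r}")
        if not self.duration_s > 0:
            raise ParameterError("waveform duration_s must be > 0")
        if not 0 <= self.sign_probability <= 1:
            raise ParameterError("sign_probability must be in [0, 1]")


@dataclass
class BurstWindow:
    """Piecewise-constant elevation of the spike rate inside [start_s, end_s]."""

    start_s: float
    end_s: float
    rate_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ParameterError("burst window must satisfy 0 <= start < end")
        if self.rate_multiplier < 1:
            raise ParameterError("burst rate_multiplier must be >= 1")


@dataclass
class SlowWaves:
    """Long-period wave packets (single slow cycles) added after stimulation."""

    period_s: float = 600.0
    amplitude_mV: float = 1.5
    count: int = 4

    def __post_init__(self) -> None:
        if not self.period_s > 0 or self.amplitude_mV < 0 or self.count < 0:
            raise ParameterError("invalid slow-wave configuration")


@dataclass
class TreatmentProfile:
    """Generating model for one treatment (water, nutrient, PEG or NaCl).

    The baseline is colored noise with spectral exponent ``baseline_beta``
    (power ~ 1/f^beta) and standard deviation ``baseline_sigma`` mV; spikes
    are drawn from phase-specific :class:`SpikeProfile` s. ``post_beta`` /
    ``post_sigma`` optionally override the baseline after stimulation,
    matching the observed phase dependence of the spectral exponent.
    """

    name: str
    baseline_beta: float = 1.75
    baseline_sigma: float = 0.02
    pre_spikes: SpikeProfile = field(default_factory=SpikeProfile)
    post_spikes: SpikeProfile = field(default_factory=SpikeProfile)
    post_beta: Optional[float] = None
    post_sigma: Optional[float] = None
    burst: Optional[BurstWindow] = None
    slow_waves: Optional[SlowWaves] = None

    def __post_init__(self) -> None:
        if self.baseline_beta < 0:
            raise ParameterError("baseline_beta must be >= 0")
        if not self.baseline_sigma > 0:
            raise ParameterError("baseline_sigma must be > 0")

    def beta_for(self, phase: Phase) -> float:
        if phase == "after" and self.post_beta is not None:
            return self.post_beta
        return self.baseline_beta

    def sigma_for(self, phase: Phase) -> float:
        if phase == "after" and self.post_sigma is not None:
            return self.post_sigma
        return self.baseline_sigma

    def spikes_for(self, phase: Phase) -> SpikeProfile:
        if phase == "before":
            return self.pre_spikes
        if phase == "after":
            return self.post_spikes
        raise ConfigError(f"unknown phase {phase!r}")

    def validate_timing(self, duration_s: float) -> None:
        """Check that burst windows fit inside a recording of given length."""
        if self.burst is not None and self.burst.end_s > duration_s:
            raise ParameterError(
                f"burst window ends at {self.burst.end_s} s but the recording "
                f"lasts {duration_s} s")


@dataclass
class ExperimentDesign:
    """Series counts for one experiment (treatment)."""

    name: str
    n_plants: int
    n_reference: int = 0
    phases: Sequence[Phase] = ("before", "after")

    def __post_init__(self) -> None:
        if self.n_plants < 0 or self.n_reference < 0:
            raise ParameterError("series counts must be >= 0")


@dataclass
class SessionManifest:
    """The experimental design: which series exist, and at what size."""

    experiments: Sequence[ExperimentDesign]
    rate: float = DEFAULT_RATE_HZ
    duration_s: float = DEFAULT_DURATION_S

    @property
    def samples_per_series(self) -> int:
        return int(round(self.rate * self.duration_s))

    @property
    def n_electrome_series(self) -> int:
        return sum(e.n_plants * len(e.phases) for e in self.experiments)

    @property
    def n_reference_series(self) -> int:
        return sum(e.n_reference for e in self.experiments)

    @property
    def total_points(self) -> int:
        return (self.n_electrome_series + self.n_reference_series) \
            * self.samples_per_series

    def entries(self) -> list[dict]:
        """Enumerate every (experiment, plant, phase) series plus references."""
        out = []
        for exp in self.experiments:
            for plant in range(exp.n_plants):
                for phase in exp.phases:
                    out.append({"experiment": exp.name, "plant_id": plant,
                                "phase": phase, "is_reference": False})
            for ref in range(exp.n_reference):
                out.append({"experiment": exp.name, "plant_id": ref,
                            "phase": "reference", "is_reference": True})
        return out
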