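"""Hierarchical plain-text (YAML) configuration for profiles, designs and runs.

One dialect serves the whole pipeline:

.. code-block:: yaml

    treatments:
      nacl:
        baseline_beta: 1.9
        pre_spikes: {events_per_hour: 6, ...}
        burst: {start_s: 0, end_s: 1500, rate_multiplier: 4}
    design:
      rate: 62.5
      duration_s: 7200
      experiments:
        - {name: nacl, n_plants: 39, n_reference: 26}
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import ConfigError
from .types import (BurstWindow, ExperimentDesign, SessionManifest, SlowWaves,
                    SpikeProfile, TreatmentProfile, DEFAULT_DURATION_S,
                    DEFAULT_RATE_HZ)


def _load_yaml(source: Union[str, Path]) -> dict:
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config {source} is not a mapping")
    return data


def _spike_profile(d: dict) -> SpikeProfile:
    try:
        return SpikeProfile(**d)
    except TypeError as exc:
        raise ConfigError(f"bad spike profile {d!r}: {exc}") from exc


def treatment_from_dict(name: str, d: dict) -> TreatmentProfile:
    """Build a :class:`TreatmentProfile` from one ``treatments:`` entry."""
    d = dict(d)
    kwargs = {"name": name}
    for key in ("baseline_beta", "baseline_sigma", "post_beta", "post_sigma"):
        if key in d:
            kwargs[key] = d.pop(key)
    for key in ("pre_spikes", "post_spikes"):
        if key in d:
            kwargs[key] = _spike_profile(d.pop(key))
    if "burst" in d and d["burst"] is not None:
        kwargs["burst"] = BurstWindow(**d.pop("burst"))
    else:
        d.pop("burst", None)
    if "slow_waves" in d and d["slow_waves"] is not None:
        kwargs["slow_waves"] = SlowWaves(**d.pop("slow_waves"))
    else:
        d.pop("slow_waves", None)
    if d:
        raise ConfigError(f"unknown keys in treatment {name!r}: {sorted(d)}")
    return TreatmentProfile(**kwargs)


def profiles_from_dict(data: dict) -> dict[str, TreatmentProfile]:
    treatments = data.get("treatments")
    if not isinstance(treatments, dict):
        raise ConfigError("config has no 'treatments' mapping")
    return {name: treatment_from_dict(name, spec)
            for name, spec in treatments.items()}


def load_profiles(path: Union[str, Path]) -> dict[str, TreatmentProfile]:
    """Read treatment profiles from a YAML file."""
    return profiles_from_dict(_load_yaml(path))


def default_profiles() -> dict[str, TreatmentProfile]:
    """The shipped profiles for the four water-availability treatments."""
    text = (resources.files("electrome") / "data"
            / "default_profiles.yaml").read_text()
    return profiles_from_dict(yaml.safe_load(text))


def manifest_from_dict(data: dict) -> SessionManifest:
    design = data.get("design", data)
    exps = design.get("experiments")
    if exps is None:
        raise ConfigError("design has no 'experiments' list")
    return SessionManifest(
        experiments=[ExperimentDesign(**e) for e in exps],
        rate=design.get("rate", DEFAULT_RATE_HZ),
        duration_s=design.get("duration_s", DEFAULT_DURATION_S))


def load_manifest(path: Union[str, Path]) -> SessionManifest:
    """Read a session design from a YAML file."""
    return manifest_from_dict(_load_yaml(path))


def load_run_config(path: Union[str, Path]) -> dict:
    """Read a full pipeline configuration (design + profiles + stage knobs).

    Returns the raw mapping; :mod:`electrome.pipeline` interprets the
    stage-specific sections and applies defaults.
    """
    data = _load_yaml(path)
    if "treatments" not in data:
        data["treatments"] = None  # pipeline falls back to shipped defaults
    return data
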