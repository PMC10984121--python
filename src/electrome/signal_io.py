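"""Text-based series I/O and acquisition-filter emulation.

Series files are delimited text: ``#``-prefixed ``key = value`` header lines
(``rate`` in Hz is mandatory, units are mV) followed by one voltage value per
line. The format is inspectable and diff-friendly; values round-trip through
``repr``-precision floats.
"""

from __future__ import annotations

import ast
from pathlib import Path
from typing import Union

import numpy as np
from scipy import signal as sp_signal

from .errors import DegenerateInputError, FormatError, ParameterError
from .types import ElectromeSeries

_META_KEYS_NUMERIC = {"plant_id"}


def write_series(series: ElectromeSeries, path: Union[str, Path]) -> Path:
    """Write a series to a text file. Returns the path written."""
    path = Path(path)
    lines = [f"# rate = {series.rate!r}", "# units = mV"]
    for key, value in series.meta.items():
        if key == "spike_times_s":
            continue  # generator bookkeeping, not part of the recording
        lines.append(f"# {key} = {value!r}")
    lines.extend(repr(float(v)) for v in series.samples)
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_meta_value(raw: str):
    try:
        return ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        return raw


def read_series(path: Union[str, Path]) -> ElectromeSeries:
    """Read a series file written by :func:`write_series`.

    Raises :class:`FormatError` (with the offending line number) on a
    missing ``rate`` header, a non-numeric or non-finite record, or an
    empty file.
    """
    path = Path(path)
    rate = None
    meta: dict = {}
    values: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    continue
                key, _, raw = body.partition("=")
                key = key.strip()
                value = _parse_meta_value(raw.strip())
                if key == "rate":
                    try:
                        rate = float(value)
                    except (TypeError, ValueError):
                        raise FormatError(
                            f"{path}:{lineno}: non-numeric rate {raw!r}")
                elif key != "units":
                    meta[key] = value
                continue
            try:
                v = float(line)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric record {line!r}")
            if not np.isfinite(v):
                raise FormatError(
                    f"{path}:{lineno}: non-finite record {line!r}")
            values.append(v)
    if rate is None and not values:
        raise FormatError(f"{path}: empty file")
    if rate is None:
        raise FormatError(f"{path}: missing 'rate' header")
    if not values:
        raise FormatError(f"{path}: no samples")
    return ElectromeSeries(np.asarray(values), rate=rate, meta=meta)


def apply_acquisition_filter(series: ElectromeSeries,
                             highpass_hz: float = 0.5) -> ElectromeSeries:
    """Emulate the acquisition front end: zero-phase 2nd-order Butterworth
    high-pass (default cutoff 0.5 Hz, the ECG-standard configuration).

    The hardware low-pass and mains notch act above the Nyquist frequency
    of the 62.5 Hz stream and are therefore not modelled digitally.
    """
    nyquist = series.rate / 2.0
    if not 0 < highpass_hz < nyquist:
        raise ParameterError(
            f"high-pass cutoff {highpass_hz} Hz must lie in (0, {nyquist}) Hz")
    if len(series) < 10:
        raise DegenerateInputError("series too short to filter")
    sos = sp_signal.butter(2, highpass_hz, btype="highpass",
                           fs=series.rate, output="sos")
    filtered = sp_signal.sosfiltfilt(sos, series.samples)
    out = series.with_samples(filtered)
    out.meta["highpass_hz"] = highpass_hz
    return out
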