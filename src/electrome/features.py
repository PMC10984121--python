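"""The nine-statistic characterization ledger for electrophytograms.

Per series: (1) arithmetic average of voltage variation, (2) skewness,
(3) kurtosis, (4) power-law exponent mu of the |dV| probability density,
(5) autocorrelation decay, (6) power-spectral-density exponent beta,
(7) approximate entropy, (8) FFT magnitude spectrum, (9) multiscale
approximate entropy across coarse-graining scales 1..50.

Scaling exponents mu and beta are the package's own log-log regression
estimators; regularity statistics implement the Pincus ApEn definition
(Chebyshev distance, self-matches included) with a chunked O(N^2) kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats
from statsmodels.tsa.stattools import acf as sm_acf

from .errors import DegenerateInputError, ParameterError
from .types import ElectromeSeries

ArrayLike = Union[Sequence[float], np.ndarray, ElectromeSeries]


def _as_array(series: ArrayLike) -> np.ndarray:
    if isinstance(series, ElectromeSeries):
        return series.samples
    return np.asarray(series, dtype=float)


def _rate_of(series: ArrayLike, rate: Optional[float]) -> float:
    if rate is not None:
        return rate
    if isinstance(series, ElectromeSeries):
        return series.rate
    raise ParameterError("sampling rate required for a bare array")


# ---------------------------------------------------------------------------
# (1)-(3) moments

def mean_voltage_variation(series: ArrayLike, signed: bool = False) -> float:
    """Arithmetic average of voltage variation.

    By default the mean of |dV_i| (the signed mean of a high-passed,
    near-zero-mean recording is uninformatively close to zero); pass
    ``signed=True`` for the plain mean.
    """
    x = _as_array(series)
    if x.size == 0:
        raise DegenerateInputError("empty series")
    return float(np.mean(x if signed else np.abs(x)))


def moments(series: ArrayLike) -> Tuple[float, float]:
    """(skewness, excess kurtosis) of the voltage-variation distribution.

    Standardized third moment and Fisher kurtosis (normal -> 0).
    """
    x = _as_array(series)
    if x.size < 4:
        raise DegenerateInputError("need at least 4 samples for moments")
    if np.var(x) == 0:
        raise DegenerateInputError("zero variance: moments undefined")
    return float(sp_stats.skew(x)), float(sp_stats.kurtosis(x))


# ---------------------------------------------------------------------------
# (4) PDF power-law exponent

@dataclass
class ExponentFit:
    """A log-log regression exponent with its fit diagnostics."""

    value: float
    r_squared: float
    n_points: int
    fit_range: Tuple[float, float]
    ok: bool = True
    message: str = ""


def fit_pdf_exponent(series: ArrayLike, bins: int = 40,
                     fit_range: Optional[Tuple[float, float]] = None,
                     tail_quantile: float = 0.90,
                     min_points: int = 10) -> ExponentFit:
    """Exponent mu of the power-law density P(dV) ~ |dV|^-mu.

    |dV| values are binned in log-spaced bins; ``log10 density`` is
    regressed on ``log10 |dV|`` over ``fit_range`` (default: above the
    ``tail_quantile`` of |dV|), and mu is the negative slope. A failed
    fit (too few tail points / bins) is reported via ``ok=False``, not
    raised.
    """
    x = np.abs(_as_array(series))
    x = x[x > 0]
    if fit_range is None:
        if x.size == 0:
            return ExponentFit(np.nan, np.nan, 0, (np.nan, np.nan), ok=False,
                               message="no nonzero values")
        fit_range = (float(np.quantile(x, tail_quantile)), float(x.max()))
    lo, hi = fit_range
    tail = x[(x >= lo) & (x <= hi)]
    if tail.size < min_points or not 0 < lo < hi:
        return ExponentFit(np.nan, np.nan, int(tail.size), (lo, hi), ok=False,
                           message=f"only {tail.size} points in fit range")
    edges = np.logspace(np.log10(lo), np.log10(hi), bins + 1)
    counts, edges = np.histogram(tail, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    density = counts / (tail.size * widths)
    mask = density > 0
    if mask.sum() < 3:
        return ExponentFit(np.nan, np.nan, int(tail.size), (lo, hi), ok=False,
                           message="fewer than 3 occupied bins")
    lx, ly = np.log10(centers[mask]), np.log10(density[mask])
    slope, intercept, r, _, _ = sp_stats.linregress(lx, ly)
    return ExponentFit(value=float(-slope), r_squared=float(r ** 2),
                       n_points=int(tail.size), fit_range=(lo, hi))


# ---------------------------------------------------------------------------
# (5) autocorrelation decay

@dataclass
class AcfSummary:
    """First 1/e crossing of the sample autocorrelation function."""

    lag_samples: int
    lag_seconds: float
    censored: bool = False     # ACF never fell below 1/e within max_lag
    max_lag: int = 0


def autocorrelation_summary(series: ArrayLike, rate: Optional[float] = None,
                            threshold: float = 1.0 / np.e,
                            max_lag: Optional[int] = None) -> AcfSummary:
    """Decorrelation lag: smallest lag where the ACF first drops below
    ``threshold`` (default 1/e), reported in samples and seconds.

    If the ACF stays above threshold up to ``max_lag`` the result is
    right-censored (``censored=True`` with ``lag_samples == max_lag``).
    """
    x = _as_array(series)
    fs = _rate_of(series, rate)
    if x.size < 100:
        raise DegenerateInputError("need at least 100 samples for the ACF")
    if np.var(x) == 0:
        raise DegenerateInputError("zero variance: ACF undefined")
    if max_lag is None:
        max_lag = x.size // 2
    max_lag = min(max_lag, x.size - 1)
    rho = sm_acf(x, nlags=max_lag, fft=True)
    below = np.nonzero(rho < threshold)[0]
    if below.size == 0:
        return AcfSummary(lag_samples=max_lag, lag_seconds=max_lag / fs,
                          censored=True, max_lag=max_lag)
    lag = int(below[0])
    return AcfSummary(lag_samples=lag, lag_seconds=lag / fs, max_lag=max_lag)


# ---------------------------------------------------------------------------
# (6) PSD exponent

def fit_psd_exponent(series: ArrayLike, rate: Optional[float] = None,
                     fit_band_hz: Tuple[float, float] = (0.05, 10.0),
                     n_segments: int = 8, overlap: float = 0.5,
                     min_points: int = 10) -> ExponentFit:
    """Spectral exponent beta of the 1/f^beta power spectral density.

    The PSD is estimated with an averaged periodogram (Hann window,
    ``n_segments`` segments at ``overlap`` fractional overlap); beta is
    the negative slope of ``log10 power`` vs ``log10 frequency`` over
    ``fit_band_hz``. beta=0 white, beta=1 pink, beta=2 brown noise.
    """
    x = _as_array(series)
    fs = _rate_of(series, rate)
    if x.size < 4096:
        raise DegenerateInputError("need at least 4096 samples for a PSD fit")
    nperseg = int(x.size / (n_segments * (1 - overlap) + overlap))
    nperseg = max(256, min(nperseg, x.size))
    freqs, power = sp_signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                                   noverlap=int(nperseg * overlap),
                                   detrend="constant")
    lo, hi = fit_band_hz
    mask = (freqs >= lo) & (freqs <= hi) & (power > 0)
    if mask.sum() < min_points:
        return ExponentFit(np.nan, np.nan, int(mask.sum()), fit_band_hz,
                           ok=False,
                           message=f"only {int(mask.sum())} frequencies in band")
    lx, ly = np.log10(freqs[mask]), np.log10(power[mask])
    slope, intercept, r, _, _ = sp_stats.linregress(lx, ly)
    return ExponentFit(value=float(-slope), r_squared=float(r ** 2),
                       n_points=int(mask.sum()), fit_range=fit_band_hz)


# ---------------------------------------------------------------------------
# (8) FFT spectrum

def fft_spectrum(series: ArrayLike, rate: Optional[float] = None
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude spectrum up to the Nyquist frequency.

    Magnitudes are scaled so a unit-amplitude sinusoid at a bin frequency
    yields magnitude ~1 at that bin.
    """
    x = _as_array(series)
    fs = _rate_of(series, rate)
    if x.size == 0:
        raise DegenerateInputError("empty series")
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    mags = np.abs(spec) * 2.0 / x.size
    mags[0] /= 2.0
    if x.size % 2 == 0:
        mags[-1] /= 2.0
    return freqs, mags


# ---------------------------------------------------------------------------
# (7) approximate entropy and (9) its multiscale profile

def _phi(x: np.ndarray, m: int, r: float, block: int = 512) -> float:
    """Phi^m(r) = mean_i ln( C_i^m(r) ), Chebyshev distance, self-matches in."""
    n_vec = x.size - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    counts = np.empty(n_vec)
    for i0 in range(0, n_vec, block):
        chunk = emb[i0:i0 + block]
        d = np.abs(chunk[:, None, :] - emb[None, :, :]).max(axis=2)
        counts[i0:i0 + block] = np.count_nonzero(d <= r, axis=1)
    return float(np.mean(np.log(counts / n_vec)))


def approximate_entropy(series: ArrayLike, m: int = 2,
                        r: Optional[float] = None,
                        r_factor: float = 0.2) -> float:
    """ApEn(m, r) = Phi^m(r) - Phi^(m+1)(r) (Pincus definition).

    Pattern vectors of length ``m`` are compared under the Chebyshev
    (maximum) norm with tolerance ``r`` (default ``r_factor`` times the
    sample SD); self-matches are included, so ApEn >= 0 and a constant
    series scores exactly 0. Lower values indicate a more regular signal.
    """
    x = _as_array(series)
    if m < 1:
        raise ParameterError("m must be >= 1")
    if x.size < m + 2:
        raise ParameterError(
            f"series of {x.size} samples too short for m={m} (need >= {m + 2})")
    if r is None:
        sd = float(np.std(x))
        if sd == 0.0:
            return 0.0  # constant signal: perfectly regular
        r = r_factor * sd
    if not r > 0:
        raise ParameterError(f"tolerance r must be > 0, got {r}")
    return _phi(x, m, r) - _phi(x, m + 1, r)


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping means of ``scale`` consecutive samples."""
    if scale < 1:
        raise ParameterError("scale must be >= 1")
    n = x.size // scale
    return x[:n * scale].reshape(n, scale).mean(axis=1)


def multiscale_apen(series: ArrayLike, max_scale: int = 50, m: int = 2,
                    r: Optional[float] = None,
                    r_factor: float = 0.2) -> np.ndarray:
    """ApEn of coarse-grained series at scales 1..max_scale.

    The tolerance ``r`` is fixed from the SD of the *original* series
    (unless given), so entropy changes across scales reflect structure,
    not renormalization. ``result[0]`` (scale 1) equals
    :func:`approximate_entropy` of the raw series.
    """
    x = _as_array(series)
    if max_scale < 1:
        raise ParameterError("max_scale must be >= 1")
    shortest = x.size // max_scale
    if shortest < m + 2:
        feasible = x.size // (m + 2)
        raise ParameterError(
            f"series of {x.size} samples supports at most scale {feasible}, "
            f"got max_scale={max_scale}")
    if r is None:
        sd = float(np.std(x))
        r = r_factor * sd if sd > 0 else None
        if r is None:
            return np.zeros(max_scale)
    out = np.empty(max_scale)
    for scale in range(1, max_scale + 1):
        out[scale - 1] = approximate_entropy(coarse_grain(x, scale), m=m, r=r)
    return out


# ---------------------------------------------------------------------------
# the full ledger

@dataclass
class FeatureConfig:
    """Knobs for the nine-statistic ledger."""

    apen_m: int = 2
    apen_r_factor: float = 0.2
    apen_max_points: int = 10_000   # decimate before the O(N^2) kernel
    max_scale: int = 50
    psd_fit_band_hz: Tuple[float, float] = (0.05, 10.0)
    pdf_tail_quantile: float = 0.90
    pdf_bins: int = 40
    acf_threshold: float = 1.0 / np.e
    signed_mean: bool = False
    compute_msapen: bool = True


@dataclass
class FeatureLedger:
    """All nine statistics of one series, with per-statistic failure flags."""

    mean_dv: float = np.nan
    skew: float = np.nan
    kurt: float = np.nan
    pdf_mu: Optional[ExponentFit] = None
    acf: Optional[AcfSummary] = None
    psd_beta: Optional[ExponentFit] = None
    apen: float = np.nan
    fft_freqs: Optional[np.ndarray] = None
    fft_mags: Optional[np.ndarray] = None
    msapen: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten to one table row (column names follow field usage)."""
        return {
            "experiment": self.meta.get("experiment"),
            "plant_id": self.meta.get("plant_id"),
            "phase": self.meta.get("phase"),
            "mean_dv": self.mean_dv,
            "skew": self.skew,
            "kurt": self.kurt,
            "pdf_mu": self.pdf_mu.value if self.pdf_mu else np.nan,
            "pdf_r2": self.pdf_mu.r_squared if self.pdf_mu else np.nan,
            "ac_lag_s": self.acf.lag_seconds if self.acf else np.nan,
            "psd_beta": self.psd_beta.value if self.psd_beta else np.nan,
            "psd_r2": self.psd_beta.r_squared if self.psd_beta else np.nan,
            "apen": self.apen,
            "n_errors": len(self.errors),
        }


def _decimate_for_apen(x: np.ndarray, max_points: int) -> np.ndarray:
    if x.size <= max_points:
        return x
    step = int(np.ceil(x.size / max_points))
    return x[::step]


def feature_ledger(series: ElectromeSeries,
                   config: Optional[FeatureConfig] = None) -> FeatureLedger:
    """Compute the full nine-statistic ledger for one series.

    Individual statistic failures (e.g. moments of a constant series) are
    recorded in ``ledger.errors`` rather than aborting the ledger. The
    result is deterministic given the series and config.
    """
    cfg = config or FeatureConfig()
    led = FeatureLedger(meta=dict(series.meta))
    x = series.samples

    def attempt(name, fn):
        try:
            return fn()
        except (DegenerateInputError, ParameterError) as exc:
            led.errors[name] = str(exc)
            return None

    v = attempt("mean_dv",
                lambda: mean_voltage_variation(x, signed=cfg.signed_mean))
    if v is not None:
        led.mean_dv = v
    mk = attempt("moments", lambda: moments(x))
    if mk is not None:
        led.skew, led.kurt = mk
    led.pdf_mu = attempt("pdf_mu", lambda: fit_pdf_exponent(
        x, bins=cfg.pdf_bins, tail_quantile=cfg.pdf_tail_quantile))
    led.acf = attempt("acf", lambda: autocorrelation_summary(
        x, rate=series.rate, threshold=cfg.acf_threshold))
    led.psd_beta = attempt("psd_beta", lambda: fit_psd_exponent(
        x, rate=series.rate, fit_band_hz=cfg.psd_fit_band_hz))
    spec = attempt("fft", lambda: fft_spectrum(x, rate=series.rate))
    if spec is not None:
        led.fft_freqs, led.fft_mags = spec

    xa = _decimate_for_apen(x, cfg.apen_max_points)
    v = attempt("apen", lambda: approximate_entropy(
        xa, m=cfg.apen_m, r_factor=cfg.apen_r_factor))
    if v is not None:
        led.apen = v
    if cfg.compute_msapen:
        led.msapen = attempt("msapen", lambda: multiscale_apen(
            xa, max_scale=cfg.max_scale, m=cfg.apen_m,
            r_factor=cfg.apen_r_factor))
    return led
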