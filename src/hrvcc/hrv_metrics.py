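"""Time- and frequency-domain heart-rate-variability measures.

Time domain: AVNN (mean NN interval, ms), mean heart rate (60000/AVNN, bpm)
and RMSSD (root mean square of successive differences, ms).

Frequency domain: power of the NN series in the low-frequency band
(0.04-0.15 Hz, mostly mixed autonomic influences) and the high-frequency
band (0.15-0.40 Hz, respiratory/vagal), in ms^2.  Because a beat series is
sampled unevenly in time, the default estimator interpolates the series onto
a uniform 4 Hz grid (cubic), linearly detrends, applies a Hann taper and
takes the periodogram; a Lomb-Scargle estimator working directly on the
uneven samples is provided as a cross-check.  HF power is strongly
right-skewed across subjects, so its natural log (lnHF) is what enters
cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import interpolate, signal

from .io_filtering import CleanIBISeries

__all__ = [
    "TimeDomainMeasures",
    "SpectralConfig",
    "SpectralMeasures",
    "Spectrum",
    "time_domain",
    "power_spectrum",
    "band_power",
    "ln_transform",
    "spectral_measures",
]

LF_BAND: Tuple[float, float] = (0.04, 0.15)
HF_BAND: Tuple[float, float] = (0.15, 0.40)


@dataclass(frozen=True)
class TimeDomainMeasures:
    avnn: float  # mean NN interval, ms
    hr: float  # mean heart rate, beats/min (= 60000/avnn)
    rmssd: float  # root mean square of successive differences, ms


@dataclass(frozen=True)
class SpectralConfig:
    """Settings for the NN power-spectrum estimate."""

    method: str = "resampled_fft"  # or "lomb"
    resample_rate: float = 4.0  # Hz, uniform grid for resampled_fft
    lf_band: Tuple[float, float] = LF_BAND
    hf_band: Tuple[float, float] = HF_BAND
    detrend: str = "linear"  # or "none"
    window: str = "hann"  # taper for resampled_fft; "none" disables

    def __post_init__(self) -> None:
        if self.method not in ("resampled_fft", "lomb"):
            raise ValueError(f"unknown spectral method {self.method!r}")
        lf, hf = self.lf_band, self.hf_band
        if not (0 <= lf[0] < lf[1] and hf[0] < hf[1]):
            raise ValueError("band edges must be ordered")
        if lf[1] != hf[0]:
            raise ValueError("LF upper edge must equal HF lower edge")
        if self.detrend not in ("linear", "none"):
            raise ValueError("detrend must be 'linear' or 'none'")


@dataclass(frozen=True)
class Spectrum:
    """One-sided power spectral density of the NN series.

    ``psd`` is in ms^2/Hz on the (uniform) frequency grid ``freqs``, so band
    powers are integrals of ``psd`` over the band.
    """

    freqs: np.ndarray
    psd: np.ndarray
    method: str


@dataclass(frozen=True)
class SpectralMeasures:
    lf_power: float  # ms^2
    hf_power: float  # ms^2

    @property
    def ln_hf(self) -> float:
        return ln_transform(self.hf_power)


def _intervals(series: CleanIBISeries | np.ndarray) -> np.ndarray:
    if isinstance(series, CleanIBISeries):
        return series.intervals
    return np.asarray(series, dtype=float)


def time_domain(series: CleanIBISeries | np.ndarray) -> TimeDomainMeasures:
    """AVNN, mean HR and RMSSD of an NN series."""
    x = _intervals(series)
    if x.size < 2:
        raise ValueError("need at least 2 intervals (RMSSD undefined)")
    avnn = float(x.mean())
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    return TimeDomainMeasures(avnn=avnn, hr=60000.0 / avnn, rmssd=rmssd)


def power_spectrum(
    series: CleanIBISeries | np.ndarray, cfg: SpectralConfig | None = None
) -> Spectrum:
    """Estimate the one-sided PSD of the NN series, in ms^2/Hz."""
    cfg = cfg or SpectralConfig()
    x = _intervals(series)
    t = np.cumsum(x) / 1000.0  # beat end times, s
    duration = t[-1] - t[0]
    if duration < 1.0 / cfg.lf_band[0]:
        raise ValueError(
            f"series spans {duration:.1f} s; need >= {1.0 / cfg.lf_band[0]:.0f} s "
            "to resolve the lowest band edge"
        )
    if cfg.method == "resampled_fft":
        return _resampled_fft_spectrum(t, x, cfg)
    return _lomb_spectrum(t, x, cfg)


def _resampled_fft_spectrum(t: np.ndarray, x: np.ndarray, cfg: SpectralConfig) -> Spectrum:
    fs = cfg.resample_rate
    n_u = int(np.floor((t[-1] - t[0]) * fs)) + 1
    tu = t[0] + np.arange(n_u) / fs
    spline = interpolate.CubicSpline(t, x)
    xu = spline(tu)
    window = cfg.window if cfg.window != "none" else "boxcar"
    detrend = "linear" if cfg.detrend == "linear" else False
    freqs, psd = signal.periodogram(
        xu, fs=fs, window=window, detrend=detrend, scaling="density"
    )
    return Spectrum(freqs=freqs, psd=psd, method="resampled_fft")


def _lomb_spectrum(t: np.ndarray, x: np.ndarray, cfg: SpectralConfig) -> Spectrum:
    # Linear detrend on the uneven samples, then Lomb-Scargle on a uniform
    # frequency grid. Raw Lomb power is rescaled so the full-range integral
    # equals the variance of the detrended series (Parseval-consistent),
    # which makes band powers directly comparable with the FFT route.
    if cfg.detrend == "linear":
        coef = np.polyfit(t, x, 1)
        xd = x - np.polyval(coef, t)
    else:
        xd = x - x.mean()
    duration = t[-1] - t[0]
    df = 1.0 / duration
    f_nyq = 0.5 / np.median(np.diff(t))
    freqs = np.arange(df, f_nyq, df)
    pgram = signal.lombscargle(t, xd, 2 * np.pi * freqs)
    total = np.trapezoid(pgram, freqs)
    var = float(np.var(xd))
    scale = var / total if total > 0 else 0.0
    return Spectrum(freqs=freqs, psd=pgram * scale, method="lomb")


def band_power(spectrum: Spectrum, band: Tuple[float, float]) -> float:
    """Integral of the PSD over ``[lo, hi)``, in ms^2.

    Half-open so adjacent bands sharing an edge never double-count a bin.
    """
    lo, hi = band
    if hi < lo:
        raise ValueError(f"inverted band ({lo}, {hi})")
    if hi == lo:
        return 0.0
    mask = (spectrum.freqs >= lo) & (spectrum.freqs < hi)
    if not mask.any():
        return 0.0
    df = float(np.median(np.diff(spectrum.freqs)))
    return float(spectrum.psd[mask].sum() * df)


def ln_transform(power: float) -> float:
    """Natural log of a band power (used for lnHF)."""
    if power <= 0:
        raise ValueError(f"cannot log-transform non-positive power {power!r}")
    return float(np.log(power))


def spectral_measures(
    series: CleanIBISeries | np.ndarray, cfg: SpectralConfig | None = None
) -> SpectralMeasures:
    """LF and HF band power of an NN series."""
    cfg = cfg or SpectralConfig()
    spec = power_spectrum(series, cfg)
    return SpectralMeasures(
        lf_power=band_power(spec, cfg.lf_band),
        hf_power=band_power(spec, cfg.hf_band),
    )
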