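"""Synthetic interbeat-interval series and cohorts for pipeline validation.

No ambulatory recordings ship with this package, so every stage is exercised
on generated data with the statistical structure the analysis assumes:

* ~120-minute IBI series at a mean interval of ~650 ms (heart rate near
  90 bpm, i.e. roughly 9,000-12,000 beats), optionally carrying
  respiratory-band (HF) and slower (LF) sinusoidal modulation, long-range
  correlated fluctuations with a tunable Hurst exponent (exact-autocovariance
  fractional Gaussian noise via circulant embedding), AR(1) correlation, or
  planted artifacts (out-of-band values and local spikes).

* Two-group cohorts (default 86 girls / 80 boys, sex coded 1 = boys,
  2 = girls) whose cardiac measures are drawn per group from configurable
  means/SDs — defaults reproduce the magnitudes typical of adolescent
  ambulatory recordings — with a configurable correlation with heart rate,
  and 0-3-scaled internalizing-symptom subscale totals generated from a
  linear model on sex and standardized cardiac measures, truncated at zero,
  with missing-completely-at-random dropout.

All generators are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .io_filtering import RawIBIRecording

__all__ = [
    "SeriesSpec",
    "CohortSpec",
    "gen_series",
    "gen_cohort",
    "fgn",
    "MEASURE_COLUMNS",
    "SYMPTOM_COLUMNS",
    "MEASURE_DEFAULTS",
    "SYMPTOM_DEFAULTS",
]


# ---------------------------------------------------------------------------
# Interbeat-interval series


@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for one synthetic IBI series.

    ``kind`` selects the fluctuation model:

    * ``white`` — iid Gaussian intervals.
    * ``fgn`` — fractional Gaussian noise with Hurst exponent ``hurst``.
    * ``ar1`` — first-order autoregression with coefficient ``phi``.
    * ``modulated`` — sinusoids at ``hf_freq``/``lf_freq`` Hz on the
      cumulative beat-time axis plus white noise (emulates respiratory
      sinus arrhythmia and slower oscillations).
    * ``ramp`` — deterministic linear trend (a regularity anchor).
    * ``periodic`` — deterministic cycle of ``period`` beats.

    ``n`` overrides ``duration_minutes``; with the defaults (120 min at a
    650 ms mean interval) a series has ~11,000 beats.
    """

    kind: str = "white"
    n: Optional[int] = None
    duration_minutes: float = 120.0
    mean_ibi: float = 650.0  # ms; ~92 bpm
    sd_ibi: float = 40.0  # ms
    hurst: float = 0.9
    phi: float = 0.5
    hf_freq: float = 0.25  # Hz, respiratory band
    hf_amp: float = 25.0  # ms
    lf_freq: float = 0.1  # Hz
    lf_amp: float = 10.0  # ms
    period: int = 2  # beats, for kind="periodic"
    artifact_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("white", "fgn", "ar1", "modulated", "ramp", "periodic"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        if not 400 < self.mean_ibi < 1100:
            raise ValueError("mean_ibi must lie in (400, 1100) ms")
        if not 0 < self.hurst < 1:
            raise ValueError("hurst must be in (0, 1)")
        if not abs(self.phi) < 1:
            raise ValueError("|phi| must be < 1")
        if not 0 <= self.artifact_rate < 1:
            raise ValueError("artifact_rate must be in [0, 1)")

    @property
    def n_beats(self) -> int:
        if self.n is not None:
            return int(self.n)
        return int(round(self.duration_minutes * 60000.0 / self.mean_ibi))


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    The circulant embedding of the fGn autocovariance
    gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H) / 2 has non-negative
    eigenvalues for 0 < H < 1, so the construction reproduces the target
    autocovariance exactly (up to floating error).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    m = row.size
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)
    # Hermitian-symmetric spectral increments (exact Davies-Harte sampling)
    w = np.zeros(m, dtype=complex)
    g = rng.standard_normal(m)
    w[0] = np.sqrt(eig[0] / m) * g[0]
    w[n] = np.sqrt(eig[n] / m) * g[1]
    half = np.arange(1, n)
    re = g[2 : n + 1]
    im = rng.standard_normal(n - 1)
    w[half] = np.sqrt(eig[half] / (2 * m)) * (re + 1j * im)
    w[m - half] = np.conj(w[half])
    return np.fft.fft(w).real[:n]


def _plant_artifacts(
    x: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Replace ~rate*n isolated intervals with artifacts; return indices.

    Half the planted artifacts are out-of-band values (recoverable by the
    band filter), half are in-band spikes 35-60% away from the local level
    (recoverable by the central-window filter). Planted positions are kept
    non-adjacent and away from the series edges.
    """
    n = x.size
    n_art = int(round(rate * n))
    if n_art == 0:
        return x, np.array([], dtype=int)
    candidates = rng.permutation(np.arange(10, n - 10))
    chosen: list[int] = []
    taken = np.zeros(n, dtype=bool)
    for idx in candidates:
        if len(chosen) == n_art:
            break
        if not taken[max(0, idx - 2) : idx + 3].any():
            chosen.append(int(idx))
            taken[idx] = True
    idx = np.sort(np.array(chosen, dtype=int))
    out = x.copy()
    for j, i in enumerate(idx):
        local = float(np.mean(out[i - 5 : i + 6]))
        if j % 2 == 0:  # out of band
            out[i] = rng.uniform(1150.0, 1800.0) if j % 4 == 0 else rng.uniform(150.0, 380.0)
        else:  # in-band spike, >=35% off the local mean
            frac = rng.uniform(0.35, 0.60)
            sign = 1.0 if local * (1 + frac) <= 1100 else -1.0
            out[i] = local * (1 + sign * frac)
            out[i] = float(np.clip(out[i], 150.0, 1800.0))
    return out, idx


def gen_series(
    spec: SeriesSpec, return_artifact_index: bool = False
) -> RawIBIRecording | tuple[RawIBIRecording, np.ndarray]:
    """Generate one synthetic IBI recording from a :class:`SeriesSpec`."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_beats
    mu, sd = spec.mean_ibi, spec.sd_ibi

    if spec.kind == "white":
        x = rng.normal(mu, sd, n)
    elif spec.kind == "fgn":
        x = mu + sd * fgn(n, spec.hurst, rng)
    elif spec.kind == "ar1":
        innov_sd = sd * np.sqrt(1 - spec.phi**2)
        e = rng.normal(0.0, innov_sd, n)
        x = np.empty(n)
        x[0] = rng.normal(0.0, sd)
        for i in range(1, n):
            x[i] = spec.phi * x[i - 1] + e[i]
        x = mu + x
    elif spec.kind == "modulated":
        # beat times depend on the intervals themselves: build iteratively
        x = np.empty(n)
        t = 0.0
        noise = rng.normal(0.0, sd, n)
        for i in range(n):
            xi = (
                mu
                + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t)
                + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t)
                + noise[i]
            )
            xi = max(xi, 0.3 * mu)
            x[i] = xi
            t += xi / 1000.0
    elif spec.kind == "ramp":
        half = sd * np.sqrt(3.0)  # matches the SD of a uniform ramp
        x = np.linspace(mu - half, mu + half, n)
    else:  # periodic
        pattern = mu + sd * np.sqrt(2.0) * np.sin(2 * np.pi * np.arange(spec.period) / spec.period)
        x = np.tile(pattern, n // spec.period + 1)[:n]

    x = np.clip(x, 1.0, None)
    artifact_idx = np.array([], dtype=int)
    if spec.artifact_rate > 0:
        x, artifact_idx = _plant_artifacts(x, spec.artifact_rate, rng)
    rec = RawIBIRecording(subject_id=f"sim-{spec.kind}-{spec.seed}", intervals=x)
    if return_artifact_index:
        return rec, artifact_idx
    return rec


# ---------------------------------------------------------------------------
# Cohorts

MEASURE_COLUMNS = [
    "hr_bpm",
    "rmssd_ms",
    "lf_ms2",
    "ln_hf",
    "dfa_alpha1",
    "dfa_alpha2",
    "fd",
    "mse_s1",
    "mse_s5",
    "mse_s10",
    "mse_s15",
    "mse_s20",
]

SYMPTOM_COLUMNS = [
    "social_anxiety",
    "generalized_anxiety",
    "separation_anxiety",
    "panic",
    "obsessive_compulsive",
    "depression",
    "total_anxiety",
]

# (male mean, male SD, female mean, female SD, correlation with HR)
# Group magnitudes follow values typical of adolescent ambulatory
# recordings; HR correlations are signed so the heart-rate adjustment rule
# has a defined direction for each measure (positive only for short-range
# DFA, negative elsewhere), their strengths being generator assumptions.
MEASURE_DEFAULTS: Dict[str, Tuple[float, float, float, float, float]] = {
    "hr_bpm": (89.33, 11.006, 93.421, 10.407, 1.0),
    "rmssd_ms": (38.16, 13.89, 33.24, 12.31, -0.6),
    "lf_ms2": (1913.67, 767.09, 1614.65, 686.96, -0.5),
    "ln_hf": (6.26, 0.69, 5.96, 0.76, -0.6),
    "dfa_alpha1": (1.40, 0.14, 1.42, 0.13, 0.3),
    "dfa_alpha2": (0.98, 0.08, 0.96, 0.07, -0.3),
    "fd": (1.10, 0.03, 1.08, 0.02, -0.4),
    "mse_s1": (0.90, 0.23, 0.87, 0.19, -0.3),
    "mse_s5": (1.51, 0.19, 1.47, 0.17, -0.3),
    "mse_s10": (1.53, 0.13, 1.49, 0.13, -0.3),
    "mse_s15": (1.51, 0.12, 1.45, 0.12, -0.3),
    "mse_s20": (1.49, 0.12, 1.43, 0.12, -0.3),
}

# (mean, SD, {predictor: standardized slope}); predictors are 'sex' (1/2
# coding, standardized internally) or measure columns (z-scored). Slope
# magnitudes mirror small-to-moderate associations between internalizing
# symptoms, heart rate and vagal tone.
SYMPTOM_DEFAULTS: Dict[str, Tuple[float, float, Dict[str, float]]] = {
    "social_anxiety": (8.85, 5.53, {"sex": 0.18, "hr_bpm": 0.16, "ln_hf": -0.17}),
    "generalized_anxiety": (5.82, 3.61, {"ln_hf": -0.10}),
    "separation_anxiety": (1.56, 2.49, {"mse_s10": -0.08}),
    "panic": (4.71, 4.85, {"hr_bpm": 0.20}),
    "obsessive_compulsive": (3.11, 3.35, {"hr_bpm": 0.29}),
    "depression": (8.04, 5.64, {"hr_bpm": 0.20, "ln_hf": -0.17}),
    "total_anxiety": (24.06, 16.21, {"hr_bpm": 0.21, "ln_hf": -0.17}),
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a two-group cohort table.

    ``measure_params`` maps measure -> (male mean, male SD, female mean,
    female SD, correlation with HR); ``symptom_params`` maps subscale ->
    (intercept/mean, SD, {predictor: standardized slope}). Symptom totals
    are rounded, floored at 0, and dropped completely at random at
    ``missing_rate`` (whole symptom row per subject, matching listwise
    deletion downstream).
    """

    n_female: int = 86
    n_male: int = 80
    measure_params: Mapping[str, Tuple[float, float, float, float, float]] = field(
        default_factory=lambda: dict(MEASURE_DEFAULTS)
    )
    symptom_params: Mapping[str, Tuple[float, float, Dict[str, float]]] = field(
        default_factory=lambda: dict(SYMPTOM_DEFAULTS)
    )
    missing_rate: float = 0.07
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_female < 2 or self.n_male < 2:
            raise ValueError("need at least 2 subjects per group")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name, (m1, s1, m2, s2, rho) in self.measure_params.items():
            if s1 <= 0 or s2 <= 0:
                raise ValueError(f"non-positive SD for measure {name}")
            if not -1 <= rho <= 1:
                raise ValueError(f"invalid HR correlation for measure {name}")


def gen_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a cohort table: one row per subject.

    Columns: subject_id, sex_code (1 = boys, 2 = girls), age, bmi, the
    cardiac measure columns of ``MEASURE_COLUMNS`` (plus hf_ms2 derived from
    ln_hf) and the symptom subscale totals of ``SYMPTOM_COLUMNS``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_male + spec.n_female
    sex = np.concatenate([np.ones(spec.n_male), np.full(spec.n_female, 2.0)])
    female = sex == 2

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "sex_code": sex.astype(int),
            "age": np.round(rng.normal(14.96, np.where(female, 0.46, 0.36)), 2),
            "bmi": np.round(rng.normal(np.where(female, 17.68, 18.19), np.where(female, 2.74, 3.35)), 2),
        }
    )

    # latent per-subject HR factor drives the signed cross-measure structure
    z_hr = rng.standard_normal(n)
    for name, (m1, s1, m2, s2, rho) in spec.measure_params.items():
        mean = np.where(female, m2, m1)
        sd = np.where(female, s2, s1)
        if name == "hr_bpm":
            z = z_hr
        else:
            eps = rng.standard_normal(n)
            z = rho * z_hr + np.sqrt(max(0.0, 1 - rho**2)) * eps
        df[name] = mean + sd * z
    df["avnn_ms"] = 60000.0 / df["hr_bpm"]
    df["hf_ms2"] = np.exp(df["ln_hf"])

    # symptoms from a standardized linear model, rounded and floored at 0
    z_cols = {c: (df[c] - df[c].mean()) / df[c].std(ddof=0) for c in MEASURE_COLUMNS}
    z_cols["sex"] = (sex - sex.mean()) / sex.std(ddof=0)
    for sub, (mean, sd, slopes) in spec.symptom_params.items():
        lin = np.zeros(n)
        ssq = 0.0
        for pred, beta in slopes.items():
            lin += beta * np.asarray(z_cols[pred])
            ssq += beta**2
        resid_scale = np.sqrt(max(0.0, 1.0 - ssq))
        y = mean + sd * (lin + resid_scale * rng.standard_normal(n))
        df[sub] = np.maximum(np.round(y), 0.0)

    if spec.missing_rate > 0:
        drop = rng.random(n) < spec.missing_rate
        df.loc[drop, list(spec.symptom_params)] = np.nan
    return df
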