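"""Cardiac-complexity measures: DFA, allometric fractal dimension, multiscale entropy.

Three families of nonlinear measures quantify how heartbeat fluctuations are
organised across scales, as distinct from how large they are:

* **Detrended fluctuation analysis (DFA)** estimates power-law correlation
  exponents of the integrated NN series.  alpha1 covers short-range boxes
  (4-11 beats), alpha2 long-range boxes (12-64 beats by default; only the
  lower bound is physiologically canonical).  alpha = 0.5 for uncorrelated
  data; 0.5 < alpha < 1 indicates persistent long-range correlations.

* **Allometric aggregation** sums adjacent points at increasing block sizes
  and regresses log SD on log mean across aggregation levels; the slope is
  the scaling exponent h (0.5 for random fluctuations, 1 for deterministic
  regularity) and the fractal dimension is FD = 2 - h.

* **Multiscale entropy (MSE)** computes the sample entropy (SampEn) of
  coarse-grained (window-averaged) copies of the series at increasing scale
  factors.  SampEn is the negative log of the conditional probability that
  sequences similar for m points remain similar at point m+1; lower values
  mean a more regular, predictable rhythm.

Note the deliberate asymmetry: allometric aggregation sums blocks while
multiscale coarse-graining averages them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "DFAConfig",
    "DFAResult",
    "AllometricConfig",
    "AllometricResult",
    "MSEConfig",
    "MSEResult",
    "SampEnUndefinedError",
    "dfa",
    "aggregate",
    "allometric_exponent",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
]


class SampEnUndefinedError(ValueError):
    """Raised when no template matches exist and SampEn is undefined."""


# ---------------------------------------------------------------------------
# Detrended fluctuation analysis


@dataclass(frozen=True)
class DFAConfig:
    """Box-size ranges (in beats) and detrending order for DFA."""

    short_range: Tuple[int, int] = (4, 11)
    long_range: Tuple[int, int] = (12, 64)
    detrend_order: int = 1

    def __post_init__(self) -> None:
        s, l = self.short_range, self.long_range
        if not (s[0] < s[1] < l[0] < l[1]):
            raise ValueError("box ranges must be ascending and disjoint")
        if s[0] < self.detrend_order + 2:
            raise ValueError("minimum box size must be >= detrend_order + 2")


@dataclass(frozen=True)
class DFAResult:
    alpha1: float
    alpha2: float
    fluctuation_curve: Mapping[int, float]  # box size -> F(n)

    def fit_exponent(self, lo: int, hi: int) -> float:
        """Least-squares slope of log F(n) vs log n over box sizes in [lo, hi]."""
        ns = np.array([n for n in self.fluctuation_curve if lo <= n <= hi])
        if ns.size < 2:
            raise ValueError(f"fewer than 2 box sizes in [{lo}, {hi}]")
        fs = np.array([self.fluctuation_curve[n] for n in ns])
        return float(np.polyfit(np.log(ns), np.log(fs), 1)[0])


def _fluctuation(profile: np.ndarray, n: int, order: int) -> float:
    """RMS detrended fluctuation for box size n (incomplete tail dropped)."""
    n_boxes = profile.size // n
    if n_boxes == 0:
        raise ValueError(f"series too short for box size {n}")
    segs = profile[: n_boxes * n].reshape(n_boxes, n)
    t = np.arange(n, dtype=float)
    # polynomial detrend per box via a shared design matrix
    X = np.vander(t, order + 1)
    coef, *_ = np.linalg.lstsq(X, segs.T, rcond=None)
    resid = segs.T - X @ coef
    return float(np.sqrt(np.mean(resid**2)))


def dfa(series: np.ndarray, cfg: DFAConfig | None = None) -> DFAResult:
    """Detrended fluctuation analysis of an NN series.

    The mean-centred series is integrated; for every box size the integrated
    profile is split into non-overlapping boxes, the least-squares polynomial
    trend is removed per box, and F(n) is the RMS residual.  alpha1 and
    alpha2 are unweighted least-squares slopes of log F(n) vs log n over the
    configured short and long ranges.
    """
    cfg = cfg or DFAConfig()
    x = np.asarray(series, dtype=float)
    max_box = cfg.long_range[1]
    if x.size < 4 * max_box:
        raise ValueError(f"need >= {4 * max_box} points for max box size {max_box}")
    profile = np.cumsum(x - x.mean())
    sizes = list(range(cfg.short_range[0], cfg.short_range[1] + 1)) + list(
        range(cfg.long_range[0], cfg.long_range[1] + 1)
    )
    curve: Dict[int, float] = {}
    for n in sizes:
        f = _fluctuation(profile, n, cfg.detrend_order)
        if f <= 0:
            raise ValueError(
                f"zero fluctuation at box size {n} (constant series?); "
                "scaling exponent undefined"
            )
        curve[n] = f
    result = DFAResult(alpha1=0.0, alpha2=0.0, fluctuation_curve=curve)
    a1 = result.fit_exponent(*cfg.short_range)
    a2 = result.fit_exponent(*cfg.long_range)
    return DFAResult(alpha1=a1, alpha2=a2, fluctuation_curve=curve)


# ---------------------------------------------------------------------------
# Allometric aggregation


@dataclass(frozen=True)
class AllometricConfig:
    """Aggregation levels: counts of adjacent points summed per block."""

    aggregation_levels: Tuple[int, ...] = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)

    def __post_init__(self) -> None:
        lv = self.aggregation_levels
        if not all(a > 0 for a in lv) or list(lv) != sorted(set(lv)):
            raise ValueError("levels must be positive, ascending and unique")


@dataclass(frozen=True)
class AllometricResult:
    h: float  # slope of log SD vs log mean across levels
    level_means: Mapping[int, float]
    level_sds: Mapping[int, float]

    @property
    def fd(self) -> float:
        """Fractal dimension, FD = 2 - h."""
        return 2.0 - self.h


def aggregate(series: np.ndarray, level: int) -> np.ndarray:
    """Sum consecutive non-overlapping blocks of ``level`` points.

    The trailing remainder is discarded: output length = floor(N / level).
    """
    if level < 1:
        raise ValueError("aggregation level must be >= 1")
    x = np.asarray(series, dtype=float)
    if level > x.size:
        raise ValueError(f"level {level} exceeds series length {x.size}")
    n_blocks = x.size // level
    return x[: n_blocks * level].reshape(n_blocks, level).sum(axis=1)


def allometric_exponent(
    series: np.ndarray, cfg: AllometricConfig | None = None
) -> AllometricResult:
    """Allometric-aggregation scaling exponent h and fractal dimension 2 - h.

    At each aggregation level the mean and SD of the block-summed series are
    computed; h is the least-squares slope of log SD versus log mean across
    levels. Levels with zero SD are dropped with a warning; fewer than three
    usable levels is an error. Requires positive means (log scale).
    """
    cfg = cfg or AllometricConfig()
    x = np.asarray(series, dtype=float)
    max_level = max(cfg.aggregation_levels)
    if x.size < 10 * max_level:
        raise ValueError(
            f"need >= {10 * max_level} points for max aggregation level {max_level}"
        )
    means: Dict[int, float] = {}
    sds: Dict[int, float] = {}
    for level in cfg.aggregation_levels:
        agg = aggregate(x, level)
        m, s = float(agg.mean()), float(agg.std(ddof=1))
        if m <= 0:
            raise ValueError(
                f"non-positive mean at aggregation level {level}; "
                "allometric fit requires a positive-valued series"
            )
        if s == 0:
            warnings.warn(f"zero SD at aggregation level {level}; level dropped")
            continue
        means[level] = m
        sds[level] = s
    if len(means) < 3:
        raise ValueError("fewer than 3 usable aggregation levels")
    log_m = np.log([means[k] for k in means])
    log_s = np.log([sds[k] for k in means])
    h = float(np.polyfit(log_m, log_s, 1)[0])
    return AllometricResult(h=h, level_means=means, level_sds=sds)


# ---------------------------------------------------------------------------
# Multiscale sample entropy


@dataclass(frozen=True)
class MSEConfig:
    """Template length m, tolerance fraction r, and coarse-graining scales.

    ``r`` is a fraction of the SD of the *original* (scale-1) series and by
    default is reused unchanged at every scale, the canonical multiscale
    convention; set ``per_scale_r`` to re-derive the tolerance from each
    coarse-grained series instead.
    """

    m: int = 2
    r: float = 0.15
    scale_factors: Tuple[int, ...] = (1, 5, 10, 15, 20)
    per_scale_r: bool = False

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not 0 < self.r < 1:
            raise ValueError("r must be in (0, 1)")
        if not all(s >= 1 for s in self.scale_factors):
            raise ValueError("scale factors must be >= 1")


@dataclass(frozen=True)
class MSEResult:
    sampen_by_scale: Mapping[int, float]  # NaN where undefined
    undefined_scales: Tuple[int, ...] = ()


def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Average consecutive non-overlapping windows of ``scale`` points."""
    if scale < 1:
        raise ValueError("scale must be >= 1")
    x = np.asarray(series, dtype=float)
    if scale > x.size:
        raise ValueError(f"scale {scale} exceeds series length {x.size}")
    n_blocks = x.size // scale
    return x[: n_blocks * scale].reshape(n_blocks, scale).mean(axis=1)


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts of Chebyshev template matches of lengths m (B) and m+1 (A).

    Pairs (i, j), i < j, both restricted to i, j <= N - m - 1 so that both
    the m- and (m+1)-length templates are defined; self-matches excluded.
    """
    n = x.size
    n_templates = n - m  # number of (m+1)-length template start positions
    b = a = 0
    from numpy.lib.stride_tricks import sliding_window_view

    for d in range(1, n_templates):
        e = np.abs(x[:-d] - x[d:])  # length n - d
        if e.size < m:
            break
        wm = sliding_window_view(e, m).max(axis=1)  # i = 0 .. n-d-m
        valid_m = wm[: n_templates - d]  # restrict i <= n-m-1-d
        b += int(np.count_nonzero(valid_m <= r))
        if e.size >= m + 1:
            wm1 = sliding_window_view(e, m + 1).max(axis=1)
            a += int(np.count_nonzero(wm1[: n_templates - d] <= r))
    return b, a


def sample_entropy(
    series: np.ndarray,
    m: int = 2,
    r_fraction: float = 0.15,
    tolerance: float | None = None,
) -> float:
    """Sample entropy, -ln(A/B), of a series.

    B counts pairs of m-length templates within Chebyshev distance r of each
    other (self-matches excluded), A the same for length m+1. The tolerance
    is ``r_fraction`` times the series SD unless an absolute ``tolerance``
    is given (as multiscale analysis does, fixing r from the scale-1 series).
    """
    x = np.asarray(series, dtype=float)
    if x.size < m + 2:
        raise ValueError(f"need at least {m + 2} points for m={m}")
    if tolerance is None:
        sd = float(x.std(ddof=0))
        if sd == 0:
            raise ValueError("constant series: tolerance would be zero")
        tolerance = r_fraction * sd
    b, a = _match_counts(x, m, tolerance)
    if b == 0:
        raise SampEnUndefinedError(f"no template matches of length {m}")
    if a == 0:
        raise SampEnUndefinedError(f"no template matches of length {m + 1}")
    return float(-np.log(a / b))


def multiscale_entropy(series: np.ndarray, cfg: MSEConfig | None = None) -> MSEResult:
    """SampEn of coarse-grained copies of the series at each scale factor.

    Undefined scales (no matches, or a coarse-grained series too short) are
    reported as NaN and listed in ``undefined_scales``; other scales are
    still returned.
    """
    cfg = cfg or MSEConfig()
    x = np.asarray(series, dtype=float)
    max_scale = max(cfg.scale_factors)
    if x.size // max_scale < 10 * (cfg.m + 1):
        raise ValueError(
            f"series too short: length/max_scale must be >= {10 * (cfg.m + 1)}"
        )
    sd = float(x.std(ddof=0))
    if sd == 0:
        raise ValueError("constant series: tolerance would be zero")
    tol = cfg.r * sd
    values: Dict[int, float] = {}
    undefined: list[int] = []
    for scale in cfg.scale_factors:
        cg = coarse_grain(x, scale)
        try:
            if cfg.per_scale_r:
                values[scale] = sample_entropy(cg, m=cfg.m, r_fraction=cfg.r)
            else:
                values[scale] = sample_entropy(cg, m=cfg.m, tolerance=tol)
        except (SampEnUndefinedError, ValueError):
            values[scale] = float("nan")
            undefined.append(scale)
    return MSEResult(sampen_by_scale=values, undefined_scales=tuple(undefined))
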