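"""Independent brute-force oracles, kept separate from the library code paths.

Each oracle re-derives a quantity by the most direct definition available
(explicit all-pairs loops, closed forms, naive re-scans) so it can serve as
an external check on the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> float:
    """Sample entropy by explicit all-pairs template comparison.

    B counts pairs (i < j) of m-length templates within Chebyshev distance r,
    A the same for m+1; both indices restricted so the (m+1)-length template
    exists. Returns -ln(A/B).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    last = n - m - 1  # largest start index with an (m+1)-template
    b = a = 0
    for i in range(last + 1):
        for j in range(i + 1, last + 1):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0 or a == 0:
        raise ZeroDivisionError("no template matches")
    return -math.log(a / b)


def rmssd_direct(x) -> float:
    """RMSSD from its defining formula, no numpy vector ops."""
    diffs = [(x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)]
    return math.sqrt(sum(diffs) / len(diffs))


def central_window_rescan(x, w: int, frac: float):
    """Naive re-implementation of the single-pass evolving central filter.

    Returns the surviving values and the excluded original values, computed
    with explicit slice means over a shrinking list.
    """
    xs = list(map(float, x))
    excluded = []
    i = w
    while i + w < len(xs):
        window = xs[i - w : i + w + 1]
        mean = (sum(window) - xs[i]) / (2 * w)
        if abs(xs[i] - mean) > frac * mean:
            excluded.append(xs.pop(i))
        else:
            i += 1
    return xs, excluded


def fgn_autocovariance(k: int, hurst: float) -> float:
    """Closed-form autocovariance of unit-variance fractional Gaussian noise."""
    h2 = 2 * hurst
    return 0.5 * (abs(k + 1) ** h2 - 2 * abs(k) ** h2 + abs(k - 1) ** h2)


def dfa_fluctuation_direct(x: np.ndarray, n: int) -> float:
    """F(n) by per-box polyfit loops (order-1 detrend)."""
    x = np.asarray(x, dtype=float)
    y = np.cumsum(x - x.mean())
    n_boxes = len(y) // n
    t = np.arange(n, dtype=float)
    sq = []
    for b in range(n_boxes):
        seg = y[b * n : (b + 1) * n]
        coef = np.polyfit(t, seg, 1)
        resid = seg - np.polyval(coef, t)
        sq.extend(resid**2)
    return math.sqrt(sum(sq) / len(sq))
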