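"""Reading, trimming and artifact-filtering of interbeat-interval (IBI) recordings.

Ambulatory single-lead recorders export one interbeat interval per detected
beat, in milliseconds.  Before any variability or complexity measure is
computed the raw series is (1) trimmed of its adaptation windows at both
ends, (2) band-filtered to remove physiologically impossible intervals and
(3) scanned with a moving central-interval filter that rejects beats far from
their local neighbourhood mean.  Rejected intervals are *removed*, not
interpolated; every downstream measure operates on the gapless surviving
sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "RawIBIRecording",
    "FilterConfig",
    "FilterReport",
    "CleanIBISeries",
    "read_ibi_file",
    "write_ibi_file",
    "trim_recording",
    "band_filter",
    "central_window_filter",
    "preprocess",
]


class IBIParseError(ValueError):
    """Raised when an IBI text file cannot be parsed."""


@dataclass(frozen=True)
class RawIBIRecording:
    """An ordered sequence of interbeat intervals in milliseconds, pre-filtering.

    Parameters
    ----------
    subject_id : str
        Identifier carried through to all per-subject outputs.
    intervals : ndarray
        Interbeat intervals in ms, in recording order. All must be positive.
    start_time : str or None
        Optional wall-clock start time (informational only).
    """

    subject_id: str
    intervals: np.ndarray
    start_time: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValueError("intervals must be a 1-D sequence")
        if arr.size and not np.all(arr > 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise ValueError(f"non-positive interval at position {bad}")
        object.__setattr__(self, "intervals", arr)

    @property
    def n_intervals(self) -> int:
        return int(self.intervals.size)

    @property
    def total_duration_min(self) -> float:
        """Total recording duration in minutes (sum of intervals)."""
        return float(self.intervals.sum() / 60000.0)


@dataclass(frozen=True)
class FilterConfig:
    """Trim and artifact-filter settings.

    Defaults follow standard ambulatory practice: 15-minute trims at each
    end, a 400-1100 ms acceptance band, and an 11-interval central window
    (5 neighbours on each side) with a 20% relative-deviation threshold.
    """

    trim_minutes: float = 15.0
    low_pass_ms: float = 1100.0
    high_pass_ms: float = 400.0
    window_halfwidth: int = 5
    exclusion_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.high_pass_ms < self.low_pass_ms:
            raise ValueError("require 0 < high_pass_ms < low_pass_ms")
        if self.window_halfwidth < 1:
            raise ValueError("window_halfwidth must be >= 1")
        if not 0 < self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must be in (0, 1)")
        if self.trim_minutes < 0:
            raise ValueError("trim_minutes must be >= 0")


@dataclass(frozen=True)
class FilterReport:
    """Per-subject accounting of excluded intervals."""

    n_input: int
    n_excluded_band: int
    n_excluded_window: int

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_excluded_band - self.n_excluded_window

    @property
    def excluded_fraction(self) -> float:
        if self.n_input == 0:
            return 0.0
        return (self.n_excluded_band + self.n_excluded_window) / self.n_input


@dataclass(frozen=True)
class CleanIBISeries:
    """Filtered NN-interval series plus its exclusion report."""

    subject_id: str
    intervals: np.ndarray
    report: FilterReport

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        if arr.size != self.report.n_output:
            raise ValueError("series length inconsistent with filter report")

    @property
    def n_intervals(self) -> int:
        return int(self.intervals.size)


def read_ibi_file(
    path: str | Path,
    dialect: str = "single_column",
    subject_id: str | None = None,
) -> RawIBIRecording:
    """Read a plain-text IBI file.

    Two dialects are supported:

    * ``single_column`` — one interval in ms per line.
    * ``two_column_timestamped`` — ``cumulative_seconds<TAB>interval_ms``.

    Non-numeric or non-positive lines raise :class:`IBIParseError` naming the
    offending line; nothing is silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("single_column", "two_column_timestamped"):
        raise ValueError(f"unknown dialect {dialect!r}")

    intervals: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "single_column":
                    if len(fields) != 1:
                        raise ValueError
                    value = float(fields[0])
                else:
                    if len(fields) != 2:
                        raise ValueError
                    value = float(fields[1])
            except ValueError:
                raise IBIParseError(
                    f"{path}:{lineno}: cannot parse {line!r} as {dialect}"
                ) from None
            if not np.isfinite(value) or value <= 0:
                raise IBIParseError(
                    f"{path}:{lineno}: non-positive interval {value!r}"
                )
            intervals.append(value)
    if not intervals:
        raise IBIParseError(f"{path}: no intervals found")
    return RawIBIRecording(
        subject_id=subject_id or path.stem, intervals=np.asarray(intervals)
    )


def write_ibi_file(
    path: str | Path,
    intervals: Sequence[float] | np.ndarray,
    dialect: str = "single_column",
) -> None:
    """Write intervals (ms) as plain text in the given dialect."""
    arr = np.asarray(intervals, dtype=float)
    path = Path(path)
    with open(path, "w") as fh:
        if dialect == "single_column":
            for v in arr:
                fh.write(f"{v:.6g}\n")
        elif dialect == "two_column_timestamped":
            t = np.cumsum(arr) / 1000.0
            for ti, v in zip(t, arr):
                fh.write(f"{ti:.6f}\t{v:.6g}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def trim_recording(rec: RawIBIRecording, trim_minutes: float) -> RawIBIRecording:
    """Remove ``trim_minutes`` of cumulative time from each end of a recording.

    Boundaries are half-open in cumulative time: an interval is kept iff its
    end time exceeds the leading trim and its start time precedes the start
    of the trailing trim. A 120-min recording trimmed by 15 min therefore
    yields a series of about 90 min, give or take one interval at each edge.
    """
    if trim_minutes == 0:
        return rec
    trim_ms = trim_minutes * 60000.0
    total_ms = float(rec.intervals.sum())
    if total_ms <= 2 * trim_ms:
        raise ValueError(
            f"recording of {total_ms / 60000.0:.1f} min is too short to trim "
            f"{trim_minutes} min from each end"
        )
    end_t = np.cumsum(rec.intervals)
    start_t = end_t - rec.intervals
    keep = (end_t > trim_ms) & (start_t < total_ms - trim_ms)
    return RawIBIRecording(
        subject_id=rec.subject_id,
        intervals=rec.intervals[keep],
        start_time=rec.start_time,
    )


def band_filter(
    intervals: np.ndarray,
    low_pass_ms: float = 1100.0,
    high_pass_ms: float = 400.0,
) -> tuple[np.ndarray, int]:
    """Remove intervals outside ``[high_pass_ms, low_pass_ms]``.

    Returns the surviving intervals (original order) and the exclusion count.
    """
    if not 0 < high_pass_ms < low_pass_ms:
        raise ValueError("require 0 < high_pass_ms < low_pass_ms")
    arr = np.asarray(intervals, dtype=float)
    keep = (arr >= high_pass_ms) & (arr <= low_pass_ms)
    return arr[keep], int(arr.size - keep.sum())


def central_window_filter(
    intervals: np.ndarray,
    window_halfwidth: int = 5,
    exclusion_fraction: float = 0.20,
) -> tuple[np.ndarray, int]:
    """Moving central-interval filter.

    Each candidate interval is compared with the mean of its
    ``2 * window_halfwidth`` neighbours (the candidate itself excluded); it is
    removed when it deviates from that mean by more than
    ``exclusion_fraction`` of the mean.  The scan is a single forward pass
    over the *evolving* series: once removed, an interval no longer
    participates in later windows.  The first and last ``window_halfwidth``
    intervals have no complete window and are never candidates.
    """
    w = int(window_halfwidth)
    if w < 1:
        raise ValueError("window_halfwidth must be >= 1")
    if not 0 < exclusion_fraction < 1:
        raise ValueError("exclusion_fraction must be in (0, 1)")
    xs = list(np.asarray(intervals, dtype=float))
    if len(xs) <= 2 * w:
        raise ValueError(
            f"series of length {len(xs)} too short for a full "
            f"{2 * w + 1}-interval window"
        )
    n_excluded = 0
    i = w
    while i < len(xs) - w:
        neighbours = xs[i - w : i] + xs[i + 1 : i + w + 1]
        mean = sum(neighbours) / (2 * w)
        if abs(xs[i] - mean) > exclusion_fraction * mean:
            del xs[i]
            n_excluded += 1
            # the next interval shifts into position i: window advances
        else:
            i += 1
    return np.asarray(xs), n_excluded


def preprocess(rec: RawIBIRecording, cfg: FilterConfig | None = None) -> CleanIBISeries:
    """Full preprocessing chain: trim, band filter, central-window filter."""
    cfg = cfg or FilterConfig()
    trimmed = trim_recording(rec, cfg.trim_minutes)
    n_input = trimmed.n_intervals
    banded, n_band = band_filter(trimmed.intervals, cfg.low_pass_ms, cfg.high_pass_ms)
    cleaned, n_window = central_window_filter(
        banded, cfg.window_halfwidth, cfg.exclusion_fraction
    )
    report = FilterReport(
        n_input=n_input, n_excluded_band=n_band, n_excluded_window=n_window
    )
    return CleanIBISeries(subject_id=rec.subject_id, intervals=cleaned, report=report)
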