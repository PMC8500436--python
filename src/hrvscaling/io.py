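"""Reading, writing and quality screening of RR-interval records.

An RR series is the sequence of times between successive heart beats,
in milliseconds, as extracted from a Holter (24-h ambulatory ECG)
recording.  Two plain-text layouts are supported: one interval per line,
and CSV with an ``rr_ms`` column plus an optional ``time_s`` column of
beat times in seconds since the start of the record.

The quality screen implements the computable subset of the Holter
normality criteria: no pauses of 3 s or more and a minimum mean
night-time rate of 60 beats/min.  Criteria that need ECG morphology
(ectopy counts, conduction disturbances) cannot be evaluated from the
interval sequence alone and are out of scope.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "RRSeries",
    "ScreenReport",
    "read_rr_series",
    "write_rr_series",
    "screen_record",
    "drop_out_of_bounds",
    "read_population_table",
    "write_population_table",
    "PAUSE_THRESHOLD_MS",
    "PHYSIOLOGICAL_BOUNDS_MS",
]

#: An interval at least this long counts as a cardiac pause.
PAUSE_THRESHOLD_MS = 3000.0

#: Intervals outside this range are physiologically implausible for
#: sinus rhythm and are counted by the screen (200 ms = 300 bpm).
PHYSIOLOGICAL_BOUNDS_MS = (200.0, 3000.0)

_SEXES = ("male", "female", "unknown")


@dataclass
class RRSeries:
    """One subject's RR-interval sequence with demographic metadata.

    Parameters
    ----------
    intervals
        RR durations in milliseconds; every value finite and positive,
        length at least 2.
    beat_times
        Optional beat clock times in seconds since record start;
        strictly increasing, same length as ``intervals``.
    age_years
        Age as a continuous variable (0.08 = one month).
    """

    intervals: np.ndarray
    beat_times: Optional[np.ndarray] = None
    subject_id: str = ""
    age_years: Optional[float] = None
    sex: str = "unknown"
    source: str = ""

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1 or self.intervals.size < 2:
            raise ValueError("RR series must be 1-D with at least 2 intervals")
        if not np.all(np.isfinite(self.intervals)):
            raise ValueError("RR intervals must all be finite")
        if np.any(self.intervals <= 0):
            raise ValueError("RR intervals must all be positive")
        if self.beat_times is not None:
            self.beat_times = np.asarray(self.beat_times, dtype=float)
            if self.beat_times.shape != self.intervals.shape:
                raise ValueError("beat_times must match intervals in length")
            if np.any(np.diff(self.beat_times) <= 0):
                raise ValueError("beat_times must be strictly increasing")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.age_years is not None and self.age_years <= 0:
            raise ValueError("age_years must be positive")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def mean_rr_ms(self) -> float:
        return float(self.intervals.mean())

    def replace(self, **changes) -> "RRSeries":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ScreenReport:
    """Outcome of the record-quality screen on one RR series."""

    max_pause_ms: float
    pause_violation: bool
    min_rate_violation: bool
    n_out_of_bounds: int

    @property
    def passed(self) -> bool:
        return not (self.pause_violation or self.min_rate_violation)


def _parse_float(token: str, lineno: int, path) -> float:
    try:
        value = float(token)
    except ValueError:
        raise ValueError(
            f"{path}: line {lineno}: not a number: {token!r}"
        ) from None
    if not np.isfinite(value) or value <= 0:
        raise ValueError(
            f"{path}: line {lineno}: RR interval must be a finite positive "
            f"number of ms, got {token!r}"
        )
    return value


def read_rr_series(
    path,
    format: Optional[str] = None,
    units: str = "ms",
    **metadata,
) -> RRSeries:
    """Read an RR series from ``path``.

    ``format`` is ``"plain"`` (one interval per line) or ``"csv"``
    (columns ``rr_ms`` and optionally ``time_s``); when omitted it is
    inferred from the file extension.  ``units`` is ``"ms"`` or ``"s"``
    and applies to the interval column; values are converted to ms on
    ingest.  Extra keyword arguments (``subject_id``, ``age_years``,
    ``sex``, ``source``) populate the series metadata.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "plain"
    if units not in ("ms", "s"):
        raise ValueError("units must be 'ms' or 's'")
    scale = 1000.0 if units == "s" else 1.0

    if format == "plain":
        values = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                token = line.strip()
                if not token:
                    continue
                values.append(_parse_float(token, lineno, path))
        if not values:
            raise ValueError(f"{path}: empty file, no RR intervals found")
        return RRSeries(np.asarray(values) * scale, **metadata)

    if format == "csv":
        try:
            frame = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise ValueError(f"{path}: empty file, no RR intervals found") from None
        if "rr_ms" not in frame.columns:
            raise ValueError(
                f"{path}: malformed CSV header: required column 'rr_ms' "
                f"missing (found {list(frame.columns)})"
            )
        rr = pd.to_numeric(frame["rr_ms"], errors="coerce")
        if rr.isna().any():
            bad = int(rr.index[rr.isna()][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: line {bad}: non-numeric rr_ms value")
        times = None
        if "time_s" in frame.columns:
            times = pd.to_numeric(frame["time_s"], errors="coerce")
            if times.isna().any():
                bad = int(times.index[times.isna()][0]) + 2
                raise ValueError(f"{path}: line {bad}: non-numeric time_s value")
            times = times.to_numpy()
        return RRSeries(rr.to_numpy() * scale, beat_times=times, **metadata)

    raise ValueError(f"unknown format {format!r}; expected 'plain' or 'csv'")


def write_rr_series(series: RRSeries, path, format: Optional[str] = None) -> None:
    """Write ``series`` so that :func:`read_rr_series` reproduces it exactly.

    Values are rendered with ``repr``, which round-trips IEEE doubles.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "plain"
    if format == "plain":
        with open(path, "w", encoding="utf-8") as fh:
            for v in series.intervals:
                fh.write(f"{float(v)!r}\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if series.beat_times is not None:
                fh.write("time_s,rr_ms\n")
                for t, v in zip(series.beat_times, series.intervals):
                    fh.write(f"{float(t)!r},{float(v)!r}\n")
            else:
                fh.write("rr_ms\n")
                for v in series.intervals:
                    fh.write(f"{float(v)!r}\n")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'plain' or 'csv'")


def screen_record(
    series: RRSeries,
    night_window: Optional[tuple[float, float]] = None,
) -> ScreenReport:
    """Apply the interval-computable Holter normality criteria.

    ``night_window`` is ``(start_s, end_s)`` in seconds since record
    start (requires ``beat_times``); callers with a wall-clock record
    start should map their clock window to record time.  Without a
    window the whole series is treated as the night segment, which is
    conservative for both criteria.
    """
    if night_window is not None:
        if series.beat_times is None:
            raise ValueError(
                "night_window given but the series has no beat_times"
            )
        lo, hi = night_window
        if hi <= lo:
            raise ValueError("night_window must satisfy start < end")
        mask = (series.beat_times >= lo) & (series.beat_times <= hi)
        window = series.intervals[mask]
        if window.size == 0:
            raise ValueError("night_window contains no beats")
    else:
        window = series.intervals

    max_pause = float(window.max())
    pause_violation = bool(max_pause >= PAUSE_THRESHOLD_MS)
    # mean rate < 60/min  <=>  mean RR > 1000 ms
    min_rate_violation = bool(window.mean() > 1000.0)
    lo_ms, hi_ms = PHYSIOLOGICAL_BOUNDS_MS
    n_oob = int(
        np.count_nonzero(
            (series.intervals < lo_ms) | (series.intervals > hi_ms)
        )
    )
    return ScreenReport(
        max_pause_ms=max_pause,
        pause_violation=pause_violation,
        min_rate_violation=min_rate_violation,
        n_out_of_bounds=n_oob,
    )


def drop_out_of_bounds(series: RRSeries) -> tuple[RRSeries, int]:
    """Return a copy without physiologically out-of-bounds intervals.

    No automatic ectopy correction is attempted; this merely removes
    intervals outside :data:`PHYSIOLOGICAL_BOUNDS_MS` and reports how
    many were dropped.  Beat times are dropped alongside their interval.
    """
    lo, hi = PHYSIOLOGICAL_BOUNDS_MS
    keep = (series.intervals >= lo) & (series.intervals <= hi)
    n_dropped = int(np.count_nonzero(~keep))
    if n_dropped == 0:
        return series, 0
    times = series.beat_times[keep] if series.beat_times is not None else None
    return series.replace(intervals=series.intervals[keep], beat_times=times), n_dropped


_POP_COLUMNS = ("age_years", "sex", "index_name", "value")


def read_population_table(path) -> pd.DataFrame:
    """Read a population table (age_years, sex, index_name, value[, source])."""
    frame = pd.read_csv(path)
    missing = [c for c in _POP_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"{path}: population table missing columns {missing} "
            f"(found {list(frame.columns)})"
        )
    if "source" not in frame.columns:
        frame["source"] = ""
    frame["age_years"] = pd.to_numeric(frame["age_years"])
    frame["value"] = pd.to_numeric(frame["value"])
    if (frame["age_years"] <= 0).any():
        raise ValueError(f"{path}: ages must be positive")
    bad_sex = set(frame["sex"].unique()) - set(_SEXES)
    if bad_sex:
        raise ValueError(f"{path}: unknown sex labels {sorted(bad_sex)}")
    return frame


def write_population_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
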