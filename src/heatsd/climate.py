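"""Daily climate series, heat-wave episode detection and table functions.

The climate driver of the model is the daily maximum temperature.  Heat-wave
episodes are detected with the China Meteorological Administration (CMA)
operational rules: a run of consecutive days with Tmax exceeding 35 °C lasting
at least 5 days, or at least 2 consecutive days exceeding 38 °C, is a *strong*
heat wave; 8 days over 35 °C or 3 consecutive days over 38 °C make it
*extreme*.  "Exceeding" is read strictly (``tmax > threshold``); both
thresholds are arguments so other conventions can be explored.

Table functions — ordered piecewise-linear breakpoint lists with clamped
extrapolation — are the standard system-dynamics device for empirical
input–output relations that have no closed form; here they carry the
maximum-temperature amplification (MA) and the hot-day amplification (HDAF)
curves.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "DailyClimateRecord",
    "TemperatureSeries",
    "HeatWaveEpisode",
    "Severity",
    "TableFunction",
    "detect_heatwaves",
    "hot_day_count",
    "apply_offset",
    "table_eval",
    "HOT_THRESHOLD",
    "SEVERE_THRESHOLD",
]

#: CMA heat-wave thresholds (°C).
HOT_THRESHOLD = 35.0
SEVERE_THRESHOLD = 38.0


@dataclass(frozen=True)
class DailyClimateRecord:
    """One day of station-level climate observations.

    Only ``tmax`` is required — it is the variable the model is driven by.
    ``tmean``/``tmin``/``humidity`` are carried through for completeness of
    the climate-system indicator set.
    """

    date: dt.date
    tmax: float
    tmean: float | None = None
    tmin: float | None = None
    humidity: float | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.date, dt.date):
            raise InputError(f"date must be a datetime.date, got {self.date!r}")
        if self.tmin is not None and self.tmean is not None:
            if not (self.tmin <= self.tmean <= self.tmax):
                raise InputError(
                    f"{self.date}: require tmin <= tmean <= tmax, "
                    f"got {self.tmin}, {self.tmean}, {self.tmax}"
                )
        elif self.tmin is not None and self.tmin > self.tmax:
            raise InputError(f"{self.date}: tmin {self.tmin} > tmax {self.tmax}")
        if self.humidity is not None and not (0.0 <= self.humidity <= 100.0):
            raise InputError(f"{self.date}: humidity {self.humidity} outside [0, 100]")


@dataclass(frozen=True)
class TemperatureSeries:
    """An ordered, gap-free run of daily climate records."""

    records: tuple[DailyClimateRecord, ...]

    def __init__(self, records: Iterable[DailyClimateRecord]):
        recs = tuple(records)
        if not recs:
            raise InputError("temperature series must be non-empty")
        for prev, cur in zip(recs, recs[1:]):
            if cur.date != prev.date + dt.timedelta(days=1):
                raise InputError(
                    f"dates must be strictly increasing and consecutive; "
                    f"{prev.date} is followed by {cur.date}"
                )
        object.__setattr__(self, "records", recs)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> DailyClimateRecord:
        return self.records[i]

    def __iter__(self):
        return iter(self.records)

    @property
    def dates(self) -> list[dt.date]:
        return [r.date for r in self.records]

    @property
    def tmax(self) -> np.ndarray:
        """Daily maximum temperatures as a float array (°C)."""
        return np.array([r.tmax for r in self.records], dtype=float)


class Severity(str, enum.Enum):
    """CMA heat-wave grade."""

    NONE = "none"
    STRONG = "strong"
    EXTREME = "extreme"


@dataclass(frozen=True)
class HeatWaveEpisode:
    """A maximal run of hot days classified by the CMA rules.

    ``start_index``/``end_index`` are 0-based inclusive offsets into the
    series the episode was detected in; human-facing reports use 1-based
    "day N within episode".
    """

    start_index: int
    end_index: int
    severity: Severity

    @property
    def duration(self) -> int:
        return self.end_index - self.start_index + 1

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise InputError("episode must span at least one day")


def _classify_run(
    tmax: np.ndarray, hot_threshold: float, severe_threshold: float
) -> Severity:
    """Grade one maximal run of days with tmax > hot_threshold."""
    duration = len(tmax)
    severe = tmax > severe_threshold
    longest_severe = 0
    cur = 0
    for flag in severe:
        cur = cur + 1 if flag else 0
        longest_severe = max(longest_severe, cur)
    if duration >= 8 or longest_severe >= 3:
        return Severity.EXTREME
    if duration >= 5 or longest_severe >= 2:
        return Severity.STRONG
    return Severity.NONE


def detect_heatwaves(
    series: TemperatureSeries,
    hot_threshold: float = HOT_THRESHOLD,
    severe_threshold: float = SEVERE_THRESHOLD,
) -> list[HeatWaveEpisode]:
    """Find all CMA heat-wave episodes in a daily series.

    Episodes are maximal runs of consecutive days with
    ``tmax > hot_threshold``; a run is returned only when it satisfies at
    least the strong-grade rule.  When a run satisfies both grades the most
    severe wins.  Returned episodes are disjoint and in chronological order.
    """
    if hot_threshold <= 0 or severe_threshold <= 0:
        raise InputError("thresholds must be positive")
    if severe_threshold <= hot_threshold:
        raise InputError("severe_threshold must exceed hot_threshold")
    tmax = series.tmax
    hot = tmax > hot_threshold
    episodes: list[HeatWaveEpisode] = []
    i = 0
    n = len(tmax)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1]:
            j += 1
        severity = _classify_run(tmax[i : j + 1], hot_threshold, severe_threshold)
        if severity is not Severity.NONE:
            episodes.append(HeatWaveEpisode(i, j, severity))
        i = j + 1
    return episodes


def hot_day_count(
    series: TemperatureSeries, day_index: int, hot_threshold: float = HOT_THRESHOLD
) -> int:
    """Consecutive hot days ending at ``day_index`` (0 if that day is cool).

    This is the "hot days" state variable: it counts how long the current
    heat wave has continued, and resets on the first non-hot day.
    """
    if not 0 <= day_index < len(series):
        raise InputError(
            f"day_index {day_index} out of range for series of length {len(series)}"
        )
    count = 0
    for i in range(day_index, -1, -1):
        if series[i].tmax > hot_threshold:
            count += 1
        else:
            break
    return count


def hot_day_counts(
    series: TemperatureSeries, hot_threshold: float = HOT_THRESHOLD
) -> np.ndarray:
    """Vector of ``hot_day_count`` for every day of the series."""
    tmax = series.tmax
    out = np.zeros(len(tmax), dtype=int)
    run = 0
    for i, t in enumerate(tmax):
        run = run + 1 if t > hot_threshold else 0
        out[i] = run
    return out


def apply_offset(series: TemperatureSeries, delta: float) -> TemperatureSeries:
    """Shift every temperature field by ``delta`` °C, keeping dates.

    Used to construct the marginal-warming scenarios (+1 °C, +2 °C on every
    day's maximum temperature).
    """
    shifted = [
        replace(
            r,
            tmax=r.tmax + delta,
            tmean=None if r.tmean is None else r.tmean + delta,
            tmin=None if r.tmin is None else r.tmin + delta,
        )
        for r in series
    ]
    return TemperatureSeries(shifted)


@dataclass(frozen=True)
class TableFunction:
    """Piecewise-linear lookup with clamped (constant) extrapolation.

    Breakpoints are ``(x, y)`` pairs with strictly increasing x.  Evaluation
    at a breakpoint returns its y exactly; outside the breakpoint range the
    nearest endpoint value is returned, which keeps the amplification factors
    bounded outside the calibrated range.
    """

    breakpoints: tuple[tuple[float, float], ...]

    def __init__(self, breakpoints: Sequence[Sequence[float]]):
        pts = tuple((float(x), float(y)) for x, y in breakpoints)
        if len(pts) < 2:
            raise ConfigurationError("table function needs at least 2 breakpoints")
        xs = [p[0] for p in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigurationError("table-function x values must strictly increase")
        object.__setattr__(self, "breakpoints", pts)

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.breakpoints])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.breakpoints])

    def __call__(self, x: float) -> float:
        return float(np.interp(x, self.x, self.y))

    def with_y(self, index: int, value: float) -> "TableFunction":
        """Copy of this table with breakpoint ``index``'s height replaced."""
        pts = list(self.breakpoints)
        pts[index] = (pts[index][0], float(value))
        return TableFunction(pts)


def table_eval(tf: TableFunction, x: float) -> float:
    """Evaluate a table function (functional form of ``tf(x)``)."""
    return tf(x)
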