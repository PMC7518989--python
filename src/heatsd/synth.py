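"""Synthetic inputs: heat-wave fixtures, city profiles, daily death series.

The real station records and CDC mortality microdata behind the Shanghai
analyses are not publicly deposited, so every pipeline input is emulated
here:

* **Heat-wave temperature fixtures.**  Stylized Tmax profiles with cool
  shoulders and a contiguous hot plateau whose length matches the two
  historical episodes — 19 days for the July/August 2003 extreme event and
  15 days for the July 2013 event.  The within-plateau shape is a designed
  curve (a main crest around days 6–8 and, for the 2013-like event, a
  secondary crest around day 12), not a reconstruction of the historical
  trace.  Small seeded jitter (±0.3 °C) adds day-to-day texture and is
  bounded so it can never move a day across the 35 °C episode threshold,
  keeping episode durations exact by construction.

* **City profiles.**  Fixed, documented yearbook-like indicator sets; the
  2013-like profile has total population 24.1 million and a minimum living
  allowance of 790 currency units per month.

* **Daily deaths.**  A two-level background generator (≈114 persons per ten
  million per day on cool days, ≈124 on hot days) with Poisson day-to-day
  noise, and a forward-simulation generator producing ground-truth death
  series from known parameters for calibration-recovery experiments.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adaptation import CityProfile
from .climate import DailyClimateRecord, TemperatureSeries
from .engine import ModelParameters, Scenario, simulate
from .errors import InputError

__all__ = [
    "FixtureSpec",
    "gen_constant_series",
    "gen_heatwave_series",
    "gen_city_profile",
    "gen_baseline_mortality",
    "gen_observed_deaths",
    "COOL_DEATH_RATE",
    "HOT_DEATH_RATE",
]

#: Observed average daily mortality (persons per ten million per day) on days
#: with Tmax at or below / above 35 °C.
COOL_DEATH_RATE = 114.0
HOT_DEATH_RATE = 124.0

#: Within-plateau Tmax (°C) of the 15-day 2013-like fixture: a fast rise to
#: a sustained crest around days 4-7 (peak 40.5 on day 7), a decline through
#: day 11 and a secondary crest on day 12 before the wave breaks.  Stylized,
#: not historical; the committed default calibration is fitted against this
#: exact curve.
_HW2013_PLATEAU = (
    36.4, 37.89, 39.25, 40.30, 40.30, 40.27, 40.5, 39.73,
    38.78, 38.18, 37.40, 39.27, 38.78, 37.30, 36.5,
)

#: Start dates placing the plateaus in their historical months.
_HW2013_PLATEAU_START = dt.date(2013, 7, 15)
_HW2003_PLATEAU_START = dt.date(2003, 7, 20)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic heat-wave temperature fixture."""

    kind: str = "custom"
    n_days: int = 25
    plateau_days: int = 15
    peak_tmax: float = 40.5
    shoulder_tmax: float = 32.0
    seed: int = 0

    KINDS = ("hw2003", "hw2013", "custom")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InputError(f"unknown fixture kind {self.kind!r}")
        if self.n_days < 1:
            raise InputError("n_days must be at least 1")
        if not 0 <= self.plateau_days <= self.n_days:
            raise InputError("plateau_days must lie in [0, n_days]")
        if self.plateau_days > 0 and not (self.peak_tmax > 35.0 > self.shoulder_tmax):
            raise InputError(
                "need peak_tmax > 35 > shoulder_tmax for a detectable episode"
            )

    @classmethod
    def hw2003(cls, seed: int = 0) -> "FixtureSpec":
        """The 19-day 2003-like extreme episode (5-day shoulders)."""
        return cls(kind="hw2003", n_days=29, plateau_days=19,
                   peak_tmax=39.8, shoulder_tmax=32.0, seed=seed)

    @classmethod
    def hw2013(cls, seed: int = 0) -> "FixtureSpec":
        """The 15-day 2013-like episode (5-day shoulders)."""
        return cls(kind="hw2013", n_days=25, plateau_days=15,
                   peak_tmax=40.5, shoulder_tmax=32.0, seed=seed)


def _plateau_curve(spec: FixtureSpec) -> np.ndarray:
    """Deterministic within-plateau Tmax values (before jitter)."""
    m = spec.plateau_days
    if spec.kind == "hw2013":
        return np.array(_HW2013_PLATEAU, dtype=float)
    # generic single-crest profile between 36.2 °C and the peak
    base = 36.2
    x = np.linspace(0.0, np.pi, m)
    return base + (spec.peak_tmax - base) * np.sin(x) ** 1.5 if m > 1 else np.array(
        [spec.peak_tmax]
    )


def gen_heatwave_series(spec: FixtureSpec) -> TemperatureSeries:
    """Generate a rise–plateau–fall daily Tmax fixture.

    Shoulder days sit at ``shoulder_tmax``; the plateau is a contiguous
    block of exactly ``plateau_days`` days above 35 °C whose maximum equals
    ``peak_tmax``.  Jitter is uniform in ±0.3 °C, seeded, and clipped so no
    day crosses the 35 °C threshold and the plateau maximum stays exact.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.plateau_days
    n_shoulder = spec.n_days - m
    lead = n_shoulder // 2
    tail = n_shoulder - lead

    shoulders_lead = np.full(lead, spec.shoulder_tmax)
    shoulders_tail = np.full(tail, spec.shoulder_tmax)
    plateau = _plateau_curve(spec) if m > 0 else np.empty(0)

    tmax = np.concatenate([shoulders_lead, plateau, shoulders_tail])
    jitter = rng.uniform(-0.3, 0.3, size=spec.n_days)
    tmax = tmax + jitter
    # threshold preservation: shoulders stay below 35, plateau stays above
    if lead:
        tmax[:lead] = np.minimum(tmax[:lead], 34.5)
    if tail:
        tmax[-tail:] = np.minimum(tmax[-tail:], 34.5)
    if m > 0:
        lo, hi = lead, lead + m
        tmax[lo:hi] = np.clip(tmax[lo:hi], 35.05, spec.peak_tmax - 0.05)
        peak_at = lo + int(np.argmax(plateau))
        tmax[peak_at] = spec.peak_tmax

    if spec.kind == "hw2003":
        start = _HW2003_PLATEAU_START - dt.timedelta(days=lead)
    elif spec.kind == "hw2013":
        start = _HW2013_PLATEAU_START - dt.timedelta(days=lead)
    else:
        start = dt.date(2013, 7, 1)
    records = [
        DailyClimateRecord(date=start + dt.timedelta(days=i), tmax=float(t))
        for i, t in enumerate(tmax)
    ]
    return TemperatureSeries(records)


def gen_constant_series(
    tmax: float, n_days: int, start: dt.date = dt.date(2008, 6, 1)
) -> TemperatureSeries:
    """A flat daily series at one temperature (long-run rate estimation)."""
    if n_days < 1:
        raise InputError("n_days must be at least 1")
    return TemperatureSeries(
        DailyClimateRecord(date=start + dt.timedelta(days=i), tmax=float(tmax))
        for i in range(n_days)
    )


#: Documented fixture profiles (yearbook-like constants, not real records).
_PROFILES = {
    "y2013": CityProfile(
        pop_under14=2.41e6,     # 10% of 24.1 million
        pop_15_64=18.075e6,     # 75%
        pop_over65=3.615e6,     # 15%
        hospitals=338.0,
        beds=1.15e5,
        staff=1.9e5,
        ac_rate=0.95,
        income=3600.0,          # currency/month per capita
        allowance=790.0,        # minimum living allowance, 2013
        insurance=0.85,
    ),
    "y2003": CityProfile(
        pop_under14=2.41e6,
        pop_15_64=18.075e6,
        pop_over65=3.615e6,
        hospitals=338.0,
        beds=8.0e4,
        staff=1.2e5,
        ac_rate=0.70,
        income=1240.0,
        allowance=560.0,
        insurance=0.60,
    ),
}


def gen_city_profile(year_like: str = "y2013") -> CityProfile:
    """A fixed, documented city profile fixture (``y2003`` or ``y2013``).

    The 2013-like profile carries the printed anchors — total population
    24.1 million, allowance 790/month; the 2003-like profile differs only in
    beds, staff, ac_rate, income, allowance and insurance (lower capacity).
    """
    try:
        return _PROFILES[year_like]
    except KeyError:
        raise InputError(
            f"unknown profile {year_like!r}; expected one of {sorted(_PROFILES)}"
        ) from None


def gen_baseline_mortality(
    series: TemperatureSeries, population: float, seed: int = 0
) -> pd.Series:
    """Poisson daily death counts from the two-level background rates.

    λ_t = population/1e7 × (114 if tmax_t ≤ 35 °C else 124).  Returns an
    integer series indexed by date; deterministic given the seed.
    """
    if population <= 0:
        raise InputError("population must be positive")
    rng = np.random.default_rng(seed)
    tmax = series.tmax
    lam = population / 1.0e7 * np.where(tmax <= 35.0, COOL_DEATH_RATE, HOT_DEATH_RATE)
    counts = rng.poisson(lam)
    return pd.Series(counts, index=pd.Index(series.dates, name="date"), name="deaths")


def gen_observed_deaths(
    series: TemperatureSeries,
    profile: CityProfile,
    true_params: ModelParameters,
    seed: int = 0,
    noise: str = "poisson",
    initial_ap: float = 0.0,
) -> pd.Series:
    """Forward-simulated daily death counts for parameter-recovery studies.

    Runs the baseline scenario with ``true_params``; the expected total
    deaths (heat-attributable flow + cool-day background) become either the
    rounded series itself (``noise="none"``) or Poisson draws around it
    (``noise="poisson"``).
    """
    if noise not in ("none", "poisson"):
        raise InputError(f"noise must be 'none' or 'poisson', got {noise!r}")
    result = simulate(series, profile, true_params, Scenario(), initial_ap=initial_ap)
    lam = result.total_deaths
    if noise == "poisson":
        counts = np.random.default_rng(seed).poisson(lam)
    else:
        counts = np.rint(lam).astype(int)
    return pd.Series(counts, index=pd.Index(series.dates, name="date"), name="deaths")
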