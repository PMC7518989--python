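"""Stock–flow engine: daily integration, scenarios and trajectory comparison.

One stock — the affected population AP — is integrated by explicit Euler at
Δt = 1 day:

    AP(t+1) = AP(t) + APF(t) − TPF(t) − D(t)

with inflow APF from the exposure–response channel, treated outflow
TPF = AP · AF, and death outflow D = AP · μ · CF.  When the outflow demand
exceeds stock plus inflow, both outflows are scaled proportionally so the
stock never goes negative and the TPF:death ratio is preserved.

Reported daily deaths are the model's heat-attributable death flow plus a
constant background rate, so trajectories are directly comparable with
observed all-cause daily death curves.

Scenarios are declarative: a temperature offset (marginal-warming
experiments), hospital-bed readiness (beds × (1 + fraction) from the
warning day), or a minimum-living-allowance increase (allowance ×
multiplier from the warning day).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import adaptation as ad
from . import exposure as ex
from .climate import (
    HeatWaveEpisode,
    TableFunction,
    TemperatureSeries,
    apply_offset,
    hot_day_counts,
)
from .errors import ComputationError, InputError

__all__ = [
    "ModelParameters",
    "ModelState",
    "Scenario",
    "SimulationResult",
    "step",
    "simulate",
    "compare",
    "episode_table",
    "peak_reduction_days",
]

logger = logging.getLogger(__name__)


def _neutral_table() -> TableFunction:
    return TableFunction([(0.0, 1.0), (50.0, 1.0)])


@dataclass(frozen=True)
class ModelParameters:
    """Complete coefficient set of one model configuration.

    ``background_rate`` is the non-heat death rate in persons per ten
    million per day added to the heat-attributable flow at reporting time.
    ``bed_capacity`` is the treatment throughput of one hospital bed
    (persons/day/bed): the treated outflow is capped at
    ``beds × bed_capacity``, so the health system saturates during the worst
    days of a severe wave and readying extra beds relieves exactly that
    bottleneck; the default ``inf`` disables the cap.
    ``allowance_elasticity`` routes the minimum living allowance into the
    exposure side: the affected inflow is multiplied by
    ``(allowance / reference allowance) ** (-elasticity)``, so raising the
    income floor shrinks the vulnerable population feeding the stock (0
    disables the channel).
    ``elderly_vulnerability`` scales the exposed population with the over-65
    share: exposed = total · (1 + v · share_over65); the default 0 keeps the
    whole population exposed.  ``cf_on_apf`` optionally routes the climate
    factor into the affected inflow as well (sensitivity analysis; default
    off).  ``tpf_delay`` applies a one-day delay to the treated outflow
    (default off).
    """

    exposure: ex.ExposureParameters
    adaptation: ad.AdaptationParameters
    ma_table: TableFunction = field(default_factory=_neutral_table)
    hdaf_table: TableFunction = field(default_factory=_neutral_table)
    background_rate: float = 114.0
    bed_capacity: float = float("inf")
    allowance_elasticity: float = 0.0
    elderly_vulnerability: float = 0.0
    hot_threshold: float = 35.0
    cf_on_apf: bool = False
    tpf_delay: bool = False

    def exposed_population(self, profile: ad.CityProfile) -> float:
        total = profile.total_population
        return total * (1.0 + self.elderly_vulnerability * profile.share_over65)

    def fingerprint(self) -> str:
        """Stable short identifier of the parameter values."""
        text = repr(self).encode()
        return hashlib.sha1(text).hexdigest()[:12]


@dataclass(frozen=True)
class ModelState:
    """Engine state after ``day`` completed steps."""

    day: int = 0
    ap: float = 0.0
    cum_treated: float = 0.0
    cum_deaths: float = 0.0

    def __post_init__(self) -> None:
        if self.ap < 0 or self.cum_treated < 0 or self.cum_deaths < 0:
            raise InputError("state fields must be non-negative")


@dataclass(frozen=True)
class Scenario:
    """Declarative description of one simulation experiment."""

    kind: str = "baseline"
    delta_temp: float = 0.0
    bed_fraction: float = 0.20
    allowance_multiplier: float = 1.20
    warning_day: int = 0

    KINDS = ("baseline", "temp_offset", "bed_readiness", "allowance_increase")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InputError(f"unknown scenario kind {self.kind!r}")
        if self.bed_fraction < 0:
            raise InputError("bed_fraction must be non-negative")
        if self.allowance_multiplier <= 0:
            raise InputError("allowance_multiplier must be positive")
        if self.warning_day < 0:
            raise InputError("warning_day must be non-negative")


@dataclass(frozen=True)
class SimulationResult:
    """Per-day trajectories of one scenario run.

    ``deaths`` is the heat-attributable death flow; ``total_deaths`` adds
    the constant background.  All arrays share the series length.
    """

    apf: np.ndarray
    tpf: np.ndarray
    deaths: np.ndarray
    ap: np.ndarray
    tmax: np.ndarray
    hot_days: np.ndarray
    background: float
    scenario: Scenario
    fingerprint: str
    initial_ap: float

    def __len__(self) -> int:
        return len(self.deaths)

    @property
    def total_deaths(self) -> np.ndarray:
        return self.deaths + self.background

    @property
    def final_ap(self) -> float:
        return float(self.ap[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; ``day`` is 1-based, ``deaths`` is the total flow."""
        return pd.DataFrame(
            {
                "day": np.arange(1, len(self) + 1),
                "tmax": self.tmax,
                "hot_days": self.hot_days,
                "apf": self.apf,
                "tpf": self.tpf,
                "deaths": self.total_deaths,
                "ap": self.ap,
            }
        )


def step(
    state: ModelState,
    tmax: float,
    hot_days: float,
    profile: ad.CityProfile,
    params: ModelParameters,
) -> tuple[ModelState, dict[str, float]]:
    """Advance the stock–flow system by one day.

    Returns the new state and a record of the day's flows.  Outflows are
    proportionally rescaled if their demand exceeds stock + inflow, so the
    affected-people stock stays non-negative.
    """
    pop = params.exposed_population(profile)
    cf = ex.climate_factor(tmax, hot_days, params.ma_table, params.hdaf_table)
    apf = ex.affected_flow(tmax, pop, params.exposure)
    if params.cf_on_apf:
        apf *= cf
    if params.allowance_elasticity:
        # higher income floor -> smaller vulnerable population exposed
        ratio = profile.allowance / params.adaptation.reference_profile.allowance
        apf *= ratio ** (-params.allowance_elasticity)
    ec = ad.economic_factor(profile, params.adaptation)
    hf = ad.health_factor(profile, params.adaptation)
    gf = ad.governance_factor(profile, params.adaptation)
    af = ad.adaptation_factor(ec, hf, gf, params.adaptation)
    tpf = ad.treated_flow(state.ap, af)
    tpf = min(tpf, profile.beds * params.bed_capacity)  # throughput bottleneck
    d = ex.death_flow(state.ap, cf, params.exposure.mu)

    available = state.ap + apf
    demand = tpf + d
    if demand > available and demand > 0.0:
        scale = available / demand
        tpf *= scale
        d *= scale

    new_ap = state.ap + apf - tpf - d
    if new_ap < 0.0:  # numerical guard; proportional scaling already applied
        new_ap = 0.0
    flows = {
        "apf": apf, "tpf": tpf, "deaths": d,
        "af": af, "cf": cf, "ec": ec, "hf": hf, "gf": gf,
    }
    for name, value in flows.items():
        if not np.isfinite(value) or value < 0.0:
            raise ComputationError(
                f"day {state.day}: invalid {name}={value!r} "
                f"(tmax={tmax}, ap={state.ap})"
            )
    new_state = ModelState(
        day=state.day + 1,
        ap=new_ap,
        cum_treated=state.cum_treated + tpf,
        cum_deaths=state.cum_deaths + d,
    )
    return new_state, flows


def _scenario_profile(
    profile: ad.CityProfile, scenario: Scenario, day: int
) -> ad.CityProfile:
    if day < scenario.warning_day:
        return profile
    if scenario.kind == "bed_readiness":
        return profile.replace(beds=profile.beds * (1.0 + scenario.bed_fraction))
    if scenario.kind == "allowance_increase":
        return profile.replace(
            allowance=profile.allowance * scenario.allowance_multiplier
        )
    return profile


def simulate(
    series: TemperatureSeries,
    profile: ad.CityProfile,
    params: ModelParameters,
    scenario: Scenario | None = None,
    initial_ap: float = 0.0,
) -> SimulationResult:
    """Run the stock–flow model over a daily series under one scenario.

    The scenario transformation is applied first (temperature offset to the
    series, or indicator change to the profile from ``warning_day`` on);
    hot-day counters are computed on the transformed series.  Deterministic
    given its inputs.
    """
    scenario = scenario or Scenario()
    if initial_ap < 0:
        raise InputError("initial_ap must be non-negative")
    if scenario.kind == "temp_offset":
        series = apply_offset(series, scenario.delta_temp)
    tmax = series.tmax
    hot = hot_day_counts(series, params.hot_threshold).astype(float)

    n = len(series)
    apf = np.empty(n)
    tpf = np.empty(n)
    deaths = np.empty(n)
    ap = np.empty(n)
    state = ModelState(day=0, ap=initial_ap)
    delayed_tpf: float | None = None
    for t in range(n):
        prof_t = _scenario_profile(profile, scenario, t)
        new_state, flows = step(state, tmax[t], hot[t], prof_t, params)
        if params.tpf_delay:
            # one-day treatment delay: today's realised outflow is yesterday's
            # demand, bounded by what the stock can supply today
            demand = delayed_tpf if delayed_tpf is not None else 0.0
            delayed_tpf = flows["tpf"]
            realised = min(demand, state.ap + flows["apf"] - flows["deaths"])
            realised = max(realised, 0.0)
            new_state = ModelState(
                day=state.day + 1,
                ap=state.ap + flows["apf"] - realised - flows["deaths"],
                cum_treated=state.cum_treated + realised,
                cum_deaths=state.cum_deaths + flows["deaths"],
            )
            flows["tpf"] = realised
        apf[t] = flows["apf"]
        tpf[t] = flows["tpf"]
        deaths[t] = flows["deaths"]
        ap[t] = new_state.ap
        logger.debug(
            "day=%d tmax=%.2f hot=%d apf=%.3f tpf=%.3f deaths=%.3f ap=%.3f",
            t, tmax[t], int(hot[t]), apf[t], tpf[t], deaths[t], ap[t],
        )
        state = new_state

    background = (
        profile.total_population / ex.TEN_MILLION * params.background_rate
    )
    result = SimulationResult(
        apf=apf, tpf=tpf, deaths=deaths, ap=ap, tmax=tmax, hot_days=hot.astype(int),
        background=background, scenario=scenario,
        fingerprint=params.fingerprint(), initial_ap=initial_ap,
    )
    logger.info(
        "scenario=%s days=%d cum_heat_deaths=%.1f final_ap=%.1f",
        scenario.kind, n, float(deaths.sum()), result.final_ap,
    )
    return result


def compare(baseline: SimulationResult, alt: SimulationResult) -> pd.DataFrame:
    """Per-day reduction of an alternative run relative to the baseline.

    Works on total daily deaths (heat-attributable + background).  Columns:
    1-based ``day``, both death series, absolute ``reduction`` and
    ``pct_reduction`` (NaN where the baseline is zero).
    """
    if len(baseline) != len(alt):
        raise InputError(
            f"trajectory lengths differ: {len(baseline)} vs {len(alt)}"
        )
    base = baseline.total_deaths
    other = alt.total_deaths
    reduction = base - other
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(base != 0.0, 100.0 * reduction / base, np.nan)
    return pd.DataFrame(
        {
            "day": np.arange(1, len(baseline) + 1),
            "baseline_deaths": base,
            "scenario_deaths": other,
            "reduction": reduction,
            "pct_reduction": pct,
        }
    )


def episode_table(table: pd.DataFrame, episode: HeatWaveEpisode) -> pd.DataFrame:
    """Slice a comparison table to one episode, renumbering day 1..duration."""
    out = table.iloc[episode.start_index : episode.end_index + 1].reset_index(drop=True)
    out = out.assign(day=np.arange(1, len(out) + 1))
    return out


def peak_reduction_days(table: pd.DataFrame, n: int = 2) -> list[int]:
    """The ``n`` days (1-based) with largest percentage reduction, descending.

    Ties resolve to the earliest day.
    """
    ordered = table.sort_values(
        ["pct_reduction", "day"], ascending=[False, True], kind="stable"
    )
    return [int(d) for d in ordered["day"].head(n)]
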