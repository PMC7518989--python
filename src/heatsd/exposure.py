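"""Exposure–response: temperature to affected-people inflow and climate factor.

Morbidity and mortality respond to daily maximum temperature above distinct
thresholds (defaults 36.6 °C for morbidity and 37.6 °C for mortality, the
empirical thresholds estimated for Shanghai/Ningbo summer data).  The
affected-people inflow (APF) is linear in the °C exceedance above the
morbidity threshold on top of a baseline inflow; the climate severity factor
CF = MA(tmax) · HDAF(hot_days) multiplies the death outflow, with MA equal to
1 below the mortality threshold by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .climate import TableFunction
from .errors import InputError

__all__ = ["ExposureParameters", "affected_flow", "climate_factor", "death_flow"]

TEN_MILLION = 1.0e7


@dataclass(frozen=True)
class ExposureParameters:
    """Thresholds and rates of the temperature → health-burden channel.

    Attributes
    ----------
    t_morb : float
        Morbidity threshold (°C); excess affected cases accrue above it.
    t_mort : float
        Mortality threshold (°C); the MA table should equal 1 below it.
    beta_morb : float
        Excess affected persons per ten million population per °C of
        exceedance above ``t_morb``, per day.
    r_base : float
        Baseline (non-heat) affected inflow, persons per ten million per day.
    mu : float
        Baseline per-day case-fatality fraction of the affected-people stock.
    """

    t_morb: float = 36.6
    t_mort: float = 37.6
    beta_morb: float = 0.0
    r_base: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.t_mort <= self.t_morb:
            raise InputError(
                f"t_mort ({self.t_mort}) must exceed t_morb ({self.t_morb})"
            )
        if self.beta_morb < 0 or self.r_base < 0:
            raise InputError("beta_morb and r_base must be non-negative")
        if not 0.0 <= self.mu <= 1.0:
            raise InputError(f"mu must lie in [0, 1], got {self.mu}")


def affected_flow(tmax: float, population: float, params: ExposureParameters) -> float:
    """Daily inflow into the affected-people stock (persons/day).

    ``(population / 1e7) * (r_base + beta_morb * max(0, tmax - t_morb))`` —
    zero excess at or below the morbidity threshold, linear above it.
    """
    if population <= 0:
        raise InputError(f"population must be positive, got {population}")
    exceedance = max(0.0, tmax - params.t_morb)
    return (population / TEN_MILLION) * (params.r_base + params.beta_morb * exceedance)


def climate_factor(
    tmax: float,
    hot_days: float,
    ma_table: TableFunction,
    hdaf_table: TableFunction,
) -> float:
    """Climate severity multiplier CF = MA(tmax) · HDAF(hot_days).

    MA amplifies mortality with the day's maximum temperature, HDAF with the
    number of days the heat wave has already lasted; both are empirical
    piecewise-linear table functions.
    """
    if hot_days < 0:
        raise InputError(f"hot_days must be non-negative, got {hot_days}")
    return ma_table(tmax) * hdaf_table(hot_days)


def death_flow(ap: float, cf: float, mu: float) -> float:
    """Daily heat-attributable death outflow ``ap * mu * cf`` (persons/day).

    The engine step additionally caps total outflows at stock + inflow; this
    function is the uncapped demand.
    """
    if ap < 0 or cf < 0 or mu < 0:
        raise InputError("ap, cf and mu must be non-negative")
    return ap * mu * cf
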