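"""Least-squares calibration and peak-based validation.

The free coefficients (typically the morbidity slope ``beta_morb``, the
case-fatality fraction ``mu``, the baseline treatment fraction ``af0`` and a
few table-function heights) are fitted by minimizing the squared error
between simulated and observed total daily deaths.  The objective is cheap
but non-smooth (clamps, caps), so the default optimizer is bounded
Nelder–Mead restarted from several seeded random initial points; any
bounded derivative-free method would do.

Validation follows the peak criteria used for this class of model: root
mean squared error, relative peak-value error, and the peak lag in days
(argmax of simulated minus argmax of observed, ties broken by the earliest
day).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .adaptation import CityProfile
from .climate import TemperatureSeries
from .engine import ModelParameters, Scenario, simulate
from .errors import ConfigurationError, InputError

__all__ = [
    "CalibrationSpec",
    "CalibrationResult",
    "calibrate",
    "validate",
    "set_parameter",
    "get_parameter",
]

_TABLE_RE = re.compile(r"^(ma|hdaf)\.(\d+)$")


def set_parameter(params: ModelParameters, name: str, value: float) -> ModelParameters:
    """Return a copy of ``params`` with one named coefficient replaced.

    Recognised names: exposure fields (``beta_morb``, ``mu``, ``r_base``,
    ``t_morb``, ``t_mort``), ``af0``, ``af_cap``, adaptation weights as
    ``w_<indicator>`` (e.g. ``w_beds``), ``background_rate``,
    ``elderly_vulnerability``, and table heights ``ma.<i>`` / ``hdaf.<i>``
    (the y-value of breakpoint i).
    """
    exposure_fields = {f.name for f in dataclasses.fields(params.exposure)}
    if name in exposure_fields:
        return dataclasses.replace(
            params, exposure=dataclasses.replace(params.exposure, **{name: value})
        )
    if name in ("af0", "af_cap"):
        return dataclasses.replace(
            params, adaptation=dataclasses.replace(params.adaptation, **{name: value})
        )
    if name.startswith("w_"):
        indicator = name[2:]
        weights = dict(params.adaptation.weights)
        weights[indicator] = value
        return dataclasses.replace(
            params, adaptation=dataclasses.replace(params.adaptation, weights=weights)
        )
    if name in ("background_rate", "bed_capacity", "allowance_elasticity",
                "elderly_vulnerability"):
        return dataclasses.replace(params, **{name: value})
    m = _TABLE_RE.match(name)
    if m:
        table_attr = "ma_table" if m.group(1) == "ma" else "hdaf_table"
        table = getattr(params, table_attr)
        idx = int(m.group(2))
        if idx >= len(table.breakpoints):
            raise ConfigurationError(f"{name}: breakpoint index out of range")
        return dataclasses.replace(params, **{table_attr: table.with_y(idx, value)})
    raise ConfigurationError(f"unknown parameter name {name!r}")


def get_parameter(params: ModelParameters, name: str) -> float:
    """Read a named coefficient (same naming scheme as :func:`set_parameter`)."""
    exposure_fields = {f.name for f in dataclasses.fields(params.exposure)}
    if name in exposure_fields:
        return getattr(params.exposure, name)
    if name in ("af0", "af_cap"):
        return getattr(params.adaptation, name)
    if name.startswith("w_"):
        return params.adaptation.weight(name[2:])
    if name in ("background_rate", "bed_capacity", "allowance_elasticity",
                "elderly_vulnerability"):
        return getattr(params, name)
    m = _TABLE_RE.match(name)
    if m:
        table_attr = "ma_table" if m.group(1) == "ma" else "hdaf_table"
        return getattr(params, table_attr).breakpoints[int(m.group(2))][1]
    raise ConfigurationError(f"unknown parameter name {name!r}")


@dataclass(frozen=True)
class CalibrationSpec:
    """Which coefficients are free, their bounds, and optimizer settings."""

    free: dict[str, tuple[float, float]] = field(default_factory=dict)
    objective: str = "sse"
    max_iter: int = 2000
    tol: float = 1.0e-10
    restarts: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("sse", "rmse"):
            raise ConfigurationError("objective must be 'sse' or 'rmse'")
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ConfigurationError(
                    f"free parameter {name!r} needs finite bounds with lower < upper"
                )
        if self.restarts < 1:
            raise ConfigurationError("restarts must be at least 1")


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of one calibration run."""

    fitted: dict[str, float]
    params: ModelParameters
    objective_value: float
    residuals: np.ndarray
    converged: bool
    n_evaluations: int
    start_objectives: tuple[float, ...]


def _objective_value(kind: str, residuals: np.ndarray) -> float:
    sse = float(np.sum(residuals**2))
    return sse if kind == "sse" else float(np.sqrt(sse / len(residuals)))


def calibrate(
    observed_deaths: pd.Series,
    series: TemperatureSeries,
    profile: CityProfile,
    spec: CalibrationSpec,
    params0: ModelParameters,
    initial_ap: float = 0.0,
) -> CalibrationResult:
    """Fit the free coefficients to an observed daily death series.

    ``observed_deaths`` must be indexed by the same dates as ``series``.
    The best of ``spec.restarts`` bounded Nelder–Mead runs (random initial
    points drawn from a generator seeded with ``spec.seed``; the first start
    at the bound midpoints) is returned.  Deterministic given the seed.
    """
    dates = series.dates
    if list(observed_deaths.index) != dates:
        raise InputError("observed deaths are not aligned with the climate series")
    obs = np.asarray(observed_deaths, dtype=float)

    names = list(spec.free)
    n_eval = 0

    def run(theta: Sequence[float]) -> np.ndarray:
        params = params0
        for name, value in zip(names, theta):
            params = set_parameter(params, name, float(value))
        sim = simulate(series, profile, params, Scenario(), initial_ap=initial_ap)
        return sim.total_deaths - obs

    def objective(theta: Sequence[float]) -> float:
        nonlocal n_eval
        n_eval += 1
        return _objective_value(spec.objective, run(theta))

    if not names:
        residuals = run(())
        value = _objective_value(spec.objective, residuals)
        return CalibrationResult(
            fitted={}, params=params0, objective_value=value,
            residuals=residuals, converged=True, n_evaluations=1,
            start_objectives=(value,),
        )

    lo = np.array([spec.free[n][0] for n in names])
    hi = np.array([spec.free[n][1] for n in names])
    rng = np.random.default_rng(spec.seed)
    starts = [0.5 * (lo + hi)]
    starts += [rng.uniform(lo, hi) for _ in range(spec.restarts - 1)]

    best = None
    start_objectives = []
    any_converged = False
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={
                "maxiter": spec.max_iter,
                "xatol": spec.tol ** 0.5,
                "fatol": spec.tol,
            },
        )
        start_objectives.append(float(res.fun))
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res

    fitted_theta = np.clip(best.x, lo, hi)
    fitted = {n: float(v) for n, v in zip(names, fitted_theta)}
    params = params0
    for name, value in fitted.items():
        params = set_parameter(params, name, value)
    residuals = run(fitted_theta)
    return CalibrationResult(
        fitted=fitted,
        params=params,
        objective_value=_objective_value(spec.objective, residuals),
        residuals=residuals,
        converged=any_converged,
        n_evaluations=n_eval,
        start_objectives=tuple(start_objectives),
    )


def validate(observed_deaths, simulated_deaths) -> dict[str, float]:
    """Peak-based goodness-of-fit report.

    Returns ``rmse``, ``peak_value_error`` (relative, |max(sim) − max(obs)| /
    max(obs)) and ``peak_lag`` (argmax(sim) − argmax(obs) in days; the
    earliest day wins ties).
    """
    obs = np.asarray(observed_deaths, dtype=float)
    sim = np.asarray(simulated_deaths, dtype=float)
    if obs.size == 0 or sim.size == 0:
        raise InputError("series must be non-empty")
    if obs.shape != sim.shape:
        raise InputError("observed and simulated series must have equal length")
    rmse = float(np.sqrt(np.mean((sim - obs) ** 2)))
    peak_obs = float(np.max(obs))
    peak_err = abs(float(np.max(sim)) - peak_obs) / peak_obs if peak_obs else np.nan
    lag = int(np.argmax(sim)) - int(np.argmax(obs))  # np.argmax takes the first max
    return {"rmse": rmse, "peak_value_error": peak_err, "peak_lag": lag}
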