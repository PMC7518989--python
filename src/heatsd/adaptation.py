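"""Adaptation capacity: economic, health-system and governance factors.

The treated-people outflow is TPF = AP · AF, where the adaptation factor
AF = af0 · EC · HF · GF composes three dimensionless capacity indices:

* EC — economic factor: air-conditioning usage rate and personal income;
* HF — health factor: medical staff, hospital beds, number of hospitals;
* GF — governance factor: minimum living allowance and insurance coverage.

Each index is a weighted power law (Cobb–Douglas) of indicator/reference
ratios, so it equals exactly 1 at the reference city profile, is monotone in
every indicator with positive weight, and is dimensionless.  ``af0`` is the
calibrated baseline daily treatment fraction at the reference profile;
floors and caps keep AF a valid fraction in [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ConfigurationError, InputError

__all__ = [
    "CityProfile",
    "AdaptationParameters",
    "economic_factor",
    "health_factor",
    "governance_factor",
    "adaptation_factor",
    "treated_flow",
]


@dataclass(frozen=True)
class CityProfile:
    """Socioeconomic / health-system indicators of one city-year.

    Units: populations and counts in persons; ``ac_rate`` and ``insurance``
    as fractions in [0, 1]; ``income`` and ``allowance`` in currency per
    month per capita.
    """

    pop_under14: float
    pop_15_64: float
    pop_over65: float
    hospitals: float
    beds: float
    staff: float
    ac_rate: float
    income: float
    allowance: float
    insurance: float

    def __post_init__(self) -> None:
        for name in (
            "pop_under14", "pop_15_64", "pop_over65",
            "hospitals", "beds", "staff", "income", "allowance",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        for name in ("ac_rate", "insurance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1], got {v}")

    @property
    def total_population(self) -> float:
        return self.pop_under14 + self.pop_15_64 + self.pop_over65

    @property
    def share_over65(self) -> float:
        return self.pop_over65 / self.total_population

    def replace(self, **changes: float) -> "CityProfile":
        """Copy with some indicators changed (used by mitigation scenarios)."""
        return dataclasses.replace(self, **changes)


#: Indicator groups entering each factor.
_ECONOMIC_FIELDS = ("ac_rate", "income")
_HEALTH_FIELDS = ("staff", "beds", "hospitals")
_GOVERNANCE_FIELDS = ("allowance", "insurance")


def _default_weights() -> dict[str, float]:
    return {
        "ac_rate": 0.5, "income": 0.5,
        "staff": 0.3, "beds": 0.4, "hospitals": 0.3,
        "allowance": 0.5, "insurance": 0.5,
    }


@dataclass(frozen=True)
class AdaptationParameters:
    """Reference profile, per-indicator weights and AF scaling.

    ``weights`` maps indicator name → Cobb–Douglas exponent in [0, 1].
    ``af0`` is the daily treated fraction when the city matches the
    reference profile exactly.  ``factor_floor``/``factor_cap`` clamp each
    of EC/HF/GF away from 0 and infinity; ``af_cap`` bounds the composed
    daily fraction.
    """

    reference_profile: CityProfile
    weights: dict[str, float] = field(default_factory=_default_weights)
    af0: float = 0.1
    af_cap: float = 0.95
    factor_floor: float = 1.0e-3
    factor_cap: float = 10.0

    def __post_init__(self) -> None:
        known = set(_ECONOMIC_FIELDS) | set(_HEALTH_FIELDS) | set(_GOVERNANCE_FIELDS)
        for name, w in self.weights.items():
            if name not in known:
                raise ConfigurationError(f"unknown adaptation weight {name!r}")
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError(f"weight {name!r} must lie in [0, 1], got {w}")
        if not 0.0 < self.af_cap <= 1.0:
            raise ConfigurationError(f"af_cap must lie in (0, 1], got {self.af_cap}")
        if not 0.0 <= self.af0 <= 1.0:
            raise ConfigurationError(f"af0 must lie in [0, 1], got {self.af0}")
        for name in known:
            if self.weights.get(name, 0.0) > 0 and getattr(self.reference_profile, name) <= 0:
                raise ConfigurationError(
                    f"reference {name} must be strictly positive (it is a denominator)"
                )

    def weight(self, name: str) -> float:
        return self.weights.get(name, 0.0)


def _powerlaw(profile: CityProfile, params: AdaptationParameters, fields: tuple[str, ...]) -> float:
    """Π (indicator / reference)^weight over a field group, clamped."""
    value = 1.0
    for name in fields:
        w = params.weight(name)
        if w == 0.0:
            continue
        ref = getattr(params.reference_profile, name)
        if ref <= 0:
            raise ConfigurationError(f"reference {name} must be positive")
        ratio = getattr(profile, name) / ref
        ratio = max(ratio, params.factor_floor)  # degenerate-input clamp, never 0
        value *= ratio**w
    return min(max(value, params.factor_floor), params.factor_cap)


def economic_factor(profile: CityProfile, params: AdaptationParameters) -> float:
    """EC: air-conditioning usage and personal income relative to reference."""
    return _powerlaw(profile, params, _ECONOMIC_FIELDS)


def health_factor(profile: CityProfile, params: AdaptationParameters) -> float:
    """HF: medical staff, hospital beds and hospitals relative to reference."""
    return _powerlaw(profile, params, _HEALTH_FIELDS)


def governance_factor(profile: CityProfile, params: AdaptationParameters) -> float:
    """GF: minimum living allowance and insurance coverage relative to reference."""
    return _powerlaw(profile, params, _GOVERNANCE_FIELDS)


def adaptation_factor(
    ec: float, hf: float, gf: float, params: AdaptationParameters
) -> float:
    """AF = min(af_cap, af0 · EC · HF · GF), a daily fraction in [0, 1]."""
    if ec < 0 or hf < 0 or gf < 0:
        raise InputError("factors must be non-negative")
    return min(params.af_cap, params.af0 * ec * hf * gf)


def treated_flow(ap: float, af: float) -> float:
    """Treated-people outflow TPF = AP · AF (persons/day)."""
    if ap < 0:
        raise InputError(f"ap must be non-negative, got {ap}")
    if not 0.0 <= af <= 1.0:
        raise InputError(f"af must lie in [0, 1], got {af}")
    return ap * af
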