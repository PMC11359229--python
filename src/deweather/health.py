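"""Log-linear health impact assessment of concentration reductions.

The classic chain: a concentration change Δc (µg/m³, magnitude of the
reduction) maps to a relative risk RR = exp(β·Δc) under a log-linear
concentration-response function, to an attributable fraction
AF = (RR − 1)/RR = 1 − exp(−β·Δc), and to avoided deaths
ΔMort = AF · (daily cause-specific deaths) · (lockdown days), where the
daily deaths may equivalently be supplied as a per-capita rate y0 times a
population.

Default coefficients β per µg/m³ NO2: 0.009 (non-accidental), 0.009
(cardiovascular), 0.012 (respiratory).  β is applied per µg/m³ because the
risk model applies it directly to Δc; if your β is quoted per 10 µg/m³,
divide by 10 before use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "CAUSES",
    "DEFAULT_BETA",
    "CauseParams",
    "HealthBurden",
    "relative_risk",
    "attributable_fraction",
    "avoided_mortality",
    "cohort_burden",
]

CAUSES = ("non_accidental", "cardiovascular", "respiratory")

DEFAULT_BETA = {"non_accidental": 0.009, "cardiovascular": 0.009, "respiratory": 0.012}

#: lockdown length in days under the default period scheme (23 Jan - 18 Mar 2020)
DEFAULT_N_DAYS = 56


@dataclass(frozen=True)
class CauseParams:
    """Concentration-response and baseline-mortality inputs for one cause.

    Exactly one parameterisation of the baseline must be given: either
    ``daily_deaths`` (deaths/day in the city) or the pair ``y0`` (daily
    per-capita mortality rate) and ``pop`` (persons); the two are equivalent
    via daily_deaths = y0 · pop.
    """

    cause: str
    beta: float
    daily_deaths: float | None = None
    y0: float | None = None
    pop: float | None = None

    def __post_init__(self) -> None:
        if self.cause not in CAUSES:
            raise ValidationError(f"cause: unknown cause '{self.cause}'")
        if self.beta <= 0:
            raise ValidationError("beta: must be > 0")
        rate_given = self.y0 is not None or self.pop is not None
        if self.daily_deaths is not None:
            if rate_given:
                raise ValidationError(
                    "supply either daily_deaths or (y0, pop), not both"
                )
            if self.daily_deaths < 0:
                raise ValidationError("daily_deaths: must be >= 0")
        else:
            if self.y0 is None or self.pop is None:
                raise ValidationError("supply daily_deaths, or both y0 and pop")
            if self.y0 < 0 or self.pop < 0:
                raise ValidationError("y0 and pop must be >= 0")

    @property
    def deaths_per_day(self) -> float:
        if self.daily_deaths is not None:
            return self.daily_deaths
        return self.y0 * self.pop  # type: ignore[operator]


@dataclass(frozen=True)
class HealthBurden:
    """Avoided-mortality result for one (city, cause)."""

    city_id: str
    cause: str
    delta_c: float  # µg/m³ reduction magnitude
    rr: float
    af: float
    avoided_deaths: float


def relative_risk(beta: float, delta_c: float) -> float:
    """RR = exp(β·Δc).  Δc is the magnitude of the reduction (>= 0)."""
    if delta_c < 0:
        raise ValidationError("delta_c: pass the reduction magnitude (>= 0)")
    return math.exp(beta * delta_c)


def attributable_fraction(beta: float, delta_c: float) -> float:
    """AF = 1 − exp(−β·Δc), identically (RR − 1)/RR; in [0, 1)."""
    if delta_c < 0:
        raise ValidationError("delta_c: pass the reduction magnitude (>= 0)")
    return -math.expm1(-beta * delta_c)


def avoided_mortality(params: CauseParams, delta_c: float, n_days: int = DEFAULT_N_DAYS) -> float:
    """ΔMort = AF · daily deaths · days; linear in baseline deaths and days."""
    if n_days < 1:
        raise ValidationError("n_days: must be >= 1")
    return attributable_fraction(params.beta, delta_c) * params.deaths_per_day * n_days


def cohort_burden(
    estimates,
    params: dict[str, dict[str, CauseParams]],
    n_days: int = DEFAULT_N_DAYS,
) -> tuple[list[HealthBurden], dict[str, float]]:
    """Per-city, per-cause burdens plus cause totals.

    ``params`` maps city_id → cause → :class:`CauseParams`; every city needs
    all three causes.  Cities whose machine-learning delta is non-negative
    (no reduction) contribute zero.  Accepts ReductionEstimate objects or a
    DataFrame with ``city_id`` and ``delta_ml`` columns.
    """
    if isinstance(estimates, pd.DataFrame):
        rows = list(estimates[["city_id", "delta_ml"]].itertuples(index=False))
    else:
        rows = [(e.city_id, e.delta_ml) for e in estimates]

    burdens: list[HealthBurden] = []
    totals = {cause: 0.0 for cause in CAUSES}
    for city_id, delta_ml in rows:
        city_params = params.get(city_id)
        if city_params is None:
            raise ValidationError(f"no health parameters for city '{city_id}'")
        delta_c = max(0.0, -float(delta_ml))
        for cause in CAUSES:
            p = city_params.get(cause)
            if p is None:
                raise ValidationError(
                    f"missing health parameters for city '{city_id}', cause '{cause}'"
                )
            deaths = avoided_mortality(p, delta_c, n_days) if delta_c > 0 else 0.0
            burdens.append(
                HealthBurden(
                    city_id=city_id,
                    cause=cause,
                    delta_c=delta_c,
                    rr=relative_risk(p.beta, delta_c),
                    af=attributable_fraction(p.beta, delta_c),
                    avoided_deaths=deaths,
                )
            )
            totals[cause] += deaths
    return burdens, totals


def params_from_table(
    table: pd.DataFrame, beta: dict[str, float] | None = None
) -> dict[str, dict[str, CauseParams]]:
    """Build the params mapping from a demographic fixture table.

    Accepts either columns ``(city_id, cause, daily_deaths)`` or
    ``(city_id, cause, y0, pop)``; β defaults per cause may be overridden.
    """
    beta = {**DEFAULT_BETA, **(beta or {})}
    out: dict[str, dict[str, CauseParams]] = {}
    rate_layout = {"y0", "pop"}.issubset(table.columns)
    if not rate_layout and "daily_deaths" not in table.columns:
        raise ValidationError(
            "demographic table needs (city_id, cause, daily_deaths) or (city_id, cause, y0, pop)"
        )
    for row in table.itertuples(index=False):
        city, cause = str(row.city_id), str(row.cause)
        if rate_layout:
            p = CauseParams(cause=cause, beta=beta[cause], y0=float(row.y0), pop=float(row.pop))
        else:
            p = CauseParams(cause=cause, beta=beta[cause], daily_deaths=float(row.daily_deaths))
        out.setdefault(city, {})[cause] = p
    return out
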