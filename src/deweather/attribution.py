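"""Lockdown attribution: machine-learning and difference-to-difference estimators.

Two estimators of the lockdown-induced concentration change are computed per
city and compared:

* **machine learning**: observed mean minus business-as-usual (counterfactual)
  mean over the lockdown period — the forest absorbs the intervention
  winter's actual meteorology;
* **difference-to-difference**: the 2020-minus-historical difference during
  lockdown, adjusted by subtracting the same difference computed before
  lockdown,

      Cd,X      = C̄(2020, X) − C̄(hist, X)        for X in {BLP, DLP, ALP}
      Cadj_d,DLP = Cd,DLP − Cd,BLP.

Deltas are signed throughout (negative = reduction); prose summaries report
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CoverageError, ValidationError
from .features import HolidayCalendar
from .metrics import pearson_r2
from .periods import DEFAULT_SCHEME, DateInterval, PeriodScheme
from .series import CityDailySeries

__all__ = [
    "PeriodMeans",
    "DiffToDiff",
    "ReductionEstimate",
    "CohortSummary",
    "period_means",
    "diff_to_diff",
    "ml_reduction",
    "compare_approaches",
]

DEFAULT_COVERAGE = 0.7


@dataclass(frozen=True)
class PeriodMeans:
    """The six phase means: intervention winter vs pooled reference winters."""

    blp_2020: float
    dlp_2020: float
    alp_2020: float
    blp_ref: float
    dlp_ref: float
    alp_ref: float


@dataclass(frozen=True)
class DiffToDiff:
    """Raw phase differences and the BLP-adjusted lockdown difference."""

    cd_blp: float
    cd_dlp: float
    cd_alp: float
    cadj_d_dlp: float


@dataclass(frozen=True)
class ReductionEstimate:
    """Per-city lockdown concentration change from both approaches.

    ``delta_ml`` and ``delta_d2d`` are signed µg/m³ (negative = reduction);
    ``percent_change`` is delta_ml as a percentage of the counterfactual mean.
    """

    city_id: str
    delta_ml: float
    delta_d2d: float
    percent_change: float
    n_days_used: int


def _phase_mean(
    series: CityDailySeries, interval: DateInterval, coverage: float, what: str
) -> float:
    vals = series.no2_between(interval)
    n_cal = interval.n_days
    n_ok = int(vals.notna().sum())
    if n_ok < coverage * n_cal:
        raise CoverageError(
            f"{series.city_id}: {what} has {n_ok}/{n_cal} non-missing days "
            f"(coverage threshold {coverage:.0%})"
        )
    return float(vals.mean())


def _reference_phase_mean(
    series: CityDailySeries,
    interval: DateInterval,
    scheme: PeriodScheme,
    coverage: float,
    what: str,
    align: str,
    cal: HolidayCalendar | None,
) -> float:
    """Mean over the reference winters: average within each winter, then across.

    ``align='calendar'`` maps the 2020 phase onto each reference winter by
    month-day identity (Feb 29 dropped for non-leap winters);
    ``align='lunar'`` shifts the window so it sits at the same distance from
    that winter's Lunar New Year holiday.
    """
    idx = series.indexed()["no2"]
    per_winter = []
    for label in scheme.reference_winters:
        if align == "calendar":
            dates = interval.map_to_winter(label)
        elif align == "lunar":
            cal = cal or HolidayCalendar.default()
            shift = cal.holiday_start(label) - cal.holiday_start(scheme.analysis_winter)
            window = scheme.winter_window(label)
            dates = pd.DatetimeIndex(
                [d + shift for d in interval.dates() if (d + shift) in window]
            )
        else:
            raise ValidationError(f"align: unknown alignment '{align}'")
        vals = idx.reindex(dates)
        n_ok = int(vals.notna().sum())
        if n_ok < coverage * len(dates):
            raise CoverageError(
                f"{series.city_id}: {what} in winter {label} has {n_ok}/{len(dates)} "
                f"non-missing days (coverage threshold {coverage:.0%})"
            )
        per_winter.append(float(vals.mean()))
    return float(np.mean(per_winter))


def period_means(
    series: CityDailySeries,
    scheme: PeriodScheme = DEFAULT_SCHEME,
    coverage: float = DEFAULT_COVERAGE,
    align: str = "calendar",
    cal: HolidayCalendar | None = None,
) -> PeriodMeans:
    """The six phase means needed by the difference-to-difference estimator.

    Historical means weight the reference winters equally (mean of
    within-winter means), which is robust to unequal missingness across
    winters.
    """
    phases = scheme.phases()
    m2020 = {
        name: _phase_mean(series, iv, coverage, f"{name} (intervention winter)")
        for name, iv in phases.items()
    }
    mref = {
        name: _reference_phase_mean(
            series, iv, scheme, coverage, f"{name} (reference)", align, cal
        )
        for name, iv in phases.items()
    }
    return PeriodMeans(
        blp_2020=m2020["pre_lockdown"],
        dlp_2020=m2020["lockdown"],
        alp_2020=m2020["post_lockdown"],
        blp_ref=mref["pre_lockdown"],
        dlp_ref=mref["lockdown"],
        alp_ref=mref["post_lockdown"],
    )


def diff_to_diff(means: PeriodMeans) -> DiffToDiff:
    """Phase differences and the BLP-adjusted during-lockdown difference."""
    cd_blp = means.blp_2020 - means.blp_ref
    cd_dlp = means.dlp_2020 - means.dlp_ref
    cd_alp = means.alp_2020 - means.alp_ref
    return DiffToDiff(cd_blp, cd_dlp, cd_alp, cd_dlp - cd_blp)


def ml_reduction(
    observed: pd.Series,
    counterfactual: pd.Series,
    expected_days: int | None = None,
    coverage: float = DEFAULT_COVERAGE,
) -> tuple[float, float]:
    """Observed-minus-counterfactual change over the lockdown period.

    Pairs the two date-indexed series on their common complete days, then
    returns ``(delta, percent)`` with delta = mean(obs) − mean(counterfactual)
    and percent = 100·delta / mean(counterfactual).  ``expected_days``
    (default: length of the counterfactual index) sets the denominator of the
    coverage check.
    """
    joined = pd.concat(
        {"obs": observed, "bau": counterfactual}, axis=1, join="inner"
    ).dropna()
    n_expected = expected_days if expected_days is not None else len(counterfactual)
    if n_expected < 1:
        raise ValidationError("expected_days must be >= 1")
    if len(joined) < coverage * n_expected:
        raise CoverageError(
            f"only {len(joined)}/{n_expected} paired complete lockdown days "
            f"(coverage threshold {coverage:.0%})"
        )
    bau_mean = float(joined["bau"].mean())
    if bau_mean <= 0:
        raise ValidationError(f"counterfactual mean must be positive, got {bau_mean:.3g}")
    delta = float(joined["obs"].mean()) - bau_mean
    return delta, 100.0 * delta / bau_mean


@dataclass(frozen=True)
class CohortSummary:
    """Cohort roll-up of per-city reduction estimates.

    Means are over signed machine-learning deltas; min/max report the
    smallest and largest reduction *magnitudes* with their city labels.
    """

    n_cities: int
    mean_delta_ml: float
    mean_magnitude: float
    min_magnitude: float
    min_city: str
    max_magnitude: float
    max_city: str
    n_reduced: int
    r2_ml_vs_d2d: float
    discrepancy: pd.Series  # per-city delta_ml − delta_d2d

    def as_dict(self) -> dict:
        return {
            "n_cities": self.n_cities,
            "mean_delta_ml": self.mean_delta_ml,
            "mean_magnitude": self.mean_magnitude,
            "min_magnitude": self.min_magnitude,
            "min_city": self.min_city,
            "max_magnitude": self.max_magnitude,
            "max_city": self.max_city,
            "n_reduced": self.n_reduced,
            "r2_ml_vs_d2d": self.r2_ml_vs_d2d,
        }


def compare_approaches(estimates) -> CohortSummary:
    """Summarise a cohort of per-city estimates and correlate the approaches.

    Accepts a list of :class:`ReductionEstimate` or a DataFrame with columns
    ``city_id, delta_ml, delta_d2d``.  Requires at least 3 cities (the
    between-approach R² is meaningless below that).
    """
    if isinstance(estimates, pd.DataFrame):
        table = estimates
    else:
        table = pd.DataFrame(
            [
                {"city_id": e.city_id, "delta_ml": e.delta_ml, "delta_d2d": e.delta_d2d}
                for e in estimates
            ]
        )
    for col in ("city_id", "delta_ml", "delta_d2d"):
        if col not in table.columns:
            raise ValidationError(f"estimates table missing column '{col}'")
    if len(table) < 3:
        raise ValidationError(f"need at least 3 cities, got {len(table)}")

    ml = table["delta_ml"].astype(float)
    mag = ml.abs()
    imin, imax = mag.idxmin(), mag.idxmax()
    return CohortSummary(
        n_cities=int(len(table)),
        mean_delta_ml=float(ml.mean()),
        mean_magnitude=float(mag.mean()),
        min_magnitude=float(mag[imin]),
        min_city=str(table.loc[imin, "city_id"]),
        max_magnitude=float(mag[imax]),
        max_city=str(table.loc[imax, "city_id"]),
        n_reduced=int((ml < 0).sum()),
        r2_ml_vs_d2d=pearson_r2(ml, table["delta_d2d"].astype(float)),
        discrepancy=pd.Series(
            (ml - table["delta_d2d"]).to_numpy(), index=table["city_id"], name="ml_minus_d2d"
        ),
    )
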