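"""End-to-end orchestration: simulate → features → fit → validate → attribute → health.

The pipeline is a plain-Python composition of the library stages, driven by a
:class:`RunConfig` (loadable from one YAML file).  Every stage's outputs are
persisted as delimited tables plus one structured summary, and all
randomness flows from a single global seed (per-city model seeds are derived
as seed + city index).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .attribution import (
    CohortSummary,
    ReductionEstimate,
    compare_approaches,
    diff_to_diff,
    ml_reduction,
    period_means,
)
from .datasets import read_estimates_table
from .errors import DeweatherError, ValidationError
from .features import HolidayCalendar, build_features
from .health import DEFAULT_BETA, cohort_burden, params_from_table
from .io import read_daily_city_table, write_daily_city_table
from .metrics import MetricReport, error_metrics
from .model import FittedCityModel, ModelSpec, cross_validate_by_year, fit, predict_counterfactual
from .periods import DEFAULT_SCHEME, PeriodScheme
from .series import CityDailySeries
from .synthetic import SyntheticCityConfig, generate_cohort

__all__ = ["RunConfig", "CityResult", "analyze_city", "analyze_cohort",
           "simulate_cohort", "run_pipeline", "table2_summary"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    Either ``input_dir`` (canonical per-city CSV tables) or a synthetic
    cohort spec (``n_cities``/``effect_range``) must be given.
    """

    out_dir: str = "deweather_out"
    seed: int = 0
    input_dir: str | None = None
    n_cities: int = 31
    effect_range: tuple[float, float] = (5.0, 30.0)
    n_trees: int = 500
    m_try: int = 4
    coverage: float = 0.7
    align: str = "calendar"
    holidays: dict[int, dt.date] | None = None
    beta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    demographics: str | None = None
    run_cv: bool = True
    skip_health: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "holidays" in raw and raw["holidays"] is not None:
            raw["holidays"] = {
                int(y): dt.date.fromisoformat(str(d)) for y, d in raw["holidays"].items()
            }
        if "effect_range" in raw:
            raw["effect_range"] = tuple(raw["effect_range"])
        return cls(**raw)

    def calendar(self) -> HolidayCalendar:
        if self.holidays is None:
            return HolidayCalendar.default()
        merged = {**HolidayCalendar.default().holidays, **self.holidays}
        return HolidayCalendar(merged)

    def model_spec(self, city_index: int = 0) -> ModelSpec:
        return ModelSpec(
            n_trees=self.n_trees, m_try=self.m_try, random_seed=self.seed + city_index
        )


@dataclass
class CityResult:
    """One city's fitted model, validation metrics, and reduction estimate."""

    city_id: str
    model: FittedCityModel
    estimate: ReductionEstimate
    pre_lockdown_report: MetricReport
    cv_reports: dict[int, MetricReport] | None = None


def analyze_city(
    series: CityDailySeries,
    scheme: PeriodScheme = DEFAULT_SCHEME,
    cal: HolidayCalendar | None = None,
    spec: ModelSpec = ModelSpec(),
    coverage: float = 0.7,
    align: str = "calendar",
    run_cv: bool = True,
) -> CityResult:
    """Full single-city chain: features, fit, validate, counterfactual, attribute."""
    cal = cal or HolidayCalendar.default()
    features = build_features(series, cal)
    train = features.loc[features["year"].isin(scheme.reference_winters)]
    model = fit(train, spec, city_id=series.city_id)

    cv_reports = None
    if run_cv:
        cv_reports = cross_validate_by_year(train, spec, scheme)

    analysis = features.loc[features["year"] == scheme.analysis_winter]

    def _phase_frame(interval):
        mask = (analysis.index >= pd.Timestamp(interval.start)) & (
            analysis.index <= pd.Timestamp(interval.end)
        )
        return analysis.loc[mask]

    blp = _phase_frame(scheme.pre_lockdown)
    blp_pred = predict_counterfactual(model, blp)
    pre_report = error_metrics(blp.loc[blp_pred.index, "no2"], blp_pred)

    dlp = _phase_frame(scheme.lockdown)
    dlp_pred = predict_counterfactual(model, dlp)
    delta_ml, percent = ml_reduction(
        dlp["no2"], dlp_pred, expected_days=scheme.lockdown.n_days, coverage=coverage
    )
    n_used = int(pd.concat({"o": dlp["no2"], "p": dlp_pred}, axis=1).dropna().shape[0])

    means = period_means(series, scheme, coverage=coverage, align=align, cal=cal)
    d2d = diff_to_diff(means)

    estimate = ReductionEstimate(
        city_id=series.city_id,
        delta_ml=delta_ml,
        delta_d2d=d2d.cadj_d_dlp,
        percent_change=percent,
        n_days_used=n_used,
    )
    return CityResult(series.city_id, model, estimate, pre_report, cv_reports)


def analyze_cohort(
    cohort: list[CityDailySeries],
    scheme: PeriodScheme = DEFAULT_SCHEME,
    cal: HolidayCalendar | None = None,
    base_seed: int = 0,
    n_trees: int = 500,
    m_try: int = 4,
    coverage: float = 0.7,
    align: str = "calendar",
    run_cv: bool = False,
) -> tuple[list[CityResult], CohortSummary]:
    """Run the per-city chain over a cohort and summarise the two approaches."""
    results = []
    for i, series in enumerate(cohort):
        spec = ModelSpec(n_trees=n_trees, m_try=m_try, random_seed=base_seed + i)
        try:
            results.append(
                analyze_city(series, scheme, cal, spec, coverage, align, run_cv)
            )
        except DeweatherError as exc:
            raise DeweatherError(f"city {series.city_id}: {exc}") from exc
    summary = compare_approaches([r.estimate for r in results])
    return results, summary


def simulate_cohort(config: RunConfig, scheme: PeriodScheme = DEFAULT_SCHEME) -> Path:
    """Write canonical city tables plus a truth table of injected effects."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(
        config.n_cities, config.seed, config.effect_range,
        scheme=scheme, cal=config.calendar(),
    )
    truth = []
    for series, effect in cohort:
        write_daily_city_table(series, out / f"{series.city_id}.csv")
        truth.append({"city_id": series.city_id, "true_effect": effect})
    pd.DataFrame(truth).to_csv(out / "truth.csv", index=False, float_format="%.6g")
    log.info("wrote %d city tables to %s", len(cohort), out)
    return out


def _persist(results: list[CityResult], summary: CohortSummary, out: Path) -> None:
    est = pd.DataFrame(
        [
            {
                "city_id": r.estimate.city_id,
                "delta_ml": r.estimate.delta_ml,
                "delta_d2d": r.estimate.delta_d2d,
                "percent_change": r.estimate.percent_change,
                "n_days_used": r.estimate.n_days_used,
            }
            for r in results
        ]
    )
    est.to_csv(out / "estimates.csv", index=False, float_format="%.6g")

    rows = []
    for r in results:
        rows.append({"city_id": r.city_id, "context": "pre_lockdown", **r.pre_lockdown_report.as_dict()})
        for winter, rep in (r.cv_reports or {}).items():
            rows.append({"city_id": r.city_id, "context": f"cv_{winter}", **rep.as_dict()})
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False, float_format="%.6g")

    imp = pd.DataFrame({r.city_id: r.model.variable_importance for r in results}).T
    imp.rename_axis("city_id").to_csv(out / "importance.csv", float_format="%.4g")

    (out / "summary.json").write_text(json.dumps(summary.as_dict(), indent=2) + "\n")


def run_pipeline(
    config: RunConfig, scheme: PeriodScheme = DEFAULT_SCHEME
) -> tuple[list[CityResult], CohortSummary]:
    """Execute every stage in order and persist all outputs under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cal = config.calendar()

    if config.input_dir is not None:
        paths = sorted(Path(config.input_dir).glob("*.csv"))
        paths = [p for p in paths if p.stem != "truth"]
        if not paths:
            raise ValidationError(f"no city tables found in {config.input_dir}")
        cohort = [read_daily_city_table(p) for p in paths]
    else:
        cohort = [s for s, _ in generate_cohort(
            config.n_cities, config.seed, config.effect_range, scheme=scheme, cal=cal
        )]
    log.info("analyzing %d cities", len(cohort))

    results, summary = analyze_cohort(
        cohort, scheme, cal,
        base_seed=config.seed, n_trees=config.n_trees, m_try=config.m_try,
        coverage=config.coverage, align=config.align, run_cv=config.run_cv,
    )
    _persist(results, summary, out)

    if not config.skip_health and config.demographics is not None:
        demo = pd.read_csv(config.demographics)
        params = params_from_table(demo, config.beta)
        burdens, totals = cohort_burden(
            [r.estimate for r in results], params, n_days=scheme.lockdown.n_days
        )
        btab = pd.DataFrame([dataclasses.asdict(b) for b in burdens])
        btab.to_csv(out / "burdens.csv", index=False, float_format="%.6g")
        (out / "burden_totals.json").write_text(json.dumps(totals, indent=2) + "\n")
        log.info("cause totals: %s", totals)

    log.info(
        "cohort: mean reduction %.1f µg/m³ (max %.1f %s, min %.1f %s), R²=%.3f",
        summary.mean_magnitude, summary.max_magnitude, summary.max_city,
        summary.min_magnitude, summary.min_city, summary.r2_ml_vs_d2d,
    )
    return results, summary


def table2_summary(path: str | Path | None = None) -> CohortSummary:
    """Cohort summary of a per-city estimates table (default: the bundled one)."""
    if path is None:
        from .datasets import load_table2

        table = load_table2()
    else:
        table = read_estimates_table(path)
    return compare_approaches(table)
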