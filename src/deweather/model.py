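"""Per-city random-forest business-as-usual models.

One random forest is fitted per city on the reference winters only (the
intervention winter is never trained on) and then used to predict what
concentrations *would have been* in the intervention winter given its actual
meteorology and calendar — the business-as-usual counterfactual.  Model
quality is assessed by leave-one-winter-out cross-validation over the three
reference winters and by out-of-sample prediction of the pre-lockdown weeks.

Defaults follow common practice for this kind of de-weathering model:
500 trees with 4 candidate predictors per split, selected from a
5 x 6 (n_trees x m_try) grid by cross-validated index of agreement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .errors import ValidationError
from .features import DEFAULT_PREDICTORS, complete_rows
from .metrics import MetricReport, error_metrics
from .periods import PeriodScheme

__all__ = [
    "ModelSpec",
    "FittedCityModel",
    "fit",
    "predict_counterfactual",
    "cross_validate_by_year",
    "tune",
    "DEFAULT_TREE_GRID",
    "DEFAULT_MTRY_GRID",
]

DEFAULT_TREE_GRID = (50, 100, 200, 500, 1000)
DEFAULT_MTRY_GRID = (2, 3, 4, 5, 6, 7)

#: minimum complete training rows per city model
MIN_TRAINING_ROWS = 100


@dataclass(frozen=True)
class ModelSpec:
    """Hyperparameters of one city model.

    ``m_try`` is the number of candidate predictors considered at each split
    (randomForest's mtry); it must not exceed the number of predictors.
    """

    n_trees: int = 500
    m_try: int = 4
    random_seed: int = 0
    predictor_names: tuple[str, ...] = DEFAULT_PREDICTORS

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees: must be >= 1")
        if not self.predictor_names:
            raise ValidationError("predictor_names: must be non-empty")
        if not 1 <= self.m_try <= len(self.predictor_names):
            raise ValidationError(
                f"m_try: must be in [1, {len(self.predictor_names)}], got {self.m_try}"
            )


@dataclass
class FittedCityModel:
    """A fitted per-city forest plus its audit trail."""

    city_id: str
    spec: ModelSpec
    training_rows: int
    variable_importance: pd.Series  # normalised to percent, sums to 100
    estimator: RandomForestRegressor = field(repr=False)

    def save(self, path) -> None:
        """Persist as a versioned joblib artifact with spec and importance embedded."""
        import joblib

        joblib.dump(
            {
                "format_version": 1,
                "city_id": self.city_id,
                "spec": self.spec,
                "training_rows": self.training_rows,
                "variable_importance": self.variable_importance,
                "estimator": self.estimator,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "FittedCityModel":
        import joblib

        blob = joblib.load(path)
        if blob.get("format_version") != 1:
            raise ValidationError(f"unknown model artifact version in {path}")
        return cls(
            city_id=blob["city_id"],
            spec=blob["spec"],
            training_rows=blob["training_rows"],
            variable_importance=blob["variable_importance"],
            estimator=blob["estimator"],
        )


def _training_matrix(features: pd.DataFrame, spec: ModelSpec):
    missing = [c for c in spec.predictor_names if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing predictor columns {missing}")
    fit_rows = complete_rows(features)
    return fit_rows[list(spec.predictor_names)], fit_rows["no2"]


def fit(
    features: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    city_id: str = "",
    min_rows: int = MIN_TRAINING_ROWS,
) -> FittedCityModel:
    """Fit one city's forest on (already period-restricted) training features.

    The caller restricts ``features`` to the reference winters; rows flagged
    incomplete are dropped.  Deterministic for a fixed ``spec.random_seed``.
    Variable importance (impurity-based) is normalised to percent.
    """
    X, y = _training_matrix(features, spec)
    if len(X) < min_rows:
        raise ValidationError(
            f"{city_id or 'city'}: {len(X)} complete training rows; "
            f"at least {min_rows} required"
        )
    forest = RandomForestRegressor(
        n_estimators=spec.n_trees,
        max_features=spec.m_try,
        random_state=spec.random_seed,
        n_jobs=1,
    )
    forest.fit(X.to_numpy(), y.to_numpy())
    raw = forest.feature_importances_
    importance = pd.Series(100.0 * raw / raw.sum(), index=list(spec.predictor_names))
    return FittedCityModel(
        city_id=city_id,
        spec=spec,
        training_rows=int(len(X)),
        variable_importance=importance,
        estimator=forest,
    )


def predict_counterfactual(model: FittedCityModel, features: pd.DataFrame) -> pd.Series:
    """Business-as-usual predictions for every complete-predictor row.

    Returns a date-indexed series (µg/m³, clipped at zero).  Rows with any
    missing predictor are skipped; a missing predictor *column* is an error.
    """
    missing = [c for c in model.spec.predictor_names if c not in features.columns]
    if missing:
        raise ValidationError(f"feature table missing predictor columns {missing}")
    X = features[list(model.spec.predictor_names)].dropna()
    if len(X) == 0:
        return pd.Series(dtype=float, name="no2_bau")
    pred = model.estimator.predict(X.to_numpy())
    return pd.Series(np.clip(pred, 0.0, None), index=X.index, name="no2_bau")


def cross_validate_by_year(
    features: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
    scheme: PeriodScheme | None = None,
    min_rows: int = MIN_TRAINING_ROWS,
) -> dict[int, MetricReport]:
    """Leave-one-winter-out cross-validation over the reference winters.

    Requires exactly three reference winters in the table; each fold trains
    on two and scores held-out predictions on the third with the full metric
    suite.  Fold seeds derive from ``spec.random_seed`` plus the held-out
    winter label so folds are independent but reproducible.
    """
    ref = features
    if scheme is not None:
        ref = features.loc[features["year"].isin(scheme.reference_winters)]
    winters = sorted(ref["year"].unique())
    if len(winters) != 3:
        raise ValidationError(
            f"cross-validation needs exactly 3 reference winters, found {winters}"
        )
    reports: dict[int, MetricReport] = {}
    for held_out in winters:
        train = ref.loc[ref["year"] != held_out]
        test = complete_rows(ref.loc[ref["year"] == held_out])
        fold_spec = ModelSpec(
            n_trees=spec.n_trees,
            m_try=spec.m_try,
            random_seed=spec.random_seed + int(held_out) % 1000,
            predictor_names=spec.predictor_names,
        )
        model = fit(train, fold_spec, city_id=f"fold-{held_out}", min_rows=min_rows)
        pred = predict_counterfactual(model, test)
        reports[int(held_out)] = error_metrics(test.loc[pred.index, "no2"], pred)
    return reports


def tune(
    features: pd.DataFrame,
    n_trees_grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    m_try_grid: tuple[int, ...] = DEFAULT_MTRY_GRID,
    base_spec: ModelSpec = ModelSpec(),
    min_rows: int = MIN_TRAINING_ROWS,
) -> tuple[ModelSpec, pd.DataFrame]:
    """Grid search maximising mean cross-validated index of agreement.

    Returns the winning spec and the full grid report (one row per
    combination).  Ties break toward fewer trees, then smaller m_try.
    """
    if not n_trees_grid or not m_try_grid:
        raise ValidationError("hyperparameter grid must be non-empty")
    rows = []
    for n_trees, m_try in itertools.product(n_trees_grid, m_try_grid):
        spec = ModelSpec(
            n_trees=n_trees,
            m_try=m_try,
            random_seed=base_spec.random_seed,
            predictor_names=base_spec.predictor_names,
        )
        reports = cross_validate_by_year(features, spec, min_rows=min_rows)
        mean_ioa = float(np.mean([r.ioa for r in reports.values()]))
        rows.append({"n_trees": n_trees, "m_try": m_try, "mean_cv_ioa": mean_ioa})
    report = pd.DataFrame(rows)
    best = report.sort_values(
        ["mean_cv_ioa", "n_trees", "m_try"], ascending=[False, True, True]
    ).iloc[0]
    best_spec = ModelSpec(
        n_trees=int(best["n_trees"]),
        m_try=int(best["m_try"]),
        random_seed=base_spec.random_seed,
        predictor_names=base_spec.predictor_names,
    )
    return best_spec, report
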