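import numpy as np
import pandas as pd
import pytest

import deweather as dw
from deweather import ModelSpec, ValidationError
from deweather.features import complete_rows
from deweather.model import cross_validate_by_year, fit, predict_counterfactual, tune
from deweather.synthetic import MetCoefficients, SyntheticCityConfig


@pytest.fixture(scope="module")
def wind_only_features(scheme, cal):
    """Noiseless city whose concentration depends only on wind speed."""
    cfg = SyntheticCityConfig(
        city_id="windy", seed=6, noise_sd=0.0, missing_fraction=0.0,
        year_trend=0.0, seasonal_amplitude=0.0, weekday_effects=(0.0,) * 7,
        holiday_dip=0.0, lockdown_effect=0.0,
        met_coefficients=MetCoefficients(
            wind_speed=30.0, temperature=0.0, relative_humidity=0.0, direction=0.0
        ),
    )
    series = dw.generate_city(cfg, scheme, cal)
    feats = dw.build_features(series, cal)
    return feats[feats["year"].isin(scheme.reference_winters)]


class TestModelSpec:
    def test_mtry_beyond_predictor_count_rejected(self):
        assert len(ModelSpec().predictor_names) == 7
        with pytest.raises(ValidationError, match="m_try"):
            ModelSpec(m_try=8)

    def test_invalid_tree_count_rejected(self):
        with pytest.raises(ValidationError):
            ModelSpec(n_trees=0)


class TestFit:
    def test_wind_speed_dominates_importance(self, wind_only_features, small_spec):
        model = fit(wind_only_features, small_spec, city_id="windy")
        imp = model.variable_importance
        assert imp.idxmax() == "wind_speed"
        assert imp.sum() == pytest.approx(100.0, abs=0.01)
        assert (imp >= 0).all()

    def test_duplicated_training_rows_keep_ranking(self, wind_only_features, small_spec):
        m1 = fit(wind_only_features, small_spec)
        doubled = pd.concat([wind_only_features, wind_only_features])
        m2 = fit(doubled, small_spec)
        r1 = m1.variable_importance.sort_values(ascending=False).index[:2]
        r2 = m2.variable_importance.sort_values(ascending=False).index[:2]
        assert list(r1) == list(r2)
        assert m2.training_rows == 2 * m1.training_rows

    def test_too_few_rows_states_the_floor(self, wind_only_features, small_spec):
        with pytest.raises(ValidationError, match="100"):
            fit(wind_only_features.head(40), small_spec)

    def test_fixed_seed_is_bit_reproducible(self, wind_only_features, small_spec):
        m1 = fit(wind_only_features, small_spec)
        m2 = fit(wind_only_features, small_spec)
        pd.testing.assert_series_equal(m1.variable_importance, m2.variable_importance)
        p1 = predict_counterfactual(m1, wind_only_features)
        p2 = predict_counterfactual(m2, wind_only_features)
        assert (p1 == p2).all()

    def test_artifact_round_trip(self, wind_only_features, small_spec, tmp_path):
        model = fit(wind_only_features, small_spec, city_id="windy")
        model.save(tmp_path / "windy.joblib")
        back = dw.FittedCityModel.load(tmp_path / "windy.joblib")
        assert back.city_id == "windy" and back.spec == small_spec
        pd.testing.assert_series_equal(back.variable_importance, model.variable_importance)


class TestPredict:
    def test_in_sample_fidelity_on_deterministic_process(self, wind_only_features):
        spec = ModelSpec(n_trees=200, m_try=4, random_seed=0)
        model = fit(wind_only_features, spec)
        pred = predict_counterfactual(model, wind_only_features)
        truth = complete_rows(wind_only_features)["no2"]
        within = (np.abs(pred - truth) <= 1.0).mean()
        assert within >= 0.95
        assert (pred >= 0).all()

    def test_identical_rows_identical_predictions(self, wind_only_features, small_spec):
        model = fit(wind_only_features, small_spec)
        row = wind_only_features.iloc[[0]]
        twice = pd.concat([row, row])
        pred = model.estimator.predict(twice[list(small_spec.predictor_names)].to_numpy())
        assert pred[0] == pred[1]

    def test_empty_table_empty_output(self, wind_only_features, small_spec):
        model = fit(wind_only_features, small_spec)
        out = predict_counterfactual(model, wind_only_features.iloc[0:0])
        assert len(out) == 0

    def test_missing_predictor_column_is_an_error(self, wind_only_features, small_spec):
        model = fit(wind_only_features, small_spec)
        with pytest.raises(ValidationError, match="wind_speed"):
            predict_counterfactual(model, wind_only_features.drop(columns=["wind_speed"]))


class TestCrossValidation:
    def test_three_folds_high_ioa_on_noiseless_data(self, noiseless_features, scheme):
        train = noiseless_features[noiseless_features["year"].isin(scheme.reference_winters)]
        reports = cross_validate_by_year(train, ModelSpec(n_trees=200, m_try=4, random_seed=0))
        assert sorted(reports) == [2017, 2018, 2019]
        for rep in reports.values():
            assert rep.ioa > 0.9

    def test_pure_noise_response_gives_low_ioa(self, noiseless_features, scheme):
        train = noiseless_features[
            noiseless_features["year"].isin(scheme.reference_winters)
        ].copy()
        rng = np.random.default_rng(1)
        train["no2"] = rng.uniform(20, 60, len(train))
        reports = cross_validate_by_year(train, ModelSpec(n_trees=60, m_try=4, random_seed=0))
        for rep in reports.values():
            assert rep.ioa < 0.4

    def test_wrong_winter_count_rejected(self, noiseless_features):
        two = noiseless_features[noiseless_features["year"].isin((2017, 2018))]
        with pytest.raises(ValidationError, match="3"):
            cross_validate_by_year(two)

    def test_noise_predictor_barely_moves_heldout_ioa(self, noiseless_features, scheme):
        """Robustness guard: an uninformative extra predictor shifts held-out
        IOA by less than 0.05."""
        train = noiseless_features[
            noiseless_features["year"].isin(scheme.reference_winters)
        ].copy()
        base = cross_validate_by_year(train, ModelSpec(n_trees=100, m_try=4, random_seed=0))
        rng = np.random.default_rng(2)
        train["junk"] = rng.normal(size=len(train))
        wide_spec = ModelSpec(
            n_trees=100, m_try=4, random_seed=0,
            predictor_names=ModelSpec().predictor_names + ("junk",),
        )
        wide = cross_validate_by_year(train, wide_spec)
        for winter in base:
            assert abs(base[winter].ioa - wide[winter].ioa) < 0.05


class TestTune:
    def test_single_spec_grid_returns_it(self, wind_only_features):
        best, report = tune(wind_only_features, n_trees_grid=(60,), m_try_grid=(3,))
        assert (best.n_trees, best.m_try) == (60, 3)
        assert len(report) == 1

    def test_report_covers_grid(self, wind_only_features):
        best, report = tune(wind_only_features, n_trees_grid=(40, 80), m_try_grid=(2, 4))
        assert len(report) == 4
        assert {tuple(r) for r in report[["n_trees", "m_try"]].to_numpy()} == {
            (40, 2), (40, 4), (80, 2), (80, 4)
        }

    def test_default_grid_shape(self):
        from deweather.model import DEFAULT_MTRY_GRID, DEFAULT_TREE_GRID

        assert len(DEFAULT_TREE_GRID) * len(DEFAULT_MTRY_GRID) == 30

    def test_empty_grid_rejected(self, wind_only_features):
        with pytest.raises(ValidationError):
            tune(wind_only_features, n_trees_grid=(), m_try_grid=(2,))
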