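import math

import numpy as np
import pandas as pd
import pytest

from deweather import (
    CauseParams,
    ValidationError,
    attributable_fraction,
    avoided_mortality,
    cohort_burden,
    relative_risk,
)
from deweather.health import params_from_table


class TestRelativeRisk:
    def test_zero_change_unit_risk(self):
        assert relative_risk(0.009, 0.0) == 1.0

    @pytest.mark.parametrize(
        "beta,dc,expected",
        [(0.009, 16.0, math.exp(0.144)), (0.012, 10.0, math.exp(0.12))],
    )
    def test_log_linear_values(self, beta, dc, expected):
        assert relative_risk(beta, dc) == pytest.approx(expected, rel=1e-12)
        assert relative_risk(0.009, 16.0) == pytest.approx(1.1549, abs=1e-4)

    def test_negative_change_rejected(self):
        with pytest.raises(ValidationError):
            relative_risk(0.009, -1.0)


class TestAttributableFraction:
    def test_zero_change_zero_fraction(self):
        assert attributable_fraction(0.009, 0.0) == 0.0

    def test_reference_value(self):
        assert attributable_fraction(0.009, 16.0) == pytest.approx(
            1 - math.exp(-0.144), rel=1e-12
        )
        assert attributable_fraction(0.009, 16.0) == pytest.approx(0.1341, abs=1e-4)

    def test_both_algebraic_forms_agree(self):
        """1 − exp(−βΔc) and (RR−1)/RR agree to 1e-12 over 1000 random inputs."""
        rng = np.random.default_rng(0)
        for beta, dc in zip(rng.uniform(1e-4, 0.05, 1000), rng.uniform(0, 40, 1000)):
            rr = relative_risk(beta, dc)
            assert attributable_fraction(beta, dc) == pytest.approx(
                (rr - 1.0) / rr, abs=1e-12
            )

    def test_small_change_first_order_limit(self):
        beta, dc = 0.009, 1e-6
        assert attributable_fraction(beta, dc) == pytest.approx(beta * dc, rel=1e-8)

    def test_bounded_in_unit_interval(self):
        assert 0.0 <= attributable_fraction(0.012, 300.0) < 1.0


class TestAvoidedMortality:
    def test_reference_value(self):
        p = CauseParams("non_accidental", beta=0.009, daily_deaths=100.0)
        # 0.1341126... * 100 * 56
        assert avoided_mortality(p, 16.0, n_days=56) == pytest.approx(751.03, abs=0.1)

    def test_zero_change_zero_deaths(self):
        p = CauseParams("respiratory", beta=0.012, daily_deaths=50.0)
        assert avoided_mortality(p, 0.0) == 0.0

    def test_exactly_linear_in_deaths_and_days(self):
        p1 = CauseParams("cardiovascular", beta=0.009, daily_deaths=40.0)
        p2 = CauseParams("cardiovascular", beta=0.009, daily_deaths=80.0)
        assert avoided_mortality(p2, 12.0, 56) == pytest.approx(
            2.0 * avoided_mortality(p1, 12.0, 56), rel=1e-12
        )
        assert avoided_mortality(p1, 12.0, 112) == pytest.approx(
            2.0 * avoided_mortality(p1, 12.0, 56), rel=1e-12
        )

    def test_rate_parameterisation_equivalent(self):
        direct = CauseParams("non_accidental", beta=0.009, daily_deaths=120.0)
        rate = CauseParams("non_accidental", beta=0.009, y0=1.2e-5, pop=1e7)
        assert avoided_mortality(rate, 9.0) == pytest.approx(
            avoided_mortality(direct, 9.0), rel=1e-12
        )

    def test_monotone_in_every_argument(self):
        p = CauseParams("non_accidental", beta=0.009, daily_deaths=100.0)
        hot = CauseParams("non_accidental", beta=0.011, daily_deaths=100.0)
        assert avoided_mortality(p, 10.0) < avoided_mortality(p, 11.0)
        assert avoided_mortality(p, 10.0) < avoided_mortality(hot, 10.0)
        assert avoided_mortality(p, 10.0, 56) < avoided_mortality(p, 10.0, 57)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"daily_deaths": 10.0, "y0": 1e-5, "pop": 1e6},
            {"y0": 1e-5},
            {},
            {"daily_deaths": -1.0},
        ],
    )
    def test_inconsistent_parameterisation_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CauseParams("non_accidental", beta=0.009, **kwargs)


class TestCohortBurden:
    def _params(self, cities, deaths=100.0):
        table = pd.DataFrame(
            [
                {"city_id": c, "cause": cause, "daily_deaths": deaths}
                for c in cities
                for cause in ("non_accidental", "cardiovascular", "respiratory")
            ]
        )
        return params_from_table(table)

    def test_zero_reductions_zero_totals(self):
        est = pd.DataFrame({"city_id": ["a", "b"], "delta_ml": [0.0, 3.0]})
        _, totals = cohort_burden(est, self._params(["a", "b"]))
        assert totals == {"non_accidental": 0.0, "cardiovascular": 0.0, "respiratory": 0.0}

    def test_single_city_matches_closed_form(self):
        est = pd.DataFrame({"city_id": ["a"], "delta_ml": [-16.0]})
        burdens, totals = cohort_burden(est, self._params(["a"]), n_days=56)
        p = CauseParams("respiratory", beta=0.012, daily_deaths=100.0)
        resp = [b for b in burdens if b.cause == "respiratory"][0]
        assert resp.avoided_deaths == pytest.approx(avoided_mortality(p, 16.0, 56))
        assert totals["respiratory"] == pytest.approx(resp.avoided_deaths)
        assert resp.af == pytest.approx(1 - 1 / resp.rr, abs=1e-12)

    def test_cohort_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        cities = [f"c{i}" for i in range(31)]
        deltas = -rng.uniform(5, 30, 31)
        deaths = rng.uniform(20, 300, 31)
        est = pd.DataFrame({"city_id": cities, "delta_ml": deltas})
        table = pd.DataFrame(
            [
                {"city_id": c, "cause": cause, "daily_deaths": d}
                for c, d in zip(cities, deaths)
                for cause in ("non_accidental", "cardiovascular", "respiratory")
            ]
        )
        _, totals = cohort_burden(est, params_from_table(table), n_days=56)
        for cause, beta in (("non_accidental", 0.009), ("cardiovascular", 0.009),
                            ("respiratory", 0.012)):
            expected = sum(
                (1 - math.exp(-beta * (-dm))) * dd * 56
                for dm, dd in zip(deltas, deaths)
            )
            assert totals[cause] == pytest.approx(expected, abs=1e-9)

    def test_totals_invariant_to_city_order(self):
        est = pd.DataFrame({"city_id": ["a", "b", "c"], "delta_ml": [-5.0, -10.0, -20.0]})
        params = self._params(["a", "b", "c"])
        _, t1 = cohort_burden(est, params)
        _, t2 = cohort_burden(est.iloc[::-1], params)
        for cause in t1:
            assert t1[cause] == pytest.approx(t2[cause], rel=1e-12)

    def test_missing_cause_names_city_and_cause(self):
        est = pd.DataFrame({"city_id": ["a"], "delta_ml": [-5.0]})
        partial = self._params(["a"])
        del partial["a"]["respiratory"]
        with pytest.raises(ValidationError, match="a.*respiratory"):
            cohort_burden(est, partial)
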