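import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import deweather as dw

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scheme() -> dw.PeriodScheme:
    return dw.DEFAULT_SCHEME


@pytest.fixture(scope="session")
def cal() -> dw.HolidayCalendar:
    return dw.HolidayCalendar.default()


@pytest.fixture(scope="session")
def aligned_cal() -> dw.HolidayCalendar:
    """Holidays on the same calendar day every winter: no holiday-timing
    confounding between day_lunar and day_julian."""
    return dw.HolidayCalendar(
        {y: dt.date(y, 2, 5) for y in (2017, 2018, 2019, 2020)}
    )


@pytest.fixture(scope="session")
def noiseless_config() -> dw.SyntheticCityConfig:
    """Deterministic structural world: no observation noise, no missing days,
    no year trend (a trend is unidentifiable when extrapolating the year
    ordinal to an unseen winter)."""
    return dw.SyntheticCityConfig(
        city_id="noiseless", seed=0, noise_sd=0.0, missing_fraction=0.0, year_trend=0.0
    )


@pytest.fixture(scope="session")
def noiseless_city(noiseless_config, scheme, cal) -> dw.CityDailySeries:
    return dw.generate_city(noiseless_config, scheme, cal)


@pytest.fixture(scope="session")
def noiseless_features(noiseless_city, cal):
    return dw.build_features(noiseless_city, cal)


@pytest.fixture(scope="session")
def default_city(scheme, cal) -> dw.CityDailySeries:
    """One city under the default (noisy) study conditions."""
    return dw.generate_city(dw.SyntheticCityConfig(city_id="default", seed=5), scheme, cal)


@pytest.fixture(scope="session")
def small_spec() -> dw.ModelSpec:
    """A fast forest for unit tests that exercise mechanics, not accuracy."""
    return dw.ModelSpec(n_trees=60, m_try=4, random_seed=0)
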