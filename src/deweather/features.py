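"""Time-variable construction and assembly of the model-ready feature table.

Four time variables act as emission proxies alongside the measured
meteorology:

``year``
    the winter-season label, an ordinal capturing slow emission-factor change;
``day_julian``
    day of year (1-366), the within-year emission trend;
``weekday``
    1 = Monday ... 7 = Sunday, the within-week trend;
``day_lunar``
    signed days relative to the first day of the Chinese Lunar New Year
    holiday of that winter (0 on the holiday's first day, negative before),
    the proxy for the large holiday-driven emission dip.

The holiday dates are a plain lookup table, not a lunisolar computation: the
2017 anchor (27 January) is fixed; later defaults follow the Lunar New Year
date and can be overridden in configuration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from .errors import CalendarError, ValidationError
from .periods import winter_label
from .series import MET_COLUMNS, CityDailySeries

__all__ = [
    "HolidayCalendar",
    "day_lunar",
    "build_features",
    "TIME_VARIABLES",
    "DEFAULT_PREDICTORS",
    "ALL_PREDICTORS",
]

TIME_VARIABLES = ("year", "day_julian", "weekday", "day_lunar")

#: The seven predictors the final per-city models use (weekday is constructed
#: in the feature table but not part of the default model predictor set).
DEFAULT_PREDICTORS = (
    "year",
    "day_julian",
    "day_lunar",
    "wind_direction",
    "wind_speed",
    "temperature",
    "relative_humidity",
)

ALL_PREDICTORS = TIME_VARIABLES + MET_COLUMNS


_DEFAULT_HOLIDAYS = {
    2017: dt.date(2017, 1, 27),
    2018: dt.date(2018, 2, 16),
    2019: dt.date(2019, 2, 5),
    2020: dt.date(2020, 1, 25),
}


@dataclass(frozen=True)
class HolidayCalendar:
    """Winter label → first day of the Lunar New Year holiday.

    Entries must fall in January or February.  A December date references the
    upcoming holiday (its winter's label), so each Dec-Apr window sees exactly
    one holiday.
    """

    holidays: dict[int, dt.date] = field(default_factory=lambda: dict(_DEFAULT_HOLIDAYS))

    def __post_init__(self) -> None:
        for year, day in self.holidays.items():
            if day.month not in (1, 2):
                raise ValidationError(
                    f"holiday for {year} is {day}; must fall in January or February"
                )
            if winter_label(day) != year:
                raise ValidationError(f"holiday {day} does not belong to winter {year}")

    @classmethod
    def default(cls) -> "HolidayCalendar":
        return cls()

    def holiday_start(self, label: int) -> dt.date:
        try:
            return self.holidays[label]
        except KeyError:
            raise CalendarError(
                f"no Lunar New Year holiday entry for winter season {label}"
            ) from None


def day_lunar(date: dt.date | pd.Timestamp, cal: HolidayCalendar) -> int:
    """Signed calendar-day distance to the holiday's first day.

    Returns 0 on the first holiday day, negative before it, positive after
    (e.g. with a 27 January start, 26-28 January map to -1, 0, +1).
    """
    d = pd.Timestamp(date).date()
    return (d - cal.holiday_start(winter_label(d))).days


def build_features(
    series: CityDailySeries, cal: HolidayCalendar | None = None
) -> pd.DataFrame:
    """Assemble the feature table: one row per day, date-indexed.

    Columns are the four time variables, the four meteorological variables,
    the ``no2`` response and a boolean ``incomplete`` flag marking rows with
    any missing predictor or response.  Flagged rows are retained (they keep
    the calendar accounting honest) but are excluded from model fitting.
    """
    if len(series) == 0:
        raise ValidationError(f"{series.city_id}: empty series")
    cal = cal or HolidayCalendar.default()

    f = series.indexed()
    dates = f.index
    out = pd.DataFrame(index=dates)
    out["year"] = [winter_label(d.date()) for d in dates]
    out["day_julian"] = dates.dayofyear
    out["weekday"] = dates.dayofweek + 1  # 1=Monday ... 7=Sunday
    out["day_lunar"] = [day_lunar(d, cal) for d in dates]
    for col in MET_COLUMNS:
        out[col] = f[col]
    out["no2"] = f["no2"]
    out["incomplete"] = out[list(ALL_PREDICTORS) + ["no2"]].isna().any(axis=1)
    return out


def complete_rows(features: pd.DataFrame) -> pd.DataFrame:
    """The fit-ready subset: rows with every predictor and the response."""
    return features.loc[~features["incomplete"]]
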