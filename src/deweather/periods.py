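"""Study-period bookkeeping: winter analysis windows and the lockdown phases.

The analysis is organised around "winters" running 1 December to 30 April and
labelled by the calendar year containing the April end (the 2016-12-01 to
2017-04-30 window is winter 2017).  The intervention winter (2020) is split
into three contiguous phases:

* BLP, before-lockdown: 2019-12-01 to 2020-01-22
* DLP, during-lockdown: 2020-01-23 to 2020-03-18 (56 days)
* ALP, after-lockdown: 2020-03-19 to 2020-04-30

The three preceding winters (2017, 2018, 2019) are the reference period the
business-as-usual models are trained on.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

__all__ = ["DateInterval", "PeriodScheme", "winter_label", "DEFAULT_SCHEME"]


def winter_label(date: dt.date) -> int:
    """Label a date with its winter season (year of the season's April end).

    December dates belong to the following year's winter; any month from July
    onward is treated the same way so labels are total over the calendar.
    """
    return date.year + 1 if date.month >= 7 else date.year


@dataclass(frozen=True)
class DateInterval:
    """A closed interval of calendar dates."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"interval end {self.end} precedes start {self.start}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")

    def __contains__(self, date: object) -> bool:
        d = pd.Timestamp(date).date()  # Timestamp subclasses date; normalise both
        return self.start <= d <= self.end

    def map_to_winter(self, label: int) -> pd.DatetimeIndex:
        """Project the interval onto another winter by month-day identity.

        Feb 29 is dropped when the target winter's February has no leap day.
        """
        out = []
        for ts in self.dates():
            year = label - 1 if ts.month >= 12 else label
            try:
                out.append(pd.Timestamp(year=year, month=ts.month, day=ts.day))
            except ValueError:  # Feb 29 into a non-leap year
                continue
        return pd.DatetimeIndex(out)


def _winter_interval(label: int) -> DateInterval:
    return DateInterval(dt.date(label - 1, 12, 1), dt.date(label, 4, 30))


@dataclass(frozen=True)
class PeriodScheme:
    """The pre/during/post lockdown windows and the reference winters.

    Defaults follow the national timeline: lockdown begins with Wuhan's
    closure on 23 January 2020 and ends 18 March 2020.  Per-city overrides are
    expressed by constructing a different scheme for that city.
    """

    pre_lockdown: DateInterval = DateInterval(dt.date(2019, 12, 1), dt.date(2020, 1, 22))
    lockdown: DateInterval = DateInterval(dt.date(2020, 1, 23), dt.date(2020, 3, 18))
    post_lockdown: DateInterval = DateInterval(dt.date(2020, 3, 19), dt.date(2020, 4, 30))
    reference_winters: tuple[int, ...] = (2017, 2018, 2019)

    def __post_init__(self) -> None:
        if self.lockdown.start != self.pre_lockdown.end + dt.timedelta(days=1):
            raise ValidationError("pre_lockdown and lockdown must be contiguous")
        if self.post_lockdown.start != self.lockdown.end + dt.timedelta(days=1):
            raise ValidationError("lockdown and post_lockdown must be contiguous")
        if len(self.reference_winters) == 0:
            raise ValidationError("reference_winters must be non-empty")
        if winter_label(self.pre_lockdown.start) != self.analysis_winter:
            raise ValidationError("the three phases must fall inside one winter")

    @property
    def analysis_winter(self) -> int:
        """Winter label of the intervention season (2020 under defaults)."""
        return winter_label(self.lockdown.end)

    @property
    def study_winters(self) -> tuple[int, ...]:
        return tuple(sorted(self.reference_winters)) + (self.analysis_winter,)

    def winter_window(self, label: int) -> DateInterval:
        """The Dec 1 - Apr 30 window of a given winter."""
        return _winter_interval(label)

    def phases(self) -> dict[str, DateInterval]:
        return {
            "pre_lockdown": self.pre_lockdown,
            "lockdown": self.lockdown,
            "post_lockdown": self.post_lockdown,
        }


DEFAULT_SCHEME = PeriodScheme()
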