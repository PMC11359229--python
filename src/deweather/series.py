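"""The core in-memory container: one city's aligned daily record.

A :class:`CityDailySeries` holds a pandas DataFrame with one row per calendar
day and the five measured columns — NO2 concentration (µg/m³, may be missing)
plus the four meteorological drivers (wind speed m/s, wind direction degrees,
temperature °C, relative humidity %).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["CityDailySeries", "MET_COLUMNS", "DATA_COLUMNS"]

MET_COLUMNS = ("wind_speed", "wind_direction", "temperature", "relative_humidity")
DATA_COLUMNS = ("no2",) + MET_COLUMNS


@dataclass
class CityDailySeries:
    """Daily pollutant + meteorology record for one city.

    Parameters
    ----------
    city_id:
        Label for the city (used in reports and error messages).
    frame:
        DataFrame with a ``date`` column (datetime-like) and the columns in
        :data:`DATA_COLUMNS`.  Dates must be strictly increasing with no
        duplicates; ``no2`` may contain NaN for missing days.
    """

    city_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in ("date",) + DATA_COLUMNS if c not in f.columns]
        if missing:
            raise ValidationError(f"{self.city_id}: missing columns {missing}")
        f = f.copy()
        f["date"] = pd.to_datetime(f["date"])
        if f["date"].duplicated().any():
            dup = f.loc[f["date"].duplicated(), "date"].iloc[0].date()
            raise ValidationError(f"{self.city_id}: duplicate date {dup}")
        if not f["date"].is_monotonic_increasing:
            f = f.sort_values("date", ignore_index=True)
        wd = f["wind_direction"].dropna()
        if ((wd < 0) | (wd >= 360)).any():
            raise ValidationError(f"{self.city_id}: wind_direction outside [0, 360)")
        rh = f["relative_humidity"].dropna()
        if ((rh < 0) | (rh > 100)).any():
            raise ValidationError(f"{self.city_id}: relative_humidity outside [0, 100]")
        if (f["no2"].dropna() < 0).any():
            raise ValidationError(f"{self.city_id}: negative no2 concentration")
        self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["date"])

    def indexed(self) -> pd.DataFrame:
        """The frame indexed by date (copy)."""
        return self.frame.set_index("date")

    def no2_between(self, interval) -> pd.Series:
        """NO2 values (date-indexed, NaN kept) within a DateInterval."""
        idx = self.indexed()
        mask = (idx.index >= pd.Timestamp(interval.start)) & (
            idx.index <= pd.Timestamp(interval.end)
        )
        return idx.loc[mask, "no2"]

    def equals(self, other: "CityDailySeries", *, atol: float = 0.0) -> bool:
        if self.city_id != other.city_id or len(self) != len(other):
            return False
        a, b = self.frame, other.frame
        if not a["date"].equals(b["date"]):
            return False
        for col in DATA_COLUMNS:
            x, y = a[col].to_numpy(float), b[col].to_numpy(float)
            same_nan = np.isnan(x) == np.isnan(y)
            close = np.isclose(x, y, atol=atol, rtol=0.0, equal_nan=True)
            if not (same_nan.all() and close.all()):
                return False
        return True
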