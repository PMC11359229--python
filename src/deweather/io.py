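"""Reading/writing the canonical daily tables and matching sites to weather stations.

The canonical interchange format is one comma-delimited file per city with
columns ``date,no2,wind_speed,wind_direction,temperature,relative_humidity``,
ISO-8601 dates and empty cells for missing values.  Importers are provided
for long-format station weather archives (station, date, element, value with
per-element unit scaling, the layout of GHCN-Daily extracts) and for matching
each air-quality site to its nearest weather station by great-circle
distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .series import DATA_COLUMNS, MET_COLUMNS, CityDailySeries

__all__ = [
    "read_daily_city_table",
    "write_daily_city_table",
    "StationRecord",
    "great_circle_km",
    "match_nearest_station",
    "pivot_weather",
    "aggregate_city_sites",
]

log = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

# physical plausibility bounds; violations become missing, with a logged count
_BOUNDS = {
    "no2": (0.0, 1000.0),
    "wind_speed": (0.0, 75.0),
    "wind_direction": (0.0, 360.0),  # half-open upper bound
    "temperature": (-90.0, 60.0),
    "relative_humidity": (0.0, 100.0),
}


def write_daily_city_table(series: CityDailySeries, path: str | Path) -> Path:
    """Write a series in the canonical format (ISO dates, empty = missing)."""
    path = Path(path)
    out = series.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.6g")
    return path


def read_daily_city_table(path: str | Path, city_id: str | None = None) -> CityDailySeries:
    """Read a canonical daily city table.

    Out-of-range values (negative concentration, humidity above 100, ...) are
    set to missing and counted in the log rather than rejected wholesale;
    rows are returned sorted by date.
    """
    path = Path(path)
    table = pd.read_csv(path)
    missing_cols = [c for c in ("date",) + DATA_COLUMNS if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"{path.name}: missing mandatory columns {missing_cols}")
    try:
        table["date"] = pd.to_datetime(table["date"], format="ISO8601")
    except ValueError as exc:
        raise ValidationError(f"{path.name}: unparseable date ({exc})") from None

    rejected = 0
    for col, (lo, hi) in _BOUNDS.items():
        vals = table[col].astype(float)
        if col == "wind_direction":
            bad = vals.notna() & ((vals < lo) | (vals >= hi))
        else:
            bad = vals.notna() & ((vals < lo) | (vals > hi))
        if bad.any():
            rejected += int(bad.sum())
            vals[bad] = np.nan
        table[col] = vals
    if rejected:
        log.warning("%s: %d out-of-range values set to missing", path.name, rejected)

    table = table.sort_values("date", ignore_index=True)
    return CityDailySeries(city_id or path.stem, table)


def aggregate_city_sites(site_tables: dict[str, pd.DataFrame], city_id: str) -> CityDailySeries:
    """Combine several monitoring-site tables into one city series.

    The city-level value for each day and variable is the unweighted mean
    over sites reporting that day.
    """
    if not site_tables:
        raise ValidationError(f"{city_id}: no site tables supplied")
    frames = []
    for sid, tab in site_tables.items():
        t = tab.copy()
        t["date"] = pd.to_datetime(t["date"])
        frames.append(t.set_index("date")[list(DATA_COLUMNS)])
    stacked = pd.concat(frames)
    daily = stacked.groupby(level=0).mean().reset_index()
    return CityDailySeries(city_id, daily)


@dataclass(frozen=True)
class StationRecord:
    """A monitoring or weather station with its coordinates."""

    station_id: str
    latitude: float
    longitude: float
    kind: str = "weather"  # {"air_quality", "weather"}

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValidationError(f"{self.station_id}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValidationError(f"{self.station_id}: longitude {self.longitude} out of range")


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance on a spherical Earth (R = 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def match_nearest_station(
    site: StationRecord, candidates: list[StationRecord]
) -> StationRecord:
    """The candidate with minimal great-circle distance; ties → smaller id."""
    if not candidates:
        raise ValidationError(f"{site.station_id}: empty candidate station list")
    return min(
        candidates,
        key=lambda c: (
            great_circle_km(site.latitude, site.longitude, c.latitude, c.longitude),
            c.station_id,
        ),
    )


def pivot_weather(
    table: pd.DataFrame, station_id: str, unit_map: dict[str, tuple[str, float]]
) -> pd.DataFrame:
    """Pivot a long (station, date, element, value) table to daily wide rows.

    ``unit_map`` maps source element codes to ``(canonical_name, scale)``,
    e.g. ``{"TAVG": ("temperature", 0.1)}`` for tenths-of-degree conventions.
    Unknown element codes are skipped with a warning; duplicate
    (station, date, element) triples are an error.  Output columns are the
    four canonical meteorology variables (m/s, degrees, °C, %), with NaN
    where an element is absent for a date.
    """
    required = {"station_id", "date", "element", "value"}
    if not required.issubset(table.columns):
        raise ValidationError(f"long weather table needs columns {sorted(required)}")
    sub = table.loc[table["station_id"] == station_id].copy()
    sub["date"] = pd.to_datetime(sub["date"])
    dup = sub.duplicated(subset=["date", "element"])
    if dup.any():
        row = sub.loc[dup].iloc[0]
        raise ValidationError(
            f"duplicate element record: ({station_id}, {row['date'].date()}, {row['element']})"
        )
    unknown = sorted(set(sub["element"]) - set(unit_map))
    if unknown:
        log.warning("%s: skipping unknown element codes %s", station_id, unknown)
        sub = sub.loc[sub["element"].isin(unit_map)]

    sub["canonical"] = sub["element"].map(lambda e: unit_map[e][0])
    sub["scaled"] = [v * unit_map[e][1] for e, v in zip(sub["element"], sub["value"])]
    wide = sub.pivot(index="date", columns="canonical", values="scaled")
    for col in MET_COLUMNS:
        if col not in wide.columns:
            wide[col] = np.nan
    return wide[list(MET_COLUMNS)].sort_index()
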