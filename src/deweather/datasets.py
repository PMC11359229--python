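"""Bundled reference tables.

``load_table2`` returns the published 31-city table of lockdown NO2
concentration reductions (µg/m³, signed, negative = reduction) estimated by
the machine-learning and difference-to-difference approaches — the in-study
benchmark the cohort summary is checked against.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .errors import ValidationError

__all__ = ["load_table2", "read_estimates_table"]


def read_estimates_table(path_or_buf) -> pd.DataFrame:
    """Read a per-city estimates table (header-driven, column order free)."""
    table = pd.read_csv(path_or_buf)
    missing = [c for c in ("city_id", "delta_ml", "delta_d2d") if c not in table.columns]
    if missing:
        raise ValidationError(f"estimates table missing columns {missing}")
    return table


def load_table2() -> pd.DataFrame:
    """The packaged 31-city reduction table (city_id, delta_ml, delta_d2d)."""
    resource = files("deweather.data").joinpath("table2_no2_reductions.csv")
    with resource.open("r") as fh:
        return read_estimates_table(fh)
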