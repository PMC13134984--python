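"""Reading and writing daily fields as CSV and NetCDF.

CSV is the primary interchange format (long form: cell_id, year, doy,
tmin, tmax). NetCDF export goes through xarray's scipy backend with a
``365_day`` calendar attribute; the time coordinate is the integer day
index into the no-leap series, with year/doy stored as auxiliary
variables, so files round-trip without any special calendar library.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import InvalidArgumentError
from .synthetic import TemperatureField


def field_to_csv(field: TemperatureField, path) -> Path:
    path = Path(path)
    field.to_dataframe().to_csv(path, index=False, float_format="%.4f")
    return path


def field_from_csv(path) -> TemperatureField:
    df = pd.read_csv(path)
    cells = np.sort(df["cell_id"].unique())
    first = df[df["cell_id"] == cells[0]].sort_values(["year", "doy"])
    years = first["year"].to_numpy()
    doys = first["doy"].to_numpy()
    n_days = len(years)
    tmin = np.empty((len(cells), n_days))
    tmax = np.empty((len(cells), n_days))
    for i, cid in enumerate(cells):
        sub = df[df["cell_id"] == cid].sort_values(["year", "doy"])
        if len(sub) != n_days:
            raise InvalidArgumentError(f"cell {cid} has a ragged series")
        tmin[i] = sub["tmin"].to_numpy()
        tmax[i] = sub["tmax"].to_numpy()
    return TemperatureField(cells, years, doys, tmin, tmax)


def field_to_dataset(field: TemperatureField) -> xr.Dataset:
    time_index = np.arange(field.n_days)
    ds = xr.Dataset(
        {
            "tmin": (("cell", "time"), field.tmin, {"units": "degC"}),
            "tmax": (("cell", "time"), field.tmax, {"units": "degC"}),
        },
        coords={
            "cell": ("cell", field.cell_ids),
            "time": (
                "time",
                time_index,
                {
                    "units": f"days since {int(field.years[0])}-01-01",
                    "calendar": "365_day",
                },
            ),
            "year": ("time", field.years),
            "doy": ("time", field.doys),
        },
        attrs={"calendar": "365_day", "conventions": "CF-like"},
    )
    return ds


def field_to_netcdf(field: TemperatureField, path) -> Path:
    path = Path(path)
    field_to_dataset(field).to_netcdf(path, engine="scipy")
    return path


def field_from_netcdf(path) -> TemperatureField:
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        return TemperatureField(
            ds["cell"].values.astype(int),
            ds["year"].values.astype(int),
            ds["doy"].values.astype(int),
            np.array(ds["tmin"].values),
            np.array(ds["tmax"].values),
        )
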