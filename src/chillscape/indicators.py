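"""Per-cell per-season agroclimatic indicators from a daily field.

Glue between the daily :class:`~chillscape.synthetic.TemperatureField`
containers and the hourly accumulation models: reconstructs hourly
temperatures (in day-chunks to bound memory), slices the fixed chill and
heat windows for every season, and returns tidy tables. Seasons are
labelled by harvest year: season Y spans Nov 1 of Y−1 through the spring
of Y.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frost import last_frost_doy
from .synthetic import TemperatureField
from .thermal import (
    CHILL_WINDOW,
    HEAT_WINDOW,
    chill_accumulate,
    gdh_hour,
    window_day_mask,
)
from .solar import hourly_series

_CHUNK_DAYS = 1500


def hourly_field(field: TemperatureField, lats: np.ndarray) -> np.ndarray:
    """Hourly array (n_cells, n_days, 24) for a whole daily field."""
    n_days = field.n_days
    out = np.empty((field.n_cells, n_days, 24))
    for start in range(0, n_days, _CHUNK_DAYS):
        stop = min(start + _CHUNK_DAYS, n_days)
        lo = max(start - 1, 0)  # one-day halo for night-curve continuity
        hi = min(stop + 1, n_days)
        block = hourly_series(
            field.tmin[:, lo:hi], field.tmax[:, lo:hi], lats, field.doys[lo:hi]
        )
        out[:, start:stop] = block[:, start - lo : start - lo + (stop - start)]
    return out


def available_seasons(field: TemperatureField) -> list[int]:
    """Harvest years whose chill and heat windows are fully covered."""
    years = np.unique(field.years)
    seasons = []
    for y in years:
        try:
            chill_ok = window_day_mask(field.years, field.doys, y - 1, CHILL_WINDOW)
            heat_ok = window_day_mask(field.years, field.doys, y - 1, HEAT_WINDOW)
        except Exception:  # pragma: no cover - defensive
            continue
        if chill_ok.sum() == CHILL_WINDOW.n_days and heat_ok.sum() == HEAT_WINDOW.n_days:
            seasons.append(int(y))
    return seasons


def seasonal_indicators(
    field: TemperatureField, lats: np.ndarray, seasons: list[int] | None = None
) -> pd.DataFrame:
    """Chill portions and GDH per cell and season (harvest-year label)."""
    if seasons is None:
        seasons = available_seasons(field)
    hourly = hourly_field(field, lats)
    n_cells = field.n_cells
    chill_stack = np.empty((n_cells, len(seasons), CHILL_WINDOW.n_days * 24))
    heat_stack = np.empty((n_cells, len(seasons), HEAT_WINDOW.n_days * 24))
    for j, season in enumerate(seasons):
        cmask = window_day_mask(field.years, field.doys, season - 1, CHILL_WINDOW)
        hmask = window_day_mask(field.years, field.doys, season - 1, HEAT_WINDOW)
        chill_stack[:, j] = hourly[:, cmask].reshape(n_cells, -1)
        heat_stack[:, j] = hourly[:, hmask].reshape(n_cells, -1)
    cp = chill_accumulate(chill_stack)
    gdh = gdh_hour(heat_stack).sum(axis=-1)
    return pd.DataFrame(
        {
            "cell_id": np.repeat(field.cell_ids, len(seasons)),
            "season": np.tile(seasons, n_cells),
            "cp": cp.ravel(),
            "gdh": gdh.ravel(),
        }
    )


def seasonal_last_frosts(
    field: TemperatureField, seasons: list[int] | None = None
) -> pd.DataFrame:
    """Last-frost events per cell and season from daily Tmin.

    Columns: cell_id, season, last_frost_doy (NaN when frost-free),
    previous_year (autumn-only frost flag).
    """
    if seasons is None:
        seasons = available_seasons(field)
    rows = []
    for cid in field.cell_ids:
        series = field.series(int(cid))
        for season in seasons:
            event = last_frost_doy(series, season)
            rows.append(
                {
                    "cell_id": int(cid),
                    "season": season,
                    "last_frost_doy": np.nan if event is None else event.doy,
                    "previous_year": bool(event.previous_year) if event else False,
                }
            )
    return pd.DataFrame(rows)
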