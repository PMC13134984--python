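"""Synthetic daily temperature generator with known ground truth.

Emulates the statistical structure of a 1 km observational temperature grid
and of a coarse climate-model ensemble: an elevation-lapsed annual cycle,
AR(1) day-to-day noise shared between Tmin and Tmax, independent
perturbations of the diurnal half-range, and — for model members — additive
and multiplicative biases plus a linear scenario warming trend. Because
every component is known in closed form, downstream stages (bias
correction, anomaly attribution, sign tests) can be validated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .calendar365 import noleap_daily_index
from .errors import AlignmentError, InvalidArgumentError
from .grid import GridDefinition

#: day-of-year of the warmest day of the annual cycle (mid July)
DOY_PEAK = 197
#: first year from which the scenario warming trend is counted
TREND_PIVOT_YEAR = 2006
#: multiplier applied to ``warming_per_decade`` per scenario
SCENARIO_TREND_FACTOR = {"hist": 0.0, "rcp45": 1.0, "rcp85": 2.0}

_OBS_STREAM = 0
_MEMBER_STREAM = 1


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of the synthetic climate, all in °C unless noted.

    ``noise_sd`` is the marginal (stationary) standard deviation of the
    AR(1) daily temperature anomaly; the innovation variance is derived
    from it and ``ar1_rho``. ``warming_per_decade`` is the RCP4.5 rate;
    RCP8.5 applies twice that (see :data:`SCENARIO_TREND_FACTOR`).
    """

    annual_mean_at_sea_level: float = 16.5
    seasonal_amplitude: float = 8.5
    lapse_rate: float = 6.5  # °C per km
    diurnal_range_mean: float = 10.0
    ar1_rho: float = 0.7
    noise_sd: float = 2.0
    warming_per_decade: float = 0.3
    model_bias_add: float = 1.0
    model_bias_mult: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diurnal_range_mean <= 0:
            raise InvalidArgumentError("diurnal_range_mean must be > 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if not 0 <= self.ar1_rho < 1:
            raise InvalidArgumentError("ar1_rho must be in [0, 1)")


@dataclass
class DailySeries:
    """Daily Tmin/Tmax for one cell on the gap-free no-leap calendar."""

    cell_id: int
    years: np.ndarray
    doys: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray

    @property
    def n_days(self) -> int:
        return len(self.years)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "year": self.years,
                "doy": self.doys,
                "tmin": self.tmin,
                "tmax": self.tmax,
            }
        )


@dataclass
class TemperatureField:
    """Daily Tmin/Tmax for a whole grid: arrays of shape (n_cells, n_days).

    The canonical in-memory container the rest of the pipeline consumes;
    per-cell :class:`DailySeries` views are available via :meth:`series`.
    """

    cell_ids: np.ndarray
    years: np.ndarray
    doys: np.ndarray
    tmin: np.ndarray
    tmax: np.ndarray

    def __post_init__(self) -> None:
        if self.tmin.shape != self.tmax.shape or self.tmin.shape != (
            len(self.cell_ids),
            len(self.years),
        ):
            raise AlignmentError("tmin/tmax shape must be (n_cells, n_days)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_days(self) -> int:
        return len(self.years)

    def series(self, cell_id: int) -> DailySeries:
        (i,) = np.nonzero(self.cell_ids == cell_id)
        if len(i) != 1:
            raise InvalidArgumentError(f"unknown cell_id {cell_id}")
        i = int(i[0])
        return DailySeries(cell_id, self.years, self.doys, self.tmin[i], self.tmax[i])

    def to_dataframe(self) -> pd.DataFrame:
        n_c, n_d = self.tmin.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, n_d),
                "year": np.tile(self.years, n_c),
                "doy": np.tile(self.doys, n_c),
                "tmin": self.tmin.ravel(),
                "tmax": self.tmax.ravel(),
            }
        )


def _seasonal_cycle(doys: np.ndarray, amplitude: float) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (doys - DOY_PEAK) / 365.0)


def _ar1_noise(
    rng: np.random.Generator, n_cells: int, n_days: int, rho: float, sd: float
) -> np.ndarray:
    """Stationary AR(1) noise, marginal sd ``sd``, per cell."""
    if sd == 0:
        return np.zeros((n_cells, n_days))
    innov = rng.standard_normal((n_cells, n_days)) * sd * np.sqrt(1.0 - rho**2)
    innov[:, 0] = rng.standard_normal(n_cells) * sd  # stationary start
    return lfilter([1.0], [1.0, -rho], innov, axis=1)


def _simulate_process(
    grid: GridDefinition,
    start_year: int,
    end_year: int,
    params: SyntheticParams,
    rng: np.random.Generator,
) -> TemperatureField:
    years, doys = noleap_daily_index(start_year, end_year)
    base = (
        params.annual_mean_at_sea_level
        - params.lapse_rate * grid.elevation / 1000.0
    )[:, None]
    tmean = (
        base
        + _seasonal_cycle(doys, params.seasonal_amplitude)[None, :]
        + _ar1_noise(rng, grid.n_cells, len(years), params.ar1_rho, params.noise_sd)
    )
    half = params.diurnal_range_mean / 2.0
    pert_sd = 0.5 * params.noise_sd
    dmin = pert_sd * rng.standard_normal(tmean.shape) if pert_sd > 0 else 0.0
    dmax = pert_sd * rng.standard_normal(tmean.shape) if pert_sd > 0 else 0.0
    tmin = tmean - half + dmin
    tmax = tmean + half + dmax
    lo = np.minimum(tmin, tmax)  # enforce tmax >= tmin by swapping
    hi = np.maximum(tmin, tmax)
    return TemperatureField(grid.cell_id.copy(), years, doys, lo, hi)


def simulate_daily_obs(
    grid: GridDefinition, start_year: int, end_year: int, params: SyntheticParams
) -> TemperatureField:
    """Observation-like daily Tmin/Tmax on the fine grid.

    Per cell, Tmean(d) = annual mean − lapse·elev/1000 + seasonal cosine +
    AR(1) noise; Tmin/Tmax sit half a diurnal range below/above Tmean with
    independent perturbations, swapped where needed so tmax ≥ tmin.
    Bit-reproducible for a fixed ``params.seed``.
    """
    if end_year < start_year:
        raise InvalidArgumentError("end_year must be >= start_year")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, _OBS_STREAM]))
    return _simulate_process(grid, start_year, end_year, params, rng)


def simulate_model_ensemble(
    grid_coarse: GridDefinition,
    start_year: int,
    end_year: int,
    params: SyntheticParams,
    n_members: int,
    scenario: str = "hist",
) -> list[TemperatureField]:
    """Biased, trend-bearing model members on the coarse grid.

    Each member is an independent draw of the observation process (member
    seeds derived deterministically from ``params.seed``), transformed as
    ``value + bias_add + (bias_mult − 1)·(value − cell mean) + trend(year)``
    where the trend is linear per decade from :data:`TREND_PIVOT_YEAR`
    (zero for the ``hist`` scenario).
    """
    if n_members < 1:
        raise InvalidArgumentError("n_members must be >= 1")
    if scenario not in SCENARIO_TREND_FACTOR:
        raise InvalidArgumentError(
            f"unknown scenario {scenario!r}; expected one of "
            f"{sorted(SCENARIO_TREND_FACTOR)}"
        )
    factor = SCENARIO_TREND_FACTOR[scenario]
    base = (
        params.annual_mean_at_sea_level
        - params.lapse_rate * grid_coarse.elevation / 1000.0
    )[:, None]
    members: list[TemperatureField] = []
    scen_code = sorted(SCENARIO_TREND_FACTOR).index(scenario)
    for m in range(n_members):
        # stream depends on member, scenario and span: runs are independent
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [params.seed, _MEMBER_STREAM, m, scen_code, start_year]
            )
        )
        field = _simulate_process(grid_coarse, start_year, end_year, params, rng)
        trend = (
            factor
            * params.warming_per_decade
            * (field.years - TREND_PIVOT_YEAR)
            / 10.0
        )[None, :]
        mult = params.model_bias_mult
        tmin = base + mult * (field.tmin - base) + params.model_bias_add + trend
        tmax = base + mult * (field.tmax - base) + params.model_bias_add + trend
        members.append(
            TemperatureField(field.cell_ids, field.years, field.doys, tmin, tmax)
        )
    return members


def truth_without_bias(
    grid_coarse: GridDefinition,
    start_year: int,
    end_year: int,
    params: SyntheticParams,
    n_members: int,
    scenario: str = "hist",
) -> list[TemperatureField]:
    """Same member realizations with biases removed — the recovery target."""
    clean = replace(params, model_bias_add=0.0, model_bias_mult=1.0)
    return simulate_model_ensemble(
        grid_coarse, start_year, end_year, clean, n_members, scenario
    )
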