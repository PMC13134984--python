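"""End-to-end orchestration: simulate → regrid → bias-correct → indicators
→ anomalies → change indices → bivariate densities.

The pipeline mirrors a regional agroclimatic study design: a fine
observational grid provides the 1971-2000 reference climate; a coarse
model ensemble (historical + scenario runs) is bilinearly regridded to
the fine grid, bias-corrected per member with empirical quantile mapping,
and turned into chill-portion, growing-degree-hour and spring-frost
indicators whose changes are expressed as standardized anomalies.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .anomaly import ClimatePeriod, anomalies, change_indices_table, period_stats
from .density import kde2d, q5q95_filter, quartile_summary, spearman_rho
from .eqm import correct_field, self_adjust_diagnostics
from .errors import (
    AlignmentError,
    InsufficientSampleError,
    InvalidArgumentError,
    InvalidGridError,
)
from .frost import sfpo
from .grid import GridDefinition, coarsen, make_grid
from .indicators import seasonal_indicators, seasonal_last_frosts
from .synthetic import SyntheticParams, TemperatureField, simulate_daily_obs, simulate_model_ensemble

logger = logging.getLogger("chillscape")


class BilinearRegridder:
    """Bilinear interpolation from a coarse lattice to arbitrary fine cells.

    Fine coordinates are clamped to the coarse bounding box (nearest-edge
    extension), weights are precomputed once and reused for every day.
    Exact for any affine function of (lon, lat).
    """

    def __init__(self, coarse: GridDefinition, fine: GridDefinition):
        if not coarse.is_lattice() or coarse.nx < 2 or coarse.ny < 2:
            raise InvalidGridError("coarse grid must be a lattice of at least 2x2")
        nx, ny = coarse.nx, coarse.ny
        lon_axis = coarse.lon.reshape(ny, nx)[0]
        lat_axis = coarse.lat.reshape(ny, nx)[:, 0]
        x = np.clip(fine.lon, lon_axis[0], lon_axis[-1])
        y = np.clip(fine.lat, lat_axis[0], lat_axis[-1])
        ix = np.clip(np.searchsorted(lon_axis, x, side="right") - 1, 0, nx - 2)
        iy = np.clip(np.searchsorted(lat_axis, y, side="right") - 1, 0, ny - 2)
        fx = (x - lon_axis[ix]) / (lon_axis[ix + 1] - lon_axis[ix])
        fy = (y - lat_axis[iy]) / (lat_axis[iy + 1] - lat_axis[iy])
        self._idx = np.stack(
            [
                iy * nx + ix,
                iy * nx + ix + 1,
                (iy + 1) * nx + ix,
                (iy + 1) * nx + ix + 1,
            ]
        )
        self._w = np.stack(
            [(1 - fx) * (1 - fy), fx * (1 - fy), (1 - fx) * fy, fx * fy]
        )

    def __call__(self, coarse_values: np.ndarray) -> np.ndarray:
        """Map values (..., n_coarse) onto the fine cells (..., n_fine)."""
        v = np.asarray(coarse_values, dtype=float)
        return np.einsum("kf,...kf->...f", self._w, v[..., self._idx])

    def regrid_field(self, field: TemperatureField, fine: GridDefinition) -> TemperatureField:
        tmin = self(field.tmin.T).T
        tmax = self(field.tmax.T).T
        return TemperatureField(fine.cell_id.copy(), field.years, field.doys, tmin, tmax)


def regrid_bilinear(
    coarse_values: np.ndarray, coarse: GridDefinition, fine: GridDefinition
) -> np.ndarray:
    """One-shot bilinear regridding of values on the coarse grid."""
    return BilinearRegridder(coarse, fine)(coarse_values)


@dataclass
class EnsembleStats:
    """Per-cell per-day mean and sample sd across ensemble members."""

    cell_ids: np.ndarray
    years: np.ndarray
    doys: np.ndarray
    tmin_mean: np.ndarray
    tmin_sd: np.ndarray
    tmax_mean: np.ndarray
    tmax_sd: np.ndarray


def ensemble_stats(members: list[TemperatureField]) -> EnsembleStats:
    """Multimodel ensemble mean and sd of aligned member fields."""
    first = members[0]
    for m in members[1:]:
        if (
            not np.array_equal(m.cell_ids, first.cell_ids)
            or not np.array_equal(m.years, first.years)
            or not np.array_equal(m.doys, first.doys)
        ):
            raise AlignmentError("ensemble members must share cells and dates")
    tmin = np.stack([m.tmin for m in members])
    tmax = np.stack([m.tmax for m in members])
    ddof = 1 if len(members) > 1 else 0
    return EnsembleStats(
        first.cell_ids.copy(),
        first.years,
        first.doys,
        tmin.mean(axis=0),
        tmin.std(axis=0, ddof=ddof),
        tmax.mean(axis=0),
        tmax.std(axis=0, ddof=ddof),
    )


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run (defaults = the synthetic study)."""

    n_cells: int = 100
    obs_start: int = 1966
    obs_end: int = 2000
    calib_start: int = 1971
    calib_end: int = 2000
    scenarios: tuple[str, ...] = ("rcp45", "rcp85")
    future_periods: tuple[tuple[int, int], ...] = ((2041, 2070),)
    n_members: int = 2
    coarsen_k: int = 5
    fruit_fraction: float = 0.4
    lat_range: tuple[float, float] = (40.0, 42.5)
    elev_range: tuple[float, float] = (150.0, 1500.0)
    sfpo_threshold_doy: int = 60
    kde_bandwidth: float = 0.1
    seed: int = 0
    out_dir: str | None = None

    def synthetic_params(self) -> SyntheticParams:
        return SyntheticParams(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("scenarios",):
            if key in d:
                d[key] = tuple(d[key])
        if "future_periods" in d:
            d["future_periods"] = tuple(tuple(p) for p in d["future_periods"])
        for key in ("lat_range", "elev_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineResult:
    """Bundle of every table the pipeline produces."""

    grid: pd.DataFrame
    indicators: pd.DataFrame  # cell_id, season, cp, gdh, dataset
    sfpo_table: pd.DataFrame  # cell_id, dataset, period, n_seasons, sfpo
    anomaly_table: pd.DataFrame
    change_table: pd.DataFrame
    density_summary: pd.DataFrame
    eqm_diagnostics: pd.DataFrame
    out_dir: Path | None = None
    timings: dict = dc_field(default_factory=dict)


def _log_stage(name: str, t0: float, **counts) -> None:
    extras = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage %-14s %6.1fs  %s", name, time.perf_counter() - t0, extras)


def _calib_slice(field: TemperatureField, start: int, end: int) -> TemperatureField:
    mask = (field.years >= start) & (field.years <= end)
    return TemperatureField(
        field.cell_ids, field.years[mask], field.doys[mask],
        field.tmin[:, mask], field.tmax[:, mask],
    )


def _density_block(xcp, y, x_name, y_name, label, scenario, bandwidth):
    try:
        x_f, y_f = q5q95_filter(xcp, y)
    except InsufficientSampleError:
        logger.warning(
            "density %s-%s %s/%s skipped: fewer than 20 fruit-area pairs",
            x_name, y_name, scenario, label,
        )
        return None
    rho = spearman_rho(x_f, y_f)
    q1, q2, q3, iqr = quartile_summary(x_f)
    surface = kde2d(x_f, y_f, bandwidth=bandwidth)
    return {
        "pair": f"{x_name}-{y_name}",
        "period": label,
        "scenario": scenario,
        "n_pairs": len(x_f),
        "rho": rho,
        "x_q1": q1,
        "x_q2": q2,
        "x_q3": q3,
        "x_iqr": iqr,
        "density_max": float(surface.density.max()),
    }


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and return (and optionally write) the bundle.

    Deterministic for a fixed ``config.seed``: reruns produce
    byte-identical CSV output.
    """
    if config.calib_start < config.obs_start or config.calib_end > config.obs_end:
        raise InvalidArgumentError("calibration window must lie within the obs span")
    timings: dict[str, float] = {}
    params = config.synthetic_params()

    t0 = time.perf_counter()
    fine = make_grid(
        config.n_cells,
        lat_range=config.lat_range,
        elev_range=config.elev_range,
        fruit_fraction=config.fruit_fraction,
        seed=config.seed,
    )
    coarse = coarsen(fine, config.coarsen_k)
    regridder = BilinearRegridder(coarse, fine)
    obs = simulate_daily_obs(fine, config.obs_start, config.obs_end, params)
    _log_stage("simulate-obs", t0, cells=fine.n_cells, days=obs.n_days)
    timings["simulate_obs"] = time.perf_counter() - t0

    # --- observational indicators and reference statistics ----------------
    t0 = time.perf_counter()
    lats = fine.lat
    obs_ind = seasonal_indicators(obs, lats)
    obs_ind["dataset"] = "obs"
    obs_frost = seasonal_last_frosts(obs)
    ref_period = ClimatePeriod(
        f"{config.calib_start}-{config.calib_end}",
        config.calib_start,
        config.calib_end,
    )
    _log_stage("obs-indicators", t0, seasons=obs_ind["season"].nunique())
    timings["obs_indicators"] = time.perf_counter() - t0

    # --- model historical runs: regrid + EQM calibration ------------------
    t0 = time.perf_counter()
    hist_members = simulate_model_ensemble(
        coarse, config.calib_start - 1, config.calib_end, params,
        config.n_members, "hist",
    )
    hist_fine = [regridder.regrid_field(m, fine) for m in hist_members]
    obs_calib = _calib_slice(obs, config.calib_start, config.calib_end)
    hist_calib = [
        _calib_slice(m, config.calib_start, config.calib_end) for m in hist_fine
    ]
    diag_rows = []
    for i, m in enumerate(hist_calib):
        for var in ("tmin", "tmax"):
            d = self_adjust_diagnostics(
                getattr(obs_calib, var).ravel(), getattr(m, var).ravel()
            ).before_after()
            d.insert(0, "member", i)
            d.insert(1, "variable", var)
            diag_rows.append(d)
    eqm_diag = pd.concat(diag_rows, ignore_index=True)
    _log_stage("bias-calib", t0, members=config.n_members)
    timings["bias_calibration"] = time.perf_counter() - t0

    # --- scenario runs: simulate, regrid, correct, indicators --------------
    indicator_tables = [obs_ind]
    sfpo_rows = []
    for cid, sub in obs_frost.groupby("cell_id"):
        ref_sub = sub[sub["season"].isin(set(ref_period.years))]
        events = [
            None if np.isnan(r.last_frost_doy)
            else (0 if r.previous_year else int(r.last_frost_doy))
            for r in ref_sub.itertuples()
        ]
        est = sfpo(events, config.sfpo_threshold_doy, cell_id=int(cid))
        sfpo_rows.append(
            {
                "cell_id": int(cid),
                "dataset": "obs",
                "scenario": "hist",
                "period": ref_period.label,
                "n_seasons": est.n_seasons,
                "sfpo": est.probability,
            }
        )

    scenario_periods: list[tuple[str, ClimatePeriod]] = []
    for scenario in config.scenarios:
        for start, end in config.future_periods:
            period = ClimatePeriod(f"{start}-{end}", start, end, scenario)
            scenario_periods.append((scenario, period))
            t0 = time.perf_counter()
            members = simulate_model_ensemble(
                coarse, start - 1, end, params, config.n_members, scenario
            )
            frost_events_by_cell: dict[int, list] = {
                int(c): [] for c in fine.cell_id
            }
            for i, member in enumerate(members):
                fine_member = regridder.regrid_field(member, fine)
                corrected, _ = correct_field(obs_calib, hist_calib[i], fine_member)
                ind = seasonal_indicators(corrected, lats)
                ind["dataset"] = f"{scenario}:{period.label}:m{i}"
                indicator_tables.append(ind)
                frost = seasonal_last_frosts(corrected)
                for cid, sub in frost.groupby("cell_id"):
                    frost_events_by_cell[int(cid)].extend(
                        None if np.isnan(r.last_frost_doy)
                        else (0 if r.previous_year else int(r.last_frost_doy))
                        for r in sub.itertuples()
                    )
            for cid, events in frost_events_by_cell.items():
                est = sfpo(events, config.sfpo_threshold_doy, cell_id=cid)
                sfpo_rows.append(
                    {
                        "cell_id": cid,
                        "dataset": "ensemble",
                        "scenario": scenario,
                        "period": period.label,
                        "n_seasons": est.n_seasons,
                        "sfpo": est.probability,
                    }
                )
            _log_stage(f"scenario-{scenario}", t0, period=period.label)
            timings[f"scenario_{scenario}_{period.label}"] = (
                time.perf_counter() - t0
            )

    indicators = pd.concat(indicator_tables, ignore_index=True)
    sfpo_table = pd.DataFrame(sfpo_rows)

    # --- anomalies and change indices --------------------------------------
    t0 = time.perf_counter()
    anomaly_frames = []
    for ind_name in ("cp", "gdh"):
        obs_long = obs_ind.rename(columns={ind_name: "value"})[
            ["cell_id", "season", "value"]
        ]
        ref_stats = period_stats(obs_long, ref_period)
        ref_anom = anomalies(ref_stats, ref_stats)
        ref_anom["indicator"] = ind_name
        ref_anom["scenario"] = "hist"
        anomaly_frames.append(ref_anom)
        for scenario, period in scenario_periods:
            member_mask = indicators["dataset"].str.startswith(
                f"{scenario}:{period.label}:"
            )
            fut_long = indicators[member_mask].rename(columns={ind_name: "value"})
            fut_stats = (
                fut_long.groupby("cell_id")["value"]
                .agg(["mean", "std"])
                .rename(columns={"std": "sd"})
                .reset_index()
            )
            fut_stats["period"] = period.label
            anom = anomalies(fut_stats, ref_stats)
            anom["indicator"] = ind_name
            anom["scenario"] = scenario
            anomaly_frames.append(anom)
    anomaly_table = pd.concat(anomaly_frames, ignore_index=True)

    # SFPO: delta changes only (a probability has no interannual sd here)
    sfpo_ref = sfpo_table[sfpo_table["dataset"] == "obs"][["cell_id", "sfpo"]]
    sfpo_fut = sfpo_table[sfpo_table["dataset"] == "ensemble"].merge(
        sfpo_ref.rename(columns={"sfpo": "sfpo_ref"}), on="cell_id"
    )
    sfpo_fut["delta"] = sfpo_fut["sfpo"] - sfpo_fut["sfpo_ref"]

    future_anoms = anomaly_table[anomaly_table["scenario"] != "hist"]
    change_table = change_indices_table(future_anoms)
    _log_stage("anomalies", t0, rows=len(anomaly_table))
    timings["anomalies"] = time.perf_counter() - t0

    # --- bivariate densities over fruit cells -------------------------------
    t0 = time.perf_counter()
    fruit_ids = set(fine.cell_id[fine.fruit_area])
    density_rows = []
    ref_stats_by_ind = {}
    for ind_name in ("cp", "gdh"):
        obs_long = obs_ind.rename(columns={ind_name: "value"})[
            ["cell_id", "season", "value"]
        ]
        ref_stats_by_ind[ind_name] = period_stats(obs_long, ref_period).set_index(
            "cell_id"
        )["mean"]
    fruit_index = [c for c in fine.cell_id if c in fruit_ids]
    cp_ref = ref_stats_by_ind["cp"].loc[fruit_index].to_numpy()
    gdh_ref = ref_stats_by_ind["gdh"].loc[fruit_index].to_numpy()
    sfpo_ref_fruit = (
        sfpo_ref.set_index("cell_id")["sfpo"].loc[fruit_index].to_numpy()
    )
    for block in (
        _density_block(cp_ref, gdh_ref, "cp", "gdh", ref_period.label, "hist",
                       config.kde_bandwidth),
        _density_block(cp_ref, sfpo_ref_fruit, "cp", "sfpo", ref_period.label,
                       "hist", config.kde_bandwidth),
    ):
        if block is not None:
            density_rows.append(block)
    for scenario, period in scenario_periods:
        member_mask = indicators["dataset"].str.startswith(
            f"{scenario}:{period.label}:"
        )
        fut = indicators[member_mask].groupby("cell_id")[["cp", "gdh"]].mean()
        cp_fut = fut["cp"].loc[fruit_index].to_numpy()
        gdh_fut = fut["gdh"].loc[fruit_index].to_numpy()
        sf = sfpo_table[
            (sfpo_table["scenario"] == scenario)
            & (sfpo_table["period"] == period.label)
        ].set_index("cell_id")["sfpo"].loc[fruit_index].to_numpy()
        for block in (
            _density_block(cp_fut, gdh_fut, "cp", "gdh", period.label, scenario,
                           config.kde_bandwidth),
            _density_block(cp_fut, sf, "cp", "sfpo", period.label, scenario,
                           config.kde_bandwidth),
        ):
            if block is not None:
                density_rows.append(block)
    density_summary = pd.DataFrame(density_rows)
    _log_stage("density", t0, blocks=len(density_rows))
    timings["density"] = time.perf_counter() - t0

    sfpo_out = pd.concat(
        [
            sfpo_table[sfpo_table["dataset"] == "obs"].assign(
                sfpo_ref=np.nan, delta=np.nan
            ),
            sfpo_fut,
        ],
        ignore_index=True,
    )

    result = PipelineResult(
        grid=fine.to_dataframe(),
        indicators=indicators,
        sfpo_table=sfpo_out,
        anomaly_table=anomaly_table,
        change_table=change_table,
        density_summary=density_summary,
        eqm_diagnostics=eqm_diag,
        timings=timings,
    )
    if config.out_dir is not None:
        result.out_dir = write_bundle(result, config)
    return result


def write_bundle(result: PipelineResult, config: PipelineConfig) -> Path:
    """Write every table as deterministic CSV plus a config/timing JSON."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "grid.csv": result.grid,
        "indicators.csv": result.indicators,
        "sfpo.csv": result.sfpo_table,
        "anomalies.csv": result.anomaly_table,
        "change_indices.csv": result.change_table,
        "density_summary.csv": result.density_summary,
        "eqm_diagnostics.csv": result.eqm_diagnostics,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False, float_format="%.6f")
    meta = {"config": asdict(config), "timings": result.timings}
    (out / "run_meta.json").write_text(json.dumps(meta, indent=2, default=str))
    return out
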