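"""Empirical quantile mapping (EQM) bias correction.

A transfer function is calibrated per cell and variable over a common
historical window (1971-2000 in the study design): empirical quantiles of
the observed and the model-historical series are taken at probability
knots 0, 0.05, …, 1. Correcting a value means locating its relative
quantile in the model distribution and reading off the observed quantile
at the same probability; beyond the calibrated range a constant additive
correction from the nearest end knot is applied. The method assumes the
model bias is stationary in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CalibrationMismatchError, InsufficientSampleError
from .synthetic import TemperatureField

#: default probability knots: resolution 0.05, endpoints included
DEFAULT_PROBS = np.round(np.linspace(0.0, 1.0, 21), 2)


def empirical_quantiles(values, probs=DEFAULT_PROBS) -> np.ndarray:
    """Linear-rank-interpolated empirical quantiles at ``probs``."""
    values = np.asarray(values, dtype=float).ravel()
    probs = np.asarray(probs, dtype=float)
    if values.size < len(probs):
        raise InsufficientSampleError(
            f"need at least {len(probs)} values, got {values.size}"
        )
    if np.any((probs < 0) | (probs > 1)):
        raise InsufficientSampleError("probs must lie within [0, 1]")
    return np.quantile(values, probs, method="linear")


@dataclass
class QuantileTransfer:
    """Calibrated quantile-mapping transfer for one cell and variable."""

    probs: np.ndarray
    obs_q: np.ndarray
    mod_q: np.ndarray
    cell_id: int = -1
    variable: str = "tmin"
    calibration: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name in ("probs", "obs_q", "mod_q"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.obs_q) < 0) or np.any(np.diff(self.mod_q) < 0):
            raise CalibrationMismatchError("quantile knots must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "variable": self.variable,
                "prob": self.probs,
                "obs_q": self.obs_q,
                "mod_q": self.mod_q,
            }
        )


def build_transfer(
    obs,
    mod_hist,
    probs=DEFAULT_PROBS,
    cell_id: int = -1,
    variable: str = "tmin",
    calibration: tuple[int, int] | None = None,
) -> QuantileTransfer:
    """Calibrate a transfer from equal-length obs and model-historical series."""
    obs = np.asarray(obs, dtype=float).ravel()
    mod_hist = np.asarray(mod_hist, dtype=float).ravel()
    if obs.size != mod_hist.size:
        raise CalibrationMismatchError(
            f"calibration series differ in length: {obs.size} vs {mod_hist.size}"
        )
    return QuantileTransfer(
        probs=np.asarray(probs, dtype=float),
        obs_q=empirical_quantiles(obs, probs),
        mod_q=empirical_quantiles(mod_hist, probs),
        cell_id=cell_id,
        variable=variable,
        calibration=calibration,
    )


def apply_transfer(transfer: QuantileTransfer, values) -> np.ndarray:
    """Map ``values`` through the transfer (monotone, rank-preserving).

    Inside the calibrated range this is linear interpolation between the
    knot pairs; outside, the additive correction of the nearest end knot.
    """
    x = np.asarray(values, dtype=float)
    out = np.interp(x, transfer.mod_q, transfer.obs_q)
    lo, hi = transfer.mod_q[0], transfer.mod_q[-1]
    out = np.where(x < lo, x + (transfer.obs_q[0] - lo), out)
    out = np.where(x > hi, x + (transfer.obs_q[-1] - hi), out)
    return out


@dataclass
class QuantileDiagnostics:
    """q5/q50/q95 of obs, raw model, and self-adjusted model."""

    obs: dict = field(default_factory=dict)
    model_raw: dict = field(default_factory=dict)
    model_adjusted: dict = field(default_factory=dict)

    _LEVELS = (0.05, 0.50, 0.95)

    def before_after(self) -> pd.DataFrame:
        rows = []
        for q in self._LEVELS:
            rows.append(
                {
                    "quantile": q,
                    "obs": self.obs[q],
                    "model_raw": self.model_raw[q],
                    "model_adjusted": self.model_adjusted[q],
                    "diff_before": self.model_raw[q] - self.obs[q],
                    "diff_after": self.model_adjusted[q] - self.obs[q],
                }
            )
        return pd.DataFrame(rows)


def self_adjust_diagnostics(
    obs, mod_raw, probs=DEFAULT_PROBS
) -> QuantileDiagnostics:
    """Re-correct the calibration model series itself and compare quantiles.

    Running the historical model series through its own transfer should
    reproduce the observed q5/q50/q95; the before/after differences
    quantify how much bias the mapping removes.
    """
    transfer = build_transfer(obs, mod_raw, probs)
    adjusted = apply_transfer(transfer, np.asarray(mod_raw, dtype=float))
    levels = QuantileDiagnostics._LEVELS
    qs = lambda v: dict(zip(levels, np.quantile(np.ravel(v), levels)))  # noqa: E731
    return QuantileDiagnostics(
        obs=qs(obs), model_raw=qs(mod_raw), model_adjusted=qs(adjusted)
    )


def correct_field(
    obs_calib: TemperatureField,
    mod_calib: TemperatureField,
    mod_future: TemperatureField,
    probs=DEFAULT_PROBS,
) -> tuple[TemperatureField, list[QuantileTransfer]]:
    """Bias-correct a whole model field cell by cell.

    Tmin and Tmax are corrected independently with their own transfers;
    any corrected pair with tmax < tmin is repaired by swapping. The three
    fields must share the cell ordering; the calibration fields must share
    dates.
    """
    if not np.array_equal(obs_calib.cell_ids, mod_calib.cell_ids) or not np.array_equal(
        obs_calib.cell_ids, mod_future.cell_ids
    ):
        raise CalibrationMismatchError("fields must share cell ids and order")
    out_tmin = np.empty_like(mod_future.tmin)
    out_tmax = np.empty_like(mod_future.tmax)
    transfers: list[QuantileTransfer] = []
    for i, cid in enumerate(obs_calib.cell_ids):
        for var, obs_v, mod_v, fut_v, out in (
            ("tmin", obs_calib.tmin[i], mod_calib.tmin[i], mod_future.tmin[i], out_tmin),
            ("tmax", obs_calib.tmax[i], mod_calib.tmax[i], mod_future.tmax[i], out_tmax),
        ):
            tr = build_transfer(obs_v, mod_v, probs, cell_id=int(cid), variable=var)
            out[i] = apply_transfer(tr, fut_v)
            transfers.append(tr)
    lo = np.minimum(out_tmin, out_tmax)
    hi = np.maximum(out_tmin, out_tmax)
    corrected = TemperatureField(
        mod_future.cell_ids.copy(),
        mod_future.years,
        mod_future.doys,
        lo,
        hi,
    )
    return corrected, transfers
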