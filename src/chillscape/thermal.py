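"""Winter-chill (Dynamic Model) and spring-heat (GDH) accumulation.

The Dynamic Model treats chill as a two-step chemical kinetic process: low
temperatures build an intermediate product (which heat can destroy); once
the intermediate crosses a fixed threshold it is irreversibly banked as one
chill portion (CP). Growing degree hours (GDH) accumulate heat between a
base of 4 °C and a critical 36 °C with a cosine response peaking at the
26 °C optimum. Both run on hourly temperatures over fixed seasonal
windows: chill from November 1 to February 28 (120 no-leap days), heat
from February 1 to March 31 (59 days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calendar365 import doy_noleap
from .errors import InvalidArgumentError, MissingDataError


@dataclass(frozen=True)
class DynamicModelParams:
    """Kinetic constants of the Dynamic Model (canonical published set)."""

    slp: float = 1.6
    tetmlt: float = 277.0  # K, transition temperature
    a0: float = 1.395e5
    a1: float = 2.567e18
    e0: float = 4153.5  # K
    e1: float = 12888.8  # K
    kelvin_offset: float = 273.0

    def __post_init__(self) -> None:
        if not (self.e1 > self.e0 and self.a1 > self.a0 > 0):
            raise InvalidArgumentError("require e1 > e0 and a1 > a0 > 0")


DEFAULT_DYNAMIC = DynamicModelParams()


@dataclass
class ChillState:
    """State of the chill recursion after some number of hourly steps.

    ``xi_prev`` is the transfer fraction evaluated at the previous hour's
    temperature; the published recursion needs it whenever the
    intermediate exceeds one, so it is carried in the state.
    """

    intermediate_E: float = 0.0
    portions: float = 0.0
    xi_prev: float = 0.0


def _kinetics(temp_c: np.ndarray, p: DynamicModelParams):
    """Per-temperature quantities (xi, xs, ak1) of the recursion."""
    tk = np.asarray(temp_c, dtype=float) + p.kelvin_offset
    sr = np.exp(p.slp * p.tetmlt * (tk - p.tetmlt) / tk)
    xi = sr / (1.0 + sr)
    xs = (p.a0 / p.a1) * np.exp((p.e1 - p.e0) / tk)
    ak1 = p.a1 * np.exp(-p.e1 / tk)
    return xi, xs, ak1


def chill_step(
    state: ChillState, temp_c: float, params: DynamicModelParams = DEFAULT_DYNAMIC
) -> ChillState:
    """Advance the Dynamic Model by one hour at ``temp_c`` °C."""
    if not np.isfinite(temp_c) or not -50.0 <= temp_c <= 60.0:
        raise InvalidArgumentError("temperature must be finite and within [-50, 60] °C")
    xi, xs, ak1 = _kinetics(temp_c, params)
    e_prev = state.intermediate_E
    s = e_prev if e_prev < 1.0 else e_prev * (1.0 - state.xi_prev)
    e_new = xs - (xs - s) * np.exp(-ak1)
    delivered = xi * e_new if e_new >= 1.0 else 0.0
    return ChillState(
        intermediate_E=float(e_new),
        portions=state.portions + float(delivered),
        xi_prev=float(xi),
    )


def chill_accumulate(
    temps: np.ndarray, params: DynamicModelParams = DEFAULT_DYNAMIC
) -> np.ndarray:
    """Total chill portions along the last axis of an hourly array.

    Vectorized over leading axes: ``temps`` of shape (..., n_hours) gives
    portions of shape (...). Identical, to floating-point roundoff, to
    iterating :func:`chill_step` hour by hour from a zero state.
    """
    temps = np.asarray(temps, dtype=float)
    if not np.all(np.isfinite(temps)):
        raise InvalidArgumentError("non-finite temperature in hourly series")
    lead = temps.shape[:-1]
    n_hours = temps.shape[-1]
    xi_all, xs_all, ak1_all = _kinetics(temps, params)
    decay = np.exp(-ak1_all)
    e = np.zeros(lead)
    xi_prev = np.zeros(lead)
    portions = np.zeros(lead)
    for t in range(n_hours):
        over = e >= 1.0
        s = np.where(over, e * (1.0 - xi_prev), e)
        e = xs_all[..., t] - (xs_all[..., t] - s) * decay[..., t]
        portions += np.where(e >= 1.0, xi_all[..., t] * e, 0.0)
        xi_prev = xi_all[..., t]
    return portions


@dataclass(frozen=True)
class GdhParams:
    """Cardinal temperatures (°C) of the growing-degree-hour response."""

    base: float = 4.0
    optimum: float = 26.0
    critical: float = 36.0
    stress: float = 1.0  # multiplicative stress factor F

    def __post_init__(self) -> None:
        if not self.base < self.optimum < self.critical:
            raise InvalidArgumentError("require base < optimum < critical")


DEFAULT_GDH = GdhParams()


def gdh_hour(temp_c, params: GdhParams = DEFAULT_GDH) -> float | np.ndarray:
    """Degree-hours contributed by one hour at ``temp_c`` °C.

    Cosine response: 0 at the 4 °C base, maximal (optimum − base = 22) at
    26 °C, back to 0 at the 36 °C critical temperature, and exactly zero
    outside [base, critical]. Continuous everywhere.
    """
    t = np.asarray(temp_c, dtype=float)
    tb, tu, tc, f = params.base, params.optimum, params.critical, params.stress
    below = f * ((tu - tb) / 2.0) * (1.0 + np.cos(np.pi + np.pi * (t - tb) / (tu - tb)))
    above = f * (tu - tb) * (
        1.0 + np.cos(np.pi / 2.0 + (np.pi / 2.0) * (t - tu) / (tc - tu))
    )
    out = np.where(t <= tu, below, above)
    out = np.where((t < tb) | (t > tc), 0.0, out)
    return float(out) if np.isscalar(temp_c) else out


@dataclass(frozen=True)
class AccumulationWindow:
    """A fixed month-day window within a season crossing the new year."""

    start_month: int
    start_day: int
    end_month: int
    end_day: int
    label: str

    @property
    def start_doy(self) -> int:
        return doy_noleap(self.start_month, self.start_day)

    @property
    def end_doy(self) -> int:
        return doy_noleap(self.end_month, self.end_day)

    def crosses_new_year(self) -> bool:
        return self.start_doy > self.end_doy

    @property
    def n_days(self) -> int:
        if self.crosses_new_year():
            return 365 - self.start_doy + 1 + self.end_doy
        return self.end_doy - self.start_doy + 1


#: chill window Nov 1 – Feb 28: 120 no-leap days = 2880 hours
CHILL_WINDOW = AccumulationWindow(11, 1, 2, 28, "chill")
#: heat window Feb 1 – Mar 31: 59 days = 1416 hours
HEAT_WINDOW = AccumulationWindow(2, 1, 3, 31, "heat")


def window_day_mask(
    years: np.ndarray, doys: np.ndarray, season_year: int, window: AccumulationWindow
) -> np.ndarray:
    """Boolean day mask of ``window`` for the season starting in ``season_year``.

    For a window crossing the new year the start months fall in
    ``season_year`` and the end months in ``season_year + 1``; otherwise
    the whole window lies in ``season_year + 1`` (the harvest year).
    """
    if window.crosses_new_year():
        return ((years == season_year) & (doys >= window.start_doy)) | (
            (years == season_year + 1) & (doys <= window.end_doy)
        )
    return (
        (years == season_year + 1)
        & (doys >= window.start_doy)
        & (doys <= window.end_doy)
    )


def _window_hours(hourly, years, doys, season_year, window):
    mask = window_day_mask(np.asarray(years), np.asarray(doys), season_year, window)
    n_found = int(mask.sum())
    if n_found != window.n_days:
        raise MissingDataError(
            f"window {window.label!r} of season {season_year} needs "
            f"{window.n_days} days, found {n_found}"
        )
    sub = np.asarray(hourly)[..., mask, :]
    return sub.reshape(sub.shape[:-2] + (window.n_days * 24,))


def accumulate_chill_portions(
    hourly: np.ndarray,
    years: np.ndarray,
    doys: np.ndarray,
    season_year: int,
    window: AccumulationWindow = CHILL_WINDOW,
    params: DynamicModelParams = DEFAULT_DYNAMIC,
) -> float | np.ndarray:
    """Chill portions over one season's window from a zero state.

    ``hourly`` has shape (..., n_days, 24) aligned with ``years``/``doys``;
    incomplete coverage raises :class:`~chillscape.errors.MissingDataError`.
    """
    temps = _window_hours(hourly, years, doys, season_year, window)
    out = chill_accumulate(temps, params)
    return float(out) if out.ndim == 0 else out


def accumulate_gdh(
    hourly: np.ndarray,
    years: np.ndarray,
    doys: np.ndarray,
    season_year: int,
    window: AccumulationWindow = HEAT_WINDOW,
    params: GdhParams = DEFAULT_GDH,
) -> float | np.ndarray:
    """Growing degree hours summed over one season's heat window."""
    temps = _window_hours(hourly, years, doys, season_year, window)
    out = np.sum(gdh_hour(temps, params), axis=-1)
    return float(out) if np.ndim(out) == 0 else out
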