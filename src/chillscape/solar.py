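"""Solar geometry and hourly temperature reconstruction.

Hourly temperatures are rebuilt from daily extremes with the classic
diurnal-curve model used throughout horticultural chill research: a sine
rise from sunrise to the daily maximum and a logarithmic nocturnal decline
from sunset towards the following day's minimum, with sunrise/sunset from
the Spencer Fourier series for solar declination. Pre-sunrise hours
continue the previous day's night curve so the series is continuous across
days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateDaylengthError,
    InvalidArgumentError,
    UnsupportedLatitudeError,
)

#: maximum |latitude| (degrees) before polar day/night breaks the geometry
POLAR_LAT_LIMIT = 66.0
#: stretch (hours) added to daylength in the sine denominator, placing the
#: daily maximum two hours after solar noon for a 12 h day
SINE_STRETCH_H = 4.0


@dataclass(frozen=True)
class SunTimes:
    """Sunrise, sunset and daylength (solar hours) for one day."""

    doy: int
    sunrise: float
    sunset: float

    @property
    def daylength(self) -> float:
        return self.sunset - self.sunrise


def solar_declination(doy) -> float | np.ndarray:
    """Solar declination (radians) from the Spencer Fourier series.

    ``doy`` is the 1-365 day of the no-leap year; scalar or array.
    """
    doy_arr = np.asarray(doy)
    if np.any((doy_arr < 1) | (doy_arr > 365)):
        raise InvalidArgumentError("doy must be within 1-365")
    g = 2.0 * np.pi * (doy_arr - 1) / 365.0
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return float(decl) if np.isscalar(doy) else decl


def _sun_geometry(lat, doys):
    """(sunrise, sunset, daylength) arrays for lat (…,1) × doys (n,)."""
    lat_arr = np.atleast_1d(np.asarray(lat, dtype=float))
    if np.any(np.abs(lat_arr) > POLAR_LAT_LIMIT):
        raise UnsupportedLatitudeError(
            f"|latitude| must be <= {POLAR_LAT_LIMIT} degrees"
        )
    decl = solar_declination(np.atleast_1d(doys))
    cos_ws = np.clip(
        -np.tan(np.deg2rad(lat_arr))[:, None] * np.tan(decl)[None, :], -1.0, 1.0
    )
    daylength = np.arccos(cos_ws) * 24.0 / np.pi
    sunrise = 12.0 - daylength / 2.0
    sunset = 12.0 + daylength / 2.0
    return sunrise, sunset, daylength


def sun_times(lat: float, doy: int) -> SunTimes:
    """Sunrise/sunset/daylength at latitude ``lat`` (degrees) on ``doy``."""
    sunrise, sunset, _ = _sun_geometry(lat, doy)
    return SunTimes(int(doy), float(sunrise[0, 0]), float(sunset[0, 0]))


def night_curve(ts: float, tmin_next: float, night_length: float, n) -> np.ndarray:
    """Temperature ``n`` hours after sunset on the logarithmic night curve.

    Anchored at the sunset temperature ``ts`` and reaching ``tmin_next``
    exactly at ``n = night_length``; ``n`` starts at 1 to avoid ln(0).
    """
    if night_length <= 1:
        raise DegenerateDaylengthError("night shorter than one hour")
    n_arr = np.clip(np.asarray(n, dtype=float), 1.0, night_length)
    return ts - (ts - tmin_next) * np.log(n_arr) / np.log(night_length)


def hourly_series(
    tmin: np.ndarray, tmax: np.ndarray, lat, doys: np.ndarray
) -> np.ndarray:
    """Hourly temperatures for every cell and day.

    Parameters
    ----------
    tmin, tmax : arrays (n_cells, n_days)
    lat : array (n_cells,) latitude in degrees
    doys : array (n_days,) no-leap day-of-year per column

    Returns an array of shape (n_cells, n_days, 24) on the integer solar
    hour grid 0-23. The first day's pre-sunrise hours and the last day's
    night use the same day's values as the missing neighbour.
    """
    tmin = np.atleast_2d(np.asarray(tmin, dtype=float))
    tmax = np.atleast_2d(np.asarray(tmax, dtype=float))
    if np.any(tmax < tmin):
        raise InvalidArgumentError("tmax < tmin in input")
    sunrise, sunset, daylength = _sun_geometry(lat, doys)
    if np.any(daylength < SINE_STRETCH_H):
        raise DegenerateDaylengthError("daylength below 4 h")
    night_len = 24.0 - daylength
    if np.any(night_len <= 1.0):
        raise DegenerateDaylengthError("night shorter than one hour")

    trange = tmax - tmin
    # temperature at sunset on the day curve (night-curve anchor)
    ts = tmin + trange * np.sin(np.pi * daylength / (daylength + SINE_STRETCH_H))

    # previous/next day values with edge replication
    tmin_next = np.concatenate([tmin[:, 1:], tmin[:, -1:]], axis=1)
    tmin_prev_day = tmin  # current day's own Tmin is the pre-sunrise target
    ts_prev = np.concatenate([ts[:, :1], ts[:, :-1]], axis=1)
    sunset_prev = np.concatenate([sunset[:, :1], sunset[:, :-1]], axis=1)
    night_prev = np.concatenate([night_len[:, :1], night_len[:, :-1]], axis=1)

    h = np.arange(24.0)[None, None, :]
    sr = sunrise[:, :, None]
    ss = sunset[:, :, None]
    dl = daylength[:, :, None]
    nl = night_len[:, :, None]

    t_day = tmin[:, :, None] + trange[:, :, None] * np.sin(
        np.pi * (h - sr) / (dl + SINE_STRETCH_H)
    )

    n_post = np.clip(h - ss, 1.0, nl)
    t_post = ts[:, :, None] - (ts[:, :, None] - tmin_next[:, :, None]) * (
        np.log(n_post) / np.log(nl)
    )

    n_pre = np.clip(h + 24.0 - sunset_prev[:, :, None], 1.0, night_prev[:, :, None])
    t_pre = ts_prev[:, :, None] - (
        ts_prev[:, :, None] - tmin_prev_day[:, :, None]
    ) * (np.log(n_pre) / np.log(night_prev[:, :, None]))

    out = np.where(h < sr, t_pre, np.where(h > ss, t_post, t_day))
    return out


def hourly_from_daily(
    tmin_prev: float,
    tmax_prev: float,
    tmin: float,
    tmax: float,
    tmin_next: float,
    tmax_next: float,
    lat: float,
    doy: int,
) -> np.ndarray:
    """The 24 hourly temperatures of one day given its two neighbours."""
    for lo, hi in ((tmin_prev, tmax_prev), (tmin, tmax), (tmin_next, tmax_next)):
        if hi < lo:
            raise InvalidArgumentError("tmax < tmin in day triplet")
    doys = np.array([(doy - 2) % 365 + 1, doy, doy % 365 + 1])  # wrap the year
    tmin_a = np.array([[tmin_prev, tmin, tmin_next]])
    tmax_a = np.array([[tmax_prev, tmax, tmax_next]])
    return hourly_series(tmin_a, tmax_a, [lat], doys)[0, 1, :]
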