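"""365-day ("no-leap") calendar arithmetic.

The whole pipeline runs on a calendar with every February 29 removed, so
day-of-year (DOY) indices are uniform across years: March 1 is always day
60, December 31 is always day 365, and a 30-year daily series always has
10,950 records.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidDateError

DAYS_IN_MONTH = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
#: cumulative days before each month (index 0 unused)
_CUM = np.concatenate([[0, 0], np.cumsum(DAYS_IN_MONTH)[:-1]])

DAYS_PER_YEAR = 365


def doy_noleap(month: int, day: int) -> int:
    """Day-of-year (1-365) of ``month``/``day`` in the no-leap calendar.

    ``doy_noleap(3, 1) == 60``; February 29 raises
    :class:`~chillscape.errors.InvalidDateError`.
    """
    month = int(month)
    day = int(day)
    if not 1 <= month <= 12:
        raise InvalidDateError(f"month {month} out of range 1-12")
    if month == 2 and day == 29:
        raise InvalidDateError("February 29 does not exist in the 365-day calendar")
    if not 1 <= day <= DAYS_IN_MONTH[month - 1]:
        raise InvalidDateError(f"day {day} out of range for month {month}")
    return int(_CUM[month]) + day


def month_day_from_doy(doy: int) -> tuple[int, int]:
    """Inverse of :func:`doy_noleap`."""
    doy = int(doy)
    if not 1 <= doy <= DAYS_PER_YEAR:
        raise InvalidDateError(f"doy {doy} out of range 1-365")
    month = int(np.searchsorted(_CUM[2:], doy, side="left")) + 1
    return month, doy - int(_CUM[month])


def noleap_daily_index(start_year: int, end_year: int) -> tuple[np.ndarray, np.ndarray]:
    """Gap-free (year, doy) arrays covering ``start_year``..``end_year``."""
    if end_year < start_year:
        raise InvalidDateError("end_year before start_year")
    n_years = end_year - start_year + 1
    years = np.repeat(np.arange(start_year, end_year + 1), DAYS_PER_YEAR)
    doys = np.tile(np.arange(1, DAYS_PER_YEAR + 1), n_years)
    return years, doys


def drop_leap_days(obj, date_col: str = "date"):
    """Remove every February 29 from a real-calendar daily record.

    Accepts a :class:`pandas.DataFrame` with a datetime column ``date_col``,
    a :class:`pandas.DatetimeIndex`, or anything ``pandas.to_datetime``
    understands. Returns the same kind of object with Feb 29 rows removed
    and all other records preserved in order.
    """
    if isinstance(obj, pd.DataFrame):
        dates = pd.to_datetime(obj[date_col])
        keep = ~((dates.dt.month == 2) & (dates.dt.day == 29))
        return obj.loc[keep.to_numpy()]
    dates = pd.DatetimeIndex(pd.to_datetime(obj))
    keep = ~((dates.month == 2) & (dates.day == 29))
    return dates[keep]


def noleap_doy_of_dates(dates) -> np.ndarray:
    """No-leap DOY for real calendar dates (Feb 29 must be absent)."""
    dates = pd.DatetimeIndex(pd.to_datetime(dates))
    if bool(((dates.month == 2) & (dates.day == 29)).any()):
        raise InvalidDateError("series still contains February 29")
    return np.array(
        [doy_noleap(m, d) for m, d in zip(dates.month, dates.day)], dtype=int
    )
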