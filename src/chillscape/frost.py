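"""Last spring frost extraction and frost-probability statistics.

The spring frost probability of occurrence (SFPO) is the empirical
probability, over seasons, that the last day with Tmin ≤ 0 °C falls after
March 1 (day 60 of the no-leap year). Seasons span October through June;
a season whose only frosts fall in October–December carries a large DOY
from the previous calendar year and is treated as having no spring frost,
and frost-free seasons count in the denominator but never in the
numerator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.distributions.empirical_distribution import ECDF

from .calendar365 import doy_noleap
from .errors import EmptySampleError, MissingDataError
from .synthetic import DailySeries

FROST_THRESHOLD_C = 0.0
MARCH1_DOY = doy_noleap(3, 1)  # 60

_SEASON_START_DOY = doy_noleap(10, 1)  # Oct 1
_SEASON_END_DOY = doy_noleap(6, 30)  # Jun 30


@dataclass(frozen=True)
class LastFrost:
    """Last frost of a season: its DOY and which calendar year it fell in."""

    doy: int
    previous_year: bool = False  # True when the frost was in Oct–Dec


@dataclass(frozen=True)
class SfpoEstimate:
    cell_id: int
    probability: float
    n_seasons: int
    threshold_doy: int = MARCH1_DOY


def last_frost_doy(series: DailySeries, season_year: int) -> LastFrost | None:
    """Last day with Tmin ≤ 0 °C in the Oct–Jun season ending in ``season_year``.

    Prefers the January–June segment of ``season_year``; if that segment is
    frost-free but October–December of the previous year was not, returns
    the autumn DOY flagged ``previous_year=True``. Returns ``None`` for a
    frost-free season. The series must fully cover Oct 1 (year − 1)
    through Jun 30 (year).
    """
    years = np.asarray(series.years)
    doys = np.asarray(series.doys)
    spring = (years == season_year) & (doys <= _SEASON_END_DOY)
    autumn = (years == season_year - 1) & (doys >= _SEASON_START_DOY)
    if spring.sum() != _SEASON_END_DOY or autumn.sum() != 365 - _SEASON_START_DOY + 1:
        raise MissingDataError(
            f"season {season_year} not fully covered (Oct 1 of "
            f"{season_year - 1} through Jun 30 of {season_year})"
        )
    tmin = np.asarray(series.tmin)
    frost_spring = spring & (tmin <= FROST_THRESHOLD_C)
    if frost_spring.any():
        return LastFrost(int(doys[frost_spring].max()), previous_year=False)
    frost_autumn = autumn & (tmin <= FROST_THRESHOLD_C)
    if frost_autumn.any():
        return LastFrost(int(doys[frost_autumn].max()), previous_year=True)
    return None


def empirical_cdf(values) -> ECDF:
    """Right-continuous empirical CDF: F(x) = #{v ≤ x} / n."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise EmptySampleError("empirical CDF of an empty sample")
    return ECDF(values)


def _effective_doy(event) -> float:
    """Map a season's last frost onto the spring-DOY axis.

    Frost-free seasons and autumn-only frosts land at 0, below any spring
    threshold, so they can never count as late frosts.
    """
    if event is None:
        return 0.0
    if isinstance(event, LastFrost):
        return 0.0 if event.previous_year else float(event.doy)
    return float(event)


def sfpo(
    last_frosts, threshold_doy: int = MARCH1_DOY, cell_id: int = -1
) -> SfpoEstimate:
    """Spring frost probability of occurrence: 1 − CDF(threshold).

    ``last_frosts`` is one entry per season: a :class:`LastFrost`, a plain
    DOY integer (taken as a spring frost of that season), or ``None`` for
    a frost-free season.
    """
    events = list(last_frosts)
    if not events:
        raise EmptySampleError("SFPO of an empty season collection")
    doys = np.array([_effective_doy(e) for e in events])
    # 1 - CDF(threshold) evaluated in exact counting arithmetic, so the
    # result equals the per-season indicator mean bit for bit
    n_after = int(len(doys) - round(empirical_cdf(doys)(threshold_doy) * len(doys)))
    prob = n_after / len(doys)
    return SfpoEstimate(
        cell_id=cell_id,
        probability=prob,
        n_seasons=len(events),
        threshold_doy=threshold_doy,
    )
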