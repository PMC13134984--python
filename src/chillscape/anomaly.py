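"""Overlapping climate periods, standardized anomalies, change indices.

Analysis periods are 30-year windows stepped by a decade. Per cell and
indicator, a period's mean is compared to the 1971-2000 reference: the
difference Δ and the standardized anomaly Sa = Δ / sd_ref, where sd_ref is
the interannual sample standard deviation of the reference period in that
cell. Across periods and scenarios three change indices summarize each
cell: magnitude (mean |Sa|), direction (mean Sa) and variability
(sample sd of Sa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientSampleError, InvalidRangeError, MissingDataError


@dataclass(frozen=True)
class ClimatePeriod:
    label: str
    start_year: int
    end_year: int
    scenario: str = "hist"

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @property
    def length(self) -> int:
        return self.end_year - self.start_year + 1


def moving_windows(
    first_year: int, last_year: int, length: int = 30, step: int = 10
) -> list[ClimatePeriod]:
    """Maximal set of ``length``-year windows stepped back from ``last_year``.

    (1950, 2020) yields the five classic windows 1951-1980 … 1991-2020.
    """
    if last_year - first_year + 1 < length:
        raise InvalidRangeError(
            f"span {first_year}-{last_year} shorter than window length {length}"
        )
    windows = []
    end = last_year
    while end - length + 1 >= first_year:
        start = end - length + 1
        windows.append(ClimatePeriod(f"{start}-{end}", start, end))
        end -= step
    windows.reverse()
    return windows


def period_stats(
    records: pd.DataFrame,
    period: ClimatePeriod,
    value_col: str = "value",
    season_col: str = "season",
) -> pd.DataFrame:
    """Per-cell mean and interannual sample sd over a period's seasons.

    ``records`` is long-form with columns cell_id, ``season_col`` (harvest
    year) and ``value_col``. Every season of the period must be present
    for every cell.
    """
    wanted = set(period.years)
    sub = records[records[season_col].isin(wanted)]
    counts = sub.groupby("cell_id")[season_col].nunique()
    bad = counts[counts != period.length]
    if len(bad) or sub.empty:
        missing = {}
        for cid in records["cell_id"].unique():
            have = set(sub.loc[sub["cell_id"] == cid, season_col])
            gap = sorted(wanted - have)
            if gap:
                missing[int(cid)] = gap
        raise MissingDataError(f"missing seasons per cell: {missing}")
    g = sub.groupby("cell_id")[value_col]
    out = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1)}).reset_index()
    out["period"] = period.label
    return out


def anomalies(
    stats: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Δ and Sa of period means relative to the reference period.

    ``stats`` and ``reference`` come from :func:`period_stats`. Cells with
    zero reference sd get Sa = NaN and ``sa_defined = False`` (Δ is still
    reported).
    """
    merged = stats.merge(
        reference[["cell_id", "mean", "sd"]].rename(
            columns={"mean": "ref_mean", "sd": "ref_sd"}
        ),
        on="cell_id",
        how="inner",
    )
    merged["delta"] = merged["mean"] - merged["ref_mean"]
    defined = merged["ref_sd"] > 0
    merged["sa"] = np.where(defined, merged["delta"] / merged["ref_sd"], np.nan)
    merged["sa_defined"] = defined
    return merged


def change_indices(sa_values) -> tuple[float, float, float]:
    """(magnitude, direction, variability) of a cell's anomaly collection."""
    sa = np.asarray(list(sa_values), dtype=float)
    if sa.size < 2:
        raise InsufficientSampleError("change indices need at least 2 anomalies")
    return (
        float(np.mean(np.abs(sa))),
        float(np.mean(sa)),
        float(np.std(sa, ddof=1)),
    )


def change_indices_table(anomaly_df: pd.DataFrame) -> pd.DataFrame:
    """Per-cell (and per-indicator, if present) change indices table."""
    keys = ["cell_id"] + (["indicator"] if "indicator" in anomaly_df else [])
    rows = []
    for key, sub in anomaly_df.groupby(keys):
        mag, direction, var = change_indices(sub["sa"].dropna())
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(magnitude=mag, direction=direction, variability=var)
        rows.append(row)
    return pd.DataFrame(rows)
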