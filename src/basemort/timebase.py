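"""ISO-8601 weekly calendar grid and time covariates.

Every other module works on a *week grid*: one row per ISO week, carrying

- ``iso_year``, ``iso_week`` — ISO-8601 year/week labels;
- ``weeks_in_year`` — 52 or 53 (53 for ISO "long" years, e.g. 2015, 2020);
- ``t_days`` — days since 1970-01-01 of the week's Monday (ISO weeks start on
  Monday; the epoch follows the convention of using actual time as the
  long-term-trend covariate);
- ``w`` — week of the year scaled to [0, 1): ``(iso_week - 1) / weeks_in_year``,
  so that a cyclic seasonal function never evaluates week 1 and the last week
  of the year at the same point.

A *weekly series* is a week grid plus a ``deaths`` column (and, for simulated
data, the true mean ``mu``).
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable

import numpy as np
import pandas as pd

_EPOCH = _dt.date(1970, 1, 1)

#: Column layout of the weekly-series CSV (also the fixture layout standing in
#: for Eurostat ``demo_r_mwk_ts``-style exports).
CSV_COLUMNS = ["iso_year", "iso_week", "deaths"]


def weeks_in_iso_year(year: int) -> int:
    """Number of ISO-8601 weeks (52 or 53) in ``year``.

    December 28 always lies in the last ISO week of its year.
    """
    return _dt.date(year, 12, 28).isocalendar()[1]


def scale_week(iso_week: int, weeks_in_year: int) -> float:
    """Scale a week-of-year to [0, 1): ``(iso_week - 1) / weeks_in_year``."""
    if weeks_in_year not in (52, 53):
        raise ValueError(f"weeks_in_year must be 52 or 53, got {weeks_in_year}")
    if not 1 <= iso_week <= weeks_in_year:
        raise ValueError(
            f"iso_week must be in 1..{weeks_in_year}, got {iso_week}"
        )
    return (iso_week - 1) / weeks_in_year


def build_week_grid(start_year: int, end_year: int) -> pd.DataFrame:
    """One row per ISO week of every ISO year in ``[start_year, end_year]``.

    Returns a DataFrame with columns ``iso_year, iso_week, weeks_in_year,
    t_days, w``. Consecutive rows differ by exactly 7 in ``t_days``.
    """
    if start_year < 1970:
        raise ValueError(f"start_year must be >= 1970, got {start_year}")
    if end_year < start_year:
        raise ValueError(
            f"end_year ({end_year}) must not precede start_year ({start_year})"
        )
    rows = []
    for year in range(start_year, end_year + 1):
        n_weeks = weeks_in_iso_year(year)
        for week in range(1, n_weeks + 1):
            monday = _dt.date.fromisocalendar(year, week, 1)
            rows.append(
                (
                    year,
                    week,
                    n_weeks,
                    (monday - _EPOCH).days,
                    scale_week(week, n_weeks),
                )
            )
    return pd.DataFrame(
        rows, columns=["iso_year", "iso_week", "weeks_in_year", "t_days", "w"]
    )


def yearly_totals(series: pd.DataFrame, years: Iterable[int]) -> pd.Series:
    """Sum weekly death counts per ISO year: ``M_y = sum_{t: y[t]=y} D_t``.

    Every requested year must be fully covered by the series (53-week years
    sum 53 values). Returns a Series indexed by year.
    """
    years = list(years)
    out = {}
    for year in years:
        rows = series.loc[series["iso_year"] == year]
        expected = weeks_in_iso_year(year)
        if len(rows) != expected:
            raise ValueError(
                f"year {year} is only partially covered: "
                f"{len(rows)} of {expected} ISO weeks present"
            )
        out[year] = rows["deaths"].sum()
    return pd.Series(out, dtype=float, name="deaths")


def write_weekly_csv(series: pd.DataFrame, path) -> None:
    """Write a weekly series as ``iso_year,iso_week,deaths`` CSV."""
    series[CSV_COLUMNS].to_csv(path, index=False)


def read_weekly_csv(path) -> pd.DataFrame:
    """Read an ``iso_year,iso_week,deaths`` CSV and rebuild the week grid.

    The file must carry the header; time covariates (``t_days``, ``w``) are
    reconstructed from the ISO calendar and validated against the rows.
    """
    raw = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"weekly CSV is missing columns: {missing}")
    raw = raw[CSV_COLUMNS].copy()
    grid = build_week_grid(int(raw["iso_year"].min()), int(raw["iso_year"].max()))
    merged = grid.merge(raw, on=["iso_year", "iso_week"], how="inner")
    if len(merged) != len(raw):
        bad = raw.merge(grid, on=["iso_year", "iso_week"], how="left", indicator=True)
        bad = bad.loc[bad["_merge"] == "left_only", ["iso_year", "iso_week"]]
        raise ValueError(
            f"rows do not exist on the ISO calendar: {bad.to_dict('records')}"
        )
    merged["deaths"] = merged["deaths"].astype(np.int64)
    return merged
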