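"""Cleaning of nest-box visit records into per-box-per-year occupancy.

Monitoring visits are reduced to one presence/absence record per box and
year using the result of the *first* visit (equal search effort across
boxes), and box-years whose first visit falls after June are discarded.
Red-squirrel data additionally carry a two-level ``time_period`` factor
splitting the series at 2006, when monitoring became more rigorous.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["first_visit_filter", "attach_time_period"]

JUNE = 6


def first_visit_filter(
    raw_visits: pd.DataFrame,
    last_month: int = JUNE,
) -> pd.DataFrame:
    """One record per box-year: the earliest visit, dropped if after June.

    ``raw_visits`` needs columns box_id, date, occupied; multiple visits per
    box-year are allowed.  Returns columns box_id, year, occupied sorted by
    (box_id, year).  Dates that cannot be parsed raise with the offending row
    index; drop counts are logged.
    """
    required = {"box_id", "date", "occupied"}
    if not required <= set(raw_visits.columns):
        raise ValueError(f"raw visits need columns {sorted(required)}")
    df = raw_visits.copy()
    parsed = pd.to_datetime(df["date"], errors="coerce")
    bad = parsed.isna() & df["date"].notna()
    if bad.any():
        idx = df.index[bad][0]
        raise ValueError(f"unparseable date {df.loc[idx, 'date']!r} at row index {idx}")
    if parsed.isna().any():
        idx = df.index[parsed.isna()][0]
        raise ValueError(f"missing date at row index {idx}")
    df["date"] = parsed
    df["year"] = df["date"].dt.year
    if not df["occupied"].isin([0, 1]).all():
        raise ValueError("occupied must be 0/1")

    n_raw = len(df)
    first = (
        df.sort_values(["box_id", "year", "date"], kind="mergesort")
        .groupby(["box_id", "year"], as_index=False, sort=True)
        .first()
    )
    n_dupes = n_raw - len(first)
    late = first["date"].dt.month > last_month
    n_late = int(late.sum())
    out = first.loc[~late, ["box_id", "year", "occupied"]].reset_index(drop=True)
    out["occupied"] = out["occupied"].astype(int)
    logger.info(
        "first-visit filter: %d visits -> %d box-years (%d later visits dropped, "
        "%d box-years with first visit after month %d dropped)",
        n_raw, len(out), n_dupes, n_late, last_month,
    )
    return out


def attach_time_period(records: pd.DataFrame, split_year: int = 2006) -> pd.DataFrame:
    """Add the two-level monitoring-period factor (1 before split_year, 2 after)."""
    out = records.copy()
    out["time_period"] = (out["year"] >= split_year).astype(int) + 1
    return out
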