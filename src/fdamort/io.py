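"""Delimited-text I/O for the weather-mortality series, with validation.

Inputs are plain CSV: hourly temperature (timestamp, temperature), daily
temperature (date, temperature) and daily death counts (date, deaths).
Readers sort, de-duplicate, validate and — for the annual application —
drop February 29 so every year has exactly 365 days.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_series",
    "write_series",
    "count_days",
    "count_season_days",
    "KINDS",
]

log = logging.getLogger("fdamort")

KINDS = ("hourly_temp", "daily_temp", "daily_counts")

_COLUMNS = {
    "hourly_temp": ("timestamp", "temperature"),
    "daily_temp": ("timestamp", "temperature"),
    "daily_counts": ("date", "deaths"),
}


def read_series(path, kind: str, drop_feb29: bool | None = None) -> pd.DataFrame:
    """Read and validate one series; errors carry 1-based data line numbers.

    ``drop_feb29`` defaults to True for daily kinds (annual application) and
    False for hourly temperature.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown series kind {kind!r}; expected one of {KINDS}")
    if drop_feb29 is None:
        drop_feb29 = kind != "hourly_temp"
    time_col, value_col = _COLUMNS[kind]
    df = pd.read_csv(path)
    for col in (time_col, value_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    lines = np.arange(2, len(df) + 2)  # header is line 1

    ts = pd.to_datetime(df[time_col], format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        raise ValueError(
            f"{path}: unparseable {time_col} on line(s) {[int(x) for x in lines[bad][:5]]}"
        )
    vals = pd.to_numeric(df[value_col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        raise ValueError(
            f"{path}: non-numeric {value_col} on line(s) {[int(x) for x in lines[bad][:5]]}"
        )
    if kind == "daily_counts":
        neg = vals < 0
        if neg.any():
            raise ValueError(
                f"{path}: negative count on line(s) {[int(x) for x in lines[neg][:5]]}"
            )
        frac = vals != np.floor(vals)
        if frac.any():
            raise ValueError(
                f"{path}: non-integer count on line(s) {[int(x) for x in lines[frac][:5]]}"
            )

    out = pd.DataFrame({time_col: ts, value_col: vals, "_line": lines})
    dup = out.duplicated(subset=time_col, keep=False)
    if dup.any():
        conflicting = (
            out[dup].groupby(time_col)[value_col].nunique() > 1
        )
        if conflicting.any():
            bad_ts = conflicting[conflicting].index
            bad_lines = [int(x) for x in out.loc[out[time_col].isin(bad_ts), "_line"]]
            raise ValueError(
                f"{path}: duplicate {time_col} with conflicting values on "
                f"line(s) {bad_lines[:6]}"
            )
        out = out.drop_duplicates(subset=time_col, keep="first")
        log.info("%s: dropped duplicate timestamps", path)

    if drop_feb29:
        feb29 = (out[time_col].dt.month == 2) & (out[time_col].dt.day == 29)
        if feb29.any():
            log.info(
                "%s: dropped %d Feb-29 row(s) (line(s) %s)",
                path,
                int(feb29.sum()),
                out.loc[feb29, "_line"].tolist()[:5],
            )
            out = out[~feb29]

    out = out.sort_values(time_col).drop(columns="_line").reset_index(drop=True)

    # gap report
    step = pd.Timedelta(hours=1) if kind == "hourly_temp" else pd.Timedelta(days=1)
    diffs = out[time_col].diff().dropna()
    n_gaps = int((diffs > step).sum())
    if n_gaps:
        log.info("%s: %d gap(s) larger than %s", path, n_gaps, step)
    return out


def write_series(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            if (out[col].dt.normalize() == out[col]).all():
                out[col] = out[col].dt.strftime("%Y-%m-%d")
            else:
                out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calendar-aware day counting
# ---------------------------------------------------------------------------

def count_days(start, end, drop_feb29: bool = False) -> int:
    """Number of days from ``start`` to ``end`` inclusive (real calendar)."""
    days = pd.date_range(pd.Timestamp(start), pd.Timestamp(end), freq="D")
    if drop_feb29:
        days = days[~((days.month == 2) & (days.day == 29))]
    return int(days.size)


def count_season_days(
    start_year: int, end_year: int, months: tuple = (6, 7, 8)
) -> int:
    """Total days falling in the given months across the year range."""
    days = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    return int(days.month.isin(months).sum())
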