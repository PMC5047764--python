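"""Reading and writing the pipeline's CSV formats.

A community's daily series is one CSV with columns ``date`` (ISO-8601),
``deaths`` (non-negative integer, empty for missing), ``tmin``, ``tmean``,
``tmax`` (°C) and optionally ``rh`` (%); missing values are empty fields.
The community metadata table has columns ``community_id``, ``country``,
``annual_mean_temp``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["read_daily_csv", "write_daily_csv", "read_metadata_csv", "write_results_csv"]

_TEMP_COLS = ("tmin", "tmean", "tmax")


def read_daily_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate one community's daily series.

    Rejects malformed dates, non-integer or negative death counts and rows
    with tmin > tmax, naming the offending row; non-monotone dates are an
    error, calendar gaps are accepted with a warning.
    """
    df = pd.read_csv(path)
    required = {"date", "deaths", *_TEMP_COLS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = dates.isna() & df["date"].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: malformed date {df['date'].iloc[row]!r} at row {row + 2}")
    df["date"] = dates
    if not dates.is_monotonic_increasing or dates.duplicated().any():
        raise ValueError(f"{path}: dates must be strictly increasing")
    gaps = dates.diff().dt.days.iloc[1:]
    if (gaps > 1).any():
        logger.warning("%s: %d calendar gap(s) in dates; downstream handling is "
                       "complete-case", path, int((gaps > 1).sum()))

    deaths = pd.to_numeric(df["deaths"], errors="coerce")
    present = df["deaths"].notna()
    nonint = present & (deaths.isna() | (deaths != deaths.round()) | (deaths < 0))
    if nonint.any():
        row = int(np.flatnonzero(nonint)[0])
        raise ValueError(
            f"{path}: deaths must be non-negative integers; "
            f"got {df['deaths'].iloc[row]!r} at row {row + 2}"
        )
    df["deaths"] = deaths

    for c in _TEMP_COLS + ("rh",):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    with np.errstate(invalid="ignore"):
        inverted = (df["tmin"].to_numpy(float) > df["tmax"].to_numpy(float))
    if inverted.any():
        row = int(np.flatnonzero(inverted)[0])
        raise ValueError(f"{path}: tmin > tmax at row {row + 2}")
    return df


def write_daily_csv(series: pd.DataFrame, path: str | Path) -> None:
    """Write a daily series; read_daily_csv(write_daily_csv(x)) round-trips."""
    out = series.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    cols = [c for c in ("community_id", "date", "deaths", *_TEMP_COLS, "rh")
            if c in out.columns]
    out = out[cols]
    # keep deaths integral in the file; missing stays an empty field
    out["deaths"] = out["deaths"].map(
        lambda v: "" if pd.isna(v) else str(int(round(v))))
    for c in _TEMP_COLS + ("rh",):
        if c in out.columns:
            out[c] = out[c].round(4)
    out.to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"community_id", "country", "annual_mean_temp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_results_csv(results: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False)
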