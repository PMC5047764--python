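"""Composite temperature-variability (TV) index.

TV over an exposure window 0–k is the sample standard deviation of the
2(k+1) daily minimum and maximum temperatures of the current day and the k
preceding days, e.g.::

    TV_0-1(t) = SD(tmin_t, tmax_t, tmin_{t-1}, tmax_{t-1})

This single index captures intraday variability (the spread between a day's
minimum and maximum) and interday variability (level changes between
neighbouring days) jointly, together with their lag structure.

Conventions (configurable, documented in docs/methods.md):

* sample SD with denominator ``n - 1``;
* the IQR used for effect scaling is the 75th minus 25th percentile of the
  non-missing TV series under linear-interpolation ("type 7") quantiles;
* a day's TV is undefined if *any* constituent tmin/tmax is missing — no
  partial windows, which would silently deflate the variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TVExposure", "compute_tv", "compute_lead_tv", "compute_iqr"]


@dataclass
class TVExposure:
    """Per-day TV values for one community and one exposure window.

    ``values`` is aligned with the input series; days where the window is
    incomplete (series head for lagged TV, tail for lead TV, or any missing
    tmin/tmax in the window) hold NaN.
    """

    window: int
    values: np.ndarray
    iqr: float = field(default=np.nan)
    kind: str = "lag"  # "lag" for TV_{0-k}, "lead" for future windows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.values).sum())


def _minmax_matrix(series: pd.DataFrame) -> np.ndarray:
    if not {"tmin", "tmax"}.issubset(series.columns):
        raise ValueError("series must have 'tmin' and 'tmax' columns")
    return np.column_stack(
        [series["tmin"].to_numpy(float), series["tmax"].to_numpy(float)]
    )


def _window_sd(x: np.ndarray, length: int) -> np.ndarray:
    """Sample SD over sliding windows of `length` consecutive days.

    ``x`` is (n, 2) with per-day (tmin, tmax); the SD pools both columns of
    the window, i.e. 2*length numbers. Returns an array of length
    ``n - length + 1``; NaN propagates from any constituent.
    """
    win = np.lib.stride_tricks.sliding_window_view(x, (length, 2)).reshape(
        -1, 2 * length
    )
    return np.std(win, axis=1, ddof=1)


def compute_tv(series: pd.DataFrame, window_k: int) -> TVExposure:
    """TV_{0-k}: SD of {tmin, tmax} over the current and k preceding days.

    Parameters
    ----------
    series : DataFrame with at least ``tmin`` and ``tmax`` columns,
        one row per day in date order.
    window_k : k >= 1; the window covers k+1 days (2(k+1) numbers).

    Returns
    -------
    TVExposure with ``values`` aligned to the series (first k days NaN)
    and ``iqr`` filled when at least 4 values are defined.
    """
    window_k = int(window_k)
    if window_k < 1:
        raise ValueError(f"window_k must be >= 1, got {window_k}")
    x = _minmax_matrix(series)
    n = len(x)
    values = np.full(n, np.nan)
    if n >= window_k + 1:
        values[window_k:] = _window_sd(x, window_k + 1)
    iqr = np.nan
    if np.isfinite(values).sum() >= 4:
        iqr = compute_iqr(values)
    return TVExposure(window=window_k, values=values, iqr=iqr, kind="lag")


def compute_lead_tv(series: pd.DataFrame, lead_window: int) -> TVExposure:
    """Future TV: SD of {tmin, tmax} over days t+1 .. t+lead_window.

    Used by the Granger-style residual-confounding check: the future cannot
    cause the past, so an association between today's mortality and future
    TV signals uncontrolled confounding.
    """
    lead_window = int(lead_window)
    if lead_window < 1:
        raise ValueError(f"lead_window must be >= 1, got {lead_window}")
    x = _minmax_matrix(series)
    n = len(x)
    values = np.full(n, np.nan)
    if n >= lead_window + 1:
        # window over days t+1..t+L == lagged window of length L ending at t+L
        sd = _window_sd(x, lead_window)  # sd[i] covers days i..i+L-1
        values[: n - lead_window] = sd[1:]
    iqr = np.nan
    if np.isfinite(values).sum() >= 4:
        iqr = compute_iqr(values)
    return TVExposure(window=lead_window, values=values, iqr=iqr, kind="lead")


def compute_iqr(values: np.ndarray | TVExposure) -> float:
    """Interquartile range (75th − 25th pct) of the non-missing TV values.

    Linear-interpolation quantiles; requires at least 4 defined values.
    """
    if isinstance(values, TVExposure):
        values = values.values
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        raise ValueError("all TV values are missing")
    if finite.size < 4:
        raise ValueError(f"need >= 4 non-missing TV values, got {finite.size}")
    q25, q75 = np.percentile(finite, [25.0, 75.0])
    return float(q75 - q25)
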