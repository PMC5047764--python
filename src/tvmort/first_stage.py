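"""Community-level quasi-Poisson time-series regression.

The first stage of the two-stage design: for each community, daily death
counts are regressed on the linear TV term with

* a natural cubic spline of the day index (7 df per year by default) for
  long-term trend and seasonality,
* day-of-week indicator variables (Monday reference),
* a distributed-lag cross-basis of daily mean temperature (4 df for
  temperature, lag spline with knots at 1.4 and 5.5 days plus intercept,
  up to 21 lag days) to control for the non-linear, delayed main effect
  of temperature,
* optionally a 3-df spline of same-day relative humidity and heat-wave /
  cold-spell indicators,

assuming a quasi-Poisson distribution: Poisson maximum-likelihood point
estimates with standard errors scaled by the square root of the Pearson
dispersion. Effects are reported as the percent change in mortality per
community-specific interquartile-range increase of TV,
100 * (exp(beta * IQR) - 1), with Wald 95% CIs on the log scale.

Season-stratified slopes, sensitivity variants (28-day lag, 3-6 temperature
df, min+max temperature control) and the Granger-style lead-exposure check
are all driven through ``ModelConfig``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .basis import (
    build_crossbasis,
    lag_spline_spec,
    ns_basis,
    temperature_spline_spec,
    time_spline_df,
    CrossBasisSpec,
    SplineSpec,
)
from .tv import TVExposure, compute_iqr, compute_lead_tv, compute_tv

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "FirstStageResult",
    "SeasonLabels",
    "QuasiPoissonFit",
    "fit_quasipoisson",
    "build_design",
    "fit_community",
    "assign_seasons",
    "fit_seasonal",
    "detect_episodes",
    "granger_lead_check",
]

SEASONS = ("cold", "moderate", "hot")
Z975 = 1.959963984540054


@dataclass
class ModelConfig:
    """First-stage model configuration (defaults = the primary analysis)."""

    tv_window: int = 1  # TV_{0-k}, k in 1..7
    max_lag: int = 21  # temperature cross-basis lag, 21 or 28 in sensitivity
    temp_df: int = 4  # temperature spline df, 3..6
    time_df_per_year: float = 7.0
    lag_knots: tuple[float, ...] = (1.4, 5.5)
    include_humidity: bool = False
    humidity_df: int = 3
    include_heatwave_coldspell: bool = False
    control_variable: Literal[
        "mean_temperature", "min_and_max_temperature", "none"
    ] = "mean_temperature"
    season_stratified: bool = False

    def __post_init__(self) -> None:
        if not 1 <= int(self.tv_window) <= 7:
            raise ValueError("tv_window must be in 1..7")
        if not 3 <= int(self.temp_df) <= 6:
            raise ValueError("temp_df must be in 3..6")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.control_variable not in (
            "mean_temperature", "min_and_max_temperature", "none",
        ):
            raise ValueError(f"unknown control_variable {self.control_variable!r}")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["lag_knots"] = list(self.lag_knots)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "lag_knots" in d:
            d["lag_knots"] = tuple(d["lag_knots"])
        return cls(**d)


@dataclass
class SeasonLabels:
    """Per-calendar-month season assignment: 4 cold, 4 hot, 4 moderate."""

    month_to_season: dict[int, str]
    tie_broken: bool = False

    def __post_init__(self) -> None:
        counts = pd.Series(list(self.month_to_season.values())).value_counts()
        if sorted(self.month_to_season) != list(range(1, 13)):
            raise ValueError("season labels must cover months 1..12")
        if not all(counts.get(s, 0) == 4 for s in SEASONS):
            raise ValueError(f"each season must get exactly 4 months, got {dict(counts)}")

    def of_dates(self, dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
        months = pd.DatetimeIndex(dates).month
        return np.array([self.month_to_season[m] for m in months])


@dataclass
class SeasonEffect:
    coefficient: float
    se: float
    percent_change_per_iqr: float
    ci_low: float
    ci_high: float


@dataclass
class FirstStageResult:
    community_id: str
    tv_window: int
    tv_coefficient: float  # per-°C log-rate
    tv_se: float
    iqr: float  # °C, community-specific TV IQR
    percent_change_per_iqr: float
    ci_low: float
    ci_high: float
    dispersion: float
    n_days_used: int
    n_days_dropped: int
    seasonal: dict[str, SeasonEffect] | None = None

    @staticmethod
    def percent_change(coef: float, se: float, iqr: float) -> tuple[float, float, float]:
        """Per-IQR percent change with Wald 95% CI (log scale, exponentiated)."""
        est = 100.0 * (np.exp(coef * iqr) - 1.0)
        lo = 100.0 * (np.exp((coef - Z975 * se) * iqr) - 1.0)
        hi = 100.0 * (np.exp((coef + Z975 * se) * iqr) - 1.0)
        return float(est), float(lo), float(hi)


@dataclass
class QuasiPoissonFit:
    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    n_obs: int
    n_params: int
    iterations: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def fit_quasipoisson(design: np.ndarray, deaths: np.ndarray) -> QuasiPoissonFit:
    """Quasi-Poisson GLM: Poisson MLE via IRLS, Pearson-χ² dispersion.

    Coefficients are the Poisson maximum-likelihood estimates; the
    covariance is dispersion × inverse Fisher information, so standard
    errors scale by √dispersion but point estimates do not. Rows must
    already be complete cases.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(deaths, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("design/deaths contain non-finite values; drop them first")
    if (y < 0).any():
        raise ValueError("deaths must be non-negative")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient: rank {rank} < {X.shape[1]} columns"
        )
    model = sm.GLM(y, X, family=sm.families.Poisson())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        # deviance-change tolerance: 1e-6 on deviances of O(n) is orders of
        # magnitude below estimate precision, and avoids terminal IRLS
        # oscillation at machine precision in near-collinear designs
        res = model.fit(scale="X2", maxiter=300, tol=1e-6)
    if not res.converged:
        raise RuntimeError(
            f"IRLS failed to converge in {res.fit_history['iteration']} iterations; "
            f"deviance {res.deviance:.4g}"
        )
    return QuasiPoissonFit(
        coefficients=np.asarray(res.params, dtype=float),
        covariance=np.asarray(res.cov_params(), dtype=float),
        dispersion=float(res.scale),
        n_obs=int(res.nobs),
        n_params=X.shape[1],
        iterations=int(res.fit_history["iteration"]),
    )


def _dow_dummies(dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Six day-of-week indicators, Monday as reference category."""
    dow = pd.DatetimeIndex(dates).dayofweek.to_numpy()
    return np.column_stack([(dow == d).astype(float) for d in range(1, 7)])


def _control_columns(series: pd.DataFrame, config: ModelConfig) -> list[np.ndarray]:
    """Temperature-control cross-basis column blocks per ``control_variable``."""
    if config.control_variable == "none":
        return []
    lag_spec = lag_spline_spec(config.max_lag, config.lag_knots)
    variables = (
        ["tmean"]
        if config.control_variable == "mean_temperature"
        else ["tmin", "tmax"]
    )
    if config.control_variable == "min_and_max_temperature":
        logger.warning(
            "controlling for tmin and tmax via two separate cross-bases; "
            "these are strongly collinear — interpret with care"
        )
    blocks = []
    for var in variables:
        x = series[var].to_numpy(float)
        var_spec = temperature_spline_spec(x, df=config.temp_df)
        spec = CrossBasisSpec(var_spec=var_spec, lag_spec=lag_spec,
                              max_lag=config.max_lag)
        center = float(np.nanmedian(x))
        blocks.append(build_crossbasis(x, spec, center=center).matrix)
    return blocks


def build_design(
    series: pd.DataFrame,
    config: ModelConfig,
    tv: TVExposure | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, TVExposure, dict[str, slice]]:
    """Assemble the first-stage design matrix.

    Returns ``(X, y, used_mask, tv_exposure, column_slices)`` where ``X``
    and ``y`` contain complete-case rows only and ``column_slices`` maps
    term names to column ranges of ``X`` (the TV column is ``slices['tv']``).
    """
    n = len(series)
    if n < 365:
        raise ValueError("first-stage fit needs at least one year of data")
    if tv is None:
        tv = compute_tv(series, config.tv_window)

    cols: list[np.ndarray] = []
    slices: dict[str, slice] = {}

    def add(name: str, block: np.ndarray) -> None:
        block = np.atleast_2d(block.T).T if block.ndim == 1 else block
        start = sum(c.shape[1] for c in cols)
        cols.append(block)
        slices[name] = slice(start, start + block.shape[1])

    add("intercept", np.ones((n, 1)))
    add("tv", tv.values[:, None])
    add("time", ns_basis(np.arange(n, dtype=float),
                         time_spline_df(n, config.time_df_per_year)))
    add("dow", _dow_dummies(series["date"]))
    for i, block in enumerate(_control_columns(series, config)):
        add(f"crossbasis_{i}", block)
    if config.include_humidity:
        if "rh" not in series.columns:
            raise ValueError("include_humidity=True but series has no 'rh' column")
        rh = series["rh"].to_numpy(float)
        finite = rh[np.isfinite(rh)]
        pct = 100.0 * np.arange(1, config.humidity_df) / config.humidity_df
        spec = SplineSpec(
            tuple(np.percentile(finite, pct)),
            (float(finite.min()), float(finite.max())),
        )
        add("humidity", ns_basis(rh, spec))
    if config.include_heatwave_coldspell:
        heat, cold = detect_episodes(series)
        add("heatwave", heat.astype(float)[:, None])
        add("coldspell", cold.astype(float)[:, None])

    X = np.hstack(cols)
    y = series["deaths"].to_numpy(float)
    used = np.isfinite(X).all(axis=1) & np.isfinite(y)
    return X[used], y[used], used, tv, slices


def fit_community(
    series: pd.DataFrame,
    config: ModelConfig,
    community_id: str | None = None,
) -> FirstStageResult:
    """Fit the community-specific model and report the per-IQR TV effect."""
    if community_id is None:
        community_id = str(series["community_id"].iloc[0]) \
            if "community_id" in series.columns else "community"
    X, y, used, tv, slices = build_design(series, config)
    fit = fit_quasipoisson(X, y)
    j = slices["tv"].start
    coef, se = float(fit.coefficients[j]), float(fit.se()[j])
    iqr = compute_iqr(tv)
    est, lo, hi = FirstStageResult.percent_change(coef, se, iqr)
    n_dropped = int(len(series) - used.sum())
    logger.info(
        "%s: n=%d (dropped %d), dispersion=%.3f, IRLS iters=%d",
        community_id, fit.n_obs, n_dropped, fit.dispersion, fit.iterations,
    )
    result = FirstStageResult(
        community_id=community_id,
        tv_window=config.tv_window,
        tv_coefficient=coef,
        tv_se=se,
        iqr=iqr,
        percent_change_per_iqr=est,
        ci_low=lo,
        ci_high=hi,
        dispersion=fit.dispersion,
        n_days_used=fit.n_obs,
        n_days_dropped=n_dropped,
    )
    if config.season_stratified:
        result.seasonal = fit_seasonal(series, config, community_id=community_id)
    return result


def assign_seasons(series: pd.DataFrame) -> SeasonLabels:
    """Label the 4 coldest months cold, the 4 hottest hot, the rest moderate.

    Months are ranked by their long-run mean of daily mean temperature. Ties
    (e.g. a constant-temperature series) are broken deterministically by
    calendar month order, and flagged.
    """
    dates = pd.DatetimeIndex(series["date"])
    months = dates.month
    means = pd.Series(series["tmean"].to_numpy(float), index=months).groupby(level=0).mean()
    if set(means.index) != set(range(1, 13)):
        missing = sorted(set(range(1, 13)) - set(means.index))
        raise ValueError(f"every calendar month needs data; missing months {missing}")
    tie = means.round(12).duplicated(keep=False).any()
    order = sorted(range(1, 13), key=lambda m: (means[m], m))
    mapping = {m: "cold" for m in order[:4]}
    mapping.update({m: "hot" for m in order[-4:]})
    mapping.update({m: "moderate" for m in order[4:8]})
    if tie:
        logger.warning("tied monthly mean temperatures; month-order tie-break applied")
    return SeasonLabels(month_to_season=mapping, tie_broken=bool(tie))


def fit_seasonal(
    series: pd.DataFrame,
    config: ModelConfig,
    community_id: str | None = None,
) -> dict[str, SeasonEffect]:
    """Season-stratified TV slopes from a single interaction model.

    One model with season main effects (moderate reference) and a TV×season
    interaction coded so each season carries its own TV slope; per-season
    percent changes use the community-wide IQR so they are comparable.
    """
    labels = assign_seasons(series)
    season = labels.of_dates(series["date"])
    tv = compute_tv(series, config.tv_window)
    X, y, used, tv, slices = build_design(series, config, tv=tv)

    season_used = season[used]
    tv_used = X[:, slices["tv"].start]
    # replace the single TV column with three season-specific slopes and
    # add two season main effects (moderate is the reference)
    keep = np.ones(X.shape[1], dtype=bool)
    keep[slices["tv"]] = False
    extra = [
        np.where(season_used == s, tv_used, 0.0)[:, None] for s in SEASONS
    ] + [
        (season_used == s).astype(float)[:, None] for s in ("cold", "hot")
    ]
    Xs = np.hstack([np.hstack(extra), X[:, keep]])
    fit = fit_quasipoisson(Xs, y)
    iqr = compute_iqr(tv)
    out: dict[str, SeasonEffect] = {}
    for i, s in enumerate(SEASONS):
        coef, se = float(fit.coefficients[i]), float(fit.se()[i])
        est, lo, hi = FirstStageResult.percent_change(coef, se, iqr)
        out[s] = SeasonEffect(coef, se, est, lo, hi)
    return out


def detect_episodes(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Heat-wave and cold-spell indicators.

    A day is in a heat wave iff it belongs to a run of consecutive days with
    daily mean temperature above the community's 95th percentile lasting
    strictly more than 2 days (>= 3); cold spells are symmetric below the
    5th percentile. Percentiles are computed over the full study period.
    """
    tmean = series["tmean"].to_numpy(float)
    finite = tmean[np.isfinite(tmean)]
    hi, lo = np.percentile(finite, [95.0, 5.0])

    def runs(exceed: np.ndarray) -> np.ndarray:
        flag = np.zeros(len(exceed), dtype=bool)
        start = None
        for i, e in enumerate(exceed):
            if e and start is None:
                start = i
            elif not e and start is not None:
                if i - start > 2:
                    flag[start:i] = True
                start = None
        if start is not None and len(exceed) - start > 2:
            flag[start:] = True
        return flag

    with np.errstate(invalid="ignore"):
        return runs(tmean > hi), runs(tmean < lo)


def granger_lead_check(
    series: pd.DataFrame,
    config: ModelConfig,
    leads: int = 7,
) -> pd.DataFrame:
    """Granger-style negative-control check: regress deaths on *future* TV.

    For each lead window 1..``leads`` the community model is refitted with
    the lagged TV term replaced by the TV of days t+1..t+lead, keeping every
    confounder control. The future cannot cause the past, so coefficients
    systematically different from zero indicate residual confounding.

    Returns a DataFrame with columns lead, coefficient, se, z.
    """
    leads = int(leads)
    if leads < 1:
        raise ValueError("leads must be >= 1")
    rows = []
    for lead in range(1, leads + 1):
        lead_tv = compute_lead_tv(series, lead)
        X, y, used, _, slices = build_design(series, config, tv=lead_tv)
        fit = fit_quasipoisson(X, y)
        j = slices["tv"].start
        coef, se = float(fit.coefficients[j]), float(fit.se()[j])
        rows.append({"lead": lead, "coefficient": coef, "se": se, "z": coef / se})
    return pd.DataFrame(rows)
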