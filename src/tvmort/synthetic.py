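"""Synthetic multi-community daily weather and mortality series.

The two-stage estimator pipeline is exercised end-to-end on simulated data
with known ground truth, because multi-city mortality registries are not
redistributable. The generator is the exact generative counterpart of the
regression model fitted downstream:

* daily mean temperature = annual sinusoid + AR(1) noise; tmin/tmax are
  placed symmetrically around tmean at half the (stochastic, seasonally
  modulated) diurnal range;
* daily death counts are overdispersed Poisson with log-mean assembled
  additively from: log baseline, a linear TV effect (the ground truth
  recovered by the first stage), a long-term trend, a seasonal mortality
  cycle, day-of-week offsets, and a non-linear lagged mean-temperature
  surface (U-shaped around an optimum, geometrically decaying over lags);
* an ensemble draws community TV slopes from Normal(mu, tau^2) — the
  generative counterpart of the second-stage random-effects model.

Overdispersion phi is implemented as a gamma-mixed Poisson with
mean-proportional variance inflation: Var = phi * mean (phi = 1 is plain
Poisson). Quasi-Poisson fitting assumes only this variance function, so
this is the natural generative stand-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .tv import compute_tv

__all__ = [
    "WeatherParams",
    "MortalityParams",
    "CommunityEnsembleParams",
    "quadratic_lag_surface",
    "simulate_weather",
    "simulate_mortality",
    "simulate_community",
    "simulate_ensemble",
]

DAYS_PER_YEAR = 365.25
_MIN_DIURNAL_RANGE = 0.1  # °C floor so tmax - tmin > 0 always holds


@dataclass
class WeatherParams:
    """Parameters of one community's temperature process (all °C unless noted)."""

    baseline_mean_temp: float = 15.0
    seasonal_amplitude: float = 10.0
    seasonal_phase: float = -math.pi / 2  # peak around day 182 (early July)
    ar1_coefficient: float = 0.7  # dimensionless, in [0, 1)
    daily_noise_sd: float = 2.5
    diurnal_range_mean: float = 8.0
    diurnal_range_sd: float = 1.5
    diurnal_seasonal_amplitude: float = 1.0

    def validate(self) -> None:
        vals = [
            self.baseline_mean_temp, self.seasonal_amplitude, self.seasonal_phase,
            self.ar1_coefficient, self.daily_noise_sd, self.diurnal_range_mean,
            self.diurnal_range_sd, self.diurnal_seasonal_amplitude,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError(f"non-finite weather parameter in {self}")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.daily_noise_sd < 0 or self.diurnal_range_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.diurnal_range_mean <= 0:
            raise ValueError("diurnal_range_mean must be positive")


def quadratic_lag_surface(
    optimum: float = 18.0,
    curvature: float = 2e-4,
    lag_decay: float = 0.7,
    max_lag: int = 14,
) -> Callable[[np.ndarray, int], np.ndarray]:
    """U-shaped temperature effect distributed over lags with geometric decay.

    Log-rate contribution of temperature T at lag l:
    ``curvature * (T - optimum)^2 * (1 - lag_decay) * lag_decay^l``
    (weights sum to ~1 over lags), reproducing the cold-delayed / heat-acute
    structure the first-stage cross-basis is there to control for.
    """
    norm = (1.0 - lag_decay) / (1.0 - lag_decay ** (max_lag + 1))

    def surface(temp: np.ndarray, lag: int) -> np.ndarray:
        if lag > max_lag:
            return np.zeros_like(np.asarray(temp, dtype=float))
        w = norm * lag_decay**lag
        return curvature * (np.asarray(temp, dtype=float) - optimum) ** 2 * w

    surface.max_lag = max_lag  # type: ignore[attr-defined]
    return surface


@dataclass
class MortalityParams:
    """Generative parameters of one community's daily death counts."""

    log_baseline: float = math.log(30.0)
    tv_effect: float = 0.002  # per-°C log-rate slope on TV
    tv_window: int = 1  # TV_{0-k} window used by the generator
    trend_slope: float = 0.005  # per-year log-rate drift
    seasonal_mortality_amplitude: float = 0.08  # log-rate winter excess
    seasonal_mortality_phase: float = math.pi / 2  # peak in winter
    dow_effects: tuple[float, ...] = (0.0, -0.01, -0.01, 0.0, 0.01, 0.02, 0.01)
    temp_surface: Callable[[np.ndarray, int], np.ndarray] | None = None
    temp_surface_max_lag: int = 14
    overdispersion: float = 1.3  # dimensionless, >= 1

    def validate(self) -> None:
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1 (1 = Poisson)")
        if len(self.dow_effects) != 7:
            raise ValueError("dow_effects must have 7 entries (Mon..Sun)")
        if not 1 <= int(self.tv_window) <= 7:
            raise ValueError("tv_window must be in 1..7")


@dataclass
class CommunityEnsembleParams:
    """Multi-community design with heterogeneous true TV slopes."""

    n_communities: int = 20
    pooled_tv_effect: float = 0.002
    between_community_sd: float = 0.0005  # tau on the per-°C log-rate slope
    baseline_temp_range: tuple[float, float] = (7.0, 27.0)
    seasonal_amplitude_range: tuple[float, float] = (4.0, 12.0)
    diurnal_range_range: tuple[float, float] = (6.0, 11.0)
    log_baseline_range: tuple[float, float] = (math.log(15.0), math.log(60.0))
    n_countries: int = 4
    random_seed: int = 0
    weather_template: WeatherParams = field(default_factory=WeatherParams)
    mortality_template: MortalityParams = field(default_factory=MortalityParams)
    # U-shaped lagged temperature surface, optimum at each community's own
    # baseline temperature (populations adapted to their local climate)
    use_temp_surface: bool = True
    surface_curvature: float = 2e-4
    surface_lag_decay: float = 0.7
    surface_max_lag: int = 14

    def validate(self) -> None:
        if self.n_communities < 1:
            raise ValueError("n_communities must be >= 1")
        if self.between_community_sd < 0:
            raise ValueError("between_community_sd must be >= 0")


def _dates(n_days: int, start: str) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_days, freq="D")


def simulate_weather(
    params: WeatherParams,
    n_days: int,
    seed: int | np.random.Generator,
    start_date: str = "2000-01-03",  # a Monday
) -> pd.DataFrame:
    """Simulate daily tmin/tmean/tmax for one community.

    tmean follows sinusoid + stationary AR(1) noise; tmin/tmax are tmean
    minus/plus half the diurnal range, which is floored at a small positive
    value so tmin < tmax on every day. Deterministic under a fixed seed.
    """
    params.validate()
    n_days = int(n_days)
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days, dtype=float)
    season = params.seasonal_amplitude * np.sin(
        2 * np.pi * t / DAYS_PER_YEAR + params.seasonal_phase
    )

    rho, sd = params.ar1_coefficient, params.daily_noise_sd
    eps = rng.normal(0.0, sd, size=n_days) if sd > 0 else np.zeros(n_days)
    noise = np.empty(n_days)
    # stationary start so the analytic mean/variance hold from day 0
    noise[0] = eps[0] / math.sqrt(1.0 - rho**2) if sd > 0 else 0.0
    for i in range(1, n_days):
        noise[i] = rho * noise[i - 1] + eps[i]

    tmean = params.baseline_mean_temp + season + noise
    drange = (
        params.diurnal_range_mean
        + params.diurnal_seasonal_amplitude
        * np.sin(2 * np.pi * t / DAYS_PER_YEAR + params.seasonal_phase)
        + (rng.normal(0.0, params.diurnal_range_sd, size=n_days)
           if params.diurnal_range_sd > 0 else 0.0)
    )
    drange = np.maximum(drange, _MIN_DIURNAL_RANGE)
    return pd.DataFrame(
        {
            "date": _dates(n_days, start_date),
            "tmin": tmean - drange / 2.0,
            "tmean": tmean,
            "tmax": tmean + drange / 2.0,
        }
    )


def expected_log_mean(
    weather: pd.DataFrame, params: MortalityParams
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the generator's log-mean; NaN where TV or lags are undefined.

    Returns (log_mu, tv_values)."""
    n = len(weather)
    t = np.arange(n, dtype=float)
    tv = compute_tv(weather, params.tv_window).values
    log_mu = (
        params.log_baseline
        + params.tv_effect * tv
        + params.trend_slope * t / DAYS_PER_YEAR
        + params.seasonal_mortality_amplitude
        * np.sin(2 * np.pi * t / DAYS_PER_YEAR + params.seasonal_mortality_phase)
    )
    dow = pd.DatetimeIndex(weather["date"]).dayofweek.to_numpy()
    log_mu = log_mu + np.asarray(params.dow_effects, dtype=float)[dow]

    surface = params.temp_surface
    if surface is not None:
        tmean = weather["tmean"].to_numpy(float)
        max_lag = getattr(surface, "max_lag", params.temp_surface_max_lag)
        contrib = np.zeros(n)
        for lag in range(max_lag + 1):
            vals = np.asarray(surface(tmean, lag), dtype=float)
            shifted = np.full(n, np.nan)
            shifted[lag:] = vals[: n - lag] if lag > 0 else vals
            contrib = contrib + shifted
        log_mu = log_mu + contrib
    return log_mu, tv


def simulate_mortality(
    weather: pd.DataFrame,
    params: MortalityParams,
    seed: int | np.random.Generator,
    extra_log_rate: np.ndarray | None = None,
) -> pd.DataFrame:
    """Add overdispersed daily death counts to a simulated weather series.

    Counts are Poisson(mu) when overdispersion phi = 1, else gamma-mixed
    Poisson with Var = phi * mu (day-specific gamma shape mu/(phi-1)).
    Days in the burn-in where TV or the temperature-surface lags are
    undefined carry missing deaths (complete-case downstream).

    ``extra_log_rate`` adds an arbitrary per-day log-rate term — used to
    inject unmodelled confounders in negative/positive-control studies.
    """
    params.validate()
    surface_lag = (
        getattr(params.temp_surface, "max_lag", params.temp_surface_max_lag)
        if params.temp_surface is not None
        else 0
    )
    burn_in = max(int(params.tv_window), surface_lag)
    if len(weather) < burn_in + 1:
        raise ValueError(
            f"weather must cover more than the {burn_in}-day exposure burn-in"
        )
    rng = np.random.default_rng(seed)
    log_mu, tv = expected_log_mean(weather, params)
    if extra_log_rate is not None:
        log_mu = log_mu + np.asarray(extra_log_rate, dtype=float)
    mu = np.exp(log_mu)
    ok = np.isfinite(mu)

    deaths = np.full(len(weather), np.nan)
    phi = params.overdispersion
    if phi > 1.0:
        shape = mu[ok] / (phi - 1.0)
        mixed = rng.gamma(shape, scale=phi - 1.0)
        deaths[ok] = rng.poisson(mixed)
    else:
        deaths[ok] = rng.poisson(mu[ok])

    out = weather.copy()
    out["deaths"] = deaths
    return out


def simulate_community(
    weather_params: WeatherParams,
    mortality_params: MortalityParams,
    n_days: int,
    seed: int | np.random.Generator,
    start_date: str = "2000-01-03",
) -> pd.DataFrame:
    """Weather + mortality for one community from a single seed stream."""
    rng = np.random.default_rng(seed)
    weather = simulate_weather(weather_params, n_days, rng, start_date=start_date)
    return simulate_mortality(weather, mortality_params, rng)


def simulate_ensemble(
    params: CommunityEnsembleParams,
    n_days: int = 3653,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate a multi-community ensemble with heterogeneous TV slopes.

    Community slopes are drawn Normal(pooled_tv_effect,
    between_community_sd^2); weather parameters are spread uniformly over
    the configured ranges so communities span cold-to-hot climates.

    Returns (series by community id, ground-truth/metadata table) with the
    true slope, country label, and annual mean temperature per community —
    everything the recovery tests and the second stage need.
    """
    params.validate()
    n = params.n_communities
    root = np.random.SeedSequence(params.random_seed)
    children = root.spawn(n + 1)
    param_rng = np.random.default_rng(children[0])

    slopes = (
        np.full(n, params.pooled_tv_effect)
        if params.between_community_sd == 0
        else param_rng.normal(
            params.pooled_tv_effect, params.between_community_sd, size=n
        )
    )
    baselines = param_rng.uniform(*params.baseline_temp_range, size=n)
    amplitudes = param_rng.uniform(*params.seasonal_amplitude_range, size=n)
    dranges = param_rng.uniform(*params.diurnal_range_range, size=n)
    log_bases = param_rng.uniform(*params.log_baseline_range, size=n)

    series: dict[str, pd.DataFrame] = {}
    rows = []
    for i in range(n):
        cid = f"C{i:03d}"
        wp = replace(
            params.weather_template,
            baseline_mean_temp=float(baselines[i]),
            seasonal_amplitude=float(amplitudes[i]),
            diurnal_range_mean=float(dranges[i]),
        )
        surface = (
            quadratic_lag_surface(
                optimum=float(baselines[i]),
                curvature=params.surface_curvature,
                lag_decay=params.surface_lag_decay,
                max_lag=params.surface_max_lag,
            )
            if params.use_temp_surface
            else params.mortality_template.temp_surface
        )
        mp = replace(
            params.mortality_template,
            tv_effect=float(slopes[i]),
            log_baseline=float(log_bases[i]),
            temp_surface=surface,
        )
        df = simulate_community(wp, mp, n_days, np.random.default_rng(children[i + 1]))
        df.insert(0, "community_id", cid)
        series[cid] = df
        rows.append(
            {
                "community_id": cid,
                "country": f"country_{i % params.n_countries}",
                "annual_mean_temp": float(df["tmean"].mean()),
                "true_tv_effect": float(slopes[i]),
                "true_log_baseline": float(log_bases[i]),
            }
        )
    truth = pd.DataFrame(rows)
    return series, truth
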