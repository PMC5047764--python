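"""Second stage: random-effects meta-analysis by maximum likelihood.

Per-community log-scale estimates y_i with standard errors se_i are pooled
under the model y_i ~ Normal(mu, se_i^2 + tau^2): community-level true
effects are drawn from a normal distribution with between-community
variance tau^2. (mu, tau^2) maximise the marginal normal likelihood with
tau^2 >= 0 constrained; the pooled SE comes from the information at the
optimum, 1 / sum w_i with w_i = 1/(se_i^2 + tau^2). ML (not REML, not
DerSimonian–Laird) is the primary estimator; REML is available as an
option. Cochran's Q and I^2 are reported as heterogeneity summaries.

Communities are grouped for pooling by country or by climate zone: the
quartiles of community annual mean temperature define cold (<= 25th),
moderate cold (25th–50th), moderate hot (50th–75th) and hot (> 75th) areas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .first_stage import FirstStageResult, Z975

logger = logging.getLogger(__name__)

__all__ = [
    "PooledEstimate",
    "pool_random_effects",
    "assign_climate_zones",
    "pool_by_group",
    "CLIMATE_ZONES",
]

CLIMATE_ZONES = ("cold", "moderate_cold", "moderate_hot", "hot")


@dataclass
class PooledEstimate:
    group: str
    mu: float  # pooled log-effect (per community IQR unless pooled per °C)
    se: float
    tau2: float  # between-community variance of the log-effect
    n_communities: int
    Q: float
    I2: float  # percent
    p_heterogeneity: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (np.exp(self.mu) - 1.0)

    @property
    def ci_low(self) -> float:
        return 100.0 * (np.exp(self.mu - Z975 * self.se) - 1.0)

    @property
    def ci_high(self) -> float:
        return 100.0 * (np.exp(self.mu + Z975 * self.se) - 1.0)


def _profile_mu(tau2: float, y: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    return mu, float(1.0 / np.sum(w))


def _neg_loglik(tau2: float, y: np.ndarray, v: np.ndarray, reml: bool) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    ll = -0.5 * np.sum(np.log(v + tau2)) - 0.5 * np.sum(w * (y - mu) ** 2)
    if reml:
        ll -= 0.5 * np.log(np.sum(w))
    return -ll


def pool_random_effects(
    estimates: Sequence[float] | np.ndarray,
    standard_errors: Sequence[float] | np.ndarray,
    group: str = "all",
    method: str = "ml",
) -> PooledEstimate:
    """ML (or REML) random-effects pooling of log-scale estimates.

    A single-community group is passed through unchanged with ``tau2`` NaN
    and a warning, mirroring how a one-study meta-analysis degenerates.
    """
    y = np.asarray(estimates, dtype=float)
    se = np.asarray(standard_errors, dtype=float)
    if y.shape != se.shape or y.ndim != 1:
        raise ValueError("estimates and standard_errors must be 1-D and equal length")
    ok = np.isfinite(y) & np.isfinite(se) & (se > 0)
    y, se = y[ok], se[ok]
    k = len(y)
    if k == 0:
        raise ValueError("no finite estimates to pool")
    if k == 1:
        logger.warning("group %r has a single community; pass-through, tau2 undefined",
                       group)
        return PooledEstimate(group, float(y[0]), float(se[0]), float("nan"),
                              1, float("nan"), float("nan"), float("nan"))
    if method not in ("ml", "reml"):
        raise ValueError("method must be 'ml' or 'reml'")
    v = se**2
    reml = method == "reml"

    # bracket tau^2 between 0 and a generous multiple of the sample spread
    hi = max(float(np.var(y)) * 10.0, float(v.max()) * 10.0, 1e-8)
    res = minimize_scalar(
        _neg_loglik, bounds=(0.0, hi), args=(y, v, reml), method="bounded",
        options={"xatol": 1e-12},
    )
    tau2 = float(res.x)
    # the bounded optimiser never lands exactly on the boundary; snap to 0
    # when the likelihood there is at least as high
    if _neg_loglik(0.0, y, v, reml) <= res.fun + 1e-12:
        tau2 = 0.0
    mu, var_mu = _profile_mu(tau2, y, v)

    w_fixed = 1.0 / v
    mu_fe = np.sum(w_fixed * y) / np.sum(w_fixed)
    Q = float(np.sum(w_fixed * (y - mu_fe) ** 2))
    dfQ = k - 1
    I2 = float(max(0.0, (Q - dfQ) / Q) * 100.0) if Q > 0 else 0.0
    p_het = float(chi2.sf(Q, dfQ))
    return PooledEstimate(group, mu, float(np.sqrt(var_mu)), tau2, k, Q, I2, p_het)


def assign_climate_zones(metadata: pd.DataFrame) -> pd.Series:
    """Climate-zone labels from quartiles of community annual mean temperature.

    Brackets: <= 25th percentile cold, (25th, 50th] moderate cold,
    (50th, 75th] moderate hot, > 75th hot. Degenerate (all-equal)
    temperatures put every community in the lowest bracket, with a warning.
    Input order does not matter.
    """
    temps = metadata["annual_mean_temp"].astype(float)
    if not np.isfinite(temps).all():
        raise ValueError("every community needs a finite annual mean temperature")
    q25, q50, q75 = np.percentile(temps, [25.0, 50.0, 75.0])
    if q25 == q75:
        logger.warning("degenerate annual-temperature distribution; "
                       "all communities labelled 'cold' by the <= convention")
    zones = np.select(
        [temps <= q25, temps <= q50, temps <= q75],
        ["cold", "moderate_cold", "moderate_hot"],
        default="hot",
    )
    return pd.Series(zones, index=metadata["community_id"].values, name="climate_zone")


def _results_frame(results: Iterable[FirstStageResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "community_id": r.community_id,
            "tv_window": r.tv_window,
            "season": "all",
            "coefficient": r.tv_coefficient * r.iqr,  # log effect per IQR
            "se": r.tv_se * r.iqr,
        })
        if r.seasonal:
            for s, eff in r.seasonal.items():
                rows.append({
                    "community_id": r.community_id,
                    "tv_window": r.tv_window,
                    "season": s,
                    "coefficient": eff.coefficient * r.iqr,
                    "se": eff.se * r.iqr,
                })
    return pd.DataFrame(rows)


def pool_by_group(
    results: Iterable[FirstStageResult] | pd.DataFrame,
    groups: pd.Series | dict[str, str],
    method: str = "ml",
) -> pd.DataFrame:
    """Pool per-IQR log effects within groups (countries or climate zones).

    ``results`` is a collection of FirstStageResult (possibly spanning
    several TV windows and seasons) or an equivalent DataFrame with columns
    community_id, tv_window, season, coefficient, se — the coefficient
    already on the per-IQR log scale. ``groups`` maps community_id to its
    group label. Returns one row per (group, tv_window, season) with the
    pooled percent change, CI, tau^2, Q and I^2; empty groups are skipped
    with a warning.
    """
    df = results if isinstance(results, pd.DataFrame) else _results_frame(results)
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    df = df.copy()
    df["group"] = df["community_id"].map(groups)
    missing = df["group"].isna()
    if missing.any():
        logger.warning("%d first-stage rows have no group label; skipped",
                       int(missing.sum()))
        df = df[~missing]

    rows = []
    for (grp, window, season), sub in df.groupby(["group", "tv_window", "season"]):
        if sub.empty:
            logger.warning("empty cell (%s, %s, %s) skipped", grp, window, season)
            continue
        pooled = pool_random_effects(
            sub["coefficient"].to_numpy(), sub["se"].to_numpy(),
            group=str(grp), method=method,
        )
        rows.append({
            "group": grp,
            "tv_window": window,
            "season": season,
            "n_communities": pooled.n_communities,
            "pooled_log_effect": pooled.mu,
            "pooled_se": pooled.se,
            "tau2": pooled.tau2,
            "percent_change": pooled.percent_change,
            "ci_low": pooled.ci_low,
            "ci_high": pooled.ci_high,
            "Q": pooled.Q,
            "I2": pooled.I2,
            "p_heterogeneity": pooled.p_heterogeneity,
        })
    return pd.DataFrame(rows)
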