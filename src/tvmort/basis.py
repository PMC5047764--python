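"""Natural cubic spline bases and the distributed-lag cross-basis.

The distributed lag non-linear model (DLNM) controls for the non-linear,
delayed effect of daily mean temperature. Its design matrix — the
*cross-basis* — is the tensor product of a basis over the exposure value
(temperature) and a basis over the lag dimension:

    cb[t, (j, k)] = sum_{l=0..L} R_j(tmean_{t-l}) * C_k(l)

Defaults follow the standard multi-city temperature–mortality setup:
natural cubic spline with 4 df for temperature (three internal knots at the
25th/50th/75th percentiles, boundary knots at the observed range), natural
cubic spline for lag with internal knots at 1.4 and 5.5 days plus an
intercept, maximum lag 21 days.

Natural cubic splines here use the truncated-power construction: piecewise
cubic, C²-continuous, with zero second derivative at and beyond the
boundary knots (linear extrapolation outside). With m internal knots the
basis has m+1 columns, plus one for an explicit intercept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasisMatrix",
    "ns_basis",
    "build_crossbasis",
    "crossbasis_from_bases",
    "time_spline_df",
    "temperature_spline_spec",
    "lag_spline_spec",
]


@dataclass
class SplineSpec:
    """Knot layout of a natural cubic spline basis."""

    internal_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]
    include_intercept: bool = False

    def __post_init__(self) -> None:
        self.internal_knots = tuple(float(k) for k in self.internal_knots)
        lo, hi = (float(b) for b in self.boundary_knots)
        if not lo < hi:
            raise ValueError(f"boundary knots must satisfy lo < hi, got ({lo}, {hi})")
        self.boundary_knots = (lo, hi)
        ks = self.internal_knots
        if any(k2 <= k1 for k1, k2 in zip(ks, ks[1:])):
            raise ValueError(f"internal knots must be strictly increasing: {ks}")
        if ks and not (lo < ks[0] and ks[-1] < hi):
            raise ValueError(
                f"internal knots {ks} must lie strictly inside ({lo}, {hi})"
            )

    @property
    def dim(self) -> int:
        return len(self.internal_knots) + 1 + (1 if self.include_intercept else 0)

    def to_dict(self) -> dict:
        return {
            "internal_knots": list(self.internal_knots),
            "boundary_knots": list(self.boundary_knots),
            "include_intercept": self.include_intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineSpec":
        return cls(
            internal_knots=tuple(d["internal_knots"]),
            boundary_knots=tuple(d["boundary_knots"]),
            include_intercept=bool(d.get("include_intercept", False)),
        )


def ns_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``x``.

    Truncated-power natural-spline construction with all knots
    ``xi_1 < ... < xi_K`` (boundary + internal): columns are ``x`` and, for
    each internal knot, ``d_k(x) - d_{K-1}(x)`` with

        d_k(x) = [ (x - xi_k)^3_+ - (x - xi_K)^3_+ ] / (xi_K - xi_k).

    The cubic and quadratic leading terms cancel, so every column is exactly
    linear beyond the boundary knots. NaN in ``x`` yields a NaN row.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = spec.boundary_knots
    knots = np.array([lo, *spec.internal_knots, hi])
    K = len(knots)

    def d(k: int) -> np.ndarray:
        num = np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[K - 1], 0.0) ** 3
        return num / (knots[K - 1] - knots[k])

    cols = []
    if spec.include_intercept:
        cols.append(np.ones_like(x))
    cols.append(x)
    if K > 2:
        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)


@dataclass
class CrossBasisSpec:
    """DLNM design: exposure-value basis × lag basis, up to ``max_lag`` days."""

    var_spec: SplineSpec
    lag_spec: SplineSpec
    max_lag: int = 21

    def __post_init__(self) -> None:
        self.max_lag = int(self.max_lag)
        if self.max_lag < 0:
            raise ValueError("max_lag must be >= 0")

    @property
    def dim(self) -> int:
        return self.var_spec.dim * self.lag_spec.dim

    def to_dict(self) -> dict:
        return {
            "var_spec": self.var_spec.to_dict(),
            "lag_spec": self.lag_spec.to_dict(),
            "max_lag": self.max_lag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CrossBasisSpec":
        return cls(
            var_spec=SplineSpec.from_dict(d["var_spec"]),
            lag_spec=SplineSpec.from_dict(d["lag_spec"]),
            max_lag=int(d["max_lag"]),
        )


@dataclass
class CrossBasisMatrix:
    matrix: np.ndarray  # (n_days, var_dim * lag_dim); NaN rows where lags missing
    spec: CrossBasisSpec
    centering_value: float = field(default=np.nan)

    @property
    def valid_rows(self) -> np.ndarray:
        return np.isfinite(self.matrix).all(axis=1)


def build_crossbasis(
    tmean: np.ndarray,
    spec: CrossBasisSpec,
    center: float | None = None,
) -> CrossBasisMatrix:
    """Build the cross-basis matrix for a daily mean-temperature series.

    Column (j, k) at day t is ``sum_l R_j(tmean_{t-l}) C_k(l)`` for
    l = 0..max_lag; columns are ordered with the temperature index j outer.
    Rows whose lag window reaches before the series start, or contains a
    missing temperature, are NaN and are dropped by complete-case fitting.

    ``center`` subtracts R(center) from the temperature basis, which shifts
    the model intercept only (asserted by test); default is no centering.
    """
    tmean = np.asarray(tmean, dtype=float)
    L = spec.max_lag
    n = len(tmean)
    if n <= L:
        raise ValueError(f"series length {n} must exceed max_lag {L}")

    R = ns_basis(tmean, spec.var_spec)  # (n, J)
    if center is not None:
        R = R - ns_basis(np.array([float(center)]), spec.var_spec)
    C = ns_basis(np.arange(L + 1, dtype=float), spec.lag_spec)  # (L+1, K)
    out = crossbasis_from_bases(R, C)
    return CrossBasisMatrix(
        matrix=out,
        spec=spec,
        centering_value=np.nan if center is None else float(center),
    )


def crossbasis_from_bases(R: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Tensor contraction of an (n, J) exposure basis with an (L+1, K) lag basis.

    out[t, j*K + k] = sum_l R[t - l, j] * C[l, k]; the first L rows are NaN.
    Bilinear in (R, C) — the linearity properties of the cross-basis are
    tested on this function directly.
    """
    R = np.asarray(R, dtype=float)
    C = np.asarray(C, dtype=float)
    n, J = R.shape
    L = C.shape[0] - 1
    K = C.shape[1]
    if n <= L:
        raise ValueError(f"series length {n} must exceed max_lag {L}")
    # windows[i, j, w] = R[i + w, j]; day t = i + L, lag l has w = L - l
    windows = np.lib.stride_tricks.sliding_window_view(R, L + 1, axis=0)
    cb = np.einsum("ijw,wk->ijk", windows, C[::-1])
    out = np.full((n, J * K), np.nan)
    out[L:] = cb.reshape(n - L, J * K)
    return out


def temperature_spline_spec(
    tmean: np.ndarray, df: int = 4, include_intercept: bool = False
) -> SplineSpec:
    """Temperature spline with ``df`` degrees of freedom.

    df - 1 internal knots at equally spaced percentiles of the observed
    series (df=4 gives the 25th/50th/75th), boundary knots at the observed
    min/max.
    """
    df = int(df)
    if df < 2:
        raise ValueError("temperature spline needs df >= 2")
    t = np.asarray(tmean, dtype=float)
    t = t[np.isfinite(t)]
    if t.size == 0:
        raise ValueError("no finite temperatures to place knots on")
    pct = 100.0 * np.arange(1, df) / df
    internal = np.percentile(t, pct)
    lo, hi = float(t.min()), float(t.max())
    internal = tuple(k for k in internal if lo < k < hi)
    return SplineSpec(internal, (lo, hi), include_intercept=include_intercept)


def lag_spline_spec(
    max_lag: int = 21, internal_knots: tuple[float, ...] = (1.4, 5.5)
) -> SplineSpec:
    """Lag-dimension spline: natural cubic with intercept over [0, max_lag].

    Default internal knots at 1.4 and 5.5 days (log-spaced placement over
    the 21-day window); user-supplied knots are accepted for other lags.
    """
    return SplineSpec(
        tuple(internal_knots), (0.0, float(max_lag)), include_intercept=True
    )


def time_spline_df(n_days: int, df_per_year: float = 7.0) -> SplineSpec:
    """Long-term-trend/seasonality spline over the day index.

    Total df = round(df_per_year * n_days / 365.25); internal knots equally
    spaced over the day index, boundary at the first and last day.
    """
    n_days = int(n_days)
    if df_per_year <= 0:
        raise ValueError("df_per_year must be > 0")
    if n_days < 365:
        raise ValueError("time spline needs at least one year of days")
    total_df = int(round(df_per_year * n_days / 365.25))
    total_df = max(total_df, 1)
    knots = np.linspace(0.0, n_days - 1.0, total_df + 1)
    return SplineSpec(tuple(knots[1:-1]), (0.0, n_days - 1.0), include_intercept=False)
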