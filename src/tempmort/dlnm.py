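"""First-stage distributed lag non-linear model (DLNM).

One location's daily mortality counts are regressed on a bidimensional
cross-basis of temperature and lag (0..21 days by default) with a
quasi-Poisson likelihood, controlling for season and long-term trend
(natural cubic spline of time) and day of the week.  The fitted
exposure-lag-response surface is then reduced to the overall cumulative
exposure-response curve: the log relative risk accumulated over all lags
for a day at constant temperature, together with its covariance.  That
reduced curve is the quantity pooled across locations by the second stage.

The exposure basis is a natural cubic spline, so predicted log-RR is
log-linear beyond the boundary knots, allowing extrapolation to
temperatures outside the observed range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._splines import ns_basis

DEFAULT_MAX_LAG = 21
#: percentiles stored with every reduced curve (prediction grids, MMT search)
CURVE_PERCENTILES = (1.0, 2.5, 10.0, 25.0, 50.0, 75.0, 90.0, 97.5, 99.0)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class DailySeries:
    """Observed daily series for one location: date, mean temperature, deaths."""

    location_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    deaths: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        self.deaths = np.asarray(self.deaths)
        if len(self.dates) != len(self.tmean) or len(self.dates) != len(self.deaths):
            raise ValueError("dates, tmean and deaths must have equal length")
        if len(self.dates) > 1:
            step = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(step == np.timedelta64(1, "D")):
                raise ValueError("dates must be strictly consecutive calendar days")
        ok = ~pd.isna(self.deaths)
        if np.any(np.asarray(self.deaths)[ok].astype(float) < 0):
            raise ValueError("death counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "tmean": self.tmean, "deaths": self.deaths}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, path, location_id: str | None = None) -> "DailySeries":
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(
            location_id=location_id or str(path),
            dates=pd.DatetimeIndex(df["date"]),
            tmean=df["tmean"].to_numpy(float),
            deaths=df["deaths"].to_numpy(),
        )


def _default_lag_knots(max_lag: int, n_knots: int = 3) -> np.ndarray:
    """Interior lag knots equally spaced on the log scale over 1..max_lag."""
    return np.exp(np.linspace(np.log(1.0), np.log(max_lag), n_knots + 2))[1:-1]


@dataclass
class CrossBasisSpec:
    """Knot layout of the bidimensional temperature x lag cross-basis."""

    var_knots: np.ndarray
    var_boundary: tuple[float, float]
    max_lag: int = DEFAULT_MAX_LAG
    lag_knots: np.ndarray | None = None
    centering_value: float = 0.0

    def __post_init__(self) -> None:
        from ._splines import _check_knots

        self.var_knots = np.asarray(self.var_knots, dtype=float)
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.lag_knots is None:
            self.lag_knots = _default_lag_knots(self.max_lag)
        self.lag_knots = np.asarray(self.lag_knots, dtype=float)
        _check_knots(self.var_knots, self.var_boundary)
        _check_knots(self.lag_knots, (0.0, float(self.max_lag)))

    @classmethod
    def from_temperatures(
        cls,
        tmean: np.ndarray,
        knot_percentiles=(10.0, 75.0, 90.0),
        max_lag: int = DEFAULT_MAX_LAG,
        centering_value: float | None = None,
    ) -> "CrossBasisSpec":
        """Default layout: exposure knots at the 10th/75th/90th percentiles,
        boundary knots at the observed min/max, centering at the median."""
        t = np.asarray(tmean, dtype=float)
        t = t[np.isfinite(t)]
        knots = np.percentile(t, knot_percentiles)
        center = float(np.median(t)) if centering_value is None else centering_value
        return cls(
            var_knots=knots,
            var_boundary=(float(t.min()), float(t.max())),
            max_lag=max_lag,
            centering_value=center,
        )

    # basis evaluators -----------------------------------------------------

    def var_basis(self, x, centered: bool = True) -> np.ndarray:
        """Exposure basis b(x), optionally centred at the centering value."""
        B = ns_basis(x, self.var_knots, self.var_boundary)
        if centered:
            B = B - ns_basis([self.centering_value], self.var_knots, self.var_boundary)
        return B

    def lag_basis(self) -> np.ndarray:
        """Lag basis matrix C of shape (max_lag + 1, k_lag), intercept included."""
        lags = np.arange(self.max_lag + 1, dtype=float)
        N = ns_basis(lags, self.lag_knots, (0.0, float(self.max_lag)))
        return np.column_stack([np.ones(len(lags)), N])

    @property
    def k_var(self) -> int:
        return len(self.var_knots) + 1

    @property
    def k_lag(self) -> int:
        return len(self.lag_knots) + 2


@dataclass
class FirstStageFit:
    """Quasi-Poisson fit of one location's cross-basis model."""

    location_id: str
    coef: np.ndarray  # cross-basis block of beta, length k_var * k_lag
    vcov: np.ndarray  # dispersion-scaled covariance of that block
    dispersion: float
    n_days: int
    spec: CrossBasisSpec
    converged: bool = True
    temp_percentiles: dict = field(default_factory=dict)


@dataclass
class ReducedCurve:
    """Overall cumulative exposure-response curve for one location.

    ``theta`` lives on the (centred) exposure natural-spline basis; the
    predicted log-RR at the centering temperature is exactly zero.
    """

    location_id: str
    theta: np.ndarray
    V: np.ndarray
    var_knots: np.ndarray
    var_boundary: tuple[float, float]
    centering_value: float
    temp_percentiles: dict

    def basis(self, x, center: float | None = None) -> np.ndarray:
        c = self.centering_value if center is None else float(center)
        return ns_basis(x, self.var_knots, self.var_boundary) - ns_basis(
            [c], self.var_knots, self.var_boundary
        )

    def to_json(self, path) -> None:
        obj = {
            "schema": "tempmort.reduced_curve.v1",
            "location_id": self.location_id,
            "theta": list(self.theta),
            "V": [list(row) for row in np.asarray(self.V)],
            "var_knots": list(self.var_knots),
            "var_boundary": list(self.var_boundary),
            "centering_value": self.centering_value,
            "temp_percentiles": {str(k): v for k, v in self.temp_percentiles.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReducedCurve":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            location_id=obj["location_id"],
            theta=np.asarray(obj["theta"], float),
            V=np.asarray(obj["V"], float),
            var_knots=np.asarray(obj["var_knots"], float),
            var_boundary=tuple(obj["var_boundary"]),
            centering_value=float(obj["centering_value"]),
            temp_percentiles={float(k): v for k, v in obj["temp_percentiles"].items()},
        )


# ---------------------------------------------------------------------------
# cross-basis


def build_crossbasis(
    tmean: np.ndarray, spec: CrossBasisSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Build the cross-basis matrix for a daily temperature series.

    Entry (t, i * k_lag + j) accumulates b_i(x_{t-l}) * c_j(l) over lags
    l = 0..max_lag, with the exposure basis centred at the spec's centering
    value.  Rows without a complete lag history (the first max_lag days)
    are returned as NaN and flagged.

    Returns
    -------
    X : ndarray (n_days, k_var * k_lag)
    complete : boolean ndarray flagging rows with full lag history
    """
    x = np.asarray(tmean, dtype=float)
    n = len(x)
    L = spec.max_lag
    if n <= L:
        raise ValueError(f"series of length {n} is too short for max_lag={L}")
    B = spec.var_basis(x)  # (n, k_var), centred
    C = spec.lag_basis()  # (L+1, k_lag)
    kv, kl = B.shape[1], C.shape[1]
    X = np.zeros((n, kv * kl))
    for lag in range(L + 1):
        # day t draws on exposure at t - lag
        Bl = np.empty_like(B)
        Bl[lag:] = B[: n - lag]
        Bl[:lag] = np.nan
        X += np.einsum("ti,j->tij", Bl, C[lag]).reshape(n, kv * kl)
    complete = np.ones(n, dtype=bool)
    complete[:L] = False
    return X, complete


def reduce_to_overall(fit: FirstStageFit) -> ReducedCurve:
    """Sum the fitted surface over lags: theta = M beta, V = M vcov M'.

    M collapses each exposure-basis coefficient's lag-basis block with the
    lag-basis functions summed over lags 0..max_lag.
    """
    spec = fit.spec
    C = spec.lag_basis()
    S = C.sum(axis=0)  # (k_lag,) lag-basis functions summed over the window
    kv, kl = spec.k_var, spec.k_lag
    if fit.coef.shape != (kv * kl,):
        raise ValueError(
            f"coefficient length {fit.coef.shape} inconsistent with spec ({kv}x{kl})"
        )
    M = np.kron(np.eye(kv), S[None, :])  # (kv, kv*kl)
    theta = M @ fit.coef
    V = M @ fit.vcov @ M.T
    V = 0.5 * (V + V.T)
    return ReducedCurve(
        location_id=fit.location_id,
        theta=theta,
        V=V,
        var_knots=spec.var_knots.copy(),
        var_boundary=spec.var_boundary,
        centering_value=spec.centering_value,
        temp_percentiles=dict(fit.temp_percentiles),
    )


def predict_curve(
    curve: ReducedCurve, temps, center: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted overall cumulative log-RR and pointwise SE on a grid.

    log-RR(x) = (b(x) - b(center))' theta; the same contrast propagates the
    covariance.  Predictions are exactly zero (SE zero) at the centre and
    linear in x beyond the boundary knots.
    """
    Z = curve.basis(temps, center=center)
    logrr = Z @ curve.theta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Z, curve.V, Z), 0.0))
    return logrr, se


# ---------------------------------------------------------------------------
# first-stage regression


@dataclass
class ControlSpec:
    """Season/trend/day-of-week confounder control."""

    time_df_per_year: float = 8.0
    day_of_week: bool = True


def _time_spline(dates: pd.DatetimeIndex, df_per_year: float) -> np.ndarray:
    n = len(dates)
    years = n / 365.25
    df = max(int(round(df_per_year * years)), 2)
    t = np.arange(n, dtype=float)
    probs = np.linspace(0, 1, df + 1)[1:-1]
    interior = np.quantile(t, probs)
    return ns_basis(t, interior, (0.0, float(n - 1)))


def fit_first_stage(
    series: DailySeries,
    spec: CrossBasisSpec | None = None,
    control: ControlSpec | None = None,
) -> FirstStageFit:
    """Quasi-Poisson regression of daily deaths on the cross-basis.

    The linear predictor holds the cross-basis, a natural cubic spline of
    time (default 8 df per year, absorbing season and long-term trend) and
    day-of-week indicators.  Dispersion is the Pearson chi-square divided
    by the residual degrees of freedom; the coefficient covariance is
    scaled by it.  The first max_lag days (incomplete lag history) and any
    day with a missing lagged temperature or missing count are excluded.
    """
    if spec is None:
        spec = CrossBasisSpec.from_temperatures(series.tmean)
    if control is None:
        control = ControlSpec()

    X_cb, complete = build_crossbasis(series.tmean, spec)
    time_cols = _time_spline(series.dates, control.time_df_per_year)
    blocks = [np.ones((len(series.dates), 1)), X_cb, time_cols]
    names = (
        ["intercept"]
        + [f"cb_{i}_{j}" for i in range(spec.k_var) for j in range(spec.k_lag)]
        + [f"time_{i}" for i in range(time_cols.shape[1])]
    )
    if control.day_of_week:
        dow = pd.get_dummies(series.dates.dayofweek, drop_first=True).to_numpy(float)
        blocks.append(dow)
        names += [f"dow_{i}" for i in range(dow.shape[1])]
    X = np.column_stack(blocks)

    deaths = np.asarray(series.deaths, dtype=float)
    keep = complete & np.isfinite(X).all(axis=1) & np.isfinite(deaths)
    X_fit, y_fit = X[keep], deaths[keep]
    if X_fit.shape[0] <= X_fit.shape[1]:
        raise ValueError("not enough complete days for the design's degrees of freedom")
    rank = np.linalg.matrix_rank(X_fit)
    if rank < X_fit.shape[1]:
        # name the columns involved in the deficiency for the error message
        _, R = np.linalg.qr(X_fit)
        bad = [names[i] for i in np.where(np.abs(np.diag(R)) < 1e-8)[0]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X_fit.shape[1]}); "
            f"collinear columns: {bad}"
        )

    model = sm.GLM(y_fit, X_fit, family=sm.families.Poisson())
    # relative deviance change < 1e-8, at most 50 IRLS iterations
    res = model.fit(scale="X2", maxiter=50, atol=0.0, rtol=1e-8)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge for {series.location_id}: "
            f"deviance={res.deviance:.6g} after {res.fit_history['iteration']} iterations"
        )

    ncb = spec.k_var * spec.k_lag
    sl = slice(1, 1 + ncb)  # cross-basis block follows the intercept
    cov = np.asarray(res.cov_params())[sl, sl]
    tobs = series.tmean[np.isfinite(series.tmean)]
    pct = {p: float(np.percentile(tobs, p)) for p in CURVE_PERCENTILES}
    return FirstStageFit(
        location_id=series.location_id,
        coef=np.asarray(res.params)[sl],
        vcov=0.5 * (cov + cov.T),
        dispersion=float(res.scale),
        n_days=int(keep.sum()),
        spec=spec,
        converged=bool(res.converged),
        temp_percentiles=pct,
    )


def fit_location(
    series: DailySeries,
    spec: CrossBasisSpec | None = None,
    control: ControlSpec | None = None,
) -> ReducedCurve:
    """Convenience: first-stage fit followed by reduction to the overall curve."""
    return reduce_to_overall(fit_first_stage(series, spec=spec, control=control))
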