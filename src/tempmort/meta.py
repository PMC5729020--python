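"""Second stage: multivariate meta-regression of reduced curves, with BLUPs.

The location-specific overall cumulative curves (coefficient vectors
theta_i with within-location covariances V_i, all on one shared exposure
basis) are pooled under the random-effects model

    theta_i ~ MVN( Z_i gamma,  psi + V_i ),

where Z_i carries the location's meta-predictors (region and climate-class
indicators, GDP per capita, average and range of temperature) and psi is
the between-location covariance, estimated by REML with psi parameterised
through its Cholesky factor (hence always positive semidefinite).  Best
linear unbiased predictions shrink each location's curve toward the
meta-regression prediction in proportion to its imprecision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .dlnm import ReducedCurve

#: meta-predictor columns treated as categorical
CATEGORICAL = ("region", "climate_class")


class BlupCurve(ReducedCurve):
    """A location curve updated by BLUP shrinkage; same basis metadata."""


# ---------------------------------------------------------------------------
# design construction


@dataclass
class MetaDesign:
    X: np.ndarray  # (N, p) including the leading intercept
    names: list[str]
    center: np.ndarray  # standardisation offsets (0 for indicators)
    spread: np.ndarray  # standardisation scales (1 for indicators)


def build_design(
    predictors: pd.DataFrame | None,
    location_ids: list[str],
    formula: tuple[str, ...] = (),
) -> MetaDesign:
    """Intercept + reference-coded indicators + z-scored continuous columns.

    Categorical reference level is the first alphabetically.  Missing
    values are an error.  With an empty formula the design is
    intercept-only.
    """
    n = len(location_ids)
    cols = [np.ones(n)]
    names = ["intercept"]
    center = [0.0]
    spread = [1.0]
    if formula:
        if predictors is None:
            raise ValueError("a predictor table is required for a non-empty formula")
        tab = predictors.set_index("location_id").loc[location_ids]
        for name in formula:
            if name not in tab.columns:
                raise KeyError(f"meta-predictor {name!r} missing from the table")
            col = tab[name]
            if col.isna().any():
                bad = list(tab.index[col.isna()])
                raise ValueError(f"missing values for meta-predictor {name!r}: {bad}")
            if name in CATEGORICAL or col.dtype == object:
                levels = sorted(col.unique())
                for lev in levels[1:]:  # first level alphabetically is the reference
                    cols.append((col == lev).to_numpy(float))
                    names.append(f"{name}[{lev}]")
                    center.append(0.0)
                    spread.append(1.0)
            else:
                v = col.to_numpy(float)
                mu, sd = float(v.mean()), float(v.std())
                if sd == 0:
                    raise ValueError(f"meta-predictor {name!r} is constant")
                cols.append((v - mu) / sd)
                names.append(f"{name}_z")
                center.append(mu)
                spread.append(sd)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"meta-regression design is collinear (rank {rank} < {X.shape[1]}): {names}"
        )
    return MetaDesign(
        X=X, names=names, center=np.asarray(center), spread=np.asarray(spread)
    )


def _check_shared_basis(curves: list[ReducedCurve]) -> None:
    ref = curves[0]
    for c in curves[1:]:
        if len(c.theta) != len(ref.theta) or len(c.var_knots) != len(ref.var_knots):
            raise ValueError(
                f"curve {c.location_id} is not on the same basis as {ref.location_id}"
            )


# ---------------------------------------------------------------------------
# REML


@dataclass
class MetaFit:
    fixed_coefs: np.ndarray  # (p, k): one row per design column
    psi: np.ndarray  # (k, k) between-location covariance
    gamma_vcov: np.ndarray  # (p*k, p*k) covariance of vec(fixed_coefs)
    loglik_reml: float
    design: MetaDesign
    location_ids: list[str] = field(default_factory=list)
    converged: bool = True
    n_locations: int = 0
    k: int = 0

    def fitted_theta(self, x_row: np.ndarray) -> np.ndarray:
        """Meta-regression predicted curve coefficients for one design row."""
        return np.asarray(x_row, float) @ self.fixed_coefs


def _reml_neg2ll(
    Lvec: np.ndarray, thetas: np.ndarray, Vs: np.ndarray, X: np.ndarray
) -> float:
    N, k = thetas.shape
    p = X.shape[1]
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = Lvec
    psi = L @ L.T
    XtWX = np.zeros((p * k, p * k))
    XtWy = np.zeros(p * k)
    logdet_sum = 0.0
    Sinvs = np.empty((N, k, k))
    for i in range(N):
        S = psi + Vs[i]
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf
        logdet_sum += logdet
        Sinv = np.linalg.inv(S)
        Sinvs[i] = Sinv
        Zi = np.kron(X[i], np.eye(k))  # (k, p*k)
        XtWX += Zi.T @ Sinv @ Zi
        XtWy += Zi.T @ Sinv @ thetas[i]
    sign, logdet_X = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    gamma = np.linalg.solve(XtWX, XtWy)
    quad = 0.0
    for i in range(N):
        r = thetas[i] - np.kron(X[i], np.eye(k)) @ gamma
        quad += r @ Sinvs[i] @ r
    return logdet_sum + logdet_X + quad


def fit_meta_regression(
    curves: list[ReducedCurve],
    predictors: pd.DataFrame | None = None,
    formula: tuple[str, ...] = (),
    n_restarts: int = 3,
    seed: int = 0,
) -> MetaFit:
    """REML fit of the multivariate meta-regression.

    psi is optimised through its Cholesky factor (quasi-Newton, with
    jittered restarts and the psi = 0 boundary evaluated as a candidate);
    continuous predictors are standardised internally.
    """
    _check_shared_basis(curves)
    loc_ids = [c.location_id for c in curves]
    design = build_design(predictors, loc_ids, formula)
    X = design.X
    thetas = np.stack([c.theta for c in curves])
    Vs = np.stack([c.V for c in curves])
    N, k = thetas.shape
    p = X.shape[1]
    if N < p + 2:
        raise ValueError(
            f"{N} locations cannot support {p} fixed-effect columns (need >= p + 2)"
        )

    # moment start: between-location covariance net of average within-location
    resid = thetas - thetas.mean(axis=0)
    S0 = resid.T @ resid / max(N - 1, 1) - Vs.mean(axis=0)
    w, U = np.linalg.eigh(0.5 * (S0 + S0.T))
    S0 = U @ np.diag(np.clip(w, 1e-10, None)) @ U.T
    L0 = np.linalg.cholesky(S0 + 1e-10 * np.eye(k))
    x0 = L0[np.tril_indices(k)]

    rng = np.random.default_rng(seed)
    obj = lambda v: _reml_neg2ll(v, thetas, Vs, X)
    candidates = []
    starts = [x0] + [x0 * rng.uniform(0.5, 1.5, size=x0.shape) for _ in range(n_restarts - 1)]
    for s in starts:
        res = optimize.minimize(obj, s, method="L-BFGS-B", options={"maxiter": 500})
        candidates.append((res.fun, res.x, res.success))
    zero = np.zeros_like(x0)  # psi = 0 boundary
    candidates.append((obj(zero), zero, True))
    best = min(candidates, key=lambda c: c[0])
    if not np.isfinite(best[0]):
        raise RuntimeError(f"REML optimisation failed; last objective {best[0]}")

    Lbest = np.zeros((k, k))
    Lbest[np.tril_indices(k)] = best[1]
    psi = Lbest @ Lbest.T
    # final GLS pass at the optimum
    XtWX = np.zeros((p * k, p * k))
    XtWy = np.zeros(p * k)
    for i in range(N):
        Sinv = np.linalg.inv(psi + Vs[i])
        Zi = np.kron(X[i], np.eye(k))
        XtWX += Zi.T @ Sinv @ Zi
        XtWy += Zi.T @ Sinv @ thetas[i]
    gamma = np.linalg.solve(XtWX, XtWy)
    return MetaFit(
        fixed_coefs=gamma.reshape(p, k),
        psi=0.5 * (psi + psi.T),
        gamma_vcov=np.linalg.inv(XtWX),
        loglik_reml=-0.5 * best[0],
        design=design,
        location_ids=loc_ids,
        converged=bool(best[2]),
        n_locations=N,
        k=k,
    )


# ---------------------------------------------------------------------------
# BLUP


def blup_joint_components(
    fit: MetaFit, curves: list[ReducedCurve]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-location pieces of the joint BLUP error distribution.

    The uncertainty of location i's true curve decomposes into a
    fixed-effects component shared by every location and an independent
    conditional residual:

        theta*_i | data  ~  blup_i + G_i g + e_i,
        g ~ N(0, Var(gamma)),   e_i ~ N(0, psi - psi S_i^{-1} psi),

    with G_i = (I - psi S_i^{-1}) Z_i.  Returns [(G_i, C_i), ...]; Monte
    Carlo samplers that aggregate over locations must share the g draw
    across locations (the fixed-effect error is common), otherwise the
    pooled uncertainty is understated.
    """
    k = fit.k
    out = []
    for i, curve in enumerate(curves):
        x = fit.design.X[i]
        A = fit.psi @ np.linalg.inv(fit.psi + curve.V)
        IA = np.eye(k) - A
        G = IA @ np.kron(x, np.eye(k))
        C = fit.psi - A @ fit.psi
        out.append((G, 0.5 * (C + C.T)))
    return out


def compute_blups(fit: MetaFit, curves: list[ReducedCurve]) -> list[BlupCurve]:
    """Best linear unbiased predictions of each location's curve.

    theta_blup = Z gamma + psi (psi + V_i)^{-1} (theta_i - Z gamma); as
    V_i -> 0 the BLUP returns the location's own estimate, as psi -> 0 it
    collapses to the fixed-effect prediction.  The BLUP covariance
    combines the conditional variance with the fixed-effect uncertainty.
    """
    if len(curves) != len(fit.location_ids):
        raise ValueError("curve list does not match the fitted locations")
    k = fit.k
    out: list[BlupCurve] = []
    for i, curve in enumerate(curves):
        if curve.location_id != fit.location_ids[i]:
            raise ValueError("curve order must match the fitted location order")
        x = fit.design.X[i]
        mean_i = fit.fitted_theta(x)
        S = fit.psi + curve.V
        try:
            A = fit.psi @ np.linalg.inv(S)  # shrinkage weight toward theta_i
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular psi + V for location {curve.location_id}"
            ) from err
        theta_blup = mean_i + A @ (curve.theta - mean_i)
        Zi = np.kron(x, np.eye(k))
        IA = np.eye(k) - A
        V_blup = (
            fit.psi
            - A @ fit.psi
            + IA @ Zi @ fit.gamma_vcov @ Zi.T @ IA.T
        )
        V_blup = 0.5 * (V_blup + V_blup.T)
        out.append(
            BlupCurve(
                location_id=curve.location_id,
                theta=theta_blup,
                V=V_blup,
                var_knots=curve.var_knots.copy(),
                var_boundary=curve.var_boundary,
                centering_value=curve.centering_value,
                temp_percentiles=dict(curve.temp_percentiles),
            )
        )
    return out
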