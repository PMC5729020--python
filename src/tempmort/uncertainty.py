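"""Monte Carlo empirical confidence intervals (eCIs).

Uncertainty in the projected attributable fractions has two sources: the
estimation of the exposure-lag-response curves and the spread of the
climate projections across GCMs.  Both propagate through the same device:
S coefficient vectors are drawn from each location's BLUP distribution,
each draw is pushed through the attribution under every GCM series, and
the empirical 2.5th/97.5th percentiles of the pooled S x G statistics form
the 95% eCI.  Point estimates remain the GCM-ensemble averages at the
BLUP coefficients.  Net-change eCIs difference the statistic within each
(draw, GCM) pair across decades, never the endpoint intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dlnm import ReducedCurve

DEFAULT_MC_SAMPLES = 1000


@dataclass
class CoefficientSamples:
    location_id: str
    samples: np.ndarray  # (S, k)
    seed: int


@dataclass
class EmpiricalCI:
    point: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("empirical CI bounds are inverted")

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _sqrt_psd(V: np.ndarray) -> np.ndarray:
    """Matrix square root tolerating semidefinite (or slightly negative-
    rounded) covariances; raises on genuinely indefinite input."""
    V = 0.5 * (V + V.T)
    try:
        return np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(V)
        tol = -1e-8 * max(1.0, float(np.abs(w).max()))
        if w.min() < tol:
            raise np.linalg.LinAlgError(
                f"covariance is not positive semidefinite (min eigenvalue {w.min():.3g})"
            )
        return U * np.sqrt(np.clip(w, 0.0, None))


def location_seed(master_seed: int, index: int) -> int:
    """Per-location seed from a master seed via a counter scheme, stable
    under parallel execution order."""
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31)
    )


def sample_coefficients(
    curve: ReducedCurve, S: int = DEFAULT_MC_SAMPLES, seed: int = 0
) -> CoefficientSamples:
    """S multivariate-normal draws around the curve's coefficients."""
    if S < 2:
        raise ValueError("at least 2 Monte Carlo samples are required")
    root = _sqrt_psd(curve.V)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((S, len(curve.theta)))
    return CoefficientSamples(
        location_id=curve.location_id,
        samples=curve.theta + z @ root.T,
        seed=seed,
    )


def sample_blup_ensemble(
    blup_thetas: list[np.ndarray],
    components: list[tuple[np.ndarray, np.ndarray]],
    gamma_vcov: np.ndarray,
    S: int = DEFAULT_MC_SAMPLES,
    seed: int = 0,
) -> list[np.ndarray]:
    """Jointly sample every location's curve coefficients.

    One fixed-effects draw per Monte Carlo sample is shared by all
    locations (their BLUPs inherit the same pooled-curve error), plus an
    independent conditional residual per location; ``components`` comes
    from :func:`tempmort.meta.blup_joint_components`.  Returns one (S, k)
    array per location, in input order.
    """
    if S < 2:
        raise ValueError("at least 2 Monte Carlo samples are required")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((S, gamma_vcov.shape[0])) @ _sqrt_psd(gamma_vcov).T
    out = []
    for theta, (G, C) in zip(blup_thetas, components):
        eps = rng.standard_normal((S, len(theta))) @ _sqrt_psd(C).T
        out.append(theta + g @ G.T + eps)
    return out


def empirical_ci(values: np.ndarray, point: float) -> EmpiricalCI:
    """95% eCI from the pooled per-(draw, GCM) statistics.

    Quantiles use linear interpolation between order statistics (the
    type-7 convention), so endpoints are reproducible across platforms.
    The point estimate is supplied by the caller (the GCM-ensemble average
    at the BLUP coefficients) and is not constrained to lie inside the
    empirical bounds.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot form an empirical CI from no values")
    lo, hi = np.percentile(v, [2.5, 97.5])  # numpy default is type-7 linear
    return EmpiricalCI(point=float(point), lower=float(lo), upper=float(hi))
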