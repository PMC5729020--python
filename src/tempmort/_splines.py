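"""Natural cubic spline bases.

The exposure, lag and seasonal-control dimensions of the model all use
natural cubic splines: piecewise cubics that are constrained to be linear
beyond the boundary knots.  The linear tails are what allow log-linear
extrapolation of the exposure-response curve beyond the observed
temperature range, so the basis is built from the truncated-power
representation where that property holds exactly (not merely to rounding):

    N_1(x) = x
    N_{k+1}(x) = d_k(x) - d_{K-1}(x),   k = 1..K-2
    d_k(x) = [ (x - t_k)_+^3 - (x - t_K)_+^3 ] / (t_K - t_k)

with t_1 < ... < t_K the full (boundary + interior) knot sequence.  The
constant function is omitted; callers that need an intercept add it
explicitly.  The span of {1, N_1, ..., N_{K-1}} is the K-dimensional space
of natural cubic splines on these knots.
"""

from __future__ import annotations

import numpy as np


def _check_knots(interior: np.ndarray, boundary: tuple[float, float]) -> np.ndarray:
    lo, hi = float(boundary[0]), float(boundary[1])
    interior = np.asarray(interior, dtype=float).ravel()
    all_knots = np.concatenate([[lo], np.sort(interior), [hi]])
    if not np.all(np.diff(all_knots) > 0):
        raise ValueError(
            f"knots must be strictly increasing and inside the boundary: {all_knots}"
        )
    return all_knots


def ns_basis(
    x: np.ndarray,
    interior_knots,
    boundary: tuple[float, float],
) -> np.ndarray:
    """Evaluate the natural cubic spline basis (without intercept).

    Parameters
    ----------
    x
        Points at which to evaluate; any shape, flattened to 1-D.
    interior_knots
        Strictly increasing interior knots, all inside ``boundary``.
    boundary
        (lower, upper) boundary knots; the basis is linear outside them.

    Returns
    -------
    ndarray of shape (len(x), K - 1) where K = len(interior_knots) + 2.
    """
    knots = _check_knots(interior_knots, boundary)
    x = np.asarray(x, dtype=float).ravel()
    K = len(knots)
    t1, tK, tKm1 = knots[0], knots[-1], knots[-2]
    span = tK - t1

    def d(xv: np.ndarray, tk: float) -> np.ndarray:
        return (
            np.clip(xv - tk, 0.0, None) ** 3 - np.clip(xv - tK, 0.0, None) ** 3
        ) / (tK - tk)

    def raw_cols(xv: np.ndarray) -> list[np.ndarray]:
        cols = [xv / span]
        d_last = d(xv, tKm1)
        for k in range(K - 2):
            cols.append(d(xv, knots[k]) - d_last)
        return cols

    # normalise every column to O(1) over the knot span so coefficients are
    # comparable in size; scaling depends only on the knots
    ref = np.linspace(t1, tK, 201)
    scales = np.array([max(np.abs(c).max(), 1e-12) for c in raw_cols(ref)])
    scales[0] = 1.0  # the linear column is already span-scaled
    return np.column_stack(raw_cols(x)) / scales


def ns_dim(n_interior: int) -> int:
    """Basis dimension (without intercept) for a given interior knot count."""
    return n_interior + 1


def quantile_knots(x: np.ndarray, df: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Interior knots at equally spaced quantiles giving ``df`` basis columns.

    Boundary knots sit at the observed min/max; ``df`` columns require
    ``df - 1`` interior knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("df must be >= 2 for a natural cubic spline")
    probs = np.linspace(0, 1, df + 1)[1:-1]
    interior = np.quantile(x, probs)
    # nudge duplicates apart (heavy ties); strictly increasing knots required
    interior = np.maximum.accumulate(interior + np.arange(len(interior)) * 0.0)
    return interior, (float(x.min()), float(x.max()))
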