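"""Attribution of mortality to non-optimal temperature, and its aggregation.

Each day's temperature carries an overall cumulative relative risk (from
the location's BLUP exposure-response curve, referenced to the minimum
mortality temperature).  Under the forward perspective, the fraction
1 - exp(-logRR(x_t)) of the deaths expected over the next 21 days (the
lag window) is attributable to day t's temperature; attributable numbers
use the mean expected deaths over that forward window.  Contributions are
split into heat (x_t above the MMT) and cold (x_t below), summed by
calendar decade, and pooled into GCM-ensemble attributable fractions with
the total expected deaths as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ProjectionInputs
from .dlnm import DEFAULT_MAX_LAG, ReducedCurve, predict_curve

REFERENCE_DECADE = "2010-19"


def decade_label(year: int) -> str:
    start = (year // 10) * 10
    return f"{start}-{str(start + 9)[-2:]}"


# ---------------------------------------------------------------------------
# minimum mortality temperature


@dataclass
class MmtEstimate:
    location_id: str
    mmt: float
    mmt_percentile: float
    search_bounds: tuple[float, float]  # percentile pair


def find_mmt(
    curve: ReducedCurve,
    search_percentiles: tuple[float, float] = (1.0, 99.0),
    grid_step: float = 0.1,
) -> MmtEstimate:
    """Grid search for the minimum of the overall cumulative curve.

    The search runs over a fine grid between the location's search-bound
    temperature percentiles (default 1st-99th); ties break toward the
    lower temperature.
    """
    lo_p, hi_p = search_percentiles
    pct = curve.temp_percentiles
    if lo_p not in pct or hi_p not in pct:
        raise KeyError(
            f"curve percentile table lacks the search bounds {search_percentiles}"
        )
    lo, hi = pct[lo_p], pct[hi_p]
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    logrr, _ = predict_curve(curve, grid)
    if np.any(~np.isfinite(logrr)):
        raise FloatingPointError("non-finite curve predictions in the MMT search")
    mmt = float(grid[int(np.argmin(logrr))])  # argmin returns the first (lowest) tie
    keys = np.array(sorted(pct))
    vals = np.array([pct[k] for k in keys])
    mmt_pct = float(np.interp(mmt, vals, keys))
    return MmtEstimate(
        location_id=curve.location_id,
        mmt=mmt,
        mmt_percentile=mmt_pct,
        search_bounds=(lo_p, hi_p),
    )


# ---------------------------------------------------------------------------
# daily attribution


def forward_window_mean(
    values: np.ndarray, max_lag: int = DEFAULT_MAX_LAG, tail: str = "truncated"
) -> np.ndarray:
    """Mean of ``values`` over days t..t+max_lag for each t.

    ``tail='truncated'`` averages whatever days remain near the end of the
    series; ``tail='drop'`` marks incomplete windows NaN.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    w = max_lag + 1
    cs = np.concatenate([[0.0], np.cumsum(v)])
    stop = np.minimum(np.arange(n) + w, n)
    sums = cs[stop] - cs[:n]
    if tail == "truncated":
        return sums / (stop - np.arange(n))
    if tail == "drop":
        out = sums / w
        out[n - w + 1 :] = np.nan
        return out
    raise ValueError("tail must be 'truncated' or 'drop'")


def attributable_numbers(
    inputs: ProjectionInputs,
    curve: ReducedCurve,
    mmt: MmtEstimate,
    max_lag: int = DEFAULT_MAX_LAG,
    tail: str = "truncated",
    theta: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-day attributable deaths under the forward perspective.

    af_t = 1 - exp(-eta(x_t)) with eta the overall cumulative log-RR
    centred at the MMT; an_t = af_t x mean expected deaths over the next
    max_lag + 1 days.  Days at exactly the MMT contribute zero and belong
    to neither component.  ``theta`` substitutes alternative curve
    coefficients (e.g. a Monte Carlo draw) on the same basis.
    """
    if len(inputs.dates) <= max_lag:
        raise ValueError("projection series must be longer than the lag window")
    Z = curve.basis(inputs.tmean, center=mmt.mmt)
    eta = Z @ (curve.theta if theta is None else np.asarray(theta, float))
    af = 1.0 - np.exp(-eta)
    fwd = forward_window_mean(inputs.expected_deaths, max_lag=max_lag, tail=tail)
    an = af * fwd
    return pd.DataFrame(
        {
            "date": inputs.dates,
            "tmean": inputs.tmean,
            "an": an,
            "heat": inputs.tmean > mmt.mmt,
            "cold": inputs.tmean < mmt.mmt,
        }
    )


def decompose_and_total(
    an: np.ndarray, temps: np.ndarray, mmt: float
) -> tuple[float, float, float]:
    """Split daily contributions into heat/cold sums; total is their sum
    exactly (days at the MMT contribute zero by construction)."""
    an = np.asarray(an, dtype=float)
    temps = np.asarray(temps, dtype=float)
    an_heat = float(an[temps > mmt].sum())
    an_cold = float(an[temps < mmt].sum())
    return an_heat + an_cold, an_heat, an_cold


# ---------------------------------------------------------------------------
# decadal results


@dataclass
class AttributionResult:
    location_id: str
    gcm_id: str
    rcp_id: str
    decade: str
    an_total: float
    an_heat: float
    an_cold: float
    denom_deaths: float

    @property
    def af_total(self) -> float:
        return self.an_total / self.denom_deaths

    @property
    def af_heat(self) -> float:
        return self.an_heat / self.denom_deaths

    @property
    def af_cold(self) -> float:
        return self.an_cold / self.denom_deaths


def attribution_by_decade(
    inputs: ProjectionInputs,
    curve: ReducedCurve,
    mmt: MmtEstimate,
    max_lag: int = DEFAULT_MAX_LAG,
    tail: str = "truncated",
    theta: np.ndarray | None = None,
) -> list[AttributionResult]:
    """Decadal attributable numbers for one location x GCM x RCP.

    A forward window crossing a decade boundary is assigned entirely to
    the exposure day's decade; denominators are the expected deaths
    falling inside each decade.
    """
    daily = attributable_numbers(
        inputs, curve, mmt, max_lag=max_lag, tail=tail, theta=theta
    )
    years = inputs.dates.year.to_numpy()
    decades = (years // 10) * 10
    out = []
    for dec in np.unique(decades):
        sel = decades == dec
        total, heat, cold = decompose_and_total(
            daily["an"].to_numpy()[sel], inputs.tmean[sel], mmt.mmt
        )
        out.append(
            AttributionResult(
                location_id=inputs.location_id,
                gcm_id=inputs.gcm_id,
                rcp_id=inputs.rcp_id,
                decade=decade_label(int(dec)),
                an_total=total,
                an_heat=heat,
                an_cold=cold,
                denom_deaths=float(inputs.expected_deaths[sel].sum()),
            )
        )
    return out


def decadal_an_draws(
    inputs: ProjectionInputs,
    curve: ReducedCurve,
    mmt: MmtEstimate,
    thetas: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    tail: str = "truncated",
    grid_step: float = 0.1,
    redo_mmt: bool = False,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Decadal attributable numbers for many coefficient vectors at once.

    ``thetas`` is (S, k); returns (decade labels, an_total (n_dec, S),
    an_heat, an_cold).  Equivalent to running ``attribution_by_decade``
    per draw, vectorised for Monte Carlo use.  By default every draw is
    referenced to the point-estimate MMT: re-minimising within each draw
    would stack a second minimum-selection bias on top of the one already
    present in the point estimate (percentile intervals double bias rather
    than cancel it).  ``redo_mmt=True`` re-searches the MMT per draw
    instead, referencing each sampled curve to its own minimum.
    """
    thetas = np.asarray(thetas, float)
    if redo_mmt:
        lo, hi = (
            curve.temp_percentiles[mmt.search_bounds[0]],
            curve.temp_percentiles[mmt.search_bounds[1]],
        )
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        Gv = curve.basis(grid)  # any fixed centring; argmin is unaffected
        imin = np.argmin(Gv @ thetas.T, axis=0)  # first minimum: lower temp
        mmt_s = grid[imin]  # (S,)
        B = curve.basis(inputs.tmean)
        Bc = curve.basis(mmt_s)
        eta = B @ thetas.T - np.einsum("sk,sk->s", Bc, thetas)[None, :]
        heat = inputs.tmean[:, None] > mmt_s[None, :]
        cold = inputs.tmean[:, None] < mmt_s[None, :]
    else:
        Z = curve.basis(inputs.tmean, center=mmt.mmt)
        eta = Z @ thetas.T  # (n, S)
        heat = (inputs.tmean > mmt.mmt)[:, None]
        cold = (inputs.tmean < mmt.mmt)[:, None]
    af = 1.0 - np.exp(-eta)
    fwd = forward_window_mean(inputs.expected_deaths, max_lag=max_lag, tail=tail)
    an = af * fwd[:, None]
    years = inputs.dates.year.to_numpy()
    decades = (years // 10) * 10
    uniq = np.unique(decades)
    labels, tot, hot, cld = [], [], [], []
    for dec in uniq:
        sel = decades == dec
        hot_d = (an[sel] * heat[sel]).sum(axis=0)
        cld_d = (an[sel] * cold[sel]).sum(axis=0)
        labels.append(decade_label(int(dec)))
        hot.append(hot_d)
        cld.append(cld_d)
        tot.append(hot_d + cld_d)
    return labels, np.vstack(tot), np.vstack(hot), np.vstack(cld)


def results_to_frame(results: list[AttributionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "location_id": r.location_id,
                "gcm_id": r.gcm_id,
                "rcp_id": r.rcp_id,
                "decade": r.decade,
                "an_total": r.an_total,
                "an_heat": r.an_heat,
                "an_cold": r.an_cold,
                "denom_deaths": r.denom_deaths,
            }
            for r in results
        ]
    )


def aggregate(
    results: pd.DataFrame,
    grouping: str = "region",
    reference_decade: str = REFERENCE_DECADE,
    location_groups: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """GCM-ensemble attributable fractions by grouping x decade x RCP.

    Within each cell the fraction is the sum of attributable numbers over
    locations and GCMs divided by the corresponding sum of expected deaths
    (deaths-weighted, so pooling over GCMs is the ensemble average).  Net
    change is af_total minus the same cell's value in the reference
    decade.
    """
    df = results.copy()
    if grouping not in df.columns:
        if location_groups is None:
            raise KeyError(
                f"results lack a '{grouping}' column and no location table was given"
            )
        df = df.merge(
            location_groups[["location_id", grouping]], on="location_id", how="left"
        )
        if df[grouping].isna().any():
            missing = df.loc[df[grouping].isna(), "location_id"].unique()
            raise KeyError(f"locations missing a '{grouping}' value: {list(missing)}")

    g = (
        df.groupby([grouping, "decade", "rcp_id"], as_index=False)[
            ["an_total", "an_heat", "an_cold", "denom_deaths"]
        ].sum()
    )
    for part in ("total", "heat", "cold"):
        g[f"af_{part}"] = g[f"an_{part}"] / g["denom_deaths"]
    ref = g[g["decade"] == reference_decade][[grouping, "rcp_id", "af_total"]].rename(
        columns={"af_total": "_af_ref"}
    )
    if ref.empty:
        raise ValueError(f"reference decade {reference_decade!r} absent from results")
    g = g.merge(ref, on=[grouping, "rcp_id"], how="left")
    if g["_af_ref"].isna().any():
        raise ValueError(
            f"reference decade {reference_decade!r} missing for some groups"
        )
    g["net_change"] = g["af_total"] - g["_af_ref"]
    return g.drop(columns="_af_ref").rename(columns={grouping: "grouping"}).assign(
        grouping_kind=grouping
    )
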