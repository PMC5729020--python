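"""Synthetic data with known ground truth.

The real two-stage analysis runs on multi-city mortality archives and
bias-corrected climate-model output, neither of which is redistributable.
This module generates substitutes in which every quantity the pipeline
estimates is known by construction:

* daily temperature as seasonal cycle + AR(1) weather noise,
* overdispersed daily death counts driven by a known exposure-lag-response
  surface (a U-shaped cumulative log-RR curve distributed over lags 0..21
  by a non-negative weight vector summing to one) plus a sinusoidal
  seasonal mortality confounder,
* multi-location ensembles whose true curves differ by meta-predictor
  effects and random heterogeneity, and
* pseudo-GCM scenario series with injected bias (offset and scale) and a
  linear scenario warming ramp anchored so the 2010-19 decadal mean is
  unchanged.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from ._splines import ns_basis
from .climate import ModelledSeries
from .dlnm import DEFAULT_MAX_LAG, DailySeries

RCP_LABELS = ("RCP2.6", "RCP4.5", "RCP6.0", "RCP8.5")

# warming ramp anchors: decimal-year decadal midpoints of 2010-19 and 2090-99
_RAMP_REF_YEAR = 2015.0
_RAMP_END_YEAR = 2095.0


# ---------------------------------------------------------------------------
# ground-truth risk surfaces


@dataclass
class TrueRiskSurface:
    """Ground truth: cumulative log-RR curve, lag weights, and its MMT."""

    curve_fn: Callable[[np.ndarray], np.ndarray]
    lag_weights: np.ndarray
    mmt_true: float

    def __post_init__(self) -> None:
        w = np.asarray(self.lag_weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("lag weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag weights must sum to 1 within 1e-12")
        self.lag_weights = w

    @property
    def max_lag(self) -> int:
        return len(self.lag_weights) - 1


def decay_lag_weights(max_lag: int = DEFAULT_MAX_LAG, tau: float = 5.0) -> np.ndarray:
    """Geometric-decay lag weights over 0..max_lag, normalised to sum 1."""
    w = np.exp(-np.arange(max_lag + 1) / tau)
    return w / w.sum()


def basis_lag_weights(
    max_lag: int = DEFAULT_MAX_LAG,
    lag_knots: Sequence[float] | None = None,
    tau: float = 5.0,
) -> np.ndarray:
    """Decaying lag weights constrained to the span of the default lag basis.

    The geometric decay is projected (least squares) onto the natural-spline
    lag basis with intercept, shifted to be non-negative (the constant lies
    in the span) and rescaled to sum 1; useful when the simulated surface
    should be exactly representable by the fitted cross-basis.
    """
    from .dlnm import CrossBasisSpec

    spec = CrossBasisSpec(
        var_knots=[0.0], var_boundary=(-1.0, 1.0), max_lag=max_lag,
        lag_knots=lag_knots,
    )
    C = spec.lag_basis()
    target = np.exp(-np.arange(max_lag + 1) / tau)
    alpha, *_ = np.linalg.lstsq(C, target, rcond=None)
    w = C @ alpha
    if w.min() < 0:
        w = w - w.min()  # constant shift stays inside the span
    return w / w.sum()


def quadratic_risk_surface(
    mmt: float = 21.0,
    cold_logrr: float = 0.30,
    heat_logrr: float = 0.40,
    cold_ref_delta: float = 18.0,
    heat_ref_delta: float = 7.0,
    lag_weights: np.ndarray | None = None,
) -> TrueRiskSurface:
    """U-shaped curve: separate quadratic limbs below/above the MMT.

    ``cold_logrr`` is the cumulative log-RR ``cold_ref_delta`` degrees below
    the MMT; ``heat_logrr`` the analogue above it.  Defaults give RR ~ 1.35
    at deep cold and ~ 1.49 at extreme heat, the order of magnitude seen in
    multi-city temperature-mortality studies.
    """
    if lag_weights is None:
        lag_weights = decay_lag_weights()

    def curve(x):
        x = np.asarray(x, dtype=float)
        cold = cold_logrr * (np.clip(mmt - x, 0, None) / cold_ref_delta) ** 2
        heat = heat_logrr * (np.clip(x - mmt, 0, None) / heat_ref_delta) ** 2
        return cold + heat

    return TrueRiskSurface(curve_fn=curve, lag_weights=lag_weights, mmt_true=mmt)


def spline_risk_surface(
    theta: np.ndarray,
    var_knots: Sequence[float],
    var_boundary: tuple[float, float],
    lag_weights: np.ndarray | None = None,
    grid_step: float = 0.01,
) -> TrueRiskSurface:
    """Curve defined on a natural-spline basis (so a matching cross-basis
    can represent the simulated surface exactly)."""
    theta = np.asarray(theta, dtype=float)
    if lag_weights is None:
        lag_weights = basis_lag_weights()

    def raw(x):
        return ns_basis(x, var_knots, var_boundary) @ theta

    lo, hi = var_boundary
    grid = np.arange(lo, hi + grid_step, grid_step)
    vals = raw(grid)
    i = int(np.argmin(vals))
    mmt, offset = float(grid[i]), float(vals[i])

    def curve(x):
        return raw(x) - offset

    return TrueRiskSurface(curve_fn=curve, lag_weights=lag_weights, mmt_true=mmt)


def project_curve_to_spline(
    curve_fn: Callable[[np.ndarray], np.ndarray],
    var_knots: Sequence[float],
    var_boundary: tuple[float, float],
    n_grid: int = 400,
) -> np.ndarray:
    """Least-squares coefficients of a curve on the natural-spline basis
    (intercept absorbed, so only the shape is matched)."""
    lo, hi = var_boundary
    grid = np.linspace(lo, hi, n_grid)
    B = np.column_stack([np.ones(n_grid), ns_basis(grid, var_knots, var_boundary)])
    coef, *_ = np.linalg.lstsq(B, curve_fn(grid), rcond=None)
    return coef[1:]


# ---------------------------------------------------------------------------
# one location


@dataclass
class SyntheticLocationSpec:
    """Generating conditions for one location's observed daily series."""

    n_years: int = 10
    start_year: int = 2000
    base_rate: float = 30.0
    temp_mean: float = 15.0
    seasonal_amplitude: float = 10.0
    ar1_coef: float = 0.6
    noise_sd: float = 3.0
    overdispersion: float = 1.3
    mortality_seasonality: float = 0.10
    seed: int = 0
    location_id: str = "loc"
    meta_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be positive")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")
        if not (0 <= self.ar1_coef < 1):
            raise ValueError("ar1_coef must be in [0, 1)")


def _seasonal_temp(dates: pd.DatetimeIndex, mean: float, amplitude: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(float)
    return mean + amplitude * np.cos(2 * np.pi * (doy - 200.0) / 365.25)


def _ar1_noise(n: int, rho: float, marginal_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise with the given marginal SD."""
    if marginal_sd == 0 or n == 0:
        return np.zeros(n)
    innov_sd = marginal_sd * np.sqrt(1 - rho**2)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, marginal_sd)  # stationary start
    return lfilter([1.0], [1.0, -rho], e)


def generate_temperature_series(spec: SyntheticLocationSpec) -> pd.Series:
    """Daily mean temperature: seasonal sinusoid + stationary AR(1) noise.

    Returns a Series indexed by consecutive calendar dates covering
    ``n_years`` whole years (leap days included); deterministic per seed.
    """
    dates = pd.date_range(
        f"{spec.start_year}-01-01", f"{spec.start_year + spec.n_years - 1}-12-31",
        freq="D",
    )
    rng = np.random.default_rng(spec.seed)
    temps = _seasonal_temp(dates, spec.temp_mean, spec.seasonal_amplitude)
    temps = temps + _ar1_noise(len(dates), spec.ar1_coef, spec.noise_sd, rng)
    return pd.Series(temps, index=dates, name="tmean")


def _seasonal_mortality_factor(dates: pd.DatetimeIndex, amplitude: float) -> np.ndarray:
    doy = dates.dayofyear.to_numpy(float)
    return 1.0 + amplitude * np.cos(2 * np.pi * (doy - 15.0) / 365.25)


def expected_deaths(
    temps: pd.Series, surface: TrueRiskSurface, spec: SyntheticLocationSpec
) -> np.ndarray:
    """Expected daily deaths under the true surface (no count noise).

    Day t's rate is base_rate x seasonal factor x
    exp(sum_l w_l f(x_{t-l})); the lag history of the first max_lag days is
    padded with the first observed temperature (burn-in).
    """
    L = surface.max_lag
    x = temps.to_numpy(float)
    if len(x) < L + 1:
        raise ValueError("temperature series shorter than the lag window")
    padded = np.concatenate([np.full(L, x[0]), x])
    fx = surface.curve_fn(padded)
    eta = lfilter(surface.lag_weights, [1.0], fx)[L:]
    season = _seasonal_mortality_factor(
        pd.DatetimeIndex(temps.index), spec.mortality_seasonality
    )
    return spec.base_rate * season * np.exp(eta)


def generate_mortality_series(
    temps: pd.Series, surface: TrueRiskSurface, spec: SyntheticLocationSpec
) -> np.ndarray:
    """Draw daily death counts around the true rate.

    Counts are negative binomial with variance = overdispersion x mean
    (mean-scaled Gamma-Poisson mixture), reducing to Poisson when the
    overdispersion is exactly 1 -- the same variance law quasi-Poisson
    assumes when fitting.
    """
    mu = expected_deaths(temps, surface, spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 911]))
    phi = spec.overdispersion
    if phi == 1.0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=mu / (phi - 1.0), scale=phi - 1.0)
    return rng.poisson(lam)


def generate_location(
    spec: SyntheticLocationSpec, surface: TrueRiskSurface
) -> DailySeries:
    temps = generate_temperature_series(spec)
    deaths = generate_mortality_series(temps, surface, spec)
    return DailySeries(
        location_id=spec.location_id,
        dates=pd.DatetimeIndex(temps.index),
        tmean=temps.to_numpy(float),
        deaths=deaths,
    )


# ---------------------------------------------------------------------------
# pseudo-GCM scenario series


@dataclass
class ScenarioSpec:
    """One emission pathway emulated by ``n_gcms`` biased pseudo-GCMs."""

    rcp_id: str = "RCP8.5"
    warming_by_2099: float = 4.5
    gcm_bias_offset: float = 0.0
    gcm_bias_scale: float = 1.0
    n_gcms: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rcp_id not in RCP_LABELS:
            raise ValueError(f"rcp_id must be one of {RCP_LABELS}")
        if self.n_gcms < 1:
            raise ValueError("n_gcms must be >= 1")
        if self.gcm_bias_scale <= 0:
            raise ValueError("gcm_bias_scale must be positive")


def _fit_climatology(temps: pd.Series, n_harmonics: int = 2):
    """Smooth day-of-year climatology by harmonic regression; returns
    (predict_fn, anomalies, ar1, sd)."""
    dates = pd.DatetimeIndex(temps.index)
    y = temps.to_numpy(float)

    def design(idx: pd.DatetimeIndex) -> np.ndarray:
        doy = idx.dayofyear.to_numpy(float)
        ang = 2 * np.pi * doy / 365.25
        cols = [np.ones(len(idx))]
        for h in range(1, n_harmonics + 1):
            cols += [np.cos(h * ang), np.sin(h * ang)]
        return np.column_stack(cols)

    coef, *_ = np.linalg.lstsq(design(dates), y, rcond=None)
    anom = y - design(dates) @ coef
    sd = float(anom.std())
    rho = 0.0
    if sd > 0 and len(anom) > 2:
        rho = float(np.corrcoef(anom[:-1], anom[1:])[0, 1])
        rho = min(max(rho, 0.0), 0.99)
    return (lambda idx: design(idx) @ coef), anom, rho, sd


def _warming_ramp(dates: pd.DatetimeIndex, warming_by_2099: float) -> np.ndarray:
    yf = dates.year.to_numpy(float) + (dates.dayofyear.to_numpy(float) - 0.5) / 365.25
    return warming_by_2099 * (yf - _RAMP_REF_YEAR) / (_RAMP_END_YEAR - _RAMP_REF_YEAR)


def generate_modelled_climate(
    observed: pd.Series,
    scenario: ScenarioSpec,
    location_id: str = "loc",
    horizon: tuple[str, str] = ("1990-01-01", "2099-12-31"),
) -> tuple[list[ModelledSeries], dict]:
    """Pseudo-GCM daily series over the projection horizon, plus a truth record.

    Each GCM reproduces the observed day-of-year climatology plus weather
    anomalies (the observed anomalies are reused on dates inside the
    observed window, so the injected bias is identifiable on the overlap;
    fresh AR(1) anomalies elsewhere), distorted by the scenario's additive
    offset and multiplicative anomaly scale, plus a linear warming ramp
    reaching ``warming_by_2099`` degrees in 2090-99 relative to 2010-19.
    """
    dates = pd.date_range(horizon[0], horizon[1], freq="D")
    if len(dates) < 3653:
        raise ValueError("projection horizon must span at least one decade")
    clim_fn, anom_obs, rho, sd = _fit_climatology(observed)
    clim = clim_fn(dates)
    ramp = _warming_ramp(dates, scenario.warming_by_2099)
    obs_index = pd.DatetimeIndex(observed.index)
    in_obs = dates.isin(obs_index)
    obs_anom_series = pd.Series(anom_obs, index=obs_index)
    # bias scale acts on departures from the calendar-month anomaly mean, so
    # the injected offset stays identifiable from monthly overlap means
    manom = obs_anom_series.groupby(obs_index.month).mean().reindex(
        range(1, 13), fill_value=0.0
    ).to_numpy()
    manom_dates = manom[dates.month.to_numpy() - 1]

    out: list[ModelledSeries] = []
    truth: dict = {
        "rcp_id": scenario.rcp_id,
        "warming_by_2099": scenario.warming_by_2099,
        "gcm_bias_offset": scenario.gcm_bias_offset,
        "gcm_bias_scale": scenario.gcm_bias_scale,
        "ramp_reference": "2010-19 decadal mean",
        "gcms": [],
    }
    rcp_key = int.from_bytes(scenario.rcp_id.encode(), "little") % (2**31)
    ss = np.random.SeedSequence([scenario.seed, rcp_key])
    children = ss.spawn(scenario.n_gcms)
    for g in range(scenario.n_gcms):
        rng = np.random.default_rng(children[g])
        anom = _ar1_noise(len(dates), rho, sd, rng)
        if in_obs.any():
            anom[in_obs] = obs_anom_series.loc[dates[in_obs]].to_numpy()
        tmean = (
            clim
            + manom_dates
            + scenario.gcm_bias_offset
            + scenario.gcm_bias_scale * (anom - manom_dates)
            + ramp
        )
        gcm_id = f"GCM{g + 1}"
        out.append(
            ModelledSeries(
                location_id=location_id,
                gcm_id=gcm_id,
                rcp_id=scenario.rcp_id,
                dates=dates,
                tmean=tmean,
            )
        )
        truth["gcms"].append({"gcm_id": gcm_id, "seed_spawn": g})
    return out, truth


# ---------------------------------------------------------------------------
# multi-location ensembles


@dataclass
class LocationTruth:
    """One ensemble member: observed series, metadata row, true surface."""

    series: DailySeries
    metadata: dict
    surface: TrueRiskSurface
    theta_true: np.ndarray | None = None  # spline-family coefficients, if any


#: shared exposure-basis layout for spline-family ensembles; chosen to match
#: the 10th/75th/90th percentiles of the default location climatology
ENSEMBLE_VAR_KNOTS = (6.0, 21.0, 25.0)
ENSEMBLE_VAR_BOUNDARY = (-5.0, 35.0)

_REGIONS = ("North", "South")
_CLIMATES = ("temperate", "warm")


def make_multilocation_ensemble(
    n_locations: int,
    heterogeneity_sd: float = 0.02,
    seed: int = 0,
    n_years: int = 8,
    base_rate: float = 30.0,
    gdp_effect: float = 0.1,
    overdispersion: float = 1.3,
) -> list[LocationTruth]:
    """Ensemble with known between-location structure, on a shared basis.

    Each location's true cumulative curve is a natural cubic spline on the
    shared ``ENSEMBLE_VAR_KNOTS`` layout: a common U-shaped base curve,
    plus ``gdp_effect`` x (GDP z-score) added to the heat limb, plus
    independent N(0, heterogeneity_sd^2) deviations on every spline
    coefficient.  All truths (curves, coefficient vectors, GDP effect in
    coefficient space) are recorded for recovery tests.
    """
    if n_locations < 2:
        raise ValueError("n_locations must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    knots, boundary = np.asarray(ENSEMBLE_VAR_KNOTS), ENSEMBLE_VAR_BOUNDARY

    base = quadratic_risk_surface()
    theta0 = project_curve_to_spline(base.curve_fn, knots, boundary)
    heat = quadratic_risk_surface(cold_logrr=0.0, heat_logrr=1.0)
    theta_heat = project_curve_to_spline(heat.curve_fn, knots, boundary)
    lag_w = basis_lag_weights()

    gdp_z = rng.normal(0.0, 1.0, size=n_locations)
    out: list[LocationTruth] = []
    for i in range(n_locations):
        theta_i = (
            theta0
            + gdp_effect * gdp_z[i] * theta_heat
            + rng.normal(0.0, heterogeneity_sd, size=len(theta0))
        )
        surface = spline_risk_surface(theta_i, knots, boundary, lag_weights=lag_w)
        loc_id = f"loc{i:03d}"
        spec = SyntheticLocationSpec(
            n_years=n_years,
            base_rate=base_rate,
            overdispersion=overdispersion,
            seed=int(rng.integers(0, 2**31 - 1)),
            location_id=loc_id,
            meta_values={
                "region": _REGIONS[i % 2],
                "climate_class": _CLIMATES[(i // 2) % 2],
                "gdp_pc": 30000.0 * np.exp(0.5 * gdp_z[i]),
            },
        )
        series = generate_location(spec, surface)
        meta = {
            "location_id": loc_id,
            **spec.meta_values,
            "gdp_z_true": float(gdp_z[i]),
            "temp_avg": float(series.tmean.mean()),
            "temp_range": float(series.tmean.max() - series.tmean.min()),
        }
        out.append(
            LocationTruth(
                series=series, metadata=meta, surface=surface, theta_true=theta_i
            )
        )
    return out


def ensemble_truth_record(ensemble: list[LocationTruth]) -> dict:
    return {
        "var_knots": list(ENSEMBLE_VAR_KNOTS),
        "var_boundary": list(ENSEMBLE_VAR_BOUNDARY),
        "locations": [
            {
                "location_id": m.metadata["location_id"],
                "theta_true": list(map(float, m.theta_true)),
                "mmt_true": m.surface.mmt_true,
                "gdp_z_true": m.metadata["gdp_z_true"],
            }
            for m in ensemble
        ],
    }
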