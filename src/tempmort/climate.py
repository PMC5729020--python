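"""Climate-model series handling: grid linkage, recalibration, projection inputs.

Modelled daily temperature arrives per location x GCM x RCP over the
projection horizon (1990-2099).  Before attribution, each modelled series
is recalibrated against the location's observed series so that the
modelled climatology reproduces the observed one while the modelled
long-term warming trend is preserved: calendar-month additive offsets are
applied to the running monthly means, and a multiplicative factor corrects
the within-month daily variability.  Baseline mortality for the projection
period is the day-of-year average of observed counts, repeated along the
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .dlnm import DailySeries

PROJECTION_START = "1990-01-01"
PROJECTION_END = "2099-12-31"
GRID_RES = 0.5  # degrees; half-open cells, centres at 0.25-degree offsets


# ---------------------------------------------------------------------------
# containers


@dataclass
class ModelledSeries:
    """One GCM x RCP daily temperature series for one location."""

    location_id: str
    gcm_id: str
    rcp_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) != len(self.tmean):
            raise ValueError("dates and tmean must have equal length")
        if len(self.dates) > 1:
            step = np.diff(self.dates.values).astype("timedelta64[D]")
            if not np.all(step == np.timedelta64(1, "D")):
                raise ValueError("modelled series must cover its horizon with no gaps")

    def to_csv(self, path) -> None:
        pd.DataFrame({"date": self.dates, "tmean": self.tmean}).to_csv(
            path, index=False, date_format="%Y-%m-%d"
        )

    @classmethod
    def from_csv(cls, path, location_id: str, gcm_id: str, rcp_id: str):
        df = pd.read_csv(path, parse_dates=["date"])
        return cls(
            location_id=location_id,
            gcm_id=gcm_id,
            rcp_id=rcp_id,
            dates=pd.DatetimeIndex(df["date"]),
            tmean=df["tmean"].to_numpy(float),
        )


@dataclass
class RecalibrationMap:
    """Per-calendar-month offset (deg C, applied to monthly means) and
    weather-residual scale factor, plus the reference day-of-year shape
    (harmonic coefficients of the observed climatology) the residuals are
    defined against."""

    offset: np.ndarray  # 12 values, January first
    scale: np.ndarray  # 12 values, > 0
    seasonal_coefs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.offset.shape != (12,) or self.scale.shape != (12,):
            raise ValueError("recalibration map needs exactly 12 monthly entries")
        if np.any(self.scale <= 0):
            raise ValueError("scale factors must be positive")
        if self.seasonal_coefs is not None:
            self.seasonal_coefs = np.asarray(self.seasonal_coefs, dtype=float)


@dataclass
class BaselineMortalityProfile:
    """Expected deaths for day-of-year 1..366 (day 366 is Feb 29)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (366,):
            raise ValueError("profile must have 366 entries")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("profile values must be finite and non-negative")


@dataclass
class ProjectionInputs:
    """Daily recalibrated temperature + expected deaths over the horizon."""

    location_id: str
    gcm_id: str
    rcp_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    expected_deaths: np.ndarray

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "date": self.dates,
                "tmean": self.tmean,
                "expected_deaths": self.expected_deaths,
            }
        ).to_csv(path, index=False, date_format="%Y-%m-%d")


# ---------------------------------------------------------------------------
# grid linkage


def extract_grid_series(grid: xr.DataArray, lon: float, lat: float) -> pd.Series:
    """Daily series of the 0.5-degree cell containing (lon, lat).

    Cells are half-open intervals [west, west + 0.5) x [south, south + 0.5)
    with centres at 0.25-degree offsets; a point exactly on a west/south
    edge belongs to that cell.  ``grid`` must carry ``lat``/``lon``
    coordinates at cell centres and a ``time`` dimension.
    """
    lons = np.asarray(grid["lon"].values, dtype=float)
    lats = np.asarray(grid["lat"].values, dtype=float)
    west = lons - GRID_RES / 2
    south = lats - GRID_RES / 2
    i = np.where((lon >= west) & (lon < west + GRID_RES))[0]
    j = np.where((lat >= south) & (lat < south + GRID_RES))[0]
    if len(i) == 0 or len(j) == 0:
        raise KeyError(
            f"point (lon={lon}, lat={lat}) falls outside the grid bounds"
        )
    cell = grid.isel(lon=int(i[0]), lat=int(j[0]))
    return pd.Series(
        np.asarray(cell.values, dtype=float), index=pd.DatetimeIndex(cell["time"].values)
    )


# ---------------------------------------------------------------------------
# recalibration


def _month_instance_means(dates: pd.DatetimeIndex, x: np.ndarray) -> np.ndarray:
    """Per-day value of the mean of x over that day's (year, month) block."""
    df = pd.DataFrame({"x": x}, index=dates)
    return df.groupby([dates.year, dates.month])["x"].transform("mean").to_numpy()


def _harmonic_coefs(dates: pd.DatetimeIndex, x: np.ndarray, n_harmonics: int = 2):
    ang = 2 * np.pi * dates.dayofyear.to_numpy(float) / 365.25
    cols = [np.ones(len(dates))]
    for h in range(1, n_harmonics + 1):
        cols += [np.cos(h * ang), np.sin(h * ang)]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return coef


def _harmonic_values(dates: pd.DatetimeIndex, coef: np.ndarray) -> np.ndarray:
    n_harmonics = (len(coef) - 1) // 2
    ang = 2 * np.pi * dates.dayofyear.to_numpy(float) / 365.25
    cols = [np.ones(len(dates))]
    for h in range(1, n_harmonics + 1):
        cols += [np.cos(h * ang), np.sin(h * ang)]
    return np.column_stack(cols) @ coef


def _seasonal_shape(dates: pd.DatetimeIndex, coef: np.ndarray) -> np.ndarray:
    """Deterministic within-month day-of-year shape: the harmonic
    climatology minus its own (year, month) instance means."""
    h = _harmonic_values(dates, coef)
    return h - _month_instance_means(dates, h)


def calibrate(
    modelled: ModelledSeries, observed: DailySeries
) -> tuple[RecalibrationMap, ModelledSeries]:
    """Month-wise recalibration of a modelled series against observations.

    Each daily value decomposes into its (year, month) instance mean, a
    deterministic within-month seasonal shape (harmonic day-of-year
    climatology detrended per instance), and a weather residual.  On the
    overlap period, the additive offset delta_m per calendar month m is
    the observed-minus-modelled monthly mean; the factor s_m is the ratio
    of weather-residual standard deviations.  The correction shifts the
    running monthly means by delta_m (so the modelled long-term trend is
    preserved exactly) and rescales the weather residuals by s_m; on the
    overlap the corrected monthly means reproduce the observed ones
    exactly and the within-month weather variability matches the observed
    level.
    """
    obs_idx = pd.DatetimeIndex(observed.dates)
    mod_idx = modelled.dates
    overlap = mod_idx.intersection(obs_idx)
    if len(overlap) < int(5 * 365):
        raise ValueError(
            f"overlap between modelled and observed series is {len(overlap)} days; "
            "at least 5 years are required for recalibration"
        )
    obs = pd.Series(observed.tmean, index=obs_idx).loc[overlap].to_numpy()
    mod_all = pd.Series(modelled.tmean, index=mod_idx)
    mod = mod_all.loc[overlap].to_numpy()

    # one reference day-of-year shape, taken from the observations, defines
    # the weather residuals of both series (and of any recalibrated output,
    # which makes the map idempotent)
    ref_harm = _harmonic_coefs(overlap, obs)
    shape = _seasonal_shape(overlap, ref_harm)
    obs_resid = obs - _month_instance_means(overlap, obs) - shape
    mod_resid = mod - _month_instance_means(overlap, mod) - shape
    months = overlap.month.to_numpy()

    offset = np.empty(12)
    scale = np.empty(12)
    for m in range(1, 13):
        sel = months == m
        if not sel.any():
            raise ValueError(f"overlap period has no days in calendar month {m}")
        offset[m - 1] = obs[sel].mean() - mod[sel].mean()
        s_obs = obs_resid[sel].std()
        s_mod = mod_resid[sel].std()
        scale[m - 1] = s_obs / s_mod if s_mod > 0 and s_obs > 0 else 1.0
    rmap = RecalibrationMap(offset=offset, scale=scale, seasonal_coefs=ref_harm)
    return rmap, apply_recalibration(modelled, rmap)


def apply_recalibration(
    modelled: ModelledSeries, rmap: RecalibrationMap
) -> ModelledSeries:
    """Apply a recalibration map: shift running monthly means by the
    offsets, rescale weather residuals about the reference day-of-year
    shape; the shape itself and the long-term trend pass through."""
    m = modelled.dates.month.to_numpy() - 1
    mbar = _month_instance_means(modelled.dates, modelled.tmean)
    if rmap.seasonal_coefs is None:
        shape = np.zeros(len(modelled.dates))
    else:
        shape = _seasonal_shape(modelled.dates, rmap.seasonal_coefs)
    resid = modelled.tmean - mbar - shape
    corrected = mbar + rmap.offset[m] + shape + rmap.scale[m] * resid
    return ModelledSeries(
        location_id=modelled.location_id,
        gcm_id=modelled.gcm_id,
        rcp_id=modelled.rcp_id,
        dates=modelled.dates,
        tmean=corrected,
    )


# ---------------------------------------------------------------------------
# baseline mortality


def _profile_index(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map each date to the profile slot: non-leap day-of-year 1..365,
    with Feb 29 sent to slot 366."""
    doy = dates.dayofyear.to_numpy()
    leap = dates.is_leap_year
    feb29 = leap & (dates.month == 2) & (dates.day == 29)
    idx = doy.copy()
    after = leap & (doy > 59)  # dates past Feb 28 in leap years
    idx[after] -= 1
    idx[feb29] = 366
    return idx


def baseline_mortality_profile(series: DailySeries) -> BaselineMortalityProfile:
    """Average observed deaths for each day of the year.

    Day 366 holds the mean of observed Feb 29 counts; if the observation
    window contains no Feb 29, it falls back to the mean of the Feb 28 and
    Mar 1 profile values.
    """
    if len(series.dates) < 365:
        raise ValueError("at least one complete year of observations is required")
    idx = _profile_index(pd.DatetimeIndex(series.dates))
    deaths = np.asarray(series.deaths, dtype=float)
    ok = np.isfinite(deaths)
    values = np.zeros(366)
    sums = np.bincount(idx[ok], weights=deaths[ok], minlength=367)[1:367]
    counts = np.bincount(idx[ok], minlength=367)[1:367]
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if counts[365] == 0:  # no Feb 29 observed
        values[365] = 0.5 * (values[58] + values[59])  # Feb 28 + Mar 1 slots
    if np.any(~np.isfinite(values)):
        missing = np.where(~np.isfinite(values))[0] + 1
        raise ValueError(f"no observations for day-of-year slots {missing}")
    return BaselineMortalityProfile(values=values)


def expected_deaths_for_dates(
    profile: BaselineMortalityProfile, dates: pd.DatetimeIndex
) -> np.ndarray:
    return profile.values[_profile_index(dates) - 1]


def build_projection_inputs(
    recal: ModelledSeries, profile: BaselineMortalityProfile
) -> ProjectionInputs:
    """Pair the recalibrated temperature series with the baseline mortality
    profile mapped onto every calendar date of the projection horizon."""
    return ProjectionInputs(
        location_id=recal.location_id,
        gcm_id=recal.gcm_id,
        rcp_id=recal.rcp_id,
        dates=recal.dates,
        tmean=recal.tmean,
        expected_deaths=expected_deaths_for_dates(profile, recal.dates),
    )
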