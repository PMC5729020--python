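"""Grid linkage, recalibration, baseline mortality, projection inputs."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import tempmort as tm
from tempmort.climate import calibrate, expected_deaths_for_dates


def _daily(loc, dates, tmean, deaths=None):
    n = len(dates)
    return tm.DailySeries(
        location_id=loc,
        dates=dates,
        tmean=np.asarray(tmean, float),
        deaths=np.zeros(n, int) if deaths is None else deaths,
    )


def _modelled(dates, tmean, gcm="GCM1", rcp="RCP8.5"):
    return tm.ModelledSeries(
        location_id="loc", gcm_id=gcm, rcp_id=rcp, dates=dates,
        tmean=np.asarray(tmean, float),
    )


@pytest.fixture(scope="module")
def observed():
    spec = tm.SyntheticLocationSpec(n_years=10, start_year=1995, seed=33)
    t = tm.generate_temperature_series(spec)
    rng = np.random.default_rng(1)
    return _daily("loc", pd.DatetimeIndex(t.index), t.to_numpy(),
                  rng.poisson(30, len(t)))


@pytest.fixture(scope="module")
def grid():
    lons = np.arange(10.25, 12.0, 0.5)  # cells [10,10.5), [10.5,11), ...
    lats = np.arange(45.25, 46.5, 0.5)
    time = pd.date_range("2000-01-01", periods=3, freq="D")
    vals = np.zeros((3, len(lats), len(lons)))
    for j in range(len(lats)):
        for i in range(len(lons)):
            vals[:, j, i] = 100 * i + 10 * j + np.arange(3)
    return xr.DataArray(
        vals, dims=("time", "lat", "lon"),
        coords={"time": time, "lat": lats, "lon": lons},
    )


class TestGridExtraction:

    def test_half_open_edge_belongs_to_cell(self, grid):
        # lon 10.5 is the west edge of the second cell (centre 10.75)
        s = tm.extract_grid_series(grid, lon=10.5, lat=45.1)
        np.testing.assert_allclose(s.to_numpy(), 100 * 1 + 10 * 0 + np.arange(3))

    def test_constructed_grid_oracle(self, grid):
        s = tm.extract_grid_series(grid, lon=11.3, lat=46.2)
        # lon 11.3 in [11.0, 11.5) -> i=2; lat 46.2 in [46.0, 46.5) -> j=2
        np.testing.assert_allclose(s.to_numpy(), 100 * 2 + 10 * 2 + np.arange(3))

    def test_resolution_is_half_degree(self, grid):
        from tempmort.climate import GRID_RES

        assert GRID_RES == 0.5
        assert np.allclose(np.diff(grid["lon"].values), 0.5)

    def test_out_of_bounds_rejected(self, grid):
        with pytest.raises(KeyError):
            tm.extract_grid_series(grid, lon=50.0, lat=45.3)


class TestCalibration:
    def test_pure_offset_recovered(self, observed):
        mod = _modelled(pd.DatetimeIndex(observed.dates), observed.tmean + 2.0)
        rmap, recal = calibrate(mod, observed)
        np.testing.assert_allclose(rmap.offset, -2.0, atol=1e-9)
        np.testing.assert_allclose(rmap.scale, 1.0, atol=1e-9)
        np.testing.assert_allclose(recal.tmean, observed.tmean, atol=1e-9)

    def test_identity_map_for_identical_series(self, observed):
        mod = _modelled(pd.DatetimeIndex(observed.dates), observed.tmean)
        rmap, recal = calibrate(mod, observed)
        np.testing.assert_allclose(rmap.offset, 0.0, atol=1e-9)
        np.testing.assert_allclose(rmap.scale, 1.0, atol=1e-9)

    def test_constructed_distortion_recovered(self, observed):
        """Modelled = 1.5 x anomalies + climatological month mean + 1:
        the map recovers scale 1/1.5 and removes the +1 offset, and the
        recalibrated overlap reproduces observed monthly means."""
        dates = pd.DatetimeIndex(observed.dates)
        months = dates.month
        clim = pd.Series(observed.tmean, index=dates).groupby(months).transform("mean")
        mod_vals = 1.5 * (observed.tmean - clim.to_numpy()) + clim.to_numpy() + 1.0
        rmap, recal = calibrate(_modelled(dates, mod_vals), observed)
        # the distortion also scales the within-month seasonal shape, which
        # the map deliberately leaves unscaled, so recovery is approximate
        np.testing.assert_allclose(rmap.scale, 1 / 1.5, atol=0.06)
        obs = pd.Series(observed.tmean, index=dates)
        rec = pd.Series(recal.tmean, index=dates)
        for m in range(1, 13):
            np.testing.assert_allclose(
                rec[months == m].mean(), obs[months == m].mean(), atol=1e-9
            )

    def test_idempotence(self, observed):
        dates = pd.DatetimeIndex(observed.dates)
        mod = _modelled(dates, observed.tmean * 1.2 + 3.0)
        rmap1, recal1 = calibrate(mod, observed)
        rmap2, _ = calibrate(recal1, observed)
        np.testing.assert_allclose(rmap2.offset, 0.0, atol=1e-9)
        np.testing.assert_allclose(rmap2.scale, 1.0, atol=1e-9)

    def test_trend_preserved(self, observed):
        """A linear warming trend in the modelled series survives the
        correction: fitted decadal slope unchanged within 1%."""
        dates = pd.date_range("1990-01-01", "2049-12-31", freq="D")
        rng = np.random.default_rng(5)
        yf = dates.year + dates.dayofyear / 365.25
        trend = 0.03 * (yf - 1990)  # 0.3 C per decade
        base = 12 + 8 * np.cos(2 * np.pi * (dates.dayofyear - 200) / 365.25)
        mod_vals = base + trend + rng.normal(0, 2.0, len(dates)) + 1.5
        mod = _modelled(dates, mod_vals)
        _, recal = calibrate(mod, observed)
        A = np.column_stack([np.ones(len(dates)), yf - 1990])
        slope_before = np.linalg.lstsq(A, mod.tmean, rcond=None)[0][1]
        slope_after = np.linalg.lstsq(A, recal.tmean, rcond=None)[0][1]
        assert abs(slope_after - slope_before) / abs(slope_before) < 0.01

    def test_injected_gcm_bias_recovered(self, observed):
        """Pseudo-GCM series with known offset/scale: the map recovers them
        within 0.05 C and 0.02."""
        scen = tm.ScenarioSpec(
            rcp_id="RCP4.5", warming_by_2099=0.0, gcm_bias_offset=1.3,
            gcm_bias_scale=1.25, n_gcms=1, seed=6,
        )
        temps = pd.Series(observed.tmean, index=pd.DatetimeIndex(observed.dates))
        series, _ = tm.generate_modelled_climate(temps, scen)
        rmap, _ = calibrate(series[0], observed)
        np.testing.assert_allclose(rmap.offset, -1.3, atol=0.05)
        np.testing.assert_allclose(rmap.scale, 1 / 1.25, atol=0.02)

    def test_insufficient_overlap_rejected(self, observed):
        dates = pd.date_range("1995-01-01", periods=800, freq="D")
        mod = _modelled(dates, np.zeros(800))
        with pytest.raises(ValueError):
            calibrate(mod, observed)


class TestBaselineProfile:
    def test_constant_deaths_give_constant_profile(self):
        dates = pd.date_range("2001-01-01", "2004-12-31", freq="D")
        s = _daily("loc", dates, np.zeros(len(dates)), np.full(len(dates), 30))
        profile = tm.baseline_mortality_profile(s)
        np.testing.assert_allclose(profile.values, 30.0)

    def test_two_year_arithmetic_mean(self):
        dates = pd.date_range("2001-01-01", "2002-12-31", freq="D")
        deaths = np.where(dates.year == 2001, 10, 20)
        s = _daily("loc", dates, np.zeros(len(dates)), deaths)
        profile = tm.baseline_mortality_profile(s)
        np.testing.assert_allclose(profile.values[:365], 15.0)
        # no Feb 29 observed: slot 366 falls back to the Feb 28 / Mar 1 mean
        assert profile.values[365] == pytest.approx(15.0)

    def test_feb29_slot_uses_leap_day_only(self):
        dates = pd.date_range("2004-01-01", "2005-12-31", freq="D")
        deaths = np.full(len(dates), 10.0)
        feb29 = (dates.month == 2) & (dates.day == 29)
        deaths[feb29] = 99.0
        s = _daily("loc", dates, np.zeros(len(dates)), deaths)
        profile = tm.baseline_mortality_profile(s)
        assert profile.values[365] == 99.0
        np.testing.assert_allclose(profile.values[:365], 10.0)


class TestProjectionInputs:
    def test_horizon_and_leap_days(self, observed):
        dates = pd.date_range("1990-01-01", "2099-12-31", freq="D")
        mod = _modelled(dates, np.full(len(dates), 15.0))
        profile = tm.baseline_mortality_profile(observed)
        inputs = tm.build_projection_inputs(mod, profile)
        assert inputs.dates[0] == pd.Timestamp("1990-01-01")
        assert inputs.dates[-1] == pd.Timestamp("2099-12-31")
        feb29 = (inputs.dates.month == 2) & (inputs.dates.day == 29)
        assert feb29.sum() == 27  # leap days in 1990-2099 (2100 excluded)
        np.testing.assert_allclose(
            inputs.expected_deaths[feb29], profile.values[365]
        )

    def test_non_leap_year_total_is_sum_of_profile(self, observed):
        profile = tm.baseline_mortality_profile(observed)
        dates = pd.date_range("2001-01-01", "2001-12-31", freq="D")
        expected = expected_deaths_for_dates(profile, dates)
        assert expected.sum() == pytest.approx(profile.values[:365].sum())

    def test_projection_total_matches_profile_bookkeeping(self, observed):
        """Total expected deaths over the horizon equal the profile total
        per year type summed over the calendar."""
        profile = tm.baseline_mortality_profile(observed)
        dates = pd.date_range("1990-01-01", "1999-12-31", freq="D")
        mod = _modelled(dates, np.full(len(dates), 15.0))
        inputs = tm.build_projection_inputs(mod, profile)
        n_leap = sum(pd.Timestamp(f"{y}-12-31").is_leap_year for y in range(1990, 2000))
        expected_total = 10 * profile.values[:365].sum() + n_leap * profile.values[365]
        assert inputs.expected_deaths.sum() == pytest.approx(expected_total)
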