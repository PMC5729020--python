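"""MMT search, forward attribution, heat/cold split, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tempmort as tm
from tempmort.attribution import (
    REFERENCE_DECADE,
    attribution_by_decade,
    decadal_an_draws,
    decade_label,
    forward_window_mean,
    results_to_frame,
)
from tempmort.synth import project_curve_to_spline

from conftest import constant_inputs, linear_curve


def _spline_curve(curve_fn, knots, boundary, percentiles):
    theta = project_curve_to_spline(curve_fn, knots, boundary)
    return tm.ReducedCurve(
        location_id="c", theta=theta, V=np.zeros((len(theta), len(theta))),
        var_knots=np.asarray(knots, float), var_boundary=boundary,
        centering_value=float(np.mean(boundary)), temp_percentiles=percentiles,
    )


class TestMmt:
    PCT = {1.0: 8.0, 50.0: 18.0, 99.0: 28.0}

    def test_quadratic_minimum_found(self):
        curve = _spline_curve(
            lambda x: 0.01 * (np.asarray(x, float) - 18.0) ** 2,
            [12.0, 18.0, 24.0], (5.0, 31.0), self.PCT,
        )
        est = tm.find_mmt(curve)
        assert est.mmt == pytest.approx(18.0, abs=0.2)
        assert 8.0 <= est.mmt <= 28.0

    def test_monotone_curve_hits_lower_bound(self):
        est = tm.find_mmt(linear_curve(theta0=2.0))
        assert est.mmt == pytest.approx(2.0)  # 1st percentile temperature
        assert est.mmt_percentile == pytest.approx(1.0)

    def test_flat_curve_ties_to_lower_bound(self):
        est = tm.find_mmt(linear_curve(theta0=0.0))
        assert est.mmt == pytest.approx(2.0)


class TestDailyAttribution:
    def test_all_days_at_mmt_give_zero(self):
        inputs = constant_inputs(temp=10.0)
        curve = linear_curve(theta0=1.5, center=10.0)
        mmt = tm.MmtEstimate("loc", 10.0, 50.0, (1.0, 99.0))
        daily = tm.attributable_numbers(inputs, curve, mmt)
        np.testing.assert_allclose(daily["an"], 0.0, atol=1e-15)

    def test_log2_curve_attributes_half_the_deaths(self):
        # eta = log 2 at 20 C: theta chosen so (20 - 10)/30 * theta = log 2
        curve = linear_curve(theta0=np.log(2.0) * 3.0, center=10.0)
        inputs = constant_inputs(temp=20.0, deaths=30.0)
        mmt = tm.MmtEstimate("loc", 10.0, 50.0, (1.0, 99.0))
        daily = tm.attributable_numbers(inputs, curve, mmt)
        np.testing.assert_allclose(daily["an"], 15.0, atol=1e-10)

    def test_matches_day_by_day_loop_oracle(self):
        rng = np.random.default_rng(3)
        n = 600
        dates = pd.date_range("2015-01-01", periods=n, freq="D")
        temps = rng.uniform(0, 30, n)
        deaths = rng.uniform(20, 40, n)
        inputs = tm.ProjectionInputs("loc", "GCM1", "RCP8.5", dates, temps, deaths)
        curve = linear_curve(theta0=0.9, center=12.0)
        mmt = tm.MmtEstimate("loc", 12.0, 50.0, (1.0, 99.0))
        daily = tm.attributable_numbers(inputs, curve, mmt)

        L = 21
        for t in range(0, n, 37):
            eta = (temps[t] - 12.0) / 30.0 * 0.9
            window = deaths[t : min(t + L + 1, n)]
            oracle = (1 - np.exp(-eta)) * window.mean()
            assert abs(daily["an"].iloc[t] - oracle) < 1e-10

    def test_forward_window_tail_modes(self):
        v = np.arange(10.0)
        trunc = forward_window_mean(v, max_lag=3, tail="truncated")
        assert trunc[0] == pytest.approx(np.mean([0, 1, 2, 3]))
        assert trunc[-1] == 9.0  # single remaining day
        drop = forward_window_mean(v, max_lag=3, tail="drop")
        assert np.isnan(drop[-3:]).all()
        assert drop[6] == pytest.approx(np.mean([6, 7, 8, 9]))


class TestDecomposition:
    def test_all_cold_days_have_no_heat_component(self):
        an = np.ones(50)
        temps = np.full(50, 5.0)
        total, heat, cold = tm.decompose_and_total(an, temps, mmt=20.0)
        assert heat == 0.0 and cold == 50.0 and total == 50.0

    def test_all_hot_days_have_no_cold_component(self):
        total, heat, cold = tm.decompose_and_total(
            np.ones(10), np.full(10, 30.0), mmt=20.0
        )
        assert cold == 0.0 and heat == 10.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_partition_identity_exact(self, seed):
        rng = np.random.default_rng(seed)
        an = rng.normal(size=100)
        temps = rng.uniform(0, 30, 100)
        total, heat, cold = tm.decompose_and_total(an, temps, mmt=15.0)
        assert heat + cold == total  # exact, no tolerance


class TestAggregation:
    def _results(self):
        rows = []
        for (loc, grp, dec, an, denom) in [
            ("a", "North", "2010-19", 10.0, 100.0),
            ("a", "North", "2090-99", 30.0, 100.0),
            ("b", "North", "2010-19", 20.0, 300.0),
            ("b", "North", "2090-99", 30.0, 300.0),
        ]:
            rows.append(
                dict(location_id=loc, gcm_id="GCM1", rcp_id="RCP8.5",
                     decade=dec, an_total=an, an_heat=an, an_cold=0.0,
                     denom_deaths=denom)
            )
        df = pd.DataFrame(rows)
        groups = pd.DataFrame(
            {"location_id": ["a", "b"], "region": ["North", "North"]}
        )
        return df, groups

    def test_deaths_weighted_pooling(self):
        df, groups = self._results()
        agg = tm.aggregate(df, grouping="region", location_groups=groups)
        row = agg[agg.decade == "2090-99"].iloc[0]
        # deaths-weighted: (30 + 30) / (100 + 300), not mean(0.3, 0.1)
        assert row["af_total"] == pytest.approx(60.0 / 400.0)

    def test_equal_denominators_reduce_to_arithmetic_mean(self):
        df, groups = self._results()
        df.loc[df.location_id == "b", "denom_deaths"] = 100.0
        agg = tm.aggregate(df, grouping="region", location_groups=groups)
        row = agg[agg.decade == "2090-99"].iloc[0]
        assert row["af_total"] == pytest.approx((0.3 + 0.3) / 2)

    def test_reference_decade_net_change_zero(self):
        df, groups = self._results()
        agg = tm.aggregate(df, grouping="region", location_groups=groups)
        ref = agg[agg.decade == REFERENCE_DECADE]
        np.testing.assert_allclose(ref["net_change"], 0.0)

    def test_missing_reference_decade_errors(self):
        df, groups = self._results()
        with pytest.raises(ValueError):
            tm.aggregate(
                df, grouping="region", reference_decade="2050-59",
                location_groups=groups,
            )

    def test_single_location_single_gcm_passthrough(self):
        df, groups = self._results()
        df = df[df.location_id == "a"]
        agg = tm.aggregate(df, grouping="region", location_groups=groups)
        assert agg[agg.decade == "2090-99"]["af_total"].iloc[0] == pytest.approx(0.3)


class TestProperties:
    def test_heat_monotone_in_uniform_warming(self):
        """+1 C on every projected day never decreases the heat total nor
        increases the cold total (positive heat slope)."""
        rng = np.random.default_rng(8)
        n = 3700
        dates = pd.date_range("2010-01-01", periods=n, freq="D")
        temps = 15 + 8 * np.sin(np.arange(n) / 58.0) + rng.normal(0, 2, n)
        deaths = np.full(n, 30.0)
        curve = _spline_curve(
            lambda x: 0.002 * (np.asarray(x, float) - 17.0) ** 2,
            [10.0, 17.0, 24.0], (-5.0, 35.0),
            {1.0: 2.0, 50.0: 15.0, 99.0: 28.0},
        )
        mmt = tm.find_mmt(curve)
        totals = {}
        for shift in (0.0, 1.0):
            inputs = tm.ProjectionInputs(
                "loc", "GCM1", "RCP8.5", dates, temps + shift, deaths
            )
            res = results_to_frame(attribution_by_decade(inputs, curve, mmt))
            totals[shift] = (res["an_heat"].sum(), res["an_cold"].sum())
        assert totals[1.0][0] >= totals[0.0][0]
        assert totals[1.0][1] <= totals[0.0][1]

    def test_scaling_baseline_deaths_scales_numbers_not_fractions(self):
        inputs = constant_inputs(n_days=400, temp=22.0, deaths=30.0)
        doubled = constant_inputs(n_days=400, temp=22.0, deaths=60.0)
        curve = linear_curve(theta0=0.8, center=10.0)
        mmt = tm.MmtEstimate("loc", 10.0, 50.0, (1.0, 99.0))
        r1 = results_to_frame(attribution_by_decade(inputs, curve, mmt))
        r2 = results_to_frame(attribution_by_decade(doubled, curve, mmt))
        np.testing.assert_allclose(r2["an_total"], 2 * r1["an_total"], rtol=1e-12)
        np.testing.assert_allclose(
            r2["an_total"] / r2["denom_deaths"],
            r1["an_total"] / r1["denom_deaths"],
            rtol=1e-12,
        )

    def test_vectorised_draws_match_per_draw_attribution(self):
        rng = np.random.default_rng(12)
        inputs = constant_inputs(n_days=900, temp=24.0, deaths=30.0)
        inputs.tmean = inputs.tmean + rng.normal(0, 4, 900)
        curve = linear_curve(theta0=0.7, center=12.0)
        mmt = tm.MmtEstimate("loc", 12.0, 50.0, (1.0, 99.0))
        thetas = rng.normal(0.7, 0.1, size=(5, 1))
        labels, tot, hot, cld = decadal_an_draws(
            inputs, curve, mmt, thetas, redo_mmt=False
        )
        for s in range(5):
            res = attribution_by_decade(inputs, curve, mmt, theta=thetas[s])
            for d, r in enumerate(res):
                assert r.decade == labels[d]
                assert tot[d, s] == pytest.approx(r.an_total, abs=1e-10)
                assert hot[d, s] == pytest.approx(r.an_heat, abs=1e-10)

    def test_per_draw_mmt_matches_per_draw_search(self):
        """With the per-draw MMT re-search, each draw reproduces a scalar
        run that first re-finds the MMT for that draw's curve."""
        rng = np.random.default_rng(21)
        inputs = constant_inputs(n_days=800, temp=18.0, deaths=30.0)
        inputs.tmean = inputs.tmean + rng.normal(0, 5, 800)
        knots, bnd = [10.0, 17.0, 24.0], (-5.0, 35.0)
        pct = {1.0: 6.0, 50.0: 18.0, 99.0: 30.0}
        base = _spline_curve(
            lambda x: 0.003 * (np.asarray(x, float) - 18.0) ** 2, knots, bnd, pct
        )
        mmt0 = tm.find_mmt(base)
        thetas = base.theta + rng.normal(0, 0.02, size=(4, len(base.theta)))
        labels, tot, hot, cld = decadal_an_draws(
            inputs, base, mmt0, thetas, redo_mmt=True
        )
        for s in range(4):
            draw_curve = tm.ReducedCurve(
                location_id="c", theta=thetas[s], V=np.zeros_like(base.V),
                var_knots=base.var_knots, var_boundary=base.var_boundary,
                centering_value=base.centering_value, temp_percentiles=pct,
            )
            mmt_s = tm.find_mmt(draw_curve)
            res = attribution_by_decade(inputs, draw_curve, mmt_s)
            for d, r in enumerate(res):
                assert tot[d, s] == pytest.approx(r.an_total, abs=1e-8)
                assert hot[d, s] == pytest.approx(r.an_heat, abs=1e-8)


def test_decade_labels_anchor_at_calendar_decades():
    assert decade_label(1994) == "1990-99"
    assert decade_label(2090) == "2090-99"
    assert decade_label(2019) == "2010-19"
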