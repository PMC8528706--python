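"""Functional-property estimators: closed-form oracles, recovery, contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoaxes import efp
from ecoaxes.flux_io import GrowingSeasonMask
from ecoaxes.efp import (
    WindowFit,
    aerodynamic_conductance,
    efp_acue,
    efp_ef,
    efp_etmax,
    efp_gppsat,
    efp_gsmax,
    efp_nepmax,
    efp_rb_stats,
    efp_uwue,
    efp_wuet,
    fit_e0,
    fit_g1,
    fit_light_response_windows,
    fit_rb_daily,
    lloyd_taylor,
    penman_monteith_le,
    rb_daily_series,
    surface_conductance,
)


def _gs_mask_all(index):
    days = pd.DatetimeIndex(index.normalize().unique())
    return GrowingSeasonMask(pd.Series(True, index=days), 0.0, 10.0)


class TestAerodynamicConductance:
    def test_hand_value(self):
        # 1 / (2/0.3^2 + 6.2*0.3^-0.67) = 1/(22.222 + 13.890)
        assert aerodynamic_conductance(2.0, 0.3) == pytest.approx(0.02769, abs=1e-5)

    def test_monotone_decreasing_in_wind(self):
        u = np.linspace(0.5, 10, 50)
        ga = aerodynamic_conductance(u, 0.3)
        assert (np.diff(ga) < 0).all()

    def test_vanishing_friction_velocity(self):
        assert aerodynamic_conductance(2.0, 1e-9) == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_inputs_missing(self):
        assert np.isnan(aerodynamic_conductance(0.0, 0.3))
        assert np.isnan(aerodynamic_conductance(2.0, 0.0))


class TestPenmanMonteith:
    def test_forward_inverse_identity_on_grid(self):
        rng = np.random.default_rng(42)
        n = 10_000
        t = rng.uniform(-5, 40, n)
        vpd = rng.uniform(0.05, 5.0, n)
        rn = rng.uniform(20, 900, n)
        ga = rng.uniform(0.002, 0.15, n)
        gs = rng.uniform(5e-4, 0.06, n)
        le = penman_monteith_le(gs, ga, rn, 0.0, 0.0, vpd, t)
        back = surface_conductance(le, ga, rn, 0.0, 0.0, vpd, t)
        assert np.nanmax(np.abs(back - gs) / gs) < 1e-8

    def test_zero_le_gives_zero_gs(self):
        assert surface_conductance(0.0, 0.02, 400.0, 0.0, 0.0, 1.0, 20.0) == 0.0

    def test_nonpositive_denominator_is_missing(self):
        # huge LE against tiny available energy drives the denominator negative
        gs = surface_conductance(2000.0, 0.02, 10.0, 0.0, 0.0, 0.1, 20.0)
        assert np.isnan(gs)


class TestLightResponse:
    def _hyperbola_table(self, alpha=0.05, beta=30.0, days=6):
        idx = pd.date_range("2001-06-01", periods=days * 48, freq="30min")
        hour = idx.hour + idx.minute / 60
        q = pd.Series(np.where(abs(hour - 12) < 6,
                               2000 * np.cos((hour - 12) / 6 * np.pi / 2) ** 2,
                               0.0), index=idx)
        gpp = alpha * q * beta / (alpha * q + beta)
        return gpp, q

    def test_noiseless_hyperbola_recovers_gppsat(self):
        gpp, q = self._hyperbola_table()
        fits = fit_light_response_windows(gpp, q)
        assert fits
        for f in fits:
            assert f.params["gpp_sat"] == pytest.approx(23.0769, rel=1e-4)

    def test_constant_gpp_rejected_by_curvature_check(self):
        gpp, q = self._hyperbola_table()
        flat = pd.Series(5.0, index=gpp.index)
        assert fit_light_response_windows(flat, q) == []

    def test_sparse_window_skipped(self):
        gpp, q = self._hyperbola_table(days=1)
        keep = gpp.index[:3]
        assert fit_light_response_windows(gpp[keep], q[keep]) == []

    def test_gppsat_is_90th_percentile(self, oracle_quantile):
        fits = [WindowFit(pd.Timestamp("2001-01-01"), {"gpp_sat": float(v)},
                          0.0, 30) for v in range(1, 11)]
        assert efp_gppsat(fits) == pytest.approx(oracle_quantile(range(1, 11), 0.9))
        assert efp_gppsat(fits) == pytest.approx(9.1)

    def test_gppsat_needs_enough_windows(self):
        fits = [WindowFit(pd.Timestamp("2001-01-01"), {"gpp_sat": 5.0}, 0.0, 30)]
        assert np.isnan(efp_gppsat(fits))
        assert np.isnan(efp_gppsat([]))


class TestNepMax:
    def test_constant_nee(self, half_hourly_index):
        idx = half_hourly_index(40)
        nee = pd.Series(-5.0, index=idx)
        assert efp_nepmax(nee, _gs_mask_all(idx)) == pytest.approx(5.0)

    def test_uniform_grid(self, half_hourly_index, oracle_quantile):
        idx = half_hourly_index(40)[:101]
        nee = pd.Series(-np.linspace(0, 100, 101), index=idx)
        got = efp_nepmax(nee, _gs_mask_all(idx))
        assert got == pytest.approx(oracle_quantile(np.linspace(0, 100, 101), 0.9))
        assert got == pytest.approx(90.0)

    def test_all_missing(self, half_hourly_index):
        idx = half_hourly_index(2)
        assert np.isnan(efp_nepmax(pd.Series(np.nan, index=idx),
                                   _gs_mask_all(idx)))


def _night_series(e0=150.0, rb=2.0, days=40, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.date_range("2001-01-01", periods=days * 12, freq="30min")
    t = pd.Series(5 + 15 * rng.random(days * 12), index=idx)
    resp = pd.Series(lloyd_taylor(t.to_numpy(), rb, e0), index=idx)
    return resp, t


class TestRespiration:
    def test_noiseless_e0_recovery(self):
        resp, t = _night_series(e0=150.0)
        assert fit_e0(resp, t) == pytest.approx(150.0, abs=1e-3)

    def test_isothermal_nights_unidentifiable(self):
        resp, t = _night_series()
        t[:] = 10.0
        resp[:] = 2.0
        with pytest.raises(ValueError, match="temperature range"):
            fit_e0(resp, t)

    def test_e0_clipped_at_bounds(self):
        resp, t = _night_series(e0=420.0)   # generated beyond the upper bound
        assert fit_e0(resp, t) == 400.0

    def test_too_few_points(self):
        resp, t = _night_series(days=2)
        with pytest.raises(ValueError, match="night points"):
            fit_e0(resp, t)

    def test_constant_rb_recovered_in_every_window(self):
        resp, t = _night_series(rb=2.0)
        fits = fit_rb_daily(resp, t, e0=150.0)
        assert fits
        for f in fits:
            assert f.params["rb_d"] == pytest.approx(2.0, rel=1e-9)

    def test_seasonal_rb_recovered_within_one_percent(self):
        rng = np.random.default_rng(1)
        idx = pd.date_range("2001-01-01", periods=200 * 12, freq="30min")
        doy = idx.dayofyear.to_numpy()
        rb_true = 2.0 + np.sin(2 * np.pi * doy / 365) * 0.8
        t = pd.Series(5 + 15 * rng.random(len(idx)), index=idx)
        resp = pd.Series(lloyd_taylor(t.to_numpy(), rb_true, 150.0), index=idx)
        fits = fit_rb_daily(resp, t, e0=150.0)
        rb_d = rb_daily_series(fits)
        truth = pd.Series(2.0 + np.sin(2 * np.pi * rb_d.index.dayofyear / 365) * 0.8,
                          index=rb_d.index)
        rmse = float(np.sqrt(((rb_d - truth) ** 2).mean()))
        assert rmse / truth.mean() < 0.01

    def test_empty_nights(self):
        idx = pd.date_range("2001-01-01", periods=10, freq="30min")
        assert fit_rb_daily(pd.Series(np.nan, index=idx),
                            pd.Series(10.0, index=idx), 150.0) == []

    def test_rb_stats(self, oracle_quantile):
        rb = pd.Series(np.arange(1.0, 22.0),
                       index=pd.date_range("2001-01-01", periods=21))
        mean, q95 = efp_rb_stats(rb)
        assert mean == pytest.approx(11.0)
        assert q95 == pytest.approx(oracle_quantile(np.arange(1.0, 22.0), 0.95))
        assert q95 == pytest.approx(20.0)

    def test_rb_stats_too_few(self):
        rb = pd.Series([1.0, 2.0], index=pd.date_range("2001-01-01", periods=2))
        assert np.isnan(efp_rb_stats(rb)[0])


class TestACUE:
    def _daily(self, gpp, rb):
        idx = pd.date_range("2001-01-01", periods=len(gpp))
        mask = GrowingSeasonMask(pd.Series(True, index=idx), 0.0, 10.0)
        return (pd.Series(gpp, index=idx), pd.Series(rb, index=idx), mask)

    def test_balanced_respiration_gives_zero(self):
        g, r, m = self._daily([4.0] * 30, [4.0] * 30)
        assert efp_acue(g, r, m) == pytest.approx(0.0)

    def test_direct_formula(self):
        g, r, m = self._daily([8.0] * 30, [2.0] * 30)
        assert efp_acue(g, r, m) == pytest.approx(0.75)

    def test_zero_rb_gives_one(self):
        g, r, m = self._daily([8.0] * 30, [0.0] * 30)
        assert efp_acue(g, r, m) == pytest.approx(1.0)

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(3)
        gpp = 5 + rng.random(60) * 5
        rb = 1 + rng.random(60)
        g, r, m = self._daily(gpp, rb)
        g2, r2, _ = self._daily(gpp * 3.7, rb * 3.7)
        assert efp_acue(g, r, m) == pytest.approx(efp_acue(g2, r2, m))

    def test_floor_excludes_tiny_gpp_days(self):
        g, r, m = self._daily([0.1] * 30, [2.0] * 30)
        assert np.isnan(efp_acue(g, r, m))


class TestConductanceEFPs:
    def test_gsmax_quantile(self, half_hourly_index, oracle_quantile):
        idx = half_hourly_index(3)[:100]
        gs = pd.Series(np.linspace(0.001, 0.010, 100), index=idx)
        mask = pd.Series(True, index=idx)
        assert efp_gsmax(gs, mask) == pytest.approx(
            oracle_quantile(gs.to_numpy(), 0.9))

    def test_gsmax_constant(self, half_hourly_index):
        idx = half_hourly_index(3)[:60]
        gs = pd.Series(0.01, index=idx)
        assert efp_gsmax(gs, pd.Series(True, index=idx)) == pytest.approx(0.01)

    def test_gsmax_empty_mask(self, half_hourly_index):
        idx = half_hourly_index(3)[:60]
        gs = pd.Series(0.01, index=idx)
        assert np.isnan(efp_gsmax(gs, pd.Series(False, index=idx)))

    def test_g1_noiseless_recovery(self, half_hourly_index):
        rng = np.random.default_rng(5)
        idx = half_hourly_index(5)
        n = len(idx)
        g1_true, ca, t, p = 3.0, 400.0, 20.0, 101.325
        gpp = pd.Series(5 + 20 * rng.random(n), index=idx)
        vpd = pd.Series(0.3 + 3 * rng.random(n), index=idx)
        gs_mol = 1.6 * (1 + g1_true / np.sqrt(vpd)) * gpp / ca
        gs = gs_mol / efp.molar_air_density(t, p)
        mask = pd.Series(True, index=idx)
        got = fit_g1(gs, gpp, vpd, pd.Series(ca, index=idx),
                     pd.Series(t, index=idx), p, mask)
        assert got == pytest.approx(3.0, abs=1e-6)

    def test_g1_unidentifiable_when_gpp_zero(self, half_hourly_index):
        idx = half_hourly_index(5)
        zero = pd.Series(0.0, index=idx)
        one = pd.Series(1.0, index=idx)
        mask = pd.Series(True, index=idx)
        assert np.isnan(fit_g1(zero, zero, one, one * 400, one * 20, 101.325,
                               mask))


class TestWaterEFPs:
    def test_uwue_direct(self, half_hourly_index):
        idx = half_hourly_index(1)
        gpp = pd.Series(10.0, index=idx)
        vpd = pd.Series(9.0, index=idx)
        et = pd.Series(3.0, index=idx)
        mask = pd.Series(True, index=idx)
        assert efp_uwue(gpp, vpd, et, mask) == pytest.approx(10.0)

    def test_uwue_scaling(self, half_hourly_index):
        rng = np.random.default_rng(6)
        idx = half_hourly_index(2)
        gpp = pd.Series(5 + rng.random(len(idx)), index=idx)
        vpd = pd.Series(5 + rng.random(len(idx)), index=idx)
        et = pd.Series(0.05 + 0.1 * rng.random(len(idx)), index=idx)
        mask = pd.Series(True, index=idx)
        assert efp_uwue(gpp, vpd, 2 * et, mask) == pytest.approx(
            efp_uwue(gpp, vpd, et, mask) / 2)

    def test_uwue_single_point(self, half_hourly_index):
        idx = half_hourly_index(1)
        mask = pd.Series(False, index=idx)
        mask.iloc[20] = True
        got = efp_uwue(pd.Series(10.0, index=idx), pd.Series(4.0, index=idx),
                       pd.Series(2.0, index=idx), mask)
        assert got == pytest.approx(10.0)

    def test_wuet_ratio(self, half_hourly_index):
        idx = half_hourly_index(2)
        # constant GPP in umol m-2 s-1 whose daily mean is 5 gC m-2 d-1
        gpp_const = 5.0 / (efp.UMOL_TO_GC * 86400.0)
        gpp = pd.Series(gpp_const, index=idx)
        transp = pd.Series(2.0 / 48.0, index=idx)   # 2 mm/day
        assert efp_wuet(gpp, transp) == pytest.approx(2.5)

    def test_wuet_missing_without_transpiration(self, half_hourly_index):
        idx = half_hourly_index(1)
        assert np.isnan(efp_wuet(pd.Series(5.0, index=idx), None))

    def test_etmax_quantile(self, half_hourly_index, oracle_quantile):
        idx = half_hourly_index(4)[:101]
        et = pd.Series(np.linspace(0, 1, 101), index=idx)
        mask = pd.Series(True, index=idx)
        assert efp_etmax(et, mask) == pytest.approx(0.95)
        assert efp_etmax(et, mask) == pytest.approx(
            oracle_quantile(et.to_numpy(), 0.95))

    def test_ef_balanced_fluxes(self, half_hourly_index):
        idx = half_hourly_index(10)
        h = pd.Series(100.0, index=idx)
        le = pd.Series(100.0, index=idx)
        mask = pd.Series(True, index=idx)
        ef, ampl = efp_ef(h, le, mask)
        assert ef == pytest.approx(0.5)
        assert ampl == pytest.approx(0.0)

    def test_ef_quartiles(self, half_hourly_index, oracle_quantile):
        idx = half_hourly_index(4)
        daily_ef = [0.2, 0.4, 0.6, 0.8]
        le = pd.Series(np.repeat([e * 100 for e in daily_ef], 48), index=idx)
        h = pd.Series(np.repeat([(1 - e) * 100 for e in daily_ef], 48), index=idx)
        mask = pd.Series(True, index=idx)
        ef, ampl = efp_ef(h, le, mask)
        assert ef == pytest.approx(0.5)
        assert ampl == pytest.approx(
            oracle_quantile(daily_ef, 0.75) - oracle_quantile(daily_ef, 0.25))
        assert ampl == pytest.approx(0.3)

    def test_ef_single_day(self, half_hourly_index):
        idx = half_hourly_index(1)
        ef, ampl = efp_ef(pd.Series(50.0, index=idx),
                          pd.Series(150.0, index=idx),
                          pd.Series(True, index=idx))
        assert ef == pytest.approx(0.75)
        assert ampl == pytest.approx(0.0)


class TestOrderStatisticProperties:
    @given(st.lists(st.floats(-50, 50), min_size=60, max_size=120),
           st.floats(5, 40))
    @settings(max_examples=25, deadline=None)
    def test_permutation_invariance_and_monotonicity(self, values, extra):
        idx = pd.date_range("2001-06-01", periods=len(values), freq="30min")
        et = pd.Series(values, index=idx)
        mask = pd.Series(True, index=idx)
        base = efp_etmax(et, mask)
        rng = np.random.default_rng(0)
        perm = pd.Series(rng.permutation(values), index=idx)
        assert efp_etmax(perm, mask) == pytest.approx(base, rel=1e-12)
        bigger = et.copy()
        bigger.iloc[0] = max(values) + abs(extra)
        assert efp_etmax(bigger, mask) >= base - 1e-12


def test_uwue_and_g1_move_oppositely_on_stomatal_gradient():
    """Stronger stomatal closure (lower G1) must raise uWUE and vice versa."""
    from ecoaxes.flux_io import dry_daytime_filter, le_to_et
    from ecoaxes.synthetic import SiteTruth, simulate_drivers, simulate_fluxes

    results = {}
    for g1 in (2.0, 5.0):
        truth = SiteTruth(seed=12, g1=g1)
        d = simulate_drivers(365, truth)
        table = simulate_fluxes(d, truth, with_noise=False)
        mask = dry_daytime_filter(table)
        et = pd.Series(le_to_et(table["le"], table["t_air"]), index=table.index)
        uwue = efp_uwue(table["gpp"], table["vpd"], et, mask)
        results[g1] = uwue
    assert results[2.0] > results[5.0]
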