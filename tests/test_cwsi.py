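import numpy as np
import pytest

from cwsilag import (CampaignConfig, CanopyConfig, EmpiricalBaseline,
                     TheoreticalParams, TimeSeries, aerodynamic_resistance,
                     apply_time_lag, canopy_resistance_inversion,
                     ctd_from_resistance, cwsi_empirical, cwsi_theoretical,
                     delta_slope, fit_nwsb, generate_campaign,
                     psychrometric_gamma, saturation_vapor_pressure, vpd, vpg)
from cwsilag.errors import (AboveUpperLimitError, CwsilagError,
                            DegenerateBoundsError, InvalidConfigError)


class TestThermodynamicComponents:
    def test_gamma_sea_level_exact(self):
        assert float(psychrometric_gamma(0.0)) == pytest.approx(
            0.665 * 101.3, abs=1e-12)

    def test_gamma_at_1000m(self):
        assert float(psychrometric_gamma(1000.0)) == pytest.approx(59.87, abs=0.05)

    def test_gamma_decreasing_in_altitude(self):
        z = np.linspace(0, 4000, 50)
        assert np.all(np.diff(psychrometric_gamma(z)) < 0)

    def test_gamma_negative_altitude_rejected(self):
        with pytest.raises(InvalidConfigError):
            psychrometric_gamma(-10.0)

    def test_delta_at_20c(self):
        assert float(delta_slope(20.0, 20.0)) == pytest.approx(144.61, abs=0.01)

    def test_delta_depends_only_on_mean(self):
        assert float(delta_slope(22.0, 18.0)) == float(delta_slope(20.0, 20.0))

    def test_delta_increasing_on_0_40(self):
        t = np.linspace(0, 40, 100)
        assert np.all(np.diff(delta_slope(t, t)) > 0)

    def test_delta_matches_tetens_derivative_within_3pct(self):
        # cross-oracle: central-difference slope of the Tetens curve (Pa/degC)
        t = np.linspace(5, 35, 61)
        h = 1e-3
        num = (saturation_vapor_pressure(t + h)
               - saturation_vapor_pressure(t - h)) / (2 * h) * 1000.0
        rel = np.abs(delta_slope(t, t) - num) / num
        assert rel.max() < 0.03

    def test_aerodynamic_resistance_hand_values(self):
        assert float(aerodynamic_resistance(2.0, 1.0, 2.0)) == pytest.approx(
            4.72 * np.log((2 - 0.63) / 0.13) ** 2 / (1 + 0.54 * 2), abs=1e-9)
        assert float(aerodynamic_resistance(0.0, 1.0, 2.0)) == pytest.approx(
            4.72 * np.log((2 - 0.63) / 0.13) ** 2, abs=1e-9)

    def test_aerodynamic_resistance_decreasing_in_wind(self):
        u = np.linspace(0, 10, 50)
        ra = aerodynamic_resistance(u, 1.0, 2.0)
        assert np.all(np.diff(ra) < 0) and ra[-1] < 5.0

    def test_aerodynamic_geometry_violations(self):
        with pytest.raises(InvalidConfigError):
            aerodynamic_resistance(2.0, 4.0, 2.0)  # z <= 0.63 h

    def test_vpd_values(self):
        assert float(vpd(25.0, 50.0)) == pytest.approx(1.580, abs=0.001)
        assert float(vpd(25.0, 100.0)) == 0.0
        assert float(vpd(25.0, 0.0)) == pytest.approx(
            float(saturation_vapor_pressure(25.0)))
        with pytest.raises(InvalidConfigError):
            vpd(25.0, 120.0)

    def test_vpg_values(self):
        assert float(vpg(25.0, 0.0)) == 0.0
        assert float(vpg(25.0, 2.5)) == pytest.approx(-0.5015, abs=0.001)
        assert np.sign(float(vpg(25.0, 2.0))) == -1
        assert np.sign(float(vpg(25.0, -2.0))) == 1


class TestEmpiricalModel:
    def test_fit_nwsb_exact_line(self):
        t = np.arange(760.0, 920.0, 2.0)
        x = 1.0 + 0.01 * (t - 760.0)
        y = -2.0 * x + 2.5
        bl = fit_nwsb(TimeSeries(t, y), TimeSeries(t, x))
        assert bl.a == pytest.approx(-2.0, abs=1e-12)
        assert bl.b == pytest.approx(2.5, abs=1e-12)
        assert bl.r2 == pytest.approx(1.0)

    def test_fit_nwsb_noisy_slope_within_ols_ci(self):
        # OLS sampling-distribution oracle: truth within the 95% CI
        from scipy import stats
        rng = np.random.default_rng(3)
        t = np.arange(780.0, 902.0, 2.0)
        x = 1.0 + 0.8 * np.sin((t - 780) / 40.0)
        y = -1.8 * x + 2.2 + rng.normal(0, 0.2, t.size)
        bl = fit_nwsb(TimeSeries(t, y), TimeSeries(t, x))
        res = stats.linregress(x, y)
        assert abs(bl.a - (-1.8)) <= 1.96 * res.stderr

    def test_fit_nwsb_degenerate_vpd(self):
        t = np.arange(780.0, 902.0, 2.0)
        with pytest.raises(CwsilagError):
            fit_nwsb(TimeSeries(t, t * 0.01), TimeSeries(t, np.full(t.size, 1.5)))

    def test_endpoints(self):
        bl = EmpiricalBaseline(-2.0, 2.5)
        ta, rh = 25.0, 50.0
        nwsb = bl.a * float(vpd(ta, rh)) + bl.b
        ntb = bl.a * float(vpg(ta, bl.b)) + bl.b
        for ctd, expected in ((nwsb, 0.0), (ntb, 1.0), ((nwsb + ntb) / 2, 0.5)):
            rec = cwsi_empirical(ta + ctd, ta, rh, bl)
            assert float(rec.cwsi_raw.iloc[0]) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_raw_value_kept_next_to_clamped(self):
        bl = EmpiricalBaseline(-2.0, 2.5)
        rec = cwsi_empirical(45.0, 25.0, 50.0, bl)  # deep into stress
        raw = float(rec.cwsi_raw.iloc[0])
        assert raw > 1.0
        assert float(rec.cwsi_clamped.iloc[0]) == 1.0

    def test_degenerate_bounds_rejected(self):
        bl = EmpiricalBaseline(0.0, 0.0)  # NWSB == NTB == 0
        with pytest.raises(DegenerateBoundsError):
            cwsi_empirical(26.0, 25.0, 50.0, bl)


class TestTheoreticalModel:
    GAMMA = float(psychrometric_gamma(0.0))
    RA = float(aerodynamic_resistance(2.0, 1.0, 2.0))

    def test_inversion_round_trip(self):
        delta = float(delta_slope(22.0, 20.0))
        for rc in (13.01, 26.02, 130.1):
            ctd = float(ctd_from_resistance(rc, 600.0, 60.0, self.RA, 1500.0,
                                            delta, self.GAMMA))
            rec, flag = canopy_resistance_inversion(ctd, 600.0, 60.0, self.RA,
                                                    1500.0, delta, self.GAMMA)
            assert rec == pytest.approx(rc, abs=1e-9)
            assert flag is None

    def test_inversion_floors_negative_resistance(self):
        rc, flag = canopy_resistance_inversion(0.0, 600.0, 60.0, self.RA, 0.0,
                                               145.0, self.GAMMA)
        assert rc == 0.0 and flag == "rc_floored"

    def test_inversion_monotone_in_ctd(self):
        delta = float(delta_slope(20.0, 20.0))
        ctds = np.linspace(-2.0, 2.0, 9)
        rcs = [canopy_resistance_inversion(c, 600.0, 60.0, self.RA, 1500.0,
                                           delta, self.GAMMA)[0] for c in ctds]
        assert np.all(np.diff(rcs) >= 0)

    def test_inversion_above_limit_rejected(self):
        with pytest.raises(AboveUpperLimitError):
            canopy_resistance_inversion(10.0, 600.0, 60.0, self.RA, 1500.0,
                                        145.0, self.GAMMA)

    def test_closed_form_at_twice_minimum_resistance(self):
        # independent hand evaluation of the index formula
        gamma, ra, delta, rcp = 67.36, 12.59, 144.6, 13.01
        gp = gamma * (1 + 2 * rcp / ra)
        gstar = gamma * (1 + rcp / ra)
        expected = (gp - gstar) / (delta + gp)
        params = TheoreticalParams(altitude=0.0, h=1.0, z=2.0)
        # build a timestamp whose inversion lands on rc = 2*rcp
        ta, rh, u, rn, g = 20.0, 50.0, 2.0, 600.0, 60.0
        ra_x = float(aerodynamic_resistance(u, params.h, params.z))
        gamma_x = float(psychrometric_gamma(params.altitude))
        vpd_pa = float(vpd(ta, rh)) * 1000.0
        ctd = 0.0
        for _ in range(60):  # fixed point: delta depends on the mean temperature
            delta_x = float(delta_slope(ta + ctd, ta))
            ctd = float(ctd_from_resistance(2 * params.rcp, rn, g, ra_x, vpd_pa,
                                            delta_x, gamma_x))
        rec = cwsi_theoretical(ta + ctd, ta, rh, rn, g, u, params)
        got = float(rec.cwsi_raw.iloc[0])
        gp_x = gamma_x * (1 + 2 * params.rcp / ra_x)
        gstar_x = gamma_x * (1 + params.rcp / ra_x)
        assert got == pytest.approx((gp_x - gstar_x) / (delta_x + gp_x), abs=1e-9)
        assert got == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("rc,check", [
        (None, lambda v: v == pytest.approx(0.0, abs=1e-9)),   # rc = rcp
        (1e6, lambda v: v > 0.999),
    ])
    def test_limits(self, rc, check):
        params = TheoreticalParams(altitude=0.0, h=1.0, z=2.0)
        rc = params.rcp if rc is None else rc
        ta, rh, u, rn, g = 20.0, 50.0, 2.0, 600.0, 60.0
        ra_x = float(aerodynamic_resistance(u, params.h, params.z))
        gamma_x = float(psychrometric_gamma(params.altitude))
        vpd_pa = float(vpd(ta, rh)) * 1000.0
        ctd = 0.0
        for _ in range(200):
            delta_x = float(delta_slope(ta + ctd, ta))
            ctd = float(ctd_from_resistance(rc, rn, g, ra_x, vpd_pa, delta_x,
                                            gamma_x))
        rec = cwsi_theoretical(ta + ctd, ta, rh, rn, g, u, params)
        assert check(float(rec.cwsi_raw.iloc[0]))

    def test_nondecreasing_in_canopy_temperature(self):
        params = TheoreticalParams(altitude=0.0, h=1.0, z=2.0)
        tcs = np.linspace(18.0, 22.0, 9)
        vals = [float(cwsi_theoretical(tc, 20.0, 50.0, 600.0, 60.0, 2.0,
                                       params).cwsi_raw.iloc[0]) for tc in tcs]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_component_consistency(self):
        # the stored (gamma, gamma*, Delta, ra, rc) must reproduce the index
        params = TheoreticalParams(altitude=0.0, h=1.0, z=2.0)
        rec = cwsi_theoretical([21.0, 20.5], [20.0, 20.0], [50.0, 55.0],
                               [600.0, 580.0], [60.0, 58.0], [2.0, 1.8], params)
        gp = rec.gamma * (1 + rec.rc / rec.ra)
        again = (gp - rec.gamma_star) / (rec.delta + gp)
        np.testing.assert_allclose(again, rec.cwsi_raw, atol=1e-12)


class TestApplyTimeLag:
    @pytest.fixture
    def campaign(self):
        return generate_campaign(
            CampaignConfig(n_days=1, canopy=CanopyConfig(noise_sd=0.0)), seed=2)

    def test_zero_lag_identity(self, campaign):
        meteo = campaign.days[0]
        tc = campaign.tc[(0, "T1")]
        pairs = apply_time_lag(tc, meteo, 0.0)
        day = meteo.daytime()
        np.testing.assert_array_equal(pairs.ta, day.ta)
        np.testing.assert_array_equal(pairs.tc, tc.v)

    def test_indexing_contract(self, campaign):
        meteo = campaign.days[0]
        tc = campaign.tc[(0, "T1")]
        pairs = apply_time_lag(tc, meteo, 44.0)
        i = np.flatnonzero(pairs.t == 800.0)[0]
        j = np.flatnonzero(meteo.t == 800.0 - 44.0)[0]
        assert pairs.ta[i] == meteo.ta[j]
        assert pairs.rh[i] == meteo.rh[j]
        # contemporaneous channels stay at clock time
        k = np.flatnonzero(meteo.t == 800.0)[0]
        assert pairs.rn[i] == meteo.rn[k]

    def test_off_grid_lag_rejected(self, campaign):
        with pytest.raises(CwsilagError):
            apply_time_lag(campaign.tc[(0, "T1")], campaign.days[0], 3.0)

    def test_correction_is_invertible_bookkeeping(self, campaign):
        # re-pairing the shifted air series forward by tau restores alignment
        meteo = campaign.days[0]
        tc = campaign.tc[(0, "T1")]
        tau = 60.0
        pairs = apply_time_lag(tc, meteo, tau)
        k = int(tau / meteo.step)
        i0 = np.flatnonzero(meteo.t == pairs.t[0])[0]
        restored = meteo.ta[i0 - k + k: i0 - k + k + pairs.t.size]
        day = meteo.daytime()
        np.testing.assert_array_equal(restored, day.ta[-pairs.t.size:])
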