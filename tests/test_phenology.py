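"""Phenology model: cardinal-temperature responses, phyllotherm, growth-stage
simulation and the weather generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxesim.phenology import (
    CultivarPhenologyParams,
    SeasonTooShortError,
    photoperiod_factor,
    phyllotherm,
    simulate_growth_stages,
    thermal_time_daily,
    vernalization_factor,
    vernalizing_day,
)
from gxesim.weather import ClimateParams, daylength, generate_weather

from conftest import constant_weather


class TestCardinalResponses:
    @pytest.mark.parametrize(
        "tmean,expected",
        [(-5.0, 0.0), (0.0, 0.0), (24.0, 24.0), (35.0, 0.0), (40.0, 0.0),
         (12.0, 12.0), (29.5, 12.0)],
    )
    def test_thermal_time_knots(self, tmean, expected):
        assert thermal_time_daily(tmean) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "tmean,expected",
        [(6.0, 1.0), (-1.0, 0.0), (17.0, 0.0), (-10.0, 0.0), (25.0, 0.0), (2.5, 0.5), (11.5, 0.5)],
    )
    def test_vernalizing_day_knots(self, tmean, expected):
        assert vernalizing_day(tmean) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "ph,expected", [(20.0, 1.0), (6.3, 0.0), (13.15, 0.5), (24.0, 1.0), (2.0, 0.0)]
    )
    def test_photoperiod_factor(self, ph, expected):
        assert photoperiod_factor(ph) == pytest.approx(expected)

    @pytest.mark.parametrize("vdd,expected", [(45.0, 1.0), (0.0, 0.0), (22.5, 0.5), (90.0, 1.0)])
    def test_vernalization_factor(self, vdd, expected):
        assert vernalization_factor(vdd) == pytest.approx(expected)

    @given(st.floats(-20, 50))
    @settings(max_examples=200, deadline=None)
    def test_responses_bounded_and_continuous(self, t):
        tt = thermal_time_daily(t)
        assert 0.0 <= tt <= 24.0
        vd = vernalizing_day(t)
        assert 0.0 <= vd <= 1.0
        # continuity: small perturbation, small change (Lipschitz bound)
        eps = 1e-6
        assert abs(thermal_time_daily(t + eps) - tt) < 1e-4
        assert abs(vernalizing_day(t + eps) - vd) < 1e-4


class TestPhyllotherm:
    def test_clamped_to_bounds(self):
        # decreasing daylength drives the raw value negative -> lower bound
        assert phyllotherm(9.0, 11.0, 150.0, 800.0, 250.0) == 66.0
        # tiny positive photoperiod change -> huge raw value -> upper bound
        assert phyllotherm(10.0001, 10.0, 150.0, 800.0, 250.0) == 120.0

    def test_matches_symbolic_evaluation(self):
        sympy = pytest.importorskip("sympy")
        P10, P00, GDD, Rg, d = sympy.symbols("P10 P00 GDD Rg d", positive=True)
        expr = (100 / ((sympy.Rational(254, 100) * (P10 - P00)) / (GDD + sympy.Rational(14396, 1000) / Rg + sympy.Rational(10104, 10000)))) * sympy.Rational(9393, 10000) + sympy.Rational(379, 1000000) * d
        subs = {P10: sympy.Rational(105, 10), P00: sympy.Rational(98, 10), GDD: 160, Rg: 700, d: 250}
        raw = float(expr.subs(subs))
        expected = min(max(raw, 66.0), 120.0)
        assert phyllotherm(10.5, 9.8, 160.0, 700.0, 250.0) == pytest.approx(expected, rel=1e-9)

    def test_zero_radiation_errors(self):
        with pytest.raises(ValueError):
            phyllotherm(10.5, 9.8, 160.0, 0.0, 250.0)


class TestDaylength:
    def test_equinox_about_12h(self):
        assert daylength(48.0, 80) == pytest.approx(12.0, abs=0.3)

    def test_equator_12h_all_year(self):
        for doy in (1, 100, 200, 300, 365):
            assert daylength(0.0, doy) == pytest.approx(12.0, abs=0.2)

    def test_summer_solstice_lat48_matches_almanac(self):
        # standard almanac value for 48°N around June 21 is ~15.9-16.2 h
        assert daylength(48.0, 172) == pytest.approx(16.05, abs=0.25)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError):
            daylength(70.0, 100)


class TestGrowthStages:
    def test_emergence_at_150_degree_days(self, ref_params):
        w = constant_weather(tmean=15.0)
        gs = simulate_growth_stages(w, ref_params, "1999-10-15")
        days_to_gs10 = (gs.dates["GS10"] - gs.dates["GS00"]).days
        assert days_to_gs10 == 10  # 150 / 15 °C-days per day
        assert gs.tt_cum["GS10"] == pytest.approx(150.0)

    def test_gs65_formula(self):
        gs55 = 1000.0
        assert gs55 + 0.05899 * (1.596 * gs55 - 93.61) == pytest.approx(1088.63, abs=0.01)

    def test_post_heading_offsets(self, one_season_weather, ref_params):
        gs = simulate_growth_stages(one_season_weather, ref_params, "2004-10-15")
        assert gs.tt_cum["GS75"] - gs.tt_cum["GS55"] == pytest.approx(430.0)
        assert gs.tt_cum["GS92"] - gs.tt_cum["GS55"] == pytest.approx(770.0)
        expected65 = gs.tt_cum["GS55"] + 0.05899 * (1.596 * gs.tt_cum["GS55"] - 93.61)
        assert gs.tt_cum["GS65"] == pytest.approx(expected65)
        assert gs.tt_cum["GS39"] == pytest.approx(gs.tt_cum["GS55"] - 1.2 * gs.phyll)

    def test_stage_ordering(self, one_season_weather, ref_params):
        gs = simulate_growth_stages(one_season_weather, ref_params, "2004-10-15")
        gs.validate()
        tts = [gs.tt_cum[s] for s in ("GS00", "GS10", "GS30", "GS39", "GS55", "GS65", "GS75", "GS92")]
        assert tts == sorted(tts)
        assert gs.tt_cum["GS39"] < gs.tt_cum["GS55"]

    def test_warmer_weather_weakly_earlier(self, ref_params):
        base = generate_weather(47.0, 2003, ClimateParams(t_anom_sd=0, rg_anom_sd=0,
                                rain_p_wet_after_dry=0, rain_p_wet_after_wet=0), seed=0)
        warm_df = base.data[["date", "tmin", "tmax", "radiation", "rain"]].copy()
        bump = np.where(base.data["tmean"] < 22.0, 2.0, 0.0)  # stay below the optimum
        warm_df["tmin"] += bump
        warm_df["tmax"] += bump
        warm = type(base)(warm_df, latitude=47.0)
        g1 = simulate_growth_stages(base, ref_params, "2002-10-15")
        g2 = simulate_growth_stages(warm, ref_params, "2002-10-15")
        for s in ("GS10", "GS30", "GS55", "GS92"):
            assert g2.dates[s] <= g1.dates[s]

    def test_short_series_raises_with_last_stage(self, ref_params):
        w = constant_weather(tmean=15.0, days=60)
        with pytest.raises(SeasonTooShortError) as exc:
            simulate_growth_stages(w, ref_params, "1999-10-15")
        assert exc.value.last_stage in ("GS00", "GS10", "GS30")


class TestWeatherGenerator:
    def test_zero_noise_is_exactly_sinusoidal(self):
        p = ClimateParams(t_anom_sd=0, rg_anom_sd=0, rain_p_wet_after_dry=0,
                          rain_p_wet_after_wet=0, t_year_anom_sd=0, rg_year_anom_sd=0,
                          t_lat_gradient=0)
        w = generate_weather(46.0, 2010, p, seed=5)
        doy = w.data["date"].dt.dayofyear.to_numpy(dtype=float)
        season = -np.cos(2 * np.pi * (doy - p.doy_peak + 182.625) / 365.25)
        np.testing.assert_allclose(w.data["tmean"], p.tmean_annual + p.t_amplitude * season, atol=1e-9)
        assert (w.data["rain"] == 0).all()

    def test_reproducible_under_seed(self):
        a = generate_weather(46.0, 2010, seed=9)
        b = generate_weather(46.0, 2010, seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_weather(46.0, 2010, seed=10)
        assert not a.data["tmean"].equals(c.data["tmean"])

    def test_longrun_mean_matches_configured(self):
        # year anomalies off (mean-zero but slow to average out); exactly one
        # 12-month window per series so the seasonal cycle averages to zero
        p = ClimateParams(t_year_anom_sd=0, rg_year_anom_sd=0)
        means = [
            generate_weather(
                p.lat_ref, y, p, seed=1, start=f"{y-1}-09-01", end=f"{y}-08-31"
            ).data["tmean"].mean()
            for y in range(2000, 2010)
        ]
        assert np.mean(means) == pytest.approx(p.tmean_annual, abs=0.2)

    def test_regional_structure(self):
        p = ClimateParams(t_anom_sd=0, rg_anom_sd=0)
        south = generate_weather(44.0, 2010, p, seed=2).data["tmean"].mean()
        north = generate_weather(49.0, 2010, p, seed=2).data["tmean"].mean()
        assert south - north == pytest.approx(5.0 * p.t_lat_gradient, abs=1e-6)
        # same-year anomaly is shared across locations, so two locations at
        # the same latitude and seed differ only through daily noise (zeroed)
        a = generate_weather(46.0, 2011, p, seed=2, location="A").data["tmean"]
        b = generate_weather(46.0, 2011, p, seed=2, location="B").data["tmean"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_invariants(self, one_season_weather):
        d = one_season_weather.data
        assert (d["tmin"] <= d["tmax"]).all()
        assert (d["radiation"] >= 0).all()
        assert (d["rain"] >= 0).all()
        assert d["photoperiod"].between(0, 24).all()
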