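import numpy as np
import pandas as pd
import pytest

from clisagri import (
    ClimateSpec,
    IncompleteSeasonError,
    PhotoperiodParams,
    StageWindow,
    VarietyParams2,
    VarietyParamsMulti,
    VernalizationParams,
    daylength,
    effective_temperature,
    generate_series,
    photoperiod_factor,
    resolve_window,
    simulate_2phase,
    simulate_multiphase,
    vernalization_factor,
)
from _oracles import oracle_daylength, oracle_dvs_2phase, oracle_dvs_multiphase
from conftest import make_constant_series

SOW = pd.Timestamp("2001-01-01")


def constant_params2(tsum1=600.0, tsum2=600.0, **kw):
    return VarietyParams2(
        tsum1=tsum1, tsum2=tsum2, sowing_date=SOW, vern=None, photo=None, **kw
    )


def random_season(seed: int):
    """A 2-year synthetic series and a randomized variety, October sowing."""
    rng = np.random.default_rng(seed)
    series = generate_series(
        ClimateSpec(
            n_years=2,
            seed=seed,
            t_mean_annual=float(rng.uniform(12, 16)),
            t_amplitude=float(rng.uniform(7, 11)),
        )
    )
    sowing = pd.Timestamp(year=2001, month=10, day=int(rng.integers(10, 31)))
    return series, sowing, rng


class TestDaylength:
    def test_equator_near_twelve_hours_all_year(self):
        dl = daylength(0.0, np.arange(1, 366))
        assert np.all(np.abs(dl - 12.0) < 0.3)

    def test_polar_night_zero(self):
        assert daylength(70.0, 355) == 0.0

    def test_matches_geometry_oracle(self):
        assert daylength(45.0, 172) == pytest.approx(oracle_daylength(45.0, 172), rel=1e-12)


class TestResponseFunctions:
    @pytest.mark.parametrize(
        "tavg,expected", [(20.0, 20.0), (-5.0, 0.0), (35.0, 30.0), (0.0, 0.0)]
    )
    def test_effective_temperature_clamps(self, tavg, expected):
        assert effective_temperature(tavg, 0.0, 30.0) == expected

    def test_effective_temperature_with_base(self):
        assert effective_temperature(8.0, 9.0, 30.0) == 0.0  # below ripening base
        assert effective_temperature(12.0, 9.0, 30.0) == 3.0

    def test_vernalization_saturation_and_midpoint(self):
        v = VernalizationParams(v_base=10.0, v_sat=40.0)
        assert vernalization_factor(50.0, v) == 1.0
        assert vernalization_factor(5.0, v) == 0.0
        assert vernalization_factor(25.0, v) == 0.5

    def test_vernalization_effectiveness_curve(self):
        v = VernalizationParams()
        assert v.effectiveness(5.0) == 1.0  # inside the 3-10 degC plateau
        assert v.effectiveness(-10.0) == 0.0
        assert v.effectiveness(25.0) == 0.0
        assert 0.0 < v.effectiveness(0.0) < 1.0

    def test_photoperiod_edges_and_midpoint(self):
        p = PhotoperiodParams(d_critical=8.0, d_optimal=16.0)
        assert photoperiod_factor(18.0, p) == 1.0
        assert photoperiod_factor(8.0, p) == 0.0
        assert photoperiod_factor(12.0, p) == 0.5


class TestTwoPhase:
    def test_constant_temperature_arithmetic(self):
        s = make_constant_series(tavg=20.0)
        track = simulate_2phase(s, constant_params2())
        assert (track.stage_dates["flowering"] - SOW).days == 30
        assert (track.stage_dates["maturity"] - SOW).days == 60
        assert track.dvs[30] == pytest.approx(1.0, abs=1e-9)
        assert track.dvs[60] == pytest.approx(2.0, abs=1e-9)
        assert track.complete

    def test_dvs_nondecreasing_and_capped(self, med_series):
        p = VarietyParams2(tsum1=800, tsum2=800, sowing_date="2001-10-25")
        track = simulate_2phase(med_series, p)
        assert (np.diff(track.dvs) >= 0).all()
        assert track.dvs.max() <= 2.0

    def test_insensitive_above_max_effective_temperature(self):
        a = make_constant_series(tavg=30.0)
        b = make_constant_series(tavg=38.0)
        ta = simulate_2phase(a, constant_params2())
        tb = simulate_2phase(b, constant_params2())
        np.testing.assert_array_equal(ta.dvs, tb.dvs)

    def test_sowing_outside_series_rejected(self):
        s = make_constant_series(n_days=10)
        p = VarietyParams2(tsum1=600, tsum2=600, sowing_date="2005-01-01", vern=None, photo=None)
        with pytest.raises(ValueError, match="sowing"):
            simulate_2phase(s, p)

    def test_matches_literal_day_loop_oracle(self):
        for seed in range(5):
            series, sowing, rng = random_season(seed)
            params = VarietyParams2(
                tsum1=float(rng.uniform(600, 1000)),
                tsum2=float(rng.uniform(600, 1000)),
                sowing_date=sowing,
            )
            track = simulate_2phase(series, params)
            sub = series.data.loc[sowing:]
            tavg = (0.5 * (sub["tmin"] + sub["tmax"])).to_numpy()
            doys = sub.index.dayofyear.to_numpy()
            expected = oracle_dvs_2phase(tavg, doys, series.latitude, params)
            np.testing.assert_allclose(track.dvs, expected, atol=1e-9)


class TestMultiPhase:
    def test_constant_temperature_boundaries(self):
        s = make_constant_series(tavg=20.0)
        p = VarietyParamsMulti(
            tsums=[200, 100, 200, 200, 100, 500],
            t_bases=[0] * 6,
            sowing_date=SOW,
            vern=None,
            photo=None,
        )
        track = simulate_multiphase(s, p)
        days = [(track.first_date_at(float(k)) - SOW).days for k in range(1, 7)]
        assert days == [10, 15, 25, 35, 40, 65]
        assert track.max_dvs == 6.0

    def test_high_base_temperature_blocks_progress(self):
        # ripening sub-phase with base 9 degC makes no progress at tavg 8
        s = make_constant_series(tavg=8.0, n_days=200)
        p = VarietyParamsMulti(
            tsums=[10, 10, 10, 10, 10, 450],
            t_bases=[2, -2, -2, 0, 0, 9],
            sowing_date=SOW,
            vern=None,
            photo=None,
        )
        track = simulate_multiphase(s, p)
        assert track.max_dvs == pytest.approx(5.0, abs=1e-9)
        assert not track.complete

    def test_matches_literal_day_loop_oracle(self):
        from clisagri.phenology import TABLE_TSUM_BOUNDS

        for seed in range(5):
            series, sowing, rng = random_season(100 + seed)
            params = VarietyParamsMulti(
                tsums=[float(rng.uniform(lo, hi)) for lo, hi in TABLE_TSUM_BOUNDS],
                sowing_date=sowing,
            )
            track = simulate_multiphase(series, params)
            sub = series.data.loc[sowing:]
            tavg = (0.5 * (sub["tmin"] + sub["tmax"])).to_numpy()
            doys = sub.index.dayofyear.to_numpy()
            expected = oracle_dvs_multiphase(tavg, doys, series.latitude, params)
            np.testing.assert_allclose(track.dvs, expected, atol=1e-9)

    def test_degenerate_equivalence_with_two_phase(self):
        # same base temperature everywhere, Vf=Pf=1, sub-phase requirements
        # summing to TSUM1 (phases 1-5) and TSUM6=TSUM2: flowering and
        # maturity fall on the same days in both models
        s = make_constant_series(tavg=17.3, n_days=300)
        p2 = constant_params2(tsum1=600.0, tsum2=500.0)
        pm = VarietyParamsMulti(
            tsums=[120, 120, 120, 120, 120, 500],
            t_bases=[0.0] * 6,
            sowing_date=SOW,
            vern=None,
            photo=None,
        )
        t2 = simulate_2phase(s, p2)
        tm = simulate_multiphase(s, pm)
        assert tm.first_date_at(5.0) == t2.stage_dates["flowering"]
        assert tm.first_date_at(6.0) == t2.stage_dates["maturity"]


class TestResolveWindow:
    def test_static_identity(self):
        w = StageWindow(mode="static", start="2001-03-01", end="2001-03-31")
        assert resolve_window(w) == (pd.Timestamp("2001-03-01"), pd.Timestamp("2001-03-31"))

    def test_dynamic_from_constant_track(self):
        s = make_constant_series(tavg=20.0)
        track = simulate_2phase(s, constant_params2())
        w = StageWindow(mode="dynamic", start_dvs=1.0, end_dvs=2.0)
        start, end = resolve_window(w, track)
        assert (start - SOW).days == 30
        assert (end - SOW).days == 60

    def test_incomplete_season_carries_max_dvs(self):
        s = make_constant_series(tavg=20.0, n_days=20)
        track = simulate_2phase(s, constant_params2())
        with pytest.raises(IncompleteSeasonError) as exc:
            resolve_window(StageWindow(mode="dynamic", start_dvs=1.0, end_dvs=2.0), track)
        assert exc.value.max_dvs < 1.0

    def test_warmer_year_flowers_earlier(self):
        for seed in range(3):
            series, sowing, rng = random_season(200 + seed)
            params = VarietyParams2(
                tsum1=800, tsum2=800, sowing_date=sowing, vern=None, photo=None
            )
            warmer = series.data.copy()
            warmer[["tmin", "tmax"]] += 2.0
            from clisagri import WeatherSeries

            w_series = WeatherSeries(warmer, latitude=series.latitude)
            cool = simulate_2phase(series, params)
            warm = simulate_2phase(w_series, params)
            win = StageWindow(mode="dynamic", start_dvs=0.9, end_dvs=2.0)
            assert resolve_window(win, warm)[0] <= resolve_window(win, cool)[0]
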