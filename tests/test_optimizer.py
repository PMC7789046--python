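import numpy as np
import pandas as pd
import pytest

from clisagri import (
    GAConfig,
    VarietyParams2,
    VarietyParamsMulti,
    WeatherEnsemble,
    clis_agri,
    fitness,
    ga_optimize,
    ga_optimize_ensemble,
    grid_scan,
)
from clisagri.indicators import IndicatorResult
from clisagri.optimizer import FitnessEvaluator, _ga_run


@pytest.fixture(scope="module")
def base_multi():
    return VarietyParamsMulti(sowing_date="2011-10-25", vern=None, photo=None)


@pytest.fixture(scope="module")
def heat_config():
    # heat-only fitness: no water-balance precomputation needed, fast
    return GAConfig(population_size=12, n_generations=8, seed=0, indicator_ids=(15, 16))


class TestGridScan:
    def test_degenerate_grid_equals_direct_call(self, med_series):
        params = VarietyParams2(tsum1=800, tsum2=800, sowing_date="2011-10-25")
        grid = grid_scan(med_series, params, [800.0], [800.0], selection=[16])
        direct = clis_agri(med_series, params, selection=[16])
        assert len(grid.table) == 1
        assert grid.table["value"].iloc[0] == direct[0].value

    def test_full_cross_product_unique_keys(self, med_series):
        params = VarietyParams2(tsum1=700, tsum2=700, sowing_date="2011-10-25")
        grid = grid_scan(
            med_series, params, [600.0, 800.0, 1000.0], [600.0, 800.0, 1000.0],
            selection=[16],
        )
        keys = set(zip(grid.table["tsum1"], grid.table["tsum2"]))
        assert len(keys) == 9
        pivot = grid.pivot(16)
        assert pivot.shape == (3, 3)

    def test_heat_exposure_nondecreasing_in_tsum2(self, med_series):
        # later maturity extends grain filling into hotter weather
        params = VarietyParams2(
            tsum1=700, tsum2=700, sowing_date="2011-10-25", vern=None, photo=None
        )
        grid = grid_scan(
            med_series, params, [700.0], [600.0, 750.0, 900.0, 1050.0], selection=[16]
        )
        vals = grid.table.sort_values("tsum2")["value"].to_numpy()
        assert (np.diff(vals) >= 0).all()

    def test_empty_value_list_rejected(self, med_series):
        params = VarietyParams2(tsum1=700, tsum2=700, sowing_date="2011-10-25")
        with pytest.raises(ValueError):
            grid_scan(med_series, params, [], [700.0])


class TestFitness:
    def test_zero_penalty_is_maximum(self, med_series, base_multi):
        # mild mid-range variety on the default synthetic climate: construct
        # the score and check the no-stress components are exactly zero-based
        cfg = GAConfig(indicator_ids=(15, 16))
        score = FitnessEvaluator(med_series, base_multi, cfg).score(base_multi.tsums)
        assert score.total == -sum(score.penalties.values())
        assert all(p >= 0 for p in score.penalties.values())

    def test_spei_hinge_arithmetic(self, med_series, base_multi):
        cfg = GAConfig(indicator_ids=(5,))
        ev = FitnessEvaluator(med_series, base_multi, cfg)
        res = IndicatorResult(
            5, "", (pd.Timestamp("2012-05-01"), pd.Timestamp("2012-06-01")), -1.5, None, True
        )
        assert ev._penalty(res) == pytest.approx(0.5)
        res_ok = IndicatorResult(5, "", res.window, 0.8, None, True)
        assert ev._penalty(res_ok) == 0.0

    def test_count_penalty_normalized_by_window_length(self, med_series, base_multi):
        cfg = GAConfig(indicator_ids=(16,))
        ev = FitnessEvaluator(med_series, base_multi, cfg)
        window = (pd.Timestamp("2012-06-01"), pd.Timestamp("2012-06-20"))
        res = IndicatorResult(16, "", window, 5.0, None, True)
        assert ev._penalty(res) == pytest.approx(5.0 / 20.0)

    def test_matches_hand_summed_recomputation(self, med_series, base_multi):
        from clisagri.indicators import compute_indicators
        from clisagri.phenology import DEFAULT_STAGE_DVS_MULTI, simulate_multiphase
        from dataclasses import replace

        cfg = GAConfig(indicator_ids=(4, 5, 15, 16))
        ev = FitnessEvaluator(med_series, base_multi, cfg)
        chrom = (150.0, 90.0, 180.0, 160.0, 90.0, 470.0)
        score = ev.score(chrom)

        params = replace(base_multi, tsums=chrom)
        track = simulate_multiphase(med_series, params)
        results = compute_indicators(
            med_series, params.sowing_date, track, DEFAULT_STAGE_DVS_MULTI,
            selection=[4, 5, 15, 16], wb=ev.wb,
        )
        expected = 0.0
        for r in results:
            if r.id in (4, 5):
                expected += max(0.0, abs(r.value) - 1.0)
            else:
                ndays = (r.window[1] - r.window[0]).days + 1
                expected += r.value / ndays
        assert score.total == pytest.approx(-expected, abs=1e-12)

    def test_incomplete_season_gets_fixed_penalty(self, med_series, base_multi):
        cfg = GAConfig(indicator_ids=(15, 16))
        ev = FitnessEvaluator(med_series, base_multi, cfg)
        # sow very late with huge requirements: cannot mature by series end
        from dataclasses import replace

        late = replace(base_multi, sowing_date=pd.Timestamp("2012-09-01"))
        score = FitnessEvaluator(med_series, late, cfg).score(
            (200.0, 140.0, 220.0, 200.0, 150.0, 550.0)
        )
        assert score.total == -10.0
        assert not score.season_complete

    def test_out_of_bounds_chromosome_rejected(self, med_series, base_multi):
        with pytest.raises(ValueError, match="bounds"):
            fitness((999.0, 80.0, 150.0, 150.0, 100.0, 500.0), med_series,
                    GAConfig(indicator_ids=(15, 16)), base_multi)


class TestGaOptimize:
    def test_collapsed_bounds_return_unique_chromosome(self, med_series, base_multi, heat_config):
        point = (160.0, 90.0, 160.0, 150.0, 100.0, 500.0)
        bounds = [(g, g) for g in point]
        res = ga_optimize(med_series, base_multi, heat_config, bounds=bounds)
        assert res.best_chromosome == point
        direct = fitness(point, med_series, heat_config, base_multi, bounds=bounds)
        assert res.best_fitness == direct.total

    def test_elitism_trace_nondecreasing(self, med_series, base_multi, heat_config):
        res = ga_optimize(med_series, base_multi, heat_config)
        assert (np.diff(res.trace["best"].to_numpy()) >= 0).all()

    def test_same_seed_same_result(self, med_series, base_multi, heat_config):
        a = ga_optimize(med_series, base_multi, heat_config)
        b = ga_optimize(med_series, base_multi, heat_config)
        assert a.best_chromosome == b.best_chromosome
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_infeasible_bounds_rejected(self, med_series, base_multi, heat_config):
        bounds = [(200.0, 120.0)] + [(50.0, 150.0)] * 5
        with pytest.raises(ValueError, match="infeasible"):
            ga_optimize(med_series, base_multi, heat_config, bounds=bounds)

    def test_ga_beats_random_search_on_matched_budget(self):
        # GA machinery check on a cheap surrogate: sphere fitness, 20 seeds
        bounds = [(0.0, 10.0)] * 6
        target = np.array([7.0, 2.0, 5.0, 1.0, 9.0, 4.0])

        def surrogate(ind):
            return -float(np.sum((np.asarray(ind) - target) ** 2))

        ga_best, rnd_best = [], []
        for seed in range(20):
            cfg = GAConfig(population_size=20, n_generations=10, seed=seed)
            _, best, _ = _ga_run(surrogate, bounds, cfg)
            ga_best.append(best)
            rng = np.random.default_rng(seed)
            n_evals = 20 * 11
            samples = rng.uniform(0, 10, size=(n_evals, 6))
            rnd_best.append(max(surrogate(s) for s in samples))
        assert np.median(ga_best) >= np.median(rnd_best)


class TestGaEnsemble:
    def test_single_member_reduces_to_plain_ga(self, med_series, base_multi, heat_config):
        ens = WeatherEnsemble([med_series])
        res_e = ga_optimize_ensemble(ens, base_multi, heat_config)
        res_s = ga_optimize(med_series, base_multi, heat_config)
        assert res_e.best_chromosome == res_s.best_chromosome
        assert res_e.best_fitness == res_s.best_fitness

    def test_identical_members_mean_equals_single(self, med_series, base_multi, heat_config):
        ens = WeatherEnsemble([med_series, med_series])
        ev = FitnessEvaluator(med_series, base_multi, heat_config)
        chrom = (160.0, 90.0, 160.0, 150.0, 100.0, 500.0)
        evs = [FitnessEvaluator(m, base_multi, heat_config) for m in ens.members]
        mean_total = np.mean([e.score(chrom).total for e in evs])
        assert mean_total == ev.score(chrom).total

    def test_mean_fitness_is_hand_average(self, base_multi, heat_config, med_spec):
        from clisagri import generate_ensemble

        ens = generate_ensemble(med_spec, 3)
        chrom = (160.0, 90.0, 160.0, 150.0, 100.0, 500.0)
        evs = [FitnessEvaluator(m, base_multi, heat_config) for m in ens.members]
        per_member = [e.score(chrom).total for e in evs]
        res = ga_optimize_ensemble(
            ens, base_multi, heat_config, bounds=[(g, g) for g in chrom]
        )
        assert res.best_fitness == pytest.approx(np.mean(per_member), abs=1e-12)
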