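import itertools

import numpy as np
import pytest

import nirband as nb
from nirband.ga_engine import WORST_FITNESS, derive_cell_seed


def make_scores(rng, n_cal=30, n_val=15, m=8, n_informative=3, noise=0.3):
    """Synthetic score system: y depends on a few columns, rest is noise."""
    sc = rng.normal(size=(n_cal, m))
    sv = rng.normal(size=(n_val, m))
    beta = np.zeros(m)
    beta[:n_informative] = rng.uniform(1.0, 2.0, size=n_informative)
    yc = sc @ beta + noise * rng.normal(size=n_cal)
    yv = sv @ beta + noise * rng.normal(size=n_val)
    return sc, yc, sv, yv


def exhaustive_best(sc, yc, sv, yv):
    """Brute force over every nonempty subset of score columns."""
    m = sc.shape[1]
    best = WORST_FITNESS
    for bits in itertools.product([0, 1], repeat=m):
        if not any(bits):
            continue
        f = nb.fitness(np.array(bits, bool), sc, yc, sv, yv)
        best = min(best, f)
    return best


class TestFitness:
    def test_noise_free_full_selection_is_exact(self, rng):
        sc, yc, sv, yv = make_scores(rng, noise=0.0)
        f = nb.fitness(np.ones(8, bool), sc, yc, sv, yv)
        assert f < 1e-6

    def test_single_column_matches_simple_regression(self, rng):
        sc, yc, sv, yv = make_scores(rng)
        flags = np.zeros(8, bool)
        flags[0] = True
        x = sc[:, 0]
        slope = np.cov(x, yc, ddof=1)[0, 1] / np.var(x, ddof=1)
        pred = yc.mean() + slope * (sv[:, 0] - x.mean())
        expected = float(np.sqrt(np.mean((pred - yv) ** 2)))
        assert nb.fitness(flags, sc, yc, sv, yv) == pytest.approx(expected, rel=1e-10)

    def test_all_zero_is_sentinel(self, rng):
        sc, yc, sv, yv = make_scores(rng)
        assert nb.fitness(np.zeros(8, bool), sc, yc, sv, yv) == WORST_FITNESS

    def test_nested_model_calibration_monotonicity(self, rng):
        # adding a column can never worsen the calibration-set least-squares fit
        sc, yc, sv, yv = make_scores(rng)
        def cal_rmse(flags):
            A = np.column_stack([np.ones(len(yc)), sc[:, flags]])
            beta, *_ = np.linalg.lstsq(A, yc, rcond=None)
            return float(np.sqrt(np.mean((A @ beta - yc) ** 2)))
        small = np.zeros(8, bool); small[:2] = True
        big = small.copy(); big[5] = True
        assert cal_rmse(big) <= cal_rmse(small) + 1e-12

    def test_length_mismatch_rejected(self, rng):
        sc, yc, sv, yv = make_scores(rng)
        with pytest.raises(ValueError):
            nb.fitness(np.ones(5, bool), sc, yc, sv, yv)


class TestGAConfig:
    @pytest.mark.parametrize("kw", [
        dict(p_crossover=0.0, p_mutation=0.01),
        dict(p_crossover=0.5, p_mutation=1.5),
        dict(p_crossover=0.5, p_mutation=0.01, population_size=5),
        dict(p_crossover=0.5, p_mutation=0.01, max_iterations=0),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            nb.GAConfig(**kw)

    def test_from_percent(self):
        cfg = nb.GAConfig.from_percent(50, 1.2)
        assert cfg.p_crossover == 0.5 and cfg.p_mutation == pytest.approx(0.012)

    def test_population_scales_with_input(self):
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012)
        assert cfg.resolve_population(5) == 20
        assert cfg.resolve_population(36) == 72
        assert cfg.resolve_population(15) == 30


class TestEvolve:
    def test_single_candidate(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=1, n_informative=1)
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, seed=0)
        trace = nb.evolve(sc, yc, sv, yv, cfg)
        assert trace.best_chromosome.tolist() == [True]
        assert trace.best_rmsev == trace.best_rmsev_per_iteration[0]

    def test_trace_non_increasing(self, rng):
        sc, yc, sv, yv = make_scores(rng)
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, max_iterations=60, seed=3)
        trace = nb.evolve(sc, yc, sv, yv, cfg)
        assert (np.diff(trace.best_rmsev_per_iteration) <= 1e-15).all()

    def test_bit_reproducible(self, rng):
        sc, yc, sv, yv = make_scores(rng)
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, max_iterations=40, seed=9)
        t1 = nb.evolve(sc, yc, sv, yv, cfg)
        t2 = nb.evolve(sc, yc, sv, yv, cfg)
        assert np.array_equal(t1.best_chromosome, t2.best_chromosome)
        np.testing.assert_array_equal(t1.best_rmsev_per_iteration,
                                      t2.best_rmsev_per_iteration)
        assert t1.stop_iteration == t2.stop_iteration

    def test_finds_exhaustive_optimum(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=8)
        oracle = exhaustive_best(sc, yc, sv, yv)
        # generous budget: no stalling, full iteration ceiling
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, seed=11,
                          max_iterations=500, stall_window=500)
        trace = nb.evolve(sc, yc, sv, yv, cfg)
        assert trace.best_rmsev == pytest.approx(oracle, rel=1e-12)

    def test_constant_landscape_stalls_immediately(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=4)
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, seed=2)
        trace = nb.evolve(sc, yc, sv, yv, cfg, objective=lambda flags: 1.0)
        assert trace.stop_reason == "stalled"
        assert trace.stop_iteration <= cfg.stall_window + 1


class TestStoppingRules:
    def test_stall_after_exactly_twenty_unchanged_iterations(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=4)
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, seed=5)
        trace = nb.evolve(sc, yc, sv, yv, cfg, objective=lambda flags: 2.5)
        assert trace.stop_reason == "stalled"
        assert trace.stop_iteration == cfg.stall_window + 1
        assert np.ptp(trace.best_rmsev_per_iteration) == 0.0

    def test_hard_iteration_ceiling(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=4)
        cfg = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, max_iterations=500,
                          stall_window=501, seed=5)
        trace = nb.evolve(sc, yc, sv, yv, cfg, objective=lambda flags: 2.5)
        assert trace.stop_reason == "max_iterations"
        assert trace.stop_iteration == 500
        assert trace.best_rmsev_per_iteration.size == 500


class TestParametricScan:
    def test_grid_shape(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=6)
        base = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, max_iterations=30, seed=4)
        _, _, traces = nb.parametric_scan(sc, yc, sv, yv, (40, 50, 60),
                                          (0.8, 1.2, 1.5), base)
        assert len(traces) == 9
        assert set(traces) == {(c, m) for c in (40, 50, 60) for m in (0.8, 1.2, 1.5)}

    def test_single_cell_equals_direct_evolve(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=6)
        base = nb.GAConfig(p_crossover=0.9, p_mutation=0.5, max_iterations=30, seed=4)
        cfg, trace, _ = nb.parametric_scan(sc, yc, sv, yv, (50,), (1.2,), base)
        direct = nb.evolve(sc, yc, sv, yv, cfg)
        assert trace.best_rmsev == direct.best_rmsev
        np.testing.assert_array_equal(trace.best_chromosome, direct.best_chromosome)

    def test_minimum_matches_rerun_oracle(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=6)
        base = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, max_iterations=25, seed=8)
        best_cfg, best_trace, traces = nb.parametric_scan(
            sc, yc, sv, yv, (40, 60), (0.8, 1.5), base)
        rerun = {}
        for idx, (cp, mp) in enumerate((c, m) for c in (40, 60) for m in (0.8, 1.5)):
            cfg = nb.GAConfig(p_crossover=cp / 100, p_mutation=mp / 100,
                              max_iterations=25,
                              seed=derive_cell_seed(8, idx))
            rerun[(cp, mp)] = nb.evolve(sc, yc, sv, yv, cfg).best_rmsev
        assert best_trace.best_rmsev == min(rerun.values())
        for key, val in rerun.items():
            assert traces[key].best_rmsev == val

    def test_empty_grid_rejected(self, rng):
        sc, yc, sv, yv = make_scores(rng, m=4)
        base = nb.GAConfig(p_crossover=0.5, p_mutation=0.012, seed=1)
        with pytest.raises(ValueError):
            nb.parametric_scan(sc, yc, sv, yv, (), (1.2,), base)
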