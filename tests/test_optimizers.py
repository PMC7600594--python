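"""The four metaheuristics: convergence, invariants, and the quantization
fitness applied to code streams."""

import numpy as np
import pytest

from ppgfuzz import optimizers
from ppgfuzz.codewords import VALUE_MAX
from ppgfuzz.optimizers import (
    OptimizerConfig,
    OptimizerConfigError,
    QuantizationFitness,
    SearchSpace,
    amo_replacement_probability,
    deal_memeplexes,
    init_population,
    optimize_stream,
    random_search,
    ring_neighborhood,
    run,
    ws_alpha_schedule,
)


def sphere(x):
    return float(np.sum(x * x))


SPACE5 = SearchSpace.cube(5, -1.0, 1.0)

#: sphere thresholds per algorithm at NP=20, 200 iterations
SPHERE_THRESHOLDS = {"DS": 1e-2, "SFLA": 1e-2, "WS": 1e-3, "AMO": 1e-2}


def cfg_for(alg, seed, max_iter=200):
    return OptimizerConfig(algorithm=alg, np_size=20, max_iter=max_iter, seed=seed)


class TestSearchSpace:
    def test_bounds_must_be_ordered(self):
        with pytest.raises(OptimizerConfigError):
            SearchSpace(np.array([0.0, 1.0]), np.array([1.0, 1.0]))

    def test_init_population_respects_bounds(self):
        pop = init_population(SPACE5, 50, 0)
        assert pop.shape == (50, 5)
        assert (pop >= -1).all() and (pop <= 1).all()

    def test_init_population_near_degenerate_bounds(self):
        eps = 1e-9
        space = SearchSpace.cube(3, 0.5 - eps, 0.5 + eps)
        pop = init_population(space, 10, 1)
        assert np.allclose(pop, 0.5, atol=2 * eps)

    def test_init_population_deterministic(self):
        np.testing.assert_array_equal(
            init_population(SPACE5, 8, 42), init_population(SPACE5, 8, 42)
        )


class TestConfigValidation:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(OptimizerConfigError):
            OptimizerConfig(algorithm="GA").validate()

    def test_tiny_population_rejected(self):
        with pytest.raises(OptimizerConfigError):
            OptimizerConfig(np_size=3).validate()

    def test_sfla_population_must_factor(self):
        cfg = OptimizerConfig(
            algorithm="SFLA", np_size=19, sfla_memeplexes=4, sfla_frogs_per_memeplex=5
        )
        with pytest.raises(OptimizerConfigError):
            cfg.validate()


@pytest.mark.parametrize("alg", optimizers.ALGORITHMS)
class TestAllAlgorithms:
    def test_sphere_convergence_in_9_of_10_seeds(self, alg):
        passes = 0
        for seed in range(10):
            res = run(sphere, SPACE5, cfg_for(alg, seed))
            if res.best_fitness < SPHERE_THRESHOLDS[alg]:
                passes += 1
        assert passes >= 9, f"{alg}: {passes}/10 below threshold"

    def test_trace_is_nonincreasing_and_consistent(self, alg):
        res = run(sphere, SPACE5, cfg_for(alg, 3, max_iter=50))
        trace = np.asarray(res.fitness_trace)
        assert (np.diff(trace) <= 0).all()
        assert res.best_fitness == trace[-1]
        assert res.best_fitness == pytest.approx(sphere(res.best_position))

    def test_constant_fitness_gives_flat_trace(self, alg):
        res = run(lambda x: 7.25, SPACE5, cfg_for(alg, 0, max_iter=10))
        assert res.best_fitness == 7.25
        assert set(res.fitness_trace) == {7.25}

    def test_best_position_within_bounds(self, alg):
        res = run(sphere, SPACE5, cfg_for(alg, 5, max_iter=30))
        assert (res.best_position >= SPACE5.lower - 1e-12).all()
        assert (res.best_position <= SPACE5.upper + 1e-12).all()

    def test_bit_reproducible_given_seed(self, alg):
        r1 = run(sphere, SPACE5, cfg_for(alg, 9, max_iter=30))
        r2 = run(sphere, SPACE5, cfg_for(alg, 9, max_iter=30))
        np.testing.assert_array_equal(r1.best_position, r2.best_position)
        assert r1.fitness_trace == r2.fitness_trace
        assert r1.evaluations == r2.evaluations

    def test_beats_random_search_at_equal_budget(self, alg):
        wins = 0
        for seed in range(10):
            res = run(sphere, SPACE5, cfg_for(alg, seed))
            base = random_search(sphere, SPACE5, res.evaluations, seed + 1000)
            if res.best_fitness < base.best_fitness:
                wins += 1
        assert wins >= 9, f"{alg} beat random search in only {wins}/10 seeds"

    def test_seeded_member_caps_best_fitness(self, alg):
        x0 = np.full(5, 0.1)
        res = run(sphere, SPACE5, cfg_for(alg, 2, max_iter=5), x0=x0)
        assert res.best_fitness <= sphere(x0)


class TestAlgorithmSpecifics:
    def test_memeplex_dealing_round_robin_by_rank(self):
        order = np.arange(20)  # already rank-sorted
        plexes = deal_memeplexes(order, 4)
        np.testing.assert_array_equal(plexes[0], [0, 4, 8, 12, 16])
        np.testing.assert_array_equal(plexes[3], [3, 7, 11, 15, 19])

    def test_ws_alpha_schedule_endpoints(self):
        assert ws_alpha_schedule(0, 200) == 2.0
        assert ws_alpha_schedule(200, 200) == 0.0
        assert ws_alpha_schedule(100, 200) == 1.0

    def test_ring_neighborhood_wraps_like_publication_example(self):
        # 1-based: animal 1 has neighbors NP-1, NP, 1, 2, 3
        np_size = 20
        assert ring_neighborhood(1, np_size, 2, one_based=True) == [19, 20, 1, 2, 3]
        assert ring_neighborhood(0, np_size, 2) == [18, 19, 0, 1, 2]
        assert ring_neighborhood(np_size - 1, np_size, 2) == [17, 18, 19, 0, 1]

    def test_amo_replacement_probability_rank_extremes(self):
        fit = np.array([3.0, 1.0, 2.0, 5.0, 4.0])
        pa = amo_replacement_probability(fit)
        assert pa[np.argmin(fit)] == pytest.approx(1 / 5)
        assert pa[np.argmax(fit)] == pytest.approx(1.0)
        assert sorted(pa) == pytest.approx([1 / 5, 2 / 5, 3 / 5, 4 / 5, 1.0])


class TestQuantizationFitness:
    def test_matches_bruteforce_evaluation(self, rng):
        data = rng.random(40)
        x = rng.random(6)
        fit = QuantizationFitness(data)
        brute = np.mean([min((v - xi) ** 2 for xi in x) for v in data])
        assert fit(x) == pytest.approx(brute, abs=1e-15)

    def test_zero_iff_every_value_is_represented(self):
        data = np.array([0.1, 0.3, 0.1])
        fit = QuantizationFitness(data)
        assert fit(np.array([0.1, 0.3])) == 0.0
        assert fit(np.array([0.1, 0.2])) > 0.0


class TestOptimizeStream:
    def test_constant_stream_reaches_zero_fitness(self):
        values = np.full(10, 0.25)
        cfg = OptimizerConfig(algorithm="DS", np_size=8, max_iter=5, seed=0)
        best = optimize_stream(values, cfg)
        assert QuantizationFitness(values)(best) == pytest.approx(0.0, abs=1e-15)

    def test_two_values_two_representatives_reach_grid_optimum(self):
        values = np.array([0.1, 0.4])
        cfg = OptimizerConfig(algorithm="WS", np_size=10, max_iter=30, seed=1)
        best = optimize_stream(values, cfg)
        fit = QuantizationFitness(values)
        # brute-force 2-D grid oracle at step 1e-3
        grid = np.arange(0.0, VALUE_MAX, 1e-3)
        g_best = min(
            fit(np.array([a, b])) for a in grid[::10] for b in grid[::10]
        )
        assert fit(best) <= g_best + 1e-12
        assert fit(best) == pytest.approx(0.0, abs=1e-12)

    def test_never_worse_than_raw_vector(self, rng):
        values = rng.random(30) * VALUE_MAX
        fit = QuantizationFitness(values)
        for alg in optimizers.ALGORITHMS:
            cfg = OptimizerConfig(algorithm=alg, np_size=20, max_iter=5, seed=2)
            best = optimize_stream(values, cfg)
            assert fit(best) <= fit(values) + 1e-15

    def test_empty_stream_rejected(self):
        cfg = OptimizerConfig()
        with pytest.raises(ValueError):
            optimize_stream(np.array([]), cfg)
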