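import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from elmselect import (
    FitnessParams,
    FitnessResult,
    GAConfig,
    ValidationError,
    best_solution,
    evaluate_subset,
    evolve,
    hybrid_crossover,
    init_population,
    mutate,
    run_ga,
    selection_probabilities,
    two_point_crossover,
    uniform_crossover,
)
from elmselect.ga import GAState, Individual, repair


def onemax(bits, generation=0):
    """Surrogate fitness: fraction of ones (plus the bookkeeping fields)."""
    k = int(bits.sum())
    frac = k / bits.size
    return FitnessResult(mean_accuracy=frac, n_selected=max(k, 1), fitness=frac)


class _StubRNG:
    """Generator stand-in returning scripted draws for the crossover cut points."""

    def __init__(self, choices):
        self._choices = list(choices)

    def choice(self, n, size=None, replace=True, p=None):
        return np.asarray(self._choices.pop(0))

    def random(self, size=None):
        return 0.0 if size is None else np.zeros(size)

    def integers(self, lo, hi=None, size=None):
        return 0


class TestGAConfig:
    def test_reference_defaults(self):
        cfg = GAConfig()
        assert cfg.population_size == 200
        assert cfg.crossover_prob == 0.80
        assert cfg.mutation_prob == 0.20
        assert cfg.selection_q == 0.01
        assert cfg.max_generations == 50
        assert cfg.init_gene_range == (20, 200)

    @pytest.mark.parametrize("kwargs", [
        {"population_size": 7}, {"population_size": 0},
        {"crossover_prob": 1.5}, {"mutation_prob": -0.1},
        {"selection_q": 0.0}, {"selection_q": 1.0},
        {"init_gene_range": (0, 10)}, {"init_gene_range": (5, 2)},
    ])
    def test_invalid(self, kwargs):
        with pytest.raises(ValidationError):
            GAConfig(**kwargs)


class TestInitPopulation:
    def test_set_bit_counts_within_range(self):
        cfg = GAConfig(population_size=50, init_gene_range=(20, 200))
        pop = init_population(500, cfg, seed=0)
        assert len(pop) == 50
        for bits in pop:
            assert 20 <= bits.sum() <= 200
            assert bits.size == 500

    def test_degenerate_range(self):
        cfg = GAConfig(population_size=10, init_gene_range=(5, 5))
        for bits in init_population(100, cfg, seed=1):
            assert bits.sum() == 5

    def test_range_exceeding_gene_count_rejected(self):
        cfg = GAConfig(population_size=10, init_gene_range=(20, 200))
        with pytest.raises(ValidationError):
            init_population(100, cfg, seed=0)

    def test_set_bit_count_distribution_uniform(self):
        # chi-square on the set-bit counts of 10,000 chromosomes
        cfg = GAConfig(population_size=10000, init_gene_range=(20, 200))
        pop = init_population(250, cfg, seed=7)
        counts = np.bincount([b.sum() for b in pop], minlength=201)[20:201]
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 0.01


class TestSelectionProbabilities:
    def test_single_individual(self):
        np.testing.assert_allclose(selection_probabilities(1, 0.01), [1.0])

    @pytest.mark.parametrize("n", [1, 10, 200])
    @pytest.mark.parametrize("q", [0.005, 0.01, 0.1])
    def test_sum_and_monotone(self, n, q):
        p = selection_probabilities(n, q)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(np.diff(p) < 0) or n == 1

    def test_rank_one_closed_form(self):
        p = selection_probabilities(200, 0.01)
        assert p[0] == pytest.approx(0.01 / (1 - 0.99**200))

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.5])
    def test_invalid_q(self, q):
        with pytest.raises(ValidationError):
            selection_probabilities(10, q)


class TestUniformCrossover:
    def test_identical_parents(self):
        p = np.array([1, 0, 1, 1, 0], dtype=np.uint8)
        c1, c2 = uniform_crossover(p, p, seed=0)
        np.testing.assert_array_equal(c1, p)
        np.testing.assert_array_equal(c2, p)

    def test_complementary_children(self):
        a = np.zeros(8, dtype=np.uint8)
        b = np.ones(8, dtype=np.uint8)
        c1, c2 = uniform_crossover(a, b, seed=3)
        np.testing.assert_array_equal(c1 ^ c2, np.ones(8, dtype=np.uint8))

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            uniform_crossover(np.ones(3, dtype=np.uint8), np.ones(4, dtype=np.uint8), 0)

    @given(seed=st.integers(0, 2**31), data_seed=st.integers(0, 2**31))
    @settings(max_examples=100, deadline=None)
    def test_allele_inheritance(self, seed, data_seed):
        rng = np.random.default_rng(data_seed)
        a = rng.integers(0, 2, 30).astype(np.uint8)
        b = rng.integers(0, 2, 30).astype(np.uint8)
        for child in uniform_crossover(a, b, seed):
            assert np.all((child == a) | (child == b))
            np.testing.assert_array_equal(child & ~(a | b), 0)
            np.testing.assert_array_equal((a & b) & ~child, 0)


class TestTwoPointCrossover:
    def test_worked_example_cuts_1_3(self):
        a = np.array([0, 0, 0, 0], dtype=np.uint8)
        b = np.array([1, 1, 1, 1], dtype=np.uint8)
        c1, c2 = two_point_crossover(a, b, _StubRNG([[1, 3]]))
        np.testing.assert_array_equal(c1, [0, 1, 1, 0])
        np.testing.assert_array_equal(c2, [1, 0, 0, 1])

    def test_whole_string_cuts_swap_parents(self):
        a = np.array([0, 1, 0, 1], dtype=np.uint8)
        b = np.array([1, 0, 1, 0], dtype=np.uint8)
        c1, c2 = two_point_crossover(a, b, _StubRNG([[0, 4]]))
        np.testing.assert_array_equal(c1, b)
        np.testing.assert_array_equal(c2, a)

    def test_identical_parents(self):
        p = np.array([1, 0, 1, 1], dtype=np.uint8)
        c1, c2 = two_point_crossover(p, p, seed=5)
        np.testing.assert_array_equal(c1, p)
        np.testing.assert_array_equal(c2, p)

    def test_too_short_rejected(self):
        one = np.array([1], dtype=np.uint8)
        with pytest.raises(ValidationError):
            two_point_crossover(one, one, seed=0)

    @given(seed=st.integers(0, 2**31), data_seed=st.integers(0, 2**31))
    @settings(max_examples=100, deadline=None)
    def test_allele_inheritance(self, seed, data_seed):
        rng = np.random.default_rng(data_seed)
        a = rng.integers(0, 2, 25).astype(np.uint8)
        b = rng.integers(0, 2, 25).astype(np.uint8)
        for child in two_point_crossover(a, b, seed):
            assert np.all((child == a) | (child == b))


class TestMutate:
    def test_rate_zero_is_identity(self):
        bits = np.array([1, 0, 1], dtype=np.uint8)
        np.testing.assert_array_equal(mutate(bits, 0.0, seed=0), bits)

    def test_rate_one_is_complement(self):
        bits = np.array([1, 0, 1, 0], dtype=np.uint8)
        np.testing.assert_array_equal(mutate(bits, 1.0, seed=0), [0, 1, 0, 1])

    def test_rate_one_all_ones_repairs_to_single_bit(self):
        bits = np.ones(6, dtype=np.uint8)
        out = mutate(bits, 1.0, seed=0)
        assert out.sum() == 1

    def test_invalid_rate(self):
        with pytest.raises(ValidationError):
            mutate(np.ones(3, dtype=np.uint8), 1.5, seed=0)

    def test_expected_hamming_distance(self):
        # per-bit rate 1/L over 10,000 trials: mean flips ~ Binomial(L, 1/L)
        L, trials = 100, 10000
        bits = np.ones(L, dtype=np.uint8)  # cannot go all-zero, repair never fires
        rng = np.random.default_rng(12)
        dist = [np.sum(mutate(bits, 1 / L, rng) != bits) for _ in range(trials)]
        expected = 1.0
        se = np.sqrt(L * (1 / L) * (1 - 1 / L) / trials)
        assert abs(np.mean(dist) - expected) <= 3 * se


class TestHybridCrossover:
    def test_identical_parents_return_parents(self):
        p = np.array([1, 0, 1, 1, 0, 1], dtype=np.uint8)
        out = hybrid_crossover(p, p, onemax, seed=4)
        for bits, _ in out:
            np.testing.assert_array_equal(bits, p)

    def test_returns_two_of_exactly_four_offspring(self):
        rng = np.random.default_rng(21)
        a = rng.integers(0, 2, 12).astype(np.uint8)
        b = rng.integers(0, 2, 12).astype(np.uint8)
        out = hybrid_crossover(a, b, onemax, seed=33)
        assert len(out) == 2
        # replay the operator's draws to enumerate the same four offspring
        replay = np.random.default_rng(33)
        u1, u2 = uniform_crossover(a, b, replay)
        t1, t2 = two_point_crossover(a, b, replay)
        four = [repair(c, replay) for c in (u1, u2, t1, t2)]
        top = sorted(int(c.sum()) for c in four)[-2:]
        got = sorted(int(bits.sum()) for bits, _ in out)
        assert got == top

    def test_results_attached(self):
        rng = np.random.default_rng(2)
        a = rng.integers(0, 2, 10).astype(np.uint8)
        b = rng.integers(0, 2, 10).astype(np.uint8)
        for bits, res in hybrid_crossover(a, b, onemax, seed=1):
            assert res.fitness == onemax(bits).fitness


class TestRunGA:
    def _config(self, **kw):
        base = dict(population_size=20, max_generations=40,
                    init_gene_range=(1, 15), master_seed=0)
        base.update(kw)
        return GAConfig(**base)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_onemax_selection_pressure(self, seed):
        cfg = self._config(master_seed=seed)
        state = run_ga(30, onemax, cfg)
        initial_best = state.history[0]["best_fitness"]
        assert state.best_ever.result.fitness > initial_best
        mean_first = state.history[0]["mean_fitness"]
        mean_last = state.history[-1]["mean_fitness"]
        assert mean_last > mean_first

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_elitism_monotonicity(self, seed):
        state = run_ga(30, onemax, self._config(master_seed=seed))
        best = [h["best_ever_fitness"] for h in state.history]
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_population_size_constant_and_repaired(self):
        state = run_ga(30, onemax, self._config(max_generations=10))
        assert len(state.population) == 20
        for ind in state.population:
            assert ind.bits.sum() >= 1

    def test_zero_generations_returns_initial_best(self):
        cfg = self._config(max_generations=0)
        state = run_ga(30, onemax, cfg)
        assert state.generation == 0
        best = max(ind.result.fitness for ind in state.population)
        assert state.best_ever.result.fitness == best

    def test_target_fitness_stops_early(self):
        cfg = self._config(target_fitness=0.01, max_generations=40)
        state = run_ga(30, onemax, cfg)
        assert state.generation == 0  # initial population already satisfies it

    def test_determinism(self):
        cfg = self._config(max_generations=15)
        s1 = run_ga(30, onemax, cfg)
        s2 = run_ga(30, onemax, cfg)
        np.testing.assert_array_equal(s1.best_ever.bits, s2.best_ever.bits)
        assert s1.history == s2.history


class TestEvolve:
    def test_recovers_planted_genes(self, easy_synthetic):
        dataset, truth = easy_synthetic
        cfg = GAConfig(population_size=10, max_generations=6,
                       init_gene_range=(3, 15), master_seed=1)
        params = FitnessParams(n_splits=5)
        state = evolve(dataset, cfg, params)
        genes, result = best_solution(state, dataset.gene_ids)
        hits = len(set(genes) & set(truth.informative_gene_ids))
        assert hits / len(truth.informative_gene_ids) >= 0.6
        assert result.mean_accuracy >= 0.8

    def test_full_reproducibility(self, easy_synthetic):
        dataset, _ = easy_synthetic
        cfg = GAConfig(population_size=10, max_generations=3,
                       init_gene_range=(3, 10), master_seed=5)
        params = FitnessParams(n_splits=3)
        g1, r1 = best_solution(evolve(dataset, cfg, params), dataset.gene_ids)
        g2, r2 = best_solution(evolve(dataset, cfg, params), dataset.gene_ids)
        assert g1 == g2
        assert r1.per_split_accuracies == r2.per_split_accuracies

    def test_best_fitness_matches_its_own_record(self, easy_synthetic):
        from elmselect.fitness import parsimony_fitness
        dataset, _ = easy_synthetic
        params = FitnessParams(n_splits=3)
        cfg = GAConfig(population_size=10, max_generations=3,
                       init_gene_range=(3, 10), master_seed=2)
        state = evolve(dataset, cfg, params)
        res = state.best_ever.result
        assert res.fitness == parsimony_fitness(res.mean_accuracy, res.n_selected, params)
        assert res.mean_accuracy == pytest.approx(np.mean(res.per_split_accuracies))

    def test_cached_fitness_matches_recomputation(self, easy_synthetic):
        # chromosomes evaluated in generation g used seed (master_seed, g)
        dataset, _ = easy_synthetic
        params = FitnessParams(n_splits=3)
        cfg = GAConfig(population_size=10, max_generations=0,
                       init_gene_range=(3, 10), master_seed=9)
        state = evolve(dataset, cfg, params)
        ind = state.best_ever
        redo = evaluate_subset(dataset, ind.bits, params, seed=(9, 0))
        assert redo.per_split_accuracies == ind.result.per_split_accuracies


class TestBestSolution:
    def test_bit_to_id_mapping(self):
        bits = np.array([0, 1, 0, 1, 0], dtype=np.uint8)
        res = FitnessResult(mean_accuracy=0.9, n_selected=2, fitness=0.9)
        state = GAState(generation=0, population=[],
                        best_ever=Individual(bits=bits, result=res))
        genes, got = best_solution(state, ["g1", "g2", "g3", "g4", "g5"])
        assert genes == ["g2", "g4"]
        assert got is res
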