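"""Genetic-algorithm operators and driver: encoding, selection, variation, search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from qsaropt.ga import (
    GAConfig,
    crossover,
    decode,
    encode,
    init_population,
    mutate,
    roulette_select,
    run_ga,
)


class TestEncoding:
    def test_endpoint_genes(self):
        assert decode(np.zeros(20, dtype=np.uint8), 20) == pytest.approx(0.0)
        assert decode(np.ones(20, dtype=np.uint8), 20) == pytest.approx(1.0)

    def test_msb_gene_value(self):
        gene = np.zeros(20, dtype=np.uint8)
        gene[0] = 1
        assert decode(gene, 20) == pytest.approx(524288 / 1048575)

    def test_round_trip_within_quantization(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=30)
        back = decode(encode(x, 20), 20)
        assert np.abs(back - x).max() <= 2**-20

    def test_multi_gene_decode_shape(self):
        rng = np.random.default_rng(1)
        pop = rng.integers(0, 2, size=(7, 5 * 8), dtype=np.uint8)
        assert decode(pop, 8).shape == (7, 5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode(np.zeros(21, dtype=np.uint8), 20)
        with pytest.raises(ValueError):
            encode(np.array([0.5, 1.5]), 20)


class TestInitPopulation:
    def cfg(self, **kw):
        base = dict(population_size=30, generations=1, n_genes=4, bits_per_gene=8, seed=0)
        base.update(kw)
        return GAConfig(**base)

    def test_seeded_rows_recovered(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(np.random.default_rng(1).uniform(size=(30, 4)))
        pop = init_population(data, self.cfg(seeded_fraction=1.0), rng)
        decoded = decode(pop, 8)
        # every population member equals some data row to quantization error
        data_sorted = np.sort(data.to_numpy(), axis=0)
        dec_sorted = np.sort(decoded, axis=0)
        assert np.abs(dec_sorted - data_sorted).max() <= 2**-8

    def test_fraction_zero_is_fully_random(self):
        rng = np.random.default_rng(0)
        pop = init_population(None, self.cfg(seeded_fraction=0.0), rng)
        assert pop.shape == (30, 32)

    def test_partial_seeding_counts(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(np.full((10, 4), 0.5))
        pop = init_population(data, self.cfg(), rng)  # default: min(rows, pop)=10 seeded
        decoded = decode(pop, 8)
        seeded_like = np.isclose(decoded, 0.5, atol=2**-8).all(axis=1).sum()
        assert seeded_like >= 10

    def test_seeding_without_data_rejected(self):
        with pytest.raises(ValueError):
            init_population(None, self.cfg(seeded_fraction=0.5), np.random.default_rng(0))


class TestRoulette:
    def test_selection_frequencies_match_fitness_shares(self):
        rng = np.random.default_rng(0)
        picks = roulette_select(np.array([1.0, 3.0]), 100_000, rng)
        freq1 = (picks == 1).mean()
        assert abs(freq1 - 0.75) < 0.01

    def test_uniform_fallback_and_symmetry(self):
        rng = np.random.default_rng(0)
        picks = roulette_select(np.zeros(4), 40_000, rng)
        counts = np.bincount(picks, minlength=4) / 40_000
        assert np.abs(counts - 0.25).max() < 0.01

    def test_single_individual(self):
        picks = roulette_select(np.array([2.0]), 5, np.random.default_rng(0))
        assert (picks == 0).all()

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            roulette_select(np.array([1.0, -0.5]), 2, np.random.default_rng(0))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roulette_select(np.array([]), 1, np.random.default_rng(0))


class TestCrossover:
    def test_rate_zero_copies_parents(self):
        rng = np.random.default_rng(0)
        a = np.array([0, 1, 0, 1], dtype=np.uint8)
        b = np.array([1, 1, 0, 0], dtype=np.uint8)
        c1, c2 = crossover(a, b, 0.0, rng)
        np.testing.assert_array_equal(c1, a)
        np.testing.assert_array_equal(c2, b)
        assert c1 is not a  # copies, not views

    def test_rate_one_complementary_prefix_suffix(self):
        rng = np.random.default_rng(1)
        a, b = np.zeros(16, dtype=np.uint8), np.ones(16, dtype=np.uint8)
        c1, c2 = crossover(a, b, 1.0, rng)
        # children are 0...01...1 and 1...10...0 with one switch point each
        assert (np.diff(c1.astype(int)) != 0).sum() == 1
        assert (np.diff(c2.astype(int)) != 0).sum() == 1
        np.testing.assert_array_equal(c1 + c2, np.ones(16))

    def test_bit_multiset_conserved_for_all_cuts(self):
        rng = np.random.default_rng(2)
        a = np.array([0, 1, 1, 0, 1, 0, 0, 1], dtype=np.uint8)
        b = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=np.uint8)
        for _ in range(50):  # cut point varies with the rng draw
            c1, c2 = crossover(a, b, 1.0, rng)
            assert c1.sum() + c2.sum() == a.sum() + b.sum()

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            crossover(np.zeros(4, dtype=np.uint8), np.zeros(5, dtype=np.uint8), 1.0, np.random.default_rng(0))


class TestMutate:
    def test_rate_zero_identity(self):
        c = np.array([0, 1, 1, 0], dtype=np.uint8)
        np.testing.assert_array_equal(mutate(c, 0.0, np.random.default_rng(0)), c)

    def test_rate_one_complement(self):
        c = np.array([0, 1, 1, 0], dtype=np.uint8)
        np.testing.assert_array_equal(mutate(c, 1.0, np.random.default_rng(0)), 1 - c)

    def test_flip_count_in_binomial_band(self):
        """Rate 0.1 per bit: total flips over seeded draws sit in the 99% band."""
        c = np.zeros(10_000, dtype=np.uint8)
        flips = sum(int(mutate(c, 0.1, np.random.default_rng(s)).sum()) for s in range(10))
        # Binomial(100000, 0.1): 10000 +/- 2.576*sqrt(9000) -> [9756, 10244]
        assert 9756 <= flips <= 10244


class TestRunGA:
    def separable_cfg(self, seed=0, generations=50):
        return GAConfig(
            population_size=50,
            generations=generations,
            n_genes=3,
            bits_per_gene=4,
            crossover_rate=0.6,
            mutation_rate=0.1,
            seed=seed,
        )

    @staticmethod
    def sum_fitness(X):
        return X.sum(axis=1)

    def test_attains_exhaustive_optimum_on_toy_objective(self):
        """f(x)=sum(x) over 3 genes x 4 bits: GA matches the 4096-genotype max."""
        # independent oracle: enumerate every genotype
        levels = np.array(list(itertools.product(range(16), repeat=3))) / 15.0
        oracle_best = levels.sum(axis=1).max()
        assert oracle_best == pytest.approx(3.0)
        res = run_ga(self.sum_fitness, None, self.separable_cfg(seed=1))
        assert res.best_fitness == pytest.approx(oracle_best)

    def test_zero_generations_returns_initial_best(self):
        res = run_ga(self.sum_fitness, None, self.separable_cfg(seed=2, generations=0))
        assert res.trace == []
        assert 0.0 <= res.best_fitness <= 3.0

    def test_trace_monotone_with_elitism(self):
        res = run_ga(self.sum_fitness, None, self.separable_cfg(seed=3, generations=30))
        assert len(res.trace) == 30
        assert all(a <= b for a, b in zip(res.trace, res.trace[1:]))

    def test_population_size_constant_and_box_respected(self):
        seen = []

        def probe(X):
            seen.append(X.shape[0])
            assert (X >= 0).all() and (X <= 1).all()
            return X.sum(axis=1)

        run_ga(probe, None, self.separable_cfg(seed=4, generations=5))
        # first call scores the full population; later calls only fresh genotypes
        assert seen[0] == 50
        assert all(s <= 50 for s in seen)

    def test_reproducible_from_seed(self):
        r1 = run_ga(self.sum_fitness, None, self.separable_cfg(seed=5, generations=10))
        r2 = run_ga(self.sum_fitness, None, self.separable_cfg(seed=5, generations=10))
        assert r1.best_fitness == r2.best_fitness
        assert r1.trace == r2.trace
        np.testing.assert_array_equal(r1.best_vector, r2.best_vector)

    def test_non_finite_fitness_aborts(self):
        def bad(X):
            return np.full(X.shape[0], np.nan)

        with pytest.raises(FloatingPointError):
            run_ga(bad, None, self.separable_cfg(seed=6, generations=1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(crossover_rate=1.5).validate()
        with pytest.raises(ValueError):
            GAConfig(population_size=10, elite_count=10).validate()
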