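"""Integer-coded genetic algorithm: operators, cycle, reproducibility."""

import numpy as np
import pytest
from scipy.stats import chisquare

from isograd.errors import ConfigError
from isograd.ga import (
    Chromosome,
    GAConfig,
    _threshold_cycle,
    init_population,
    mutate_offspring,
    mutation_sweep,
    run_ga,
    uniform_crossover,
)


class TestInitPopulation:
    def test_seeded_reproducibility_and_bounds(self):
        cfg = GAConfig()
        a = init_population(cfg, np.random.default_rng(7))
        b = init_population(cfg, np.random.default_rng(7))
        assert len(a) == 100
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.genes, cb.genes)
            assert ca.genes.min() >= 5 and ca.genes.max() <= 95

    def test_gene_values_approximately_uniform(self):
        cfg = GAConfig(init_population=1000)
        pop = init_population(cfg, np.random.default_rng(3))
        values = np.concatenate([c.genes for c in pop])
        counts = np.bincount(values - 5, minlength=91)
        assert chisquare(counts).pvalue > 0.001


class TestCrossover:
    def test_identical_parents_give_identical_children(self):
        p = Chromosome(np.full(11, 42))
        c1, c2 = uniform_crossover(p, p, np.random.default_rng(0))
        assert np.array_equal(c1.genes, p.genes)
        assert np.array_equal(c2.genes, p.genes)

    def test_children_complementary_per_position(self):
        rng = np.random.default_rng(1)
        p1 = Chromosome(np.arange(11) + 10)
        p2 = Chromosome(np.arange(11) + 60)
        c1, c2 = uniform_crossover(p1, p2, rng)
        for j in range(11):
            assert {c1.genes[j], c2.genes[j]} == {p1.genes[j], p2.genes[j]}

    def test_inheritance_frequency_is_half(self):
        rng = np.random.default_rng(5)
        p1 = Chromosome(np.full(11, 10))
        p2 = Chromosome(np.full(11, 90))
        from_p1 = 0
        n = 10_000
        for _ in range(n):
            c1, _ = uniform_crossover(p1, p2, rng)
            from_p1 += int(np.sum(c1.genes == 10))
        assert from_p1 / (n * 11) == pytest.approx(0.5, abs=0.02)


class TestMutation:
    def _pool(self, value=0, n=30):
        # sentinel genes outside the redraw range [5, 95] make mutated
        # positions directly countable
        return [Chromosome(np.full(11, value)) for _ in range(n)]

    def test_zero_mutations_is_identity(self):
        pool = self._pool(50)
        out = mutate_offspring(pool, 0, np.random.default_rng(0))
        assert all(np.array_equal(a.genes, b.genes) for a, b in zip(pool, out))

    def test_exact_mutation_count(self):
        out = mutate_offspring(self._pool(0), 60, np.random.default_rng(2))
        changed = sum(int(np.sum(c.genes != 0)) for c in out)
        assert changed == 60

    def test_full_pool_mutation_touches_every_gene_once(self):
        """With n = pool size the output depends only on the generator."""
        out_a = mutate_offspring(self._pool(0), 330, np.random.default_rng(9))
        out_b = mutate_offspring(self._pool(1), 330, np.random.default_rng(9))
        genes_a = np.stack([c.genes for c in out_a])
        genes_b = np.stack([c.genes for c in out_b])
        assert np.array_equal(genes_a, genes_b)
        assert genes_a.min() >= 5

    def test_oversized_mutation_count_rejected(self):
        with pytest.raises(ConfigError):
            mutate_offspring(self._pool(0), 331, np.random.default_rng(0))


class TestThresholdCycle:
    @pytest.mark.parametrize(
        "history,expected",
        [
            ([5.0, 4.0, 4.0, 4.0], 2),
            ([5.0, 5.0, 5.0], 1),
            ([5.0, 4.0, 3.0, 2.0], 4),
            ([5.0, 4.0, 4.0, 3.5, 3.5], 4),
        ],
    )
    def test_first_cycle_after_improvement_vanishes(self, history, expected):
        assert _threshold_cycle(np.asarray(history), 1e-12) == expected


class TestRunGA:
    def _convex(self, genes):
        return np.sum((genes - 50.0) ** 2, axis=1).astype(float)

    def test_converges_on_integer_convex_function(self):
        """The search collapses the quadratic from ~10^4 to a few units:
        every gene lands within one integer step of the optimum (exact
        lattice polishing is slow because mutation redraws uniformly over
        the whole 5-95 range)."""
        cfg = GAConfig(n_mutations=60, n_cycles=200, seed=11)
        record = run_ga(None, cfg, objective=self._convex)
        assert np.all(np.abs(record.best.genes - 50) <= 1)
        assert record.best.cf <= 11.0

    def test_exact_optimum_on_plateaued_convex_function(self):
        """With a minimizer set the integer operators can hit, the GA
        reaches the exact optimum value."""

        def plateaued(genes):
            return np.sum(
                np.clip(np.abs(genes - 50.0) - 2.0, 0.0, None) ** 2, axis=1
            ).astype(float)

        cfg = GAConfig(n_mutations=60, n_cycles=200, seed=11)
        record = run_ga(None, cfg, objective=plateaued)
        assert record.best.cf == 0.0
        assert np.all(np.abs(record.best.genes - 50) <= 2)

    def test_history_non_increasing(self):
        cfg = GAConfig(n_mutations=60, n_cycles=50, seed=4)
        record = run_ga(None, cfg, objective=self._convex)
        assert np.all(np.diff(record.best_cf_history) <= 0)

    def test_steady_state_population_arithmetic(self):
        cfg = GAConfig()
        # 100 -> cull 70% -> 30 parents -> 30 offspring = 330 genes
        assert cfg.n_parents == 30
        assert cfg.n_parents * cfg.n_genes == 330

    def test_seeded_runs_are_bit_identical(self, sugar_cal):
        cfg = GAConfig(n_mutations=60, n_cycles=8, seed=123, dt=0.05)
        a = run_ga(sugar_cal, cfg)
        b = run_ga(sugar_cal, cfg)
        assert np.array_equal(a.best_cf_history, b.best_cf_history)
        assert np.array_equal(a.best.genes, b.best.genes)
        assert a.threshold_cycle == b.threshold_cycle

    def test_short_fixture_run_returns_acceptable_best(self, sugar_cal):
        cfg = GAConfig(n_mutations=60, n_cycles=15, seed=2, dt=0.05)
        record = run_ga(sugar_cal, cfg)
        assert record.scored is not None and record.scored.feasible
        assert record.scored.t_analysis <= 30.0
        assert min(record.scored.resolutions) >= 3.0
        assert record.threshold_cycle <= cfg.n_cycles


class TestMutationSweep:
    def test_single_count_single_run(self, sugar_cal):
        base = GAConfig(n_cycles=6, seed=5, dt=0.1)
        table = mutation_sweep(
            sugar_cal, base, mutation_counts=[30], runs_per_count=1
        )
        assert len(table) == 1
        assert table.loc[0, "n_mutations"] == 30
        assert table.loc[0, "median_threshold_cycle"] <= 6
        assert table.loc[0, "span"] == 0
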