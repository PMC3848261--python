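"""Integer-coded genetic algorithm over 11-gene gradient chromosomes.

A chromosome is the vector of integer eluent concentrations (mM) at the
eleven 3-min time nodes 0, 3, ..., 30 min.  The cycle follows an elitist
merge scheme:

* 100 random units are valued and the worst 70% removed, leaving 30
  parents (this initial cull happens once);
* each cycle the 30 parents are paired at random into 15 disjoint pairs
  and produce 30 offspring by uniform crossover (two parents - two
  descendants, complementary gene masks);
* a fixed number of gene positions across the whole offspring pool (330
  genes at steady state) is mutated — redrawn uniformly from the integer
  concentration range — positions chosen without replacement;
* offspring are valued, merged with the parents, and the worst 50% of the
  merged population removed, restoring 30 parents.

The best criterion value is recorded after every cycle for a fixed 200
cycles; the "threshold cycle" is the first cycle after which the best-CF
improvement stays below 1e-12 for the remainder of the run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegeneratePopulationError
from .gradient import DEFAULT_DT, DEFAULT_HORIZON, GradientProfile
from .objective import CFWeights, GradientScorer, ScoredProfile
from .objective import _PENALTY_BASE as _ACCEPTABLE_LIMIT
from .retention import CalibrationSet


@dataclass
class GAConfig:
    """Configuration of one genetic-algorithm run."""

    n_genes: int = 11
    gene_min: int = 5
    gene_max: int = 95
    init_population: int = 100
    elitism_cull: float = 0.70
    merge_cull: float = 0.50
    n_mutations: int = 60
    n_cycles: int = 200
    improvement_threshold: float = 1e-12
    seed: int = 0
    horizon: float = DEFAULT_HORIZON
    dt: float = DEFAULT_DT
    rs_threshold: float | None = 3.0  # overlap acceptability rule

    def __post_init__(self):
        if self.n_genes < 2:
            raise ConfigError("n_genes must be >= 2")
        for name in ("elitism_cull", "merge_cull"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.n_mutations < 0:
            raise ConfigError("n_mutations must be non-negative")

    @property
    def node_times(self) -> np.ndarray:
        return np.linspace(0.0, self.horizon, self.n_genes)

    @property
    def n_parents(self) -> int:
        return max(2, round(self.init_population * (1.0 - self.elitism_cull)))


@dataclass
class Chromosome:
    """One candidate gradient program: integer concentrations per time node."""

    genes: np.ndarray
    cf: float = math.inf

    def __post_init__(self):
        self.genes = np.asarray(self.genes, dtype=np.int64)

    def to_profile(
        self, horizon: float = DEFAULT_HORIZON, bounds=(5.0, 95.0)
    ) -> GradientProfile:
        node_times = np.linspace(0.0, horizon, self.genes.size)
        return GradientProfile(node_times, self.genes.astype(float), bounds)


@dataclass
class GARunRecord:
    """Per-cycle best-CF trace and the winning unit of one run."""

    best_cf_history: np.ndarray
    threshold_cycle: int
    best: Chromosome
    scored: ScoredProfile | None
    config: GAConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------

def init_population(config: GAConfig, rng: np.random.Generator) -> list[Chromosome]:
    """Random units with every gene uniform on the integer range [5, 95]."""
    genes = rng.integers(
        config.gene_min,
        config.gene_max + 1,
        size=(config.init_population, config.n_genes),
    )
    return [Chromosome(g) for g in genes]


def uniform_crossover(
    parent1: Chromosome, parent2: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Two parents - two descendants with complementary random gene masks."""
    if parent1.genes.size != parent2.genes.size:
        raise ConfigError("parents must have equal gene counts")
    mask = rng.integers(0, 2, size=parent1.genes.size).astype(bool)
    child1 = np.where(mask, parent1.genes, parent2.genes)
    child2 = np.where(mask, parent2.genes, parent1.genes)
    return Chromosome(child1), Chromosome(child2)


def mutate_offspring(
    offspring: Sequence[Chromosome],
    n_mutations: int,
    rng: np.random.Generator,
    gene_min: int = 5,
    gene_max: int = 95,
) -> list[Chromosome]:
    """Redraw ``n_mutations`` distinct gene positions across the whole pool.

    Positions are chosen uniformly without replacement over all genes of
    all offspring; each selected gene is reassigned a fresh uniform integer
    from the concentration range.
    """
    pool = np.stack([c.genes for c in offspring]).copy()
    total = pool.size
    if n_mutations > total:
        raise ConfigError(
            f"n_mutations={n_mutations} exceeds the offspring gene pool ({total})"
        )
    if n_mutations > 0:
        positions = rng.choice(total, size=n_mutations, replace=False)
        flat = pool.reshape(-1)
        flat[positions] = rng.integers(gene_min, gene_max + 1, size=n_mutations)
    return [Chromosome(g) for g in pool]


# ---------------------------------------------------------------------------
# the evolutionary cycle
# ---------------------------------------------------------------------------

def _threshold_cycle(history: np.ndarray, threshold: float) -> int:
    """First cycle after which the best-CF improvement stays below threshold.

    Cycles are 1-based; a run that still improves at the end reports the
    final cycle.
    """
    diffs = np.abs(np.diff(history))
    big = np.flatnonzero(diffs >= threshold)
    if big.size == 0:
        return 1
    return min(int(big[-1]) + 2, history.size)


def run_ga(
    calibration: CalibrationSet,
    config: GAConfig,
    weights: CFWeights | None = None,
    objective: Callable[[np.ndarray], np.ndarray] | None = None,
) -> GARunRecord:
    """Run the full genetic cycle and return the record of the best unit.

    ``objective`` may replace the chromatographic criterion by a function
    mapping a (P, n_genes) gene matrix to P values (used for convergence
    checks on test functions).
    """
    weights = weights or CFWeights()
    rng = np.random.default_rng(config.seed)
    bounds = (float(config.gene_min), float(config.gene_max))

    if objective is None:
        scorer = GradientScorer(
            calibration,
            weights,
            horizon=config.horizon,
            dt=config.dt,
            bounds=bounds,
            rs_threshold=config.rs_threshold,
        )
        node_times = config.node_times

        def evaluate(genes: np.ndarray) -> np.ndarray:
            # penalized valuation: CF for acceptable units, graded penalty
            # (always behind every acceptable unit) for excluded ones
            return scorer.score_batch(node_times, genes.astype(float)).penalized

    else:
        scorer = None
        evaluate = objective

    population = init_population(config, rng)
    genes = np.stack([c.genes for c in population])
    cf = np.asarray(evaluate(genes), dtype=float)

    # initial elitist cull: keep the best (1 - elitism_cull) fraction once
    keep = config.n_parents
    order = np.argsort(cf, kind="stable")
    parents, parents_cf = genes[order[:keep]], cf[order[:keep]]
    if not np.any(np.isfinite(parents_cf)):
        raise DegeneratePopulationError(
            "entire population is infeasible after the initial cull"
        )
    if scorer is not None and not np.any(parents_cf < _ACCEPTABLE_LIMIT):
        raise DegeneratePopulationError(
            "no acceptable unit (feasible, well separated) after the initial cull"
        )

    n_parents = parents.shape[0]
    history = np.empty(config.n_cycles)
    for cycle in range(config.n_cycles):
        pairing = rng.permutation(n_parents)
        offspring: list[Chromosome] = []
        for i in range(0, n_parents - 1, 2):
            p1 = Chromosome(parents[pairing[i]])
            p2 = Chromosome(parents[pairing[i + 1]])
            offspring.extend(uniform_crossover(p1, p2, rng))
        offspring = mutate_offspring(
            offspring, config.n_mutations, rng, config.gene_min, config.gene_max
        )
        off_genes = np.stack([c.genes for c in offspring])
        off_cf = np.asarray(evaluate(off_genes), dtype=float)

        merged = np.concatenate([parents, off_genes])
        merged_cf = np.concatenate([parents_cf, off_cf])
        order = np.argsort(merged_cf, kind="stable")
        keep = max(2, merged.shape[0] - int(round(merged.shape[0] * config.merge_cull)))
        parents, parents_cf = merged[order[:keep]], merged_cf[order[:keep]]
        n_parents = parents.shape[0]
        history[cycle] = parents_cf[0]

    best = Chromosome(parents[0], float(parents_cf[0]))
    scored = None
    if scorer is not None:
        if best.cf >= _ACCEPTABLE_LIMIT:
            raise DegeneratePopulationError(
                "the run terminated without any acceptable unit"
            )
        scored = scorer.score(best.to_profile(config.horizon, bounds))
    return GARunRecord(
        best_cf_history=history,
        threshold_cycle=_threshold_cycle(history, config.improvement_threshold),
        best=best,
        scored=scored,
        config=config,
    )


def mutation_sweep(
    calibration: CalibrationSet,
    base: GAConfig,
    weights: CFWeights | None = None,
    mutation_counts: Sequence[int] = tuple(range(5, 115, 5)),
    runs_per_count: int = 10,
) -> pd.DataFrame:
    """Median and span of the threshold cycle across seeded repeat runs.

    For each mutation count, ``runs_per_count`` independent runs (seeds
    derived deterministically from ``base.seed``) are performed and the
    distribution of their threshold cycles summarized.
    """
    seed_rng = np.random.default_rng(base.seed)
    rows = []
    for count in mutation_counts:
        cycles = []
        for _ in range(runs_per_count):
            seed = int(seed_rng.integers(0, 2**31 - 1))
            cfg = replace(base, n_mutations=int(count), seed=seed)
            cycles.append(run_ga(calibration, cfg, weights).threshold_cycle)
        rows.append(
            {
                "n_mutations": int(count),
                "median_threshold_cycle": float(np.median(cycles)),
                "min_threshold_cycle": int(min(cycles)),
                "max_threshold_cycle": int(max(cycles)),
                "span": int(max(cycles) - min(cycles)),
            }
        )
    return pd.DataFrame(rows)
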