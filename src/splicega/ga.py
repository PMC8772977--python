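"""Genetic operators and the memetic evolution loop.

The search evolves a population of binary feature-subset individuals with
roulette-wheel selection on inverse fitness (fitness is an error, lower is
better), uniform crossover, and elitism.  In the memetic mode the mutation
operator is *replaced* by the capped splicing local search
(:func:`splicega.splicing.improved_splice`), which also improves every
initial individual before the first evaluation; an ablation mode restores
plain bit-flip mutation (and no splicing) so the two designs can be
compared under identical budgets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from ._exceptions import ConfigError
from .individual import Individual
from .splicing import SplicingConfig, improved_splice

logger = logging.getLogger(__name__)

_FITNESS_FLOOR = 1e-12


def init_individual(q: int, p_initial: float, rng: np.random.Generator) -> Individual:
    """Draw a random individual with i.i.d. Bernoulli(p_initial) bits.

    ``p_initial = s/q`` yields an expected subset size of ``s``.
    """
    if not 0.0 <= p_initial <= 1.0:
        raise ConfigError("p_initial must lie in [0, 1]")
    bits = (rng.random(q) < p_initial).astype(np.int8)
    return Individual(bits)


def survival_probabilities(fitnesses: np.ndarray) -> np.ndarray:
    """Inverse-fitness survival probabilities P_i = (1/F_i) / sum_j 1/F_j.

    Fitness is an error measure, so a smaller F_i earns a larger share of
    the roulette wheel.
    """
    F = np.asarray(fitnesses, dtype=float)
    if F.size == 0:
        raise ConfigError("empty fitness vector")
    if np.any(F <= 0) or not np.all(np.isfinite(F)):
        raise ConfigError("all fitness values must be positive and finite")
    inv = 1.0 / F
    return inv / inv.sum()


def roulette_select(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Sample an index with the given selection probabilities."""
    probs = np.asarray(probs, dtype=float)
    cum = np.cumsum(probs)
    if not np.isclose(cum[-1], 1.0):
        raise ConfigError("probabilities must sum to 1")
    return int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))


def uniform_crossover(
    parent1: Individual,
    parent2: Individual,
    p0: float,
    rng: np.random.Generator,
) -> tuple[Individual, Individual]:
    """Uniform crossover with disruption probability p0.

    At each position, with probability ``p0`` offspring 1 keeps parent 1's
    bit (and offspring 2 parent 2's); otherwise the bits are exchanged.
    Positions where the parents agree are identical in both offspring, so
    features common to both parents are always preserved.
    """
    if parent1.q != parent2.q:
        raise ConfigError("parents must have equal length")
    keep = rng.random(parent1.q) < p0
    o1 = np.where(keep, parent1.bits, parent2.bits)
    o2 = np.where(keep, parent2.bits, parent1.bits)
    return Individual(o1), Individual(o2)


def bitflip_mutation(
    individual: Individual, rate: float, rng: np.random.Generator
) -> Individual:
    """Independent per-bit flip with the given rate (ablation mode only)."""
    flips = rng.random(individual.q) < rate
    return Individual(np.where(flips, 1 - individual.bits, individual.bits))


@dataclass
class GAConfig:
    """Evolution hyper-parameters.

    Defaults follow the published configuration for the sheep body-weight
    study: population ``N = 20``, ``T = 30`` generations, expected initial
    subset size ``s = 2000``, early stop after 5 stalled generations.
    """

    pop_size: int = 20
    max_generations: int = 30
    crossover_p0: float = 0.5
    init_size: int = 2000
    stall_limit: int = 5
    seed: int = 0
    splicing: SplicingConfig = field(default_factory=lambda: SplicingConfig(s_max=30))
    ablation_ga: bool = False
    mutation_rate: float | None = None  # default 1/q in ablation mode

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ConfigError("pop_size must be >= 2")
        if self.max_generations < 1:
            raise ConfigError("max_generations must be >= 1")
        if not 0.0 <= self.crossover_p0 <= 1.0:
            raise ConfigError("crossover_p0 must lie in [0, 1]")
        if self.init_size < 1:
            raise ConfigError("init_size must be >= 1")
        if self.stall_limit < 1:
            raise ConfigError("stall_limit must be >= 1")


@dataclass
class GenerationStats:
    generation: int
    mean_fitness: float
    min_fitness: float
    best_size: int


@dataclass
class RunReport:
    """Full account of one evolution run, sufficient to reproduce it."""

    config: GAConfig
    seed: int
    mode: str
    generations: list[GenerationStats]
    best: Individual
    best_fitness: float
    selected_indices: list[int]
    selected_ids: list[str] | None
    stopped_by: str
    final_population: list[Individual] = field(default_factory=list)

    @property
    def min_fitness_trace(self) -> list[float]:
        return [g.min_fitness for g in self.generations]

    @property
    def mean_fitness_trace(self) -> list[float]:
        return [g.mean_fitness for g in self.generations]

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "seed": self.seed,
            "mode": self.mode,
            "stopped_by": self.stopped_by,
            "best_fitness": self.best_fitness,
            "selected_indices": list(map(int, self.selected_indices)),
            "selected_ids": self.selected_ids,
            "generations": [asdict(g) for g in self.generations],
            "config": {
                "pop_size": self.config.pop_size,
                "max_generations": self.config.max_generations,
                "crossover_p0": self.config.crossover_p0,
                "init_size": self.config.init_size,
                "stall_limit": self.config.stall_limit,
                "s_max": self.config.splicing.s_max,
                "tau_const": self.config.splicing.tau_const,
                "standardize": self.config.splicing.standardize,
                "ablation_ga": self.config.ablation_ga,
            },
        }


def evolve(
    X: np.ndarray,
    Y: np.ndarray,
    config: GAConfig,
    fitness_fn: Callable[[Individual], float],
    feature_ids: list[str] | None = None,
) -> RunReport:
    """Run the memetic (or ablation GA) feature-selection loop.

    Each generation copies the best individual unchanged (elitism), then
    fills the population with offspring of roulette-selected parents via
    uniform crossover; offspring are improved by splicing (memetic mode) or
    perturbed by bit-flip mutation (ablation mode).  Stops at
    ``max_generations`` or when the best fitness has not improved for
    ``stall_limit`` consecutive generations.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    n, q = X.shape
    rng = np.random.default_rng(config.seed)
    p_initial = min(1.0, config.init_size / q)
    mode = "ablation-ga" if config.ablation_ga else "memetic"
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / q

    cache: dict[bytes, float] = {}

    def evaluate(ind: Individual) -> float:
        key = ind.key()
        if key not in cache:
            try:
                value = float(fitness_fn(ind))
            except Exception:
                logger.error(
                    "fitness evaluation failed for individual with |A|=%d", ind.size
                )
                raise
            cache[key] = max(value, _FITNESS_FLOOR)
        ind.fitness = cache[key]
        return ind.fitness

    def refine(ind: Individual) -> Individual:
        if config.ablation_ga:
            return bitflip_mutation(ind, mut_rate, rng)
        return improved_splice(ind, X, Y, config.splicing)

    population = [init_individual(q, p_initial, rng) for _ in range(config.pop_size)]
    if not config.ablation_ga:
        population = [improved_splice(ind, X, Y, config.splicing) for ind in population]
    fitnesses = np.array([evaluate(ind) for ind in population])

    stats: list[GenerationStats] = []
    best_idx = int(np.argmin(fitnesses))
    best = population[best_idx].copy()
    best_fitness = float(fitnesses[best_idx])
    stall = 0
    stopped_by = "max_generations"

    def record(gen: int) -> None:
        stats.append(
            GenerationStats(
                generation=gen,
                mean_fitness=float(np.mean(fitnesses)),
                min_fitness=best_fitness,
                best_size=best.size,
            )
        )
        logger.info(
            "gen=%d mean=%.6g min=%.6g best|A|=%d",
            gen,
            stats[-1].mean_fitness,
            best_fitness,
            best.size,
        )

    record(0)
    for gen in range(1, config.max_generations + 1):
        probs = survival_probabilities(fitnesses)
        new_pop: list[Individual] = [best.copy()]
        while len(new_pop) < config.pop_size:
            i = roulette_select(probs, rng)
            j = roulette_select(probs, rng)
            o1, o2 = uniform_crossover(population[i], population[j], config.crossover_p0, rng)
            new_pop.extend(refine(o) for o in (o1, o2))
        population = new_pop[: config.pop_size]
        fitnesses = np.array([evaluate(ind) for ind in population])
        gen_best = int(np.argmin(fitnesses))
        if fitnesses[gen_best] < best_fitness:
            best = population[gen_best].copy()
            best_fitness = float(fitnesses[gen_best])
            stall = 0
        else:
            stall += 1
        record(gen)
        if stall >= config.stall_limit:
            stopped_by = "stall"
            break

    selected = best.active.tolist()
    return RunReport(
        config=config,
        seed=config.seed,
        mode=mode,
        generations=stats,
        best=best,
        best_fitness=best_fitness,
        selected_indices=selected,
        selected_ids=[feature_ids[i] for i in selected] if feature_ids else None,
        stopped_by=stopped_by,
        final_population=population,
    )
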