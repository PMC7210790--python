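"""Genetic algorithm for siting a fixed-size drone base network.

A *gene* is one candidate base, a *chromosome* is a set of exactly ``k``
distinct bases (a drone base network), and fitness is the mean response
time of the incident set under that network — lower is fitter.  Each
generation: all chromosomes are scored, the fittest ``elite_count`` pass
through unchanged, consecutive pairs in descending order of fitness are
crossed over (uniform random k-subset of the parent union), children
mutate with probability 10% (one gene swapped for a random outside
candidate), and fresh random chromosomes refill the population to its
fixed size.

:func:`brute_force_best` enumerates every k-subset and is the validation
oracle for the heuristic on small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .response import ResponseEvaluator

__all__ = [
    "Chromosome",
    "GAConfig",
    "init_population",
    "crossover",
    "mutate",
    "evolve",
    "brute_force_best",
]


@dataclass(frozen=True)
class Chromosome:
    """An immutable drone base network with (optionally) cached fitness."""

    base_ids: frozenset[str]
    fitness_min: float | None = None

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.base_ids))

    def with_fitness(self, f: float) -> "Chromosome":
        return Chromosome(self.base_ids, f)


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 50
    generations: int = 100
    mutation_rate: float = 0.10
    elite_count: int = 2
    k: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < self.elite_count + 2:
            raise ValueError("population_size must be >= elite_count + 2")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


def _random_chromosome(candidates: Sequence[str], k: int, rng: np.random.Generator) -> Chromosome:
    idx = rng.choice(len(candidates), size=k, replace=False)
    return Chromosome(frozenset(candidates[i] for i in idx))


def init_population(
    candidates: Sequence[str], cfg: GAConfig, rng: np.random.Generator
) -> list[Chromosome]:
    """Uniform random k-subsets, ``population_size`` of them."""
    if cfg.k > len(candidates):
        raise ValueError(f"k={cfg.k} exceeds the {len(candidates)} candidates")
    return [_random_chromosome(candidates, cfg.k, rng) for _ in range(cfg.population_size)]


def crossover(a: Chromosome, b: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Child = uniform random k-subset of the parents' union.

    Unbiased between parents and closed over set semantics: the child
    always has exactly k distinct genes.  Identical parents reproduce
    themselves exactly.
    """
    if len(a.base_ids) != len(b.base_ids):
        raise ValueError("parents must have the same k")
    k = len(a.base_ids)
    union = sorted(a.base_ids | b.base_ids)
    if len(union) <= k:
        return Chromosome(frozenset(union))
    idx = rng.choice(len(union), size=k, replace=False)
    return Chromosome(frozenset(union[i] for i in idx))


def mutate(
    c: Chromosome, candidates: Sequence[str], rate: float, rng: np.random.Generator
) -> Chromosome:
    """With probability ``rate``, swap one random gene for a random
    candidate not in the chromosome; otherwise return ``c`` unchanged."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rng.random() >= rate:
        return c
    outside = sorted(set(candidates) - c.base_ids)
    if not outside:  # chromosome already holds every candidate
        return c
    genes = sorted(c.base_ids)
    drop = genes[int(rng.integers(len(genes)))]
    add = outside[int(rng.integers(len(outside)))]
    return Chromosome(frozenset(g for g in genes if g != drop) | {add})


def _make_fitness(evaluator: ResponseEvaluator) -> Callable[[Chromosome], float]:
    cache: dict[tuple[str, ...], float] = {}

    def fitness(c: Chromosome) -> float:
        key = c.key
        if key not in cache:
            cache[key] = evaluator.mean_response(key)
        return cache[key]

    return fitness


def evolve(
    evaluator: ResponseEvaluator,
    cfg: GAConfig,
    candidates: Sequence[str] | None = None,
) -> tuple[Chromosome, list[dict]]:
    """Run the GA; returns the best-ever chromosome and a per-generation
    history of ``{"generation", "best_fitness_min", "mean_fitness_min"}``.

    Elitism guarantees the best-ever fitness is non-increasing across
    generations.  Fully deterministic under ``cfg.seed``.
    """
    candidates = sorted(candidates if candidates is not None else evaluator.base_ids)
    rng = np.random.default_rng(cfg.seed)
    fitness = _make_fitness(evaluator)
    population = init_population(candidates, cfg, rng)

    best: Chromosome | None = None
    history: list[dict] = []
    for gen in range(cfg.generations):
        scored = sorted(
            (c.with_fitness(fitness(c)) for c in population),
            key=lambda c: (c.fitness_min, c.key),
        )
        if best is None or scored[0].fitness_min < best.fitness_min:
            best = scored[0]
        history.append(
            {
                "generation": gen,
                "best_fitness_min": best.fitness_min,
                "mean_fitness_min": float(np.mean([c.fitness_min for c in scored])),
            }
        )
        if gen == cfg.generations - 1:
            break
        # elites pass through; consecutive pairs (fittest first) cross over
        next_pop: list[Chromosome] = list(scored[: cfg.elite_count])
        for i in range(0, len(scored) - 1, 2):
            if len(next_pop) >= cfg.population_size:
                break
            child = crossover(scored[i], scored[i + 1], rng)
            child = mutate(child, candidates, cfg.mutation_rate, rng)
            next_pop.append(child)
        # random refill keeps the population size constant
        while len(next_pop) < cfg.population_size:
            next_pop.append(_random_chromosome(candidates, cfg.k, rng))
        population = next_pop

    assert best is not None
    return best, history


def brute_force_best(
    evaluator: ResponseEvaluator,
    k: int,
    candidates: Sequence[str] | None = None,
    max_combinations: int = 20_000,
) -> tuple[tuple[str, ...], float]:
    """Exhaustive search over all k-subsets; the GA's validation oracle.

    Refuses instances with more than ``max_combinations`` subsets.  Ties
    are broken lexicographically on the sorted base-id tuple.
    """
    candidates = sorted(candidates if candidates is not None else evaluator.base_ids)
    n = len(candidates)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in 1..{n}")
    from math import comb

    if comb(n, k) > max_combinations:
        raise ValueError(f"C({n},{k}) = {comb(n, k)} exceeds the cap {max_combinations}")
    best_set: tuple[str, ...] | None = None
    best_fit = np.inf
    for subset in itertools.combinations(candidates, k):
        f = evaluator.mean_response(subset)
        if f < best_fit or (f == best_fit and (best_set is None or subset < best_set)):
            best_set, best_fit = subset, f
    return best_set, float(best_fit)
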