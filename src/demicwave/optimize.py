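"""Genetic-algorithm search of the demographic parameter space.

A genome is one candidate parameter set for the simulator (growth rate
is fixed and is not a gene). The GA keeps a population of 100 genomes;
each generation the 40 fittest reproduce (single-point crossover with
probability 0.8, per-gene mutation with probability 0.2) and the 5 best
are copied unchanged, for 20 generations.

The leap-distance gene is special: expansion either does not leapfrog
at all (0) or leaps 150–250 km, so initialization and mutation draw 0
with probability ½ and otherwise a uniform distance.

Because the simulator is stochastic, a genome's fitness is a single-run
draw; identical genomes are deliberately re-evaluated rather than
cached, so selection sees fresh noise each generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from demicwave.abm import Params

__all__ = [
    "GENE_ORDER",
    "Genome",
    "GAConfig",
    "ParamRanges",
    "random_genome",
    "crossover",
    "mutate",
    "evolve",
]

#: Fixed gene order used by single-point crossover.
GENE_ORDER = ("k_star", "catchment_km", "fission_threshold", "leap_km", "permanence")


@dataclass(frozen=True)
class Genome:
    k_star: float
    catchment_km: float
    fission_threshold: float
    leap_km: float
    permanence: float
    fitness: float | None = None

    def to_params(self, a: float = 0.025) -> Params:
        return Params(
            k_star=self.k_star,
            catchment_km=self.catchment_km,
            fission_threshold=self.fission_threshold,
            leap_km=self.leap_km,
            permanence=self.permanence,
            a=a,
        )

    def genes(self) -> tuple[float, ...]:
        return tuple(getattr(self, g) for g in GENE_ORDER)


@dataclass(frozen=True)
class ParamRanges:
    """Uniform initialization ranges; a degenerate (lo == hi) range pins a gene.

    Pinning ``catchment_km`` (e.g. ``(20, 20)``) reproduces the
    fixed-catchment runs used to probe equifinality between catchment
    area and maximum density.
    """

    k_star: tuple[float, float] = (20.0, 100.0)
    catchment_km: tuple[float, float] = (10.0, 30.0)
    fission_threshold: tuple[float, float] = (50.0, 300.0)
    leap_km: tuple[float, float] = (150.0, 250.0)  # or 0, drawn with prob 1/2
    permanence: tuple[float, float] = (10.0, 30.0)
    p_leap_zero: float = 0.5

    def fix_catchment(self, value: float) -> "ParamRanges":
        return replace(self, catchment_km=(value, value))


@dataclass(frozen=True)
class GAConfig:
    pop_size: int = 100
    n_parents: int = 40
    p_crossover: float = 0.8
    p_mutation: float = 0.2
    n_elite: int = 5
    generations: int = 20

    def __post_init__(self) -> None:
        if not self.n_elite <= self.n_parents <= self.pop_size:
            raise ValueError("need n_elite <= n_parents <= pop_size")


def _draw_gene(name: str, ranges: ParamRanges, rng: np.random.Generator) -> float:
    lo, hi = getattr(ranges, name)
    if name == "leap_km" and rng.random() < ranges.p_leap_zero:
        return 0.0
    return float(rng.uniform(lo, hi))


def random_genome(ranges: ParamRanges, rng: np.random.Generator) -> Genome:
    """Uniform draw per gene within its range (leap: 0 with prob ½)."""
    return Genome(**{g: _draw_gene(g, ranges, rng) for g in GENE_ORDER})


def crossover(
    p1: Genome, p2: Genome, rng: np.random.Generator, p: float = 0.8
) -> Genome:
    """Single-point crossover with probability ``p``; else a copy of ``p1``.

    The cut point falls strictly inside the fixed gene order, so each
    parent contributes at least one gene.
    """
    if rng.random() >= p:
        return replace(p1, fitness=None)
    cut = int(rng.integers(1, len(GENE_ORDER)))
    g1, g2 = p1.genes(), p2.genes()
    genes = g1[:cut] + g2[cut:]
    return Genome(**dict(zip(GENE_ORDER, genes)))


def mutate(
    g: Genome, ranges: ParamRanges, rng: np.random.Generator, p: float = 0.2
) -> Genome:
    """Independently redraw each gene with probability ``p``."""
    genes = {}
    mutated = False
    for name, val in zip(GENE_ORDER, g.genes()):
        if rng.random() < p:
            genes[name] = _draw_gene(name, ranges, rng)
            mutated = True
        else:
            genes[name] = val
    return Genome(**genes) if mutated else g


def evolve(
    fitness_fn: Callable[[Genome], float],
    config: GAConfig = GAConfig(),
    ranges: ParamRanges = ParamRanges(),
    seed: int | np.random.Generator = 0,
) -> tuple[Genome, list[tuple[float, float]]]:
    """Run the GA; returns the best-ever genome and per-generation history.

    History entries are ``(mean_fitness, max_fitness)`` of each
    generation's evaluated population. Elitism makes the best-ever
    fitness non-decreasing. Parents pair uniformly at random with
    replacement among the selected top fraction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    population = [random_genome(ranges, rng) for _ in range(config.pop_size)]
    best: Genome | None = None
    history: list[tuple[float, float]] = []

    for _ in range(config.generations):
        scored = [replace(g, fitness=float(fitness_fn(g))) for g in population]
        scored.sort(key=lambda g: g.fitness, reverse=True)
        history.append(
            (float(np.mean([g.fitness for g in scored])), float(scored[0].fitness))
        )
        if best is None or scored[0].fitness > best.fitness:
            best = scored[0]
        parents = scored[: config.n_parents]
        next_pop: list[Genome] = [
            replace(g, fitness=None) for g in scored[: config.n_elite]
        ]
        while len(next_pop) < config.pop_size:
            i, j = rng.integers(config.n_parents, size=2)
            child = crossover(parents[i], parents[j], rng, config.p_crossover)
            child = mutate(child, ranges, rng, config.p_mutation)
            next_pop.append(child)
        population = next_pop

    return best, history
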