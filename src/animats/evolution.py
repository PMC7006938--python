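"""Asexual genetic algorithm over genomes.

Each generation every genome is scored by :func:`animats.engine.score_genome`
(mean over independently seeded trials of one random clone's fitness),
parents are drawn by fitness-proportional (roulette) selection on shifted
fitness ``f - min(f) + eps`` (scores can be negative because of collision
penalties), and each offspring arises from a single parent by mutation.
There is no crossover. Every random draw is derived from the master seed
through named seed streams, so a whole lineage — or any single genome
evaluation — is replayable in isolation.

Seed derivation (``spawn_key`` of a ``numpy.random.SeedSequence`` rooted at
the master seed): ``(0, i)`` initializes genome ``i``; ``(1, g, i)``
evaluates genome ``i`` in generation ``g``; ``(2, g)`` drives selection;
``(3, g, i)`` mutates offspring ``i``. Generators use the MT19937 bit
generator throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .brain import ArchitectureSpec
from .engine import GROUP_SIZES, EvalSetup, InteractionRules, score_genome
from .genome import Genome, MutationParams, mutate, random_genome
from .world import GridWorld

__all__ = ["EvolutionConfig", "Lineage", "evolve", "select_parents"]

logger = logging.getLogger(__name__)


def _rng(master: int, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return np.random.Generator(np.random.MT19937(ss))


@dataclass(frozen=True)
class EvolutionConfig:
    """A fully resolved evolutionary setup.

    ``group_size`` is an animat count or ``"random"`` (drawn per trial
    from ``group_size_vector``). The defaults mirror the published
    campaign scale (population 100, 10,000 generations, 30 trials per
    genome); scaled-down runs simply override them.
    """

    world: GridWorld
    arch: ArchitectureSpec
    rules: InteractionRules = InteractionRules()
    group_size: int | str = 36
    population_size: int = 100
    generations: int = 10_000
    trials_per_genome: int = 30
    T: int = 500
    reward_cap: int = 4
    mutation: MutationParams = MutationParams()
    initial_genome_length: int = 5_000
    seed_gates: bool = True
    n_seeded_gates: int = 8
    selection: str = "roulette"
    tournament_k: int = 2
    epsilon: float = 1e-6
    elitism: int = 0
    master_seed: int = 0
    group_size_vector: tuple[int, ...] = GROUP_SIZES
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.selection not in ("roulette", "tournament"):
            raise ValueError(f"unknown selection scheme {self.selection!r}")

    def eval_setup(self) -> EvalSetup:
        return EvalSetup(
            arch=self.arch,
            rules=self.rules,
            trials=self.trials_per_genome,
            group_size=self.group_size,
            group_size_vector=self.group_size_vector,
            T=self.T,
            reward_cap=self.reward_cap,
        )


@dataclass
class Lineage:
    """Per-generation statistics plus final material of one evolution run."""

    label: str
    master_seed: int
    mean_fitness: np.ndarray           # (generations,)
    best_fitness: np.ndarray           # (generations,)
    best_genomes: list[Genome]         # best genome of each generation
    final_population: list[Genome]
    final_fitness: np.ndarray          # fitness of the final population

    @property
    def generations(self) -> int:
        return int(self.mean_fitness.size)

    @property
    def evolved_fitness(self) -> float:
        """Fitness of the final generation's best group."""
        return float(self.best_fitness[-1])

    @property
    def best_genome(self) -> Genome:
        return self.best_genomes[-1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": np.arange(self.generations),
                "mean_fitness": self.mean_fitness,
                "best_fitness": self.best_fitness,
            }
        )


def select_parents(
    fitnesses: np.ndarray,
    population_size: int,
    rng: np.random.Generator,
    *,
    scheme: str = "roulette",
    epsilon: float = 1e-6,
    tournament_k: int = 2,
) -> np.ndarray:
    """Draw ``population_size`` parent indices with replacement.

    Roulette weights are ``f - min(f) + epsilon``; the shift accommodates
    negative scores and the epsilon keeps an all-equal population
    samplable (uniformly). Tournament selection picks the best of
    ``tournament_k`` uniform draws per slot.
    """
    f = np.asarray(fitnesses, dtype=np.float64)
    if not np.all(np.isfinite(f)):
        raise ValueError("fitnesses must be finite")
    n = f.size
    if scheme == "roulette":
        w = f - f.min() + epsilon
        total = w.sum()
        if total <= 0:
            p = np.full(n, 1.0 / n)
        else:
            p = w / total
        return rng.choice(n, size=population_size, replace=True, p=p)
    if scheme == "tournament":
        draws = rng.integers(0, n, size=(population_size, tournament_k))
        return draws[np.arange(population_size), np.argmax(f[draws], axis=1)]
    raise ValueError(f"unknown selection scheme {scheme!r}")


def evolve(config: EvolutionConfig, progress: bool = False) -> Lineage:
    """Run the genetic algorithm and record lineage statistics.

    Generation 0 is drawn by :func:`animats.genome.random_genome`; every
    later generation is produced by selection plus single-parent mutation.
    Identical configs (including ``master_seed``) yield identical
    lineages.
    """
    P = config.population_size
    setup = config.eval_setup()
    master = config.master_seed
    population = [
        random_genome(
            config.initial_genome_length,
            _rng(master, 0, i),
            seed_gates=config.seed_gates,
            n_seeded_gates=config.n_seeded_gates,
        )
        for i in range(P)
    ]
    mean_f = np.empty(config.generations)
    best_f = np.empty(config.generations)
    best_genomes: list[Genome] = []
    fitness = np.empty(P)
    for g in range(config.generations):
        for i in range(P):
            fitness[i] = score_genome(
                config.world, population[i], setup, _rng(master, 1, g, i)
            )
        mean_f[g] = fitness.mean()
        best_idx = int(np.argmax(fitness))
        best_f[g] = fitness[best_idx]
        best_genomes.append(population[best_idx])
        if progress or logger.isEnabledFor(logging.INFO):
            logger.info(
                "gen %d: mean F = %.4f, best F = %.4f", g, mean_f[g], best_f[g]
            )
        if g == config.generations - 1:
            break
        parents = select_parents(
            fitness,
            P - config.elitism,
            _rng(master, 2, g),
            scheme=config.selection,
            epsilon=config.epsilon,
            tournament_k=config.tournament_k,
        )
        next_pop = [
            mutate(population[p], config.mutation, _rng(master, 3, g, i))
            for i, p in enumerate(parents)
        ]
        if config.elitism:
            elite = np.argsort(fitness)[::-1][: config.elitism]
            next_pop.extend(population[int(e)] for e in elite)
        population = next_pop
    return Lineage(
        label=config.label,
        master_seed=master,
        mean_fitness=mean_f,
        best_fitness=best_f,
        best_genomes=best_genomes,
        final_population=population,
        final_fitness=fitness.copy(),
    )
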