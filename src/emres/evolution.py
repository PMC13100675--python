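"""Microbial genetic algorithm over discrete reservoir hyperparameter grids.

A population of reservoir computers (individuals) is evolved by steady-state
pairwise tournaments: two distinct individuals are drawn at random, their
fitness compared, and the loser's genotype is (a) mutated — each gene has a
20% chance of shifting one grid position up or down — and then (b) partially
infected by the winner — each gene is overwritten by the winner's value with
probability 0.2.  The winner is never modified, so the best-so-far fitness
is non-decreasing under a fixed evaluation.

Fitness objectives: negative mean loss (``neg_loss``), mean psi (``psi``),
P(S) (``ps``), P(E) (``pe``), or the convex blend kappa*P(S)+(1-kappa)*P(E)
(``kappa``).

Evaluation noise is frozen: the train/test inputs are generated once before
evolution, and each individual's evaluation RNG stream derives from
(master seed, individual id, genotype version), so re-evaluating an
unchanged genotype reproduces its metrics bit-for-bit and cached metrics
are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environments import EnvironmentSpec, Trajectory, generate_trajectory
from .reservoir import (
    DEFAULT_FORECAST_LEN,
    DEFAULT_LEAK,
    DEFAULT_SPIN_UP,
    EvaluationSummary,
    Genotype,
    evaluate_reservoir,
    sample_input_direction,
)
from .topologies import BaseNetwork

__all__ = [
    "SearchSpace",
    "Individual",
    "Population",
    "EvaluationContext",
    "MicrobialGA",
    "default_search_space",
    "init_population",
    "compute_fitness",
    "microbial_generation",
    "evolve",
]

OBJECTIVES = ("neg_loss", "psi", "ps", "pe", "kappa")

GENES = ("alpha", "beta", "rho", "sigma", "theta")


@dataclass(frozen=True)
class SearchSpace:
    """Ordered discrete grids, one per gene."""

    grids: dict

    def __post_init__(self):
        for gene in GENES:
            grid = np.asarray(self.grids[gene], dtype=float)
            if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
                raise ValueError(f"grid for {gene} must be strictly increasing")
            self.grids[gene] = grid

    def genotype_from_indices(self, idx: dict) -> Genotype:
        return Genotype(**{g: float(self.grids[g][idx[g]]) for g in GENES})

    def sample_indices(self, rng: np.random.Generator) -> dict:
        return {g: int(rng.integers(len(self.grids[g]))) for g in GENES}

    def sample_genotype(self, rng: np.random.Generator) -> Genotype:
        return self.genotype_from_indices(self.sample_indices(rng))


def default_search_space() -> SearchSpace:
    """The standard hyperparameter search grids.

    alpha 0.1..2.0 (step 0.1); beta {1.0, 1.5, ..., 10.0}e-8 (the upper
    endpoint of the beta grid is read as the monotone continuation of the
    printed half-step sequence); rho 0.01..0.15 (step 0.01, bounded above
    by typical consensus-connectome density); sigma 0.01..0.10 (step 0.01);
    theta 0.1..1.9 (step 0.2).
    """
    return SearchSpace(
        grids={
            "alpha": np.round(np.arange(1, 21) * 0.1, 10),
            "beta": np.round(np.arange(2, 21) * 0.5, 10) * 1e-8,
            "rho": np.round(np.arange(1, 16) * 0.01, 10),
            "sigma": np.round(np.arange(1, 11) * 0.01, 10),
            "theta": np.round(0.1 + 0.2 * np.arange(10), 10),
        }
    )


@dataclass
class EvaluationContext:
    """The fixed inputs and protocol every individual is evaluated on."""

    base: BaseNetwork
    train: Trajectory
    tests: list
    spin_up: int = DEFAULT_SPIN_UP
    forecast_len: int = DEFAULT_FORECAST_LEN
    leak: float = DEFAULT_LEAK
    scale_mode: str = "minmax"


@dataclass
class Individual:
    """One reservoir computer in the population.

    The unit-scale input-direction matrix is fixed at birth (mutating sigma
    rescales the input weights rather than resampling them); ``version``
    counts genotype changes so evaluation streams and caches stay in sync.
    """

    id: int
    indices: dict
    input_direction: np.ndarray
    version: int = 0
    metrics: EvaluationSummary | None = None

    def genotype(self, space: SearchSpace) -> Genotype:
        return space.genotype_from_indices(self.indices)


@dataclass
class Population:
    individuals: list
    space: SearchSpace
    context: EvaluationContext
    master_seed: int

    def __len__(self):
        return len(self.individuals)


def compute_fitness(
    metrics: EvaluationSummary, objective: str, kappa: float = 0.5
) -> float:
    """Scalar fitness of an evaluation under the chosen objective."""
    if objective == "neg_loss":
        return -metrics.mean_loss
    if objective == "psi":
        return metrics.mean_psi if np.isfinite(metrics.mean_psi) else -np.inf
    if objective == "ps":
        return metrics.p_success
    if objective == "pe":
        return metrics.p_emergent
    if objective == "kappa":
        return kappa * metrics.p_success + (1.0 - kappa) * metrics.p_emergent
    raise ValueError(f"unknown objective {objective!r}; choose from {OBJECTIVES}")


def _evaluate(ind: Individual, pop: Population) -> None:
    rng = np.random.default_rng(
        np.random.SeedSequence([pop.master_seed, ind.id, ind.version])
    )
    ctx = pop.context
    ind.metrics = evaluate_reservoir(
        ctx.base,
        ind.genotype(pop.space),
        ctx.train,
        ctx.tests,
        rng,
        spin_up=ctx.spin_up,
        forecast_len=ctx.forecast_len,
        input_direction=ind.input_direction,
        leak=ctx.leak,
        scale_mode=ctx.scale_mode,
    )


def init_population(
    n: int,
    space: SearchSpace,
    context: EvaluationContext,
    rng: np.random.Generator,
    *,
    master_seed: int = 0,
    evaluate: bool = True,
) -> Population:
    """Create and (by default) evaluate a random population of size n."""
    if n < 2:
        raise ValueError("population size must be >= 2")
    individuals = [
        Individual(
            id=i,
            indices=space.sample_indices(rng),
            input_direction=sample_input_direction(context.base.n_nodes, rng),
        )
        for i in range(n)
    ]
    pop = Population(
        individuals=individuals, space=space, context=context, master_seed=master_seed
    )
    if evaluate:
        for ind in pop.individuals:
            _evaluate(ind, pop)
    return pop


def clone_population(pop: Population, context: EvaluationContext) -> Population:
    """Sister population: identical generation-0 genotypes and input
    directions, evaluated in a different context (e.g. another base
    network)."""
    sister = Population(
        individuals=[
            Individual(
                id=ind.id,
                indices=dict(ind.indices),
                input_direction=ind.input_direction.copy(),
            )
            for ind in pop.individuals
        ],
        space=pop.space,
        context=context,
        master_seed=pop.master_seed,
    )
    for ind in sister.individuals:
        _evaluate(ind, sister)
    return sister


def microbial_generation(
    pop: Population,
    objective: str,
    rng: np.random.Generator,
    *,
    kappa: float = 0.5,
    mutation_prob: float = 0.2,
    transfer_prob: float = 0.2,
) -> None:
    """One steady-state tournament: mutate and infect the loser in place.

    Mutation shifts a gene one grid position (direction uniform where both
    neighbors exist, forced inward at grid boundaries); gene transfer then
    copies the winner's value with probability ``transfer_prob`` per gene.
    The loser is re-evaluated only if its genotype actually changed (the
    evaluation is deterministic, so an unchanged genotype keeps its exact
    cached metrics).
    """
    if len(pop) < 2:
        raise ValueError("population size must be >= 2")
    i, j = rng.choice(len(pop), size=2, replace=False)
    a, b = pop.individuals[i], pop.individuals[j]
    fa = compute_fitness(a.metrics, objective, kappa)
    fb = compute_fitness(b.metrics, objective, kappa)
    winner, loser = (a, b) if fa >= fb else (b, a)

    old = dict(loser.indices)
    for gene in GENES:
        if rng.random() < mutation_prob:
            idx = loser.indices[gene]
            top = len(pop.space.grids[gene]) - 1
            if idx == 0:
                idx = 1
            elif idx == top:
                idx = top - 1
            else:
                idx += 1 if rng.random() < 0.5 else -1
            loser.indices[gene] = idx
    for gene in GENES:
        if rng.random() < transfer_prob:
            loser.indices[gene] = winner.indices[gene]

    if loser.indices != old:
        loser.version += 1
        _evaluate(loser, pop)


def evolve(
    pop: Population,
    generations: int,
    objective: str,
    rng: np.random.Generator,
    *,
    kappa: float = 0.5,
    mutation_prob: float = 0.2,
    transfer_prob: float = 0.2,
) -> pd.DataFrame:
    """Run the GA for ``generations`` tournaments, recording per-generation
    population means of loss and psi (from caches), the best fitness, and
    the best genotype.  Returns the trace as a DataFrame; the population is
    updated in place."""
    records = []
    for gen in range(generations):
        microbial_generation(
            pop,
            objective,
            rng,
            kappa=kappa,
            mutation_prob=mutation_prob,
            transfer_prob=transfer_prob,
        )
        fits = [
            compute_fitness(ind.metrics, objective, kappa) for ind in pop.individuals
        ]
        best = pop.individuals[int(np.argmax(fits))]
        losses = [ind.metrics.mean_loss for ind in pop.individuals]
        psis = [ind.metrics.mean_psi for ind in pop.individuals]
        rec = {
            "generation": gen,
            "mean_loss": float(np.mean(losses)),
            "mean_psi": float(np.nanmean(psis)),
            "best_fitness": float(np.max(fits)),
        }
        rec.update(
            {f"best_{g}": v for g, v in best.genotype(pop.space).as_dict().items()}
        )
        records.append(rec)
    return pd.DataFrame(records)


def best_individual(pop: Population, objective: str, kappa: float = 0.5) -> Individual:
    """Best-by-cached-fitness individual of the current generation."""
    fits = [compute_fitness(ind.metrics, objective, kappa) for ind in pop.individuals]
    return pop.individuals[int(np.argmax(fits))]


class MicrobialGA:
    """Convenience driver: generate fixed inputs, initialize, and evolve.

    Parameters mirror the study protocol: one training trajectory and
    ``n_tests`` test trajectories are generated up front from ``env`` and
    reused for every evaluation throughout the run.
    """

    def __init__(
        self,
        env: EnvironmentSpec,
        base: BaseNetwork,
        *,
        pop_size: int = 100,
        generations: int = 3000,
        objective: str = "neg_loss",
        kappa: float = 0.5,
        n_tests: int = 100,
        train_len: int = 2500,
        test_len: int | None = None,
        spin_up: int = DEFAULT_SPIN_UP,
        forecast_len: int = DEFAULT_FORECAST_LEN,
        scale_mode: str = "minmax",
        space: SearchSpace | None = None,
        seed: int = 0,
    ):
        if objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {objective!r}")
        self.env = env
        self.base = base
        self.pop_size = pop_size
        self.generations = generations
        self.objective = objective
        self.kappa = kappa
        self.n_tests = n_tests
        self.train_len = train_len
        self.test_len = test_len or spin_up + forecast_len
        self.spin_up = spin_up
        self.forecast_len = forecast_len
        self.scale_mode = scale_mode
        self.space = space or default_search_space()
        self.seed = seed

    def make_context(self, rng: np.random.Generator) -> EvaluationContext:
        train = generate_trajectory(self.env, self.train_len, rng)
        tests = [
            generate_trajectory(self.env, self.test_len, rng)
            for _ in range(self.n_tests)
        ]
        return EvaluationContext(
            base=self.base,
            train=train,
            tests=tests,
            spin_up=self.spin_up,
            forecast_len=self.forecast_len,
            scale_mode=self.scale_mode,
        )

    def run(self):
        """Execute the full optimization; returns (trace, population)."""
        rng = np.random.default_rng(self.seed)
        context = self.make_context(rng)
        pop = init_population(
            self.pop_size, self.space, context, rng, master_seed=self.seed
        )
        trace = evolve(
            pop, self.generations, self.objective, rng, kappa=self.kappa
        )
        return trace, pop
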