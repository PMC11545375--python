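"""The diversity-controlled hybrid metaheuristic and its baselines.

Per generation the hybrid loop (i) evaluates every individual with the
wrapper fitness, (ii) refines the current best AND the current worst member
with simulated annealing, (iii) updates the global best only on a strictly
greater fitness, (iv) sorts the population worst-first when the refined
worst now outranks the refined best (the diversity-control rule; otherwise
best-first), and (v) builds the BUMDA marginal model from the leading
selection-rate fraction of the sorted population and samples the next
generation from it.  Modeling on low-fitness individuals under that
controlled condition keeps feature-selection frequencies closer to uniform
and delays premature convergence.

Baselines: an elitist generational GA, plain simulated annealing, plain
BUMDA (no refinement, no diversity), and the hybrid without diversity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .bumda import (
    Individual,
    Population,
    repair,
    sample_population,
    select_for_model,
    update_theta,
    weighted_moments,
)
from .classifier import KernelSpec, evaluate_subset
from .config import RunConfig
from .data import LabeledDataset, PartitionSpec
from .metrics import FitnessWeights, feature_decreasing_rate, fitness as scalar_fitness
from .sa import AnnealSchedule, accept_probability, anneal, neighbor

__all__ = [
    "GenerationLog",
    "RunResult",
    "make_wrapper_fitness",
    "optimize",
    "run_hybrid",
    "run_baseline",
    "selection_frequencies",
    "frequency_stats",
    "best_generation_stats",
]

FitnessFn = Callable[[np.ndarray], float]


@dataclass
class GenerationLog:
    generation: int
    best_fitness: float
    worst_fitness: float
    gbest_fitness: float
    sort_inverted: bool
    selection_counts: np.ndarray
    theta: float | None = None

    def to_dict(self) -> dict:
        return {
            "generation": self.generation,
            "best_fitness": self.best_fitness,
            "worst_fitness": self.worst_fitness,
            "gbest_fitness": self.gbest_fitness,
            "sort_inverted": self.sort_inverted,
            "selection_counts": np.asarray(self.selection_counts).tolist(),
            "theta": self.theta,
        }


@dataclass
class RunResult:
    gbest: Individual
    logs: list[GenerationLog]
    selection_frequency: np.ndarray
    best_generation: int
    pop_size: int
    method: str = "hybrid"

    def __post_init__(self) -> None:
        if self.best_generation > len(self.logs):
            raise ValueError("best_generation exceeds the number of generations")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "gbest_bits": self.gbest.bits.tolist(),
            "gbest_fitness": self.gbest.fitness,
            "best_generation": self.best_generation,
            "pop_size": self.pop_size,
            "selection_frequency": np.asarray(self.selection_frequency).tolist(),
        }


def make_wrapper_fitness(
    ds: LabeledDataset,
    part: PartitionSpec,
    weights: FitnessWeights = FitnessWeights(),
    kernel: KernelSpec = KernelSpec(kind="linear"),
    eval_split: Literal["validation", "test"] = "validation",
    cache: bool = True,
) -> FitnessFn:
    """Wrapper fitness: w_acc * holdout accuracy + w_fdr * FDR of the mask.

    Empty masks score 0.  Results are memoized by bit pattern (the classifier
    is deterministic, and masks recur heavily as the population converges).
    """
    memo: dict[bytes, float] = {}

    def fitness_fn(bits: np.ndarray) -> float:
        bits = np.asarray(bits, dtype=np.uint8)
        key = bits.tobytes()
        if cache and key in memo:
            return memo[key]
        if not bits.any():
            value = 0.0
        else:
            _, acc = evaluate_subset(ds, part, bits.astype(bool), kernel, eval_split)
            fdr = feature_decreasing_rate(int(bits.sum()), bits.size)
            value = scalar_fitness(acc, fdr, weights)
        if cache:
            memo[key] = value
        return value

    return fitness_fn


def _random_population(
    n_features: int, npop: int, rng: np.random.Generator, generation_index: int = 1
) -> Population:
    draws = (rng.random((npop, n_features)) < 0.5).astype(np.uint8)
    return Population([Individual(repair(r, rng)) for r in draws], generation_index)


def _evaluate_all(pop: Population, fitness_fn: FitnessFn) -> None:
    for m in pop.members:
        if m.fitness is None:
            m.fitness = float(fitness_fn(m.bits))


def _refinement_schedule(cfg: RunConfig) -> AnnealSchedule:
    if cfg.sa_iters_per_refinement is None:
        return AnnealSchedule(cfg.sa_t0, cfg.sa_t_end, cfg.sa_step)
    return AnnealSchedule.with_iterations(
        cfg.sa_iters_per_refinement, cfg.sa_t0, cfg.sa_t_end
    )


def _sorted_members(members: list[Individual], ascending: bool) -> list[Individual]:
    # stable: ties keep original population order
    return sorted(
        members, key=lambda m: m.fitness if ascending else -m.fitness
    )


def optimize(
    fitness_fn: FitnessFn,
    n_features: int,
    cfg: RunConfig,
    diversity: bool = True,
    refine: bool = True,
    rng: np.random.Generator | None = None,
    method_name: str = "hybrid",
) -> RunResult:
    """Run the BUMDA(+SA) generation loop on an arbitrary bit-vector fitness."""
    rng = cfg.rng() if rng is None else rng
    npop = cfg.pop_size
    sched = _refinement_schedule(cfg)
    pop = _random_population(n_features, npop, rng)
    theta: float | None = None
    gbest: Individual | None = None
    best_generation = 1
    logs: list[GenerationLog] = []
    p_min = 1.0 / n_features

    for gen in range(1, cfg.n_generations + 1):
        pop.generation_index = gen
        _evaluate_all(pop, fitness_fn)
        f = pop.fitnesses()
        if gbest is None:
            gbest = pop.members[int(np.argmax(f))].copy()
            best_generation = gen

        inverted = False
        if refine:
            b_idx = int(np.argmax(f))
            w_idx = int(np.argmin(f))
            if w_idx == b_idx:
                w_idx = (b_idx + 1) % npop
            refined_best = anneal(pop.members[b_idx], fitness_fn, sched, rng)
            refined_worst = anneal(pop.members[w_idx], fitness_fn, sched, rng)
            pop.members[b_idx] = refined_best
            pop.members[w_idx] = refined_worst
            for cand in (refined_best, refined_worst):
                if cand.fitness > gbest.fitness:
                    gbest = cand.copy()
                    best_generation = gen
            inverted = diversity and refined_worst.fitness > refined_best.fitness
        else:
            best = pop.members[int(np.argmax(pop.fitnesses()))]
            if best.fitness > gbest.fitness:
                gbest = best.copy()
                best_generation = gen

        f = pop.fitnesses()
        pop.members = _sorted_members(pop.members, ascending=inverted)
        sorted_desc = np.sort(f)[::-1]
        theta = update_theta(sorted_desc, theta, gen)
        if refine:
            # Hybrid variants: the leading selection-rate fraction of the
            # sorted population produces the next generation, whichever way
            # the diversity controller oriented the sort.  The truncation
            # threshold is not applied as a gate here: it ratchets upward for
            # the whole run, so it would immediately filter a deliberately
            # diversified (worst-first) population back down to its top
            # members and neutralize the diversity control.  theta is still
            # tracked as the BUMDA convergence diagnostic.
            cap = math.ceil(cfg.selection_rate * pop.size)
            selected = pop.members[:cap]
        else:
            # plain BUMDA: truncation threshold as a floor, rate as a cap
            selected = select_for_model(pop, theta, cfg.selection_rate)
        model = weighted_moments(selected, beta=cfg.boltzmann_beta).clamped(p_min)
        model.theta = theta

        logs.append(
            GenerationLog(
                generation=gen,
                best_fitness=float(sorted_desc[0]),
                worst_fitness=float(sorted_desc[-1]),
                gbest_fitness=float(gbest.fitness),
                sort_inverted=bool(inverted),
                selection_counts=pop.bit_matrix().sum(axis=0),
                theta=float(theta),
            )
        )
        if gen < cfg.n_generations:
            pop = sample_population(model, npop, rng, generation_index=gen + 1)

    freqs = selection_frequencies(logs, npop)
    return RunResult(
        gbest=gbest,
        logs=logs,
        selection_frequency=freqs,
        best_generation=best_generation,
        pop_size=npop,
        method=method_name,
    )


def run_hybrid(
    ds: LabeledDataset,
    part: PartitionSpec,
    cfg: RunConfig,
    diversity: bool = True,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """The full wrapper pipeline: in-loop linear-SVM fitness + hybrid search."""
    fitness_fn = make_wrapper_fitness(
        ds, part, FitnessWeights(cfg.w_accuracy, cfg.w_fdr), KernelSpec(kind="linear")
    )
    name = "proposed" if diversity else "hybrid_no_diversity"
    return optimize(
        fitness_fn, ds.n_features, cfg, diversity=diversity, rng=rng, method_name=name
    )


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def _ga_optimize(
    fitness_fn: FitnessFn,
    n_features: int,
    cfg: RunConfig,
    rng: np.random.Generator,
    mutation_rate: float | None = None,
) -> RunResult:
    """Elitist generational GA: tournament parents from the best fraction,
    one-point crossover, per-bit mutation at rate 1/n."""
    npop = cfg.pop_size
    p_mut = 1.0 / n_features if mutation_rate is None else mutation_rate
    pop = _random_population(n_features, npop, rng)
    gbest: Individual | None = None
    best_generation = 1
    logs: list[GenerationLog] = []

    for gen in range(1, cfg.n_generations + 1):
        pop.generation_index = gen
        _evaluate_all(pop, fitness_fn)
        f = pop.fitnesses()
        best = pop.members[int(np.argmax(f))]
        if gbest is None or best.fitness > gbest.fitness:
            gbest = best.copy()
            best_generation = gen

        logs.append(
            GenerationLog(
                generation=gen,
                best_fitness=float(f.max()),
                worst_fitness=float(f.min()),
                gbest_fitness=float(gbest.fitness),
                sort_inverted=False,
                selection_counts=pop.bit_matrix().sum(axis=0),
            )
        )
        if gen == cfg.n_generations:
            break

        ranked = _sorted_members(pop.members, ascending=False)
        pool = ranked[: max(2, math.ceil(cfg.selection_rate * npop))]

        def pick_parent() -> Individual:
            a, b = rng.integers(len(pool)), rng.integers(len(pool))
            return pool[a] if pool[a].fitness >= pool[b].fitness else pool[b]

        children: list[Individual] = [ranked[0].copy()]  # elitism
        while len(children) < npop:
            p1, p2 = pick_parent(), pick_parent()
            point = int(rng.integers(1, n_features)) if n_features > 1 else 1
            for head, tail in ((p1, p2), (p2, p1)):
                if len(children) >= npop:
                    break
                bits = np.concatenate([head.bits[:point], tail.bits[point:]])
                if p_mut > 0:
                    flips = rng.random(n_features) < p_mut
                    bits = bits ^ flips.astype(np.uint8)
                children.append(Individual(repair(bits, rng)))
        pop = Population(children, generation_index=gen + 1)

    freqs = selection_frequencies(logs, npop)
    return RunResult(gbest, logs, freqs, best_generation, npop, method="ga")


def _sa_optimize(
    fitness_fn: FitnessFn,
    n_features: int,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> RunResult:
    """Single-solution annealing over the shared schedule, logged per iteration."""
    sched = AnnealSchedule(cfg.sa_t0, cfg.sa_t_end, cfg.sa_step)
    bits = repair((rng.random(n_features) < 0.5).astype(np.uint8), rng)
    current = Individual(bits, float(fitness_fn(bits)))
    gbest = current.copy()
    best_generation = 1
    logs: list[GenerationLog] = []
    for it, T in enumerate(sched.temperatures(), start=1):
        cand = neighbor(current, rng)
        cand.fitness = float(fitness_fn(cand.bits))
        p = accept_probability(cand.fitness, current.fitness, T)
        if p >= 1.0 or rng.random() < p:
            current = cand
        if current.fitness > gbest.fitness:
            gbest = current.copy()
            best_generation = it
        logs.append(
            GenerationLog(
                generation=it,
                best_fitness=float(current.fitness),
                worst_fitness=float(current.fitness),
                gbest_fitness=float(gbest.fitness),
                sort_inverted=False,
                selection_counts=current.bits.astype(np.int64),
            )
        )
    freqs = selection_frequencies(logs, 1)
    return RunResult(gbest, logs, freqs, best_generation, 1, method="sa")


def run_baseline(
    method: Literal["ga", "sa", "bumda", "hybrid_no_diversity"],
    ds: LabeledDataset,
    part: PartitionSpec,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """Run one of the comparison optimizers with the shared logging contract."""
    fitness_fn = make_wrapper_fitness(
        ds, part, FitnessWeights(cfg.w_accuracy, cfg.w_fdr), KernelSpec(kind="linear")
    )
    return optimize_baseline(method, fitness_fn, ds.n_features, cfg, rng)


def optimize_baseline(
    method: str,
    fitness_fn: FitnessFn,
    n_features: int,
    cfg: RunConfig,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> RunResult:
    rng = cfg.rng() if rng is None else rng
    if method == "ga":
        return _ga_optimize(fitness_fn, n_features, cfg, rng, **kwargs)
    if method == "sa":
        return _sa_optimize(fitness_fn, n_features, cfg, rng)
    if method == "bumda":
        return optimize(
            fitness_fn, n_features, cfg, diversity=False, refine=False, rng=rng,
            method_name="bumda",
        )
    if method == "hybrid_no_diversity":
        return optimize(
            fitness_fn, n_features, cfg, diversity=False, refine=True, rng=rng,
            method_name="hybrid_no_diversity",
        )
    raise ValueError(f"unknown baseline method {method!r}")


# ---------------------------------------------------------------------------
# Run diagnostics
# ---------------------------------------------------------------------------


def selection_frequencies(logs: Sequence[GenerationLog], pop_size: int) -> np.ndarray:
    """Per-feature selection frequency over a whole run:
    sum of per-generation selection counts / (n_generations * pop_size)."""
    if not logs:
        raise ValueError("logs must be non-empty")
    counts = np.sum([np.asarray(log.selection_counts) for log in logs], axis=0)
    return counts / (len(logs) * pop_size)


def frequency_stats(freqs) -> tuple[float, float, float, float, float, float]:
    """(min, max, median, mean, variance, std) of a frequency vector.

    Population variance (ddof = 0), so variance == std ** 2 exactly.
    """
    f = np.asarray(freqs, dtype=np.float64)
    if f.size < 1:
        raise ValueError("freqs must be non-empty")
    return (
        float(f.min()),
        float(f.max()),
        float(np.median(f)),
        float(f.mean()),
        float(f.var()),
        float(f.std()),
    )


def best_generation_stats(
    results: Sequence[RunResult],
) -> tuple[float, float, float, float, float, float]:
    """(min, max, median, mean, variance, std) of best_generation across trials."""
    if len(results) < 2:
        raise ValueError("need at least two run results")
    return frequency_stats([r.best_generation for r in results])
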