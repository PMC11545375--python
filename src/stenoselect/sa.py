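"""Simulated annealing refinement of single feature-subset individuals.

The temperature falls linearly from ``t0`` to ``t_end`` in constant steps.
Improving moves are always accepted; worsening moves are accepted with the
Metropolis probability exp(dE / T) (dE = f_new - f_old < 0), so worse
solutions are discriminated more strictly as the temperature drops.  The
neighborhood move flips each bit independently with probability 1/n, with at
least one flip forced, and the result is repaired to keep one set bit.  The
best-so-far individual is returned, so the output fitness never falls below
the input fitness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np

from .bumda import Individual, repair

__all__ = ["AnnealSchedule", "neighbor", "accept_probability", "anneal"]


@dataclass(frozen=True)
class AnnealSchedule:
    t0: float = 1.0
    t_end: float = 0.0
    step: float = 0.001

    def __post_init__(self) -> None:
        if not self.t0 > self.t_end >= 0.0:
            raise ValueError("require t0 > t_end >= 0")
        if self.step <= 0.0:
            raise ValueError("step must be positive")

    @property
    def n_iterations(self) -> int:
        return math.ceil((self.t0 - self.t_end) / self.step)

    def temperatures(self) -> Iterator[float]:
        for k in range(self.n_iterations):
            yield max(self.t0 - k * self.step, self.t_end)

    @classmethod
    def with_iterations(
        cls, n: int, t0: float = 1.0, t_end: float = 0.0
    ) -> "AnnealSchedule":
        """A t0 -> t_end schedule spending exactly ``n`` iterations."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return cls(t0=t0, t_end=t_end, step=(t0 - t_end) / n)


def neighbor(ind: Individual, rng: np.random.Generator) -> Individual:
    """Flip each bit with probability 1/n; force at least one flip; repair."""
    n = ind.bits.size
    flips = rng.random(n) < 1.0 / n
    if not flips.any():
        flips[rng.integers(n)] = True
    bits = ind.bits ^ flips.astype(np.uint8)
    return Individual(repair(bits, rng))


def accept_probability(f_new: float, f_old: float, T: float) -> float:
    """Metropolis acceptance for maximization: 1 for improvements, else
    exp((f_new - f_old)/T), and 0 in the frozen T = 0 limit."""
    if T < 0:
        raise ValueError("temperature must be non-negative")
    if f_new >= f_old:
        return 1.0
    if T == 0.0:
        return 0.0
    return math.exp((f_new - f_old) / T)


def anneal(
    start: Individual,
    fitness_fn: Callable[[np.ndarray], float],
    schedule: AnnealSchedule,
    rng: np.random.Generator,
    trace: list | None = None,
) -> Individual:
    """Refine ``start`` and return the best-so-far individual encountered.

    ``start`` must carry a fitness.  Exactly one fitness evaluation is spent
    per schedule iteration.  An optional ``trace`` list collects
    ``(T, current_fitness, best_fitness)`` tuples per iteration.
    """
    if start.fitness is None:
        raise ValueError("start individual must be evaluated")
    current = start.copy()
    best = start.copy()
    for T in schedule.temperatures():
        cand = neighbor(current, rng)
        cand.fitness = float(fitness_fn(cand.bits))
        p = accept_probability(cand.fitness, current.fitness, T)
        if p >= 1.0 or rng.random() < p:
            current = cand
        if current.fitness > best.fitness:
            best = current.copy()
        if trace is not None:
            trace.append((T, current.fitness, best.fitness))
    return best
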