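"""Boltzmann-Univariate Marginal Distribution Algorithm over bit vectors.

Each individual is a fixed-length bit vector marking the selected features.
The algorithm builds a fitness-weighted per-feature marginal model from the
selected fraction of the population and samples the next generation from it:

* weights        W(X_j)  = g(X_j) / sum_j g(X_j)
* mean           mu_i    = sum_j W(X_j) x_ij
* variance       nu_i    = sum_j W'(X_j) (x_ij - mu_i)^2,
  with W'(X_j) = g(X_j) / (sum_j g(X_j) + 1), so sum_j W'(X_j) = G/(G+1)
* truncation     theta updates from the sorted fitness vector and never
  decreases across generations.

The original formulation is a continuous-domain EDA; for feature selection
each bit is sampled independently as Bernoulli(mu_i), with mu clamped to
[p_min, 1 - p_min] (p_min = 1/n_features) so no feature ever fixates, and nu
retained as a convergence diagnostic.  g defaults to the raw fitness in
[0, 1]; an exp(beta * fitness) Boltzmann weighting is available via ``beta``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Individual",
    "Population",
    "MarginalModel",
    "boltzmann_weights",
    "weighted_moments",
    "update_theta",
    "select_for_model",
    "sample_population",
    "repair",
]


@dataclass
class Individual:
    """A candidate feature subset: bit vector plus cached fitness."""

    bits: np.ndarray
    fitness: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1 or self.bits.size < 1:
            raise ValueError("bits must be a non-empty 1-D vector")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be binary")

    @property
    def n_selected(self) -> int:
        return int(self.bits.sum())

    def copy(self) -> "Individual":
        return Individual(self.bits.copy(), self.fitness)


@dataclass
class Population:
    members: list[Individual]
    generation_index: int = 1

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("population must be non-empty")
        n = self.members[0].bits.size
        if any(m.bits.size != n for m in self.members):
            raise ValueError("all members must share the bit-vector length")
        if self.generation_index < 1:
            raise ValueError("generation_index must be >= 1")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def n_features(self) -> int:
        return int(self.members[0].bits.size)

    def fitnesses(self) -> np.ndarray:
        values = [m.fitness for m in self.members]
        if any(v is None for v in values):
            raise ValueError("population contains unevaluated members")
        return np.asarray(values, dtype=np.float64)

    def bit_matrix(self) -> np.ndarray:
        return np.stack([m.bits for m in self.members])


@dataclass
class MarginalModel:
    """Per-feature Bernoulli selection probabilities plus diagnostics."""

    mu: np.ndarray
    nu: np.ndarray
    theta: float | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.nu = np.asarray(self.nu, dtype=np.float64)
        if self.mu.shape != self.nu.shape or self.mu.ndim != 1:
            raise ValueError("mu and nu must be equal-length 1-D vectors")
        if (self.nu < -1e-12).any():
            raise ValueError("nu must be non-negative")

    def clamped(self, p_min: float) -> "MarginalModel":
        """Clamp mu into [p_min, 1 - p_min] so every bit stays sampleable."""
        if not 0.0 < p_min < 0.5:
            raise ValueError("p_min must lie in (0, 0.5)")
        return MarginalModel(np.clip(self.mu, p_min, 1.0 - p_min), self.nu, self.theta)

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "nu": self.nu.tolist(), "theta": self.theta}


def _g(fitnesses: np.ndarray, beta: float | None) -> np.ndarray:
    return fitnesses if beta is None else np.exp(beta * fitnesses)


def boltzmann_weights(fitnesses, beta: float | None = None) -> np.ndarray:
    """Normalized selection weights W(X_j) = g(X_j) / sum g(X_j)."""
    f = np.asarray(fitnesses, dtype=np.float64)
    if f.ndim != 1 or f.size < 1:
        raise ValueError("fitnesses must be a non-empty 1-D vector")
    if (f < 0).any():
        raise ValueError("fitnesses must be non-negative")
    g = _g(f, beta)
    total = g.sum()
    if total <= 0.0:
        warnings.warn("all fitnesses are zero; falling back to uniform weights")
        return np.full(f.size, 1.0 / f.size)
    return g / total


def weighted_moments(
    members: Sequence[Individual] | Population, beta: float | None = None
) -> MarginalModel:
    """Boltzmann-weighted per-feature mean mu and variance nu.

    nu uses the W' weighting whose denominator carries a +1 term, so the W'
    weights sum to G/(G+1) < 1 with G the total fitness mass.
    """
    if isinstance(members, Population):
        members = members.members
    pop = Population(list(members))
    f = pop.fitnesses()
    bits = pop.bit_matrix().astype(np.float64)
    w = boltzmann_weights(f, beta)
    mu = w @ bits
    g = _g(f, beta)
    w_prime = g / (g.sum() + 1.0)
    nu = w_prime @ (bits - mu) ** 2
    return MarginalModel(mu=mu, nu=nu)


def update_theta(sorted_fitnesses, theta_prev: float | None, t: int) -> float:
    """Advance the truncation threshold from a descending fitness vector.

    Generation 1 adopts the worst member's fitness.  Afterwards: if the
    fitness at the half-point position ceil(npop/2) clears the previous
    threshold, adopt it; otherwise adopt the smallest lower-half fitness that
    still clears the threshold, or retain the threshold if none does.  The
    result never decreases across generations.
    """
    f = np.asarray(sorted_fitnesses, dtype=np.float64)
    if f.ndim != 1 or f.size < 1:
        raise ValueError("sorted_fitnesses must be a non-empty 1-D vector")
    if (np.diff(f) > 1e-12).any():
        raise ValueError("fitnesses must be sorted in descending order")
    if t < 1:
        raise ValueError("generation index must be >= 1")
    if t == 1 or theta_prev is None:
        return float(f[-1])
    half = math.ceil(f.size / 2) - 1  # position ceil(npop/2), 0-based
    if f[half] >= theta_prev:
        return float(f[half])
    lower = f[half + 1 :]
    qualifying = lower[lower >= theta_prev]
    if qualifying.size:
        return float(qualifying.min())
    return float(theta_prev)


def select_for_model(
    pop: Population, theta: float, selection_rate: float
) -> list[Individual]:
    """Members with fitness >= theta, in current population order, capped at
    ceil(selection_rate * npop).  Never empty: falls back to the first member.

    The caller controls the population order; the diversity controller may
    have inverted it so that worst-first members lead.
    """
    if pop.size < 2:
        raise ValueError("population must have at least two members")
    if not 0.0 < selection_rate <= 1.0:
        raise ValueError("selection_rate must lie in (0, 1]")
    cap = math.ceil(selection_rate * pop.size)
    selected = [m for m in pop.members if m.fitness is not None and m.fitness >= theta]
    selected = selected[:cap]
    if not selected:
        return [pop.members[0]]
    return selected


def repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Guarantee at least one set bit by setting one uniformly at random."""
    if not bits.any():
        bits = bits.copy()
        bits[rng.integers(bits.size)] = 1
    return bits


def sample_population(
    model: MarginalModel,
    npop: int,
    rng: np.random.Generator,
    generation_index: int = 1,
) -> Population:
    """Draw ``npop`` individuals, bit i ~ Bernoulli(mu_i), each repaired to
    have at least one set bit."""
    if npop < 1:
        raise ValueError("npop must be >= 1")
    n = model.mu.size
    draws = (rng.random((npop, n)) < model.mu).astype(np.uint8)
    members = [Individual(repair(row, rng)) for row in draws]
    return Population(members, generation_index=generation_index)
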