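"""Run configuration: optimizer budget, SA schedule, fitness weights, seed.

Defaults mirror the full-scale study configuration: 1000 generations,
population 100, selection rate 0.80, SA temperature 1 -> 0 with step 0.001
(~1000 iterations), fitness weights 0.90 accuracy / 0.10 feature reduction.
The wrapper loop uses a shortened per-refinement SA schedule
(``sa_iters_per_refinement``) by default; set it to ``None`` to spend the
full schedule inside every generation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .classifier import KernelSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    n_generations: int = 1000
    pop_size: int = 100
    selection_rate: float = 0.80
    sa_t0: float = 1.0
    sa_t_end: float = 0.0
    sa_step: float = 0.001
    w_accuracy: float = 0.90
    w_fdr: float = 0.10
    seed: int = 0
    kernel: KernelSpec = field(default_factory=KernelSpec)
    # wrapper-loop economics: SA iterations spent refining each extreme
    # individual per generation (None = the full t0 -> t_end schedule)
    sa_iters_per_refinement: int | None = 50
    # g(X) in the Boltzmann weights: raw fitness (None) or exp(beta * fitness)
    boltzmann_beta: float | None = None

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not 0.0 < self.selection_rate <= 1.0:
            raise ValueError("selection_rate must lie in (0, 1]")
        if not self.sa_t0 > self.sa_t_end >= 0.0:
            raise ValueError("require sa_t0 > sa_t_end >= 0")
        if self.sa_step <= 0:
            raise ValueError("sa_step must be positive")
        if self.w_accuracy < 0 or self.w_fdr < 0:
            raise ValueError("fitness weights must be non-negative")
        if abs(self.w_accuracy + self.w_fdr - 1.0) > 1e-12:
            raise ValueError("w_accuracy + w_fdr must equal 1")
        if self.sa_iters_per_refinement is not None and self.sa_iters_per_refinement < 1:
            raise ValueError("sa_iters_per_refinement must be >= 1 or None")
        if isinstance(self.kernel, dict):
            self.kernel = KernelSpec.from_dict(self.kernel)

    # -- randomness -----------------------------------------------------
    def rng(self) -> np.random.Generator:
        """The single seeded generator owning all randomness of a run."""
        return np.random.default_rng(self.seed)

    def spawn_rngs(self, n: int) -> list[np.random.Generator]:
        """Derive ``n`` independent child generators from the run seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["kernel"] = self.kernel.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "kernel" in d and isinstance(d["kernel"], dict):
            d["kernel"] = KernelSpec.from_dict(d["kernel"])
        return cls(**d)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)
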