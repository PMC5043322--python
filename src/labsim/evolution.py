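"""Evolution stage: tournament death by age, tournament birth by pay-off,
Gaussian mutation with clamping, and literature truncation.

Each time step exactly one lab dies and one is born.  Death: the oldest of a
uniform sample of ``d`` labs (age ties broken uniformly at random).  Birth:
after the death is removed, the highest-pay-off lab of a fresh sample of
``d`` survivors reproduces; its offspring inherits the three methodological
traits, each independently perturbed by a zero-mean Gaussian with the
trait's mutation probability and magnitude, then clamped to its range.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import Lab, Literature
from .params import ConfigError, SimulationParameters

__all__ = [
    "select_death",
    "select_parent",
    "spawn_offspring",
    "truncate_literature",
    "evolution_step",
]


def _tournament(
    population: Sequence[Lab],
    d: int,
    key,
    rng: np.random.Generator,
) -> int:
    if d > len(population):
        raise ConfigError(
            f"tournament size d={d} exceeds population size {len(population)}"
        )
    sample_idx = rng.choice(len(population), size=d, replace=False)
    best: list[int] = []
    best_val = None
    for i in sample_idx:
        v = key(population[int(i)])
        if best_val is None or v > best_val:
            best, best_val = [int(i)], v
        elif v == best_val:
            best.append(int(i))
    winner = best[int(rng.integers(len(best)))] if len(best) > 1 else best[0]
    return population[winner].lab_id


def select_death(population: Sequence[Lab], d: int, rng: np.random.Generator) -> int:
    """Return the lab_id of the oldest lab in a uniform sample of size d."""
    return _tournament(population, d, lambda lab: lab.age, rng)


def select_parent(population: Sequence[Lab], d: int, rng: np.random.Generator) -> int:
    """Return the lab_id of the highest-pay-off lab in a sample of size d."""
    return _tournament(population, d, lambda lab: lab.payoff, rng)


def _mutate(value: float, mu: float, sigma: float, lo: float, hi: float,
            rng: np.random.Generator) -> float:
    if rng.random() < mu:
        value = value + rng.normal(0.0, sigma)
    return min(max(value, lo), hi)


def spawn_offspring(
    parent: Lab,
    params: SimulationParameters,
    rng: np.random.Generator,
    lab_id: int,
) -> Lab:
    """New lab inheriting the parent's traits with mutation; age and pay-off
    start at zero."""
    return Lab(
        lab_id=lab_id,
        power=_mutate(parent.power, params.mu_w, params.sigma_w, 0.0, 1.0, rng),
        effort=_mutate(parent.effort, params.mu_e, params.sigma_e,
                       params.EFFORT_MIN, params.EFFORT_MAX, rng),
        replication_rate=_mutate(parent.replication_rate, params.mu_r,
                                 params.sigma_r, 0.0, 1.0, rng),
        age=0,
        payoff=0.0,
    )


def truncate_literature(literature: Literature) -> Literature:
    """Drop the oldest records until the literature fits its capacity."""
    literature.truncate()
    return literature


def evolution_step(
    population: list[Lab],
    literature: Literature,
    params: SimulationParameters,
    rng: np.random.Generator,
    next_lab_id: int,
) -> int:
    """One death, one birth (tournament drawn post-death), then literature
    truncation.  Mutates ``population`` in place; returns the next unused
    lab_id."""
    dead_id = select_death(population, params.d, rng)
    dead_idx = next(i for i, lab in enumerate(population) if lab.lab_id == dead_id)
    population.pop(dead_idx)
    # the birth tournament cannot exceed the post-death population
    parent_id = select_parent(population, min(params.d, len(population)), rng)
    parent = next(lab for lab in population if lab.lab_id == parent_id)
    population.append(spawn_offspring(parent, params, rng, next_lab_id))
    truncate_literature(literature)
    return next_lab_id + 1
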