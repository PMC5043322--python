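"""Non-evolutionary two-type comparison model.

A fixed population of labs — half high-effort (type H), half low-effort
(type L), all at power 0.8 — does science for a burn-in phase with no
replication (to seed the literature) followed by a replication phase in
which each investigation is a replication with probability ``r``.  No lab
dies, reproduces or mutates; the question is purely how the pay-off
distributions of the two types compare once failed replications of one's
novel results carry a large penalty.

Science-stage mechanics (hypothesis selection, experimentation,
communication, pay-offs) are exactly those of :mod:`labsim.core`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Lab, Literature
from .engine import science_stage
from .params import ConfigError, SimulationParameters

__all__ = ["StaticConfig", "PayoffDistribution", "run_static",
           "run_static_replicates", "compare_types"]


@dataclass
class StaticConfig:
    """Configuration for the two-type model.

    The default efforts 75 (H) and 15 (L) give, at power 0.8, false-positive
    rates 0.05 / 0.2 and investigation rates 0.625 / 0.765 respectively.
    """

    n_labs: int = 100
    fraction_high: float = 0.5
    power_fixed: float = 0.8
    effort_high: float = 75.0
    effort_low: float = 15.0
    burn_in_steps: int = 10
    replication_steps: int = 100
    replication_rate: float = 0.0
    b: float = 0.1
    eta: float = 0.2
    c_r_pos: float = 1.0
    c_r_neg: float = 1.0
    v_n: float = 1.0
    v_r_pos: float = 0.5
    v_r_neg: float = 0.5
    v_o_pos: float = 0.1
    v_o_neg: float = -100.0

    def __post_init__(self) -> None:
        problems = []
        if self.n_labs < 1:
            problems.append("n_labs must be >= 1")
        if not 0.0 <= self.fraction_high <= 1.0:
            problems.append("fraction_high must lie in [0, 1]")
        if not 0.0 <= self.replication_rate <= 1.0:
            problems.append("replication_rate must lie in [0, 1]")
        for name in ("effort_high", "effort_low"):
            v = getattr(self, name)
            if not 1.0 <= v <= 100.0:
                problems.append(f"{name}={v} must lie in [1, 100]")
        if self.burn_in_steps < 0 or self.replication_steps < 0:
            problems.append("step counts must be non-negative")
        if problems:
            raise ConfigError("invalid static config: " + "; ".join(problems))

    def to_params(self) -> SimulationParameters:
        """Science-stage parameters shared with the evolutionary model."""
        return SimulationParameters(
            N=self.n_labs, b=self.b, eta=self.eta, w0=self.power_fixed,
            e0=self.effort_high, r0=0.0,
            c_r_pos=self.c_r_pos, c_r_neg=self.c_r_neg,
            v_n=self.v_n, v_r_pos=self.v_r_pos, v_r_neg=self.v_r_neg,
            v_o_pos=self.v_o_pos, v_o_neg=self.v_o_neg,
            n_steps=self.burn_in_steps + self.replication_steps,
        )


@dataclass
class PayoffDistribution:
    """Per-lab final pay-offs tagged by effort type."""

    lab_types: np.ndarray   # 'H' / 'L' per lab
    payoffs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lab_id": np.arange(len(self.payoffs)),
             "type": self.lab_types, "payoff": self.payoffs}
        )

    def of_type(self, lab_type: str) -> np.ndarray:
        return self.payoffs[self.lab_types == lab_type]

    def histogram(self, lab_type: str) -> dict[float, int]:
        """Count per distinct pay-off value for one type; counts sum to the
        lab count of that type."""
        values, counts = np.unique(self.of_type(lab_type), return_counts=True)
        return {float(v): int(c) for v, c in zip(values, counts)}


def run_static(config: StaticConfig, seed: int = 1) -> PayoffDistribution:
    """Run the two-type model: burn-in without replication, then
    ``replication_steps`` during which each investigation is a replication
    with probability ``replication_rate``.  Pay-offs accumulate over all
    steps."""
    rng = np.random.default_rng(seed)
    params = config.to_params()
    n_high = round(config.n_labs * config.fraction_high)
    population = [
        Lab(
            lab_id=i,
            power=config.power_fixed,
            effort=config.effort_high if i < n_high else config.effort_low,
            replication_rate=0.0,
        )
        for i in range(config.n_labs)
    ]
    lab_types = np.array(["H" if i < n_high else "L" for i in range(config.n_labs)])
    literature = Literature(capacity=10**9)  # runs stay far below any cap

    for step in range(config.burn_in_steps):
        science_stage(population, literature, params, rng, step)
    for lab in population:
        lab.replication_rate = config.replication_rate
    for step in range(config.replication_steps):
        science_stage(population, literature, params, rng,
                      config.burn_in_steps + step)

    return PayoffDistribution(
        lab_types=lab_types,
        payoffs=np.array([lab.payoff for lab in population]),
    )


def run_static_replicates(
    config: StaticConfig, n_runs: int, seed: int = 1
) -> list[PayoffDistribution]:
    """Independent replicates with seeds seed + run_index."""
    return [run_static(config, seed + i) for i in range(n_runs)]


def compare_types(dist: PayoffDistribution) -> dict:
    """Per-type mean and maximum pay-off, and the type of the single
    top-pay-off lab ('tie' when both types attain the maximum)."""
    if len(dist.payoffs) == 0:
        raise ValueError("empty pay-off distribution")
    out: dict = {}
    for t in ("H", "L"):
        vals = dist.of_type(t)
        out[f"mean_{t}"] = float(vals.mean()) if len(vals) else float("nan")
        out[f"max_{t}"] = float(vals.max()) if len(vals) else float("nan")
    top = dist.payoffs.max()
    top_types = set(dist.lab_types[dist.payoffs == top])
    out["top_lab_type"] = top_types.pop() if len(top_types) == 1 else "tie"
    return out
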