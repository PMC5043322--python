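"""Simulation parameters and declarative config I/O.

The parameter names follow the model's standard notation: ``N`` labs, base
rate ``b`` of true novel hypotheses, initial trait values ``w0`` (power),
``e0`` (effort) and ``r0`` (replication rate), productivity coefficient
``eta``, replication communication probabilities ``c_r_pos``/``c_r_neg``,
publication pay-offs ``v_n``/``v_r_pos``/``v_r_neg`` and originator pay-offs
``v_o_pos``/``v_o_neg``, tournament size ``d``, and per-trait mutation
probabilities ``mu_*`` with magnitudes ``sigma_*``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = ["SimulationParameters", "read_config", "write_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid parameter values or malformed config files."""


@dataclass
class SimulationParameters:
    """All global model parameters plus run-control settings.

    Defaults are the model's baseline values; scenario presets in
    :mod:`labsim.engine` override the mutation switches and ``r0``.
    """

    N: int = 100                  # number of labs
    b: float = 0.1                # base rate of true novel hypotheses
    r0: float = 0.0               # initial replication rate for all labs
    e0: float = 75.0              # initial effort for all labs
    w0: float = 0.8               # initial power for all labs
    eta: float = 0.2              # influence of effort on productivity
    c_r_pos: float = 1.0          # Pr(publish positive replication)
    c_r_neg: float = 1.0          # Pr(publish negative replication)
    v_n: float = 1.0              # pay-off for publishing a novel result
    v_r_pos: float = 0.5          # pay-off for publishing a positive replication
    v_r_neg: float = 0.5          # pay-off for publishing a negative replication
    v_o_pos: float = 0.1          # originator pay-off when replicated successfully
    v_o_neg: float = -100.0       # originator pay-off when replication fails
    d: int = 10                   # tournament sample size (death and birth)
    mu_r: float = 0.0             # mutation probability, replication rate
    mu_e: float = 0.0             # mutation probability, effort
    mu_w: float = 0.0             # mutation probability, power
    sigma_r: float = 0.01         # mutation s.d., replication rate
    sigma_e: float = 1.0          # mutation s.d., effort
    sigma_w: float = 0.01         # mutation s.d., power
    lit_capacity: int = 1_000_000  # most-recent publications kept replicable
    n_steps: int = 1_000_000      # time steps per run
    sample_interval: int = 2000   # record metrics every this many steps
    seed: int = 1                 # base seed for the run's random stream

    # trait bounds (model constants, not free parameters)
    EFFORT_MIN = 1.0
    EFFORT_MAX = 100.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Check every invariant; raise ConfigError listing all violations."""
        problems: list[str] = []
        for name in ("b", "r0", "w0", "c_r_pos", "c_r_neg", "mu_r", "mu_e", "mu_w"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} must be a probability in [0, 1]")
        if self.N < 1:
            problems.append(f"N={self.N} must be >= 1")
        if not 1 <= self.d <= self.N:
            problems.append(f"d={self.d} must satisfy 1 <= d <= N={self.N}")
        if not self.EFFORT_MIN <= self.e0 <= self.EFFORT_MAX:
            problems.append(f"e0={self.e0} must lie in [1, 100]")
        if self.eta < 0 or self.eta > 0.5:
            # eta <= 0.5 keeps the investigation probability h(e) >= 0 on e in [1, 100]
            problems.append(f"eta={self.eta} must lie in [0, 0.5]")
        for name in ("sigma_r", "sigma_e", "sigma_w"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be non-negative")
        if self.lit_capacity < 1:
            problems.append("lit_capacity must be >= 1")
        if self.n_steps < 0:
            problems.append("n_steps must be non-negative")
        if self.sample_interval < 1:
            problems.append("sample_interval must be >= 1")
        if not 0 <= int(self.seed) < 2**31:
            problems.append("seed must be a non-negative integer below 2**31")
        if problems:
            raise ConfigError("invalid parameters: " + "; ".join(problems))

    def replace(self, **changes: Any) -> "SimulationParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def equivalent(self, other: "SimulationParameters", *, ignore_seed: bool = True) -> bool:
        """True when all parameters match, optionally ignoring the seed."""
        a, b = self.to_dict(), other.to_dict()
        if ignore_seed:
            a.pop("seed"), b.pop("seed")
        return a == b


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationParameters)}
_INT_FIELDS = {"N", "d", "lit_capacity", "n_steps", "sample_interval", "seed"}


def read_config(path: str | Path) -> SimulationParameters:
    """Load parameters from a flat YAML key-value file.

    Unknown keys are rejected; omitted keys take their defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a flat key-value mapping")
    unknown = sorted(set(raw) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric, got {value!r}")
        kwargs[key] = int(value) if key in _INT_FIELDS else float(value)
    return SimulationParameters(**kwargs)


def write_config(params: SimulationParameters, path: str | Path) -> None:
    """Write parameters as a flat YAML mapping; round-trips losslessly."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=False, default_flow_style=False)
    )
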