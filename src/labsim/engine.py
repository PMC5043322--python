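"""Simulation driver: initialization, the Science/Evolution loop, replicate
aggregation, scenario presets and CSV/JSON/config I/O.

A run alternates the Science stage (every lab may investigate and publish)
with the Evolution stage (one tournament death, one tournament birth,
literature truncation) for ``n_steps`` time steps, recording population
summaries every ``sample_interval`` steps.  Two backends with the same
model semantics are available: ``"compiled"`` (numba kernel; use for long
runs) and ``"python"`` (the readable reference path built from
:mod:`labsim.core` and :mod:`labsim.evolution`).  Each backend is
deterministic: identical parameters and seed give byte-identical CSV
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import core
from .core import Lab, Literature, false_positive_rate, productivity_rate
from .evolution import evolution_step
from .params import ConfigError, SimulationParameters, read_config, write_config

__all__ = [
    "StepMetrics",
    "RunResult",
    "ScienceStageResult",
    "initialize",
    "science_stage",
    "run_simulation",
    "run_replicates",
    "aggregate_runs",
    "write_timeseries",
    "read_config",
    "write_config",
    "scenario_params",
    "SCENARIOS",
]

METRIC_COLUMNS = [
    "step",
    "mean_power",
    "mean_effort",
    "mean_replication",
    "mean_alpha",
    "fdr",
    "n_published",
    "n_positive",
    "n_replications",
]



@dataclass(frozen=True)
class StepMetrics:
    """Population summary at one sample point.

    ``fdr`` is the fraction of that step's published positive results that
    are false; it is NaN (missing, not zero) on steps with no published
    positives and excluded from aggregation.
    """

    step: int
    mean_power: float
    mean_effort: float
    mean_replication: float
    mean_alpha: float
    fdr: float
    n_published: int
    n_positive: int
    n_replications: int


@dataclass
class RunResult:
    """Outcome of a single seeded run."""

    params: SimulationParameters
    seed: int
    metrics: pd.DataFrame            # one row per sample point, METRIC_COLUMNS
    final_population: pd.DataFrame   # lab_id, power, effort, replication_rate, age, payoff
    backend: str

    @property
    def final_means(self) -> dict[str, float]:
        pop = self.final_population
        return {
            "mean_power": float(pop["power"].mean()),
            "mean_effort": float(pop["effort"].mean()),
            "mean_replication": float(pop["replication_rate"].mean()),
            "mean_alpha": float(
                np.mean(false_positive_rate(pop["power"].to_numpy(),
                                            pop["effort"].to_numpy()))
            ),
        }


@dataclass
class ScienceStageResult:
    records: list[core.PublicationRecord]
    payoff_deltas: list[dict[int, float]]
    n_investigations: int


# ---------------------------------------------------------------------------
# initialization and the reference (pure-Python) loop
# ---------------------------------------------------------------------------

def initialize(
    params: SimulationParameters, rng: np.random.Generator | None = None
) -> tuple[list[Lab], Literature]:
    """Fresh population of N identical labs and an empty literature."""
    params.validate()
    population = [
        Lab(lab_id=i, power=params.w0, effort=params.e0,
            replication_rate=params.r0)
        for i in range(params.N)
    ]
    return population, Literature(capacity=params.lit_capacity)


def science_stage(
    population: Sequence[Lab],
    literature: Literature,
    params: SimulationParameters,
    rng: np.random.Generator,
    step: int = 0,
) -> ScienceStageResult:
    """One Science stage: labs act in a fresh random permutation; each
    investigates with probability h(e_i).  Publications are appended (and
    pay-offs credited) immediately, so later labs within the same step can
    replicate earlier same-step publications."""
    order = rng.permutation(len(population))
    out = ScienceStageResult([], [], 0)
    for idx in order:
        lab = population[idx]
        if rng.random() >= productivity_rate(lab.effort, params.eta):
            continue
        out.n_investigations += 1
        hyp, kind = core.select_hypothesis(lab, literature, params, rng, step)
        sign = core.run_experiment(lab, hyp, rng)
        if core.communicate(sign, kind, params, rng):
            record = core.PublicationRecord(
                hyp.hyp_id, lab.lab_id, step, sign, kind, hyp.is_true
            )
            literature.add_record(record)
            out.payoff_deltas.append(
                core.apply_payoffs(record, population, literature, params)
            )
            out.records.append(record)
    return out


def _metrics_row(step: int, population: Sequence[Lab],
                 stage: ScienceStageResult) -> StepMetrics:
    w = np.array([lab.power for lab in population])
    e = np.array([lab.effort for lab in population])
    r = np.array([lab.replication_rate for lab in population])
    pos = [rec for rec in stage.records if rec.sign == "positive"]
    n_false = sum(1 for rec in pos if not rec.truth_at_publication)
    return StepMetrics(
        step=step,
        mean_power=float(w.mean()),
        mean_effort=float(e.mean()),
        mean_replication=float(r.mean()),
        mean_alpha=float(np.mean(false_positive_rate(w, e))),
        fdr=(n_false / len(pos)) if pos else float("nan"),
        n_published=len(stage.records),
        n_positive=len(pos),
        n_replications=sum(1 for rec in stage.records if rec.kind == "replication"),
    )


def _run_python(params: SimulationParameters) -> RunResult:
    rng = np.random.default_rng(params.seed)
    population, literature = initialize(params, rng)
    next_lab_id = params.N
    rows: list[StepMetrics] = []
    for t in range(params.n_steps):
        stage = science_stage(population, literature, params, rng, step=t)
        for lab in population:
            lab.age += 1
        next_lab_id = evolution_step(population, literature, params, rng, next_lab_id)
        if (t + 1) % params.sample_interval == 0:
            rows.append(_metrics_row(t + 1, population, stage))
    metrics = pd.DataFrame([vars(r) for r in rows], columns=METRIC_COLUMNS)
    final = pd.DataFrame(
        {
            "lab_id": [lab.lab_id for lab in population],
            "power": [lab.power for lab in population],
            "effort": [lab.effort for lab in population],
            "replication_rate": [lab.replication_rate for lab in population],
            "age": [lab.age for lab in population],
            "payoff": [lab.payoff for lab in population],
        }
    )
    return RunResult(params, params.seed, metrics, final, "python")


def _run_compiled(params: SimulationParameters) -> RunResult:
    from ._kernel import run_kernel

    (m, power, effort, rep, age, payoff, slot_id, _lit) = run_kernel(
        int(params.seed), int(params.n_steps), int(params.sample_interval),
        int(params.N), float(params.b), float(params.eta),
        float(params.w0), float(params.e0), float(params.r0),
        float(params.c_r_pos), float(params.c_r_neg),
        float(params.v_n), float(params.v_r_pos), float(params.v_r_neg),
        float(params.v_o_pos), float(params.v_o_neg),
        int(params.d), float(params.mu_r), float(params.mu_e), float(params.mu_w),
        float(params.sigma_r), float(params.sigma_e), float(params.sigma_w),
        int(params.lit_capacity),
    )
    metrics = pd.DataFrame(m, columns=METRIC_COLUMNS)
    final = pd.DataFrame(
        {
            "lab_id": slot_id,
            "power": power,
            "effort": effort,
            "replication_rate": rep,
            "age": age,
            "payoff": payoff,
        }
    )
    return RunResult(params, params.seed, metrics, final, "compiled")


def run_simulation(params: SimulationParameters, backend: str = "compiled") -> RunResult:
    """Run one seeded simulation.

    ``backend="compiled"`` uses the numba kernel (recommended beyond a few
    thousand steps); ``backend="python"`` runs the reference implementation.
    The two backends implement the same model but consume their random
    streams differently, so they agree statistically, not draw-for-draw.
    """
    if backend == "compiled":
        return _run_compiled(params)
    if backend == "python":
        return _run_python(params)
    raise ValueError(f"unknown backend {backend!r}")


def run_replicates(
    params: SimulationParameters, n_runs: int, backend: str = "compiled"
) -> list[RunResult]:
    """Independent replicate runs with seeds base_seed + run_index."""
    return [
        run_simulation(params.replace(seed=params.seed + i), backend)
        for i in range(n_runs)
    ]


# ---------------------------------------------------------------------------
# aggregation and I/O
# ---------------------------------------------------------------------------

def aggregate_runs(results: Sequence[RunResult]) -> pd.DataFrame:
    """Pointwise mean (and s.d.) of each metric across replicate runs.

    All runs must share parameters up to the seed.  NaN FDR values (steps
    with no published positives) are excluded from the mean.
    """
    if not results:
        raise ValueError("no runs to aggregate")
    first = results[0].params
    for res in results[1:]:
        if not first.equivalent(res.params):
            raise ValueError("cannot aggregate runs with differing parameters")
    stacked = pd.concat([res.metrics for res in results], keys=range(len(results)))
    grouped = stacked.groupby("step")
    mean = grouped.mean()
    sd = grouped.std(ddof=0)
    out = pd.DataFrame(index=mean.index)
    for col in METRIC_COLUMNS[1:]:
        out[col] = mean[col]
        out[col + "_sd"] = sd[col]
    return out.reset_index()


def write_timeseries(
    results: RunResult | Sequence[RunResult], path: str | Path
) -> pd.DataFrame:
    """Write per-run time series as headered CSV (one row per sample point);
    returns the frame written."""
    if isinstance(results, RunResult):
        results = [results]
    frames = []
    for run_idx, res in enumerate(results):
        frame = res.metrics.copy()
        frame.insert(0, "run", run_idx)
        frame.insert(1, "seed", res.seed)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
    return out


def write_summary(
    results: Sequence[RunResult], path: str | Path, elapsed: float | None = None
) -> dict:
    """JSON summary mirroring the CSV: parameter echo, seeds, per-run final
    trait means, and the replicate-averaged final sample point."""
    from . import __version__

    agg = aggregate_runs(results)
    last = agg.iloc[-1].to_dict() if len(agg) else {}
    payload = {
        "version": __version__,
        "params": results[0].params.to_dict(),
        "seeds": [res.seed for res in results],
        "backend": results[0].backend,
        "n_runs": len(results),
        "final_sample": {k: (None if pd.isna(v) else float(v)) for k, v in last.items()},
        "per_run_final_means": [res.final_means for res in results],
    }
    if elapsed is not None:
        payload["wall_clock_s"] = elapsed
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

#: Mutation/initial-condition presets for the four headline experiments.
SCENARIOS: dict[str, dict] = {
    # power free to evolve; effort and replication frozen
    "power": dict(mu_w=0.01, mu_e=0.0, mu_r=0.0, r0=0.0),
    # power fixed (institutionally enforced); effort evolves
    "effort": dict(mu_w=0.0, mu_e=0.01, mu_r=0.0, r0=0.0),
    # effort and replication coevolve from a 1% replication rate
    "coevolution": dict(mu_w=0.0, mu_e=0.01, mu_r=0.01, r0=0.01),
    # replication enforced at a fixed rate while effort evolves
    "enforced-replication": dict(mu_w=0.0, mu_e=0.01, mu_r=0.0),
}

#: Run lengths: the full protocol, and a scaled preset for desk-sized work.
RUN_PRESETS = {
    "full": dict(n_steps=1_000_000, sample_interval=2000),
    "scaled": dict(n_steps=200_000, sample_interval=2000),
}


def scenario_params(
    name: str,
    *,
    preset: str = "full",
    r0: float | None = None,
    seed: int = 1,
    **overrides,
) -> SimulationParameters:
    """Parameters for a named scenario.

    ``r0`` must be given for ``enforced-replication`` (the fixed fraction
    of investigations that are replications); any field can be overridden.
    """
    if name not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}"
        )
    kwargs = dict(SCENARIOS[name])
    kwargs.update(RUN_PRESETS[preset])
    if name == "enforced-replication":
        if r0 is None:
            raise ConfigError("enforced-replication requires an r0 level")
        kwargs["r0"] = r0
    elif r0 is not None:
        kwargs["r0"] = r0
    kwargs["seed"] = seed
    kwargs.update(overrides)
    return SimulationParameters(**kwargs)
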