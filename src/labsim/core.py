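"""Core model: labs, hypotheses, the published literature, and the Science stage.

The model couples three heritable methodological traits of a research lab —
statistical power ``W`` (probability of a positive result on a true
hypothesis), effort ``e`` (methodological rigour suppressing false
positives), and replication rate ``r`` (probability an investigation targets
a previously supported hypothesis) — to publication pay-offs under
asymmetric publishing rules: positive novel results always publish, negative
novel results never do, and replications publish with configurable
probabilities.

Closed forms
------------
* ``productivity_rate``: h(e) = 1 - eta * log10(e), the per-step probability
  a lab starts an investigation.
* ``false_positive_rate``: alpha(W, e) = W / (1 + (1 - W) * e), the convex
  power/false-positive trade-off modulated by effort.
* ``prob_positive_novel``: Pr(+) = b*W + (1-b)*alpha(W, e) for a novel test.
* ``expected_fdr_novel``: the false discovery rate among published novel
  positives, (1-b)*alpha / Pr(+).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .params import SimulationParameters

__all__ = [
    "Lab",
    "Hypothesis",
    "PublicationRecord",
    "Literature",
    "productivity_rate",
    "false_positive_rate",
    "prob_positive_novel",
    "expected_fdr_novel",
    "select_hypothesis",
    "run_experiment",
    "communicate",
    "apply_payoffs",
]

Sign = Literal["positive", "negative"]
Kind = Literal["novel", "replication"]


# ---------------------------------------------------------------------------
# closed-form functions
# ---------------------------------------------------------------------------

def productivity_rate(effort, eta: float = 0.2):
    """Per-time-step probability h(e) = 1 - eta*log10(e) that a lab
    begins a new investigation.

    Accepts scalars or arrays; effort must be >= 1 so the logarithm term is
    non-negative, and the result must land in [0, 1].
    """
    e = np.asarray(effort, dtype=float)
    if np.any(e < 1.0):
        raise ValueError(f"effort must be >= 1, got {effort!r}")
    h = 1.0 - eta * np.log10(e)
    if np.any(h < 0.0) or np.any(h > 1.0):
        raise ValueError(
            f"productivity h={h!r} outside [0, 1] for effort={effort!r}, eta={eta!r}"
        )
    return h if h.ndim else float(h)


def false_positive_rate(power, effort):
    """False-positive rate alpha(W, e) = W / (1 + (1 - W) * e).

    Strictly increasing in power, strictly decreasing in effort for W < 1;
    equals W exactly when W is 0 or 1, regardless of effort.
    """
    w = np.asarray(power, dtype=float)
    e = np.asarray(effort, dtype=float)
    if np.any((w < 0.0) | (w > 1.0)):
        raise ValueError(f"power must lie in [0, 1], got {power!r}")
    if np.any((e < 1.0) | (e > 100.0)):
        raise ValueError(f"effort must lie in [1, 100], got {effort!r}")
    a = w / (1.0 + (1.0 - w) * e)
    return a if a.ndim else float(a)


def prob_positive_novel(base_rate, power, effort):
    """Probability a test of a novel hypothesis yields a (publishable)
    positive result: b*W + (1-b)*alpha(W, e)."""
    b = np.asarray(base_rate, dtype=float)
    if np.any((b < 0.0) | (b > 1.0)):
        raise ValueError(f"base_rate must lie in [0, 1], got {base_rate!r}")
    w = np.asarray(power, dtype=float)
    p = b * w + (1.0 - b) * false_positive_rate(power, effort)
    return p if p.ndim else float(p)


def expected_fdr_novel(base_rate, power, effort):
    """Expected false discovery rate among published novel positives:
    (1-b)*alpha / (b*W + (1-b)*alpha).  Undefined when Pr(+) = 0."""
    b = np.asarray(base_rate, dtype=float)
    pr_pos = np.asarray(prob_positive_novel(base_rate, power, effort))
    if np.any(pr_pos == 0.0):
        raise ValueError(
            "expected FDR undefined: probability of a positive result is zero"
        )
    fdr = (1.0 - b) * np.asarray(false_positive_rate(power, effort)) / pr_pos
    return fdr if fdr.ndim else float(fdr)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Lab:
    """A research lab with heritable methodology.

    power and replication_rate live in [0, 1]; effort in [1, 100].  payoff
    accumulates through publication events only; age advances by one per
    completed time step while the lab is alive.
    """

    lab_id: int
    power: float
    effort: float
    replication_rate: float
    age: int = 0
    payoff: float = 0.0

    @property
    def alpha(self) -> float:
        return false_positive_rate(self.power, self.effort)


@dataclass(frozen=True)
class Hypothesis:
    """A unit of investigable knowledge with a fixed latent truth value."""

    hyp_id: int
    is_true: bool
    originator: int   # lab_id of the lab that first investigated it
    created_at: int   # time step of creation


@dataclass(frozen=True)
class PublicationRecord:
    """One published result.  Novel records always carry sign='positive'."""

    hyp_id: int
    author: int
    step: int
    sign: Sign
    kind: Kind
    truth_at_publication: bool

    def __post_init__(self) -> None:
        if self.kind == "novel" and self.sign != "positive":
            raise ValueError("negative novel results are never published")


class Literature:
    """The published record, capped at the most recent ``capacity`` entries.

    Maintains an index of replicable hypotheses — those with at least one
    retained positive record — supporting O(1) uniform sampling over
    *distinct* hypotheses (multiply-published hypotheses are not
    oversampled).
    """

    def __init__(self, capacity: int = 1_000_000) -> None:
        self.capacity = int(capacity)
        self.records: list[PublicationRecord] = []
        self._start = 0  # records[:_start] are truncated (lazy deletion)
        self._hypotheses: dict[int, Hypothesis] = {}
        self._pos_counts: dict[int, int] = {}
        self._replicable: list[int] = []          # array-backed set
        self._replicable_pos: dict[int, int] = {}  # hyp_id -> index in _replicable
        self._next_hyp_id = 0

    # -- hypotheses ---------------------------------------------------------

    def new_hypothesis(self, is_true: bool, originator: int, step: int) -> Hypothesis:
        hyp = Hypothesis(self._next_hyp_id, bool(is_true), originator, step)
        self._next_hyp_id += 1
        self._hypotheses[hyp.hyp_id] = hyp
        return hyp

    def hypothesis(self, hyp_id: int) -> Hypothesis:
        return self._hypotheses[hyp_id]

    # -- records ------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.records) - self._start

    def iter_records(self) -> Iterable[PublicationRecord]:
        return iter(self.records[self._start:])

    def add_record(self, record: PublicationRecord) -> None:
        self.records.append(record)
        if record.sign == "positive":
            c = self._pos_counts.get(record.hyp_id, 0)
            self._pos_counts[record.hyp_id] = c + 1
            if c == 0:
                self._replicable_pos[record.hyp_id] = len(self._replicable)
                self._replicable.append(record.hyp_id)

    # -- replicable index ---------------------------------------------------

    @property
    def n_replicable(self) -> int:
        return len(self._replicable)

    @property
    def replicable_index(self) -> frozenset[int]:
        return frozenset(self._replicable)

    def sample_replicable(self, rng: np.random.Generator) -> Hypothesis:
        if not self._replicable:
            raise ValueError("no replicable hypotheses in the literature")
        hyp_id = self._replicable[int(rng.integers(len(self._replicable)))]
        return self._hypotheses[hyp_id]

    def _drop_replicable(self, hyp_id: int) -> None:
        idx = self._replicable_pos.pop(hyp_id)
        last = self._replicable.pop()
        if last != hyp_id:
            self._replicable[idx] = last
            self._replicable_pos[last] = idx

    # -- truncation ---------------------------------------------------------

    def truncate(self) -> int:
        """Drop the oldest records until len <= capacity; returns #removed."""
        removed = 0
        while len(self) > self.capacity:
            rec = self.records[self._start]
            self._start += 1
            removed += 1
            if rec.sign == "positive":
                self._pos_counts[rec.hyp_id] -= 1
                if self._pos_counts[rec.hyp_id] == 0:
                    del self._pos_counts[rec.hyp_id]
                    self._drop_replicable(rec.hyp_id)
        # periodically compact the backing list
        if self._start > 4 * (self.capacity + 1):
            self.records = self.records[self._start:]
            self._start = 0
        return removed


# ---------------------------------------------------------------------------
# Science-stage mechanics
# ---------------------------------------------------------------------------

def select_hypothesis(
    lab: Lab,
    literature: Literature,
    params: SimulationParameters,
    rng: np.random.Generator,
    step: int = 0,
) -> tuple[Hypothesis, Kind]:
    """Choose what the lab investigates this step.

    With probability ``r_i`` the lab attempts a replication of a uniformly
    chosen hypothesis that has at least one retained positive record; an
    empty replicable set falls back to a novel investigation.  Novel
    hypotheses are freshly created, true with probability ``b``, and never
    reused as novel.
    """
    if rng.random() < lab.replication_rate and literature.n_replicable > 0:
        return literature.sample_replicable(rng), "replication"
    is_true = rng.random() < params.b
    return literature.new_hypothesis(is_true, lab.lab_id, step), "novel"


def run_experiment(lab: Lab, hypothesis: Hypothesis, rng: np.random.Generator) -> Sign:
    """One investigation: a true hypothesis yields a positive result with
    probability W_i, a false one with probability alpha(W_i, e_i)."""
    p = lab.power if hypothesis.is_true else false_positive_rate(lab.power, lab.effort)
    return "positive" if rng.random() < p else "negative"


def communicate(
    sign: Sign, kind: Kind, params: SimulationParameters, rng: np.random.Generator
) -> bool:
    """Whether the result enters the literature.

    Positive novel results always publish; negative novel results never do.
    Replications publish with probability c_r_pos (positive) or c_r_neg
    (negative).
    """
    if kind == "novel":
        return sign == "positive"
    c = params.c_r_pos if sign == "positive" else params.c_r_neg
    return bool(rng.random() < c)


def apply_payoffs(
    record: PublicationRecord,
    population: Sequence[Lab],
    literature: Literature,
    params: SimulationParameters,
) -> dict[int, float]:
    """Credit pay-offs for a freshly published record; returns the deltas.

    The author earns v_n for a novel result, v_r_pos / v_r_neg for a
    replication.  For replications the hypothesis's originator — if still in
    the population and distinct from the author — gains v_o_pos on success
    or v_o_neg on failure.
    """
    by_id = {lab.lab_id: lab for lab in population}
    deltas: dict[int, float] = {}
    author = by_id[record.author]
    if record.kind == "novel":
        deltas[author.lab_id] = params.v_n
    else:
        deltas[author.lab_id] = (
            params.v_r_pos if record.sign == "positive" else params.v_r_neg
        )
        originator_id = literature.hypothesis(record.hyp_id).originator
        if originator_id != record.author and originator_id in by_id:
            bonus = params.v_o_pos if record.sign == "positive" else params.v_o_neg
            deltas[originator_id] = deltas.get(originator_id, 0.0) + bonus
    for lab_id, delta in deltas.items():
        by_id[lab_id].payoff += delta
    return deltas
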