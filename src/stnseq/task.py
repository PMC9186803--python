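"""Expanded judgment task: configuration, trial records, analytic properties.

In the expanded judgment task an observer watches a sequence of binary cues
(left / right), each of which matches the true direction with a fixed
validity (0.7 by default), and responds whenever they feel they have enough
evidence.  Cues are coded numerically as L = -1, R = +1 throughout the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TaskConfig",
    "TrialRecord",
    "BehaviorSummary",
    "cue_to_int",
    "cues_to_array",
    "analytic_same_pair_prob",
    "ideal_observer_choice",
    "summarize_behavior",
]

_CUE_MAP = {"L": -1, "R": 1, -1: -1, 1: 1}
_INT_TO_CUE = {-1: "L", 1: "R"}


def cue_to_int(cue) -> int:
    """Map a cue label ('L'/'R' or -1/+1) to the internal -1/+1 coding."""
    try:
        return _CUE_MAP[cue]
    except KeyError:
        raise ValueError(f"invalid cue {cue!r}; expected 'L', 'R', -1 or +1") from None


def cues_to_array(cues: Iterable) -> np.ndarray:
    arr = np.asarray([cue_to_int(c) for c in cues], dtype=np.int8)
    if arr.size == 0:
        raise ValueError("empty cue sequence")
    return arr


@dataclass(frozen=True)
class TaskConfig:
    """Task timing and statistics.

    validity : probability that a single cue matches the true direction,
        strictly between 0.5 and 1 (0.7 in the standard task).
    cue_duration, isi : cue-on time and interstimulus interval in seconds;
        their sum is the stimulus onset asynchrony (SOA, 0.8 s).
    max_cues : longest sequence an agent may sample before being forced to
        stop (training used 2-10 set lengths, motivating the default 10).
    """

    validity: float = 0.7
    cue_duration: float = 0.200
    isi: float = 0.600
    max_cues: int = 10

    def __post_init__(self):
        if not 0.5 < self.validity < 1.0:
            raise ValueError(f"validity must be in (0.5, 1), got {self.validity}")
        if self.cue_duration <= 0 or self.isi < 0:
            raise ValueError("cue_duration must be > 0 and isi >= 0")
        if self.max_cues < 2:
            raise ValueError("max_cues must be >= 2")

    @property
    def soa(self) -> float:
        """Stimulus onset asynchrony in seconds (cue_duration + isi)."""
        return self.cue_duration + self.isi


@dataclass
class TrialRecord:
    """One trial: the sampled cue sequence and the response.

    ``choice`` is -1 (left), +1 (right) or None for trials on which the
    agent never committed; ``rt`` is seconds from the onset of the final
    sampled cue.  ``n_sampled`` always equals ``len(cues)``.
    """

    trial_id: int
    true_direction: int
    cues: np.ndarray
    choice: int | None
    rt: float | None = None
    n_sampled: int = field(default=0)

    def __post_init__(self):
        self.cues = cues_to_array(self.cues)
        self.true_direction = cue_to_int(self.true_direction)
        if self.choice is not None:
            self.choice = cue_to_int(self.choice)
        if self.n_sampled == 0:
            self.n_sampled = len(self.cues)
        if self.choice is not None and self.n_sampled != len(self.cues):
            raise ValueError("n_sampled must equal len(cues) on completed trials")

    @property
    def completed(self) -> bool:
        return self.choice is not None

    @property
    def correct(self) -> bool | None:
        if self.choice is None:
            return None
        return self.choice == self.true_direction


@dataclass(frozen=True)
class BehaviorSummary:
    """Aggregate behavior over a set of trials (fractions all in [0, 1])."""

    accuracy: float
    mean_n_sampled: float
    mean_rt: float
    frac_same_end: float
    ideal_accuracy: float
    n_trials: int
    n_incomplete: int


def analytic_same_pair_prob(validity: float) -> float:
    """Probability that two consecutive independent cues are identical.

    Each cue independently matches the true direction with probability
    ``validity`` = v, so consecutive cues agree with probability
    v^2 + (1 - v)^2 (0.58 at v = 0.7).
    """
    v = float(validity)
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"validity must lie in [0, 1], got {v}")
    return v * v + (1.0 - v) * (1.0 - v)


def ideal_observer_choice(cues: Sequence, rng: np.random.Generator) -> int:
    """Majority vote over the sampled cues; exact ties broken by a fair coin."""
    arr = cues_to_array(cues)
    total = int(arr.sum())
    if total > 0:
        return 1
    if total < 0:
        return -1
    return 1 if rng.random() < 0.5 else -1


def _ideal_correct_expectation(trial: TrialRecord) -> float:
    """P(ideal observer is correct | sampled cues); ties credit 0.5."""
    total = int(trial.cues.sum())
    if total == 0:
        return 0.5
    return 1.0 if (1 if total > 0 else -1) == trial.true_direction else 0.0


def summarize_behavior(
    trials: Sequence[TrialRecord],
    cfg: TaskConfig | None = None,
    *,
    tie_rule: str = "expected",
    rng: np.random.Generator | None = None,
) -> BehaviorSummary:
    """Summarize accuracy, sampling and same-pair statistics over trials.

    ``ideal_accuracy`` is the accuracy a majority-vote observer would have
    achieved on the very cue sequences the agent sampled.  With
    ``tie_rule="expected"`` (default) an exact tie contributes 0.5; with
    ``tie_rule="random"`` a coin is drawn from ``rng``, which then must be
    supplied.  ``frac_same_end`` is computed over completed trials with at
    least two sampled cues.
    """
    completed = [t for t in trials if t.completed]
    if not completed:
        raise ValueError("no completed trials to summarize")
    if tie_rule not in ("expected", "random"):
        raise ValueError("tie_rule must be 'expected' or 'random'")

    acc = float(np.mean([t.correct for t in completed]))
    mean_n = float(np.mean([t.n_sampled for t in completed]))
    rts = [t.rt for t in completed if t.rt is not None]
    mean_rt = float(np.mean(rts)) if rts else math.nan

    multi = [t for t in completed if t.n_sampled >= 2]
    if multi:
        frac_same = float(np.mean([t.cues[-1] == t.cues[-2] for t in multi]))
    else:
        frac_same = math.nan

    if tie_rule == "expected":
        ideal = float(np.mean([_ideal_correct_expectation(t) for t in completed]))
    else:
        if rng is None:
            raise ValueError("tie_rule='random' requires an rng")
        ideal = float(
            np.mean(
                [ideal_observer_choice(t.cues, rng) == t.true_direction for t in completed]
            )
        )

    return BehaviorSummary(
        accuracy=acc,
        mean_n_sampled=mean_n,
        mean_rt=mean_rt,
        frac_same_end=frac_same,
        ideal_accuracy=ideal,
        n_trials=len(completed),
        n_incomplete=len(trials) - len(completed),
    )
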