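"""Trial-level metrics for the sequential isometric pinch task.

A trial navigates a force-controlled cursor through five targets
(gates 1-4 plus the end gate).  A trial is an error when at least one of
the five targets is under- or overshot.  Per block (30 trials by default)
we compute the error rate, an aggregate movement time, and the composite
skill score

    a = (1 - ER) / (ER * (ln MT)^b),      b = 5.424,

which quantifies the speed-accuracy trade-off: higher is more skilled.
The exponent ``b`` is a task constant established for this pinch task.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: task constant of the speed-accuracy trade-off for the pinch task
DEFAULT_B_EXPONENT = 5.424

#: number of scored targets per trial: gates 1-4 plus the end gate
N_GATES = 5

#: single-letter encodings used in the trial CSV dialect
OUTCOME_CODES = ("H", "O", "U")  # hit, overshoot, undershoot

GATE_COLUMNS = [f"g{i}" for i in range(1, N_GATES + 1)]

TRIAL_COLUMNS = [
    "subject", "group", "day", "block", "trial", "hand", "movement_time",
    *GATE_COLUMNS, "is_error",
]

SEQUENCE_COLUMNS = [
    "subject", "group", "day", "block", "trial", "movement_time",
    "n_wrong_presses",
]


@dataclass(frozen=True)
class TrialRecord:
    """One executed pinch-task trial."""

    subject_id: str
    group: str
    day: int
    block: int
    trial: int
    hand: str
    movement_time: float
    gate_outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.movement_time <= 0:
            raise ValueError("movement_time must be positive")
        if len(self.gate_outcomes) != N_GATES:
            raise ValueError(f"expected {N_GATES} gate outcomes, "
                             f"got {len(self.gate_outcomes)}")
        bad = set(self.gate_outcomes) - set(OUTCOME_CODES)
        if bad:
            raise ValueError(f"unknown gate outcome codes: {sorted(bad)}")
        if self.hand not in ("right", "left"):
            raise ValueError(f"hand must be 'right' or 'left', got {self.hand!r}")

    @property
    def is_error(self) -> bool:
        """True iff any of the five targets was under- or overshot."""
        return any(o != "H" for o in self.gate_outcomes)


@dataclass(frozen=True)
class BlockSummary:
    """Per subject/day/block aggregate of the pinch task."""

    subject_id: str
    group: str
    day: int
    block: int
    n_trials: int
    error_rate: float
    movement_time: float
    skill: float
    b_exponent: float = DEFAULT_B_EXPONENT
    hand: str = "right"


@dataclass(frozen=True)
class SequenceBlockSummary:
    """Per block aggregate of the 10-element keypress sequence task."""

    subject_id: str
    group: str
    day: int
    block: int
    n_trials: int
    error_rate: float          # fraction of non-errorless sequences
    movement_time: float       # mean time from first to 10th correct press


def adjusted_error_rate(error_rate: float, n_trials: int) -> float:
    """Boundary-corrected error rate.

    The skill formula is undefined at ER = 0 and ER = 1; the standard
    continuity correction clips to half a trial's worth of probability
    mass, keeping the score finite and monotone.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    half = 0.5 / n_trials
    return min(max(error_rate, half), 1.0 - half)


def skill_measure(
    error_rate: float,
    movement_time: float,
    b_exponent: float = DEFAULT_B_EXPONENT,
    n_trials: int = 30,
) -> float:
    """Composite speed-accuracy skill score a = (1-ER')/(ER'*(ln MT)^b).

    Parameters
    ----------
    error_rate
        Fraction of error trials in the block, in [0, 1].  Boundary values
        are continuity-corrected by half a trial (see
        :func:`adjusted_error_rate`).
    movement_time
        Block-aggregate movement time in seconds.  Must exceed 1 s: for
        MT <= 1 the logarithm is non-positive and the non-integer power
        is undefined.
    b_exponent
        Task constant, default 5.424.
    n_trials
        Number of trials behind ``error_rate``; sets the boundary
        correction.

    Returns
    -------
    float
        Skill score; strictly decreasing in the adjusted error rate and,
        for MT > 1 s, in movement time.
    """
    if movement_time <= 1.0:
        raise ValueError(
            f"movement_time must exceed 1 s (got {movement_time}); "
            "ln(MT) <= 0 makes the skill score undefined")
    er = adjusted_error_rate(error_rate, n_trials)
    return (1.0 - er) / (er * math.log(movement_time) ** b_exponent)


def _single_key(trials: pd.DataFrame, cols: Sequence[str]) -> None:
    for c in cols:
        if trials[c].nunique() != 1:
            raise ValueError(
                f"trials span multiple values of {c!r}: "
                f"{sorted(trials[c].unique())}")


def summarize_block(
    trials: pd.DataFrame,
    b_exponent: float = DEFAULT_B_EXPONENT,
    mt_aggregate: str = "mean",
) -> BlockSummary:
    """Aggregate one subject's block of trials into a :class:`BlockSummary`.

    ``trials`` is a long-format frame with the trial CSV schema
    (``subject, group, day, block, trial, hand, movement_time, g1..g5,
    is_error``).  All rows must share subject/day/block/hand.

    ``mt_aggregate`` selects the block movement-time aggregate:
    ``"mean"`` (default) or ``"median"``.
    """
    if len(trials) == 0:
        raise ValueError("cannot summarize an empty block")
    _single_key(trials, ["subject", "day", "block", "hand"])
    if mt_aggregate == "mean":
        mt = float(trials["movement_time"].mean())
    elif mt_aggregate == "median":
        mt = float(trials["movement_time"].median())
    else:
        raise ValueError(f"unknown mt_aggregate {mt_aggregate!r}")
    n = len(trials)
    err = float(trials["is_error"].astype(bool).mean())
    return BlockSummary(
        subject_id=str(trials["subject"].iloc[0]),
        group=str(trials["group"].iloc[0]),
        day=int(trials["day"].iloc[0]),
        block=int(trials["block"].iloc[0]),
        hand=str(trials["hand"].iloc[0]),
        n_trials=n,
        error_rate=err,
        movement_time=mt,
        skill=skill_measure(err, mt, b_exponent, n),
        b_exponent=b_exponent,
    )


def summarize_trials(
    trials: pd.DataFrame,
    b_exponent: float = DEFAULT_B_EXPONENT,
    mt_aggregate: str = "mean",
) -> pd.DataFrame:
    """Summarize a whole trial table into one row per subject/day/block/hand."""
    if len(trials) == 0:
        raise ValueError("cannot summarize an empty trial table")
    rows = []
    for _, grp in trials.groupby(["subject", "hand", "day", "block"], sort=True):
        s = summarize_block(grp, b_exponent, mt_aggregate)
        rows.append({
            "subject": s.subject_id, "group": s.group, "day": s.day,
            "block": s.block, "hand": s.hand, "n_trials": s.n_trials,
            "error_rate": s.error_rate, "movement_time": s.movement_time,
            "skill": s.skill,
        })
    return pd.DataFrame(rows).sort_values(
        ["group", "subject", "hand", "day", "block"]).reset_index(drop=True)


def decompose_errors(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-gate decomposition of outcomes into hit/overshoot/undershoot rates.

    Returns a frame indexed by gate (1-5) with columns ``hit_rate``,
    ``overshoot_rate``, ``undershoot_rate`` that sum to 1 per gate.
    """
    if len(trials) == 0:
        raise ValueError("cannot decompose an empty trial table")
    n = len(trials)
    rows = []
    for i, col in enumerate(GATE_COLUMNS, start=1):
        counts = trials[col].value_counts()
        rows.append({
            "gate": i,
            "hit_rate": counts.get("H", 0) / n,
            "overshoot_rate": counts.get("O", 0) / n,
            "undershoot_rate": counts.get("U", 0) / n,
        })
    return pd.DataFrame(rows).set_index("gate")


def summarize_sequence_block(trials: pd.DataFrame) -> SequenceBlockSummary:
    """Aggregate one block of sequence-task trials.

    The error rate is the fraction of sequences that were not errorless
    (at least one wrong key press); movement time is the mean time from
    the first to the 10th correct press.
    """
    if len(trials) == 0:
        raise ValueError("cannot summarize an empty sequence block")
    _single_key(trials, ["subject", "day", "block"])
    n = len(trials)
    errorless = (trials["n_wrong_presses"] == 0).sum()
    return SequenceBlockSummary(
        subject_id=str(trials["subject"].iloc[0]),
        group=str(trials["group"].iloc[0]),
        day=int(trials["day"].iloc[0]),
        block=int(trials["block"].iloc[0]),
        n_trials=n,
        error_rate=1.0 - errorless / n,
        movement_time=float(trials["movement_time"].mean()),
    )


def summarize_sequence_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """One summary row per subject/day/block of a sequence trial table."""
    if len(trials) == 0:
        raise ValueError("cannot summarize an empty sequence trial table")
    rows = []
    for _, grp in trials.groupby(["subject", "day", "block"], sort=True):
        s = summarize_sequence_block(grp)
        rows.append({
            "subject": s.subject_id, "group": s.group, "day": s.day,
            "block": s.block, "n_trials": s.n_trials,
            "error_rate": s.error_rate, "movement_time": s.movement_time,
        })
    return pd.DataFrame(rows).sort_values(
        ["group", "subject", "day", "block"]).reset_index(drop=True)
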