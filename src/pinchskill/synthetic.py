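"""Synthetic behavioral data with the structure the analyses assume.

The generator emulates the study conditions end to end so every analysis
stage is testable without the human dataset:

* pinch-task trial tables — 2-3 groups x 1-4 days x 4 blocks x 30
  trials, group-specific learning rates on the skill scale, lognormal
  movement times with a 1.2 s floor, per-gate force execution with
  calibrated noise, and a fatigue-induced *overshoot* bias that is
  strongest at the low-force gates (modeled as a multiplicative upward
  force bias shrinking linearly with target force);
* block-level skill series — skill = baseline + slope * (block-1) +
  Gaussian noise, the minimal generative model for calibration and
  recovery studies of the inference machinery;
* force traces — exponential MVC decline during sustained contraction
  (control arm: flat 5% MVC), calibrated by default so the force halves
  ... reaches 40% MVC near the observed ~69 s time-to-fatigue;
* sequence-task trials — 10 per-press lognormal times with per-block
  speedup and a per-press wrong-key probability, identical across groups
  (the study found no fatigue effect on this task, so the generator's
  structure is null by construction).

Seed discipline: the master seed spawns one substream per (group,
subject), so adding a subject never perturbs existing subjects' data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fatigue import ForceTrace
from .metrics import DEFAULT_B_EXPONENT, GATE_COLUMNS

#: per-block decline reaching ~40% MVC at ~69 s: ln(2.5)/68.91
DEFAULT_MVC_DECAY = math.log(2.5) / 68.91


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one experimental group.

    ``slope_per_block`` may be a scalar (same every day) or one value per
    day.  ``fatigue_bias`` is the overshoot bias magnitude beta applied
    on ``fatigue_days``: executed force = target * (1 + beta * (1 -
    F_target/F_max)) + noise, so low-force gates get the largest upward
    push.  Skill-scale presets default to slope magnitudes of the order
    observed for fatigued vs non-fatigued learners (~0.17 vs ~0.04 per
    block); they are plausible config values, not ground truth.
    """

    label: str
    n_subjects: int
    baseline_skill: float = 0.35
    slope_per_block: float | Sequence[float] = 0.17
    day_carryover: float = 0.25
    fatigue_bias: float = 0.0
    fatigue_days: tuple[int, ...] = (1,)
    # left-hand transfer blocks (only simulated when transfer_trials > 0)
    transfer_baseline: float = 0.25
    transfer_gain: float = 0.13

    def slope_for_day(self, day: int) -> float:
        if np.isscalar(self.slope_per_block):
            return float(self.slope_per_block)
        seq = list(self.slope_per_block)
        return float(seq[min(day, len(seq)) - 1])


@dataclass(frozen=True)
class MovementTimeModel:
    """Lognormal movement-time model with per-block speedup.

    The median MT starts at ``start_median`` seconds and shrinks by a
    factor exp(-block_decay) per block; draws below ``floor`` (default
    1.2 s, keeping ln(MT) safely positive) are clipped up.
    """

    start_median: float = 3.2
    block_decay: float = 0.04
    sigma: float = 0.15
    floor: float = 1.2

    def median(self, block: int) -> float:
        return self.start_median * math.exp(-self.block_decay * (block - 1))


@dataclass(frozen=True)
class GateLayout:
    """Force targets as fractions of MVC; gate 2 demands the most force."""

    centers: tuple[float, ...] = (0.12, 0.357, 0.18, 0.28, 0.09)
    width_fraction: float = 0.12    # window half-width as fraction of center

    def __post_init__(self) -> None:
        if len(self.centers) != len(GATE_COLUMNS):
            raise ValueError(f"need {len(GATE_COLUMNS)} gate centers")
        for c in self.centers:
            upper = c * (1.0 + self.width_fraction)
            if not 0.0 < upper <= 0.40 + 1e-12:
                raise ValueError(
                    f"gate upper limit {upper:.3f} outside (0, 0.40]")

    def windows(self, mvc: float) -> np.ndarray:
        """(n_gates, 2) lower/upper force bounds in Newtons."""
        c = np.asarray(self.centers) * mvc
        h = c * self.width_fraction
        return np.stack([c - h, c + h], axis=1)


@dataclass(frozen=True)
class MVCModel:
    """Baseline MVC and its exponential decline under sustained effort."""

    baseline_n: float = 100.0
    decay_rate: float = DEFAULT_MVC_DECAY
    noise_sd: float = 0.0
    between_subject_sd: float = 8.0


@dataclass(frozen=True)
class SequenceParams:
    """10-element sequence task: per-press times and wrong-press rate."""

    n_elements: int = 10
    press_median_start: float = 0.50
    press_block_decay: float = 0.10
    press_sigma: float = 0.20
    wrong_press_prob: float = 0.02


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative description of one simulated experiment."""

    groups: tuple[GroupParams, ...]
    days: int = 2
    blocks_per_day: int = 4
    trials_per_block: int = 30
    transfer_trials: int = 0        # left-hand pre/post block size (Exp 2)
    mt: MovementTimeModel = field(default_factory=MovementTimeModel)
    gates: GateLayout = field(default_factory=GateLayout)
    mvc: MVCModel = field(default_factory=MVCModel)
    sequence: SequenceParams = field(default_factory=SequenceParams)
    b_exponent: float = DEFAULT_B_EXPONENT
    #: fix the per-trial error probability instead of deriving it from the
    #: skill trajectory (0 disables execution noise entirely)
    error_rate_override: float | None = None
    transduction_k: float = 10.0    # screen units per log force unit
    transduction_f0: float = 1.0    # N; softening constant
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.days < 1 or self.blocks_per_day < 1 or self.trials_per_block < 1:
            raise ValueError("days/blocks_per_day/trials_per_block must be >= 1")
        if self.mt.floor <= 1.0:
            raise ValueError("mt.floor must exceed 1 s for ln(MT) > 0")
        if not self.groups:
            raise ValueError("groups must be non-empty")


def transduce_force(force, k: float = 10.0, f0: float = 1.0):
    """Logarithmic force-to-cursor transduction x = k * ln(1 + F/f0)."""
    f = np.asarray(force, dtype=float)
    if (f < 0).any():
        raise ValueError("force must be non-negative")
    out = k * np.log1p(f / f0)
    return float(out) if out.ndim == 0 else out


def invert_transduction(position, k: float = 10.0, f0: float = 1.0):
    """Inverse of :func:`transduce_force`: F = f0 * (exp(x/k) - 1)."""
    x = np.asarray(position, dtype=float)
    out = f0 * np.expm1(x / k)
    return float(out) if out.ndim == 0 else out


def _subject_rng(master_seed: int, group_index: int, subject_index: int,
                 stream: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(
        master_seed, spawn_key=(group_index, subject_index, stream))
    return np.random.default_rng(ss)


def target_error_rate(skill: float, movement_time: float,
                      b_exponent: float = DEFAULT_B_EXPONENT) -> float:
    """Error rate at which a block of given MT realizes a target skill.

    Inverts the skill formula: ER = 1 / (1 + a * (ln MT)^b), clipped to
    [0.02, 0.95] so degenerate blocks stay simulable.
    """
    a = max(skill, 1e-6)
    er = 1.0 / (1.0 + a * math.log(movement_time) ** b_exponent)
    return float(np.clip(er, 0.02, 0.95))


def _gate_noise_sd(windows: np.ndarray, p_error: float) -> np.ndarray:
    """Per-gate Gaussian execution noise calibrated to a trial error rate.

    With unbiased execution centered in each window, P(miss gate) = q
    with (1-q)^5 = 1 - p_error; the noise SD solves 2*Phi(-h/sd) = q for
    each gate half-width h.
    """
    from scipy.stats import norm
    n_gates = windows.shape[0]
    if p_error <= 0.0:
        return np.zeros(n_gates)
    q = 1.0 - (1.0 - p_error) ** (1.0 / n_gates)
    q = min(max(q, 1e-9), 1 - 1e-9)
    z = norm.ppf(1.0 - q / 2.0)
    half = (windows[:, 1] - windows[:, 0]) / 2.0
    return half / z


def simulate_skill_series(
    n_subjects: int,
    n_blocks: int = 4,
    baseline: float = 0.35,
    slope: float = 0.17,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Block-level skill series: baseline + slope*(block-1) + N(0, sd).

    The minimal generative model used for calibration and parameter
    recovery of the learning-rate and permutation machinery; returns an
    (n_subjects, n_blocks) matrix.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    blocks = np.arange(n_blocks)
    return (baseline + slope * blocks[None, :]
            + rng.normal(0.0, noise_sd, size=(n_subjects, n_blocks)))


def _simulate_block_trials(rng: np.random.Generator, cfg: SimulationConfig,
                           gp: GroupParams, subject: str, day: int,
                           block: int, hand: str, n_trials: int,
                           skill_target: float, mvc: float,
                           biased: bool) -> list[dict]:
    mt_med = cfg.mt.median(block)
    if cfg.error_rate_override is not None:
        p_err = cfg.error_rate_override
    else:
        p_err = target_error_rate(skill_target, mt_med, cfg.b_exponent)
    windows = cfg.gates.windows(mvc)
    centers = windows.mean(axis=1)
    sds = _gate_noise_sd(windows, p_err)
    f_max = centers.max()
    if biased and gp.fatigue_bias > 0:
        bias = gp.fatigue_bias * (1.0 - centers / f_max)
    else:
        bias = np.zeros_like(centers)

    mts = mt_med * np.exp(rng.normal(0.0, cfg.mt.sigma, size=n_trials))
    mts = np.maximum(mts, cfg.mt.floor)
    executed = (centers[None, :] * (1.0 + bias[None, :])
                + rng.normal(0.0, 1.0, size=(n_trials, len(centers))) * sds)
    over = executed > windows[:, 1]
    under = executed < windows[:, 0]
    outcome = np.where(over, "O", np.where(under, "U", "H"))

    rows = []
    for t in range(n_trials):
        row = {
            "subject": subject, "group": gp.label, "day": day,
            "block": block, "trial": t + 1, "hand": hand,
            "movement_time": float(mts[t]),
        }
        for gi, col in enumerate(GATE_COLUMNS):
            row[col] = str(outcome[t, gi])
        row["is_error"] = bool((outcome[t] != "H").any())
        rows.append(row)
    return rows


def simulate_pinch_experiment(
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a full pinch-task trial table plus a ground-truth record.

    Per trial the movement time is drawn from the decaying lognormal and
    each gate's executed force is the target center, pushed up by the
    fatigue bias on fatigue days, plus signal-dependent Gaussian noise
    calibrated so the unbiased per-trial error probability matches the
    group's skill trajectory.  Deterministic under a fixed seed.

    Returns ``(trials, truth)`` where ``truth`` records the configured
    skill trajectories and per-block target error rates.
    """
    master = config.master_seed if seed is None else seed
    rows: list[dict] = []
    truth: dict = {"master_seed": int(master), "groups": {}}
    for g_idx, gp in enumerate(config.groups):
        if gp.n_subjects < 1:
            raise ValueError(f"group {gp.label!r}: n_subjects must be >= 1")
        gtruth = {"per_day_slope": {}, "target_error_rate": {}}
        for day in range(1, config.days + 1):
            gtruth["per_day_slope"][day] = gp.slope_for_day(day)
        for s_idx in range(gp.n_subjects):
            subject = f"{gp.label}_{s_idx + 1:02d}"
            rng = _subject_rng(master, g_idx, s_idx)
            mvc = max(config.mvc.baseline_n
                      + rng.normal(0.0, config.mvc.between_subject_sd), 40.0)
            for day in range(1, config.days + 1):
                slope = gp.slope_for_day(day)
                day_base = gp.baseline_skill + gp.day_carryover * (day - 1)
                biased = day in gp.fatigue_days and gp.fatigue_bias > 0
                for block in range(1, config.blocks_per_day + 1):
                    skill_t = day_base + slope * (block - 1)
                    mt_med = config.mt.median(block)
                    gtruth["target_error_rate"][f"d{day}b{block}"] = (
                        config.error_rate_override
                        if config.error_rate_override is not None
                        else target_error_rate(skill_t, mt_med,
                                               config.b_exponent))
                    rows.extend(_simulate_block_trials(
                        rng, config, gp, subject, day, block, "right",
                        config.trials_per_block, skill_t, mvc, biased))
            if config.transfer_trials > 0:
                # untrained left hand: one pre and one post block on day 1
                rng_t = _subject_rng(master, g_idx, s_idx, stream=1)
                for block, skill_t in ((1, gp.transfer_baseline),
                                       (2, gp.transfer_baseline
                                        + gp.transfer_gain)):
                    rows.extend(_simulate_block_trials(
                        rng_t, config, gp, subject, 1, block, "left",
                        config.transfer_trials, skill_t, mvc, False))
        truth["groups"][gp.label] = gtruth
    trials = pd.DataFrame(rows)
    return trials, truth


def simulate_force_trace(
    mvc: float,
    decay_rate: float = DEFAULT_MVC_DECAY,
    duration: float = 120.0,
    noise_sd: float = 0.0,
    sampling_rate: float = 100.0,
    seed: int | np.random.Generator | None = None,
    mode: str = "mvc",
) -> ForceTrace:
    """Sustained-contraction force trace.

    ``mode="mvc"``: F(t) = mvc * exp(-decay_rate * t) + noise, floored at
    zero — the fatigue-induction arm.  ``mode="control"``: flat 5% of
    MVC, the matched control contraction.
    """
    if mvc <= 0 or duration <= 0 or decay_rate < 0 or noise_sd < 0:
        raise ValueError("mvc/duration must be positive; "
                         "decay_rate/noise_sd non-negative")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    if mode == "mvc":
        f = mvc * np.exp(-decay_rate * t)
    elif mode == "control":
        f = np.full_like(t, 0.05 * mvc)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, size=t.size)
    return ForceTrace(sampling_rate=sampling_rate,
                      samples=np.maximum(f, 0.0))


def simulate_sequence_experiment(
    config: SimulationConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the 10-element keypress sequence task.

    Per trial the movement time is the sum of ``n_elements`` per-press
    lognormal times whose median shrinks per block; each press is wrong
    with probability ``wrong_press_prob`` independently.  All groups
    share the same parameters: the task showed no fatigue effect, so the
    generator's group structure is null by construction.
    """
    master = config.master_seed if seed is None else seed
    sq = config.sequence
    rows: list[dict] = []
    for g_idx, gp in enumerate(config.groups):
        for s_idx in range(gp.n_subjects):
            subject = f"{gp.label}_{s_idx + 1:02d}"
            rng = _subject_rng(master, g_idx, s_idx, stream=2)
            for day in range(1, config.days + 1):
                for block in range(1, config.blocks_per_day + 1):
                    med = (sq.press_median_start
                           * math.exp(-sq.press_block_decay * (block - 1))
                           * math.exp(-sq.press_block_decay
                                      * config.blocks_per_day * (day - 1) / 2))
                    for t in range(1, config.trials_per_block + 1):
                        presses = med * np.exp(
                            rng.normal(0.0, sq.press_sigma, sq.n_elements))
                        wrong = int(rng.binomial(sq.n_elements,
                                                 sq.wrong_press_prob))
                        rows.append({
                            "subject": subject, "group": gp.label,
                            "day": day, "block": block, "trial": t,
                            "movement_time": float(presses.sum()),
                            "n_wrong_presses": wrong,
                        })
    return pd.DataFrame(rows)
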