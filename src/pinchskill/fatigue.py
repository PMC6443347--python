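"""Force-trace quantification: MVC, fatigue decrement, time to fatigue.

Maximal voluntary contraction (MVC) is measured from a ~5 s maximal
pinch; fatigue is induced by sustaining MVC until the produced force
drops to the upper limit of gate 2 (the highest-force target, at most
40% of MVC), so the induction always stays above the force range the
task needs.  The decrement fraction 1 - MVC_post/MVC_pre quantifies how
fatigued a subject is (the study criterion is ~60%).

Traces are moving-average smoothed before any threshold logic so that
transducer noise cannot fake a crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

DEFAULT_SMOOTHING_WINDOW = 0.2   # s; rejects transducer noise
DEFAULT_HOLD = 0.5               # s; a crossing must persist this long

#: gate force windows as (lower, upper) fractions of MVC; gate 2 is the
#: highest-force target and its upper limit (40% MVC) is the fatigue
#: stopping threshold
DEFAULT_GATE_WINDOWS = (
    (0.105, 0.135),   # gate 1
    (0.315, 0.400),   # gate 2 — largest force
    (0.160, 0.205),   # gate 3
    (0.250, 0.315),   # gate 4
    (0.080, 0.105),   # end gate
)


@dataclass(frozen=True)
class ForceTrace:
    """A sampled pinch-force recording in Newtons."""

    sampling_rate: float
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if (self.samples < 0).any():
            raise ValueError("forces must be non-negative")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class FatigueSummary:
    """Per subject-session fatigue quantification."""

    mvc_pre: float
    mvc_post: float
    decrement_fraction: float
    threshold_force: float
    time_to_fatigue: float | None   # None = threshold never reached


def _smooth(trace: ForceTrace, window: float) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average; returns (times, smoothed values)."""
    w = max(1, int(round(window * trace.sampling_rate)))
    if w > trace.samples.size:
        raise ValueError("smoothing window longer than the trace")
    kernel = np.full(w, 1.0 / w)
    sm = np.convolve(trace.samples, kernel, mode="valid")
    t = (np.arange(sm.size) + (w - 1) / 2.0) / trace.sampling_rate
    return t, sm


def mvc_from_trace(trace: ForceTrace,
                   smoothing_window: float = DEFAULT_SMOOTHING_WINDOW) -> float:
    """MVC as the maximum of the moving-average-smoothed trace."""
    _, sm = _smooth(trace, smoothing_window)
    return float(sm.max())


def gate2_threshold(mvc: float,
                    gate_windows: Sequence[Sequence[float]] = DEFAULT_GATE_WINDOWS,
                    ) -> float:
    """Fatigue stopping threshold: MVC times the largest gate upper limit.

    ``gate_windows`` are (lower, upper) force-window fractions of MVC,
    all within (0, 1); with the default task layout the largest upper
    limit is gate 2's 0.40, giving 0.40 * MVC.
    """
    if mvc <= 0:
        raise ValueError("mvc must be positive")
    uppers = []
    for lo, hi in gate_windows:
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"gate window ({lo}, {hi}) outside (0, 1)")
        uppers.append(hi)
    return mvc * max(uppers)


def time_to_fatigue(trace: ForceTrace,
                    threshold_force: float,
                    hold: float = DEFAULT_HOLD,
                    smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
                    ) -> float | None:
    """First time the smoothed force stays below threshold for >= hold.

    Brief dips shorter than ``hold`` seconds are ignored.  Returns the
    time (s) at which the qualifying crossing begins, or ``None`` if the
    force never stays below the threshold.  The trace must start above
    the threshold.
    """
    t, sm = _smooth(trace, smoothing_window)
    if sm[0] <= threshold_force:
        raise ValueError("trace starts at or below the threshold")
    below = sm < threshold_force
    need = max(1, int(round(hold * trace.sampling_rate)))
    # run-length scan over the boolean 'below' vector
    run_start = None
    run_len = 0
    for i, b in enumerate(below):
        if b:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len >= need:
                return float(t[run_start])
        else:
            run_len = 0
    # a trailing run shorter than 'hold' that lasts to the end of the
    # trace still counts: the force never recovered
    if run_len > 0:
        return float(t[run_start])
    return None


def fatigue_decrement(mvc_pre: float, mvc_post: float) -> float:
    """Fractional MVC loss: 1 - MVC_post / MVC_pre."""
    if mvc_pre <= 0:
        raise ValueError("mvc_pre must be positive")
    if mvc_post < 0:
        raise ValueError("mvc_post must be non-negative")
    return 1.0 - mvc_post / mvc_pre


def summarize_fatigue(trace_pre: ForceTrace,
                      trace_sustained: ForceTrace,
                      trace_post: ForceTrace,
                      gate_windows: Sequence[Sequence[float]] = DEFAULT_GATE_WINDOWS,
                      smoothing_window: float = DEFAULT_SMOOTHING_WINDOW,
                      hold: float = DEFAULT_HOLD) -> FatigueSummary:
    """Full per-session fatigue summary from the three recorded traces."""
    mvc_pre = mvc_from_trace(trace_pre, smoothing_window)
    mvc_post = mvc_from_trace(trace_post, smoothing_window)
    threshold = gate2_threshold(mvc_pre, gate_windows)
    t2f = time_to_fatigue(trace_sustained, threshold, hold, smoothing_window)
    return FatigueSummary(
        mvc_pre=mvc_pre, mvc_post=mvc_post,
        decrement_fraction=fatigue_decrement(mvc_pre, mvc_post),
        threshold_force=threshold, time_to_fatigue=t2f)
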