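"""Learning-rate estimation by robust linear regression.

Skill is roughly linear in block number within a day, so the slope of a
line fit to (block, skill) points is the learning rate.  The fit is a
robust regression estimated by iteratively reweighted least squares
(IRLS) with a Tukey bisquare weight function (Huber selectable), which
downweights outlying blocks instead of letting them dominate the slope.

The IRLS core is written in batch form: a whole matrix of resampled
y-vectors sharing one x-vector is fit simultaneously, which is what makes
10,000-resample permutation tests cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

DEFAULT_TUNING = {"bisquare": 4.685, "huber": 1.345}
#: MAD-to-sigma consistency factor for Gaussian residuals
_MAD_NORM = 0.6745

WeightFunction = Literal["bisquare", "huber", "unit"]


@dataclass(frozen=True)
class GroupLearningFit:
    """Pooled robust-regression fit for one group-day.

    ``slope`` is the learning rate (skill units per block); ``intercept``
    is the regression constant.  ``point_weights`` are the final IRLS
    weights in [0, 1], one per pooled (block, skill) point.
    """

    slope: float
    intercept: float
    point_weights: np.ndarray
    n_points: int
    iterations: int
    converged: bool
    group: str | None = None
    day: int | None = None


def _weights(u: np.ndarray, kind: str) -> np.ndarray:
    """IRLS weights for scaled residuals u = r / (tuning * scale)."""
    au = np.abs(u)
    if kind == "bisquare":
        w = np.where(au < 1.0, (1.0 - np.minimum(au, 1.0) ** 2) ** 2, 0.0)
    elif kind == "huber":
        w = np.where(au <= 1.0, 1.0, 1.0 / np.maximum(au, 1e-300))
    else:
        raise ValueError(f"unknown weight function {kind!r}")
    return w


def _wls_line(x: np.ndarray, Y: np.ndarray, W: np.ndarray):
    """Closed-form weighted LS line per row of Y. x: (m,), Y, W: (B, m)."""
    sw = W.sum(axis=1)
    swx = W @ x
    swxx = W @ (x * x)
    swy = (W * Y).sum(axis=1)
    swxy = (W * Y) @ x
    denom = sw * swxx - swx * swx
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    return slope, intercept


def batch_irls_line(
    x: np.ndarray,
    Y: np.ndarray,
    weight_function: WeightFunction = "bisquare",
    tuning: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Fit y = a + c*x robustly to every row of ``Y`` against a shared ``x``.

    Returns ``(slope, intercept, weights, iterations, converged)`` with
    per-row arrays.  ``weight_function="unit"`` reproduces ordinary least
    squares exactly (single weighted solve, weights all one).
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    B, m = Y.shape
    if x.shape != (m,):
        raise ValueError("x and rows of Y must have equal length")
    if m < 3:
        raise ValueError("need at least 3 points per fit")
    if np.ptp(x) == 0.0:
        raise ValueError("x has zero variance; slope is undefined")

    W = np.ones_like(Y)
    slope, intercept = _wls_line(x, Y, W)
    iterations = np.ones(B, dtype=int)
    converged = np.ones(B, dtype=bool)
    if weight_function == "unit":
        return slope, intercept, W, iterations, converged

    if tuning is None:
        tuning = DEFAULT_TUNING[weight_function]

    converged = np.zeros(B, dtype=bool)
    active = np.arange(B)
    for it in range(1, max_iter + 1):
        r = Y[active] - (intercept[active, None] + slope[active, None] * x)
        med = np.median(r, axis=1, keepdims=True)
        scale = np.median(np.abs(r - med), axis=1) / _MAD_NORM
        # zero scale: the current fit is exact on (at least) the weighted
        # majority of points — converged as is, do not refit
        exact = scale <= 1e-12 * np.maximum(1.0, np.abs(Y[active]).max(axis=1))
        if exact.any():
            iterations[active[exact]] = it
            converged[active[exact]] = True
            keep = ~exact
            active = active[keep]
            r, scale = r[keep], scale[keep]
            if active.size == 0:
                break
        u = r / (tuning * scale[:, None])
        Wa = _weights(u, weight_function)
        # guard degenerate rows where every point got zero weight
        dead = Wa.sum(axis=1) < 1e-12
        if dead.any():
            Wa[dead] = 1.0
        new_slope, new_intercept = _wls_line(x, Y[active], Wa)
        delta = np.maximum(np.abs(new_slope - slope[active]),
                           np.abs(new_intercept - intercept[active]))
        slope[active] = new_slope
        intercept[active] = new_intercept
        W[active] = Wa
        iterations[active] = it
        done = delta < tol
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    return slope, intercept, W, iterations, converged


def irls_regression(
    x,
    y,
    weight_function: WeightFunction = "bisquare",
    tuning: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GroupLearningFit:
    """Robust line fit of a single (x, y) dataset via IRLS.

    With small residuals relative to ``tuning * scale`` all weights are 1
    and the result coincides with ordinary least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    slope, intercept, W, iters, conv = batch_irls_line(
        x, y[None, :], weight_function, tuning, tol, max_iter)
    return GroupLearningFit(
        slope=float(slope[0]),
        intercept=float(intercept[0]),
        point_weights=W[0],
        n_points=x.size,
        iterations=int(iters[0]),
        converged=bool(conv[0]),
    )


def fit_group_learning(
    summaries: pd.DataFrame,
    weight_function: WeightFunction = "bisquare",
    pooling: Literal["pooled", "per_subject"] = "pooled",
    **irls_kwargs,
) -> GroupLearningFit:
    """Learning rate of one group on one day from its block summaries.

    ``summaries`` holds one row per subject x block with columns
    ``subject, group, day, block, skill``; all rows must share group and
    day.  The default pools every subject's (block, skill) points into a
    single robust regression; ``pooling="per_subject"`` instead fits each
    subject separately and averages the slopes (sensitivity mode).
    """
    for col in ("subject", "block", "skill"):
        if col not in summaries.columns:
            raise ValueError(f"summaries missing column {col!r}")
    if summaries["block"].nunique() < 2:
        raise ValueError("need at least 2 distinct blocks to fit a slope")
    if summaries["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects for a group fit")
    group = str(summaries["group"].iloc[0]) if "group" in summaries else None
    day = int(summaries["day"].iloc[0]) if "day" in summaries else None
    if "group" in summaries and summaries["group"].nunique() > 1:
        raise ValueError("summaries span multiple groups")
    if "day" in summaries and summaries["day"].nunique() > 1:
        raise ValueError("summaries span multiple days")

    if pooling == "pooled":
        fit = irls_regression(
            summaries["block"].to_numpy(float),
            summaries["skill"].to_numpy(float),
            weight_function, **irls_kwargs)
        return GroupLearningFit(
            slope=fit.slope, intercept=fit.intercept,
            point_weights=fit.point_weights, n_points=fit.n_points,
            iterations=fit.iterations, converged=fit.converged,
            group=group, day=day)
    if pooling == "per_subject":
        fits = [
            irls_regression(g["block"].to_numpy(float),
                            g["skill"].to_numpy(float),
                            weight_function, **irls_kwargs)
            for _, g in summaries.groupby("subject")
        ]
        return GroupLearningFit(
            slope=float(np.mean([f.slope for f in fits])),
            intercept=float(np.mean([f.intercept for f in fits])),
            point_weights=np.concatenate([f.point_weights for f in fits]),
            n_points=int(sum(f.n_points for f in fits)),
            iterations=max(f.iterations for f in fits),
            converged=all(f.converged for f in fits),
            group=group, day=day)
    raise ValueError(f"unknown pooling mode {pooling!r}")


def transfer_delta(pre, post) -> float:
    """Two-block learning measure: post-block skill minus pre-block skill.

    Used when only two blocks exist (e.g. the untrained hand before and
    after training): the block2 - block1 skill difference stands in for
    the regression slope.  ``pre`` and ``post`` are
    :class:`~pinchskill.metrics.BlockSummary` objects for the same
    subject and hand.
    """
    if pre.subject_id != post.subject_id:
        raise ValueError("pre/post blocks belong to different subjects")
    if pre.hand != post.hand:
        raise ValueError("pre/post blocks belong to different hands")
    if (pre.day, pre.block) >= (post.day, post.block):
        raise ValueError("pre block must precede post block")
    return post.skill - pre.skill
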