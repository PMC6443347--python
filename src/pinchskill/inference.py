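"""Statistical inference on learning rates and block-level outcomes.

The central test is a subject-level permutation test on the difference in
group learning rates: under the null of no group difference, subjects are
randomly reassigned to the two groups (a subject's whole block series
moves together), the pooled regression slopes are recomputed for each
reassignment, and the observed slope difference is located in the
resulting null distribution of differences.  10,000 resamples by default;
for small groups every distinct reassignment can be enumerated exactly.

Also provided: a sign-flip permutation test for within-group day
comparisons, the classical two-way mixed ANOVA (between factor: group;
within factor: block) with Greenhouse-Geisser correction, Student's
t-test, a Shapiro-Wilk normality gate with log-transform fallback, and
Bonferroni adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .learning import batch_irls_line

#: hard cap on exhaustive enumeration, C(20, 10)
_MAX_EXHAUSTIVE = math.comb(20, 10)

Alternative = Literal["two_sided", "greater", "less"]
Estimator = Literal["robust", "ols"]


@dataclass(frozen=True)
class PermutationResult:
    """Observed slope difference, its permutation null, and the p-value."""

    observed_delta: float
    null_deltas: np.ndarray
    p_value: float
    n_perm: int
    alternative: Alternative
    seed: int | None
    exhaustive: bool
    method: str = "subject_relabel"
    estimator: Estimator = "robust"


def _as_block_matrix(series) -> np.ndarray:
    """Coerce a group's block series to an (n_subjects, n_blocks) array."""
    a = np.asarray(series, dtype=float)
    if a.ndim != 2:
        raise ValueError("block series must be 2-D: subjects x blocks")
    if not np.isfinite(a).all():
        raise ValueError("block series contains non-finite values")
    return a


def block_matrix(summaries: pd.DataFrame, value: str = "skill") -> np.ndarray:
    """Pivot long block summaries into a (subjects x blocks) matrix."""
    wide = summaries.pivot_table(index="subject", columns="block",
                                 values=value, sort=True)
    if wide.isna().any().any():
        raise ValueError("incomplete block series: missing subject x block cells")
    return wide.to_numpy(float)


def _pooled_slopes(Y: np.ndarray, x: np.ndarray, estimator: Estimator,
                   chunk: int = 20000) -> np.ndarray:
    """Pooled regression slope per row of Y (rows are flattened groups)."""
    wf = "unit" if estimator == "ols" else "bisquare"
    out = np.empty(Y.shape[0])
    for lo in range(0, Y.shape[0], chunk):
        sl, *_ = batch_irls_line(x, Y[lo:lo + chunk], weight_function=wf)
        out[lo:lo + chunk] = sl
    return out


def _stat(deltas: np.ndarray, alternative: Alternative) -> np.ndarray:
    if alternative == "two_sided":
        return np.abs(deltas)
    if alternative == "greater":
        return deltas
    if alternative == "less":
        return -deltas
    raise ValueError(f"unknown alternative {alternative!r}")


def permutation_slope_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: Alternative = "two_sided",
    exhaustive: bool = False,
    estimator: Estimator = "ols",
    blocks: Sequence[int] | None = None,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation test of the group difference in pooled learning rates.

    ``group_a`` and ``group_b`` are (n_subjects x n_blocks) skill
    matrices (block numbers default to 1..k).  The observed statistic is
    slope(A) - slope(B) from pooled fits; the null is built by relabeling
    whole subjects while preserving group sizes.  Ties count as
    exceeding; ``add_one`` switches to the (c+1)/(n+1) rule.

    The statistic inside the loop (and, for consistency, the observed
    statistic) defaults to the plain pooled OLS slope: when the groups
    truly differ, relabeled pseudo-groups are 50/50 mixtures whose
    residuals are bimodal, and a redescending bisquare fit is bistable on
    such mixtures — it chases one subgroup, inflating the null spread
    several-fold and costing power.  ``estimator="robust"`` selects the
    bisquare statistic instead.

    In exhaustive mode every distinct reassignment of the given sizes is
    enumerated (refused above C(20,10) assignments — use Monte-Carlo).
    """
    A = _as_block_matrix(group_a)
    B = _as_block_matrix(group_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups disagree on number of blocks")
    n_a, k = A.shape
    n_b = B.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    if blocks is None:
        blocks = np.arange(1, k + 1, dtype=float)
    else:
        blocks = np.asarray(blocks, dtype=float)
        if blocks.shape != (k,):
            raise ValueError("blocks must match the number of columns")

    D = np.vstack([A, B])            # (n, k)
    n = n_a + n_b
    x_a = np.tile(blocks, n_a)
    x_b = np.tile(blocks, n_b)

    def delta_for(idx_a: np.ndarray) -> np.ndarray:
        """Slope difference for each row of subject-index assignments."""
        mask = np.zeros((idx_a.shape[0], n), dtype=bool)
        np.put_along_axis(mask, idx_a, True, axis=1)
        Ya = D[np.where(mask)[1]].reshape(idx_a.shape[0], n_a * k)
        idx_b = np.where(~mask)[1].reshape(idx_a.shape[0], n_b)
        Yb = D[idx_b.ravel()].reshape(idx_a.shape[0], n_b * k)
        return (_pooled_slopes(Ya, x_a, estimator)
                - _pooled_slopes(Yb, x_b, estimator))

    observed = float(delta_for(np.arange(n_a)[None, :])[0])

    if exhaustive:
        total = math.comb(n, n_a)
        if total > _MAX_EXHAUSTIVE:
            raise ValueError(
                f"exhaustive enumeration of {total} assignments exceeds the "
                f"cap of {_MAX_EXHAUSTIVE}; use exhaustive=False (Monte-Carlo)")
        combos = np.array(list(itertools.combinations(range(n), n_a)),
                          dtype=np.int64)
        null = delta_for(combos)
        n_eff = total
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_a]
        idx.sort(axis=1)
        null = delta_for(idx)
        n_eff = n_perm

    obs_stat = _stat(np.array([observed]), alternative)[0]
    count = int((_stat(null, alternative) >= obs_stat - 1e-15).sum())
    if add_one:
        p = (count + 1) / (n_eff + 1)
    else:
        p = count / n_eff
    return PermutationResult(
        observed_delta=observed, null_deltas=null, p_value=float(p),
        n_perm=n_eff, alternative=alternative, seed=seed,
        exhaustive=exhaustive, method="subject_relabel", estimator=estimator)


def paired_day_slope_test(
    day1,
    day2,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: Alternative = "two_sided",
    exhaustive: bool = False,
    estimator: Estimator = "ols",
    blocks: Sequence[int] | None = None,
    add_one: bool = False,
) -> PermutationResult:
    """Within-group comparison of learning rates across two days.

    Rows of ``day1`` and ``day2`` are the same subjects in the same
    order.  The statistic is slope(day2) - slope(day1) from pooled fits;
    the null flips each subject's day labels (the subject's two block
    series swap), a sign-flip style resampling of the within-subject day
    assignment.  Exhaustive mode enumerates all 2^n flip patterns.
    """
    D1 = _as_block_matrix(day1)
    D2 = _as_block_matrix(day2)
    if D1.shape != D2.shape:
        raise ValueError("day1/day2 rosters differ in shape; "
                         "the same subjects must appear on both days")
    n, k = D1.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if blocks is None:
        blocks = np.arange(1, k + 1, dtype=float)
    else:
        blocks = np.asarray(blocks, dtype=float)
    x = np.tile(blocks, n)

    def delta_for(flips: np.ndarray) -> np.ndarray:
        """Slope difference per row of {0,1} flip patterns (1 = swap days)."""
        f = flips[:, :, None].astype(bool)            # (B, n, 1)
        Y1 = np.where(f, D2[None], D1[None]).reshape(flips.shape[0], n * k)
        Y2 = np.where(f, D1[None], D2[None]).reshape(flips.shape[0], n * k)
        return (_pooled_slopes(Y2, x, estimator)
                - _pooled_slopes(Y1, x, estimator))

    observed = float(delta_for(np.zeros((1, n), dtype=np.int64))[0])

    if exhaustive:
        total = 2 ** n
        if total > _MAX_EXHAUSTIVE:
            raise ValueError(
                f"exhaustive enumeration of {total} flip patterns exceeds "
                f"the cap of {_MAX_EXHAUSTIVE}; use exhaustive=False")
        flips = np.array(list(itertools.product((0, 1), repeat=n)),
                         dtype=np.int64)
        null = delta_for(flips)
        n_eff = total
    else:
        rng = np.random.default_rng(seed)
        flips = rng.integers(0, 2, size=(n_perm, n))
        null = delta_for(flips)
        n_eff = n_perm

    obs_stat = _stat(np.array([observed]), alternative)[0]
    count = int((_stat(null, alternative) >= obs_stat - 1e-15).sum())
    p = (count + 1) / (n_eff + 1) if add_one else count / n_eff
    return PermutationResult(
        observed_delta=observed, null_deltas=null, p_value=float(p),
        n_perm=n_eff, alternative=alternative, seed=seed,
        exhaustive=exhaustive, method="day_sign_flip", estimator=estimator)


def permutation_mean_test(
    values_a,
    values_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: Alternative = "two_sided",
    add_one: bool = False,
) -> PermutationResult:
    """Permutation test on a difference of group means of scalar values.

    Used for two-block learning measures (e.g. per-subject transfer
    deltas) where each subject contributes a single number rather than a
    block series.  Same relabeling scheme and counting rule as
    :func:`permutation_slope_test`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("need 1-D value vectors with >= 2 subjects per group")
    pooled = np.concatenate([a, b])
    n_a, n = a.size, a.size + b.size
    observed = float(a.mean() - b.mean())
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perm = pooled[idx]
    null = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    obs_stat = _stat(np.array([observed]), alternative)[0]
    count = int((_stat(null, alternative) >= obs_stat - 1e-15).sum())
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return PermutationResult(
        observed_delta=observed, null_deltas=null, p_value=float(p),
        n_perm=n_perm, alternative=alternative, seed=seed,
        exhaustive=False, method="subject_relabel_mean", estimator="ols")


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------

def greenhouse_geisser_epsilon(M: np.ndarray, groups: np.ndarray) -> float:
    """GG sphericity epsilon from the pooled within-group covariance.

    ``M`` is subjects x within-levels; ``groups`` labels each row.  The
    covariance of the k repeated measures is pooled across groups,
    double-centered, and epsilon = tr(S)^2 / ((k-1) * sum(S^2)), bounded
    in [1/(k-1), 1].
    """
    n, k = M.shape
    dev = np.empty_like(M)
    n_groups = 0
    for g in np.unique(groups):
        rows = groups == g
        dev[rows] = M[rows] - M[rows].mean(axis=0, keepdims=True)
        n_groups += 1
    S = dev.T @ dev / (n - n_groups)
    row = S.mean(axis=1, keepdims=True)
    col = S.mean(axis=0, keepdims=True)
    Sc = S - row - col + S.mean()
    eps = np.trace(Sc) ** 2 / ((k - 1) * (Sc * Sc).sum())
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str = "block",
    between: str = "group",
    subject: str = "subject",
) -> pd.DataFrame:
    """Two-way mixed ANOVA: between-subject group, within-subject block.

    Requires a complete balanced within design (every subject observed at
    every within level exactly once); missing cells raise rather than
    impute.  Returns a table with one row per effect (``group``,
    ``block``, ``block * group``) and columns SS, df, MS, F,
    p_uncorrected, and for within effects the Greenhouse-Geisser epsilon
    and the epsilon-corrected p_gg.
    """
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValueError(f"data missing column {col!r}")
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="count", sort=True)
    if wide.isna().any().any() or (wide != 1).any().any():
        raise ValueError("design is not complete/balanced: every subject "
                         "needs exactly one observation per within level")
    subj_group = data.groupby(subject)[between].nunique()
    if (subj_group != 1).any():
        raise ValueError("a subject appears in more than one group")

    pivot = data.pivot_table(index=subject, columns=within, values=dv,
                             sort=True)
    M = pivot.to_numpy(float)
    order = pivot.index
    groups = data.drop_duplicates(subject).set_index(subject)[between]
    groups = groups.loc[order].to_numpy()

    n, k = M.shape
    glabels, gidx = np.unique(groups, return_inverse=True)
    G = glabels.size
    if G < 2:
        raise ValueError("need at least 2 groups")
    n_g = np.bincount(gidx)

    grand = M.mean()
    subj_means = M.mean(axis=1)
    block_means = M.mean(axis=0)
    group_means = np.array([M[gidx == g].mean() for g in range(G)])
    cell_means = np.array([M[gidx == g].mean(axis=0) for g in range(G)])

    ss_total = ((M - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (n_g * (group_means - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_group
    ss_block = n * ((block_means - grand) ** 2).sum()
    ss_inter = (n_g[:, None] * (cell_means - group_means[:, None]
                                - block_means[None, :] + grand) ** 2).sum()
    ss_err_within = ss_total - ss_subj - ss_block - ss_inter

    df_group, df_eb = G - 1, n - G
    df_block = k - 1
    df_inter = (G - 1) * (k - 1)
    df_ew = (n - G) * (k - 1)

    ms_group = ss_group / df_group
    ms_eb = ss_err_between / df_eb
    ms_block = ss_block / df_block
    ms_inter = ss_inter / df_inter
    ms_ew = ss_err_within / df_ew

    f_group = ms_group / ms_eb
    f_block = ms_block / ms_ew
    f_inter = ms_inter / ms_ew

    eps = greenhouse_geisser_epsilon(M, groups)

    rows = [
        {"effect": between, "SS": ss_group, "df": df_group, "MS": ms_group,
         "F": f_group, "p_uncorrected": stats.f.sf(f_group, df_group, df_eb),
         "gg_epsilon": np.nan, "p_gg": np.nan},
        {"effect": within, "SS": ss_block, "df": df_block, "MS": ms_block,
         "F": f_block, "p_uncorrected": stats.f.sf(f_block, df_block, df_ew),
         "gg_epsilon": eps,
         "p_gg": stats.f.sf(f_block, eps * df_block, eps * df_ew)},
        {"effect": f"{within} * {between}", "SS": ss_inter, "df": df_inter,
         "MS": ms_inter, "F": f_inter,
         "p_uncorrected": stats.f.sf(f_inter, df_inter, df_ew),
         "gg_epsilon": eps,
         "p_gg": stats.f.sf(f_inter, eps * df_inter, eps * df_ew)},
    ]
    return pd.DataFrame(rows).set_index("effect")


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def two_sample_t(a, b) -> tuple[float, float, float]:
    """Student's two-sample t-test with pooled variance.

    Returns ``(t, df, p)``.  Degenerate zero-variance samples with equal
    means follow the t = 0, p = 1 convention; zero variance with unequal
    means is an error (the statistic diverges).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per sample")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1)
                  + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        raise ValueError("zero pooled variance with unequal means: "
                         "t statistic is undefined (infinite)")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class NormalityGateResult:
    """Outcome of the Shapiro-Wilk gate applied before parametric tests."""

    values: np.ndarray
    transformed: bool
    shapiro_p: float
    shapiro_p_after: float | None = None


def normality_gate(values, alpha: float = 0.05) -> NormalityGateResult:
    """Shapiro-Wilk screen; natural-log transform on rejection.

    If the W-test rejects normality at ``alpha`` the values are returned
    log-transformed (they must be positive) and flagged; otherwise they
    pass through unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    p = float(stats.shapiro(v).pvalue)
    if p >= alpha:
        return NormalityGateResult(values=v, transformed=False, shapiro_p=p)
    if (v <= 0).any():
        raise ValueError("log transform requested for non-positive values")
    logged = np.log(v)
    p_after = float(stats.shapiro(logged).pvalue)
    return NormalityGateResult(values=logged, transformed=True,
                               shapiro_p=p, shapiro_p_after=p_after)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni multiple-comparison adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)
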