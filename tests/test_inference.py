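"""Permutation inference, mixed ANOVA, and the classical tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pinchskill.inference import (block_matrix, bonferroni_adjust,
                                  greenhouse_geisser_epsilon, mixed_anova,
                                  normality_gate, paired_day_slope_test,
                                  permutation_mean_test,
                                  permutation_slope_test, two_sample_t)
from pinchskill.synthetic import simulate_skill_series


def _pooled_ols_slope(groups_rows):
    """Independent pooled OLS slope oracle (polyfit on tiled blocks)."""
    k = groups_rows.shape[1]
    x = np.tile(np.arange(1, k + 1), groups_rows.shape[0])
    return np.polyfit(x, groups_rows.ravel(), 1)[0]


def test_degenerate_groups_give_p_one():
    a = np.full((3, 4), 0.5)
    b = np.full((4, 4), 0.5)
    res = permutation_slope_test(a, b, n_perm=200, seed=0)
    assert res.observed_delta == 0.0
    assert res.p_value == 1.0


def test_exhaustive_matches_independent_enumeration():
    rng = np.random.default_rng(4)
    a = simulate_skill_series(4, 4, 0.3, 0.15, 0.05, rng)
    b = simulate_skill_series(4, 4, 0.3, 0.05, 0.05, rng)
    res = permutation_slope_test(a, b, exhaustive=True, estimator="ols")
    assert res.n_perm == math.comb(8, 4)

    pooled = np.vstack([a, b])
    obs = _pooled_ols_slope(a) - _pooled_ols_slope(b)
    count = 0
    for combo in itertools.combinations(range(8), 4):
        rest = [i for i in range(8) if i not in combo]
        d = (_pooled_ols_slope(pooled[list(combo)])
             - _pooled_ols_slope(pooled[rest]))
        if abs(d) >= abs(obs) - 1e-12:
            count += 1
    assert res.p_value == pytest.approx(count / math.comb(8, 4), abs=1e-12)
    assert res.observed_delta == pytest.approx(obs, abs=1e-10)


def test_exhaustive_p_invariant_to_labeling_and_seed():
    rng = np.random.default_rng(9)
    a = simulate_skill_series(4, 4, 0.3, 0.2, 0.05, rng)
    b = simulate_skill_series(4, 4, 0.3, 0.0, 0.05, rng)
    p0 = permutation_slope_test(a, b, exhaustive=True, seed=1).p_value
    perm = np.random.default_rng(0).permutation(4)
    p1 = permutation_slope_test(a[perm], b[perm], exhaustive=True,
                                seed=999).p_value
    assert p0 == p1


def test_montecarlo_close_to_exhaustive():
    rng = np.random.default_rng(21)
    a = simulate_skill_series(5, 4, 0.3, 0.12, 0.05, rng)
    b = simulate_skill_series(5, 4, 0.3, 0.02, 0.05, rng)
    exact = permutation_slope_test(a, b, exhaustive=True).p_value
    mc = permutation_slope_test(a, b, n_perm=10_000, seed=3).p_value
    assert abs(mc - exact) < 0.02


def test_strong_separation_is_detected():
    rng = np.random.default_rng(17)
    a = simulate_skill_series(10, 4, 0.3, 0.30, 0.02, rng)
    b = simulate_skill_series(10, 4, 0.3, 0.00, 0.02, rng)
    res = permutation_slope_test(a, b, n_perm=2000, seed=0)
    assert res.p_value <= 0.05
    assert res.observed_delta > 0.25


def test_exhaustive_refused_for_large_designs():
    a = np.zeros((15, 4))
    b = np.zeros((15, 4))
    with pytest.raises(ValueError, match="Monte-Carlo|exhaustive"):
        permutation_slope_test(a, b, exhaustive=True)
    with pytest.raises(ValueError):
        permutation_slope_test(a[:1], b, n_perm=10)


def test_paired_day_identical_days_null():
    d = np.cumsum(np.ones((4, 4)) * 0.1, axis=1)
    res = paired_day_slope_test(d, d.copy(), n_perm=100, seed=0)
    assert res.observed_delta == 0.0
    assert res.p_value == 1.0


def test_paired_day_exhaustive_matches_hand_enumeration():
    rng = np.random.default_rng(5)
    d1 = simulate_skill_series(2, 4, 0.3, 0.05, 0.03, rng)
    d2 = simulate_skill_series(2, 4, 0.4, 0.20, 0.03, rng)
    res = paired_day_slope_test(d1, d2, exhaustive=True, estimator="ols")
    assert res.n_perm == 4

    deltas = []
    for flips in itertools.product((0, 1), repeat=2):
        a = np.array([d2[i] if f else d1[i] for i, f in enumerate(flips)])
        b = np.array([d1[i] if f else d2[i] for i, f in enumerate(flips)])
        deltas.append(_pooled_ols_slope(b) - _pooled_ols_slope(a))
    obs = deltas[0]
    expect = sum(1 for d in deltas if abs(d) >= abs(obs) - 1e-12) / 4
    assert res.p_value == pytest.approx(expect)
    assert res.observed_delta == pytest.approx(obs, abs=1e-10)


def test_paired_day_detects_day_effect():
    rng = np.random.default_rng(8)
    d1 = simulate_skill_series(8, 4, 0.3, 0.05, 0.02, rng)
    d2 = simulate_skill_series(8, 4, 0.4, 0.20, 0.02, rng)
    res = paired_day_slope_test(d1, d2, n_perm=2000, seed=2)
    assert res.p_value <= 0.05
    with pytest.raises(ValueError):
        paired_day_slope_test(d1[:3], d2, n_perm=10)


def test_permutation_mean_test_basics():
    rng = np.random.default_rng(0)
    a = rng.normal(1.0, 0.1, 10)
    b = rng.normal(0.0, 0.1, 10)
    res = permutation_mean_test(a, b, n_perm=2000, seed=0)
    assert res.p_value <= 0.05
    assert res.observed_delta == pytest.approx(a.mean() - b.mean())


def test_block_matrix_pivots_and_rejects_missing_cells():
    df = pd.DataFrame({"subject": ["a", "a", "b", "b"],
                       "block": [1, 2, 1, 2],
                       "skill": [0.1, 0.2, 0.3, 0.4]})
    m = block_matrix(df)
    assert m.shape == (2, 2)
    with pytest.raises(ValueError):
        block_matrix(df.iloc[:3])


# ---------------------------------------------------------------------------
# Mixed ANOVA
# ---------------------------------------------------------------------------

def _balanced_design(rng, n_per_group=6, k=4, effect=0.0):
    rows = []
    for g, glab in enumerate(["A", "B"]):
        for s in range(n_per_group):
            subj_off = rng.normal(0, 0.5)
            for b in range(1, k + 1):
                rows.append({
                    "subject": f"{glab}{s}", "group": glab, "block": b,
                    "y": rng.normal(g * effect + 0.2 * b + subj_off, 1.0)})
    return pd.DataFrame(rows)


def bruteforce_mixed_anova(df):
    """Mean-decomposition oracle written with plain loops."""
    subjects = sorted(df["subject"].unique())
    blocks = sorted(df["block"].unique())
    G = {s: df[df["subject"] == s]["group"].iloc[0] for s in subjects}
    groups = sorted(set(G.values()))
    y = {(s, b): float(df[(df["subject"] == s) & (df["block"] == b)]["y"].iloc[0])
         for s in subjects for b in blocks}
    grand = sum(y.values()) / len(y)
    k, n = len(blocks), len(subjects)
    subj_mean = {s: sum(y[(s, b)] for b in blocks) / k for s in subjects}
    grp_members = {g: [s for s in subjects if G[s] == g] for g in groups}
    grp_mean = {g: sum(subj_mean[s] for s in grp_members[g]) / len(grp_members[g])
                for g in groups}
    blk_mean = {b: sum(y[(s, b)] for s in subjects) / n for b in blocks}
    cell_mean = {(g, b): sum(y[(s, b)] for s in grp_members[g]) / len(grp_members[g])
                 for g in groups for b in blocks}
    ss_total = sum((v - grand) ** 2 for v in y.values())
    ss_subj = k * sum((subj_mean[s] - grand) ** 2 for s in subjects)
    ss_group = k * sum(len(grp_members[g]) * (grp_mean[g] - grand) ** 2
                       for g in groups)
    ss_block = n * sum((blk_mean[b] - grand) ** 2 for b in blocks)
    ss_inter = sum(len(grp_members[g])
                   * (cell_mean[(g, b)] - grp_mean[g] - blk_mean[b] + grand) ** 2
                   for g in groups for b in blocks)
    ss_eb = ss_subj - ss_group
    ss_ew = ss_total - ss_subj - ss_block - ss_inter
    ms = {
        "group": ss_group / (len(groups) - 1),
        "eb": ss_eb / (n - len(groups)),
        "block": ss_block / (k - 1),
        "inter": ss_inter / ((len(groups) - 1) * (k - 1)),
        "ew": ss_ew / ((n - len(groups)) * (k - 1)),
    }
    return {
        "SS": {"group": ss_group, "block": ss_block, "inter": ss_inter},
        "F": {"group": ms["group"] / ms["eb"],
              "block": ms["block"] / ms["ew"],
              "inter": ms["inter"] / ms["ew"]},
    }


def test_mixed_anova_matches_bruteforce():
    rng = np.random.default_rng(10)
    df = _balanced_design(rng, effect=0.5)
    tab = mixed_anova(df, "y")
    oracle = bruteforce_mixed_anova(df)
    assert tab.loc["group", "SS"] == pytest.approx(oracle["SS"]["group"], abs=1e-8)
    assert tab.loc["block", "SS"] == pytest.approx(oracle["SS"]["block"], abs=1e-8)
    assert tab.loc["block * group", "SS"] == pytest.approx(
        oracle["SS"]["inter"], abs=1e-8)
    assert tab.loc["group", "F"] == pytest.approx(oracle["F"]["group"], abs=1e-8)
    assert tab.loc["block", "F"] == pytest.approx(oracle["F"]["block"], abs=1e-8)


def test_mixed_anova_matches_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(0)
    df = _balanced_design(rng, effect=0.5)
    tab = mixed_anova(df, "y")
    ref = pg.mixed_anova(data=df, dv="y", within="block", subject="subject",
                        between="group").set_index("Source")
    assert tab.loc["group", "F"] == pytest.approx(ref.loc["group", "F"], rel=1e-8)
    assert tab.loc["block", "F"] == pytest.approx(ref.loc["block", "F"], rel=1e-8)
    assert tab.loc["block * group", "F"] == pytest.approx(
        ref.loc["Interaction", "F"], rel=1e-8)
    # pingouin estimates epsilon from the grand covariance; we pool the
    # covariance within groups (mixed-design convention), so the two agree
    # only approximately when a group effect is present
    assert tab.loc["block", "gg_epsilon"] == pytest.approx(
        ref.loc["block", "eps"], abs=0.1)


def test_mixed_anova_location_invariance():
    rng = np.random.default_rng(3)
    df = _balanced_design(rng)
    base = mixed_anova(df, "y")
    shifted = df.assign(y=df["y"] + 100.0)
    moved = mixed_anova(shifted, "y")
    assert np.allclose(base["F"], moved["F"])
    reordered = mixed_anova(df.sample(frac=1, random_state=1), "y")
    assert np.allclose(base["F"], reordered["F"])


def test_mixed_anova_rejects_missing_cells():
    rng = np.random.default_rng(1)
    df = _balanced_design(rng)
    with pytest.raises(ValueError):
        mixed_anova(df.iloc[:-1], "y")


def test_gg_epsilon_bounds():
    rng = np.random.default_rng(2)
    for _ in range(10):
        M = rng.normal(size=(12, 4))
        groups = np.repeat(["A", "B"], 6)
        eps = greenhouse_geisser_epsilon(M, groups)
        assert 1.0 / 3 <= eps <= 1.0


def test_two_sample_t_conventions():
    t, df, p = two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0])
    assert (t, p) == (0.0, 1.0)
    with pytest.raises(ValueError):
        two_sample_t([1.0, 1.0], [2.0, 2.0])
    # closed-form pooled-variance oracle
    a = np.array([1.0, 2.0, 3.0])
    b = a + 10.0
    t, df, p = two_sample_t(a, b)
    sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
    expect = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
    assert t == pytest.approx(expect, abs=1e-12)
    assert df == 4
    t7, _, _ = two_sample_t(7 * a, 7 * b)
    assert t7 == pytest.approx(t, abs=1e-12)


def test_normality_gate_branches():
    rng = np.random.default_rng(2)
    normal = rng.normal(size=200)
    res = normality_gate(normal)
    assert not res.transformed
    assert np.array_equal(res.values, normal)
    lognorm = np.exp(rng.normal(size=200))
    res2 = normality_gate(lognorm)
    assert res2.transformed
    assert res2.shapiro_p < 0.05 <= res2.shapiro_p_after
    assert np.allclose(res2.values, np.log(lognorm))
    with pytest.raises(ValueError):
        normality_gate([1.0, 2.0])
    with pytest.raises(ValueError):
        normality_gate(np.append(np.exp(rng.normal(size=199)), -1.0))


def test_bonferroni():
    assert bonferroni_adjust([0.04]) == pytest.approx([0.04])
    assert bonferroni_adjust([0.01, 0.2, 0.6]).tolist() == \
        pytest.approx([0.03, 0.6, 1.0])
    with pytest.raises(ValueError):
        bonferroni_adjust([1.2])
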