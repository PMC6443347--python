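"""Skill score, block summaries, and error decomposition."""

import math

import numpy as np
import pandas as pd
import pytest

from pinchskill.metrics import (TrialRecord, adjusted_error_rate,
                                decompose_errors, skill_measure,
                                summarize_block, summarize_sequence_block,
                                summarize_sequence_trials, summarize_trials)

from conftest import make_trials


@pytest.mark.parametrize("er,mt,n,expected,tol", [
    # ln(e) = 1, so the denominator term is 1 and a = (1-0.5)/0.5
    (0.5, math.e, 30, 1.0, 1e-12),
    # closed form: 0.8 / (0.2 * ln(2)^5.424)
    (0.2, 2.0, 30, 29.20267872881573, 1e-9),
    # boundary ER = 0 continuity-corrected to 0.5/30
    (0.0, 2.0, 30, 430.73951125003197, 1e-9),
])
def test_skill_measure_closed_form(er, mt, n, expected, tol):
    assert skill_measure(er, mt, n_trials=n) == pytest.approx(expected, abs=tol)


def test_skill_measure_rejects_short_movement_times():
    for mt in (1.0, 0.5, -2.0):
        with pytest.raises(ValueError):
            skill_measure(0.3, mt)


def test_skill_monotone_decreasing_in_error_rate():
    grid = np.arange(0.05, 0.96, 0.05)
    vals = [skill_measure(er, 3.0) for er in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_skill_monotone_decreasing_in_movement_time():
    grid = np.linspace(1.1, 10.0, 40)
    vals = [skill_measure(0.3, mt) for mt in grid]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_adjusted_error_rate_boundaries():
    assert adjusted_error_rate(0.0, 30) == 0.5 / 30
    assert adjusted_error_rate(1.0, 30) == 1 - 0.5 / 30
    assert adjusted_error_rate(0.4, 30) == 0.4
    with pytest.raises(ValueError):
        adjusted_error_rate(1.2, 30)


def test_summarize_block_half_errors_unit_skill():
    outcomes = ["HHHHO"] * 15 + ["HHHHH"] * 15
    df = make_trials(outcomes, movement_times=[math.e] * 30)
    s = summarize_block(df)
    assert s.error_rate == 0.5
    assert s.skill == pytest.approx(1.0, abs=1e-12)
    assert s.n_trials == 30


def test_summarize_block_matches_skill_closed_form():
    df = make_trials(["OHHHH"] * 2 + ["HHHHH"] * 8)
    s = summarize_block(df)
    assert s.skill == pytest.approx(29.20267872881573, abs=1e-9)


def test_summarize_block_zero_errors_uses_adjusted_rate():
    df = make_trials(["HHHHH"] * 30)
    s = summarize_block(df)
    assert s.error_rate == 0.0
    assert s.skill == pytest.approx(
        skill_measure(0.0, 2.0, n_trials=30), abs=1e-12)


def test_summarize_block_composition_identity():
    rng = np.random.default_rng(0)
    outcomes = ["".join(rng.choice(["H", "O", "U"], 5)) for _ in range(30)]
    mts = rng.uniform(1.5, 6.0, 30)
    df = make_trials(outcomes, movement_times=mts)
    s = summarize_block(df)
    assert s.skill == pytest.approx(
        skill_measure(s.error_rate, s.movement_time, n_trials=s.n_trials))


def test_summarize_block_median_aggregate():
    df = make_trials(["HHHHH"] * 3, movement_times=[1.5, 2.0, 6.0])
    assert summarize_block(df, mt_aggregate="median").movement_time == 2.0
    assert summarize_block(df).movement_time == pytest.approx(9.5 / 3)


def test_summarize_block_rejects_bad_input():
    with pytest.raises(ValueError):
        summarize_block(make_trials([]))
    mixed = pd.concat([make_trials(["HHHHH"], block=1),
                       make_trials(["HHHHH"], block=2)])
    with pytest.raises(ValueError):
        summarize_block(mixed)


def test_decompose_errors_all_hits():
    dec = decompose_errors(make_trials(["HHHHH"] * 10))
    assert (dec["hit_rate"] == 1.0).all()
    assert (dec["overshoot_rate"] == 0.0).all()
    assert (dec["undershoot_rate"] == 0.0).all()


def test_decompose_errors_hand_counted():
    # 4 trials with known per-gate outcomes; rates from a hand count
    dec = decompose_errors(make_trials(["OHHHH", "OUHHH", "HHHHH", "HUHHO"]))
    assert dec.loc[1, "overshoot_rate"] == 0.5
    assert dec.loc[1, "hit_rate"] == 0.5
    assert dec.loc[2, "undershoot_rate"] == 0.5
    assert dec.loc[5, "overshoot_rate"] == 0.25
    assert (dec.loc[3] == [1.0, 0.0, 0.0]).all()


def test_decompose_rates_sum_to_one():
    rng = np.random.default_rng(1)
    outcomes = ["".join(rng.choice(["H", "O", "U"], 5)) for _ in range(50)]
    dec = decompose_errors(make_trials(outcomes))
    assert np.allclose(dec.sum(axis=1), 1.0)
    with pytest.raises(ValueError):
        decompose_errors(make_trials([]))


def test_trial_record_error_flag_and_validation():
    good = TrialRecord("s1", "G", 1, 1, 1, "right", 2.0,
                       ("H", "H", "H", "H", "H"))
    assert not good.is_error
    bad_gate = TrialRecord("s1", "G", 1, 1, 1, "right", 2.0,
                           ("H", "O", "H", "H", "H"))
    assert bad_gate.is_error
    with pytest.raises(ValueError):
        TrialRecord("s1", "G", 1, 1, 1, "right", -1.0, ("H",) * 5)
    with pytest.raises(ValueError):
        TrialRecord("s1", "G", 1, 1, 1, "right", 2.0, ("H",) * 4)
    with pytest.raises(ValueError):
        TrialRecord("s1", "G", 1, 1, 1, "right", 2.0, ("H", "X", "H", "H", "H"))


def _seq_table(wrongs, mts=None, block=1):
    return pd.DataFrame({
        "subject": "s1", "group": "G", "day": 1, "block": block,
        "trial": np.arange(1, len(wrongs) + 1),
        "movement_time": mts if mts is not None else [3.0] * len(wrongs),
        "n_wrong_presses": wrongs,
    })


def test_sequence_block_error_rate():
    assert summarize_sequence_block(_seq_table([0] * 30)).error_rate == 0.0
    s = summarize_sequence_block(_seq_table([0] * 24 + [1, 2, 1, 3, 1, 1]))
    assert s.error_rate == pytest.approx(0.2)
    with pytest.raises(ValueError):
        summarize_sequence_block(_seq_table([]))


def test_sequence_summaries_match_bruteforce_recount():
    rng = np.random.default_rng(2)
    frames = []
    for block in (1, 2):
        frames.append(_seq_table(rng.integers(0, 3, 30),
                                 mts=rng.uniform(2, 5, 30), block=block))
    table = pd.concat(frames, ignore_index=True)
    out = summarize_sequence_trials(table)
    for _, row in out.iterrows():
        sub = table[table["block"] == row["block"]]
        n_err = sum(1 for w in sub["n_wrong_presses"] if w > 0)
        assert row["error_rate"] == pytest.approx(n_err / len(sub))
        assert row["movement_time"] == pytest.approx(
            sum(sub["movement_time"]) / len(sub))


def test_summarize_trials_one_row_per_block():
    frames = [make_trials(["HHHHH"] * 5, subject=s, block=b)
              for s in ("a", "b") for b in (1, 2)]
    out = summarize_trials(pd.concat(frames, ignore_index=True))
    assert len(out) == 4
    assert set(out["subject"]) == {"a", "b"}
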