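import numpy as np
import pandas as pd
import pytest

from pinchskill.metrics import GATE_COLUMNS


def make_trials(outcomes, movement_times=None, subject="s1", group="G",
                day=1, block=1, hand="right"):
    """Build a trial table from per-trial gate-outcome strings like 'HHOHU'."""
    rows = []
    for t, oc in enumerate(outcomes, start=1):
        mt = 2.0 if movement_times is None else movement_times[t - 1]
        row = {"subject": subject, "group": group, "day": day, "block": block,
               "trial": t, "hand": hand, "movement_time": mt}
        for col, o in zip(GATE_COLUMNS, oc):
            row[col] = o
        row["is_error"] = any(o != "H" for o in oc)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def exp1_bundle():
    """One small experiment-1 run shared by the pipeline tests."""
    from pinchskill import experiment_preset, run_experiment
    return run_experiment(experiment_preset(1, seed=5, n_perm=300))
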