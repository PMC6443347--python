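"""End-to-end orchestration of the four experiments.

Each experiment is described by an :class:`ExperimentSpec` (groups,
days, analysis plan) and executed by :func:`run_experiment`:
simulate-or-load trial tables -> per-block summaries -> robust
learning-rate fits per group-day -> permutation comparisons -> mixed
ANOVAs -> fatigue summaries, all collected in a :class:`ResultsBundle`
that round-trips losslessly through CSV/JSON on disk.

Experiment presets mirror the study designs: (1) fatigued vs
non-fatigued learners over 2 days, (2) one-day training plus untrained
left-hand transfer blocks, (3) three groups (sham / M1-disrupted) over
2 days with within-group day comparisons, (4) the sequence task, ANOVA
only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .fatigue import summarize_fatigue
from .inference import (PermutationResult, block_matrix, mixed_anova,
                        paired_day_slope_test, permutation_mean_test,
                        permutation_slope_test)
from .learning import fit_group_learning, transfer_delta
from .metrics import (GATE_COLUMNS, OUTCOME_CODES, SEQUENCE_COLUMNS,
                      TRIAL_COLUMNS, summarize_block,
                      summarize_sequence_trials, summarize_trials)
from .synthetic import (DEFAULT_MVC_DECAY, GroupParams, SimulationConfig,
                        simulate_force_trace, simulate_pinch_experiment,
                        simulate_sequence_experiment)


@dataclass(frozen=True)
class ExperimentSpec:
    """Declarative description of one experiment run."""

    experiment: int
    groups: tuple[GroupParams, ...]
    days: int = 2
    n_perm: int = 10_000
    seed: int = 0
    estimator: str = "robust"        # learning-rate fits reported in the bundle
    perm_estimator: str = "ols"      # statistic inside the permutation loop
    input_mode: str = "simulate"      # or "load"
    input_path: str | None = None
    transfer_trials: int = 0
    config: SimulationConfig | None = None

    def simulation_config(self) -> SimulationConfig:
        if self.config is not None:
            return self.config
        return SimulationConfig(groups=self.groups, days=self.days,
                                transfer_trials=self.transfer_trials,
                                master_seed=self.seed)


def experiment_preset(experiment: int, seed: int = 0,
                      n_perm: int = 10_000) -> ExperimentSpec:
    """Packaged per-experiment specs matching the study group structure."""
    if experiment == 1:
        groups = (
            GroupParams(label="NoFTG", n_subjects=18, baseline_skill=0.35,
                        slope_per_block=0.17, day_carryover=0.25),
            GroupParams(label="FTG", n_subjects=20, baseline_skill=0.22,
                        slope_per_block=0.04, day_carryover=0.10,
                        fatigue_bias=0.10),
        )
        return ExperimentSpec(1, groups, days=2, n_perm=n_perm, seed=seed)
    if experiment == 2:
        groups = (
            GroupParams(label="NoFTG_TRANSFER", n_subjects=10,
                        baseline_skill=0.30, slope_per_block=0.03,
                        transfer_baseline=0.25, transfer_gain=0.133),
            GroupParams(label="FTG_TRANSFER", n_subjects=10,
                        baseline_skill=0.22, slope_per_block=0.008,
                        fatigue_bias=0.10, transfer_baseline=0.25,
                        transfer_gain=0.018),
        )
        return ExperimentSpec(2, groups, days=1, n_perm=n_perm, seed=seed,
                              transfer_trials=15)
    if experiment == 3:
        groups = (
            GroupParams(label="NoFTG_SHAM", n_subjects=10,
                        baseline_skill=0.30, slope_per_block=(0.049, 0.040),
                        day_carryover=0.15),
            GroupParams(label="FTG_SHAM", n_subjects=15, baseline_skill=0.22,
                        slope_per_block=(0.020, 0.022), day_carryover=0.08,
                        fatigue_bias=0.10),
            GroupParams(label="FTG_M1", n_subjects=15, baseline_skill=0.22,
                        slope_per_block=(0.016, 0.042), day_carryover=0.08,
                        fatigue_bias=0.10),
        )
        return ExperimentSpec(3, groups, days=2, n_perm=n_perm, seed=seed)
    if experiment == 4:
        groups = (
            GroupParams(label="NoFTG_SEQ", n_subjects=9),
            GroupParams(label="FTG_SEQ", n_subjects=9, fatigue_bias=0.10),
        )
        return ExperimentSpec(4, groups, days=2, n_perm=n_perm, seed=seed)
    raise ValueError(f"unknown experiment id {experiment}; expected 1-4")


@dataclass
class ResultsBundle:
    """Everything one experiment run produced, plus provenance."""

    experiment: int
    summaries: pd.DataFrame
    fits: pd.DataFrame
    permutations: list[dict]
    anovas: dict[str, pd.DataFrame]
    fatigue: list[dict]
    provenance: dict


def _spec_dict(spec: ExperimentSpec) -> dict:
    d = dataclasses.asdict(spec)
    if spec.config is not None:
        d["config"] = dataclasses.asdict(spec.config)
    return d


def config_hash(spec: ExperimentSpec) -> str:
    """Stable hash of every analysis-relevant ExperimentSpec field."""
    blob = json.dumps(_spec_dict(spec), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _perm_record(name: str, day: int | None, groups: list[str],
                 res: PermutationResult) -> dict:
    return {
        "name": name, "day": day, "groups": groups,
        "observed_delta": res.observed_delta, "p_value": res.p_value,
        "n_perm": res.n_perm, "alternative": res.alternative,
        "seed": res.seed, "exhaustive": res.exhaustive,
        "method": res.method, "estimator": res.estimator,
        "null_deltas": [float(v) for v in res.null_deltas],
    }


def _fit_rows(summaries: pd.DataFrame, estimator: str) -> pd.DataFrame:
    wf = "unit" if estimator == "ols" else "bisquare"
    rows = []
    for (group, day), sub in summaries.groupby(["group", "day"], sort=True):
        fit = fit_group_learning(sub, weight_function=wf)
        rows.append({"group": group, "day": int(day), "slope": fit.slope,
                     "intercept": fit.intercept, "n_points": fit.n_points,
                     "converged": fit.converged})
    return pd.DataFrame(rows)


def _simulate_fatigue_summaries(spec: ExperimentSpec,
                                cfg: SimulationConfig) -> list[dict]:
    """Per-subject MVC/fatigue assessment for the fatigued groups.

    The sustained contraction decays exponentially with a per-subject
    rate scattered around the calibrated default (lognormal spread, so
    time-to-fatigue is skewed as observed); the post-session MVC sits at
    the stopping threshold (40% of MVC, a ~60% decrement).
    """
    out = []
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed,
                                                       spawn_key=(901,)))
    for gp in cfg.groups:
        if gp.fatigue_bias <= 0:
            continue
        for s_idx in range(gp.n_subjects):
            mvc = max(cfg.mvc.baseline_n
                      + rng.normal(0.0, cfg.mvc.between_subject_sd), 40.0)
            # lognormal rate spread centered so E[time-to-fatigue] stays at
            # the calibrated ~69 s with a right-skewed ~32 s spread
            decay = DEFAULT_MVC_DECAY * np.exp(rng.normal(0.45**2 / 2, 0.45))
            pre = simulate_force_trace(mvc, decay_rate=0.0, duration=5.0)
            sustained = simulate_force_trace(mvc, decay_rate=decay,
                                             duration=300.0)
            post = simulate_force_trace(0.4 * mvc, decay_rate=0.0,
                                        duration=5.0)
            s = summarize_fatigue(pre, sustained, post,
                                  gate_windows=[(c * (1 - cfg.gates.width_fraction) ,
                                                 c * (1 + cfg.gates.width_fraction))
                                                for c in cfg.gates.centers])
            out.append({
                "group": gp.label, "subject": f"{gp.label}_{s_idx + 1:02d}",
                "mvc_pre": s.mvc_pre, "mvc_post": s.mvc_post,
                "decrement_fraction": s.decrement_fraction,
                "threshold_force": s.threshold_force,
                "time_to_fatigue": s.time_to_fatigue,
            })
    return out


def run_experiment(spec: ExperimentSpec) -> ResultsBundle:
    """Execute the full analysis graph for one experiment."""
    if spec.experiment not in (1, 2, 3, 4):
        raise ValueError(f"unknown experiment id {spec.experiment}")
    cfg = spec.simulation_config()
    seeds = np.random.SeedSequence(spec.seed)
    perm_seed_pool = iter(
        np.random.default_rng(seeds.spawn(1)[0])
        .integers(0, 2**31 - 1, size=512))

    permutations: list[dict] = []
    anovas: dict[str, pd.DataFrame] = {}
    fatigue: list[dict] = []
    fits = pd.DataFrame()

    if spec.experiment == 4:
        trials = simulate_sequence_experiment(cfg, spec.seed) \
            if spec.input_mode == "simulate" else read_sequence_trials(spec.input_path)
        summaries = summarize_sequence_trials(trials)
        for day in sorted(summaries["day"].unique()):
            sub = summaries[summaries["day"] == day]
            for dv in ("error_rate", "movement_time"):
                anovas[f"day{day}_{dv}"] = mixed_anova(sub, dv=dv)
    else:
        if spec.input_mode == "simulate":
            trials, _ = simulate_pinch_experiment(cfg, spec.seed)
        else:
            trials = read_trials(spec.input_path)
        summaries = summarize_trials(trials)
        right = summaries[summaries["hand"] == "right"]
        fits = _fit_rows(right, spec.estimator)

        labels = [gp.label for gp in cfg.groups]
        for day in sorted(right["day"].unique()):
            sub = right[right["day"] == day]
            for i in range(len(labels)):
                for j in range(i + 1, len(labels)):
                    a = block_matrix(sub[sub["group"] == labels[i]])
                    b = block_matrix(sub[sub["group"] == labels[j]])
                    res = permutation_slope_test(
                        a, b, n_perm=spec.n_perm,
                        seed=int(next(perm_seed_pool)),
                        estimator=spec.perm_estimator)
                    permutations.append(_perm_record(
                        f"day{day}_{labels[i]}_vs_{labels[j]}", int(day),
                        [labels[i], labels[j]], res))
            for dv in ("error_rate", "movement_time"):
                anovas[f"day{day}_{dv}"] = mixed_anova(sub, dv=dv)

        if spec.experiment == 3:
            # within-group across-day comparisons (day 2 vs day 1)
            for label in labels:
                d1 = block_matrix(right[(right["group"] == label)
                                        & (right["day"] == 1)])
                d2 = block_matrix(right[(right["group"] == label)
                                        & (right["day"] == 2)])
                res = paired_day_slope_test(
                    d1, d2, n_perm=spec.n_perm,
                    seed=int(next(perm_seed_pool)),
                    estimator=spec.perm_estimator)
                permutations.append(_perm_record(
                    f"{label}_day2_vs_day1", None, [label], res))

        if spec.experiment == 2 and spec.transfer_trials > 0:
            # untrained left hand: per-subject block2 - block1 skill delta
            left = summaries[summaries["hand"] == "left"]
            deltas: dict[str, list[float]] = {}
            for label in labels:
                vals = []
                lsub = left[left["group"] == label]
                for subject, srows in lsub.groupby("subject"):
                    pre_rows = trials[(trials["subject"] == subject)
                                      & (trials["hand"] == "left")
                                      & (trials["block"] == 1)]
                    post_rows = trials[(trials["subject"] == subject)
                                       & (trials["hand"] == "left")
                                       & (trials["block"] == 2)]
                    vals.append(transfer_delta(summarize_block(pre_rows),
                                               summarize_block(post_rows)))
                deltas[label] = vals
            res = permutation_mean_test(
                deltas[labels[0]], deltas[labels[1]], n_perm=spec.n_perm,
                seed=int(next(perm_seed_pool)))
            permutations.append(_perm_record(
                "left_hand_transfer_delta", 1, labels[:2], res))

        fatigue = _simulate_fatigue_summaries(spec, cfg) \
            if spec.input_mode == "simulate" else []

    provenance = {
        "experiment": spec.experiment,
        "config_hash": config_hash(spec),
        "seed": spec.seed,
        "n_perm": spec.n_perm,
        "estimator": spec.estimator,
        "version": _pkg_version,
    }
    return ResultsBundle(experiment=spec.experiment, summaries=summaries,
                         fits=fits, permutations=permutations, anovas=anovas,
                         fatigue=fatigue, provenance=provenance)


# ---------------------------------------------------------------------------
# CSV / JSON round-tripping
# ---------------------------------------------------------------------------

def read_trials(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a pinch-task trial CSV, validating schema and outcome codes.

    ``column_map`` renames foreign column names onto the package dialect
    (``{"their_name": "our_name"}``), so externally deposited tables can
    be loaded without code changes.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial CSV {path} missing column(s): {missing}")
    for col in GATE_COLUMNS:
        bad = ~df[col].isin(OUTCOME_CODES)
        if bad.any():
            row = int(df.index[bad][0]) + 2  # header is line 1
            raise ValueError(
                f"trial CSV {path} line {row}: outcome {df[col][bad].iloc[0]!r} "
                f"in column {col!r} not in {OUTCOME_CODES}")
    if (df["movement_time"] <= 0).any():
        row = int(df.index[df["movement_time"] <= 0][0]) + 2
        raise ValueError(f"trial CSV {path} line {row}: non-positive movement_time")
    df["is_error"] = df["is_error"].astype(bool)
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path) -> None:
    trials[TRIAL_COLUMNS].to_csv(path, index=False)


def read_sequence_trials(path) -> pd.DataFrame:
    """Read a sequence-task trial CSV."""
    df = pd.read_csv(path)
    missing = [c for c in SEQUENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sequence CSV {path} missing column(s): {missing}")
    if (df["n_wrong_presses"] < 0).any():
        raise ValueError(f"sequence CSV {path}: negative n_wrong_presses")
    return df[SEQUENCE_COLUMNS]


def write_sequence_trials(trials: pd.DataFrame, path) -> None:
    trials[SEQUENCE_COLUMNS].to_csv(path, index=False)


def write_bundle(bundle: ResultsBundle, path) -> None:
    """Persist a bundle to a directory of CSV/JSON files (lossless)."""
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    bundle.summaries.to_csv(p / "summaries.csv", index=False)
    bundle.fits.to_csv(p / "fits.csv", index=False)
    (p / "permutations.json").write_text(
        json.dumps(bundle.permutations, indent=1))
    anovas = {name: tab.reset_index().to_dict(orient="list")
              for name, tab in bundle.anovas.items()}
    (p / "anovas.json").write_text(json.dumps(anovas, indent=1))
    (p / "fatigue.json").write_text(json.dumps(bundle.fatigue, indent=1))
    (p / "provenance.json").write_text(json.dumps(bundle.provenance, indent=1))


def read_bundle(path) -> ResultsBundle:
    """Reload a bundle written by :func:`write_bundle`."""
    p = Path(path)
    provenance = json.loads((p / "provenance.json").read_text())
    anovas = {
        name: pd.DataFrame(cols).set_index("effect")
        for name, cols in json.loads((p / "anovas.json").read_text()).items()
    }
    return ResultsBundle(
        experiment=int(provenance["experiment"]),
        summaries=pd.read_csv(p / "summaries.csv"),
        fits=pd.read_csv(p / "fits.csv"),
        permutations=json.loads((p / "permutations.json").read_text()),
        anovas=anovas,
        fatigue=json.loads((p / "fatigue.json").read_text()),
        provenance=provenance,
    )


def bundles_equal(a: ResultsBundle, b: ResultsBundle) -> bool:
    """Exact equality of two bundles (used for round-trip checks)."""
    if a.experiment != b.experiment or a.provenance != b.provenance:
        return False
    try:
        pd.testing.assert_frame_equal(
            a.summaries.reset_index(drop=True).astype({"day": int, "block": int}),
            b.summaries.reset_index(drop=True).astype({"day": int, "block": int}),
            check_dtype=False)
        pd.testing.assert_frame_equal(a.fits.reset_index(drop=True),
                                      b.fits.reset_index(drop=True),
                                      check_dtype=False)
        if sorted(a.anovas) != sorted(b.anovas):
            return False
        for k in a.anovas:
            pd.testing.assert_frame_equal(a.anovas[k], b.anovas[k],
                                          check_dtype=False)
    except AssertionError:
        return False
    return a.permutations == b.permutations and a.fatigue == b.fatigue


def make_report(bundle: ResultsBundle, bins: int = 30) -> tuple[str, dict]:
    """Human-readable summary plus null-distribution histogram data.

    For each permutation comparison the histogram bin counts of the null
    slope differences sum to ``n_perm``; ``observed_delta`` marks where
    the dashed line would fall.
    """
    if (not bundle.permutations and not bundle.anovas
            and len(bundle.fits) == 0):
        raise ValueError("cannot report on an empty bundle")
    lines = [f"Experiment {bundle.experiment} "
             f"(config {bundle.provenance['config_hash']}, "
             f"seed {bundle.provenance['seed']})"]
    if len(bundle.fits):
        lines.append("\nLearning rates (pooled robust fits):")
        for _, r in bundle.fits.iterrows():
            lines.append(f"  {r['group']:>16s} day {int(r['day'])}: "
                         f"slope {r['slope']:+.4f}  "
                         f"(intercept {r['intercept']:.4f}, "
                         f"n={int(r['n_points'])})")
    hists: dict[str, dict] = {}
    if bundle.permutations:
        lines.append("\nPermutation comparisons:")
        for rec in bundle.permutations:
            null = np.asarray(rec["null_deltas"], dtype=float)
            counts, edges = np.histogram(null, bins=bins)
            hists[rec["name"]] = {
                "bin_edges": edges.tolist(),
                "counts": counts.tolist(),
                "observed_delta": rec["observed_delta"],
                "p_value": rec["p_value"],
            }
            lines.append(f"  {rec['name']}: observed Δ "
                         f"{rec['observed_delta']:+.4f}, "
                         f"p = {rec['p_value']:.4f} "
                         f"({rec['n_perm']} resamples, {rec['method']})")
    if bundle.anovas:
        lines.append("\nMixed ANOVAs (GG-corrected p for within effects):")
        for name, tab in bundle.anovas.items():
            for effect, r in tab.iterrows():
                p = r["p_gg"] if np.isfinite(r["p_gg"]) else r["p_uncorrected"]
                lines.append(f"  {name} / {effect}: "
                             f"F({int(r['df'])}, ·) = {r['F']:.3f}, "
                             f"p = {p:.4f}")
    if bundle.fatigue:
        dec = np.mean([f["decrement_fraction"] for f in bundle.fatigue])
        t2f = [f["time_to_fatigue"] for f in bundle.fatigue
               if f["time_to_fatigue"] is not None]
        lines.append(f"\nFatigue: mean MVC decrement "
                     f"{100 * dec:.1f}%, time to fatigue "
                     f"{np.mean(t2f):.1f} ± {np.std(t2f):.1f} s "
                     f"(n={len(bundle.fatigue)})")
    return "\n".join(lines), hists
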