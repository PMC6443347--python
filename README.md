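# pinchskill

Analysis pipeline for motor-skill learning in the sequential isometric
pinch task, with a focus on how muscle fatigue changes the *rate* of
learning. The package is aimed at motor-control and neurorehabilitation
researchers who need the full chain from trial-level behavioral records
to group-level inference, plus a synthetic generator that makes every
stage testable without human data.

## The science in brief

Subjects squeeze a force transducer to steer a cursor through five
force targets (gates 1–4 and an end gate, all at ≤ 40% of the subject's
maximal voluntary contraction, MVC). Per block of 30 trials the package
computes the error rate *ER* (fraction of trials with at least one
under- or overshot target), an aggregate movement time *MT*, and the
speed–accuracy skill score

```
a = (1 − ER) / (ER · (ln MT)^b),   b = 5.424
```

Skill grows roughly linearly over the four blocks of a session, so the
**learning rate** is the slope *c* of a robust linear regression
(iteratively reweighted least squares, Tukey bisquare) of skill on
block number, pooled over all subjects of a group. Group differences in
learning rate are tested by a **subject-level permutation test**:
subjects are reassigned to groups 10,000 times (whole block series move
together), the pooled slope difference Δc is recomputed each time, and
the observed Δc is located in that null distribution. Small designs can
be enumerated exhaustively for an exact p-value.

Around this core the package provides two-way mixed ANOVA
(between-subject group × within-subject block) with Greenhouse–Geisser
correction, Student's t-tests with a Shapiro–Wilk normality gate and
log-transform fallback, Bonferroni adjustment, per-gate
overshoot/undershoot error decomposition, and MVC force-trace analysis
(smoothed-maximum MVC, fatigue decrement 1 − MVC_post/MVC_pre, and
time-to-fatigue as the first sustained crossing below the gate-2 force
threshold).

## Worked example

```
pinchskill reproduce --experiment 1 --seed 1 --n-perm 10000 --out run1
```

simulates the two-group, two-day experiment (20 fatigued / 18
non-fatigued subjects, 4 blocks × 30 trials per day) and prints:

```
Experiment 1 (config 43d68dd24134aadc, seed 1)

Learning rates (pooled robust fits):
               FTG day 1: slope +0.0087  (intercept 0.1291, n=80)
               FTG day 2: slope +0.0382  (intercept 0.2472, n=80)
             NoFTG day 1: slope +0.2093  (intercept 0.1069, n=72)
             NoFTG day 2: slope +0.1126  (intercept 0.4922, n=72)

Permutation comparisons:
  day1_NoFTG_vs_FTG: observed Δ +0.2158, p = 0.0000 (10000 resamples, subject_relabel)
  day2_NoFTG_vs_FTG: observed Δ +0.0848, p = 0.0212 (10000 resamples, subject_relabel)
...
Fatigue: mean MVC decrement 60.0%, time to fatigue 83.8 ± 33.2 s (n=20)
```

Read: the non-fatigued group gains ~0.21 skill units per block on day 1
while the fatigued group is nearly flat; the permutation test puts the
observed slope difference far outside the relabeling null on both days
(p < 0.05). The fatigue block confirms the induction: force declined to
the gate-2 threshold (40% MVC, i.e. a 60% decrement) after roughly a
minute of sustained maximal contraction. The same CLI exposes
`simulate` (write a synthetic trial CSV), `analyze` (run the pipeline
on an existing trial CSV), and `report` (re-render a saved results
bundle); everything is equally accessible as library functions
(`pinchskill.run_experiment`, `permutation_slope_test`, ...).

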