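# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data generator behind `pinchskill`, and what the test suite
does and does not establish.

## Skill metric

The speed–accuracy score `a = (1 − ER) / (ER · (ln MT)^b)` with the
task constant `b = 5.424` summarizes one block: higher with fewer
errors and faster movements. Two boundary issues are handled
explicitly:

* **ER at 0 or 1.** The formula diverges. We apply the standard
  continuity correction `ER' = clip(ER, 0.5/n, 1 − 0.5/n)` with `n` the
  number of trials in the block (30 by default), keeping the score
  finite and strictly monotone.
* **MT ≤ 1 s.** `ln MT ≤ 0` makes the non-integer power undefined;
  such inputs raise. The generator keeps movement times above a 1.2 s
  floor, which is also realistic for a five-target pinch sequence.

The block MT aggregate is the arithmetic mean of trial MTs; the median
is available via `mt_aggregate="median"` (the choice is not determined
by the task definition, so it is config-exposed).

## Learning-rate estimation

Skill vs block number (1–4, per day) is fit by iteratively reweighted
least squares with a Tukey bisquare weight function, tuning constant
4.685, and MAD-based scale (median absolute deviation about the median,
divided by 0.6745), Huber (1.345) selectable. Convergence is declared
when both coefficients move < 1e−8 between iterations (cap: 100
iterations). Two numerical details:

* a vanishing MAD scale means the current fit is exact on the weighted
  majority of points; the fit is accepted as converged rather than
  refit (a naive restart from unit weights would silently revert to
  OLS when the robust fit isolates an outlier exactly);
* if every point receives zero weight (pathological), weights reset to
  1 for that iteration.

The default **pooled** mode regresses all subject × block points of a
group at once; `per_subject` fits each subject and averages slopes (a
sensitivity mode — the group-level wording of the analysis does not
fully determine which was intended, and both are provided). With only
two blocks (the untrained-hand transfer blocks) the learning measure is
the block2 − block1 skill difference.

The IRLS core is written in batch form (one shared x-vector, a matrix
of y-vectors, closed-form weighted 2-parameter solves per iteration),
which is what makes permutation tests with thousands of refits cheap.

## Permutation inference

* **Between groups:** whole subjects are relabeled, preserving group
  sizes; the statistic is the pooled slope difference. p is the
  fraction of resampled statistics that equal or exceed the observed
  one (two-sided on |Δ| by default; one-sided and a (c+1)/(n+1)
  small-sample rule are flags). Designs up to C(20,10) assignments can
  be enumerated exhaustively for an exact p.
* **Within group across days:** each subject's two day-series are
  swapped with probability ½ (sign-flip-style resampling of the day
  label). The original analysis does not state its scheme for this
  comparison; the bundle metadata labels the method (`day_sign_flip`)
  for that reason.
* **Scalar measures** (per-subject transfer deltas) use the same
  relabeling on group means.

**Estimator inside the loop.** The reported learning rates are robust
(bisquare) fits, but the permutation statistic defaults to the pooled
*OLS* slope, computed identically for the observed data and every
resample. Reason: under a genuine group difference, relabeled
pseudo-groups are ~50/50 mixtures of the two populations, their
residual distribution at the outer blocks is bimodal, and a
redescending M-estimator is bistable on bimodal mixtures — it converges
onto one subpopulation and downweights the other. Empirically this
inflates the null spread of Δc several-fold and costs substantial
power, while under the null (homogeneous groups) the two statistics
behave identically. `estimator="robust"` restores the bisquare
statistic for users who want it.

## Mixed ANOVA

The two-way mixed decomposition (between: group; within: block) is
computed directly from the classical sums of squares on the complete,
balanced-within design; missing cells raise rather than impute. The
Greenhouse–Geisser ε is computed from the within-group pooled
covariance of the k repeated measures (double-centered;
ε = tr(S)² / ((k−1)·ΣS²), clipped to [1/(k−1), 1]), and GG-corrected
p-values use ε-scaled numerator and denominator df. Note that pingouin
estimates ε from the grand covariance; with a group effect present the
two conventions differ slightly (the tests cross-check SS and F exactly
and ε approximately).

## Fatigue traces

Force traces are moving-average smoothed (window 0.2 s) before any
threshold logic; MVC is the smoothed maximum. Time-to-fatigue is the
first time the smoothed force stays below the threshold — the gate-2
upper force limit, 40% of MVC — for at least 0.5 s (`hold`), so brief
transducer dips cannot fake a crossing; a sub-`hold` run that persists
to the end of the recording still counts, since the force never
recovered. Window and hold are package choices (the trace-processing
details are not published); both bias the crossing time by less than
one smoothing window on realistic decay rates, and by less than one
sample period on noiseless exponentials.

## Synthetic generator

The generator emulates the study conditions so that every analysis
stage has a ground truth:

* **Design:** 2–3 groups × 1–4 days × 4 blocks × 30 trials; preset
  group sizes 20/18 (experiment 1), 10/10 plus 15-trial untrained-hand
  pre/post blocks (experiment 2), 10/15/15 (experiment 3), 9/9
  sequence task (experiment 4). Preset slope magnitudes (≈0.17 vs
  ≈0.04 skill units/block, and the per-day triplets of experiment 3)
  are plausible presets of the observed order, not ground truth.
* **Movement times:** lognormal, median 3.2 s shrinking 4% per block,
  σ = 0.15, floored at 1.2 s.
* **Errors:** each group-day-block has a target skill
  `baseline + carryover·(day−1) + slope·(block−1)`; inverting the
  skill formula at the block's median MT gives the per-trial error
  probability, and per-gate Gaussian execution noise is calibrated so
  that the probability of missing at least one of the five gates
  equals it. Noise SD is proportional to the gate's force window
  (signal-dependent noise). Gate centers sit at 12/35.7/18/28/9% of
  MVC (±12% windows; gate 2's upper limit is 40% MVC).
* **Fatigue bias:** on fatigue days the executed force is pushed up
  multiplicatively by `β·(1 − F_target/F_max)` — largest at the
  low-force gates, zero at the strongest gate. This is a
  sensory-attenuation-style phenomenological model chosen by this
  package; the study describes the phenomenon (overshoot concentrated
  at low-force targets), not a generative form.
* **MVC traces:** `F(t) = MVC·exp(−λt) + noise`, with
  λ = ln(2.5)/68.91 s⁻¹ so the force reaches 40% MVC (the stopping
  threshold, hence a 60% decrement) near 69 s; per-subject rates are
  lognormal (σ = 0.45, mean-centered) giving a right-skewed
  time-to-fatigue distribution with mean ≈ 69 s and SD ≈ 33 s. The
  control arm holds 5% MVC flat.
* **Sequence task:** movement time is the sum of 10 per-press
  lognormal times (median 0.5 s, 10% speedup per block); each press is
  wrong with probability 0.02. Groups share parameters — the task
  showed no fatigue effect, so the generator's group structure is null
  by construction.
* **Seed discipline:** the master seed spawns one substream per
  (group, subject), so adding a subject never perturbs existing
  subjects' data; identical seeds give byte-identical tables.

A second, minimal generator (`simulate_skill_series`) draws block-level
skill directly as `baseline + slope·(block−1) + N(0, σ)`. Calibration
and recovery studies (type-I error, slope recovery) use it because its
noise level is defined on the skill scale; the trial-level generator's
skill noise is an emergent mix of binomial error-rate and lognormal MT
variation. On trial-level output the pooled robust fit recovers the
configured slope to within a few percent, with mild attenuation from
the right-skewed skill distribution.

**What passing tests do not show about real data:** the generator has
no trial-order learning within a block, no subject-level slope
heterogeneity beyond noise, no MT–accuracy coupling within trial, and
its error mechanism is stationary within a block. Conclusions about
estimator calibration transfer to real data only to the extent these
simplifications are benign.

## Problem sizes in the test suite

The statistical tests run at the study's scale where that is cheap
(10,000 resamples for single comparisons) and at reduced but
well-powered scale for replicated studies: 400 replicates × 500
resamples for null calibration, 200 seeds for slope recovery, 100
replicates for separation detection, 50 random designs for the ANOVA
oracle. These sizes keep Monte-Carlo error well below the decision
margins involved.

## Known limitations

* The within-group across-day resampling scheme is this package's
  choice (labeled in output metadata), not a published procedure.
* ANOVA supports the complete balanced-within mixed design only — by
  design, since incomplete designs in this task indicate dropped
  blocks that should be handled upstream.
* The OSF-deposit loading path is a generic CSV reader plus column
  mapping; no downloader is shipped and no analysis here depends on
  the human dataset.
* EMG is carried only as an optional parallel channel concept; no EMG
  processing is implemented.
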