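# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `rehabdst`, in the spirit of a model-documentation page:
what the package computes, which knobs matter, and what its tests do and do
not demonstrate.

## Data model

The raw grain is one played game round: patient, calendar date, game id
(1–7), an automode flag, a map of kinematic scalars, and the three robot
difficulty parameters (stiffness/weight ∈ {Low, Mid, High}, viscosity ∈
{Low, High}). Rounds of the same game on the same date are averaged into a
*session* — one time-step — which both de-noises the kinematics and defines
the temporal grid. Dates are handled internally as integer day offsets from
each patient's first session (ISO-8601 on disk).

Choices where the procedure was genuinely open:

* **Mutuality filter.** A feature is kept when the number of games whose
  feature set contains it exceeds 70% of the *configured* number of games
  (strict `>`, denominator 7), treating the filter as a dataset-level schema
  decision rather than a per-patient one. With masks unknown, game support
  is estimated observationally from non-missing values.
* **Missing values.** Same-patient, same-date mean over any game first;
  then front-fill from the most recent prior session; a patient whose
  history starts with a gap is back-filled, and a feature never observed
  for a patient is zero-filled with a logged warning. Whether the date mean
  may pool across games is not determined by the procedure's description;
  any-game pooling is used (richer same-day information).
* **Attendances** are distinct calendar dates with at least one active
  (non-automode) session; the ≥10 boundary is inclusive. A patient failing
  both exclusion rules is counted once, under the missing-post-assessment
  reason.
* **Robot-parameter attachment.** When the rounds averaged into a session
  disagree on a level, the chronologically last round wins (the therapist's
  most recent decision); a round missing a parameter defers to the nearest
  round carrying it.

## Time-related features

Seven per-session counters/offsets (days or counts): day offset from the
first session; gap to the previous session (0 within a date); a declining
per-time-step counter L…1; rounds averaged into the session; sessions
sharing the date; a running session counter; and the automode count of the
date. The declining counter presumes a known series length, so time
features are computed **after** shrinking, on the final 64-point grid —
this keeps the counter consistent between training and inference on the
harmonized tensor.

## Normalization

All features are mapped to [0, 1] with the fitted maxima retained for exact
re-application and inversion:

* age / cohort max; gender already binary; latency via `log1p` then
  division by the cohort max of the transformed values (`log1p` rather than
  a bare log so latency 0 is representable; natural base).
* kinematics / per-(game, feature) **training-fold** maxima — the
  best-performing patients define each game's reference scale. Test values
  above the training maximum clip to 1; the alternative (cohort-wide
  maxima) would leak test information into training.
* robot levels ordinally encoded 1..k and divided by k
  ({1/3, 2/3, 1} and {1/2, 1}).
* time features / each patient's own per-feature maximum, making the unit
  "fraction of this patient's own schedule" (every nonzero feature attains
  1.0 somewhere in the series).
* clinical scores / scale maxima (57, 66, 100), inverse exact to machine
  precision.

## Padding and shrinking to 64 time-points

Short series are zero-padded at the end with a validity mask; because the
recurrence is causal and the loss masks padded steps, values stored in the
padding are provably inert (asserted by test). Long series are shrunk
iteratively: partition into date groups; rank by unique-game count
(descending), ties by the smaller day-gap to adjacent groups, then by
earlier date; remove from the top group the single session of the currently
most frequent game (ties to the lowest game id); recompute everything.
Whether an equal-diversity tie should prefer the small or the large
adjacent gap is ambiguous; the default prunes the denser temporal region
(`small_gap_first`), with the opposite order behind a config switch. All
tie-breaks are total, so shrinking is fully deterministic, and an
independent brute-force reference implementation agrees on hundreds of
randomized series.

## Models

**Outcome predictor** — six stacked 32-unit LSTM layers (tanh cell
activations, per-gate orthogonal recurrent init, forget-gate bias 1), 20%
dropout after each, and a linear 3-unit dense head shared across
time-steps; masked MSE against the normalized discharge triple repeated at
every valid step; RMSprop at batch size 1 (patient-by-patient updates);
predictions clipped to [0, 1] before denormalization. Early stopping
monitors a held-out 15% patient split (patience 20 by default, best
weights restored).

The learning rate deserves a note. The default is **0.001**. A 0.1 initial
rate was evaluated extensively for this architecture at batch size 1:
RMSprop's per-parameter normalization keeps the loss finite (no NaN), but
each update then moves weights by ~0.1, which random-walks the network into
saturated gates; held-out RMSE ends well above that of a constant
predictor, and annealing schedules started at 0.1 could not recover
(the saturated weights are a poor basin, and a small validation split
occasionally rewards lucky bounces). Higher rates remain configurable and
are guarded: a run that produces a non-finite loss, or that has not beaten
the internal constant-predictor baseline (MSE of predicting the training
labels' mean) within a 10-epoch warm-up, is declared divergent and
restarts from scratch at the fallback rate.

**Difficulty recommenders** — one classifier per parameter, consuming
look-back windows of consecutive valid time-steps and predicting the next
session's level: stiffness 2×64 units, look-back 3, dropout 0.1; weight
1×32, look-back 3, dropout 0.2; viscosity 1×64, look-back 5, dropout 0.2.
Softmax output, categorical cross-entropy, Adam, batch size 256. Windows
with fewer than L predecessors are skipped rather than padded, and no
window or label touches a masked row. The recommended level is the argmax
class; exact ties resolve toward the easier level.

**Random-forest baselines** — scikit-learn forests with fixed
hyperparameters (outcome regression: 300 trees, depth 10, split 5, leaf
20; recommendation: 350, 15, 5, 5), the regressor on per-time-step
36-feature rows, the classifiers on flattened L×36 windows, trained on the
identical patient-level folds as the recurrent models.

The recurrent engine itself (`rehabdst.nn`) is a NumPy implementation —
forward, backpropagation through time, inverted dropout, RMSprop/Adam with
optional global-norm clipping — whose sequential step loops are
JIT-compiled with numba when available (pure-NumPy fallback otherwise).
Gradients are verified against central finite differences in the test
suite. Everything is seeded through `numpy.random.Generator`; single-
threaded runs are bit-reproducible.

## Evaluation

Patient-level k-fold cross-validation (default k=5, balanced, seeded); the
normalizer is fitted per fold on training patients only. Outcome errors
are computed at every valid step against the discharge label and pooled
over sessions and patients within each test fold (pooling, not
per-patient-then-average — checked against brute force); RMSE/MAE are
reported in normalized units and scale units. Recommendation metrics are
overall accuracy and F1; for the 3-class parameters F1 is the
support-weighted average of one-vs-rest scores (macro available).
Fold-level aggregates report mean ± std and min/max.

Per-patient prediction quality uses the percentage difference
PD = (y − mean ŷ)/scale-max (positive = under-prediction), stratified
against an MCID operationalized as 10% of each scale: within for
−0.10 ≤ PD ≤ 0.10 (boundaries inclusive), over-predicted below, under-
predicted above.

Permutation importance shuffles one feature at a time across samples — by
default as whole per-sample trajectories, preserving within-series temporal
coherence; per-time-step shuffling is available — and measures the
degradation of RMSE (outcome) or accuracy (recommendation) over seeded
repeats (default 10 in the library API); negative degradations clip to 0
and scores normalize to sum to one. Model comparisons across folds use a
two-sided paired Wilcoxon signed-rank test; the choice of test is a
package decision, reported alongside descriptive deltas, with all-tied
pairs degenerating to p = 1.

## Synthetic cohorts

The generator emulates the dependence structure the pipeline assumes, not
biomechanics:

* Each patient has a latent motor ability a_t ∈ [0, 1] following an
  exponential approach to a patient-specific plateau,
  a_t = c − (c − a₀)·e^(−r·t) with a₀ ~ U(0.05, 0.35), plateau gap
  c − a₀ ~ U(0.1, 0.6) (capped at 0.95) and rate r ~ U(0.01, 0.06) per
  day, plus small Gaussian jitter. An earlier clipped-linear form was
  discarded during design because most patients saturated at the cap,
  collapsing discharge-score variance.
* Kinematic values are game-specific baselines (log-uniform over two
  decades) scaled by (0.3 + a_t) with multiplicative log-normal noise
  (σ = `noise_sd`, default 0.05) — non-negative by construction, as the
  max-division normalizer requires. In signal-injection mode a single
  designated feature carries the ability signal and the rest are
  stationary noise (used by explainability recovery tests).
* Discharge scores are monotone in final ability
  (T1 ≈ (0.1 + 0.8·a_T)·scale-max, observation noise `noise_sd`, clipped
  and rounded); baselines T0 ≈ 0.7·a₀·scale-max.
* The therapist policy makes one joint persistence draw per day (default
  0.9): repeat yesterday's levels, else move every parameter one level
  toward harder if ability exceeds the escalation threshold (0.5), easier
  otherwise, clamped at the ends.
* Automode probability decays geometrically over therapy days (0.3 ·
  0.7^day-index); automode rounds carry ability-unrelated values. Feature
  masks default to the 16 canonical features in ≥6 of 7 games plus two
  decoy features in 3 games, so the mutuality filter is exercised by
  default. Therapy spans 10–40 distinct days with 1–4 games per day, which
  places series lengths on both sides of the 64-point target; demographics
  are age ~ N(65, 12) clipped, balanced gender, log-normal latency.

What passing tests therefore show: the pipeline's invariants hold, the
models can recover planted, learnable structure (latent-recovery-driven
outcomes; a persistence-biased policy), and the evaluation machinery
measures what it claims. What they do not show: performance on real
cohorts, whose kinematics are richer, noisier and confounded in ways the
generator does not attempt (no inter-rater variability structure, no raw
force/position signals, no game-specific feature semantics).

## Problem sizes

The default test-suite and acceptance-script runs use 40–60 patient
cohorts, 5-fold cross-validation, and epoch budgets of 120–150 with early
stopping (patience 20–30) — sizes at which every recovery margin is wide
(outcome RMSE ≈ half the constant-predictor baseline; recommender accuracy
20+ points above majority class) while a full run stays in the
single-digit-minute range on one CPU.

## Known limitations

* The recurrent engine implements exactly the layers these models need; it
  is not a general deep-learning library (no GPU, no exotic layers).
* Normalization clipping discards information for test patients who exceed
  training maxima; robust/quantile scaling is out of scope.
* The difficulty recommenders imitate the (synthetic) therapist policy;
  nothing links recommendations to improved recovery.
* `remaining_day_of_therapy` encodes the final series length, which is
  only known retrospectively; real-time deployment would need a planned-
  schedule substitute.
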