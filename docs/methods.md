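# Methods

This note documents the models, parameters and design decisions behind
`dynsit`: what the synthetic signal generator emulates, how the
classification benchmark is run, and the exact semantics of the reminder
engine. It is written for readers who want to judge what results on the
synthetic data do and do not show.

## 1. Posture vocabulary

Seven classification labels, coded 0–6: stance (0), upright (1), back bent
(2), leg crossed (3), forward (4), backward (5), other (6). At acquisition
time the leg-crossed class is recorded as two sub-variants (left/right), for
eight acquired types in total; the four back-mounted channels barely
distinguish the two sides, so both encode to code 3. Standing is acquired so
the system can tell sitting from not-sitting; it belongs to no hazard tier.

## 2. Synthetic signal model

One frame is a 4-vector of capacitance values (arbitrary units). For
participant *i*, posture *p*, channel *c*:

```
x = s_ic · mu_pc + eps,   s_ic ~ N(1, sigma_s),   eps ~ N(0, sigma_n · r_p)
```

* `mu` — fixed class-mean table (`DEFAULT_CLASS_MEANS`; the "other" class is
  a 4-mode mixture, `DEFAULT_OTHER_MODES`). The table is **synthetic**: no
  published capacitance values exist, so it is constraint-driven (below).
* `s_ic` — per-participant, per-channel gain, SD `participant_scale_sd`
  = 0.04. One gain per channel, drawn once per session, models both body
  build (height/weight) and sensor seating on the garment. It is exactly
  removed by per-participant min–max normalization.
* `eps` — i.i.d. sensor noise, base SD `noise_sd` = 0.7 units, scaled by a
  per-posture factor `r_p` (0.7 for rigid standing up to 1.2 for postures
  with sustained muscle engagement, `DEFAULT_NOISE_SCALE`).

Protocol defaults mirror the acquisition campaign: 20 participants × 8
acquired types × 30 s × 2 Hz → 60 frames per posture, 480 per participant,
9600 in total. Participant *i* uses sub-seed `seed + i`, making sessions
independently reproducible.

Constraints the default table satisfies (all checked by `SimConfig.validate`
and the test suite):

1. **C1 dominates.** The between-class range of channel C1 (4–33 units) is
   strictly the largest of the four channels — C1 is the most discriminative
   sensor.
2. **Leg-crossed sub-variants are inseparable.** Left/right crossed means
   differ by at most `crossed_gap` = 0.5 units on every channel, below one
   noise SD: a 4-channel classifier cannot reliably split them, which is why
   they share one label.
3. **The catch-all class interleaves.** "Other" covers miscellaneous
   postures (tilting, slouching variants); its four mixture modes sit
   *between* the defined classes along C1 (at ≈ 13, 19, 24.7 and 30.2
   units, each ~3 noise SDs from its neighbours). Recognizing it therefore
   requires carving several narrow intervals out of the C1 axis rather than
   thresholding once.

The third constraint is the deliberate hard part of the problem, and it is
what gives the benchmark its discriminative power between classifier
families. With a unimodal "other" the task reduces to well-separated
Gaussian blobs in four dimensions, where every reasonable classifier sits at
the Bayes limit and the family comparison is a coin flip. The interleaved
geometry instead favours methods that can express fine axis-aligned
structure (tree ensembles, nearest neighbours) over a single-bandwidth RBF
kernel, reproducing the ordering observed on the real garment data: random
forest first with the smallest fold-to-fold spread, SVM accurate but less
stable. On the default cohort (seed 42) the measured ten-fold CV means are
RF ≈ 97.1 %, KNN ≈ 96.3 %, DT ≈ 96.0 %, SVM ≈ 94.5 %; across other seeds RF
stays first at 95.6–97.1 %.

**What the simulator does not model:** capacitance physics, viscoelastic
drift within a posture hold, garment slippage over a day, transition frames
between postures, class imbalance, or real left/right asymmetries. Passing
benchmarks here show the pipeline's logic is correct and that the selection
rule behaves as documented under realistic statistical structure — they are
not evidence about accuracy on real garment data.

## 3. Preprocessing

* **Validity filter** — frames with any non-finite channel or any channel
  outside configured bounds are dropped, order preserved. Default bounds are
  the simulator's signal range (class means ± 4 noise SDs) padded by 50 % of
  its own width; "invalid" has no published definition, so this is
  configuration, not doctrine.
* **Label encoding** — acquired types → codes 0–6, merging the crossed
  sub-variants; unknown names raise with the offending value.
* **Min–max normalization** — per channel, `x ↦ (x − min)/(max − min)` with
  extrema fitted on the **training partition only** (fitting on all data
  would leak test information) and applied unchanged elsewhere. Out-of-range
  values are *not* clipped, keeping the map affine and invertible; a
  constant channel maps to 0. The quotient form is used directly because it
  is exact at the training extrema. A per-participant variant
  (`minmax_normalize_per_participant`) rescales within each participant's
  session and exactly removes the multiplicative gain; the global variant is
  the default because the deployed pipeline normalizes pooled data before
  splitting by class, not by wearer.
* **Split** — stratified 80/20, seeded; classes with one member are
  rejected under stratification.

## 4. Classifier benchmark

Four families, each with a small exhaustive grid bracketing its typical
optimum: KNN (k ∈ {1,3,5,7}), RBF-SVM (C ∈ {0.1,1,10} × gamma ∈
{0.01,0.1,1}; one-vs-one multiclass, the libsvm default), decision tree and
random forest (max_depth ∈ {5,10,20,None}, min_samples_leaf ∈ {1,2},
min_samples_split ∈ {2,4}; the forest fixes 100 trees — the deployed
configuration's tree count is unpublished, and 100 is the sklearn default).

Pipeline per family: stratified 5-fold grid search on the training
partition (ties broken deterministically by lexicographic parameter order),
refit on the full training partition for held-out accuracy and the 7-class
confusion matrix, then stratified ten-fold CV on the full normalized dataset
with the grid optimum. CV reports the mean and the *population* SD of the
ten fold accuracies. The report carries both the grid-search CV score and
the held-out accuracy, since published accuracy tables rarely say which of
the two they show.

Selection rule: highest CV mean, ties broken by lowest CV SD — "highest
accuracy and strongest stability". All stochastic components (fold
shuffling, tree seeds, split) derive from one run-level seed.

## 5. Reminder engine

State: one trailing buffer + posture counter per hazard tier, and a
consecutive-sitting counter. Per tick (strict 1 s increments enforced):

1. The tick's label is appended to every tier's buffer (each capped at the
   tier's window length; older ticks fall out).
2. A tier is evaluated only once a full window of records exists since that
   tier's last reset. If some posture of the tier accounts for strictly
   more than `trigger_fraction` (default 0.70) of the window, one
   posture-change event fires (800 Hz, 3 s) and the tier's buffer is
   cleared. Tiers are checked serious → medium → low; at most one
   posture-change event per tick.
3. Any non-stance label increments the sitting run; stance resets it to
   zero. At `sedentary_window` (2700 s) a sedentary event fires (800 Hz,
   7 s) and the run restarts, so reminders repeat every 45 min of continued
   sitting.

Numerical care: "strictly more than 70 %" is evaluated as an integer
comparison `count > floor(fraction·window + 1e-9)`; the epsilon guards
against the float product landing an ulp below an integer (0.7 × 600 =
419.999…94), which would otherwise turn the strict inequality inclusive.

Design choices where the published description is ambiguous, all
configurable:

* **Trailing windows with reset-after-fire** (rather than tumbling
  windows): reproduces every documented first-fire time (300/600/900 s) and
  prevents re-firing every second once a window saturates.
* **The 70 % threshold is generalized to all tiers.** It is documented for
  the 5-min leg-crossed case; its rationale (classifier noise, micro
  movements) applies identically to the 10- and 15-min tiers.
* **Per-posture counting inside the medium tier** — the four medium
  postures are counted separately, not pooled; alternating among them all
  day correctly never fires.
* **Sedentary vibration frequency** is unpublished; it defaults to 800 Hz,
  with the 7 s duration (vs 3 s) carrying the distinction.
* **Sedentary repetition** is unpublished; the timer restarts after firing.

`recover_trigger_threshold` closes the loop behaviourally: it builds
synthetic windows containing *k* target-posture ticks (the remainder cycled
over the other sitting postures so no filler can itself trigger), bisects
*k* on the fire/no-fire boundary, and returns the largest non-firing
fraction — 0.70 under the default configuration, by construction of the
strict comparison.

A deliberately naive reference engine (`run_session_bruteforce`) re-counts
full windows from scratch at every tick with separate bookkeeping; the
incremental engine must emit the identical event list on randomized two-hour
streams (property-tested over 100 seeds, plus hypothesis-generated schedules
with shrunken windows).

## 6. Session reports and phase comparison

A session report aggregates: total sitting seconds (non-stance ticks),
posture changes, and reminder counts by kind. A *posture change* is a
transition between distinct labels after suppressing runs shorter than a
debounce (default 3 s) — per-second classifier jitter is not a real change;
the published logging counts changes without defining a transition, so the
debounce is an explicit, configurable choice. History is an append-only
JSON-lines store; corrupt lines are skipped with a counted warning.

The before/after intervention comparison is a paired-sample t-test
(`scipy.stats.ttest_rel`) on per-subject posture-change counts, computed on
`before − after` so the statistic is negative when counts rise in the
intervention phase. Zero-variance differences are flagged degenerate (t = 0
for identical vectors, no p-value). The implementation is tested against the
closed-form statistic to 1e-9.

## 7. Problem sizes

Defaults everywhere are the full study conditions: 9600-frame cohorts, ten
CV folds, two-hour engine streams, 100-seed equivalence sweeps. The
complete test suite runs in about two minutes on one CPU, the acceptance
script in under one; nothing is scaled below the documented protocol.

## 8. Known limitations

* The class-mean table is invented under constraints; absolute accuracies
  on it are properties of the synthetic geometry, not of any garment.
* The engine assumes a gapless 1 Hz label stream; dropped ticks raise
  rather than being interpolated.
* The paired-t comparison reproduces the statistical procedure; the
  published per-subject counts exist only in a figure, so its headline
  statistic (t = −8.79, n = 8) is not recomputable and is treated as
  documentation.
* `EngineConfig` requires the sedentary window to exceed every tier window
  and tiers to partition the six sitting postures; exotic configurations
  outside those invariants are rejected rather than supported.
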