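# Methods

## Signal model and preprocessing

An insole VGRF record is a 19-column time series: time (s), eight
left-foot sensor forces, eight right-foot sensor forces and the two
per-foot totals, all in newtons, nominally at 100 Hz. Parsing enforces
nonnegative forces (negative readouts are clamped to zero and logged)
and flags, without rejecting, records whose stored totals deviate from
the sensor sums by more than 0.5 N at any sample — small bookkeeping
discrepancies are common in archived recordings and harmless because
every downstream computation uses the sensor sums, never the stored
totals.

Preprocessing applies three steps in a fixed order: (1) every sample of
every sensor series strictly below the 20 N noise floor is set to zero
(a sample exactly at 20 N survives); (2) the first 20 s are discarded
to remove the gait-initiation transient; (3) the per-foot total — the
sum of the eight *floored* sensor series — is segmented into stride
cycles. Flooring per sensor before summation is the stricter choice:
it also removes sub-floor noise that happens to co-occur across
sensors.

### Segmentation

After flooring, the total force alternates between positive runs
(stance) and zero runs (swing). A stride cycle is a stance run plus
its following swing run, *closed by the next stance onset* — heel
strike to heel strike. Three kinds of material are discarded as
incomplete: a leading zero run, a positive run starting at sample 0
(its true onset precedes the series, e.g. after trimming cut it), and
any trailing stance or unclosed swing. Requiring the closing onset is
what makes every feature invariant to appending sub-floor noise at the
end of a record; accepting a trailing swing would let the record
length leak into the last swing time. The mirrored swing-first
convention (swing run paired with the following stance) is available
via `cycle_order="swing_first"`; the populations of stance, swing and
stride times are identical under either convention.

Cycles with stride time outside [0.4, 4.0] s or swing fraction outside
[0.05, 0.70] are dropped and counted. The 20 N floor removes sensor
noise but says nothing about pathological run structure (a single-
sample stance from a residual spike would otherwise produce a stride);
the bounds are generous for human walking at natural pace.

## Features

Thirteen scalars per subject, computed from the segmented cycles of one
foot (left by default, since unilateral sensor arrays are the common
acquisition):

* **cv_swing, cv_stride** — coefficient of variation of the per-cycle
  swing and stride times, in percent. The default convention is the
  standard 100·SD/mean with the sample (n−1) SD; the reciprocal
  100·mean/SD that some reports print is available as
  `cv_convention="reciprocal"`. The two are monotone reparameterizations of
  each other, so classifiers are unaffected, but the standard form
  stays finite for perfectly regular gait (SD → 0).
* **mean/sd_cop_x, mean/sd_cop_y** — the centre of pressure at one
  instant is the force-weighted mean sensor coordinate,
  CoPₐ = Σᵢ sᵢₐ·fᵢ / Σᵢ fᵢ. It is evaluated at every stance sample of
  every cycle and the mean and sample SD are taken over the pooled
  per-sample values. Pooling (rather than taking the SD of per-cycle
  means) is the larger-variance reading and captures the within-stance
  heel→toe excursion, which is exactly the contrast of interest for
  flat-footed gait.
* **mean/sd_pf_heel, mean/sd_pf_toe** — per cycle, the heel-strike peak
  is the maximum of the summed heel-role sensor force over the first
  five stance samples (50 ms at 100 Hz) and the toe-off peak the
  maximum of the summed toe-role force over the last five; the feature
  is the mean (and SD) over cycles. Summing the role sensors before
  the max keeps the feature layout-independent; a per-sensor max is
  available via `peak_mode="per_sensor"`. The 5-sample window is
  configurable; stances shorter than the window fall back to the full
  stance with a logged warning.
* **mean_kurtosis, mean_skewness** — Pearson (non-excess, normal → 3)
  kurtosis and standardized skewness of the total-force waveform within
  each cycle's stance, population (n) normalized, averaged over
  cycles. Stance-only is the default scope (the swing zeros carry no
  waveform shape); the full cycle is available via
  `shape_scope="cycle"`.
* **mean_peak_power** — 10·log₁₀ of the maximum of the one-sided
  periodogram (rectangular window, density scaling) of each cycle's
  total-force segment, averaged over cycles. Cycles are ~1 s
  (≈100 samples), far too short for Welch-style multi-segment
  averaging, so the single-segment periodogram is the honest estimator.

Subjects with fewer than 5 usable cycles are skipped with a logged
reason. Feature extraction is a pure function of (record, layout,
config); repeated runs are bit-identical.

### Sensor layout

Numeric sensor coordinates ship as a versioned YAML config
(`data/default_layout.yaml`) following the public gait-database
documentation for this insole system: a ±{300, 500, 700} × {−800 … 800}
grid with the origin between the feet and the subject facing +y. Heel
role = minimum-y sensor(s), toe role = maximum-y, unless roles are
given explicitly; all CoP and peak-force code takes the layout as a
parameter, so other insole geometries are a config file away.

## Feature selection

* **Sequential forward selection** is a single ordered pass: the two
  timing-variability features enter unconditionally (they are the
  best-established group discriminators), then each remaining feature
  in table order is kept iff the wrapper accuracy with it is at least
  the accuracy without it — only a strict decrease rejects. The
  wrapper is LOO linear-SVM accuracy. Note the tie-keep rule: once the
  wrapper reaches its ceiling every later candidate ties and is kept.
* **mRMR** greedily maximizes relevance I(f; y) minus (MID) or divided
  by (MIQ) the mean mutual information with the already-selected set.
  MI is the plug-in estimate on empirical discrete distributions in
  bits; features are discretized into three bins split at
  mean ± 0.5·SD (the customary mRMR scheme; equal-frequency quantile
  bins are available). Ties break toward the earlier column, making
  the selection deterministic.
* **MI ranking** orders features by I(f; y) with the MI values as
  weights — the degenerate k = 1 case of mRMR applied to all features.

## Classification and evaluation

Evaluation is leave-one-subject-out: each subject is held out in turn,
the z-score standardization (SVM and kNN only; trees are
scale-invariant) and, when configured, PCA are fit on the remaining
subjects, the model is trained and the held-out subject predicted.
PCA retains the smallest number of train-fit components whose
cumulative explained variance reaches the requested fraction (0.95 by
default). Pooled out-of-fold predictions give the confusion matrix
(PD positive), accuracy, sensitivity, specificity, and the AUC of the
pooled continuous scores (SVM decision values, kNN positive-neighbour
fraction, tree/ensemble class probability; ties handled by midranks).

Classifier settings: SVM C = 1 and RBF γ = 1/(n_features·Var(X));
polynomial kernels are exactly (u·v+1)^d with d = 2, 3; kNN uses
k = 10, Euclidean distance, equal weights; the decision tree uses Gini
impurity with at most 20 splits (implemented as ≤ 21 leaves under
best-first growth); the boosted ensemble is AdaBoost over 30 such
trees at learning rate 0.1, and a bagged random forest with the same
tree cap is available as a separate family.

Selection wrapper accuracy and the final comparison use the same LOO
evaluator on the same subjects. This reproduces the common
single-level protocol and is optimistic relative to nested
cross-validation; the report keeps wrapper and final metrics labeled
separately so the caveat stays visible, and deliberately does not
"fix" the protocol.

### Known calibration bias of LOO under the null

Leave-one-out with balanced classes is pessimistically biased when the
features carry no signal: holding out a subject leaves its class in
the training minority, and any classifier drawn toward the training
majority then predicts the wrong class more often than not. On a
balanced 48-subject null cohort the per-replicate accuracy also has SD
≈ 0.09–0.10, above the binomial 0.072, because the folds share almost
all their training data. Calibration checks therefore see means
slightly below 0.5 (label-permutation means around 0.39–0.46 for the
linear SVM on a 40-subject fixture) — a property of the estimator, not
an implementation error. The test suite asserts chance-level behaviour
with this bias in mind.

## Synthetic cohort generator

The generator emulates the acquisition the pipeline targets: walks of
140 s (20 s trim + 120 s analysed) at 100 Hz, both feet in approximate
anti-phase (the contralateral foot is the same stride process shifted
by half a mean stride), per-foot totals equal to the sensor sums by
construction. Per stride, the stride time is drawn from a normal with
the profile's mean and CV, truncated to [0.4, 2.5] s, and the swing
fraction likewise (clipped to [0.15, 0.60]); the stance waveform is
built from role-specific activations — a quarter-sine heel rise
peaking at the programmed heel force on stance sample 4 with a
raised-cosine decay, the mirrored shape for the toe, and a Tukey-window
midfoot plateau normalized per frame to the body force. The midfoot
sensor weights sweep linearly from low-y to high-y sensors across
stance with modulation depth `cop_y_excursion`, which is the knob for
flat-footed loading. Gaussian sensor noise (σ = 5 N) perturbs stance
frames; swing samples receive Poisson-rate spurious blips uniform in
(0, 15) N — below the 20 N floor by construction. The first and last
stance samples carry ≈ 31 % of the heel/toe peak, so with noise
disabled the floored segmentation recovers every programmed boundary
and stride/swing time exactly; this is a deliberate generator property
that makes segmentation testable to the sample.

Default profile constants (stride 1.1 s, CV 4 %, swing fraction 0.38,
body force 700 N, heel peak 600 N, toe peak 650 N) are generator
conventions for an unimpaired adult; the default PD contrast doubles
the timing CVs, scales the peaks by 0.85 and the CoP sweep by 0.6 —
strong, qualitatively realistic effect directions chosen so that group
recovery is unambiguous. The default cohort shape is 29 PD + 18
control. Per-subject seeds derive deterministically from the cohort
seed and subject index and are recorded in the ground truth, so any
subject is re-simulable in isolation.

What the generator does *not* emulate: biomechanical inverse-dynamics
realism, double-support force sharing between feet, freezing-of-gait
episodes, drift or autocorrelated sensor noise, and real
between-subject heterogeneity beyond the programmed contrasts. Tests
passing on generator output therefore demonstrate that the pipeline
recovers the statistical structure it is designed to measure — not
that any particular clinical accuracy would be reached on real
cohorts, where effect sizes are far smaller and overlapping.

## Numerical and degenerate-input choices

Half-open 0-based sample ranges everywhere; forces in newtons, times
in seconds. The noise-floor comparison is strict (< 20 N → 0). CV
with zero mean (standard) or zero SD (reciprocal) raises a degenerate-
feature error, as do CoP on a zero-force frame, shape statistics on a
constant stance, and the PSD of an all-zero segment — callers only
reach these through malformed inputs, since segmentation guarantees
positive stance totals. SD-type features use ddof = 1 except the
population-normalized moment statistics, stated so oracles are exact.
Selection and evaluation are deterministic given (data, config, seed);
tie-breaks follow the fixed feature-table order.

## Problem sizes used in the test suite

Unit tests run on records of 30–140 s and cohorts of 2–47 subjects.
The calibration check uses 50 replicates of a 24 + 24 null cohort and
200 label permutations of a 40-subject fixture; the recovery check
uses 20 replicates of the 29 + 18 contrast cohort. The acceptance
script simulates one 47-subject contrast cohort, one noiseless record
for segmentation exactness, and 10 null replicates. These sizes give
stable Monte-Carlo estimates (binomial SE ≲ 0.01 on pooled
accuracies) at desk-scale runtimes.
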