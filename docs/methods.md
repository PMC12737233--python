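# Methods

`gaitpheno` re-implements, as a tested pipeline, a data-driven gait-phenotyping
analysis for older adults: stride waveforms from a foot-mounted IMU are
clustered into gait phenotypes via dynamic-time-warping (DTW) dissimilarity,
each phenotype's faller/non-faller contrast is modelled with four classifier
families whose attributions are merged by an accuracy-weighted Borda
consensus, and a phenotype-specific Timed Up and Go (TUG) screening cutoff is
derived per phenotype.  This note records the model, the choices made where
the design was open, and what the synthetic validation does and does not
show.

## Signal model and preprocessing

Input signals are three IMU channels sampled at 104 Hz: progression-direction
acceleration (acc_y, m/s²), vertical acceleration (acc_z, m/s²), and sagittal
angular velocity (gyro_x, deg/s), segmented into strides at stride-start
events supplied with the data (half-open `[start, next_start)` windows; the
tail after the last event is discarded).  Preprocessing is:

1. **Low-pass filter** — 4th-order Butterworth at 4 Hz, applied
   forward–backward (zero phase).  Only the cutoff is externally fixed; the
   zero-phase form is our choice, made so heel-strike and push-off landmarks
   are not delayed relative to the event table.
2. **Time normalization** — every stride is linearly resampled to L = 100
   points over normalized time [0, 1].  L = 100 is the conventional
   percent-of-gait-cycle resolution; linear interpolation adds no smoothing
   beyond the stated filter.
3. **Averaging** — the subject's representative gait is the pointwise mean of
   the normalized strides, per channel.  Strides whose duration falls outside
   median ± 3×MAD are excluded from the average (switchable off); outlier
   policy is ours, the source protocol is silent on it.

## Dissimilarity and embedding

PCA is fitted across the three channels with all subjects' time points pooled
as observations; the smallest component count reaching 80 % cumulative
explained variance is kept, and each subject's curve is projected to those m
channels — so the object entering DTW is still a time series.  Because the
channels keep their physical units, the gyroscope (hundreds of deg/s)
dominates the pooled variance and m = 1 is typical; this is the standard
behaviour of unstandardized PCA and is retained deliberately (the sagittal
angular velocity is also the most shape-informative channel).

DTW is classic unconstrained dynamic programming with steps
{match, insert, delete} and dependent multivariate Euclidean local cost; no
warping window.  Two dissimilarity modes exist:

* `waveform_only` — raw DTW distances;
* `waveform_plus_basic` — the DTW block and a Euclidean block on
  cohort-standardized age and height are each max–min rescaled to [0, 1] on
  their off-diagonal entries and added, the basic block weighted by λ
  (default λ = 1, equal weight — the fusion weight is not externally fixed).

Metric MDS (SMACOF stress majorization, seeded, d = 5 by default) embeds the
matrix for the algorithms that need coordinates.  A t-SNE reducer is kept as
a configuration option only; its output is not a time series, so that route
bypasses DTW and is a documented deviation.

## Two-stage clustering-method selection

Candidate conditions are {k-means++, k-medoids++, fuzzy c-means, hierarchical
average linkage} × k ∈ {3, 4, 5} × the two matrix modes.  k-means and fuzzy
c-means run on the MDS coordinates; k-medoids (careful distance-proportional
seeding, then medoid-swap refinement, 10 restarts) and hierarchical run on
the dissimilarity matrix directly.  Fuzzy exponent m = 2.0, tolerance 1e-6,
max 300 iterations, memberships defuzzified by argmax; collapsed solutions
are re-seeded.

**Stage 1 — effect-size gate.**  For each of seven key fall-related
parameters (cadence, step speed, stride length, clearance, swing %, SPPB,
TUG), normality per cluster is tested with Shapiro–Wilk (α = 0.05).  If every
cluster is compatible with normality, one-way ANOVA with η² =
SS_between/SS_total is used; otherwise Kruskal–Wallis with
ε² = H/(N−1) (algebraically equal to H·(N+1)/(N²−1)).  A condition is
admissible when strictly more than 0.14 — the minimum clinically meaningful
effect size — is reached on at least 4 of the 7 parameters.  Clusters with
fewer than 3 members force the rank-based branch (normality untestable).

**Stage 2 — composite quality.**  Over admissible conditions, silhouette
(computed from the precomputed dissimilarity matrix), Davies–Bouldin (from
the embedding) and cluster balance (max size − min size) are max–min
normalized, direction-aligned and summed with equal weights (the combination
is only stated to be linear; equal weights are ours).  If an index is
constant across the admissible set its normalization is undefined; it then
contributes 0.5 — a neutral value that keeps the composite defined (a single
admissible condition therefore scores 1.5).  Ties break on raw silhouette.

## Faller models

Per phenotype, four families on the 25 gait/clinical features (the fall label
is never a feature; TUG time is one): random forest, gradient-boosted trees
(XGBoost, logistic objective), a single decision tree, and a feed-forward
network (MLP, Adam, early stopping on a 10 % validation split with patience
10).  Tree families use mean imputation + z-scoring; the network uses median
imputation, IQR clipping to [Q1 − 1.5·IQR, Q3 + 1.5·IQR] and robust
median/IQR scaling.  All preprocessing is fitted on training folds only.

Hyperparameters are tuned by exhaustive grid search under stratified 5-fold
CV scored by mean validation F1 (folds undefined-F1 counted as 0), with
inverse-frequency class weights; the winning setting is refit on all of the
phenotype's subjects with a raised iteration cap for the network.  The MLP
accepts neither class nor sample weights, so its class weighting is realized
by deterministic minority-row duplication to balance — equivalent to integer
inverse-frequency weights.  Metrics (accuracy, precision, recall,
specificity, F1) are computed per fold from the confusion matrix, averaged,
and reported with a normal-approximation 95 % CI (mean ± 1.96·SD/√5);
zero-denominator ratios are reported as missing, never as zero.  The full
grids from the study protocol are encoded as the defaults; the synthetic
analyses use a reduced grid (one axis of variation per regularization knob)
sized to ~35 subjects per phenotype, where a 648-point forest grid would
only multiply fits without changing the conclusions.

## Attributions and Borda consensus

Global importance per model is the mean absolute per-subject attribution
toward the faller class.  scikit-learn trees and forests use an in-package
implementation of the exact path-dependent tree-Shapley algorithm (verified
in the tests against exhaustive coalition enumeration of the cover-weighted
value function; attributions + base value reproduce the model's
positive-class probability to 1e-9).  XGBoost uses its native
`pred_contribs` (the same algorithm, in margin space).  The MLP uses
permutation-sampling Shapley values with a fixed 25-row background and 32
antithetic permutations; the telescoping sum over each permutation makes the
attributions exactly additive despite sampling.

Importances become tie-averaged descending ranks r_ij (ties share the mean
of their positions, so half-integer ranks occur — the decision tree's many
zero importances produce them naturally).  Borda points s_ij = n − r_ij + 1
with n = 25 features are weighted by w_j = the model's raw (unnormalized)
mean CV accuracy and summed: S_i = Σ_j w_j s_ij.  Raw accuracies are the
only weighting that reproduces the published worked-example score
magnitudes; with four models and accuracies in the usual range, S_i > 60
marks strong cross-model agreement.  A tree-only three-model consensus is
supported as a variant.  Ordering ties break on the first model's rank, then
feature index.

## TUG screening

Per phenotype, the decision rule is *predict faller iff TUG ≥ cutoff* (the
risk direction is explicit — longer is worse; the ≥ boundary is ours).
Candidate cutoffs are midpoints between consecutive distinct TUG values plus
below-min and above-max sentinels — midpoints are what produce cutoffs that
are not observed scores.  The cutoff maximizing Youden's J = sensitivity +
specificity − 1 is chosen, ties resolved toward higher sensitivity
(screening favors not missing fallers), reported to 2 decimals, and compared
with the conventional uniform 13.50 s standard on precision, recall, F1 and
accuracy, in-sample.  All cutoffs are exploratory reference values, not
definitive clinical thresholds.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes — not
biomechanics.  Four archetypes (high-cadence, cautious, intermediate,
robust) are parameterized by the published cohort profiles: cadence
(53.7/46.5/48.3/51.9 strides/min), step speed (0.84/0.67/0.85/1.10 m/s),
stride length, SPPB, TUG, FES-I means, with within-phenotype SDs in the
published range; gait-cycle phase fractions, clearance, angles, age and
height are chosen as field-plausible values.  Subjects split near-equally
across archetypes; per-subject latents are archetype mean + Gaussian offset.

Each stride is a sum of event-locked Gaussian bumps positioned by the phase
fractions — heel-strike impact in acc_z, braking and push-off lobes in
acc_y, a swing lobe in gyro_x — scaled by per-stride speed and clearance,
with archetype-specific bump-width and amplitude signatures, additive white
noise (0.3 m/s² accelerometer, 6 deg/s gyroscope) and per-stride timing
jitter set by the subject's stride-time SD.  Stride counts are uniform
20–60 per subject (free-walk lengths vary per subject; the source protocol
states no counts, so this is an explicit assumption).  The standard
parameters (means, SDs, totals, paths) are derived from the generated
strides themselves, so derived features and waveforms are mutually
consistent.

**Fall mechanism.**  Within each phenotype, fall probability is logistic in
one standardized *driver* feature — fear-of-falling score (Short FES-I, +)
in the high-cadence archetype, 4 m gait speed (−) in the cautious, push-phase
percentage (−) in the intermediate, stride-time SD (+) in the robust — with
|slope| = 2.0 per SD (a strong risk factor, odds ratio ≈ 7 per SD) and the
intercept calibrated by root finding so the expected prevalence equals the
archetype targets (0.56, 0.68, 0.48, 0.27).  Labels are Bernoulli draws.

**Separation dial.**  A scalar multiplier stretches every between-archetype
mean difference about the grand mean (waveform shape signatures included).
At 0 the archetypes coincide and downstream clustering performs at chance;
the property-based validation runs at 2.5, where the pipeline recovers the
planted partition with ARI ≈ 0.98.  The default 1.0 mirrors the published
between-group spreads, under which phenotypes overlap substantially — as
real cohorts do.

**What the synthetic validation does not show.**  Passing tests demonstrate
internal correctness (oracle equivalence of DTW, Youden scan, effect sizes,
Shapley values) and end-to-end recoverability of planted structure; they say
nothing about phenotype validity in real cohorts.  Specific simplifications:
clinical scores are conditionally independent given the phenotype (no
within-phenotype correlation structure beyond the driver mechanism); TUG
time is not itself a fall driver, so the synthetic TUG screening stage
exercises the machinery near chance except where the driver correlates with
mobility; waveforms contain no turning, surface, or dual-task effects; and
sensor artifacts are reduced to white noise.

## Numerical and reproducibility notes

* Every stochastic stage consumes a child seed derived from the master seed
  by an FNV-style hash (all seeds < 2³¹); two runs with the same
  configuration produce byte-identical CSV reports.
* Stochastic clusterers use 10 restarts, best cost kept; k-medoids re-seeds
  a collapsed cluster at the worst-served point.
* The DTW recurrence runs as a numba-compiled kernel over a precomputed
  local-cost matrix (an n = 146 cohort needs ~10⁴ pairwise alignments of
  100-sample series).
* Degenerate inputs are rejected with messages rather than coerced: empty
  stride lists, zero-variance curves for PCA, single-class label vectors,
  non-symmetric matrices, all-missing feature columns, ranks outside [1, n].
* Problem sizes used by the shipped analyses: 146 subjects, separation 2.5,
  reduced grids; the prevalence-calibration check uses 2000 subjects per
  archetype with 8–12 strides each (stride count does not enter the label
  mechanism).
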