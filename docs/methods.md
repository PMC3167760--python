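# Methods

This note documents the models and procedures implemented in `glaufuse`,
the defaults chosen where the design was open, and what the synthetic
cohorts do and do not establish.

## Data model and conventions

A subject record pairs one 24-2 visual-field test (52 pattern-deviation
probability categories on the 6°-spaced grid, blind-spot points (15, ±3)
excluded; Mean Deviation in dB; a hemifield-test label WNL/BORDERLINE/ONL)
with one circumpapillary OCT scan (256 A-scan RNFL thickness values in µm,
the average of three 3.4 mm scan circles; signal strength; age; spherical
equivalent).  Everything is kept in right-eye convention; files declare
`laterality: RIGHT_CONVENTION` and left-eye data must be mirrored by the
caller.  A-scan index *i* sits at scan-circle angle *i*·360/256°, index 0
on the temporal horizontal meridian, proceeding superiorly (TSNIT order).
This origin/direction is a convention of this package — instrument exports
do not state one — and is fixed in exactly one place (`glaufuse.cohort`).
The 52 grid points have a single canonical order (rows superior to
inferior, x ascending) so feature vectors are comparable across records.

## Normative database

For each of the 256 positions, thickness is regressed on age and spherical
equivalent by ordinary least squares over a healthy cohort (minimum 30
records; covariates centered, so the intercept is the prediction at the
cohort-mean covariates).  Residuals are stored per subject and position;
percentiles are empirical with a midrank tie convention (a value below all
*n* residuals maps to 100·0.5/*n*).  Empirical quantiles were preferred
over a Gaussian model because small normative cohorts make parametric
tails fragile; a zero-variance covariate is dropped with a warning rather
than producing an unstable fit.  Correction is additive in µm:
`corrected[p] = raw[p] − β_age[p]·(age − ā) − β_se[p]·(SE − SĒ)`.

Two scoring scales translate abnormality to integers.  Pattern-deviation
categories map to {GE5: 0, LT5: 2, LT2: 5, LT1: 8, LT05: 10}; this is a
documented stand-in for the hemifield-test scale, which is not public, and
is configurable — all downstream code is parameterized over the scale.
OCT percentile bands mirror it on the low side (<5%: 2, <2%: 5, <1%: 8,
<0.5%: 10) and score supra-normal thickening (>95%) −2, so fused SAP
scores can be attenuated as well as accentuated.

## Sector map and fusion transforms

The six scan-circle sectors use the classical angular boundaries
(temporal 311–40°, superotemporal 41–80°, superonasal 81–120°, nasal
121–230°, inferonasal 231–270°, inferotemporal 271–310°).  The assignment
of the 52 field points to sectors is generated by a simplified
nerve-fibre-trajectory model: the field point is inverted through the
nodal point onto the retina, fibres from nasal retina run straight to the
disc, and fibres from temporal retina arc around the fovea with their
entry angle pushed toward the vertical poles (2.9° per degree of retinal
eccentricity, clamped at ±80° so arcuate bundles never cross into the
nasal half, respecting the horizontal raphe).  The resulting map satisfies
the retinotopic inversion (superior field ↔ inferior disc) and partitions
both the 256 indices and the 52 points; it can be serialized to JSON,
inspected, and replaced by any user-supplied assignment.  It is a
reconstruction in the spirit of the published anatomical map, not a copy
of any figure.

`fuse_oct` multiplies sub-5th-percentile A-scans by `exp(−α·s̄)` with the
sector's mean PD score `s̄` and default α = 0.1.  The exponential form was
chosen so a fully normal field gives factor 1 (exact identity) and the
factor decreases monotonically with field damage; α is configuration, and
every output records the configuration used.  `fuse_sap` adds, per
sector, the score of the most extreme sub-5th-percentile position; only
when no sub-normal position exists does the most extreme supra-95th
(negative) score apply, and fused scores are floored at 0 by default so
attenuation cannot go negative.  Sub-threshold detection for `fuse_oct`
uses the single 5th-percentile cut; the graded bands enter only through
`fuse_sap` scoring.

## Features

PCA (centered, full SVD) retains the smallest leading component count
reaching 99.9% cumulative explained variance; loadings carry a fixed sign
(largest-magnitude element positive) for cross-platform determinism.  By
default the projection is fitted inside each cross-validation training
split and applied to the held-out fold ("train_fold" policy), preventing
leakage; a "whole_cohort" policy is available for comparisons.  The
retained component count is data-dependent and is reported, never assumed.
PD-score columns are not rescaled before concatenation with PCA scores;
the classifier standardizes its inputs internally (below).

## Classifier and training

Each ensemble member is a cascade-forward MLP: `h1 = tanh(W_ih1·x + b1)`,
`h2 = tanh(W_ih2·x + W_h1h2·h1 + b2)`,
`out = σ(W_io·x + W_h1o·h1 + W_h2o·h2 + b3)`, trained to mean squared
error on {0, 1} targets.  Hidden sizes default to 10/5 units for
score-vector inputs and 8/4 for compact PCA-only inputs, overridable.
Weights initialize uniformly in ±1/√fan_in per block, seeded.  Inputs are
z-scored per feature using training-set statistics inside the classifier,
keeping the tanh layers out of saturation regardless of input units
(scores vs µm-scale principal components); this mirrors the default input
preprocessing of standard neural-network toolboxes.

Training is Møller's scaled conjugate gradient: the step size comes from a
finite-difference curvature estimate along the conjugate direction
(σ₀ = 10⁻⁵), stabilised by Levenberg–Marquardt-style adaptation of a
damping parameter λ (raised when the quadratic comparison parameter
Δ < 0.25, quartered when Δ ≥ 0.75), with steepest-descent restarts every
*n_weights* iterations.  Accepted steps never increase the training error.
One iteration is one epoch; training stops at 500 epochs or after 10
accepted steps without improvement on the early-stopping set, and the
weights with the best stopping-set error are restored.

The ensemble has 35 members.  The training records are split into 9
stratified subsets; member *m* reserves subset *m* mod 9 for early
stopping (a round-robin, since the member-to-subset mapping is otherwise
unspecified) and trains on a bootstrap resample, with replacement and of
equal size, of the union of the other 8 subsets.  Members differ by both
bootstrap draw and weight initialization, each seeded from (ensemble seed,
member index).  The ensemble output is the unweighted mean of member
outputs.  Cross-validation is stratified 10-fold; out-of-fold outputs are
collected for every record, and fold assignment, subset splits and
bootstrap indices are all reproducible bit-for-bit from the seed.

## Evaluation

AROC is trapezoidal (equal to Mann–Whitney concordance with ties counted
½).  DeLong's test compares two correlated AROCs through placement-value
covariances with a two-sided normal p-value.  McNemar's test on paired
accuracies defaults to the exact two-sided binomial form
`p = min(1, 2·P(X ≤ min(b,c)))`, appropriate for the small discordant
counts at these cohort sizes; a χ² variant is available.  The operating
cutoff maximizes sensitivity × specificity (ties resolved toward higher
specificity); classification is "abnormal when score ≥ threshold".
Agreement between the function- and structure-based classifiers is an
odds ratio on the 2×2 agreement table at the fixed threshold 0.5, with
the Haldane–Anscombe +0.5 correction when a cell is empty.  Two
instrument-native comparators are provided: the hemifield-test rule
(borderline counts as abnormal) and the quadrant rule (abnormal if any of
the four 64-A-scan TSNIT quadrant means falls strictly below the
normative 5th percentile of quadrant means; the 64-A-scan blocks centred
on the temporal/superior/nasal/inferior meridians are this package's
reading of "quadrant", documented here because clock-hour groupings are
an equally defensible alternative).

## Synthetic cohorts

The generator emulates the *statistical structure* the pipeline assumes,
not instrument physics.  Healthy profiles follow a stylized double-hump
TSNIT curve (baseline 62 µm; superior/inferior humps of 65/70 µm, width
35°) with uniform covariate effects β_age = −0.2 µm/yr and
β_SE = +0.8 µm/D, recorded in cohort metadata for recovery tests.
Measurement noise of the 3-scan average decomposes into a per-test offset
(SD 2.5 µm), a smooth correlated field along the circle (SD 1.2 µm,
Gaussian kernel half-width 6 positions) and an independent component
(SD 0.6 µm).  The correlated decomposition matters: with independent
per-position noise, the sector-wise extreme-value rules of the fusion
transforms would flag nearly every sector of every healthy record,
which is not how spatially smooth RNFL profiles behave.

Glaucomatous damage thins 1–3 scan sectors by a severity-scaled fraction
and depresses the same sectors' field points through a linear coupling of
25 dB per unit thinning fraction (±15% jitter) plus a severity-scaled
diffuse loss.  Deviations are ranked against the healthy N(0, 2 dB)
distribution at the conventional 5/2/1/0.5% cuts to produce categories
(the full pattern-deviation general-height machinery is out of scope),
and records are resampled until Mean Deviation lands in the severity band
(early > −6 ≥ moderate > −12 ≥ advanced, the conventional cuts).  The
hemifield labeler is deliberately simplified — superior/inferior score
asymmetry and total-abnormality thresholds — and exists only to feed the
comparator rule; it is not the commercial algorithm.  The default study
composition is 125 healthy / 135 glaucoma with severity counts 49/32/54,
and a separate normative cohort (default 300–500 records) feeds database
construction.

What passing tests show: the transforms, statistics and training machinery
behave as specified on data with the assumed coupling structure, and the
full pipeline separates the simulated classes (out-of-fold AROC > 0.9 at
the default composition).  What they do not show: performance on clinical
data.  In particular, the simulator draws structural "thin-normal"
subjects independently of class, so fused SAP input can trail raw SAP by
a few hundredths of AROC at small cohort sizes — in clinical data such
subjects are exactly the diagnostically ambiguous ones the fusion is
meant to help with.  Real A-scan noise (speckle, segmentation failures),
media opacities, and between-subject anatomic variability beyond the
covariate effects are not modelled.

## Problem sizes and numerical choices

The test suite runs the full-scale pipeline (125/135 cohort, 10 folds,
35 members, two input types) once, plus reduced-scale end-to-end checks
(30/30 cohorts, 5 members, 5 folds) for the multi-seed coupling
diagnostic; the acceptance script uses the full composition with a
300-record normative cohort.  Logistic outputs are clamped to the nearest
representable doubles inside (0, 1).  SCG aborts with a diagnostic on
non-finite error; λ is capped at 10²⁰.  PCA retention compares cumulative
variance with a 10⁻⁹ tolerance so exact-rank data retains its rank.  Ties
in cutoff selection prefer specificity, then the higher threshold.  All
randomness flows from `numpy` `SeedSequence`s derived from the user seed;
derived seeds stay below 2³¹.
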