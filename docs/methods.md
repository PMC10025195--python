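# Methods

## Problem and data model

The package discriminates early-stage Parkinson's disease (PD) from
essential tremor (ET) from one instrumented Timed Up and Go (TUG) trial
per subject. A trial is recorded by ten inertial sensors (both wrists,
chest, waist/L5, both thighs, shanks and feet), each providing a
tri-axial accelerometer (g, range ±16 g) and gyroscope (deg/s, range
±2000 deg/s) at 100 Hz on a shared timebase. The body frame is fixed
package-wide: x anterior, y left-lateral, z superior, right-handed — so
gyro-y is the sagittal (pitch) rate of a trunk sensor and gyro-z its yaw
rate. Axis conventions and units are declared, not inferred: recordings
store physical units, and the device sensitivity constants
(16,384 LSB/g, 131 LSB/dps) are documentation-only conversion metadata.

A trial is partitioned into six contiguous half-open phases —
sit_to_stand, walk_out, turn_180, walk_back, turn_pre_sit, stand_to_sit —
grouped into four analysis components: standing, straight walk, turning,
sitting.

## Synthetic cohort generator

No clinical recordings are available to distribute, so the generator is a
first-class, tested component, not a fixture. It writes the TUG script
directly into sensor space from smooth parametric templates, making the
ground truth exact:

* **Sit-to-stand**: chest/waist pitch rate is one full sine period with
  programmed absolute peak (the trunk flexes forward and re-extends;
  flexion amplitude follows from peak × duration / π).
* **Stand-to-sit**: the pitch *angle* trajectory is laid on the sample
  grid (forward flexion ≈25°, then a backward overshoot reaching exactly
  the programmed lean angle, then return to upright) and differentiated,
  so gyro integration recovers the programmed backward peak exactly.
* **Turns**: waist/chest yaw rate is a cosine-ramp trapezoid (ramps 40 %
  of the duration each side), renormalized so the sampled integral is
  exactly 180°. Peak yaw rate is the programmed kinematic; duration is
  derived as 300/peak s from the 180° constraint, so a slower turner
  takes proportionally longer.
* **Walking**: each walk covers 5 m at the subject's stride length
  (1.1 m × a programmed scale), at least five strides. Shank/foot/thigh
  sagittal gyro follow a per-leg stride template (stance 60 % with a
  small negative plateau, swing 40 % with a sin² burst, legs offset half
  a stride), so mid-swing peaks, heel strikes (zero crossing after the
  burst) and toe offs (zero crossing before it) are well defined; ground
  truth records them. Arm swing is a sinusoid at the stride frequency,
  arms in antiphase; its per-stride amplitude is a *shared* fluctuation
  (CV ≈ 9 %, identical for both arms, emulating common-drive speed
  variation) times a per-side base amplitude. The ratio of the larger to
  the smaller side is the programmed arm asymmetry factor; the reduced
  ("affected") side is chosen at random per subject. A short 0.15 s
  cosine envelope tapers all walk oscillations at phase boundaries.
* Additive white Gaussian noise on every channel (gyro 1 deg/s, accel
  0.02 g) and a sinusoidal wrist tremor on the roll axis (PD ≈5 Hz,
  lateralized; ET ≈7 Hz, bilateral). Accelerometers carry gravity
  projected through the trunk pitch plus a small step bounce; they are
  realistic enough to validate ranges but are not used by the extractors,
  which are gyro-based.

Per-subject kinematics are drawn from group profiles (mean, SD; draws
clamped at ±3 SD with physiological floors). The ET baseline is a set of
plausible physiological magnitudes (stride time 1.08 s, turn peak
205 deg/s, sit-to-stand peak trunk pitch velocity 112 deg/s, backward
lean 8°, arm ROM 35°, arm asymmetry ratio 1.15 — healthy arm-swing
asymmetry of this order is well documented). Only the PD/ET contrasts are
anchored to the clinically reported effects: PD means are ET × 0.811
(sit-to-stand velocity), × 0.870 (turn peak), × 0.9462 (backward lean),
with slower, shorter strides (stride time 1.15 s, length scale 0.85) and
globally reduced arm swing (28°). Between-subject SDs were chosen so that
individual features discriminate only moderately (single-feature AUC
roughly 0.6–0.85, classes overlapping), which is what makes the ensemble
worthwhile.

The PD arm asymmetry ratio (1.191) is the one generator constant set by
calibration rather than direct ratio programming: the symbolic symmetry
index is a bounded nonlinear functional of the asymmetry ratio, the
shared fluctuation and the finite number of swings, so the ratio was
tuned by simulation (large-n cohorts) until the *extracted* index is
≈16 % higher in PD at cohort scale. With ~18–20 swings per arm the
per-subject index has an SD near 0.10, so a 200-per-group contrast
estimate carries a Monte-Carlo SE of roughly 1.7 percentage points — the
±3-point tolerance used for effect-recovery checks reflects that.

Seeding: a master seed expands into per-subject seeds through a
SeedSequence (splitmix-style) derivation; each subject's seed is recorded
in its ground truth. Identical (profile, seed) pairs reproduce recordings
bit for bit. The default cohort is 84 PD / 80 ET with the matched
training split 64 PD + 67 ET and test split 20 PD + 13 ET; non-default
sizes fall back to rounding the train fraction per group.

## Segmentation

Only trunk channels are used. Turns: waist yaw rate is low-pass filtered
(4th-order Butterworth, 1.5 Hz, zero-phase); candidate intervals are
sustained (≥0.5 s) excursions of |yaw| above 15 deg/s, edges relaxed
outward to the nearest local minimum of the filtered magnitude (stopping
below 1.5 deg/s), accepted if the cumulative yaw lies in [120°, 240°].
Exactly two turns are required. Postural transitions: chest pitch rate
low-passed at 5 Hz; the first sustained (≥0.3 s) excursion above
15 deg/s before the first turn is the sit-to-stand, the last one after
the second turn the stand-to-sit, with the same edge relaxation. Walks
are the residual intervals; the small detected gap between the second
turn and the stand-to-sit is split at its midpoint so the six phases are
contiguous. All thresholds are keyword-exposed.

The 15 deg/s pitch threshold matters: the stand-to-sit backward-recline
segment peaks near 28 deg/s for PD subjects, so a higher threshold can
truncate the event at the backward-lean peak and corrupt the drift
anchor — exactly the kind of group-differential artefact the extractor
must avoid. Under the default noise the detected boundaries sit within a
median of ~2 samples (≤4 in stress tests) of ground truth; zero-noise
boundaries are within ±5 samples.

Gait cycles: per leg, the low-passed (6 Hz) shank sagittal gyro inside a
walk phase (minus a 0.2 s guard band at each end, so transition motion
never contaminates the first/last cycle) yields mid-swing peaks
(≥80 deg/s, ≥0.6 s apart); the zero crossing after a peak is the heel
strike, the one before it the toe off. Cycles are consecutive ipsilateral
heel strikes.

## Parameters

The catalogue is registry-based and extensible; the implemented 34
parameters cover each family across the four components rather than an
exhaustive clinical list. Conventions:

* Lateral pairs resolve to Max (larger of left/right), Min (smaller) and
  abs (absolute left–right difference); extraction is therefore invariant
  to left/right sensor relabeling by construction.
* Trunk pitch angles come from integrating the chest sagittal gyro over a
  phase with a linear drift correction anchored at the phase endpoints
  (assumed static); backward is positive. The stand-to-sit
  "minimum lean angle" is the peak backward tilt on this convention
  (forward lean is negative).
* Turn max/mean angular velocity use a 0.15 s moving-average smoother
  rather than a sharp IIR filter: a positive kernel cannot overshoot the
  yaw plateau, where a 4th-order Butterworth adds ≈3 % ringing bias.
* The **arm symbolic symmetry index** takes the per-swing excursion
  series of each wrist (successive extrema of the integrated, low-passed
  wrist sagittal angle — two swings per stride, pooled over both walks),
  symbolizes both series into an 8-letter alphabet by equal-width binning
  over the pooled two-arm range, and reports the total-variation distance
  between the two symbol distributions: 0 iff identical, bounded by 1,
  increasing with asymmetry. At least three swings per side are required.
  Values are quantized at 1e-9 deg before binning so float jitter cannot
  flip a bin. The published index of the same name is defined only
  semantically in the source literature; this concrete definition is a
  documented, testable stand-in with the same semantics (lower = more
  symmetric). Using per-swing rather than per-full-cycle samples doubles
  the sample count per arm, halving the estimator variance of the index.

Features whose inputs are unavailable (e.g. too few detected cycles) are
reported as NaN and median-imputed inside model training only.

## Feature screening

FG I keeps features with two-sided Mann–Whitney p < 0.05 (tie-corrected
normal approximation with continuity correction; constant features get
p = 1 and a warning). No multiplicity correction is applied — the screen
is intentionally liberal, matching common practice of reporting raw
per-feature p values. FG II greedily prunes FG I in ascending-p order
(ties by name), dropping any feature with |Spearman ρ| > 0.9 against an
already-kept one; the redundancy criterion is this package's
reconstruction of an otherwise unspecified second screening stage, and is
config-exposed. FG III keeps FG I features whose single-feature
threshold-classifier stratified 5-fold CV AUC, folded for orientation
(max(AUC, 1−AUC)), reaches 0.6; fold assignment is keyed on sorted
subject ids so results are invariant to row order. All selectors accept
the training table only — test rows cannot leak in by API construction.

## Ensemble model

For each feature group and base model, four component classifiers are
trained on the component's features only. Base models: RBF-kernel SVM
(C = 1, scaled gamma, features z-scored with training-fold statistics,
probabilities via Platt sigmoid calibration on three internal stratified
folds) and random forest (500 trees by default, probabilities as vote
fractions). Under LOOCV the scaler and classifier are refit in every
fold; feature-group membership is fixed beforehand on the full training
split — a deliberate, documented protocol choice that carries a known
optimistic bias, as the selection statistics have seen the held-out
subject. The four LOOCV probabilities per subject feed a logistic
regression (light ridge, C = 100, so perfect separation cannot break the
fit); its coefficients, clipped at zero and normalized to sum to one, are
the component weights (the intercept is retained as metadata but excluded
from the score, keeping the weighted average on the probability simplex so
the 0.5 threshold is meaningful). If no coefficient is positive, equal
weights are used with a warning. The ensemble score P = Σ w_c p_c
classifies PD iff P > 0.5; a tie goes to ET (strict inequality). Model
selection evaluates all six base-model × feature-group combinations by
LOOCV accuracy (ties: kappa, then AUC); the winner is refit on the full
training split and scored once on the test split with the
training-derived weights — nothing test-derived feeds back.

## Metrics

Accuracy, sensitivity, specificity and F1 follow their standard
confusion-matrix definitions with PD positive; kappa uses the closed
form 2(TP·TN − FN·FP)/[(TP+FP)(FP+TN)+(TP+FN)(FN+TN)], verified in the
tests to coincide with Cohen's kappa on random matrices. AUC is computed
rank-based with half credit for ties, i.e. the normalized Mann–Whitney U
statistic, and is checked against both an exhaustive pairwise-comparison
oracle and an independent library implementation. Degenerate
denominators return NaN with a warning rather than raising, keeping
batch evaluation robust.

## What the synthetic data does and does not show

The generator emulates the *kinematic script* of a TUG trial and the
programmed group contrasts, with exact ground truth. It does not emulate
soft-tissue artefacts, sensor misalignment or drift, freezing of gait,
dual tasks, medication state, disease-duration effects, or the
correlation structure of hundreds of real gait parameters. Passing tests
therefore demonstrate that the pipeline's detectors and estimators
recover what is actually in the signal, and that the ensemble protocol is
leak-free and self-consistent — not that the reported clinical accuracies
would be reproduced on real patients; the clinical recordings are not
available, and the classification metrics on synthetic cohorts are
generally higher than the clinical ones because the synthetic feature
space is cleaner.

## Problem sizes and numerical choices

Effect-recovery checks run at 200 subjects per group — large enough that
the Monte-Carlo SE of each percent contrast (0.7–1.7 points) sits well
inside the stated tolerances. Ensemble property checks use 30 subjects
per group over 10 seeds with the SVM base model. Ties are broken
deterministically everywhere (ascending p, then lexicographic name;
P = 0.5 → ET); all randomness flows from explicit integer seeds through
SeedSequence derivations, and every pipeline run is reproducible bit for
bit from (config, seed).
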