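# Methods

`gaitlift` implements a single-camera markerless gait-kinematics pipeline
and the statistics used to judge whether it agrees with a marker-based
optical-capture reference. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic test bed does
and does not establish.

## Pipeline overview

Both measurement routes converge on the same representation:

```
markerless:  Body25 keypoint JSON -> gap fill -> smooth -> 2D->3D lifter
                                               -> smooth 3D -> canonical pose
marker:      marker table (mm)    -> gap fill -> smooth    -> canonical pose

canonical pose -> pelvis-centred normalization -> human frame {O}
              -> 10 joint-angle series -> heel strikes -> cycles
              -> K-point per-cycle curves -> per-cycle sample entropy
              -> participant x angle table -> agreement battery
```

## Preprocessing

Detector dropouts (confidence below 0.3 by default) and occluded markers
are gaps. Interior gaps up to `gaps.max_gap_frames` (default 15 frames,
0.25 s at 60 Hz) are filled by per-coordinate linear interpolation;
leading/trailing gaps copy the nearest observation; longer gaps are left
missing and reported rather than invented. Each univariate coordinate is
then convolved with a discrete Gaussian of standard deviation
`smoothing.sigma_frames` = 1 sample, truncated at 4 sigma and
renormalized, with edge-repeating reflective boundaries (this boundary
rule preserves the series sum exactly for a symmetric kernel).

Normalization subtracts the pelvis (midpoint of the two hip joints) from
every joint and divides by the per-frame Euclidean distance from the right
hip to the right shoulder. The result is invariant to rigid translation
and uniform scaling, and the transform is idempotent, so marker (mm) and
lifted (dimensionless) data end up in the same units.

## 2D-to-3D lifting

The lifter is a residual fully-connected network f: R^{2n} -> R^{3n} on
the canonical n = 17 joint skeleton: a linear layer raising the input to
the hidden width, two residual blocks of two (linear, batch-norm, ReLU,
dropout) stages each with an identity skip, and a linear output layer.
Weights use Kaiming initialization; training minimizes mean squared error
with Adam (lr 1e-3) on shuffled mini-batches of 64 for 200 epochs. The
whole network — forward, backpropagation through batch norm and inverted
dropout, Adam — is implemented in numpy, so a seed fixes the run
bit-for-bit.

Numerical choices worth recording:

* **Learning-rate decay.** The decay is exponential per epoch. A factor of
  0.96 drives the step size to ~3e-4 of its start within 200 epochs and
  freezes optimization far above the achievable floor; the default is
  0.99, which still anneals by ~7x over 200 epochs but keeps making
  progress. Both are configurable.
* **Input/output units.** 2D inputs are normalized per frame (centred on
  the hip midpoint, divided by the right-hip-to-right-shoulder pixel
  distance); targets are root-relative 3D divided by the same anatomical
  distance in 3D. Synthetic and real observations therefore share units,
  and a held-out mean per-joint position error (MPJPE) of 0.04 means 4% of
  trunk length.
* **Desk-scale protocol.** The shipped training protocol fits hidden width
  256, 2 blocks, dropout 0, 200 epochs on 2000 synthetic pose pairs — a
  configuration a single CPU completes in about a minute while recovering
  the synthetic camera's 2D->3D map to ~4% MPJPE. The full-scale defaults
  of this architecture family (width 1024, dropout 0.5) remain the
  `LiftingConfig` defaults.
* **Noise-matched training.** Training inputs carry Gaussian pixel noise
  matched to the simulated detector noise (2 px by default in the CLI);
  targets stay clean. Fitting under the observation noise is the standard
  robustness practice and is what lets the lifted knee-angle curves track
  the analytic ones at r ~ 0.99 instead of ~0.9.
* **Dropout at inference** is off, and batch norm uses running statistics,
  so lifting is deterministic and per-frame independent.

## Human frame and angles

Per frame, the origin o(t) is the midpoint of the right and left pelvis
landmarks PR, PL. V1 = unit(PR - PL); V2 = unit(o(t) - o(t-1)) (the first
frame copies the second). The axes are xh = V1, yh = unit(V1 x V2),
zh = unit(xh x yh) — an orthonormal right-handed triad. Note that with
this construction xh is the hip-to-hip (lateral) axis even though the
angle labels follow the R?X/R?Y/R?Z naming convention in which X is
usually described as anterior-posterior; the construction is implemented
literally and the labels kept for comparability.

Segments: upper trunk U = u - o with u the shoulder midpoint (chosen over
the literal shoulder-difference vector, which would be independent of o
and could not represent trunk inclination), thigh T = knee - hip, shank
S = knee - ankle. The knee angle RTS is the angle between T and S; the
other nine angles are each unit segment against each axis. All angles are
computed as atan2(|a x b|, a.b) rather than arccos of the clamped dot
product — identical mathematically, but accurate near 0 and pi where
arccos loses half the significant digits; this is what lets rigid-motion
invariance hold to 1e-9 even for angles that pass through zero.

**Root-relative data.** Lifted poses have a pinned pelvis, so o(t) never
moves and V2 is undefined from displacement. The progression axis is then
estimated as the first principal component of the pelvis-relative right
ankle trajectory, with its sign oriented by the knee angle: at the
anterior extreme (heel strike) the leg is extended (angle near pi), at
the posterior extreme the knee is flexed. This asymmetry is large and
survives lifting noise, unlike the anterior/posterior excursion asymmetry,
which is weak on lifted data.

## Cycles and sample entropy

Right heel strikes are positive peaks of the anterior-posterior
pelvis-relative ankle series (minimum separation 0.5 s, prominence 20% of
the series range, both configurable). A peak whose prominence is clipped
by the series boundary (a strike in the last half-stride of a recording)
is not detected; cycle counts are therefore exact for strikes interior to
the bout. Cycles are half-open [strike_i, strike_{i+1}); each angle is
resampled at K evenly spaced phase points over [0%, 100%) by linear
interpolation. K defaults to 50 (2% increments); K = 30 is a supported
alternative reading and a config key.

Sample entropy SampEn(N, m, T) = -ln(A/B), where B and A are the counts of
template pairs (Chebyshev distance <= T, self-matches excluded) at lengths
m and m + 1, both formed from the first N - m starting points
(Richman-Moorman counting; the per-template averaged variant differs only
in bookkeeping and gives the same ratio). Each within-cycle series is
standardized to zero mean and unit population variance and T = r * SD, so
the statistic is exactly invariant under affine maps of the signal.
Defaults m = 2, r = 0.2, applied to the K-point resampled curves (the
per-cycle representation). B = 0 raises an explicit undefined-entropy
error; A = 0 yields +inf, flagged, never silently propagated; undefined
cycles are excluded from participant means and counted, and an angle with
no defined cycle reports missing, never zero. Entropy is typically but
not provably decreasing in r; the package asserts that only as an
empirical spot check.

## Agreement battery

For two aligned participant x angle tables (test/retest within a system,
or markerless vs marker-based across systems), per angle:

* **ICC(C,1)** (two-way consistency) and **ICC(A,1)** (two-way absolute
  agreement), single measure, computed from the two-way ANOVA mean squares
  (MS_rows, MS_cols, MS_error); 95% CIs from the corresponding F
  distributions (Satterthwaite degrees of freedom for A,1), p-value from
  F = MS_rows/MS_error. Zero between-subject variance makes the ICC
  undefined; such angles are skipped with a warning, not fabricated.
  The implementation is cross-checked against an independent statistics
  package in the test suite.
* **SEM** = pooled SD of both ratings x sqrt(1 - ICC(A,1)) — the SEM
  family consistent with the smallest detectable change formula — and
  **SDC** = 1.96 * sqrt(2) * SEM.
* **Bland-Altman**: bias = mean difference, 95% limits of agreement =
  bias +/- 1.96 * SD(diff), and the proportional-bias slope from the
  least-squares regression of differences on pair means.
* **Difference tests** are gated: Shapiro-Wilk normality on each sample
  and median-centred Levene homogeneity; a t-test (paired by default for
  cross-system comparisons, since the same subjects are measured by both
  systems; independent optionally) when all gates pass, otherwise Wilcoxon
  (signed-rank paired / rank-sum independent). Bonferroni adjustment
  multiplies p by the number of angles compared. All tests two-sided at
  alpha 0.05.
* **Qualitative bands**, lower edges inclusive: almost perfect 0.81-1.0,
  substantial 0.61-0.80, moderate 0.41-0.60, fair 0.21-0.40, slight
  0.00-0.20; negative ICCs are labelled "below slight" and flagged.

## Synthetic test bed

The generator poses a kinematic chain with sinusoidal joint trajectories
at constant cadence: right-leg phase p(t) = 2 pi (t - t0)/P with stride
period P = 120/cadence s and first strike at t0 = 0.25 P; hip flexion
phi = A_hip cos p (A_hip = 20 deg), knee flexion
theta = A_knee (1 - cos p)/2 (A_knee = 60 deg), left leg half a stride out
of phase, trunk pitch 3 deg at step frequency. This puts the anterior
ankle peak exactly at p = 0, so heel-strike times and the knee-angle curve
RTS = pi - theta are known in closed form. Defaults: 60 Hz, 10 s, cadence
100 steps/min, segment lengths trunk 500 / thigh 420 / shank 400 mm,
hip and shoulder widths 240/380 mm. Treadmill walking is emulated by a
slow constant pelvis drift (20 mm/s) so the progression direction remains
defined without the subject leaving the view. The camera is a pinhole
3 m to the subject's side (focal 1000 px, 1920 x 1080 principal point);
observations add i.i.d. Gaussian pixel noise and Bernoulli gaps.

What this test bed does **not** contain: soft-tissue artifact, left/right
detector swaps, camera distortion, out-of-sagittal motion (hip
ab/adduction, rotation), stride-to-stride timing variability, or a
biomechanically validated motion model. Passing tests therefore establish
that the machinery is correct — geometry exact to rounding, entropy equal
to its reference, statistics equal to their closed forms, the pipeline
deterministic — not that the accuracy figures transfer to real video of
real walkers. A full-scale study — real treadmill recordings and training
on a large motion-capture corpus — is outside what this repository can
reproduce.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at sizes a single CPU
finishes in about a minute each: 2000 training poses (400 held out),
10 s bouts at 60 Hz, a 4-participant cohort for the cross-system round
trip, 50 random series for the entropy oracle battery, and n = 5000 for
the ICC variance-component recovery. All were chosen as the package's
desk-scale study conditions and are configurable upward.

## Known limitations

* The lifter is trained and evaluated on poses from the same synthetic
  family and camera; it is a protocol demonstration, not a pretrained
  general-purpose model.
* Heel strikes in the final half-stride of a bout are not detected
  (boundary prominence clipping), and strike detection assumes a
  reasonably periodic anterior ankle signal.
* Angles involving the trunk against the lateral axis are nearly constant
  under the synthetic motion model, so their per-cycle entropy can be
  degenerate (constant series); the pipeline reports these as undefined
  rather than zero, and the agreement battery skips angles without
  between-subject variance.
* Only right-side angles are computed, matching the pipeline's scope.
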