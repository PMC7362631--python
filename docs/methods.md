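# Methods

This note documents the models, algorithms and numerical choices behind
`gaitscore`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## 1. Inputs and quality control

The unit of analysis is a *walking bout*: a time-ordered sequence of
joint keypoints at a fixed frame rate (30 Hz by default), either 2D pixel
coordinates of an MPII-style 16-joint skeleton with per-joint confidences
or 3D metric coordinates of a 25-joint skeleton whose `spine_base` joint
serves as the sacrum / centre-of-mass proxy. Frames in which no person
was detected are kept as explicit missing rows so time indexing stays
uniform. Gaps of at most `max_gap_frames` (default 5) are filled by
linear interpolation per joint and axis; longer gaps remain missing and
split signals into segments rather than fabricating motion.

A bout enters the analysis only if (a) both ankles and both hips are
observed in at least 50% of frames ("tracked"), and (b) at least
`min_steps` (default 3) foot strikes are detected. Verdicts partition
every bout set into included / untracked / too-short, and the pipeline
log preserves that accounting. When several bouts of one participant
fall on the same calendar day, one is kept uniformly at random (seeded):
bouts recorded minutes apart are effectively duplicates and would bias
the cohort toward days with heavy traffic.

## 2. 2D normalization

Pixel coordinates carry no metric scale, and the walker's distance to the
camera changes within a bout. All 2D features are therefore computed in
*hip-width units*: distances are divided by the same-frame inter-hip
pixel distance. Two refinements matter in practice:

- **Smoothed scale.** The true pixels-per-hip-width scale changes only as
  fast as the walker's distance to the camera, but the raw per-frame hip
  distance carries the keypoint noise of both hips. The normalizer is
  therefore a moving average of the hip distance over `reference_window`
  frames (default 31, about one stride). This is the single change that
  most improved strike-timing robustness under realistic keypoint noise.
- **Pelvis reference.** Positions used over time (ankle height, the
  XCoM construction) are taken relative to the per-frame hip centre
  (vertical reference additionally lowpassed over a stride). This makes
  every 2D feature exactly invariant to uniform scaling *and* translation
  of the image — the property the hip normalization exists to provide —
  where dividing raw coordinates alone would leave a translation-dependent
  drift. `normalize_by_hip_distance` retains the plain per-frame division
  for direct use.

## 3. Foot-strike detection

Strikes are detected from the vertical ankle trajectory, per side:

1. The height signal (2D: pelvis-referenced, hip-width-normalized, with
   image v negated so up is positive; 3D: metric y) is lowpassed with a
   zero-phase 4th-order Butterworth filter at `lowpass_hz` (default 4 Hz;
   foot-strike-relevant gait content sits below ~5 Hz).
2. The *downward* velocity is estimated with a quadratic Savitzky–Golay
   derivative over `smoothing_window` frames (default 11 for 2D, 5 for
   the cleaner metric 3D signal; 1 disables smoothing).
3. Prominent peaks of downward velocity delimit gait cycles. A peak
   qualifies if its prominence reaches `peak_prominence_frac` (0.5) of
   the median candidate-peak height and its height reaches
   `min_peak_velocity` (0.5 hip-widths/s in 2D, 0.10 m/s in 3D) — the
   absolute floor rejects jitter peaks in stationary or noisy segments.
4. Within each cycle the strike is the first *sustained* downward
   crossing of `peak_fraction` (0.35) times that cycle's peak value after
   the peak; "sustained" means the signal stays below the threshold for
   the following samples, so a single noise dip cannot fire early. The
   crossing time is interpolated linearly between frames.
5. The left and right series are merged in time; same-side adjacency and
   pairs closer than `min_step_interval` (0.2 s) keep only the strike
   with the larger peak prominence.

A *step* is the interval between consecutive strikes and is attributed
to the side striking at its end. With these defaults the detector
recovers noise-free synthetic step counts exactly and strike times to
within one frame, and holds a pooled F1 of ~1.0 at ±2-frame tolerance
under 0.05-hip-width keypoint noise.

The direction convention deserves a note: differentiating the *image*
vertical coordinate (down-positive) makes the per-cycle peak the final
descent of the swing foot, and the fall-back through 35% of that peak is
the foot decelerating into contact. Interpreted on an up-positive height
the same rule would fire mid-swing, far from the contact event.

## 4. Features

**2D (8):** steps of walk (strike count), cadence ((strikes−1) per
strike-to-strike span, ×60), symmetry index of step time (Robinson:
|L−R| / ½(L+R) × 100 on side means), CV of step time (sample SD/mean),
average step width and its CV (within-frame horizontal ankle separation
at strike frames, hip-widths), average MOS and average per-step minimum
MOS (below). Depth-dependent quantities (step length, walking speed)
cannot be computed from one 2D view and are not attempted.

**3D (16):** walking speed (net anterior–posterior sacrum displacement
over the strike-to-strike span), mean step length (AP sacrum displacement
between consecutive strikes), mean step time, mean step width (ML ankle
separation at strikes), cadence; CVs of step length/time/width; symmetry
angles of step length/time/width (Zifchock: (45° − atan(L/R))/90° × 100,
zero at symmetry, sign flips under side swap); RMS of sacrum ML velocity,
SD and range of motion of the detrended sacrum ML path; average and
minimum MOS in millimetres.

The anatomical frame is estimated per bout: the anterior–posterior axis
is the first principal axis of the horizontal sacrum path, oriented along
the net displacement; medio-lateral is its horizontal perpendicular
(up × ap). All 3D features are therefore invariant to rigid translation
and rotation about the vertical axis. Detrending of the sacrum ML path
removes the straight line through the first- and last-second means (an
exact ramp remover immune to the sway–time correlation a least-squares
line suffers from on finite windows) followed by a zero-phase 4th-order
high-pass at 0.5 Hz, about half the stride frequency, with the
filter's edge transients trimmed before extremes are taken. On a pure
sinusoidal sway the pipeline recovers ROM → 2A, SD → A/√2 and RMS
velocity → 2πfA/√2 within 2% at 10 s.

**Margin of stability.** The extrapolated centre of mass adds a
velocity-proportional offset to the centre-of-mass proxy: in 3D,
XCoM = sacrum ML + (sacrum ML velocity)/ω₀ with ω₀ = √(g/ℓ) and leg
length ℓ defaulting to 53% of the skeleton-estimated stature
(overridable); in 2D, the hip-centre lateral position plus
`velocity_scale` times its lateral velocity, with the default scale the
1/ω₀ analogue of a one-hip-width pendulum (gravity converted through an
assumed 0.30 m hip width — the module's largest interpretive constant,
exposed as a single scalar precisely so its sensitivity can be probed).
The per-frame margin is the signed lateral distance from the XCoM to the
stance-ankle boundary, taken positive when the XCoM lies medial to
(inside) the stance foot; this stance-side-aware sign makes the statistic
meaningful across alternating stance feet and invariant to the frame
convention. The stance foot is the ankle with the smaller |vertical
velocity| (2D) or the lower ankle (3D). Averages use |margin| over the
strike-delimited frames; the "minimum" variants take each step's minimum
signed margin (least stable instant), then average over steps (2D) or
take the overall minimum (3D).

## 5. Ordinal statistics

The proportional-odds model `logit P(y ≤ j) = θ_j − xβ` is fitted by
maximum likelihood: predictors are internally centred and scaled for
conditioning, cut-points optimized through an increasing
reparameterization, BFGS with an analytic gradient, then mapped back.
Standard errors are square roots of the inverse observed information
(numerical Hessian at the MLE in the (β, θ) parameterization);
t = coefficient/SE and p-values are two-sided normal Wald tests (the
test family is a documented choice; likelihood-ratio p-values would also
be defensible). Cut-points are estimated and labelled only between
categories observed in the data, and prediction is restricted to those
categories. Non-convergence and (quasi-)separation (|standardized β| >
30, or a singular information matrix) are flagged on the returned fit
rather than raised. The fit agrees with an independent grid-initialized
Nelder–Mead optimum to ~1e−9 in log-likelihood on small instances and
with `statsmodels`' `OrderedModel` to optimizer precision.

The univariate screen fits one single-predictor model per feature and
selects p < α (default 0.05) with *no* multiplicity correction — the
screen gatekeeps a multivariate model, and a Bonferroni correction would
discard genuinely associated features. Collinearity pruning computes
Pearson r between all screened features; pairs with |r| above the
threshold (0.5) are processed in descending |r|, each dropping the member
with the smaller-magnitude Pearson correlation to the outcome (ties break
toward the earlier column; a feature already dropped triggers no further
drops). The pairwise rule is order-dependent and the processing order is
therefore fixed and documented; the retained set provably contains no
violating pair. Zero-variance features are dropped with a logged reason.

The multivariate model regresses the outcome on age, sex (male = 1) and
the pruned features. Evaluation is in-sample — the model is a
descriptive regression of annotated severity, not a held-out classifier —
via a 5×5 confusion matrix (annotated × predicted), overall accuracy,
per-participant accuracy with each participant's share of walks, and the
adjacent-agreement rate (|prediction − annotation| ≤ 1). Rows with
missing features are dropped with a logged reason rather than imputed.

## 6. The synthetic generator

The generator produces the statistical structure the analysis assumes,
not a biomechanical simulation. Kinematic template: the pelvis advances
at constant speed `step_length/step_time` with sinusoidal ML sway
(stride-periodic) and a small vertical bob; each foot alternates stance
(planted) and swing, with swing occupying 40% of the foot's stride. The
swing vertical profile is a raised-cosine lift over the first 60% of
swing followed by a *linear descent ending at nonzero downward velocity*:
heel strike is an impact, and a profile that decelerates smoothly to zero
would make any threshold-on-velocity event detector ill-posed. The ankle
vertical excursion is 0.12 m (mid-range for adult gait, dominated by heel
rise). Bouts begin with a short stationary lead-in, as in trigger-based
hallway recording. Per-step durations take multiplicative Gaussian
jitter (`step_time_cv`) and a left/right mean offset
(`step_time_asymmetry`, right slower for positive values).

2D bouts are the same skeleton projected through a perspective camera
(1000 px focal length, 1920×1080 image) mounted 2.3 m high, several
metres beyond the walk's end, looking back along the walking axis —
so apparent size grows as the walker approaches, which is exactly what
hip-width normalization must cancel. Keypoint noise is i.i.d. Gaussian,
specified in hip-widths (2D; converted per frame through the projected
hip distance) or metres (3D).

The cohort model draws, per participant, age ~ N(76, 9) truncated to
[60, 95], sex male with probability 0.57, and a latent severity baseline
~ N(0.9, 1.1); severity then follows a two-segment piecewise-linear drift
across recording days (emulating a medication change) plus per-bout noise
(SD 0.3). Severity maps monotonically onto gait parameters (cadence
−7 steps/min, step length −7.5 cm, step-time CV +0.015, asymmetry +0.04,
step width +1.2 cm and ML sway +2 mm per severity unit, all clipped to
physiological ranges), with independent multiplicative jitter (lognormal
σ = 0.18) per parameter per bout — severity does not determine gait
exactly, which keeps inter-feature correlations realistic rather than
degenerate. Bout step counts follow from a fixed hallway length (4–6.5 m)
divided by step length, so severe gait yields more, shorter steps, as a
fixed recording corridor produces. UPDRS-gait and SAS-gait are drawn
independently from proportional-odds models on 1.5× the latent severity
with separate cut-point sets (SAS shifted toward lower scores).

What the generator does **not** emulate — and hence what passing tests do
not establish about clinical video: pose-estimation failure modes
(identity switches, occlusion-correlated noise, confidence-dependent
error), non-straight or interrupted walking paths, turning, assistive
devices, inter-rater disagreement in the annotations, and any
within-bout correlation structure of keypoint noise. Validation against
this generator demonstrates the *pipeline's* correctness and calibration,
not clinical performance.

## 7. Numerical and degenerate-input conventions

- Features that cannot be computed (too few strikes, missing joints at
  strike frames, zero denominators) are NaN, never silently zero; rows
  with NaN features are dropped (and logged) before model fitting.
- Cadence needs ≥ 2 strikes; CV needs ≥ 2 values and nonzero mean; the
  symmetry index is undefined when the side means cancel; the symmetry
  angle is undefined at (0, 0).
- Coincident hips (distance < ε) mark a 2D frame unusable.
- A stationary sacrum path makes the walking-direction estimate fall back
  to the +z axis; walking speed on a degenerate path is NaN.
- All randomness flows through seeded `numpy` generators; identical
  seeds reproduce bouts, cohorts and fits byte-for-byte.

## 8. Problem sizes used in validation

The validation suite runs at the scale the generator emulates: cohorts of
14 participants × ≤28 daily bouts (≈390 bouts of 5–24 steps), 100-bout
batches for detection and invariance checks, 200 replicates of n = 500
for screen calibration, and 50 replicates of n = 2000 for parameter
recovery. These sizes make every check complete in seconds on one core
while keeping the statistical bands (binomial band for the type-I rate,
3-SE coverage) meaningful.

## 9. Known limitations

- The 2D XCoM velocity scale rests on an assumed metric hip width; only
  relative comparisons of 2D MOS values across bouts of similar builds
  are meaningful.
- The strike detector's systematic timing offset (< 1 frame on clean
  input) varies slowly along the bout with viewing geometry; step-time
  *variability* estimates therefore carry a small upward bias (~2–4%
  relative at CV ≈ 0.05).
- Step width in 2D is an image-horizontal proxy and mixes true ML
  separation with any camera roll; the generator's camera is level.
- In-sample accuracy overstates out-of-sample performance by design; a
  cross-validation switch is deliberately out of scope of the default
  report.
- The proportional-odds assumption (common slopes across cut-points) is
  imposed, not tested.
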