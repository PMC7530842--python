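# Methods

This note records the models, parameter choices and numerical conventions
behind `motortrace`, including the places where the design was genuinely
open and what the synthetic cohorts can and cannot demonstrate.

## Target-path model

A trial's target path is a chain of `n_segments = 20` cubic Bezier curves
evaluated in Bernstein form.  Construction of one segment from start point
P₀ and incoming unit direction **d**:

* P₁ = P₀ + r₁**d**, with r₁ ~ U(2.0, 2.4) cm.  Placing P₁ on the incoming
  line is our reading of the "control points restricted to collinearity"
  constraint: it enforces G1 continuity across joins, which is the standard
  way chained Beziers avoid kinks.  C0 continuity is exact (the next
  segment starts at the stored endpoint, not a recomputed one).
* P₂ = P₁ + r₂·R(±θ₂)**d** and P₃ = P₂ + r₃·R(±θ₃)**d**₂, with radii
  ~ U(2.0, 2.4) cm and turn angles θ ~ U(60°, 75°), all rotations sharing
  one sign per curve (its clockwise/counterclockwise "directionality").
  The "curvature of a control point" is thus interpreted as the polar-angle
  step, relative to the incoming direction, at which the point is placed on
  its circle — consistent with each point being "plotted along the arc of a
  circle centred on the previous point".
* The turn sign is random unless the start lies within `edge_margin =
  2.5 cm` of a screen edge (the usable screen defaults to 19.7 × 14.7 cm,
  a landscape stylus-tablet; both numbers are configuration, not inferred
  facts).  Near an edge, both candidate signs are scored with mid-range
  parameters and the one whose control points keep more clearance wins, so
  the path curves interior-ward.
* A draw whose control points leave the screen — or which leaves no room
  for the next segment's collinear P₁ (checked at both admissible radii,
  plus one turn of its P₂ at the sharpest angle) — is rejected and
  resampled up to 100 times.  Because a rectangle is convex and a Bezier
  curve lies in the convex hull of its control points, in-bounds control
  points guarantee an in-bounds curve.  If a segment still cannot be
  placed, the chain has cornered itself: the previous segment is discarded
  and redrawn (bounded backtracking) rather than failing the whole path.

Constant-speed animation uses arc-length reparameterization: each segment
is evaluated on a 1 000-point grid, cumulative chord length approximates
arc length, and positions are linearly interpolated at arc-length steps of
`speed/sampling_rate` (4.25 cm/s, 100 Hz).  On generated paths the
inter-sample speed has relative deviation below 10⁻⁴, comfortably inside
the 1 % contract.  A 20-segment path is ~105 cm long, i.e. ~24.7 s of
animation, so one path per trial realises the "15 trials of approximately
25 seconds" session layout; `PathConfig.n_trials` fresh paths make a
session.  A single RNG stream drives everything; identical seeds give
byte-identical paths and traces.

## Synthetic subjects

No subject model ships with the task description, so the simulator is an
explicit stand-in built to make every downstream stage testable:

* **Pursuit**: at each 10 ms step the cursor moves toward the target
  position `tracking_lag` seconds ago by fraction `tracking_gain`, with the
  step length capped at `speed_scale × 4.25 cm/s × dt`.  The cap models
  bradykinetic slowing while keeping the cursor on-path; with gain 1, lag
  0 and cap ≥ target speed the cursor reproduces the target to machine
  precision, which pins the zero point of every positional metric.
* **Tremor**: one sinusoid per trial, amplitude `tremor_amplitude`,
  frequency `tremor_freq` (3–10 Hz), random phase and spatial direction.
  A sinusoid (rather than a stochastic oscillation) makes the tremor
  metric's expected value analytic — the Hilbert envelope of A·sin is A.
  A band-limited-noise mode (`tremor_mode="bandnoise"`, ±1 Hz around the
  centre, RMS-matched) is available for less idealised traces.
* **Noise & force**: isotropic Gaussian positional jitter (`noise_sd`) and
  a force channel `force_mean + N(0, force_var)` in arbitrary device
  units; only the variance matters downstream.

Default profiles: control (noise 0.02 cm); PD-like (tremor 0.1 cm @ 5 Hz,
lag 0.12 s, gain 0.85, noise 0.08 cm, speed_scale 0.8, force variance 4×
control); ET-like (tremor 0.35 cm @ 6 Hz, all else control-level).  A
single `severity` scalar interpolates every pathological component between
the control baseline (severity 0) and the profile value (severity 1), and
extrapolates beyond.  The default cohort sampler jitters patient severities
(PD ~ U(0.5, 1.5), ET ~ U(0.7, 1.3)) to express between-patient
heterogeneity.  Cohorts derive per-subject seeds from one master seed via
`SeedSequence.spawn`, so they are reproducible byte for byte.

What the simulator does **not** capture: biophysical tremor dynamics
(re-emergent/postural components, amplitude fluctuation), medication or
fatigue cycles, path-learning effects, or realistic human tracking noise —
synthetic controls are far cleaner than real ones.  Consequences for
interpretation are discussed under *Scale of the scores* below.

## Epoch metrics

Trials are cut into non-overlapping 1-s epochs (100 samples); trailing
partial seconds are dropped and epochs never span trials.  Bin vectors
Cᵢ, Tᵢ are successive-sample differences of the filtered cursor/target
traces with Δt = 0.01 s; a bin belongs to the epoch of its left sample.
Per-sample and per-bin series are aggregated into the epoch value by the
arithmetic mean (the aggregator is a convention of this package); Pressure
is the population variance (ddof 0) of force within the epoch.

Filtering, per trial and zero-phase (`sosfiltfilt`):

* **Low-pass, 3 Hz, 4th-order Butterworth**, applied to *both* cursor and
  target before every non-tremor metric.  Filtering both traces keeps the
  comparison like-for-like and makes identity tracking score exactly zero;
  filtering only the cursor would charge the subject for filter transients
  on a perfect trace.
* **Tremor band-pass**: nominal band 3–10 Hz, realised as a 6th-order
  Butterworth with design corners at 2.65 and 12.2 Hz.  The corners come
  from the closed-form Butterworth magnitude response: with −3 dB corners
  at 3/10 Hz the forward-backward pass loses ~30 % of a 9.5 Hz tremor's
  amplitude, whereas this design recovers amplitude within 0.5 % across
  3.5–9.5 Hz while passing < 1 % of a 2 Hz (voluntary-movement) component.
  The tremor metric is the epoch mean of
  √(env(x̃)² + env(ỹ)²), env(·) = |Hilbert analytic signal|.

Conventions for the ambiguous cases, fixed and documented rather than
guessed as anyone's intent:

* **Slowness** `exp(b·v)` uses b = −0.042 with speed v in **mm/s**: at the
  target speed (42.5 mm/s) this gives 0.17, a responsive range, and the
  transform's maximum curvature sits at ~67 mm/s, near the upper tail of
  observed speeds.  `calibrate_b` solves the curvature-maximum condition
  `b²e^{2bv} = ½` by bisection for users who want b tied to a session's
  empirical 80th-percentile speed; the shipped default never self-tunes.
* **ExcursionDifference** defaults to the distance of the (filtered)
  cursor from the screen origin — the "position" reading; the alternative
  per-bin displacement magnitude reading duplicates speed information and
  is available as `excursion_mode="displacement"`.
* **TrackingAngle** of a numerically zero bin vector is 0: hesitations
  carry no angular disagreement, and NaN bursts would poison epoch means.
* Edge epochs are kept; zero-phase filtering makes their bias negligible
  (≲10⁻⁵ relative in the slowness closed-form test).

## MES classification

Features are z-scored against the pooled control epochs (population
mean/SD), and the scaling is stored inside the hyperplane so scoring is
self-contained.  Linear-SVM coefficient magnitudes — and therefore the
metric weights — are meaningless without a declared scaling; control-
referenced z-scores make weights comparable across subjects.

Per Monte-Carlo iteration (default 100): subsample the control pool without
replacement to exactly the patient's epoch count (1:1 balance; the literal
divide-by-a-constant protocol is available via `subsample_factor`);
stratified 80/20 split; fit `SVC(kernel="linear", C=1)` (hinge loss, no
class weighting — balance comes from the subsampling; hyperparameters fixed
a priori, never tuned per subject); record held-out accuracy.  The final
hyperplane is the arithmetic mean of per-iteration (intercept, coefficient)
pairs without per-iteration renormalization (a unit-norm averaging mode is
available and flagged in reports, since raw averaging can be scale-
dominated).  If the averaged plane scores patients below controls it is
negated, enforcing the patient-positive sign convention.

Two averaged planes are produced: one from the 80 %-trained fits (paired
with the reported accuracies) and a "full-data" plane averaged over fits on
100 % of each balanced subsample, which is the default for MES — scores
should use all available data, while accuracy must come from held-out
splits.  An optional inner 10-fold CV on the training split is exposed for
diagnostics only.

Label-shuffling nulls permute epoch labels within the pooled
patient+control data before the pipeline re-runs.  (With one patient versus
a pool, permuting *subject* labels would collapse to a binary swap; the
epoch-level permutation is the meaningful exchangeability null, and an
identity-permutation hook makes the operation testable.)  The
control-vs-control null splits the pooled control epochs at random into a
pseudo-patient set and remainder: a held-out-subject variant would not be
exchangeable here, because each subject tracks its own stochastic path and
the position-referenced Excursion metric then leaks subject identity.

The within-subject two-state classifier (DBS On vs Off analogue) runs the
same protocol with the two states as classes, the larger state subsampled
to the smaller, z-scoring against the pooled two-state data, and a
shuffled-label null included in its report.

## Evaluation analyses

* **ROC/AUC** via the trapezoidal ROC integrator (`roc_auc_score`);
  the test suite cross-checks it against the Mann-Whitney U/(n₁n₂)
  identity to 10⁻¹⁰.  Pooled comparisons use a label-permutation bootstrap
  with the (k+1)/(B+1) p-value estimator (B = 100 by default), which can
  never report p = 0.
* **Percentile scan**: per percentile p ∈ 1..100, each subject's
  session-wide MES is reduced to its empirical p-th percentile (linear
  interpolation between order statistics) and Spearman-correlated with the
  clinical score across subjects; the argmax-ρ percentile is reported.
* **Phenotype rule**: tremor-to-PIGD item-mean ratio > 1.5 → TD, < 1 →
  PIGD, else mixed; zero PIGD mean with nonzero tremor counts as TD, both
  zero is undefined and raises.  Which rating-scale items feed each mean is
  caller-supplied data, not code.
* **Severity-recovery check**: MES is scored with one fixed reference
  hyperplane (fit from a severity-1.0 subject vs the control pool) and
  applied across the severity grid {0, 0.25, 0.5, 1, 2}; refitting a plane
  per severity would confound plane noise at severity 0 with the score
  ordering.  Epoch-mean MES is strictly increasing across the grid
  (Spearman ρ = 1).
* Gaussian smoothing of MES timelines exists in `plotting` for display
  only; no analysis consumes smoothed scores.

## Scale of the scores, and what the tests show

On the synthetic cohorts the per-patient accuracies and AUCs saturate near
1.0 and MES magnitudes reach hundreds: synthetic controls are nearly
noiseless, so one control SD — the unit of the standardized space — is
tiny, and patient epochs sit far from the pool.  Clinical recordings have
far noisier controls, which compresses both numbers; the synthetic runs
therefore validate the *machinery and orderings* (chance-level nulls,
tremor-exclusion hitting ET harder than PD, tremor-dominated ET weights,
MES monotone in severity, two-state separation with chance-level shuffled
null), not the absolute values achievable on patients.

## Problem sizes

The default study-sized layout is 20 control / 26 PD / 12 ET subjects with
15 trials (~375 epochs) each; `scripts/acceptance.py` runs at that scale.
The test suite uses shortened sessions (2–9 trials) chosen so that the
statistical checks still have ≥200 epochs per class where the contract
demands it.

## Known limitations

* The pursuit/tremor model is phenomenological; parameter values labelled
  "PD-like"/"ET-like" are defaults that produce the intended qualitative
  contrasts, not claims about patients.
* MES units are control-SD multiples and depend on the control pool; MES
  from different pools are not directly comparable.
* The literal subsample-by-120 protocol and the unit-norm averaging mode
  are provided but not the defaults; switching them changes coefficient
  scales (not weight ratios within a fit).
* Only the dominant upper extremity is modelled — no gait, speech, facial
  or lower-limb channels.
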