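# Methods

## Data model

Two streams per exercise set, synchronized by frame index at a shared
30 fps (no timestamps; clock drift beyond initial synchronization is out of
scope, so alignment truncates both streams to the shorter length):

* **IMU** (left wrist): 10 channels — quaternion stored in the sensor's
  z, y, x, w order (unit norm, printed to 4 decimals; deviations beyond
  1 ± 1e-3 warn rather than fail), gyroscope in deg/s (1 decimal),
  acceleration in g (3 decimals). Canonical container: a 10-column CSV in
  that channel order.
* **Pose keypoints**: 25 Body_25 joints per frame with pixel x, y and a
  confidence in [0, 1]; confidence < 0.05 marks an occluded joint
  (pose estimators emit exact zeros for undetected joints; the margin
  tolerates near-zero noise). Containers: per-frame OpenPose-style JSON
  (`pose_keypoints_2d`, 75 floats) or a consolidated 75-column CSV.
  Coordinates of missing joints never enter analysis space silently: they
  are filled by per-joint linear interpolation from the nearest observed
  frames before filtering.

## Preprocessing

* **Moving median filter**, window 15 (≈0.5 s at 30 fps), centered, with
  the window shrunk to in-bounds samples at the edges — no padding, so no
  fabricated values at set boundaries. Removes impulsive pose artifacts up
  to ~7 frames (0.25 s), the typical occlusion dropout. Applied to joint
  coordinates and, by default, to IMU channels as well (`mmf_on_imu`
  toggles this; the filter is harmless on smooth inertial signals).
* **Position normalization**: per frame, x′ᵢ = xᵢ − x₁, y′ᵢ = yᵢ − y₁
  (joint 1 = neck), removing camera-framing offset. The torso length used
  next is the Euclidean neck–hip distance √(x′₈² + y′₈²).
* **Scale normalization**: all coordinates × 100 / torso length, so the
  torso measures exactly 100 and camera distance and body size drop out.
  A zero torso length is an error naming the frame.
* **DC removal**: mean subtraction (idempotent).
* **Windows**: size 60, overlap 0.9 → hop = round(60 × 0.1) = 6 frames
  (0.2 s); count = floor((L − 60)/6) + 1; trailing frames that do not fill
  a window are dropped.

The normalization chain makes the downstream signals invariant to global
skeleton translation and uniform scaling, which the property tests assert
directly.

## Classifier

Four input variants share one architecture (same padding convolutions,
2×2 max pooling with floor semantics): the kernel sizes 5×5 and 2×2 are the
unique square kernels consistent with the fixed per-layer parameter counts
(25·1·32 + 32 = 832; 4·32·64 + 64 = 8256), and the dense head contributes
flatten·1000 + 1000 and 6·1000 + 6 parameters. Training defaults, all
config-exposed: ReLU activations, dropout 0.25 after the second pool and
0.5 after the dense layer, Adam at 1e-3, categorical cross-entropy,
15 epochs, batch 64, per-channel z-scoring with statistics from the
training split (IMU channels differ from joint channels by orders of
magnitude). The split is window-level by default, mirroring the original
protocol, with a warning: overlapping windows from one recording can land
on both sides, so held-out accuracy overstates generalization;
`split_level="recording"` gives the leakage-safe alternative. No class
reweighting. The whole network is a self-contained NumPy implementation
(`bandrep.nn`) with analytically verified gradients (finite-difference
test).

## Repetition counting

The paper-level idea — count zero crossings of the filtered, DC-free wrist
trajectory, two per repetition — needs a concrete decision rule. Ours is a
Schmitt trigger at ±h with h = 0.25 × the signal's standard deviation: the
first excursion beyond either threshold counts as one crossing (the signal
left baseline), each later flip to the opposite state counts as one more,
and repetitions = floor(crossings / 2), ignoring a trailing odd crossing.
For a k-cycle sinusoid this yields 2k or 2k + 1 crossings for *any* phase,
amplitude or offset, hence exactly k repetitions; counting only interior
sign changes would lose the first half-cycle at some phases (19 crossings
for 10 cycles starting at phase zero → 9). The hysteresis fraction is
config-exposed; 0.25 σ suppresses near-zero chatter while clearing even
heavily clipped oscillations. "Left hand" maps to Body_25 joint 7 (LWrist):
the 25-joint set has no hand keypoint. Counting runs per set, not per
window. A constant trajectory counts 0 with a warning. Mean relative error
in the score report is anchored to the true count.

## 1-RM estimation

Dumbbell route: Epley w·(1 + r/30) and Brzycki w·36/(37 − r), both
returning w at a single rep (Epley special-cased there) and considered
valid to ~10 reps — beyond that a warning is raised but the value is still
computed. Default Epley, config-selectable. Starting weights are a
bodyweight fraction by sex and exercise, snapped to the adjustable-dumbbell
grid (2.5 kg steps to 22.5, topping out at 24 kg; ties round up; the grid
is a parameter because hardware ladders vary). The shipped per-exercise
band-force equations take forces and return 1-RM in kg; their inputs'
units are asserted nowhere upstream, so callers must pass kg-equivalent
band forces. Band color → force mapping is deliberately *not* shipped as
fact: manufacturer tables are versioned external data, so it is a user
config, and the synthetic module documents a fictitious 7-level ladder
(1.4, 2.6, 3.9, 5.8, 8.2, 11.1, 14.6 kg) as a stand-in.

## Regression and model selection

Design: intercept + 10 terms (w₁, r₁, w₁², r₁², r₁:w₁ and the heavier-set
counterparts). OLS via statsmodels; rank deficiency is an error naming the
collinear columns. Backward elimination removes one term per iteration —
the largest p-value above α (default 0.05; one exercise in the source
analyses used 0.1, so α is per-run config) — never the intercept, and
returns every intermediate model as a ladder with adjusted R², residual SE
and p-values. Diagnostics expose residuals, fitted values, internally
studentized residuals, leverage (hat diagonal) and normal Q–Q pairs — the
numeric content of the four standard plots. `select_model` (fewest terms
within 0.05 adjusted-R² of the ladder maximum) is a mechanical convenience
standing in for the analyst's judgment, not part of the elimination
procedure itself.

A selection-theoretic caveat the tests respect: a term with a true zero
coefficient has an exactly uniform p-value, so elimination at α = 0.05
retains each null candidate with probability ≈ α. With 8–9 null terms the
probability of ending on *exactly* the generating term set is bounded near
0.95⁸ ≈ 0.66 no matter how small the noise — we measured ≈ 0.55 on the
cleanest single-term case and 0.65–0.73 on the shipped equations. What the
procedure does guarantee, and what the acceptance suite asserts, is that
every generating term is *retained* (measured 0.98–1.0 per equation at
n = 30, noise SD 0.1 kg): missing structure, not a spurious extra term, is
the failure that matters when the model is used for prediction.

## Synthetic data

The generator emulates the statistical structure each stage consumes, not
biomechanics:

* **Sessions**: a seated Body_25 skeleton (torso 200 px) with per-exercise
  templates — which joints oscillate, along which axis, at what amplitude
  (55–90 px at the wrist), period (1.5–2.4 s) and phase. The left-wrist
  axis follows the counting convention (x for chest press, y otherwise);
  the non-exercise class drifts at < 10 % of exercise amplitude. Exactly
  `reps` full cycles are generated before noise. The IMU is derived
  kinematically from the wrist path: a smooth rotation (peak 60°) about an
  exercise-specific axis gives unit quaternions (within 1e-6 before
  rounding), finite differences give the gyro, second differences plus
  gravity give the acceleration at a nominal 250 px/m. White pixel noise
  on every joint and Poisson-arriving occlusion dropouts (coordinates and
  confidence zeroed, default 6 ≤ 7 frames) model pose-estimation error.
* **Band datasets**: forces are log-uniform draws snapped to the sums of
  up to three layered bands from the fictitious ladder (layering follows
  the measurement protocol), sorted so w₂ ≥ w₁; repetitions fall linearly
  with force plus noise, clipped to 1..20 (reps were recorded up to 20),
  giving force–reps correlation ≈ −0.5; y comes from a chosen equation
  plus Gaussian noise. The coupling strength was fixed once, by an
  identifiability analysis: near-deterministic reps-on-force makes r:w an
  almost exact linear combination of w and w², and no elimination rule can
  then identify the generating terms at n = 30.
* **Classification corpus**: balanced windows per class from sessions with
  jittered phase and ±10 % period.

What passing on this data does **not** show: robustness to real pose
estimators' correlated, pose-dependent errors; inter-subject kinematic
variation; camera viewpoint changes; physically calibrated IMU signals; or
the published human-subject accuracies, which require the original
recordings. The synthetic results demonstrate pipeline correctness —
recovery of programmed ground truth under the stated noise and occlusion
models — and architectural/equation conformance.

## Problem sizes and numerics

Default test-time scales, chosen as the package's own study conditions:
counting recovery over 200 sessions per exercise with 1–20 cycles, periods
2.0–2.5 s, noise SD = 10 % of wrist amplitude, one ≤ 7-frame occlusion per
10 s on average; classifier sanity on 300 windows per class (the IMU
variant — smallest input, same stack — 10 epochs); regression recovery on
50 seeds per equation at n = 30. Float32 network arithmetic; float64
elsewhere. Ties: majority vote → earliest first occurrence; dumbbell snap →
round up; nearest band force → lower force. Degenerate inputs: constant
count signal → 0 reps + warning; zero-variance paired differences → t = ±∞,
p = 0 (t = 0, p = 1 when samples are identical); all-eliminated regression →
intercept-only model + warning.
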