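# bandrep

Resistance-band exercise analytics from a wrist IMU and 2-D pose keypoints:

* **exercise-type classification** — small CNNs over 2-second windows of
  IMU channels and/or Body_25 joint trajectories, with a per-recording
  majority vote;
* **repetition counting** — hysteresis zero-crossing analysis of the
  normalized left-wrist trajectory;
* **one-repetition-maximum (1-RM) estimation** — classical load–repetition
  formulas for dumbbell sets, and per-exercise polynomial equations mapping
  two band-force/repetition observations straight to the 1-RM, re-derivable
  from data by backward-eliminated polynomial regression.

The package targets strength-training and movement-science workflows where
elastic bands replace dumbbells and the trainee's working load must still be
anchored to the gold-standard 1-RM. Five seated upper-limb exercises are
modeled (Ex1 chest press, Ex2 shoulder press, Ex3 seated row, Ex4 biceps
curl, Ex5 overhead triceps extension) plus a non-exercise class (Ex6).

## The models

**Classification.** Input windows are N × 60 × 1 (N channels, 60 frames =
2 s at 30 fps, hop 6 frames = 0.2 s, i.e. 90 % overlap), with
N ∈ {10 IMU, 50 joints, 16 upper-body joints, 60 combined}. Joints are
occlusion-filled, median-filtered (window 15) and position-normalized
(x′ᵢ = xᵢ − x₁, relative to the neck) first. All four variants share one
stack — conv 5×5/32 (same padding) → max-pool 2×2 → conv 2×2/64 →
max-pool 2×2 → dropout → flatten → dense 1000 → dropout → dense 6 →
softmax — implemented self-contained in NumPy (`bandrep.nn`), trained with
Adam on categorical cross-entropy.

**Counting.** The left wrist (Body_25 joint 7) carries the movement: its
x coordinate for the chest press, y for the other exercises. The pipeline
is position normalization → scale normalization (divide by the neck–mid-hip
torso length, ×100) → moving median filter → DC removal → Schmitt-trigger
zero crossings at ±0.25 σ; one repetition = two crossings.

**1-RM.** Dumbbell route: Epley w·(1 + r/30) or Brzycki w·36/(37 − r).
Band route: per-exercise equations over the lighter (w₁, r₁) and heavier
(w₂, r₂) band observations, e.g. chest press
1-RM = 3.516284 − 0.924192 r₁ + 0.053651 r₁w₁ (forces in kg-equivalent).
The regression module rebuilds such equations: a 10-term design
(w₁, r₁, w₁², r₁², r₁:w₁, w₂, r₂, w₂², r₂², r₂:w₂) fit by OLS, reduced by
p-value-driven backward elimination into a model ladder with adjusted R²,
residual SE and the standard diagnostics.

## Worked example

Simulate a 12-repetition seated-row set, count it, and estimate a 1-RM:

```sh
$ bandrep simulate --exercise Ex3 --reps 12 --seed 7 --out session
$ bandrep count --exercise Ex3 --keypoints session/keypoints.csv
{
 "predicted": 12,
 "axis": "y",
 "crossings": 24
}
```

The counter recovered all 12 programmed repetitions from 24 baseline
crossings of the wrist's y trajectory. Estimating a shoulder-press 1-RM
from two band sets — 11 reps at 8.2 kg-equivalent, then 6 reps at 11.1 —
and from one dumbbell set of 8 reps at 14 kg:

```sh
$ bandrep estimate-1rm --exercise Ex2 --pairs "8.2,11,11.1,6"
{
 "exercise": "Ex2",
 "method": "band",
 "one_rm_kg": 6.2761499999999995
}
$ bandrep estimate-1rm --exercise Ex2 --weight 14 --reps 8
{
 "exercise": "Ex2",
 "method": "epley",
 "one_rm_kg": 17.733333333333334
}
```

The band equation evaluates −0.629601 + 0.992013·8.2 + 0.020787·6² −
0.029686·6·11.1 ≈ 6.28 kg; the Epley estimate is 14·(1 + 8/30) ≈ 17.7 kg.
Other commands: `preprocess` (windowed features), `train` / `classify`
(CNN on synthetic corpora, per-window labels + majority vote),
`fit-regression` (model ladder from an observation CSV). A YAML file via
`--config` supplies defaults (keys such as `seed`, `reps`, `alpha`,
`variant`); explicit flags override it.

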