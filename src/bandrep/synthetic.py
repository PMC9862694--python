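"""Seeded synthetic sessions and regression datasets.

The generator emulates the statistical structure the pipeline assumes, so
every stage can be exercised without recordings:

* a seated 25-joint Body_25 skeleton performing periodic upper-limb motion
  at 30 fps, with per-exercise motion templates (which joints oscillate,
  along which axis, at what amplitude and period) — the left wrist moves in
  x for the chest press and in y for the other exercises, matching the axis
  convention the repetition counter relies on;
* a wrist IMU derived kinematically from the simulated wrist trajectory:
  a smooth rotation about an exercise-specific axis (unit quaternion in the
  sensor's z, y, x, w order), its finite-difference angular rate in deg/s,
  and the second difference of the wrist position plus gravity, in g;
* pose-estimation occlusion: short dropouts (confidence 0, coordinates 0)
  of random joints, by default no longer than 7 frames (~0.23 s);
* band-force/repetition datasets in which heavier force co-occurs with
  fewer repetitions, with the 1-RM generated from a chosen equation plus
  Gaussian noise.

Everything is deterministic for a fixed seed. The band ladder shipped here
is a documented fictitious 7-level stand-in for a manufacturer table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel_io import (
    EXERCISES,
    LEFT_ELBOW,
    LEFT_SHOULDER,
    LEFT_WRIST,
    N_JOINTS,
    RIGHT_ELBOW,
    RIGHT_SHOULDER,
    RIGHT_WRIST,
    IMUTrack,
    JointTrack,
    SessionRecording,
)
from .onerm import BandObservationPair, RMEquation
from .preprocess import WindowBatch, assemble_features
from .regression import RegressionDataset

__all__ = [
    "MotionTemplate",
    "SimulationConfig",
    "TEMPLATES",
    "SYNTHETIC_BAND_LADDER",
    "simulate_session",
    "simulate_band_dataset",
    "simulate_classification_corpus",
]

#: fictitious 7-level band ladder (kg-equivalent), synthetic stand-in for a
#: manufacturer's color-force table
SYNTHETIC_BAND_LADDER = (1.4, 2.6, 3.9, 5.8, 8.2, 11.1, 14.6)

PX_PER_METER = 250.0  # pixel scale of the synthetic camera
GRAVITY = 9.81

#: neutral seated Body_25 skeleton (pixel coordinates, y grows downward)
BASE_POSE = np.array([
    (320.0, 90.0),   # 0 nose
    (320.0, 140.0),  # 1 neck
    (270.0, 150.0),  # 2 right shoulder
    (255.0, 210.0),  # 3 right elbow
    (250.0, 265.0),  # 4 right wrist
    (370.0, 150.0),  # 5 left shoulder
    (385.0, 210.0),  # 6 left elbow
    (390.0, 265.0),  # 7 left wrist
    (320.0, 340.0),  # 8 mid-hip
    (290.0, 340.0),  # 9 right hip
    (285.0, 420.0),  # 10 right knee
    (285.0, 500.0),  # 11 right ankle
    (350.0, 340.0),  # 12 left hip
    (355.0, 420.0),  # 13 left knee
    (355.0, 500.0),  # 14 left ankle
    (310.0, 82.0),   # 15 right eye
    (330.0, 82.0),   # 16 left eye
    (300.0, 90.0),   # 17 right ear
    (340.0, 90.0),   # 18 left ear
    (360.0, 520.0),  # 19 left big toe
    (370.0, 520.0),  # 20 left small toe
    (350.0, 505.0),  # 21 left heel
    (280.0, 520.0),  # 22 right big toe
    (270.0, 520.0),  # 23 right small toe
    (290.0, 505.0),  # 24 right heel
], dtype=float)


@dataclass(frozen=True)
class MotionTemplate:
    """Per-exercise oscillation recipe over the Body_25 skeleton.

    ``moving_joints`` maps joint index -> (x amplitude px, y amplitude px,
    phase offset rad); ``axis_of_motion`` is the left-wrist axis that
    carries the counting signal; ``imu_axis`` the rotation axis of the
    simulated wrist sensor; ``rotation_deg`` its peak excursion.
    """

    exercise: str
    base_pose: np.ndarray
    moving_joints: dict[int, tuple[float, float, float]]
    axis_of_motion: str
    rep_period: float
    imu_axis: tuple[float, float, float]
    rotation_deg: float = 60.0

    def __post_init__(self) -> None:
        pose = np.asarray(self.base_pose, dtype=float)
        if pose.shape != (N_JOINTS, 2):
            raise ValueError(f"base_pose must be ({N_JOINTS}, 2)")
        object.__setattr__(self, "base_pose", pose)
        if self.axis_of_motion not in ("x", "y"):
            raise ValueError("axis_of_motion must be 'x' or 'y'")
        ax, ay, _ = self.moving_joints.get(LEFT_WRIST, (0.0, 0.0, 0.0))
        dominant = "x" if abs(ax) >= abs(ay) else "y"
        if (abs(ax) or abs(ay)) and dominant != self.axis_of_motion:
            raise ValueError(
                f"left-wrist motion is dominated by {dominant}, but "
                f"axis_of_motion is {self.axis_of_motion}")
        torso = np.linalg.norm(pose[1] - pose[8])
        if torso <= 0:
            raise ValueError("base torso length must be positive")

    @property
    def wrist_amplitude(self) -> float:
        ax, ay, _ = self.moving_joints.get(LEFT_WRIST, (0.0, 0.0, 0.0))
        return float(np.hypot(ax, ay))


def _mirror(amplitudes: dict[int, tuple[float, float, float]],
            pairs=((LEFT_WRIST, RIGHT_WRIST), (LEFT_ELBOW, RIGHT_ELBOW),
                   (LEFT_SHOULDER, RIGHT_SHOULDER))):
    """Copy left-side amplitudes onto the right side with mirrored x."""
    out = dict(amplitudes)
    for left, right in pairs:
        if left in out and right not in out:
            ax, ay, ph = out[left]
            out[right] = (-ax, ay, ph)
    return out


def _pose_with(overrides: dict[int, tuple[float, float]]) -> np.ndarray:
    pose = BASE_POSE.copy()
    for j, (x, y) in overrides.items():
        pose[j] = (x, y)
    return pose


#: one template per class; the templates are pairwise distinguishable by
#: moving-joint set, amplitude, period and IMU rotation axis
TEMPLATES: dict[str, MotionTemplate] = {
    # chest press: horizontal push, wrists travel in x
    "Ex1": MotionTemplate(
        "Ex1", BASE_POSE,
        _mirror({LEFT_WRIST: (80.0, 0.0, 0.0), LEFT_ELBOW: (45.0, 0.0, 0.0)}),
        axis_of_motion="x", rep_period=2.0, imu_axis=(0.0, 0.0, 1.0)),
    # shoulder press: vertical push from shoulder height
    "Ex2": MotionTemplate(
        "Ex2", _pose_with({LEFT_WRIST: (390.0, 160.0), RIGHT_WRIST: (250.0, 160.0),
                           LEFT_ELBOW: (385.0, 190.0), RIGHT_ELBOW: (255.0, 190.0)}),
        _mirror({LEFT_WRIST: (0.0, -90.0, 0.0), LEFT_ELBOW: (0.0, -50.0, 0.0)}),
        axis_of_motion="y", rep_period=2.4, imu_axis=(1.0, 0.0, 0.0)),
    # seated row: pull toward the torso, wrists rise slightly while pulling
    "Ex3": MotionTemplate(
        "Ex3", BASE_POSE,
        _mirror({LEFT_WRIST: (25.0, 55.0, 0.0), LEFT_ELBOW: (20.0, 35.0, 0.0),
                 LEFT_SHOULDER: (0.0, 8.0, 0.0)}),
        axis_of_motion="y", rep_period=1.7, imu_axis=(0.0, 1.0, 0.0)),
    # biceps curl: forearm swings the wrist upward, elbow nearly fixed
    "Ex4": MotionTemplate(
        "Ex4", BASE_POSE,
        _mirror({LEFT_WRIST: (0.0, -70.0, 0.0), LEFT_ELBOW: (0.0, -8.0, 0.0)}),
        axis_of_motion="y", rep_period=1.5,
        imu_axis=(0.7071067811865476, 0.7071067811865476, 0.0)),
    # overhead triceps extension: wrists above the head
    "Ex5": MotionTemplate(
        "Ex5", _pose_with({LEFT_WRIST: (345.0, 70.0), RIGHT_WRIST: (295.0, 70.0),
                           LEFT_ELBOW: (350.0, 110.0), RIGHT_ELBOW: (290.0, 110.0)}),
        _mirror({LEFT_WRIST: (0.0, -75.0, 0.0), LEFT_ELBOW: (0.0, -25.0, 0.0)}),
        axis_of_motion="y", rep_period=2.1,
        imu_axis=(0.7071067811865476, 0.0, 0.7071067811865476)),
    # non-exercise: slow low-amplitude drift (< 10% of exercise amplitudes)
    "Ex6": MotionTemplate(
        "Ex6", BASE_POSE,
        _mirror({LEFT_WRIST: (0.0, 5.0, 0.0), LEFT_ELBOW: (0.0, 3.0, 0.0)}),
        axis_of_motion="y", rep_period=5.0, imu_axis=(0.0, 0.0, 1.0),
        rotation_deg=4.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of one simulated exercise set.

    ``noise_sd`` is white pixel noise added to every joint coordinate;
    occlusion events arrive at ``occlusion_rate`` per minute, each hiding
    one random joint for ``occlusion_len`` consecutive frames (default 6,
    within the ~0.25 s the median filter absorbs); ``max_duration`` caps
    the set length.
    """

    fps: float = 30.0
    reps: int = 10
    rep_period: float | None = None  # seconds; template default when None
    noise_sd: float = 0.0
    occlusion_rate: float = 0.0
    occlusion_len: int = 6
    seed: int = 0
    max_duration: float = 300.0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.reps < 0 or self.noise_sd < 0 \
                or self.occlusion_rate < 0 or self.occlusion_len < 0:
            raise ValueError("all simulation parameters must be nonnegative")


def _quaternion_track(theta_deg: np.ndarray, axis) -> np.ndarray:
    """Unit quaternions for a rotation of theta about a fixed axis,
    in the sensor's storage order z, y, x, w."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    half = np.radians(theta_deg) / 2.0
    sin_h = np.sin(half)
    q = np.column_stack([
        axis[2] * sin_h,  # z
        axis[1] * sin_h,  # y
        axis[0] * sin_h,  # x
        np.cos(half),     # w
    ])
    return q


def simulate_session(template: MotionTemplate, cfg: SimulationConfig
                     ) -> tuple[SessionRecording, dict]:
    """One synthetic exercise set with ground truth.

    The wrist trajectory completes exactly ``cfg.reps`` full cycles before
    noise; joints and IMU share the length and fps. Returns the recording
    and ``{"exercise": ..., "reps": ...}``.
    """
    rng = np.random.default_rng(cfg.seed)
    period = cfg.rep_period if cfg.rep_period is not None else template.rep_period
    duration = max(cfg.reps, 1) * period
    if duration > cfg.max_duration:
        raise ValueError(f"requested set of {duration:.0f} s exceeds the "
                         f"{cfg.max_duration:.0f} s maximum")
    n = int(round(duration * cfg.fps))
    t = np.arange(n) / cfg.fps
    omega = 2.0 * np.pi / period
    phase_t = omega * t

    x = np.tile(template.base_pose[:, 0], (n, 1))
    y = np.tile(template.base_pose[:, 1], (n, 1))
    if cfg.reps > 0:
        for j, (ax, ay, ph) in template.moving_joints.items():
            wave = np.sin(phase_t + ph)
            x[:, j] += ax * wave
            y[:, j] += ay * wave

    # wrist IMU from the clean wrist trajectory
    wrist_x, wrist_y = x[:, LEFT_WRIST].copy(), y[:, LEFT_WRIST].copy()
    theta = template.rotation_deg * (np.sin(phase_t) if cfg.reps > 0
                                     else np.zeros(n))
    quat = _quaternion_track(theta, template.imu_axis)
    dt = 1.0 / cfg.fps
    gyro_mag = np.gradient(theta, dt)  # deg/s
    axis = np.asarray(template.imu_axis) / np.linalg.norm(template.imu_axis)
    gyro = np.outer(gyro_mag, axis)
    acc_x = np.gradient(np.gradient(wrist_x, dt), dt) / PX_PER_METER / GRAVITY
    acc_y = np.gradient(np.gradient(wrist_y, dt), dt) / PX_PER_METER / GRAVITY
    acc = np.column_stack([acc_x, acc_y, np.ones(n)])  # gravity on za

    imu_data = np.column_stack([quat, gyro, acc])
    if cfg.noise_sd > 0:
        # gyro/acceleration noise scaled off the keypoint noise level
        rel = cfg.noise_sd / max(template.wrist_amplitude, 1.0)
        imu_data[:, 4:7] += rng.normal(0, rel * template.rotation_deg, (n, 3))
        imu_data[:, 7:10] += rng.normal(0, rel * 0.1, (n, 3))

    conf = np.clip(0.95 + rng.normal(0, 0.02, (n, N_JOINTS)), 0.0, 1.0)
    if cfg.noise_sd > 0:
        x += rng.normal(0, cfg.noise_sd, (n, N_JOINTS))
        y += rng.normal(0, cfg.noise_sd, (n, N_JOINTS))

    # occlusion dropouts: confidence 0, coordinates 0 (the raw-format
    # convention for undetected joints)
    if cfg.occlusion_rate > 0 and cfg.occlusion_len > 0:
        n_events = rng.poisson(cfg.occlusion_rate * duration / 60.0)
        for _ in range(n_events):
            j = int(rng.integers(N_JOINTS))
            start = int(rng.integers(max(n - cfg.occlusion_len, 1)))
            sl = slice(start, start + cfg.occlusion_len)
            x[sl, j] = 0.0
            y[sl, j] = 0.0
            conf[sl, j] = 0.0

    joints = JointTrack(x=x, y=y, conf=conf, fps=cfg.fps, space="pixel")
    imu = IMUTrack(imu_data, fps=cfg.fps)
    rec = SessionRecording(imu=imu, joints=joints, exercise=template.exercise,
                           true_reps=cfg.reps)
    return rec, {"exercise": template.exercise, "reps": cfg.reps}


def expected_occluded_frames(cfg: SimulationConfig, duration_s: float) -> float:
    """Expected count of (frame, joint) dropout cells for one session."""
    return cfg.occlusion_rate * duration_s / 60.0 * cfg.occlusion_len


def achievable_band_forces(ladder=SYNTHETIC_BAND_LADDER,
                           max_layers: int = 3) -> np.ndarray:
    """Distinct forces reachable by layering up to ``max_layers`` bands."""
    import itertools

    sums = {float(sum(combo))
            for k in range(1, max_layers + 1)
            for combo in itertools.combinations_with_replacement(ladder, k)}
    return np.array(sorted(sums))


def simulate_band_dataset(eq: RMEquation, n: int = 30, noise_sd: float = 0.1,
                          seed: int = 0,
                          ladder=SYNTHETIC_BAND_LADDER
                          ) -> tuple[RegressionDataset, dict]:
    """Per-subject band observations with the generating equation as truth.

    Each subject's two forces are drawn (log-uniformly, then snapped to the
    nearest achievable value) from the forces reachable by layering up to
    three bands, and sorted so w2 >= w1 always holds. Repetitions fall
    linearly with force plus noise, clipped to 1..20 (sets were recorded up
    to 20 repetitions), giving the negative force-repetition coupling of
    real sets to failure; y = eq(w1, r1, w2, r2) + N(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    forces = achievable_band_forces(ladder)
    lo, hi = np.log(forces[0]), np.log(forces[-1])
    rows = []
    for _ in range(n):
        target = np.exp(rng.uniform(lo, hi, 2))
        w = np.sort([float(forces[np.abs(forces - v).argmin()]) for v in target])
        if w[0] == w[1]:  # force the pairs apart by one achievable step
            k = int(np.searchsorted(forces, w[1]))
            w[1] = float(forces[min(k + 1, len(forces) - 1)])
        w1, w2 = float(w[0]), float(w[1])
        r1 = float(np.clip(np.round(14.0 - 0.25 * w1 + rng.normal(0, 5.0)), 1, 20))
        r2 = float(np.clip(np.round(14.0 - 0.25 * w2 + rng.normal(0, 5.0)), 1, 20))
        y = eq.evaluate(BandObservationPair(w1, r1, w2, r2))
        if noise_sd > 0:
            y += rng.normal(0, noise_sd)
        rows.append({"w1": w1, "r1": r1, "w2": w2, "r2": r2, "y": y})
    ds = RegressionDataset(rows=pd.DataFrame(rows), exercise=eq.exercise)
    truth = {"terms": eq.terms, "intercept": eq.intercept,
             "coefficients": dict(eq.coefficients)}
    return ds, truth


def simulate_classification_corpus(n_per_class: int, cfg: SimulationConfig,
                                   variant: str = "imu") -> WindowBatch:
    """Balanced labeled window batch over all six classes.

    Sessions are simulated per class with jittered phase and period until
    ``n_per_class`` windows accumulate; windows carry their class label.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    batches = []
    for exercise in EXERCISES:
        template = TEMPLATES[exercise]
        collected: list[WindowBatch] = []
        total = 0
        while total < n_per_class:
            period = template.rep_period * float(rng.uniform(0.9, 1.1))
            jitter = {j: (ax, ay, float(rng.uniform(0, 2 * np.pi)))
                      for j, (ax, ay, _) in template.moving_joints.items()}
            jittered = MotionTemplate(
                template.exercise, template.base_pose, jitter,
                template.axis_of_motion, period, template.imu_axis,
                template.rotation_deg)
            sess_cfg = SimulationConfig(
                fps=cfg.fps, reps=cfg.reps, rep_period=period,
                noise_sd=cfg.noise_sd, occlusion_rate=cfg.occlusion_rate,
                occlusion_len=cfg.occlusion_len,
                seed=int(rng.integers(2**31)))
            rec, _ = simulate_session(jittered, sess_cfg)
            wins = assemble_features(rec, variant)
            collected.append(wins)
            total += len(wins)
        merged = WindowBatch.concatenate(collected)
        batches.append(WindowBatch(
            windows=merged.windows[:n_per_class],
            channel_layout=merged.channel_layout,
            labels=merged.labels[:n_per_class],
            source_index=merged.source_index[:n_per_class],
            hop=merged.hop))
    return WindowBatch.concatenate(batches)
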