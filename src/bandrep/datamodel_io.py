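"""Core data types and readers/writers for wrist-IMU and pose-keypoint streams.

The pipeline works on two synchronized 30 fps streams recorded during a
resistance-band exercise set:

* a 10-channel wrist IMU stream — quaternion (stored in the sensor's
  ``z, y, x, w`` order), gyroscope (deg/s) and accelerometer (multiples of
  g, 1 = 9.81 m/s²);
* a 25-joint 2-D skeleton stream in the Body_25 layout (joint 0 = nose,
  1 = neck, 7 = left wrist, 8 = mid-hip), each joint carrying a detection
  confidence in [0, 1]; confidence ~0 marks an occluded joint.

On-disk dialects: a plain 10-column CSV for the IMU (header optional),
and either OpenPose-style per-frame JSON files (``pose_keypoints_2d``,
75 floats) or a consolidated 75-column CSV for the keypoints.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "IMU_CHANNELS",
    "N_JOINTS",
    "NECK",
    "LEFT_WRIST",
    "MID_HIP",
    "MISSING_CONFIDENCE",
    "EXERCISES",
    "IMUSample",
    "IMUTrack",
    "KeypointFrame",
    "JointTrack",
    "SessionRecording",
    "read_imu",
    "write_imu",
    "read_keypoints",
    "write_keypoints",
    "align_streams",
]

#: IMU channel order as emitted by the sensor: quaternion z, y, x, w,
#: then gyro x, y, z (deg/s), then acceleration x, y, z (g).
IMU_CHANNELS = ("zq", "yq", "xq", "wq", "xg", "yg", "zg", "xa", "ya", "za")

#: per-channel print precision (decimals) of the sensor dump
_IMU_DECIMALS = (4, 4, 4, 4, 1, 1, 1, 3, 3, 3)

N_JOINTS = 25
NOSE, NECK, LEFT_WRIST, MID_HIP = 0, 1, 7, 8
RIGHT_SHOULDER, RIGHT_ELBOW, RIGHT_WRIST = 2, 3, 4
LEFT_SHOULDER, LEFT_ELBOW = 5, 6

#: joints with confidence below this are treated as missing (OpenPose emits
#: exact zeros for undetected joints; the margin tolerates near-zero noise)
MISSING_CONFIDENCE = 0.05

#: class labels: five exercises plus the non-exercise class
EXERCISES = ("Ex1", "Ex2", "Ex3", "Ex4", "Ex5", "Ex6")
EXERCISE_NAMES = {
    "Ex1": "chest press",
    "Ex2": "shoulder press",
    "Ex3": "seated row",
    "Ex4": "biceps curl",
    "Ex5": "overhead triceps extension",
    "Ex6": "non-exercise",
}

_SPACES = ("pixel", "position_normalized", "scale_normalized")
_QUAT_NORM_TOL = 1e-3  # sensor rounds to 4 decimals


@dataclass(frozen=True)
class IMUSample:
    """One 10-channel IMU reading (quaternion, gyro deg/s, acceleration g)."""

    zq: float
    yq: float
    xq: float
    wq: float
    xg: float
    yg: float
    zg: float
    xa: float
    ya: float
    za: float

    @property
    def quaternion_norm(self) -> float:
        return float(np.sqrt(self.zq**2 + self.yq**2 + self.xq**2 + self.wq**2))


@dataclass
class IMUTrack:
    """Ordered 10-channel IMU stream at a constant frame rate.

    ``data`` is an (n_frames, 10) float array in :data:`IMU_CHANNELS` order.
    """

    data: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(IMU_CHANNELS):
            raise ValueError(
                f"IMU data must be (n, {len(IMU_CHANNELS)}), got {self.data.shape}"
            )
        if len(self.data) == 0:
            raise ValueError("IMU track is empty")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("IMU track contains non-finite values")

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, i: int) -> IMUSample:
        return IMUSample(*self.data[i])

    @property
    def samples(self) -> Iterator[IMUSample]:
        for row in self.data:
            yield IMUSample(*row)

    def quaternion_norms(self) -> np.ndarray:
        return np.linalg.norm(self.data[:, :4], axis=1)

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, IMU_CHANNELS.index(name)]

    def truncated(self, n: int) -> "IMUTrack":
        return IMUTrack(self.data[:n].copy(), fps=self.fps)


@dataclass(frozen=True)
class KeypointFrame:
    """One frame of 25 Body_25 joints: pixel x, y and confidence c."""

    x: np.ndarray
    y: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("x", "y", "c"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (N_JOINTS,):
                raise ValueError(f"{name} must have exactly {N_JOINTS} joints")
            object.__setattr__(self, name, arr)

    def missing(self) -> np.ndarray:
        return self.c < MISSING_CONFIDENCE


@dataclass
class JointTrack:
    """Ordered 25-joint keypoint stream.

    ``x``, ``y``, ``conf`` are (n_frames, 25) arrays. ``space`` tracks the
    normalization state and may only advance
    pixel → position_normalized → scale_normalized.
    """

    x: np.ndarray
    y: np.ndarray
    conf: np.ndarray
    fps: float = 30.0
    space: str = "pixel"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        if not (self.x.shape == self.y.shape == self.conf.shape):
            raise ValueError("x, y, conf must share one shape")
        if self.x.ndim != 2 or self.x.shape[1] != N_JOINTS:
            raise ValueError(f"JointTrack must be (n, {N_JOINTS}), got {self.x.shape}")
        if len(self.x) == 0:
            raise ValueError("joint track is empty")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.space not in _SPACES:
            raise ValueError(f"unknown space {self.space!r}; expected one of {_SPACES}")

    def __len__(self) -> int:
        return len(self.x)

    def __getitem__(self, i: int) -> KeypointFrame:
        return KeypointFrame(self.x[i], self.y[i], self.conf[i])

    @property
    def frames(self) -> Iterator[KeypointFrame]:
        for i in range(len(self)):
            yield self[i]

    def missing_mask(self) -> np.ndarray:
        """(n_frames, 25) boolean mask of occluded joints."""
        return self.conf < MISSING_CONFIDENCE

    def with_space(self, space: str) -> "JointTrack":
        """Return a copy advanced to ``space`` (transition order enforced)."""
        if _SPACES.index(space) < _SPACES.index(self.space):
            raise ValueError(f"cannot move back from {self.space} to {space}")
        return replace(self, x=self.x.copy(), y=self.y.copy(),
                       conf=self.conf.copy(), space=space)

    def copy(self) -> "JointTrack":
        return replace(self, x=self.x.copy(), y=self.y.copy(), conf=self.conf.copy())

    def truncated(self, n: int) -> "JointTrack":
        return replace(self, x=self.x[:n].copy(), y=self.y[:n].copy(),
                       conf=self.conf[:n].copy())


@dataclass
class SessionRecording:
    """Time-aligned IMU + joint streams for one exercise set."""

    imu: IMUTrack
    joints: JointTrack
    exercise: str
    true_reps: int | None = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.exercise not in EXERCISES:
            raise ValueError(f"unknown exercise {self.exercise!r}")
        if len(self.imu) != len(self.joints):
            raise ValueError(
                f"streams not aligned: imu {len(self.imu)} vs joints {len(self.joints)}"
            )
        if self.imu.fps != self.joints.fps:
            raise ValueError(
                f"fps mismatch: imu {self.imu.fps} vs joints {self.joints.fps}"
            )
        if self.true_reps is not None and self.true_reps < 0:
            raise ValueError("true_reps must be nonnegative")

    def __len__(self) -> int:
        return len(self.imu)

    @property
    def fps(self) -> float:
        return self.imu.fps


# ---------------------------------------------------------------------------
# IMU I/O
# ---------------------------------------------------------------------------

def _parse_numeric_row(line: str) -> list[float] | None:
    parts = [p for p in line.replace("\t", ",").split(",") if p.strip()]
    try:
        return [float(p) for p in parts]
    except ValueError:
        return None


def read_imu(path: str | Path, fps: float = 30.0) -> IMUTrack:
    """Read a 10-column delimited IMU dump (header row optional).

    Columns, in order: zq, yq, xq, wq, xg, yg, zg, xa, ya, za. Quaternion
    norms outside 1 ± 1e-3 trigger a warning, not an error (the sensor
    rounds each component to 4 decimals). A row that does not parse into
    exactly 10 numbers raises, naming the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"IMU file not found: {path}")
    rows: list[list[float]] = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            if not line.strip():
                continue
            values = _parse_numeric_row(line)
            if values is None:
                if idx == 0 and not rows:  # header row
                    continue
                raise ValueError(f"row {idx} of {path} is not numeric")
            if len(values) != len(IMU_CHANNELS):
                raise ValueError(
                    f"row {idx} of {path} has {len(values)} values, "
                    f"expected {len(IMU_CHANNELS)}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"no IMU samples in {path}")
    track = IMUTrack(np.array(rows, dtype=float), fps=fps)
    norms = track.quaternion_norms()
    bad = np.abs(norms - 1.0) > _QUAT_NORM_TOL
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} of {len(track)} quaternions in {path.name} deviate "
            f"from unit norm by more than {_QUAT_NORM_TOL}",
            stacklevel=2,
        )
    return track


def write_imu(track: IMUTrack, path: str | Path, header: bool = False) -> None:
    """Write an IMU track as CSV at the sensor's print precisions
    (quaternion 4, gyro 1, acceleration 3 decimals)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write(",".join(IMU_CHANNELS) + "\n")
        for row in track.data:
            fh.write(
                ",".join(f"{v:.{d}f}" for v, d in zip(row, _IMU_DECIMALS)) + "\n"
            )


# ---------------------------------------------------------------------------
# Keypoint I/O
# ---------------------------------------------------------------------------

def _triplets_from_json(payload: dict, where: str) -> np.ndarray:
    if "pose_keypoints_2d" in payload:
        flat = payload["pose_keypoints_2d"]
    elif "people" in payload:
        people = payload["people"]
        if not people:
            raise ValueError(f"{where}: no people detected in frame")
        flat = people[0]["pose_keypoints_2d"]
    else:
        raise ValueError(f"{where}: no pose_keypoints_2d field")
    flat = np.asarray(flat, dtype=float)
    if flat.size != 3 * N_JOINTS:
        raise ValueError(
            f"{where}: expected {3 * N_JOINTS} values (25 x/y/c triplets), "
            f"got {flat.size}"
        )
    return flat.reshape(N_JOINTS, 3)


def read_keypoints(path: str | Path, fps: float = 30.0) -> JointTrack:
    """Read a keypoint stream into a pixel-space :class:`JointTrack`.

    ``path`` is either a directory of OpenPose per-frame JSON files (ordered
    filename-lexicographically) or a single consolidated 75-column table
    (x0, y0, c0, …, x24, y24, c24 per row).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix == ".json")
        if not files:
            raise ValueError(f"no per-frame JSON files in {path}")
        frames = []
        for f in files:
            with open(f) as fh:
                frames.append(_triplets_from_json(json.load(fh), f.name))
        data = np.stack(frames)
    elif path.exists():
        rows: list[np.ndarray] = []
        with open(path) as fh:
            for idx, line in enumerate(fh):
                if not line.strip():
                    continue
                values = _parse_numeric_row(line)
                if values is None:
                    if idx == 0 and not rows:
                        continue
                    raise ValueError(f"row {idx} of {path} is not numeric")
                if len(values) != 3 * N_JOINTS:
                    raise ValueError(
                        f"row {idx} of {path} has {len(values)} values, "
                        f"expected {3 * N_JOINTS}"
                    )
                rows.append(np.asarray(values).reshape(N_JOINTS, 3))
        if not rows:
            raise ValueError(f"no keypoint frames in {path}")
        data = np.stack(rows)
    else:
        raise FileNotFoundError(f"keypoint path not found: {path}")
    return JointTrack(x=data[:, :, 0], y=data[:, :, 1], conf=data[:, :, 2], fps=fps)


def write_keypoints(track: JointTrack, path: str | Path,
                    fmt: str = "csv") -> None:
    """Write a joint track either as a 75-column CSV (``fmt='csv'``) or a
    directory of per-frame OpenPose-style JSON files (``fmt='json'``)."""
    path = Path(path)
    flat = np.stack([track.x, track.y, track.conf], axis=2).reshape(len(track), -1)
    if fmt == "csv":
        np.savetxt(path, flat, fmt="%.6f", delimiter=",")
    elif fmt == "json":
        path.mkdir(parents=True, exist_ok=True)
        for i, row in enumerate(flat):
            payload = {"people": [{"pose_keypoints_2d": [float(v) for v in row]}]}
            with open(path / f"frame_{i:06d}_keypoints.json", "w") as fh:
                json.dump(payload, fh)
    else:
        raise ValueError(f"unknown keypoint format {fmt!r}")


def align_streams(imu: IMUTrack, joints: JointTrack, exercise: str = "Ex6",
                  true_reps: int | None = None,
                  subject_id: str = "") -> SessionRecording:
    """Frame-index alignment of the two streams at a shared fps.

    Both streams are truncated to the shorter length; an fps mismatch is an
    error (synchronization is by frame index, no resampling).
    """
    if imu.fps != joints.fps:
        raise ValueError(f"fps mismatch: imu {imu.fps} vs joints {joints.fps}")
    n = min(len(imu), len(joints))
    return SessionRecording(
        imu=imu.truncated(n),
        joints=joints.truncated(n),
        exercise=exercise,
        true_reps=true_reps,
        subject_id=subject_id,
    )
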