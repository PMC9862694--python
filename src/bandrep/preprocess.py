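"""Filtering, normalization and windowing shared by the classifier and the
repetition counter.

The stack, in pipeline order:

1. occlusion fill — joints with near-zero confidence are linearly
   interpolated from the nearest observed frames (longer gaps than the
   median filter can absorb would otherwise leak zeros into analysis space);
2. moving median filter (MMF), window 15 ≈ 0.5 s at 30 fps — removes
   impulsive pose-estimation artifacts lasting up to ~0.25 s;
3. position normalization — coordinates re-expressed relative to the neck,
   removing camera framing bias (x′ᵢ = xᵢ − x₁, y′ᵢ = yᵢ − y₁);
4. scale normalization — coordinates divided by the torso length
   (neck–mid-hip Euclidean distance) and multiplied by 100, removing
   camera distance and body size; the torso maps to length 100;
5. DC removal — per-series mean subtraction;
6. overlapping windows — 60-sample (2 s) windows with 90% overlap (hop 6
   frames = 0.2 s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datamodel_io import (
    IMU_CHANNELS,
    LEFT_ELBOW,
    LEFT_SHOULDER,
    LEFT_WRIST,
    MID_HIP,
    N_JOINTS,
    NECK,
    RIGHT_ELBOW,
    RIGHT_SHOULDER,
    RIGHT_WRIST,
    IMUTrack,
    JointTrack,
    SessionRecording,
)

__all__ = [
    "WindowBatch",
    "moving_median_filter",
    "fill_missing",
    "mmf_track",
    "position_normalize",
    "scale_normalize",
    "remove_dc",
    "segment_windows",
    "assemble_features",
    "FEATURE_VARIANTS",
    "UPPER_BODY_JOINTS",
]

logger = logging.getLogger(__name__)

DEFAULT_MMF_WINDOW = 15
DEFAULT_WINDOW_SIZE = 60
DEFAULT_OVERLAP = 0.9

#: neck, L/R shoulders, L/R elbows, L/R wrists, mid-hip
UPPER_BODY_JOINTS = (NECK, LEFT_SHOULDER, RIGHT_SHOULDER, LEFT_ELBOW,
                     RIGHT_ELBOW, LEFT_WRIST, RIGHT_WRIST, MID_HIP)

#: input variant -> channel count of the classifier input (N x 60 x 1)
FEATURE_VARIANTS = {"imu": 10, "joints": 50, "upper_joints": 16, "imu_joints": 60}


@dataclass
class WindowBatch:
    """Stack of fixed-length multichannel windows, the classifier's input.

    ``windows`` has shape (n_windows, n_channels, window_size); every window
    spans exactly 60 time steps (2 s at 30 fps) and consecutive windows from
    one recording start ``hop`` frames apart.
    """

    windows: np.ndarray
    channel_layout: tuple[str, ...]
    labels: np.ndarray | None = None
    source_index: np.ndarray | None = None
    hop: int = 6

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_channels, size)")
        n_win, n_ch, size = self.windows.shape
        if size != DEFAULT_WINDOW_SIZE:
            raise ValueError(f"every window must have {DEFAULT_WINDOW_SIZE} "
                             f"time steps, got {size}")
        if n_ch not in FEATURE_VARIANTS.values():
            raise ValueError(
                f"channel count {n_ch} not one of {sorted(set(FEATURE_VARIANTS.values()))}"
            )
        if len(self.channel_layout) != n_ch:
            raise ValueError("channel_layout length must match channel count")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n_win:
                raise ValueError("labels length must match window count")
        if self.source_index is not None:
            self.source_index = np.asarray(self.source_index, dtype=int)
            if len(self.source_index) != n_win:
                raise ValueError("source_index length must match window count")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @staticmethod
    def concatenate(batches: "list[WindowBatch]") -> "WindowBatch":
        first = batches[0]
        labels = None
        if all(b.labels is not None for b in batches):
            labels = np.concatenate([b.labels for b in batches])
        src = None
        if all(b.source_index is not None for b in batches):
            src = np.concatenate([b.source_index for b in batches])
        return WindowBatch(
            windows=np.concatenate([b.windows for b in batches]),
            channel_layout=first.channel_layout,
            labels=labels,
            source_index=src,
            hop=first.hop,
        )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def moving_median_filter(series, window: int = DEFAULT_MMF_WINDOW) -> np.ndarray:
    """Centered moving median with a shrinking window at the boundaries.

    Element t is the median of the in-bounds samples in
    ``series[t-h : t+h+1]`` with ``h = window // 2``; near the edges only
    the in-bounds samples enter the median (no padding, so no fabricated
    values at set boundaries). Impulses shorter than half the window inside
    an otherwise steady segment are removed entirely.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    n = x.size
    h = window // 2
    out = np.empty(n)
    if n > window:
        interior = np.lib.stride_tricks.sliding_window_view(x, window)
        out[h:n - h] = np.median(interior, axis=1)
        edge = h
    else:
        edge = n  # everything is boundary
    for t in range(min(edge, n)):
        out[t] = np.median(x[max(0, t - h): t + h + 1])
    for t in range(max(n - edge, min(edge, n)), n):
        out[t] = np.median(x[max(0, t - h): t + h + 1])
    return out


def fill_missing(track: JointTrack) -> JointTrack:
    """Linearly interpolate occluded joints from nearest observed frames.

    Joints missing at the ends of the recording take the nearest observed
    value. A joint never observed is left at its raw coordinates and a
    warning is logged; per-joint missingness fractions are logged at DEBUG.
    """
    out = track.copy()
    mask = track.missing_mask()
    t = np.arange(len(track), dtype=float)
    for j in range(N_JOINTS):
        miss = mask[:, j]
        if not miss.any():
            continue
        frac = miss.mean()
        logger.debug("joint %d missing in %.1f%% of frames", j, 100 * frac)
        if miss.all():
            logger.warning("joint %d missing in every frame; left unfilled", j)
            continue
        obs = ~miss
        out.x[miss, j] = np.interp(t[miss], t[obs], track.x[obs, j])
        out.y[miss, j] = np.interp(t[miss], t[obs], track.y[obs, j])
    return out


def mmf_track(track: JointTrack, window: int = DEFAULT_MMF_WINDOW) -> JointTrack:
    """Apply the moving median filter to every joint coordinate series."""
    out = track.copy()
    for j in range(N_JOINTS):
        out.x[:, j] = moving_median_filter(track.x[:, j], window)
        out.y[:, j] = moving_median_filter(track.y[:, j], window)
    return out


def mmf_imu(track: IMUTrack, window: int = DEFAULT_MMF_WINDOW) -> IMUTrack:
    """Apply the moving median filter to every IMU channel."""
    data = np.column_stack(
        [moving_median_filter(track.data[:, k], window)
         for k in range(track.data.shape[1])]
    )
    return IMUTrack(data, fps=track.fps)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def position_normalize(track: JointTrack) -> JointTrack:
    """Express every joint relative to the neck (joint 1): x′ᵢ = xᵢ − x₁.

    Removes camera-framing offset; the neck maps to the origin in every
    frame. Requires pixel space and a neck observed in at least one frame
    (fill occlusions first).
    """
    if track.space != "pixel":
        raise ValueError(f"expected pixel space, got {track.space}")
    if track.missing_mask()[:, NECK].all():
        raise ValueError("neck (joint 1) missing in every frame; cannot "
                         "position-normalize")
    out = track.with_space("position_normalized")
    out.x -= track.x[:, NECK][:, None]
    out.y -= track.y[:, NECK][:, None]
    return out


def scale_normalize(track: JointTrack) -> JointTrack:
    """Divide by the per-frame torso length and multiply by 100.

    Torso length is the Euclidean distance between the neck (origin after
    position normalization) and the mid-hip (joint 8); after scaling the
    torso measures exactly 100 in every frame, which unifies camera
    distance and body size across subjects.
    """
    if track.space != "position_normalized":
        raise ValueError(f"expected position_normalized space, got {track.space}")
    torso = np.hypot(track.x[:, MID_HIP], track.y[:, MID_HIP])
    zero = np.nonzero(torso == 0)[0]
    if zero.size:
        raise ValueError(f"zero torso length at frame {int(zero[0])}")
    out = track.with_space("scale_normalized")
    out.x *= (100.0 / torso)[:, None]
    out.y *= (100.0 / torso)[:, None]
    return out


def remove_dc(series) -> np.ndarray:
    """Subtract the series mean (idempotent; output mean is 0)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    return x - x.mean()


# ---------------------------------------------------------------------------
# Windowing and feature assembly
# ---------------------------------------------------------------------------

def window_count(length: int, size: int = DEFAULT_WINDOW_SIZE,
                 overlap: float = DEFAULT_OVERLAP) -> int:
    hop = _hop(size, overlap)
    if length < size:
        return 0
    return (length - size) // hop + 1


def _hop(size: int, overlap: float) -> int:
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    hop = int(round(size * (1 - overlap)))
    return max(hop, 1)


def segment_windows(channels: np.ndarray, size: int = DEFAULT_WINDOW_SIZE,
                    overlap: float = DEFAULT_OVERLAP,
                    channel_layout: tuple[str, ...] | None = None,
                    label: str | None = None) -> WindowBatch:
    """Cut an (n_channels, length) array into overlapping fixed windows.

    With the defaults (size 60, overlap 0.9) the hop is 6 frames = 0.2 s at
    30 fps. Window k covers frames [k·hop, k·hop + size); no window reads
    past the end, trailing frames that do not fill a window are dropped.
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    n_ch, length = channels.shape
    if length < size:
        raise ValueError(f"recording too short to window: {length} < {size}")
    hop = _hop(size, overlap)
    k = (length - size) // hop + 1
    starts = np.arange(k) * hop
    windows = np.stack([channels[:, s:s + size] for s in starts])
    if channel_layout is None:
        channel_layout = tuple(f"ch{i}" for i in range(n_ch))
    labels = np.array([label] * k) if label is not None else None
    return WindowBatch(windows=windows, channel_layout=tuple(channel_layout),
                       labels=labels, source_index=starts, hop=hop)


def _joint_channels(track: JointTrack, joints) -> tuple[np.ndarray, tuple[str, ...]]:
    chans, names = [], []
    for j in joints:
        chans.append(track.x[:, j])
        names.append(f"x{j}")
        chans.append(track.y[:, j])
        names.append(f"y{j}")
    return np.stack(chans), tuple(names)


def assemble_features(rec: SessionRecording, variant: str,
                      mmf_window: int = DEFAULT_MMF_WINDOW,
                      mmf_on_imu: bool = True,
                      size: int = DEFAULT_WINDOW_SIZE,
                      overlap: float = DEFAULT_OVERLAP) -> WindowBatch:
    """Build the classifier input windows for one recording.

    Variants (channel count): ``imu`` (10), ``joints`` (50),
    ``upper_joints`` (16: x, y of neck, both shoulders, both elbows, both
    wrists, mid-hip), ``imu_joints`` (60: IMU channels followed by all 50
    joint channels). Joints are occlusion-filled, median-filtered and
    position-normalized before stacking; IMU channels are median-filtered
    too by default (``mmf_on_imu=False`` disables that).
    """
    if variant not in FEATURE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"expected one of {sorted(FEATURE_VARIANTS)}")
    parts: list[np.ndarray] = []
    names: list[str] = []
    if variant in ("imu", "imu_joints"):
        imu = mmf_imu(rec.imu, mmf_window) if mmf_on_imu else rec.imu
        parts.append(imu.data.T)
        names.extend(IMU_CHANNELS)
    if variant != "imu":
        joints = position_normalize(mmf_track(fill_missing(rec.joints), mmf_window))
        sel = UPPER_BODY_JOINTS if variant == "upper_joints" else range(N_JOINTS)
        chans, chan_names = _joint_channels(joints, sel)
        parts.append(chans)
        names.extend(chan_names)
    channels = np.concatenate(parts, axis=0)
    assert channels.shape[0] == FEATURE_VARIANTS[variant]
    return segment_windows(channels, size=size, overlap=overlap,
                           channel_layout=tuple(names), label=rec.exercise)
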