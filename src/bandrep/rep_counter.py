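"""Repetition counting from the left-wrist trajectory.

A repetition is one full flexion–extension cycle of the hand. The counter
normalizes the skeleton (position, then scale), picks the wrist axis that
carries the movement — the x coordinate for the chest press (Ex1), the y
coordinate for the other four exercises — median-filters it, removes the
DC offset, and counts zero crossings of the resulting oscillation with a
hysteresis band so that chatter near zero is not double-counted. Two
crossings make one repetition; a trailing odd crossing is ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel_io import LEFT_WRIST, JointTrack
from .preprocess import (
    DEFAULT_MMF_WINDOW,
    fill_missing,
    mmf_track,
    moving_median_filter,
    position_normalize,
    remove_dc,
    scale_normalize,
)

__all__ = [
    "CountResult",
    "CountErrorReport",
    "select_signal",
    "hysteresis_crossings",
    "count_repetitions",
    "score_counts",
]

logger = logging.getLogger(__name__)

#: fraction of the signal's standard deviation used as the hysteresis band
DEFAULT_HYSTERESIS = 0.25

#: per-exercise wrist axis carrying the periodic movement
SIGNAL_AXIS = {"Ex1": "x", "Ex2": "y", "Ex3": "y", "Ex4": "y", "Ex5": "y"}


@dataclass
class CountResult:
    predicted: int
    signal_used: str
    crossings: int
    filtered_signal: np.ndarray

    def __post_init__(self) -> None:
        if self.predicted < 0:
            raise ValueError("predicted reps must be nonnegative")

    def as_dict(self) -> dict:
        return {"predicted": self.predicted, "axis": self.signal_used,
                "crossings": self.crossings}


@dataclass
class CountErrorReport:
    """Counting-accuracy summary over a batch of sets: mean absolute error,
    mean relative error (relative to the true count) and the fractions of
    sets counted exactly, within 1 and within 2."""

    mae: float
    mre: float
    p_exact: float
    p_within1: float
    p_within2: float

    def as_dict(self) -> dict:
        return {"mae": self.mae, "mre": self.mre, "p_exact": self.p_exact,
                "p_within1": self.p_within1, "p_within2": self.p_within2}


def select_signal(track: JointTrack, exercise: str) -> tuple[np.ndarray, str]:
    """Left-wrist series carrying the movement: x for Ex1, y for Ex2–Ex5.

    Ex6 (non-exercise) has no repetition semantics and is rejected.
    """
    if exercise not in SIGNAL_AXIS:
        raise ValueError(f"no repetition semantics for {exercise!r} "
                         f"(expected one of {sorted(SIGNAL_AXIS)})")
    axis = SIGNAL_AXIS[exercise]
    series = track.x[:, LEFT_WRIST] if axis == "x" else track.y[:, LEFT_WRIST]
    return series.copy(), axis


def hysteresis_crossings(signal: np.ndarray,
                         hysteresis: float = DEFAULT_HYSTERESIS) -> int:
    """Count baseline crossings of a zero-mean signal with hysteresis.

    A Schmitt trigger with thresholds ±h, h = ``hysteresis`` × the signal's
    standard deviation: the first excursion beyond either threshold counts
    as a crossing (the signal left the baseline), and every subsequent flip
    to the opposite state counts as one more. Small fluctuations inside the
    band are ignored. For a sinusoid of k full cycles this yields 2k or
    2k + 1 crossings regardless of phase, amplitude or offset.
    """
    x = np.asarray(signal, dtype=float)
    h = hysteresis * x.std()
    if h == 0:
        return 0
    state = 0  # -1, 0 (not yet committed), +1
    crossings = 0
    for v in x:
        if state <= 0 and v > h:
            crossings += 1
            state = 1
        elif state >= 0 and v < -h:
            crossings += 1
            state = -1
    return crossings


def count_repetitions(track: JointTrack, exercise: str, fps: float | None = None,
                      mmf_window: int = DEFAULT_MMF_WINDOW,
                      hysteresis: float = DEFAULT_HYSTERESIS) -> CountResult:
    """Count repetitions in a pixel-space joint track for one exercise set.

    Pipeline: occlusion fill → position normalize → scale normalize →
    select the wrist axis → moving median filter → DC removal → hysteresis
    zero-crossing count; repetitions = floor(crossings / 2). A degenerate
    (constant) trajectory yields 0 with a warning.
    """
    fps = fps if fps is not None else track.fps
    if len(track) < 2 * fps:
        raise ValueError(f"track too short to count: {len(track)} frames "
                         f"< 2 s at {fps} fps")
    normalized = scale_normalize(position_normalize(fill_missing(track)))
    series, axis = select_signal(normalized, exercise)
    filtered = remove_dc(moving_median_filter(series, mmf_window))
    if filtered.std() == 0:
        warnings.warn("constant wrist trajectory; counting 0 repetitions",
                      stacklevel=2)
        return CountResult(0, axis, 0, filtered)
    crossings = hysteresis_crossings(filtered, hysteresis)
    return CountResult(crossings // 2, axis, crossings, filtered)


def score_counts(predicted, truth) -> CountErrorReport:
    """Score predicted against true per-set repetition counts."""
    p = np.asarray(predicted, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if np.any(t <= 0):
        raise ValueError("true counts must be positive")
    err = np.abs(p - t)
    return CountErrorReport(
        mae=float(err.mean()),
        mre=float((err / t).mean()),
        p_exact=float((err == 0).mean()),
        p_within1=float((err <= 1).mean()),
        p_within2=float((err <= 2).mean()),
    )
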