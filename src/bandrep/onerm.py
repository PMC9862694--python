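"""One-repetition-maximum (1-RM) estimation.

Two routes to the 1-RM, the heaviest load liftable exactly once:

* **dumbbell route** — the classical load–repetition relationship applied
  to one set taken to failure at a submaximal weight: Epley
  ``w·(1 + r/30)`` or Brzycki ``w·36/(37 − r)``; both reduce to ``w`` at
  one repetition and are considered reliable up to ~10 repetitions;
* **band route** — published per-exercise polynomial equations mapping two
  band-force/repetition observations (the lighter pair ``(w1, r1)`` and the
  heavier pair ``(w2, r2)``, forces in kg-equivalent) straight to the
  dumbbell 1-RM.

Also here: the starting-weight table (fraction of bodyweight by sex and
exercise, snapped to the adjustable-dumbbell grid), the paired t-test used
to compare band force against 1-RM, and nearest-band-force selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _stats

from .datamodel_io import EXERCISE_NAMES

__all__ = [
    "LoadRepsObservation",
    "BandObservationPair",
    "RMEquation",
    "DEFAULT_RM_EQUATIONS",
    "STARTING_WEIGHT_RATIOS",
    "DUMBBELL_STEPS",
    "estimate_1rm_dumbbell",
    "starting_weight",
    "predict_1rm_band",
    "paired_t_test",
    "closest_band_force",
    "TERM_NAMES",
]

logger = logging.getLogger(__name__)

#: canonical polynomial term names over the two observation pairs
TERM_NAMES = ("w1", "r1", "w1^2", "r1^2", "r1:w1",
              "w2", "r2", "w2^2", "r2^2", "r2:w2")

#: fraction of bodyweight used to pick the first dumbbell, by sex
STARTING_WEIGHT_RATIOS = {
    ("male", "Ex1"): 0.20, ("female", "Ex1"): 0.10,
    ("male", "Ex2"): 0.15, ("female", "Ex2"): 0.10,
    ("male", "Ex3"): 0.20, ("female", "Ex3"): 0.10,
    ("male", "Ex4"): 0.10, ("female", "Ex4"): 0.05,
    ("male", "Ex5"): 0.05, ("female", "Ex5"): 0.05,
}

#: adjustable-dumbbell grid (kg): 2.5 kg steps up to 22.5, topping out at 24
DUMBBELL_STEPS = tuple(np.arange(2.5, 23.0, 2.5)) + (24.0,)

REPS_VALID_MAX = 10  # load-repetition formulas degrade beyond ~10 reps


@dataclass(frozen=True)
class LoadRepsObservation:
    """One set to failure: load (kg), repetitions achieved, exercise."""

    weight: float
    reps: int
    exercise: str

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.reps < 1:
            raise ValueError("reps must be a positive integer")


@dataclass(frozen=True)
class BandObservationPair:
    """The two heaviest band-force sets: lighter (w1, r1), heavier (w2, r2)."""

    w1: float
    r1: float
    w2: float
    r2: float

    def __post_init__(self) -> None:
        if self.w2 < self.w1:
            raise ValueError(f"w2 ({self.w2}) must be >= w1 ({self.w1})")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("repetitions must be nonnegative")

    def term_value(self, term: str) -> float:
        values = {
            "w1": self.w1, "r1": self.r1,
            "w1^2": self.w1**2, "r1^2": self.r1**2, "r1:w1": self.r1 * self.w1,
            "w2": self.w2, "r2": self.r2,
            "w2^2": self.w2**2, "r2^2": self.r2**2, "r2:w2": self.r2 * self.w2,
        }
        return values[term]


@dataclass(frozen=True)
class RMEquation:
    """Coefficient set of one exercise's band-force → 1-RM polynomial.

    ``coefficients`` maps term names from :data:`TERM_NAMES` to kg-scale
    values; absent terms are zero.
    """

    exercise: str
    intercept: float
    coefficients: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown terms {sorted(unknown)}")

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t in TERM_NAMES if self.coefficients.get(t, 0.0) != 0.0)

    def evaluate(self, pair: BandObservationPair) -> float:
        return self.intercept + sum(
            coef * pair.term_value(term)
            for term, coef in self.coefficients.items()
        )


#: published per-exercise 1-RM estimation equations (forces and 1-RM in kg)
DEFAULT_RM_EQUATIONS = {
    "Ex1": RMEquation("Ex1", 3.516284,
                      {"r1": -0.924192, "r1:w1": 0.053651}),
    "Ex2": RMEquation("Ex2", -0.629601,
                      {"w1": 0.992013, "r2^2": 0.020787, "r2:w2": -0.029686}),
    "Ex3": RMEquation("Ex3", 11.29618,
                      {"w1": -1.10259, "r1^2": -0.05265,
                       "w2": 0.84785, "r2:w2": 0.07982}),
    "Ex4": RMEquation("Ex4", 4.432227,
                      {"w1^2": 0.005706, "w2^2": 0.031340, "r1:w1": 0.004674}),
    "Ex5": RMEquation("Ex5", 0.642109,
                      {"w2": 0.063498, "r1:w1": 0.006473}),
}


def estimate_1rm_dumbbell(obs: LoadRepsObservation,
                          formula: str = "epley") -> float:
    """1-RM (kg) from one submaximal set via Epley or Brzycki.

    Both formulas return the lifted weight itself at one repetition.
    Repetition counts above 10 are outside the relationship's validity
    range; the estimate is still computed but a warning is raised.
    """
    if obs.reps > REPS_VALID_MAX:
        warnings.warn(
            f"{obs.reps} reps exceeds the ~{REPS_VALID_MAX}-rep validity "
            "range of load-repetition 1-RM formulas", stacklevel=2)
    if formula == "epley":
        if obs.reps == 1:  # a single rep to failure is the 1-RM itself
            return float(obs.weight)
        return obs.weight * (1.0 + obs.reps / 30.0)
    if formula == "brzycki":
        return obs.weight * 36.0 / (37.0 - obs.reps)
    raise ValueError(f"unknown formula {formula!r}; expected epley or brzycki")


def starting_weight(bodyweight: float, sex: str, exercise: str,
                    steps=DUMBBELL_STEPS) -> float:
    """First dumbbell weight: bodyweight × the sex/exercise ratio, snapped
    to the nearest available dumbbell step (ties round up) and clamped to
    the grid's range."""
    if bodyweight <= 0:
        raise ValueError("bodyweight must be positive")
    key = (sex, exercise)
    if key not in STARTING_WEIGHT_RATIOS:
        raise ValueError(f"no starting ratio for sex={sex!r}, "
                         f"exercise={exercise!r}")
    target = bodyweight * STARTING_WEIGHT_RATIOS[key]
    grid = np.asarray(sorted(steps), dtype=float)
    target = float(np.clip(target, grid[0], grid[-1]))
    dist = np.abs(grid - target)
    best = dist.min()
    candidates = grid[dist == best]
    return float(candidates.max())  # ties round up


def predict_1rm_band(eq: RMEquation, pair: BandObservationPair) -> float:
    """Evaluate a band-force → 1-RM equation at one observation pair.

    A negative prediction (extrapolation outside the fitted region) is
    returned as-is with a warning.
    """
    value = eq.evaluate(pair)
    if value < 0:
        warnings.warn(
            f"negative predicted 1-RM ({value:.3f} kg) for {eq.exercise} "
            f"({EXERCISE_NAMES.get(eq.exercise, eq.exercise)}): observation "
            "outside the fitted region", stacklevel=2)
    return value


def paired_t_test(a, b) -> dict[str, float]:
    """Two-tailed paired t-test between matched samples.

    Returns mean difference, SD and SE of the differences, the 95% CI of
    the mean difference, t and p. Zero-variance differences make t
    undefined; it is reported as signed infinity with p = 0 (or t = 0,
    p = 1 when the samples are identical).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / np.sqrt(n)
    if sd == 0.0:
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            t = float(np.sign(mean)) * float("inf")
            p = 0.0
        return {"mean_diff": mean, "sd": sd, "se": se, "ci95_low": mean,
                "ci95_high": mean, "t": t, "p": p, "n": n}
    t = mean / se
    p = 2.0 * _stats.t.sf(abs(t), df=n - 1)
    tcrit = _stats.t.ppf(0.975, df=n - 1)
    return {"mean_diff": mean, "sd": sd, "se": se,
            "ci95_low": mean - tcrit * se, "ci95_high": mean + tcrit * se,
            "t": float(t), "p": float(p), "n": n}


def closest_band_force(rm: float, available_forces) -> float:
    """Band force nearest to a 1-RM; ties resolve to the lower force."""
    forces = np.asarray(list(available_forces), dtype=float)
    if forces.size == 0:
        raise ValueError("available_forces must be non-empty")
    dist = np.abs(forces - rm)
    best = dist.min()
    candidates = forces[dist == best]
    choice = float(candidates.min())
    if candidates.size > 1:
        logger.info("band-force tie at |Δ|=%.3f; keeping lower force %.2f",
                    best, choice)
    return choice
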