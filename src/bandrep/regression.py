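"""Polynomial regression of the 1-RM on two band-force/repetition pairs.

The model construction procedure: build the 10-term design
(w1, r1, w1², r1², r1:w1, w2, r2, w2², r2², r2:w2) plus intercept over the
per-subject observations, fit by ordinary least squares, then reduce by
backward elimination — repeatedly drop the non-intercept term with the
largest p-value above the significance threshold and refit — until every
retained term is significant. The full model ladder is returned so the
final model can be chosen on adjusted R², parsimony and the standard
diagnostics (residuals vs fitted, normal Q–Q, scale–location, leverage).

OLS fitting itself is delegated to statsmodels; the design construction,
elimination schedule and ladder bookkeeping live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as _stats

from .onerm import TERM_NAMES, RMEquation

__all__ = [
    "RegressionDataset",
    "FittedModel",
    "build_design",
    "fit_ols",
    "backward_eliminate",
    "diagnostics",
    "select_model",
    "to_equation",
]

logger = logging.getLogger(__name__)

INTERCEPT = "const"
DESIGN_COLUMNS = (INTERCEPT,) + TERM_NAMES


@dataclass
class RegressionDataset:
    """Per-subject (w1, r1, w2, r2, y) observations for one exercise.

    ``rows`` is a DataFrame with columns w1, r1, w2, r2, y; the 1-RM y is
    in kg and w2 >= w1 rowwise (heavier pair second).
    """

    rows: pd.DataFrame
    exercise: str

    def __post_init__(self) -> None:
        required = {"w1", "r1", "w2", "r2", "y"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"dataset missing columns {sorted(missing)}")
        if self.rows[sorted(required)].isna().any().any():
            raise ValueError("dataset contains missing cells")
        if (self.rows["w2"] < self.rows["w1"]).any():
            raise ValueError("w2 must be >= w1 in every row")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class FittedModel:
    """One OLS fit: retained terms, coefficients, p-values and fit quality."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    adj_r2: float
    resid_se: float
    n: int

    def __post_init__(self) -> None:
        if set(self.terms) != set(self.p_values) or \
                set(self.terms) != set(self.coefficients):
            raise ValueError("terms, coefficients and p_values must align")

    @property
    def n_terms(self) -> int:
        """Number of non-intercept terms."""
        return sum(1 for t in self.terms if t != INTERCEPT)

    def as_dict(self) -> dict:
        return {"terms": list(self.terms), "coefficients": self.coefficients,
                "p_values": self.p_values, "adj_r2": self.adj_r2,
                "resid_se": self.resid_se, "n": self.n}


def build_design(ds: RegressionDataset) -> pd.DataFrame:
    """The 11-column design matrix (intercept + 10 polynomial terms)."""
    r = ds.rows
    X = pd.DataFrame({
        INTERCEPT: np.ones(len(r)),
        "w1": r["w1"], "r1": r["r1"],
        "w1^2": r["w1"] ** 2, "r1^2": r["r1"] ** 2, "r1:w1": r["r1"] * r["w1"],
        "w2": r["w2"], "r2": r["r2"],
        "w2^2": r["w2"] ** 2, "r2^2": r["r2"] ** 2, "r2:w2": r["r2"] * r["w2"],
    }, index=r.index)
    return X[list(DESIGN_COLUMNS)]


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        collinear = []
        for col in X.columns:
            sub = X.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(col)
        raise ValueError(f"design matrix is rank-deficient; collinear "
                         f"columns: {collinear}")


def fit_ols(X: pd.DataFrame, y) -> FittedModel:
    """Ordinary least squares of y on the given design columns.

    Reports two-sided t-test p-values per coefficient, adjusted R² and the
    residual standard error sqrt(RSS / (n − k − 1)) with k the number of
    non-intercept terms. Requires more rows than columns and a full-rank
    design (collinear columns are named in the error).
    """
    y = np.asarray(y, dtype=float)
    if len(X) <= X.shape[1]:
        raise ValueError(f"need more rows ({len(X)}) than columns "
                         f"({X.shape[1]})")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return FittedModel(
        terms=tuple(X.columns),
        coefficients={c: float(v) for c, v in res.params.items()},
        p_values={c: float(v) for c, v in res.pvalues.items()},
        adj_r2=float(res.rsquared_adj),
        resid_se=float(np.sqrt(res.mse_resid)),
        n=int(res.nobs),
    )


def backward_eliminate(X: pd.DataFrame, y, alpha: float = 0.05
                       ) -> list[FittedModel]:
    """p-value-driven backward elimination; returns the full model ladder.

    Starting from the full design, the non-intercept term with the largest
    p-value above ``alpha`` is dropped and the model refit, one term per
    iteration, until every non-intercept term is significant at ``alpha``.
    The intercept is never a removal candidate. The returned ladder starts
    with the full model and ends with the selected one; if every term is
    eliminated the last entry is the intercept-only model (with a warning).
    """
    y = np.asarray(y, dtype=float)
    current = X.copy()
    ladder = [fit_ols(current, y)]
    while True:
        model = ladder[-1]
        removable = {t: p for t, p in model.p_values.items() if t != INTERCEPT}
        if not removable:
            warnings.warn("all terms eliminated; intercept-only model",
                          stacklevel=2)
            break
        worst_term, worst_p = max(removable.items(), key=lambda kv: kv[1])
        if worst_p <= alpha:
            break
        logger.debug("dropping %s (p=%.4f)", worst_term, worst_p)
        current = current.drop(columns=[worst_term])
        if current.shape[1] == 1:  # intercept only
            res = sm.OLS(y, current).fit()
            ladder.append(FittedModel(
                terms=(INTERCEPT,),
                coefficients={INTERCEPT: float(res.params.iloc[0])},
                p_values={INTERCEPT: float(res.pvalues.iloc[0])},
                adj_r2=float(res.rsquared_adj),
                resid_se=float(np.sqrt(res.mse_resid)),
                n=int(res.nobs),
            ))
            warnings.warn("all terms eliminated; intercept-only model",
                          stacklevel=2)
            break
        ladder.append(fit_ols(current, y))
    return ladder


def diagnostics(m: FittedModel, X: pd.DataFrame, y) -> dict[str, np.ndarray]:
    """Numeric arrays behind the four standard OLS diagnostic plots.

    Returns residuals, fitted values, internally studentized residuals,
    leverage (hat-matrix diagonal, summing to the number of model terms)
    and the normal Q–Q pairs (theoretical, ordered sample quantiles of the
    studentized residuals).
    """
    y = np.asarray(y, dtype=float)
    Xm = X[list(m.terms)]
    res = sm.OLS(y, Xm).fit()
    influence = res.get_influence()
    leverage = influence.hat_matrix_diag
    std_resid = influence.resid_studentized_internal
    osm, osr = _stats.probplot(std_resid, dist="norm", fit=False)
    return {
        "residuals": np.asarray(res.resid),
        "fitted": np.asarray(res.fittedvalues),
        "std_residuals": np.asarray(std_resid),
        "leverage": np.asarray(leverage),
        "qq_pairs": np.column_stack([osm, osr]),
    }


def select_model(ladder: list[FittedModel], adj_r2_slack: float = 0.05
                 ) -> FittedModel:
    """Convenience default: the fewest-term ladder model whose adjusted R²
    is within ``adj_r2_slack`` of the ladder maximum.

    This is a mechanical stand-in for the judgment call the procedure
    leaves to the analyst (who weighs adjusted R², parsimony and the
    diagnostic plots); inspect the ladder when it matters.
    """
    if not ladder:
        raise ValueError("empty ladder")
    best = max(m.adj_r2 for m in ladder)
    eligible = [m for m in ladder if m.adj_r2 >= best - adj_r2_slack]
    return min(eligible, key=lambda m: m.n_terms)


def to_equation(m: FittedModel, exercise: str) -> RMEquation:
    """Convert a fitted model into an :class:`RMEquation`."""
    coeffs = {t: c for t, c in m.coefficients.items() if t != INTERCEPT}
    return RMEquation(exercise=exercise,
                      intercept=m.coefficients.get(INTERCEPT, 0.0),
                      coefficients=coeffs)
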