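"""Estimation contracts shared by every analysis stage.

Two fits cover the whole pipeline: ordinary least squares for
SNP/GRS -> 25(OH)D associations (beta_ZX, beta_GRS-VD) and maximum-likelihood
logistic regression for disease outcomes (beta_ZY, beta_XY).  Both return
coefficient vectors with a full variance-covariance matrix; Wald-style 95%
confidence intervals (beta +/- 1.96 se) are used throughout.

The numerical work is delegated to statsmodels (OLS / Logit with Newton
scoring, parameter tolerance 1e-10, at most 100 iterations); this module
adds the error contract: rank-deficient designs raise naming the collinear
columns, complete or quasi-complete separation raises instead of silently
diverging, and non-convergence is an error, never a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationWarning

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

#: Documented level order for categorical covariates; the first level is the
#: reference for indicator contrasts.
CATEGORICAL_LEVELS = {
    "income_band": ["<2000", "2000-3499", "3500-4999", ">=5000"],
    "smoking_status": ["never", "former", "current"],
    "alcohol_status": ["never", "former", "current"],
    "sex": ["female", "male"],
}


class RankDeficientError(ValueError):
    """The design matrix is not full rank; names the collinear columns."""


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the logistic MLE does not exist."""


class FitConvergenceError(RuntimeError):
    """The likelihood maximization did not converge within the iteration cap."""


@dataclass(frozen=True)
class AssociationEstimate:
    """One regression coefficient on the link scale with Wald uncertainty.

    ``role`` tags the arrow of the MR diagram the coefficient estimates
    (``beta_ZX`` instrument->exposure, ``beta_ZY`` instrument->outcome,
    ``beta_XY`` observational exposure->outcome, ``beta_GRS_VD``
    score->25(OH)D); ``label`` carries the instrument identity (rsid or GRS
    panel name) so downstream estimators can refuse mismatched pairs.
    """

    beta: float
    se: float
    role: str = ""
    label: str = ""
    n: int = 0
    adjusted_for: tuple[str, ...] = ()

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.beta - Z_95 * self.se, self.beta + Z_95 * self.se)

    @property
    def p(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        return float(2 * stats.norm.sf(abs(self.beta) / self.se))

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci95(self) -> tuple[float, float]:
        lo, hi = self.ci95
        return (float(np.exp(lo)), float(np.exp(hi)))


@dataclass
class FitResult:
    """Coefficients plus covariance from one regression fit."""

    params: pd.Series
    cov: pd.DataFrame
    n: int
    kind: str  # "linear" | "logistic"
    r_squared: float = float("nan")
    resid_var: float = float("nan")
    llf: float = float("nan")
    fitted: np.ndarray | None = None
    adjusted_for: tuple[str, ...] = ()

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def estimate(self, term: str, role: str = "", label: str = "") -> AssociationEstimate:
        """Package one coefficient as an :class:`AssociationEstimate`."""
        return AssociationEstimate(
            beta=float(self.params[term]),
            se=float(self.bse[term]),
            role=role,
            label=label,
            n=self.n,
            adjusted_for=self.adjusted_for,
        )


def build_design(
    data: pd.DataFrame,
    terms: Sequence[str],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Design matrix from named columns, expanding categoricals to indicators.

    Categorical covariates (income band, smoking and alcohol status, sex)
    enter as indicator contrasts against the documented first level.  Boolean
    columns are cast to 0/1.
    """
    pieces = {}
    if add_intercept:
        pieces["const"] = pd.Series(1.0, index=data.index)
    for term in terms:
        if term not in data.columns:
            raise KeyError(f"design term {term!r} not found in the data")
        col = data[term]
        if term in CATEGORICAL_LEVELS or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = CATEGORICAL_LEVELS.get(term)
            if levels is None:
                levels = sorted(col.dropna().unique().tolist())
            observed = set(col.dropna().unique())
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(f"unknown levels {sorted(unknown)} in categorical {term!r}")
            for level in levels[1:]:
                if level in observed:
                    pieces[f"{term}[{level}]"] = (col == level).astype(float)
        elif col.dtype == bool or str(col.dtype) == "boolean":
            pieces[term] = col.astype(float)
        else:
            pieces[term] = col.astype(float)
    return pd.DataFrame(pieces, index=data.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        bad = X.columns[~np.isfinite(arr).all(axis=0)].tolist()
        raise ValueError(f"non-finite values in design columns {bad}")
    # QR with column pivoting: near-zero diagonal entries of R mark columns
    # linearly dependent on the preceding ones.
    from scipy.linalg import qr

    _, r, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * max(arr.shape) * np.finfo(float).eps
    deficient = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if len(diag) < X.shape[1] or deficient:
        extra = [X.columns[p] for p in piv[len(diag):]]
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns: {deficient + extra}"
        )


def linear_fit(
    response,
    design: pd.DataFrame,
    adjusted_for: tuple[str, ...] = (),
) -> FitResult:
    """Ordinary least squares with classical covariance and R-squared."""
    y = np.asarray(response, dtype=float)
    if len(y) <= design.shape[1]:
        raise ValueError(
            f"need more observations ({len(y)}) than predictors ({design.shape[1]})"
        )
    _check_rank(design)
    model = sm.OLS(y, design)
    res = model.fit()
    return FitResult(
        params=res.params,
        cov=res.cov_params(),
        n=len(y),
        kind="linear",
        r_squared=float(res.rsquared) if "const" in design.columns else float(res.rsquared),
        resid_var=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        fitted=np.asarray(res.fittedvalues),
        adjusted_for=adjusted_for,
    )


def logistic_fit(
    outcome,
    design: pd.DataFrame,
    adjusted_for: tuple[str, ...] = (),
    maxiter: int = 100,
    tol: float = 1e-10,
) -> FitResult:
    """Maximum-likelihood logistic regression on the log-odds scale."""
    y = np.asarray(outcome, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError(f"outcome must be binary 0/1; observed values {classes}")
    if len(classes) < 2:
        raise SeparationError("outcome has a single class; the model is not estimable")
    _check_rank(design)
    model = sm.Logit(y, design)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=0)
        except PerfectSeparationWarning as exc:
            raise SeparationError(f"separation detected: {exc}") from exc
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                f"singular information matrix during Newton scoring "
                f"(likely separation): {exc}"
            ) from exc
    fitted = np.asarray(res.predict())
    if np.any(fitted <= 1e-10) or np.any(fitted >= 1.0 - 1e-10):
        # the MLE is drifting to the boundary: quasi-complete separation
        raise SeparationError(
            "fitted probabilities at the 0/1 boundary indicate quasi-complete "
            "separation; the MLE does not exist"
        )
    if not res.mle_retvals.get("converged", False):
        # Newton can oscillate below the parameter tolerance on a float
        # plateau; accept the iterate only if the first-order conditions hold.
        score = np.asarray(model.score(np.asarray(res.params)))
        if np.max(np.abs(score)) > 1e-6 * len(y):
            raise FitConvergenceError(
                "logistic fit did not converge within the iteration cap "
                f"(max |score| = {np.max(np.abs(score)):.3g})"
            )
    return FitResult(
        params=res.params,
        cov=res.cov_params(),
        n=len(y),
        kind="logistic",
        llf=float(res.llf),
        fitted=np.asarray(res.predict()),
        adjusted_for=adjusted_for,
    )
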