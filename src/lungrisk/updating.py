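"""Model updating on a new cohort: three nested logistic strategies.

When a published logistic risk model is carried to a new population its
calibration usually drifts.  Three standard remedies, in increasing order
of flexibility:

1. **Recalibration in the large** — re-estimate the intercept only, so
   the mean predicted risk matches the observed event rate; covariate
   coefficients are untouched.
2. **Logistic recalibration** — refit intercept and a single slope on the
   old linear predictor; every covariate coefficient is scaled by the
   common slope.
3. **Model revision** — re-estimate all coefficients by maximum
   likelihood on the new cohort.

Methods 1 and 2 are monotone transforms of the old linear predictor, so
they leave the ROC curve (and AUC) exactly unchanged; only method 3 can
alter discrimination.

The estimators follow the scikit-learn protocol (``fit`` /
``predict_proba`` / ``get_params``), so they drop into sklearn pipelines
and model selection; the module-level ``recalibrate_intercept``,
``recalibrate_logistic`` and ``revise_model`` functions are thin wrappers
that additionally package the result as an :class:`UpdatedModel` tied to
a base :class:`~lungrisk.registry.RiskModelSpec`.

Fits are unpenalized Newton/IRLS maximum likelihood (gradient tolerance
1e-8, at most 100 iterations).  A fit is declared separated when any
coefficient magnitude exceeds 15 or the solver fails to converge; with
single-digit event counts per covariate this is a realistic failure mode
and is reported as an error rather than returned silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from scipy.special import expit

from .registry import RiskModelSpec

__all__ = [
    "UpdateMethod",
    "UpdatedModel",
    "SeparationError",
    "InterceptRecalibrator",
    "LogisticRecalibrator",
    "ModelRevision",
    "recalibrate_intercept",
    "recalibrate_logistic",
    "revise_model",
]

_MAX_ABS_COEF = 15.0
_MAXITER = 100
_TOL = 1e-8


class SeparationError(RuntimeError):
    """The logistic fit is degenerate (separation or non-convergence)."""


class UpdateMethod(str, Enum):
    intercept_only = "intercept_only"
    logistic_recalibration = "logistic_recalibration"
    revision = "revision"


def _validate_outcomes(y) -> np.ndarray:
    y = np.asarray(y).ravel().astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcomes must be binary 0/1")
    if y.min() == y.max():
        raise SeparationError("separation/degenerate: outcomes contain a single class")
    return y


def _check_fit(params: np.ndarray, converged: bool, context: str) -> None:
    if not converged or not np.isfinite(params).all() or np.abs(params).max() > _MAX_ABS_COEF:
        raise SeparationError(f"{context}: separation suspected (|coef| > {_MAX_ABS_COEF} or no convergence)")


@dataclass(frozen=True)
class UpdatedModel:
    """A re-estimated coefficient set plus the updating method that produced it.

    ``alpha`` is the *total* new intercept (the value a registry file would
    carry), ``beta_lp`` the slope on the old linear predictor (1 for
    method 1, free for method 2, None for method 3) and ``coefficients``
    the full covariate set of the updated model.
    """

    method: UpdateMethod
    alpha: float
    beta_lp: float | None
    coefficients: dict[str, float]
    base_model: RiskModelSpec | None = None
    standard_errors: dict[str, float] = field(default_factory=dict)

    def to_model_spec(self, name: str | None = None) -> RiskModelSpec:
        """Serialize to a registry spec so the updated model scores directly."""
        if self.base_model is None:
            raise ValueError("cannot build a scoreable spec without a base model")
        name = name or f"{self.base_model.name}_{self.method.value}"
        return RiskModelSpec(
            name=name,
            family="logistic",
            intercept=self.alpha,
            coefficients=dict(self.coefficients),
            coding={c: self.base_model.coding[c] for c in self.coefficients},
            provenance=(
                f"updated from {self.base_model.name!r} by {self.method.value}"
            ),
        )


class InterceptRecalibrator(ClassifierMixin, BaseEstimator):
    """Recalibration in the large: intercept shift on a fixed linear predictor.

    ``fit(X, y)`` takes the old linear predictor as a single column and
    maximizes the Bernoulli likelihood of ``y`` under
    ``expit(shift_ + lp)`` with ``lp`` as a fixed offset.  After fitting,
    the mean predicted probability equals the observed event rate (the
    intercept score equation).

    Attributes
    ----------
    shift_ : float
        Fitted additive shift on the old linear predictor.
    """

    def fit(self, X, y):
        X, y = check_X_y(np.reshape(X, (-1, 1)), y)
        y = _validate_outcomes(y)
        lp = X[:, 0]
        res = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=lp).fit(
            maxiter=_MAXITER, tol=_TOL
        )
        _check_fit(res.params, getattr(res, "converged", True), "intercept recalibration")
        self.shift_ = float(res.params[0])
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "shift_")
        lp = check_array(np.reshape(X, (-1, 1)))[:, 0]
        p = expit(self.shift_ + lp)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class LogisticRecalibrator(ClassifierMixin, BaseEstimator):
    """Logistic recalibration: refit intercept and slope on the old LP.

    Attributes
    ----------
    intercept_ : float
        Fitted intercept of ``y ~ intercept + slope * lp``.
    slope_ : float
        Fitted slope on the old linear predictor (calibration slope).
    """

    def fit(self, X, y):
        X, y = check_X_y(np.reshape(X, (-1, 1)), y)
        y = _validate_outcomes(y)
        lp = X[:, 0]
        if np.ptp(lp) == 0:
            raise ValueError("constant linear predictor: slope not identifiable")
        try:
            res = sm.Logit(y, sm.add_constant(lp)).fit(
                method="newton", maxiter=_MAXITER, tol=_TOL, disp=False
            )
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise SeparationError(f"logistic recalibration: {exc}") from exc
        _check_fit(res.params, res.mle_retvals.get("converged", True), "logistic recalibration")
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 1
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "slope_")
        lp = check_array(np.reshape(X, (-1, 1)))[:, 0]
        p = expit(self.intercept_ + self.slope_ * lp)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class ModelRevision(ClassifierMixin, BaseEstimator):
    """Full model revision: unpenalized ML logistic fit of all coefficients.

    Attributes
    ----------
    intercept_, coef_ : fitted parameters (coef_ has one entry per column).
    se_intercept_, se_coef_ : estimated standard errors.
    feature_names_in_ : column names when fit on a DataFrame.
    """

    def fit(self, X, y):
        names = list(X.columns) if isinstance(X, pd.DataFrame) else None
        if hasattr(X, "shape") and np.ndim(X) == 2 and np.shape(X)[1] == 0:
            X = np.empty((np.shape(X)[0], 0))  # intercept-only design
        else:
            X = check_array(X)
        y = _validate_outcomes(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y length mismatch")
        if names is None:
            names = [f"x{i}" for i in range(X.shape[1])]
        design = np.column_stack([np.ones(X.shape[0]), X])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            culprits = _collinear_columns(X, names)
            raise ValueError(f"design is rank deficient; collinear columns: {culprits}")
        # IRLS degrades gracefully under quasi-separation (coefficients walk
        # off to large magnitudes instead of a singular Newton step), letting
        # the separation guard report the failure as such.
        try:
            with np.errstate(over="ignore"):
                res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                    maxiter=_MAXITER, tol=_TOL
                )
        except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
            raise SeparationError(f"model revision: {exc}") from exc
        _check_fit(res.params, getattr(res, "converged", True), "model revision")
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:], dtype=float)
        self.se_intercept_ = float(res.bse[0])
        self.se_coef_ = np.asarray(res.bse[1:], dtype=float)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns that do not increase the design rank when added."""
    culprits = []
    kept = np.ones((X.shape[0], 1))
    for j, name in enumerate(names):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(kept):
            culprits.append(name)
        else:
            kept = cand
    return culprits


def _base_intercept(base_model: RiskModelSpec | None) -> float:
    if base_model is None:
        return 0.0
    if base_model.family != "logistic":
        raise ValueError("model updating is defined for logistic-family models only")
    return base_model.intercept


def recalibrate_intercept(lp, outcomes, base_model: RiskModelSpec | None = None) -> UpdatedModel:
    """Method 1 — recalibration in the large.

    ``lp`` is the base model's linear predictor on the new cohort.  The
    covariate coefficients are untouched; the returned ``alpha`` is the
    new total intercept (base intercept plus the fitted shift).
    """
    est = InterceptRecalibrator().fit(np.asarray(lp, dtype=float), outcomes)
    coeffs = dict(base_model.coefficients) if base_model is not None else {}
    return UpdatedModel(
        method=UpdateMethod.intercept_only,
        alpha=_base_intercept(base_model) + est.shift_,
        beta_lp=1.0,
        coefficients=coeffs,
        base_model=base_model,
    )


def recalibrate_logistic(lp, outcomes, base_model: RiskModelSpec | None = None) -> UpdatedModel:
    """Method 2 — logistic recalibration.

    Fits ``y ~ a + b * lp``; every covariate coefficient becomes
    ``base * b`` and the new total intercept is ``a + b * old_intercept``,
    so that the updated linear predictor equals ``a + b * LP_old``.
    """
    est = LogisticRecalibrator().fit(np.asarray(lp, dtype=float), outcomes)
    coeffs = (
        {c: b * est.slope_ for c, b in base_model.coefficients.items()}
        if base_model is not None
        else {}
    )
    return UpdatedModel(
        method=UpdateMethod.logistic_recalibration,
        alpha=est.intercept_ + est.slope_ * _base_intercept(base_model),
        beta_lp=est.slope_,
        coefficients=coeffs,
        base_model=base_model,
    )


def revise_model(
    covariates: pd.DataFrame,
    outcomes,
    base_model: RiskModelSpec | None = None,
) -> UpdatedModel:
    """Method 3 — model revision: refit all coefficients by ML."""
    est = ModelRevision().fit(covariates, outcomes)
    names = list(est.feature_names_in_)
    return UpdatedModel(
        method=UpdateMethod.revision,
        alpha=est.intercept_,
        beta_lp=None,
        coefficients=dict(zip(names, est.coef_.tolist())),
        base_model=base_model,
        standard_errors={
            "intercept": est.se_intercept_,
            **dict(zip(names, est.se_coef_.tolist())),
        },
    )
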