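"""Risk-model registry: data-driven scoring engines for clinical risk scores.

Two model families are supported:

* ``logistic`` — a linear predictor ``LP = intercept + sum(beta_i * x_i)``
  mapped to a probability by the inverse logit.  The Eurolung morbidity
  models (2016E1, 2019E1) and the Brunelli model are of this family.
* ``aggregate`` — an integer point total over satisfied items, e.g. the
  aggregate Eurolung1 score (aE1) and the Age-adjusted Charlson
  Comorbidity Index (ACCI).

Models are loaded from JSON registry files so that coefficient corrections
never require a code change.  Each covariate carries a *coding rule* that
states how to derive its numeric value from a patient record (numeric
as-is, indicator against a reference level, threshold or age band), making
the scoring engines fully generic.
"""

from __future__ import annotations

import json
import math
from importlib import resources
from pathlib import Path
from typing import Any, Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator
from scipy.special import expit

__all__ = [
    "CodingRule",
    "RiskModelSpec",
    "RiskPrediction",
    "RegistryParseError",
    "MissingCovariateError",
    "load_model_registry",
    "default_registry",
    "compute_linear_predictor",
    "predict_probability",
    "score_aggregate",
    "score_cohort",
]

#: Fields a patient record (cohort table row) may expose to coding rules.
PATIENT_FIELDS = frozenset(
    {
        "age",
        "sex",
        "bmi",
        "height",
        "fev1_percent",
        "fvc_percent",
        "ppo_fev1_percent",
        "cad",
        "cvd",
        "ckd",
        "arrhythmia",
        "copd",
        "diabetes",
        "hypertension",
        "smoking",
        "alcohol",
        "approach",
        "resection",
        "extended_resection",
    }
)


class RegistryParseError(ValueError):
    """A registry file is malformed; the message names the offending spec."""


class MissingCovariateError(KeyError):
    """A patient record lacks a covariate required by a model (complete-case contract)."""


class CodingRule(BaseModel):
    """How to turn one field of a patient record into a model covariate value.

    kinds:
      numeric   — the field value itself (e.g. age in years)
      flag      — 1 if the boolean field is truthy
      equals    — 1 if the field equals ``value`` (indicator vs. reference level)
      threshold — 1 if ``field <op> value`` (op in gt/ge/lt/le)
      band      — 1 if ``low <= field <= high``
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["numeric", "flag", "equals", "threshold", "band"]
    source: str
    value: Any = None
    op: Literal["gt", "ge", "lt", "le"] | None = None
    low: float | None = None
    high: float | None = None

    @model_validator(mode="after")
    def _check_kind_fields(self) -> "CodingRule":
        if self.source not in PATIENT_FIELDS:
            raise ValueError(f"coding rule references unknown patient field {self.source!r}")
        if self.kind == "equals" and self.value is None:
            raise ValueError("'equals' rule requires a comparison value")
        if self.kind == "threshold" and (self.op is None or self.value is None):
            raise ValueError("'threshold' rule requires op and value")
        if self.kind == "band" and (self.low is None or self.high is None):
            raise ValueError("'band' rule requires low and high")
        return self

    def resolve(self, record: Mapping[str, Any]) -> float:
        """Evaluate the rule on a single record (mapping or pandas Series)."""
        if self.source not in record:
            raise MissingCovariateError(self.source)
        raw = record[self.source]
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            raise MissingCovariateError(self.source)
        if self.kind == "numeric":
            return float(raw)
        if self.kind == "flag":
            return float(bool(raw))
        if self.kind == "equals":
            return float(raw == self.value)
        if self.kind == "threshold":
            x = float(raw)
            ops = {"gt": x > self.value, "ge": x >= self.value, "lt": x < self.value, "le": x <= self.value}
            return float(ops[self.op])
        # band
        return float(self.low <= float(raw) <= self.high)

    def resolve_vector(self, table: pd.DataFrame) -> np.ndarray:
        """Vectorized :meth:`resolve` over a cohort table."""
        if self.source not in table.columns:
            raise MissingCovariateError(self.source)
        col = table[self.source]
        if col.isna().any():
            raise MissingCovariateError(self.source)
        if self.kind == "numeric":
            return col.to_numpy(dtype=float)
        if self.kind == "flag":
            return col.astype(bool).to_numpy(dtype=float)
        if self.kind == "equals":
            return (col == self.value).to_numpy(dtype=float)
        if self.kind == "threshold":
            x = col.to_numpy(dtype=float)
            ops = {"gt": x > self.value, "ge": x >= self.value, "lt": x < self.value, "le": x <= self.value}
            return ops[self.op].astype(float)
        x = col.to_numpy(dtype=float)
        return ((x >= self.low) & (x <= self.high)).astype(float)


class RiskModelSpec(BaseModel):
    """A named scoring function: logistic coefficient set or aggregate point table."""

    model_config = ConfigDict(frozen=True)

    name: str
    family: Literal["logistic", "aggregate"]
    intercept: float | None = None
    coefficients: dict[str, float]
    coding: dict[str, CodingRule]
    provenance: str = ""

    @model_validator(mode="after")
    def _check_family(self) -> "RiskModelSpec":
        if self.family == "logistic":
            if self.intercept is None:
                raise ValueError(f"logistic model {self.name!r} must have exactly one intercept")
        else:
            if self.intercept is not None:
                raise ValueError(f"aggregate model {self.name!r} must not carry an intercept")
            for item, pts in self.coefficients.items():
                if pts < 0 or pts != int(pts):
                    raise ValueError(
                        f"aggregate model {self.name!r}: item {item!r} has non-integer "
                        f"or negative point value {pts}"
                    )
        missing = set(self.coefficients) - set(self.coding)
        if missing:
            raise ValueError(
                f"model {self.name!r}: no coding rule for covariate(s) {sorted(missing)}"
            )
        return self

    @property
    def covariates(self) -> list[str]:
        return list(self.coefficients)


class RiskPrediction(BaseModel):
    """One patient's prediction: LP and probability (logistic) or point total (aggregate)."""

    linear_predictor: float | None = None
    total_points: int | None = None
    probability: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "RiskPrediction":
        if self.total_points is not None and self.total_points < 0:
            raise ValueError("total_points must be >= 0")
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")
        return self


def load_model_registry(path: str | Path) -> list[RiskModelSpec]:
    """Load all model specs from a JSON registry file.

    The file holds a JSON array of model objects
    ``{name, family, intercept?, coefficients, coding, provenance}``.
    An empty array is valid and yields an empty collection.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RegistryParseError(f"registry file {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise RegistryParseError(f"registry file {path} must hold a JSON array of model specs")
    specs: list[RiskModelSpec] = []
    for entry in raw:
        name = entry.get("name", "<unnamed>") if isinstance(entry, dict) else "<unnamed>"
        try:
            specs.append(RiskModelSpec.model_validate(entry))
        except ValidationError as exc:
            raise RegistryParseError(f"invalid model spec {name!r} in {path}: {exc}") from exc
    return specs


def default_registry() -> list[RiskModelSpec]:
    """The five shipped models: 2016E1, 2019E1, Brunelli, aE1, ACCI."""
    with resources.as_file(resources.files("lungrisk.data") / "default_registry.json") as p:
        return load_model_registry(p)


def get_model(registry: Iterable[RiskModelSpec], name: str) -> RiskModelSpec:
    for spec in registry:
        if spec.name == name:
            return spec
    raise KeyError(f"model {name!r} not found in registry")


def compute_linear_predictor(model: RiskModelSpec, patient: Mapping[str, Any]) -> float:
    """``intercept + sum(beta_i * x_i)`` for a logistic-family model.

    Raises :class:`MissingCovariateError` naming the covariate if any
    required field is absent or NaN — no imputation is performed.
    """
    if model.family != "logistic":
        raise ValueError(f"model {model.name!r} is not logistic")
    lp = model.intercept
    for cov, beta in model.coefficients.items():
        lp += beta * model.coding[cov].resolve(patient)
    return lp


def predict_probability(lp: float) -> float:
    """Inverse logit ``1 / (1 + exp(-lp))``; strictly increasing in lp."""
    if not math.isfinite(lp):
        raise ValueError(f"linear predictor must be finite, got {lp}")
    return float(expit(lp))


def score_aggregate(model: RiskModelSpec, patient: Mapping[str, Any]) -> RiskPrediction:
    """Sum the point values of all satisfied items of an aggregate model."""
    if model.family != "aggregate":
        raise ValueError(f"model {model.name!r} is not aggregate")
    total = 0.0
    for item, pts in model.coefficients.items():
        total += pts * model.coding[item].resolve(patient)
    return RiskPrediction(total_points=int(total))


def predict(model: RiskModelSpec, patient: Mapping[str, Any]) -> RiskPrediction:
    """Score one patient with either model family."""
    if model.family == "logistic":
        lp = compute_linear_predictor(model, patient)
        return RiskPrediction(linear_predictor=lp, probability=predict_probability(lp))
    return score_aggregate(model, patient)


def score_cohort(model: RiskModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    """Vectorized risk scores for a cohort table.

    Returns predicted probabilities for logistic models and point totals
    for aggregate models; either way, higher means higher predicted risk.
    """
    if model.family == "logistic":
        lp = np.full(len(cohort), model.intercept, dtype=float)
        for cov, beta in model.coefficients.items():
            lp += beta * model.coding[cov].resolve_vector(cohort)
        return expit(lp)
    total = np.zeros(len(cohort))
    for item, pts in model.coefficients.items():
        total += pts * model.coding[item].resolve_vector(cohort)
    return total


def linear_predictor_cohort(model: RiskModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    """Vectorized linear predictor for a logistic model over a cohort table."""
    if model.family != "logistic":
        raise ValueError(f"model {model.name!r} is not logistic")
    lp = np.full(len(cohort), model.intercept, dtype=float)
    for cov, beta in model.coefficients.items():
        lp += beta * model.coding[cov].resolve_vector(cohort)
    return lp
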