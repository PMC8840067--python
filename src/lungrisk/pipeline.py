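"""Orchestration: score a cohort, validate each model, update, and report.

Reports follow the layout of an external-validation study: one column per
model with rows AUC, 95% CI, goodness-of-fit p, sensitivity, specificity,
PPV, NPV, accuracy; an updating table with columns Original / Method 1 /
Method 2 / Method 3; and plot data (ROC and calibration curves) as TSV.
Aggregate-family models report discrimination and threshold metrics only —
the Hosmer–Lemeshow test and logit-scale calibration are defined for
probability outputs, so those cells are marked not tested.

Internal computation keeps full precision; rendered tables round to three
decimals.  Given (cohort, registry, config, seed) every emitted byte is
deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from . import metrics as _metrics
from . import registry as _registry
from . import updating as _updating
from .metrics import CalibrationResult, DiscriminationResult, HLResult, ThresholdReport
from .registry import RiskModelSpec

__all__ = [
    "OutcomeDefinition",
    "ValidationReport",
    "build_outcome_vector",
    "run_validation_suite",
    "run_updating_suite",
    "emit_report",
    "count_percent",
    "summarize_complications",
]

log = logging.getLogger("lungrisk")

OutcomeDefinition = Literal["ESTS_only", "ESTS_plus_effusion"]

_TABLE_ROWS = ["AUC", "95% CI", "Goodness-of-fit test (P value)", "Sensitivity", "Specificity", "PPV", "NPV", "Accuracy"]


@dataclass
class ValidationReport:
    """One model's performance on one cohort under one outcome definition."""

    model: str
    family: str
    outcome_definition: OutcomeDefinition
    discrimination: DiscriminationResult | None = None
    hl: HLResult | None = None
    calibration: CalibrationResult | None = None
    threshold: ThresholdReport | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        def conv(x):
            if dataclasses.is_dataclass(x):
                return {k: conv(v) for k, v in dataclasses.asdict(x).items()}
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        return {
            "model": self.model,
            "family": self.family,
            "outcome_definition": self.outcome_definition,
            "discrimination": conv(self.discrimination),
            "hosmer_lemeshow": conv(self.hl),
            "calibration": conv(self.calibration),
            "threshold": conv(self.threshold),
            "error": self.error,
        }


def count_percent(count: int, denominator: int, decimals: int = 2) -> float:
    """Percentage as rendered in cohort tables: ``round(100*count/denom, 2)``."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / denominator, decimals)


def summarize_complications(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-category complication counts and rendered percentages."""
    rows = []
    n = len(cohort)
    for col in cohort.columns:
        if col.startswith("comp_") or col == "increased_pleural_effusion":
            cnt = int(cohort[col].sum())
            rows.append((col.removeprefix("comp_"), cnt, count_percent(cnt, n)))
    return pd.DataFrame(rows, columns=["category", "count", "percent"])


def build_outcome_vector(cohort: pd.DataFrame, outcome_definition: OutcomeDefinition) -> np.ndarray:
    """Binary outcome per the chosen definition.

    ``ESTS_only`` — any ESTS-defined cardiopulmonary complication;
    ``ESTS_plus_effusion`` — additionally counts increased (nonchylous,
    nonpurulent) pleural effusion as an event.
    """
    y = cohort["complication_ests"].astype(bool).to_numpy()
    if outcome_definition == "ESTS_plus_effusion":
        y = y | cohort["increased_pleural_effusion"].astype(bool).to_numpy()
    elif outcome_definition != "ESTS_only":
        raise ValueError(f"unknown outcome definition {outcome_definition!r}")
    return y.astype(int)


def _validate_one(
    model: RiskModelSpec,
    cohort: pd.DataFrame,
    y: np.ndarray,
    g: int,
    outcome_definition: OutcomeDefinition,
    calibration_bins: int = 10,
) -> ValidationReport:
    rep = ValidationReport(model=model.name, family=model.family, outcome_definition=outcome_definition)
    try:
        scores = _registry.score_cohort(model, cohort)
        rep.discrimination = _metrics.auc_with_ci(scores, y)
        rep.threshold = _metrics.youden_threshold(scores, y)
        if model.family == "logistic":
            rep.hl = _metrics.hosmer_lemeshow(scores, y, g)
            rep.calibration = _metrics.calibration_assess(scores, y, bins=calibration_bins)
    except Exception as exc:
        rep.error = f"{type(exc).__name__}: {exc}"
        log.warning("model %s failed validation: %s", model.name, rep.error)
    return rep


def run_validation_suite(
    cohort: pd.DataFrame,
    registry: Iterable[RiskModelSpec],
    outcome_definition: OutcomeDefinition = "ESTS_only",
    calibration_bins: int = 10,
) -> list[ValidationReport]:
    """Validate every registry model on the cohort; failures are per-model."""
    registry = list(registry)
    if len(cohort) == 0 or not registry:
        raise ValueError("cohort and registry must be nonempty")
    y = build_outcome_vector(cohort, outcome_definition)
    n, m = len(y), int(y.sum())
    g = _metrics.choose_hl_groups(n, m) if 0 < m < n else 10
    log.info("validation: n=%d events=%d (%s) g=%d", n, m, outcome_definition, g)
    return [_validate_one(mod, cohort, y, g, outcome_definition, calibration_bins) for mod in registry]


def run_updating_suite(
    cohort: pd.DataFrame,
    base_model: RiskModelSpec,
    outcome_definition: OutcomeDefinition = "ESTS_only",
) -> dict:
    """Apply all three updating methods to a logistic model and re-validate.

    Returns ``{"updated": {method: UpdatedModel}, "reports": {column:
    ValidationReport}, "coefficient_table": DataFrame}`` where the
    coefficient table has columns Original / Method 1 / Method 2 /
    Method 3 over the covariate rows plus the intercept.
    """
    if base_model.family != "logistic":
        raise ValueError("model updating is defined for logistic-family models only")
    y = build_outcome_vector(cohort, outcome_definition)
    lp = _registry.linear_predictor_cohort(base_model, cohort)

    design = pd.DataFrame(
        {c: base_model.coding[c].resolve_vector(cohort) for c in base_model.coefficients}
    )
    updated = {
        "Method 1": _updating.recalibrate_intercept(lp, y, base_model),
        "Method 2": _updating.recalibrate_logistic(lp, y, base_model),
        "Method 3": _updating.revise_model(design, y, base_model),
    }
    specs = {"Original": base_model}
    specs.update({k: u.to_model_spec(f"{base_model.name}_{k}") for k, u in updated.items()})

    n, m = len(y), int(y.sum())
    g = _metrics.choose_hl_groups(n, m) if 0 < m < n else 10
    reports = {
        col: _validate_one(spec, cohort, y, g, outcome_definition) for col, spec in specs.items()
    }

    rows = list(base_model.coefficients) + ["Intercept"]
    table = pd.DataFrame(index=rows, columns=list(specs), dtype=float)
    for col, spec in specs.items():
        for cov in base_model.coefficients:
            table.loc[cov, col] = spec.coefficients[cov]
        table.loc["Intercept", col] = spec.intercept
    return {"updated": updated, "reports": reports, "coefficient_table": table}


def _fmt(x: float | None, nd: int = 3) -> str:
    return "-" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}f}"


def render_performance_table(reports: list[ValidationReport]) -> pd.DataFrame:
    """Rendered performance table: fixed row order, 3-decimal strings."""
    out = {}
    for rep in reports:
        if rep.error is not None:
            out[rep.model] = ["error"] * len(_TABLE_ROWS)
            continue
        d, t = rep.discrimination, rep.threshold
        hl_p = _fmt(rep.hl.p_value) if rep.hl is not None else "-"
        out[rep.model] = [
            _fmt(d.auc),
            f"{d.ci_low:.3f}-{d.ci_high:.3f}",
            hl_p,
            _fmt(t.sensitivity),
            _fmt(t.specificity),
            _fmt(t.ppv),
            _fmt(t.npv),
            _fmt(t.accuracy),
        ]
    return pd.DataFrame(out, index=_TABLE_ROWS)


def emit_report(
    reports: list[ValidationReport],
    out_dir: str | Path,
    cohort: pd.DataFrame | None = None,
    fmt: str = "json",
) -> list[Path]:
    """Write machine (JSON) and human (TSV/markdown) reports plus plot data.

    Idempotent and deterministic: identical inputs produce byte-identical
    files.  Returns the written paths.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to emit")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    payload = {rep.model: rep.to_dict() for rep in reports}
    p = out_dir / "validation_reports.json"
    p.write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True) + "\n")
    written.append(p)

    table = render_performance_table(reports)
    if fmt in ("tsv", "json"):
        p = out_dir / "performance_table.tsv"
        p.write_text(table.to_csv(sep="\t"))
        written.append(p)
    if fmt == "md":
        p = out_dir / "performance_table.md"
        p.write_text(table.to_markdown() + "\n")
        written.append(p)

    for rep in reports:
        if rep.calibration is not None:
            p = out_dir / f"calibration_{rep.model}.tsv"
            df = pd.DataFrame(rep.calibration.curve_points, columns=["mean_predicted", "observed_proportion"])
            p.write_text(df.to_csv(sep="\t", index=False, float_format="%.6f"))
            written.append(p)

    if cohort is not None:
        from .registry import get_model  # local import to avoid cycle confusion

        for rep in reports:
            if rep.error is not None or rep.discrimination is None:
                continue
            y = build_outcome_vector(cohort, rep.outcome_definition)
            # re-derive scores for plot data; deterministic, so cheap and safe
            model = None
            try:
                model = get_model(_registry.default_registry(), rep.model)
            except KeyError:
                continue
            scores = _registry.score_cohort(model, cohort)
            fpr, tpr, thr = roc_curve(y, scores)
            df = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
            p = out_dir / f"roc_{rep.model}.tsv"
            p.write_text(df.to_csv(sep="\t", index=False, float_format="%.6f"))
            written.append(p)
    return written
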