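"""Percent-of-predicted spirometry and predicted postoperative FEV1 (ppoFEV1%).

Reference equations are sex- and age-band-stratified linear models
``predicted litres = const + height_coef * height_cm + age_coef * age``.
Published tables of this kind typically stop at age 81; parameters for
older patients are extrapolated by fitting a linear trend of each
parameter against age-band midpoint over the oldest bands.

ppoFEV1% uses the conventional segment-counting formula

    ppoFEV1% = FEV1% * (total_segments - segments_resected) / total_segments

with 19 functional segments by default.  The segment counts removed by
each resection type come from a shipped anatomy table and are
configurable, since conventions (segment vs. subsegment counting) differ
between centres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "ReferenceBand",
    "ReferenceEquationTable",
    "load_reference_table",
    "load_segment_anatomy",
    "percent_of_predicted",
    "predicted_normal",
    "extrapolate_over81",
    "ppo_fev1_percent",
]


@dataclass(frozen=True)
class ReferenceBand:
    """Parameters of one (sex, age-band) reference-equation cell."""

    age_lo: float
    age_hi: float
    const: float
    height: float
    age: float
    extrapolated: bool = False

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_lo + self.age_hi)

    def evaluate(self, age: float, height_cm: float) -> float:
        return self.const + self.height * height_cm + self.age * age


@dataclass
class ReferenceEquationTable:
    """Banded reference equations for one measure (FEV1 or FVC) and one sex."""

    bands: list[ReferenceBand]

    def band_for(self, age: float) -> ReferenceBand:
        for band in self.bands:
            if band.age_lo <= age <= band.age_hi:
                return band
        raise ValueError(f"no reference-equation band covers age {age}")


def load_reference_table(path: str | Path | None = None) -> dict:
    """Load a reference-equation JSON table.

    Without a path, loads the shipped *synthetic* table — a structural
    stand-in with plausible magnitudes, not published reference values.
    Returns ``{measure: {sex: ReferenceEquationTable}}``.
    """
    if path is None:
        src = resources.files("lungrisk.data") / "synthetic_reference_equations.json"
        raw = json.loads(src.read_text())
    else:
        raw = json.loads(Path(path).read_text())
    out: dict[str, dict[str, ReferenceEquationTable]] = {}
    for measure, by_sex in raw["measures"].items():
        out[measure] = {
            sex: ReferenceEquationTable(
                bands=[ReferenceBand(r["age_lo"], r["age_hi"], r["const"], r["height"], r["age"]) for r in rows]
            )
            for sex, rows in by_sex.items()
        }
    return out


def load_segment_anatomy(path: str | Path | None = None) -> dict:
    """Shipped lung-segment anatomy: 19 functional segments, per-lobe counts."""
    if path is None:
        src = resources.files("lungrisk.data") / "segment_anatomy.json"
        return json.loads(src.read_text())
    return json.loads(Path(path).read_text())


def percent_of_predicted(measured: float, predicted_normal: float) -> float:
    """``100 * measured / predicted_normal`` (e.g. FEV1% or FVC%)."""
    if predicted_normal <= 0:
        raise ValueError(f"predicted normal value must be positive, got {predicted_normal}")
    return 100.0 * measured / predicted_normal


def extrapolate_over81(
    table: ReferenceEquationTable,
    window: int = 3,
    age_hi: float = 120.0,
) -> ReferenceEquationTable:
    """Extend a banded table past its oldest band by linear extrapolation.

    Each parameter (const, height, age coefficients) is regressed on the
    age-band midpoint over the ``window`` oldest bands; the fitted line is
    evaluated at the midpoint of the appended band, which spans from just
    above the previous maximum age to ``age_hi`` and is flagged
    ``extrapolated``.  Deterministic least squares; requires >= 3 bands.
    """
    if len(table.bands) < 3:
        raise ValueError("need at least 3 age bands to extrapolate a parameter trend")
    if window < 2:
        raise ValueError("extrapolation window must cover at least 2 bands")
    tail = sorted(table.bands, key=lambda b: b.midpoint)[-window:]
    x = np.array([b.midpoint for b in tail])
    new_lo = max(b.age_hi for b in table.bands) + 1.0
    new_mid = 0.5 * (new_lo + age_hi)

    def fit_at(values: np.ndarray) -> float:
        slope, intercept = np.polyfit(x, values, 1)
        return float(slope * new_mid + intercept)

    new_band = ReferenceBand(
        age_lo=new_lo,
        age_hi=age_hi,
        const=fit_at(np.array([b.const for b in tail])),
        height=fit_at(np.array([b.height for b in tail])),
        age=fit_at(np.array([b.age for b in tail])),
        extrapolated=True,
    )
    return ReferenceEquationTable(bands=list(table.bands) + [new_band])


def predicted_normal(
    age: float,
    sex: str,
    height_cm: float,
    table: ReferenceEquationTable,
    extrapolation_window: int = 3,
) -> tuple[float, bool]:
    """Predicted normal litres for (age, sex, height) from a banded table.

    Ages above the oldest tabulated band use :func:`extrapolate_over81`;
    the second return value flags that the value is extrapolated.  Ages
    below the youngest band raise, since extrapolating toward childhood
    would cross a growth phase the adult equations do not model.
    """
    del sex  # the caller selects the sex-specific table; kept for signature clarity
    lo = min(b.age_lo for b in table.bands)
    hi = max(b.age_hi for b in table.bands)
    if age < lo:
        raise ValueError(f"age {age} is below the reference table minimum {lo}")
    if age > hi:
        extended = extrapolate_over81(table, window=extrapolation_window, age_hi=max(age, 120.0))
        band = extended.band_for(age)
        return band.evaluate(age, height_cm), True
    band = table.band_for(age)
    return band.evaluate(age, height_cm), band.extrapolated


def ppo_fev1_percent(fev1_percent: float, segments_resected: int, total: int = 19) -> float:
    """Predicted postoperative FEV1% by segment counting."""
    if total <= 0:
        raise ValueError("total segment count must be positive")
    if segments_resected < 0 or segments_resected > total:
        raise ValueError(
            f"segments_resected must lie in [0, {total}], got {segments_resected}"
        )
    if fev1_percent < 0:
        raise ValueError("FEV1% must be non-negative")
    return fev1_percent * (total - segments_resected) / total
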