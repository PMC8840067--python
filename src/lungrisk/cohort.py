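"""Seeded synthetic cohorts emulating an anatomic lung-resection population.

The generator reproduces the *marginal* structure of a single-centre
Chinese surgical cohort (n = 1085): median age 60 (IQR 52–65), 38.99%
male, ppoFEV1% median 76 (IQR 68–86), low comorbidity prevalences
(CAD 5.44%, CVD 2.12%, CKD 0.46%), near-universal VATS (97.70%) and rare
extended resection (1.11%), with a cardiopulmonary complication rate of
91/1085 ≈ 8.39% under the ESTS definition and an independent increased
pleural-effusion rate of 94/1085 ≈ 8.66%.

Outcomes follow a configurable true logistic risk model: the generator
calibrates an intercept shift so the cohort mean predicted risk equals
the target event rate, then draws Bernoulli outcomes.  Covariates are
sampled independently by default (only marginals are published); a
Gaussian-copula correlation hook exists but defaults off, so the joint
structure of a real cohort is deliberately not emulated.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats
from scipy.special import expit

from . import registry as _registry
from .registry import RiskModelSpec
from .spirometry import load_segment_anatomy

__all__ = [
    "NumericMarginal",
    "CohortSimulationConfig",
    "ests_complication_counts",
    "sample_cohort",
    "assign_outcomes",
    "apply_inclusion_exclusion",
    "sample_prescreen_cohort",
    "generate_study_cohort",
    "ESSENTIAL_COLUMNS",
]

#: Columns whose absence makes a record incomplete (complete-case contract).
ESSENTIAL_COLUMNS = ("age", "sex", "fev1_percent", "fvc_percent", "ppo_fev1_percent")

#: Default seed, surfaced in the config (the cohort's publication date).
DEFAULT_SEED = 20220209

_NORMAL_IQR = 2 * 0.6744897501960817  # IQR of a standard normal


def ests_complication_counts() -> dict:
    """Published per-category complication counts used as generator defaults."""
    src = resources.files("lungrisk.data") / "complication_counts.json"
    return json.loads(src.read_text())


class NumericMarginal(BaseModel):
    """Truncated-normal marginal matched to a published median and IQR."""

    model_config = ConfigDict(frozen=True)

    median: float
    iqr_lo: float
    iqr_hi: float
    lo: float
    hi: float
    integer: bool = False

    @property
    def sigma(self) -> float:
        return (self.iqr_hi - self.iqr_lo) / _NORMAL_IQR

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a = (self.lo - self.median) / self.sigma
        b = (self.hi - self.median) / self.sigma
        x = stats.truncnorm.ppf(u, a, b, loc=self.median, scale=self.sigma)
        return np.round(x) if self.integer else x


class CohortSimulationConfig(BaseModel):
    """Marginal distributions, true outcome model and rates for one simulation."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    n: int = Field(default=1085, ge=1)
    seed: int = DEFAULT_SEED

    age: NumericMarginal = NumericMarginal(median=60.0, iqr_lo=52.0, iqr_hi=65.0, lo=18, hi=90, integer=True)
    bmi: NumericMarginal = NumericMarginal(median=23.9, iqr_lo=22.0, iqr_hi=26.1, lo=14, hi=45)
    ppo_fev1_percent: NumericMarginal = NumericMarginal(median=76.0, iqr_lo=68.0, iqr_hi=86.0, lo=30, hi=130)
    fvc_percent: NumericMarginal = NumericMarginal(median=88.91, iqr_lo=79.87, iqr_hi=98.52, lo=40, hi=140)
    height_male: NumericMarginal = NumericMarginal(median=170.0, iqr_lo=166.0, iqr_hi=174.0, lo=150, hi=195)
    height_female: NumericMarginal = NumericMarginal(median=158.0, iqr_lo=154.0, iqr_hi=162.0, lo=140, hi=185)

    male_fraction: float = 0.3899
    prevalences: dict[str, float] = Field(
        default={
            "cad": 0.0544,
            "cvd": 0.0212,
            "ckd": 0.0046,
            "arrhythmia": 0.0212,
            "copd": 0.0378,
            "diabetes": 0.1198,
            "hypertension": 0.2876,
            "smoking": 0.2166,
            "alcohol": 0.1281,
        }
    )
    vats_fraction: float = 0.9770
    # published labels for extended resection read swapped (98.89% "Yes" in a
    # 97.7% VATS cohort); the narrative comparison (1.11% vs 5.73%) fixes it.
    extended_resection_rate: float = 0.0111
    resection_probs: dict[str, float] = Field(
        default={
            "segmentectomy": 210 / 1085,
            "lobectomy": 863 / 1085,
            "bilobectomy": 11 / 1085,
            "pneumonectomy": 1 / 1085,
        }
    )

    target_event_rate: float = 91 / 1085
    pleural_effusion_rate: float = 94 / 1085
    #: sequential exclusion fractions: inclusion criteria, non-lung-cancer
    #: pathology, missing essential data (screened stream of 1924 -> 1085).
    attrition_rates: tuple[float, float, float] = (484 / 1924, 128 / 1440, 227 / 1312)

    #: optional Gaussian-copula correlation over the continuous marginals
    #: (age, bmi, ppo_fev1_percent, fvc_percent); identity when None.
    copula_correlation: list[list[float]] | None = None

    @model_validator(mode="after")
    def _check_rates(self) -> "CohortSimulationConfig":
        for name, r in [
            ("target_event_rate", self.target_event_rate),
            ("pleural_effusion_rate", self.pleural_effusion_rate),
            ("male_fraction", self.male_fraction),
            ("vats_fraction", self.vats_fraction),
            ("extended_resection_rate", self.extended_resection_rate),
            *self.prevalences.items(),
        ]:
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {name} = {r} outside [0, 1]")
        if abs(sum(self.resection_probs.values()) - 1.0) > 1e-9:
            raise ValueError("resection type probabilities must sum to 1")
        return self


_CONTINUOUS = ("age", "bmi", "ppo_fev1_percent", "fvc_percent")


def _continuous_uniforms(config: CohortSimulationConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-covariate U(0,1) draws, copula-correlated when configured."""
    if config.copula_correlation is None:
        return {name: rng.uniform(size=config.n) for name in _CONTINUOUS}
    corr = np.asarray(config.copula_correlation, dtype=float)
    if corr.shape != (len(_CONTINUOUS), len(_CONTINUOUS)):
        raise ValueError(f"copula correlation must be {len(_CONTINUOUS)}x{len(_CONTINUOUS)}")
    z = rng.multivariate_normal(np.zeros(len(_CONTINUOUS)), corr, size=config.n)
    u = stats.norm.cdf(z)
    return {name: u[:, j] for j, name in enumerate(_CONTINUOUS)}


def sample_cohort(config: CohortSimulationConfig) -> pd.DataFrame:
    """Draw an analysis-ready cohort table with the configured marginals.

    FEV1% is back-computed from the sampled ppoFEV1% and the resection
    type's segment count (19 functional segments), so the spirometry
    triplet is internally consistent.  Eligibility flags are all True:
    this is the post-selection analysis cohort.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    u = _continuous_uniforms(config, rng)

    sex = np.where(rng.uniform(size=n) < config.male_fraction, "male", "female")
    height = np.where(
        sex == "male",
        config.height_male.ppf(rng.uniform(size=n)),
        config.height_female.ppf(rng.uniform(size=n)),
    )
    resection_levels = list(config.resection_probs)
    resection = rng.choice(resection_levels, size=n, p=list(config.resection_probs.values()))

    anatomy = load_segment_anatomy()
    total_seg = anatomy["total_functional_segments"]
    seg_removed = np.array([anatomy["resection_segments"][r] for r in resection], dtype=float)
    ppo = config.ppo_fev1_percent.ppf(u["ppo_fev1_percent"])
    fev1 = ppo / (1.0 - seg_removed / total_seg)

    cohort = pd.DataFrame(
        {
            "age": config.age.ppf(u["age"]),
            "sex": sex,
            "bmi": config.bmi.ppf(u["bmi"]),
            "height": height,
            "fev1_percent": fev1,
            "fvc_percent": config.fvc_percent.ppf(u["fvc_percent"]),
            "ppo_fev1_percent": ppo,
            "approach": np.where(rng.uniform(size=n) < config.vats_fraction, "VATS", "thoracotomy"),
            "resection": resection,
            "extended_resection": rng.uniform(size=n) < config.extended_resection_rate,
        }
    )
    for name, prev in config.prevalences.items():
        cohort[name] = rng.uniform(size=n) < prev
    # eligibility flags: this is the analysis cohort, all criteria satisfied
    cohort["eligible_age"] = cohort["age"] >= 18
    cohort["anatomic_resection"] = True
    cohort["neoadjuvant"] = False
    cohort["pathology_lung_cancer"] = True
    cohort["complete_data"] = True
    return cohort


def _calibrate_shift(lp: np.ndarray, target_rate: float) -> float:
    """Intercept shift making mean expit(lp + shift) equal the target rate."""

    def gap(delta: float) -> float:
        return float(expit(lp + delta).mean() - target_rate)

    return float(optimize.brentq(gap, -40.0, 40.0, xtol=1e-12))


def assign_outcomes(
    cohort: pd.DataFrame,
    true_model: RiskModelSpec,
    target_event_rate: float,
    seed: int,
    pleural_effusion_rate: float = 94 / 1085,
) -> pd.DataFrame:
    """Draw complication outcomes from a true logistic risk model.

    The model's linear predictor is shifted by a constant so that the
    cohort mean probability equals ``target_event_rate``; ESTS-defined
    events are then Bernoulli(p_i).  Each event patient is assigned one
    complication category at the published relative frequencies.
    Increased pleural effusion is drawn independently at its own rate,
    mirroring its treatment as a separate outcome category.
    """
    if not 0.0 < target_event_rate < 1.0:
        raise ValueError(f"target event rate must lie strictly in (0, 1), got {target_event_rate}")
    if not 0.0 <= pleural_effusion_rate < 1.0:
        raise ValueError("pleural effusion rate must lie in [0, 1)")
    if true_model.family != "logistic":
        raise ValueError("outcome assignment requires a logistic true model")
    rng = np.random.default_rng(seed)
    lp = _registry.linear_predictor_cohort(true_model, cohort)
    shift = _calibrate_shift(lp, target_event_rate)
    p = expit(lp + shift)
    out = cohort.copy()
    out["true_event_probability"] = p
    events = rng.uniform(size=len(out)) < p
    out["complication_ests"] = events

    counts = ests_complication_counts()["ests_defined"]
    categories = list(counts)
    weights = np.array(list(counts.values()), dtype=float)
    weights /= weights.sum()
    for cat in categories:
        out[f"comp_{cat}"] = False
    if events.any():
        drawn = rng.choice(categories, size=int(events.sum()), p=weights)
        ev_idx = np.flatnonzero(events)
        for cat in categories:
            col = out.columns.get_loc(f"comp_{cat}")
            out.iloc[ev_idx[drawn == cat], col] = True
    out["increased_pleural_effusion"] = rng.uniform(size=len(out)) < pleural_effusion_rate
    return out


def apply_inclusion_exclusion(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequential patient-selection filter with an attrition table.

    Order matches the study flow: (1) inclusion criteria — adult age,
    anatomic resection, no neoadjuvant therapy; (2) postoperative
    pathology other than lung cancer; (3) missing essential data
    (complete-case contract: an explicit ``complete_data`` flag of False
    or a NaN in any essential column excludes the record).
    """
    df = records
    steps = []
    n0 = len(df)

    ok_incl = (
        (df["age"] >= 18)
        & df.get("eligible_age", df["age"] >= 18).astype(bool)
        & df["anatomic_resection"].astype(bool)
        & ~df["neoadjuvant"].astype(bool)
    )
    steps.append(("inclusion_criteria_not_met", int((~ok_incl).sum())))
    df = df[ok_incl]

    ok_path = df["pathology_lung_cancer"].astype(bool)
    steps.append(("non_lung_cancer_pathology", int((~ok_path).sum())))
    df = df[ok_path]

    present = [c for c in ESSENTIAL_COLUMNS if c in df.columns]
    ok_data = df.get("complete_data", pd.Series(True, index=df.index)).astype(bool) & df[
        present
    ].notna().all(axis=1)
    steps.append(("missing_essential_data", int((~ok_data).sum())))
    df = df[ok_data]

    attrition = pd.DataFrame(steps, columns=["step", "n_excluded"])
    attrition["n_remaining"] = n0 - attrition["n_excluded"].cumsum()
    assert len(df) + attrition["n_excluded"].sum() == n0
    return df.reset_index(drop=True), attrition


def sample_prescreen_cohort(
    config: CohortSimulationConfig,
    n_raw: int,
    exact_counts: tuple[int, int, int] | None = None,
) -> pd.DataFrame:
    """A pre-selection stream of records carrying realistic exclusion flags.

    Flags are drawn sequentially at ``config.attrition_rates``; with
    ``exact_counts`` the three exclusion groups get exactly those sizes
    (deterministically, by position after a seeded shuffle), which is
    useful for reproducing published attrition arithmetic.
    """
    cfg = config.model_copy(update={"n": n_raw})
    df = sample_cohort(cfg)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(n_raw)
    if exact_counts is not None:
        k1, k2, k3 = exact_counts
        if k1 + k2 + k3 > n_raw:
            raise ValueError("exclusion counts exceed stream size")
        g1, g2, g3 = order[:k1], order[k1 : k1 + k2], order[k1 + k2 : k1 + k2 + k3]
    else:
        r1, r2, r3 = config.attrition_rates
        k1 = int(round(n_raw * r1))
        k2 = int(round((n_raw - k1) * r2))
        k3 = int(round((n_raw - k1 - k2) * r3))
        g1, g2, g3 = order[:k1], order[k1 : k1 + k2], order[k1 + k2 : k1 + k2 + k3]
    df.loc[df.index[g1], "neoadjuvant"] = True
    df.loc[df.index[g2], "pathology_lung_cancer"] = False
    df.loc[df.index[g3], "complete_data"] = False
    df.loc[df.index[g3], "ppo_fev1_percent"] = np.nan
    return df


def generate_study_cohort(
    config: CohortSimulationConfig | None = None,
    true_model: RiskModelSpec | None = None,
) -> pd.DataFrame:
    """Convenience: sample covariates and outcomes in one call."""
    config = config or CohortSimulationConfig()
    if true_model is None:
        true_model = _registry.get_model(_registry.default_registry(), "2016E1")
    cohort = sample_cohort(config)
    return assign_outcomes(
        cohort,
        true_model,
        config.target_event_rate,
        seed=config.seed + 2,
        pleural_effusion_rate=config.pleural_effusion_rate,
    )
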