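"""Discrimination, calibration and threshold performance for risk predictions.

The module assesses a vector of predicted risks against observed binary
outcomes with the standard external-validation toolkit:

* AUC with a 95% CI by the DeLong structural-components method (a seeded
  bootstrap alternative is available behind a flag);
* the Hosmer–Lemeshow goodness-of-fit test with an adaptive number of
  groups g = max[10, min(m/2, (n−m)/2, 2 + 8·n²/10⁶)] for cohorts of
  1000 < n ≤ 25000 (g = 10 otherwise), floored to an integer;
* weak calibration (slope/intercept of a logistic fit of outcomes on the
  logit of the predictions) plus a decile-based calibration curve;
* threshold metrics (sensitivity, specificity, PPV, NPV, accuracy) at the
  Youden-index operating point.

Orientation is always "higher score = higher predicted risk"; a case is
called positive when its score is >= the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit, logit

__all__ = [
    "DiscriminationResult",
    "HLResult",
    "CalibrationResult",
    "ThresholdReport",
    "auc_with_ci",
    "choose_hl_groups",
    "hosmer_lemeshow",
    "calibration_assess",
    "youden_threshold",
]

_PROB_EPS = 1e-15


def _validate_pair(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("degenerate outcome: both classes must be present")
    return scores, labels


@dataclass(frozen=True)
class DiscriminationResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class HLResult:
    statistic: float
    g: int
    df: int
    p_value: float | None
    groups: list[tuple[int, float, float, float]]  # (n_g, observed, expected, mean_prob)


@dataclass(frozen=True)
class CalibrationResult:
    slope: float
    intercept: float
    curve_points: list[tuple[float, float]]  # (mean predicted, observed proportion)


@dataclass(frozen=True)
class ThresholdReport:
    threshold: float
    youden_j: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    confusion: tuple[int, int, int, int]  # (TP, FP, FN, TN)


def _delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mann–Whitney AUC (ties count 1/2) and its DeLong variance."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    # structural components
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s01 / m + s10 / n)


def auc_with_ci(
    scores,
    labels,
    ci_method: str = "delong",
    n_boot: int = 2000,
    seed: int = 0,
) -> DiscriminationResult:
    """AUC with a 95% confidence interval.

    ``ci_method="delong"`` (default, deterministic) uses the DeLong
    variance with a normal interval clipped to [0, 1];
    ``ci_method="bootstrap"`` uses a seeded stratified percentile
    bootstrap over cases.
    """
    scores, labels = _validate_pair(scores, labels)
    auc, var = _delong_auc_variance(scores, labels)
    m = int(labels.sum())
    n = int(len(labels) - m)
    if ci_method == "delong":
        se = math.sqrt(max(var, 0.0))
        lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            pi = rng.choice(pos_idx, size=m, replace=True)
            ni = rng.choice(neg_idx, size=n, replace=True)
            s = np.concatenate([scores[pi], scores[ni]])
            y = np.concatenate([np.ones(m, int), np.zeros(n, int)])
            reps[b], _ = _delong_auc_variance(s, y)
        lo, hi = np.percentile(reps, [2.5, 97.5])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = min(max(lo, 0.0), auc)
    hi = max(min(hi, 1.0), auc)
    return DiscriminationResult(auc=auc, ci_low=float(lo), ci_high=float(hi), n_pos=m, n_neg=n)


def choose_hl_groups(n: int, m: int) -> int:
    """Adaptive Hosmer–Lemeshow group count.

    For 1000 < n <= 25000 cases with m events, evaluates
    ``max[10, min(m/2, (n-m)/2, 2 + 8 n^2 / 10^6)]`` and floors the
    result; outside that range the conventional g = 10 applies.
    """
    if m < 0:
        raise ValueError("event count must be non-negative")
    if m >= n:
        raise ValueError(f"event count m={m} must be smaller than case count n={n}")
    if not 1000 < n <= 25000:
        return 10
    g = max(10.0, min(m / 2.0, (n - m) / 2.0, 2.0 + 8.0 * n**2 / 1e6))
    return int(math.floor(g))


def _hl_group_index(probs: np.ndarray, g: int) -> np.ndarray:
    """Quantile group labels, near-equal sizes, tied probabilities kept together."""
    n = len(probs)
    order = np.argsort(probs, kind="stable")
    pos_group = (np.arange(n) * g) // n  # intended group by rank
    sorted_p = probs[order]
    # first occurrence of each distinct value decides the group of the whole tie block
    uniq, first_idx, inverse = np.unique(sorted_p, return_index=True, return_inverse=True)
    block_group = pos_group[first_idx][inverse]
    groups = np.empty(n, dtype=int)
    groups[order] = block_group
    return groups


def hosmer_lemeshow(probs, outcomes, g: int) -> HLResult:
    """Hosmer–Lemeshow test with g quantile groups.

    Cases are sorted by predicted probability and cut into g near-equal
    groups (tied probabilities stay in one group).  The statistic is
    ``sum((O - E)^2 / (n_g * pbar * (1 - pbar)))`` over groups whose mean
    probability lies strictly inside (0, 1); p comes from chi-square with
    ``df = g_formed - 2`` when df >= 1, otherwise ``p_value`` is None.
    """
    probs, outcomes = _validate_pair(probs, outcomes)
    if not ((probs >= 0) & (probs <= 1)).all():
        raise ValueError("probabilities must lie in [0, 1]")
    if g < 2:
        raise ValueError("need at least 2 groups")
    if len(probs) < g:
        raise ValueError("fewer cases than groups")
    if np.unique(probs).size < 2:
        raise ValueError("cannot form g groups: all probabilities identical")
    idx = _hl_group_index(probs, g)
    labels = np.unique(idx)
    rows: list[tuple[int, float, float, float]] = []
    statistic = 0.0
    for lab in labels:
        mask = idx == lab
        n_g = int(mask.sum())
        pbar = float(probs[mask].mean())
        observed = float(outcomes[mask].sum())
        expected = float(probs[mask].sum())
        rows.append((n_g, observed, expected, pbar))
        if 0.0 < pbar < 1.0:
            statistic += (observed - expected) ** 2 / (n_g * pbar * (1.0 - pbar))
    g_formed = len(labels)
    df = g_formed - 2
    p_value = float(stats.chi2.sf(statistic, df)) if df >= 1 else None
    return HLResult(statistic=float(statistic), g=g_formed, df=df, p_value=p_value, groups=rows)


def calibration_assess(probs, outcomes, bins: int = 10) -> CalibrationResult:
    """Weak calibration: logistic fit of outcomes on logit(predicted risk).

    A perfectly calibrated model has slope 1 and intercept 0.  The curve
    points are (mean predicted, observed proportion) over ``bins``
    fixed-count risk groups, so they are deterministic rather than
    smoothed.
    """
    probs, outcomes = _validate_pair(probs, outcomes)
    if bins < 2:
        raise ValueError("need at least 2 bins")
    p = np.clip(probs, _PROB_EPS, 1 - _PROB_EPS)
    x = logit(p)
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictions: constant probabilities, no slope identifiable")
    X = sm.add_constant(x)
    try:
        fit = sm.GLM(outcomes, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-10)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes vary
        raise ValueError(f"calibration fit failed (possible separation): {exc}") from exc
    intercept, slope = fit.params
    if not np.isfinite([intercept, slope]).all() or max(abs(intercept), abs(slope)) > 15:
        raise ValueError("perfect separation detected in calibration fit")
    idx = _hl_group_index(probs, bins)
    pts = [
        (float(probs[idx == lab].mean()), float(outcomes[idx == lab].mean()))
        for lab in np.unique(idx)
    ]
    return CalibrationResult(slope=float(slope), intercept=float(intercept), curve_points=pts)


def _confusion_report(threshold: float, scores: np.ndarray, labels: np.ndarray) -> ThresholdReport:
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / len(labels)
    return ThresholdReport(
        threshold=threshold,
        youden_j=sens + spec - 1.0,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        confusion=(tp, fp, fn, tn),
    )


def report_from_confusion(tp: int, fp: int, fn: int, tn: int) -> ThresholdReport:
    """Threshold metrics straight from confusion counts (threshold unset)."""
    scores = np.concatenate([np.ones(tp + fp), np.zeros(fn + tn)])
    labels = np.concatenate([np.ones(tp, int), np.zeros(fp, int), np.ones(fn, int), np.zeros(tn, int)])
    return _confusion_report(0.5, scores, labels)


def youden_threshold(scores, labels) -> ThresholdReport:
    """Operating point maximizing the Youden index J = sens + spec - 1.

    Candidate thresholds are the midpoints of consecutive distinct scores
    plus -inf and +inf; positives are called at score >= threshold.  When
    several thresholds attain the maximal J, the lowest is returned.
    """
    scores, labels = _validate_pair(scores, labels)
    uniq = np.unique(scores)
    candidates = [-np.inf]
    candidates.extend(((uniq[:-1] + uniq[1:]) / 2.0).tolist())
    candidates.append(np.inf)
    best: ThresholdReport | None = None
    for thr in candidates:
        rep = _confusion_report(thr, scores, labels)
        if best is None or rep.youden_j > best.youden_j + 1e-12:
            best = rep
    return best
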