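"""Discrimination, calibration and threshold metrics against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import roc_auc_score

from lungrisk import metrics as M


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney oracle: concordant 1, tied 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1][:, None]
    neg = scores[labels == 0][None, :]
    return float(((pos > neg) + 0.5 * (pos == neg)).mean())


class TestAuc:
    def test_perfect_separation(self):
        r = M.auc_with_ci([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.ci_low <= r.auc <= r.ci_high

    def test_three_of_four_concordant_pairs(self):
        r = M.auc_with_ci([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)

    def test_all_tied_scores(self):
        r = M.auc_with_ci([0.3] * 6, [0, 1, 0, 1, 0, 1])
        assert r.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            M.auc_with_ci([0.1, 0.2], [1, 1])

    def test_matches_brute_force_oracle_with_ties(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(10, 300)
            scores = np.round(rng.normal(size=n), 1)  # rounding induces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            r = M.auc_with_ci(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=150)
        labels = rng.integers(0, 2, size=150)
        base = M.auc_with_ci(scores, labels).auc
        for f in (np.exp, np.tanh, lambda x: x**3, lambda x: 3 * x + 7):
            assert M.auc_with_ci(f(scores), labels).auc == pytest.approx(base)

    def test_bootstrap_ci_is_seeded_and_sane(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=120) + rng.integers(0, 2, size=120)
        labels = (scores > np.median(scores)).astype(int)
        labels[::7] = 1 - labels[::7]
        a = M.auc_with_ci(scores, labels, ci_method="bootstrap", n_boot=200, seed=3)
        b = M.auc_with_ci(scores, labels, ci_method="bootstrap", n_boot=200, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low <= a.auc <= a.ci_high


class TestChooseHlGroups:
    @pytest.mark.parametrize("n, m, g", [(1085, 91, 11), (2000, 1000, 34), (1200, 15, 10)])
    def test_formula(self, n, m, g):
        assert M.choose_hl_groups(n, m) == g

    @pytest.mark.parametrize("n", [500, 1000, 30000])
    def test_outside_stated_range_defaults_to_ten(self, n):
        assert M.choose_hl_groups(n, n // 10) == 10

    def test_events_exceeding_cases_rejected(self):
        with pytest.raises(ValueError):
            M.choose_hl_groups(100, 100)


class TestHosmerLemeshow:
    def test_two_group_hand_example(self):
        """5 cases at 0.1 and 5 at 0.9; O = (1, 4) vs E = (0.5, 4.5).

        Hand oracle: each group contributes 0.25 / (5*0.09) = 0.5556, so
        the statistic is 1.1111; with g = 2 the df is 0 and no p-value.
        """
        probs = np.array([0.1] * 5 + [0.9] * 5)
        outcomes = np.array([1, 0, 0, 0, 0, 1, 1, 1, 1, 0])
        r = M.hosmer_lemeshow(probs, outcomes, g=2)
        assert r.statistic == pytest.approx(1.1111, abs=1e-4)
        assert r.df == 0 and r.p_value is None

    def test_observed_equal_expected_gives_zero(self):
        # groups of 4 with prob p and exactly 4p events each
        probs = np.repeat([0.25, 0.5, 0.75], 4)
        outcomes = np.array([1, 0, 0, 0, 1, 1, 0, 0, 1, 1, 1, 0])
        r = M.hosmer_lemeshow(probs, outcomes, g=3)
        assert r.statistic == pytest.approx(0.0, abs=1e-12)

    def test_constant_probabilities_rejected(self):
        with pytest.raises(ValueError, match="cannot form"):
            M.hosmer_lemeshow([0.3] * 20, [0, 1] * 10, g=4)

    def test_group_accounting_invariants(self):
        rng = np.random.default_rng(9)
        probs = rng.uniform(0.02, 0.9, size=500)
        outcomes = (rng.uniform(size=500) < probs).astype(int)
        r = M.hosmer_lemeshow(probs, outcomes, g=10)
        ns = np.array([g[0] for g in r.groups])
        obs = np.array([g[1] for g in r.groups])
        exp = np.array([g[2] for g in r.groups])
        assert ns.sum() == 500
        assert obs.sum() == outcomes.sum()
        assert exp.sum() == pytest.approx(probs.sum())
        assert ns.max() - ns.min() <= 2  # near-equal with continuous probs

    def test_ties_stay_in_one_group(self):
        probs = np.concatenate([np.full(30, 0.2), np.full(5, 0.5), np.full(30, 0.8)])
        outcomes = (np.arange(65) % 4 == 0).astype(int)
        r = M.hosmer_lemeshow(probs, outcomes, g=4)
        # tied blocks cannot be split, so only 3 distinct groups can form
        assert r.g == 3


class TestCalibration:
    def test_self_fit_probabilities_are_calibrated(self):
        """Probabilities fit by ML on the same data satisfy slope 1, intercept 0."""
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        x = rng.normal(size=3000)
        y = (rng.uniform(size=3000) < 1 / (1 + np.exp(-(-1.5 + 0.8 * x)))).astype(int)
        fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit()
        probs = fit.predict(sm.add_constant(x))
        r = M.calibration_assess(probs, y, bins=10)
        assert r.slope == pytest.approx(1.0, abs=1e-6)
        assert r.intercept == pytest.approx(0.0, abs=1e-6)
        assert len(r.curve_points) == 10

    def test_recovery_of_shifted_truth(self):
        """Outcomes from true LP = logit(p) - 1 recover intercept -1, slope 1."""
        rng = np.random.default_rng(22)
        probs = rng.uniform(0.05, 0.7, size=20000)
        lp_true = np.log(probs / (1 - probs)) - 1.0
        y = (rng.uniform(size=20000) < 1 / (1 + np.exp(-lp_true))).astype(int)
        r = M.calibration_assess(probs, y)
        assert r.slope == pytest.approx(1.0, abs=0.1)
        assert r.intercept == pytest.approx(-1.0, abs=0.1)

    def test_constant_probabilities_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            M.calibration_assess([0.3] * 50, [0, 1] * 25)

    def test_curve_proportions_within_unit_interval(self):
        rng = np.random.default_rng(23)
        probs = rng.uniform(0.05, 0.95, 400)
        y = (rng.uniform(size=400) < probs).astype(int)
        r = M.calibration_assess(probs, y, bins=8)
        assert all(0 <= obs <= 1 for _, obs in r.curve_points)


def exhaustive_youden(scores, labels):
    """Independent oracle: evaluate J at every candidate threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]])
    best = (-np.inf, None)
    for t in cands:
        calls = scores >= t
        sens = (calls & (labels == 1)).sum() / max((labels == 1).sum(), 1)
        spec = (~calls & (labels == 0)).sum() / max((labels == 0).sum(), 1)
        j = sens + spec - 1
        if j > best[0] + 1e-12:
            best = (j, t)
    return best


class TestYouden:
    def test_perfect_separation(self):
        r = M.youden_threshold([1, 2, 10, 11], [0, 0, 1, 1])
        assert r.youden_j == pytest.approx(1.0)
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    def test_tied_maximum_returns_lowest_threshold(self):
        r = M.youden_threshold([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.youden_j == pytest.approx(0.5)
        assert r.threshold == pytest.approx(0.225)
        assert r.sensitivity == pytest.approx(1.0)
        assert r.specificity == pytest.approx(0.5)

    def test_confusion_arithmetic(self):
        r = M.report_from_confusion(tp=8, fp=10, fn=2, tn=80)
        assert r.sensitivity == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.889, abs=5e-4)
        assert r.ppv == pytest.approx(0.444, abs=5e-4)
        assert r.npv == pytest.approx(0.976, abs=5e-4)
        assert r.accuracy == pytest.approx(0.88)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.data())
    def test_ppv_satisfies_bayes_identity(self, data):
        n = data.draw(st.integers(12, 120))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            return
        r = M.youden_threshold(scores, labels)
        prev = labels.mean()
        denom = r.sensitivity * prev + (1 - r.specificity) * (1 - prev)
        if denom > 0 and not np.isnan(r.ppv):
            assert r.ppv == pytest.approx(r.sensitivity * prev / denom)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            n = rng.integers(8, 300)
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            r = M.youden_threshold(scores, labels)
            j, t = exhaustive_youden(scores, labels)
            assert r.youden_j == pytest.approx(j, abs=1e-12)
            assert r.threshold == pytest.approx(t)
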