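"""ROC/AUC machinery against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trisskit.evaluation import (
    auc,
    auc_ci,
    discrimination_report,
    optimal_cutoff,
    roc_curve,
)
from trisskit.exceptions import EvaluationError


def auc_pair_oracle(scores, outcome):
    """Exhaustive pair counting, ties worth 1/2."""
    s = np.asarray(scores, float)
    y = np.asarray(outcome, int)
    pos, neg = s[y == 1], s[y == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_toy_case_matches_pair_counting(self):
        scores, y = [0.9, 0.8, 0.7, 0.6], [1, 1, 0, 1]
        expected = auc_pair_oracle(scores, y)
        assert expected == pytest.approx(2 / 3)
        assert auc(scores, y) == pytest.approx(expected)

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(2)
        s = rng.random(60)
        y = rng.integers(0, 2, 60)
        y[0], y[1] = 0, 1
        assert auc(s, y) == pytest.approx(1 - auc(s, 1 - y))

    def test_one_class_absent_errors(self):
        with pytest.raises(EvaluationError):
            auc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(derandomize=True, max_examples=200)
    def test_matches_oracle_with_ties(self, data):
        n = data.draw(st.integers(4, 60))
        # coarse grid forces ties
        s = data.draw(st.lists(st.sampled_from([0.1, 0.3, 0.5, 0.7, 0.9]),
                               min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if sum(y) in (0, n):
            y[0] = 1 - y[0]
        assert auc(s, y) == pytest.approx(auc_pair_oracle(s, y), abs=1e-12)

    @given(st.data())
    @settings(derandomize=True, max_examples=100)
    def test_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(4, 50))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        s = rng.random(n)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        assert auc(np.exp(3 * s), y) == pytest.approx(auc(s, y), abs=1e-12)


class TestRocCurve:
    def test_staircase_area_equals_auc(self):
        rng = np.random.default_rng(4)
        s = rng.random(300).round(2)  # with ties
        y = rng.integers(0, 2, 300)
        roc = roc_curve(s, y)
        area = np.trapezoid(roc.sensitivity, 1 - roc.specificity)
        assert area == pytest.approx(roc.auc, abs=1e-12)

    def test_toy_threshold_count(self):
        roc = roc_curve([0.9, 0.8, 0.7, 0.6], [1, 1, 0, 1])
        assert len(roc.thresholds) == 5  # 4 unique scores + sentinel
        assert roc.auc == pytest.approx(2 / 3)

    def test_constant_scores_no_discrimination(self):
        roc = roc_curve([0.5] * 10, [1, 0] * 5)
        assert roc.auc == 0.5

    def test_replication_invariance(self):
        s = [0.9, 0.7, 0.4, 0.2]
        y = [1, 1, 0, 0]
        r1 = roc_curve(s, y)
        r2 = roc_curve(s * 3, y * 3)
        assert np.allclose(r1.sensitivity, r2.sensitivity)
        assert np.allclose(r1.specificity, r2.specificity)
        assert r1.auc == r2.auc

    def test_predict_death_orientation_is_relabelling(self):
        rng = np.random.default_rng(9)
        s = rng.random(100)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        # flipping both scores and labels (the death framing) is pure
        # relabelling: the AUC is unchanged
        assert roc_curve(s, y).auc == pytest.approx(
            roc_curve(-s, 1 - y, predict_death=False).auc
        )
        assert auc(s, y, predict_death=True) == pytest.approx(auc(s, y))


class TestConfidenceIntervals:
    def test_delong_and_bootstrap_agree_on_synthetic(self):
        rng = np.random.default_rng(12)
        n = 2_000
        y = rng.integers(0, 2, n)
        s = np.clip(0.3 * y + 0.7 * rng.random(n), 0, 1)
        a = auc(s, y)
        lo_d, hi_d = auc_ci(s, y, "delong")
        lo_b, hi_b = auc_ci(s, y, "bootstrap", reps=500, seed=1)
        assert lo_d < a < hi_d
        assert lo_b < a < hi_b
        assert max(lo_d, lo_b) < min(hi_d, hi_b)  # intervals overlap

    def test_null_interval_straddles_half(self):
        rng = np.random.default_rng(3)
        s = rng.random(1000)
        y = rng.integers(0, 2, 1000)
        lo, hi = auc_ci(s, y, "delong")
        assert lo < 0.5 < hi

    def test_bootstrap_seeded_determinism(self):
        rng = np.random.default_rng(8)
        s, y = rng.random(200), rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        assert auc_ci(s, y, "bootstrap", reps=300, seed=42) == auc_ci(
            s, y, "bootstrap", reps=300, seed=42
        )

    def test_degenerate_variance_collapses_with_warning(self):
        s = [0.9, 0.8, 0.2, 0.1]
        y = [1, 1, 0, 0]
        with pytest.warns(UserWarning):
            lo, hi = auc_ci(s, y, "delong")
        assert lo == hi == 1.0


class TestOptimalCutoff:
    @staticmethod
    def scan_oracle(scores, outcome):
        """Youden maximiser by exhaustive scan over candidate thresholds."""
        s = np.asarray(scores, float)
        y = np.asarray(outcome, int)
        best = (-np.inf, None)
        for t in sorted(set(s), reverse=True):
            sens = np.mean(s[y == 1] >= t)
            spec = np.mean(s[y == 0] < t)
            j = sens + spec - 1
            if j > best[0]:
                best = (j, t)
        return best[1]

    def test_unique_maximum_matches_scan(self):
        s = [0.95, 0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2]
        y = [1, 1, 1, 1, 0, 1, 0, 0]
        roc = roc_curve(s, y)
        cut, sens, spec = optimal_cutoff(roc)
        assert cut == self.scan_oracle(s, y)
        assert sens + spec - 1 > 0

    def test_perfect_separation_tie_rule(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        cut, sens, spec = optimal_cutoff(roc)
        assert sens == spec == 1.0
        assert cut == 0.8  # highest threshold in the gap

    def test_constant_scores_pick_max_threshold(self):
        roc = roc_curve([0.5] * 8, [1, 0] * 4)
        cut, _, _ = optimal_cutoff(roc)
        assert cut == 0.5

    @given(st.integers(0, 5_000))
    @settings(derandomize=True, max_examples=60)
    def test_youden_matches_scan_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        s = rng.random(n).round(1)
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        roc = roc_curve(s, y)
        cut, sens, spec = optimal_cutoff(roc)
        j_star = sens + spec - 1
        # same maximal Youden value as the exhaustive scan
        t = self.scan_oracle(s, y)
        sens_o = np.mean(s[y == 1] >= t)
        spec_o = np.mean(s[y == 0] < t)
        assert j_star == pytest.approx(sens_o + spec_o - 1, abs=1e-12)


class TestReport:
    def test_full_report_fields(self):
        rng = np.random.default_rng(21)
        y = rng.integers(0, 2, 500)
        s = np.clip(0.5 * y + 0.5 * rng.random(500), 0, 1)
        rep = discrimination_report(s, y)
        assert rep.ci_low <= rep.auc <= rep.ci_high
        assert 0 <= rep.cutoff_sens <= 1 and 0 <= rep.cutoff_spec <= 1
        assert rep.ci_method == "delong"
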