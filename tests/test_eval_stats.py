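"""AUC, Wilson intervals, DeLong, McNemar, serum panel, paired monitoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from breathdx import (delong_test, mcnemar_test, performance_report,
                      prepost_comparison, roc_auc, serum_panel_classify,
                      wilson_ci)


class TestRocAuc:
    def test_known_values(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([1, 1, 1, 1], [1, 0, 1, 0]) == 0.5
        assert roc_auc([0.9, 0.4, 0.5, 0.3], [1, 1, 0, 0]) == pytest.approx(0.75)

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_equals_pairwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        scores = np.round(rng.normal(0, 1, n), 1)     # force some ties
        labels = rng.random(n) < 0.5
        labels[0], labels[1] = True, False
        brute = np.mean([(a > b) + 0.5 * (a == b)
                         for a in scores[labels] for b in scores[~labels]])
        assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)


class TestWilson:
    def test_certain_failure_lower_bound_zero(self):
        lo, hi = wilson_ci(0, 10)
        assert lo == 0.0 and 0 < hi < 0.4

    def test_contains_point_estimate(self):
        for k, n in [(3, 3), (15, 21), (1, 50)]:
            lo, hi = wilson_ci(k, n)
            assert lo <= k / n <= hi

    def test_clopper_pearson_flag_differs(self):
        # exact interval for 3/3 reaches much lower than the score interval
        assert wilson_ci(3, 3, method="beta")[0] < wilson_ci(3, 3)[0] - 0.1

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            wilson_ci(5, 3)


class TestPerformanceReport:
    def test_threshold_below_all_scores(self):
        rep = performance_report([0.9, 0.8, 0.7], [1, 0, 1], threshold=0.0)
        assert rep.sensitivity == 1.0 and rep.specificity == 0.0

    def test_lung_cancer_sensitivity_interval(self):
        """41 of 47 detected: Wilson interval rounds to (75%, 94%)."""
        scores = np.r_[np.ones(41), np.zeros(6)]
        labels = np.ones(47, dtype=bool)
        rep = performance_report(np.r_[scores, [0.0]], np.r_[labels, [False]],
                                 threshold=0.5)
        assert rep.sensitivity == pytest.approx(41 / 47)
        assert round(rep.sensitivity_ci[0], 2) == 0.75
        assert round(rep.sensitivity_ci[1], 2) == 0.94

    def test_self_consistent_with_counts(self, rng):
        scores = rng.random(60)
        labels = rng.random(60) < 0.6
        labels[0], labels[1] = True, False
        rep = performance_report(scores, labels, threshold=0.5)
        assert rep.tp + rep.fp + rep.tn + rep.fn == rep.n == 60
        assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert rep.specificity == pytest.approx(rep.tn / (rep.tn + rep.fp))
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / rep.n)
        assert rep.f1 == pytest.approx(
            2 * rep.tp / (2 * rep.tp + rep.fp + rep.fn))
        assert rep.auc == pytest.approx(roc_auc(scores, labels))

    def test_subgroup_mask_restricts(self, rng):
        scores = rng.random(30)
        labels = np.r_[np.ones(15, bool), np.zeros(15, bool)]
        mask = np.r_[np.ones(10, bool), np.zeros(5, bool), np.ones(15, bool)]
        rep = performance_report(scores, labels, 0.5, subgroup_mask=mask)
        assert rep.n == mask.sum()


class TestDeLong:
    def test_model_vs_itself(self, rng):
        scores = rng.random(40)
        labels = rng.random(40) < 0.5
        labels[0], labels[1] = True, False
        a1, a2, z, p = delong_test(scores, scores, labels)
        assert a1 == a2 and z == 0.0 and p == 1.0

    def test_antisymmetric_in_model_order(self, rng):
        labels = np.r_[np.ones(20, bool), np.zeros(20, bool)]
        sa = rng.normal(labels.astype(float), 1)
        sb = rng.normal(0, 1, 40)
        _, _, z1, p1 = delong_test(sa, sb, labels)
        _, _, z2, p2 = delong_test(sb, sa, labels)
        assert z1 == pytest.approx(-z2) and p1 == pytest.approx(p2)

    def test_detects_clear_difference(self, rng):
        labels = np.r_[np.ones(30, bool), np.zeros(30, bool)]
        good = labels.astype(float) + rng.normal(0, 0.3, 60)
        noise = rng.normal(0, 1, 60)
        a_good, a_noise, z, p = delong_test(good, noise, labels)
        assert a_good > a_noise and p < 0.01


class TestMcNemar:
    def test_no_discordance(self):
        assert mcnemar_test([1, 1, 0], [1, 1, 0]) == (0, 0, 1.0)

    def test_symmetric_discordance_is_one(self):
        a = np.array([1, 1, 1, 0, 0, 0], bool)
        b = np.array([0, 0, 0, 1, 1, 1], bool)
        _, _, p = mcnemar_test(a, b)
        assert p == pytest.approx(1.0)

    def test_exact_binomial_value(self):
        # b=2, c=8: two-sided exact p = 112/1024
        a = np.r_[np.ones(2, bool), np.zeros(8, bool), np.ones(5, bool)]
        b = np.r_[np.zeros(2, bool), np.ones(8, bool), np.ones(5, bool)]
        bb, cc, p = mcnemar_test(a, b)
        assert (bb, cc) == (2, 8)
        assert p == pytest.approx(112 / 1024)

    def test_matches_full_enumeration(self):
        for b in range(0, 7):
            for c in range(0, 7):
                if b + c == 0:
                    continue
                av = np.r_[np.ones(b, bool), np.zeros(c, bool)]
                bv = np.r_[np.zeros(b, bool), np.ones(c, bool)]
                _, _, p = mcnemar_test(av, bv)
                n = b + c
                k = min(b, c)
                exact = min(1.0, 2 * binom.cdf(k, n, 0.5)
                            - (binom.pmf(k, n, 0.5) if 2 * k == n else 0.0))
                assert p == pytest.approx(exact, abs=1e-9)


class TestSerumPanel:
    def _sheet(self, **vals):
        base = {"sample_id": ["x"], "ca125": [np.nan], "progrp": [np.nan],
                "cea": [np.nan], "cyfra211": [np.nan]}
        base.update({k: [v] for k, v in vals.items()})
        return pd.DataFrame(base)

    def test_single_marker_above_range_positive(self):
        out = serum_panel_classify(self._sheet(ca125=36.0, progrp=10.0,
                                               cea=1.0, cyfra211=1.0))
        assert bool(out.loc["x", "panel_positive"])

    def test_values_at_upper_limits_negative(self):
        out = serum_panel_classify(self._sheet(ca125=35.0, progrp=46.0,
                                               cea=5.0, cyfra211=3.0))
        assert not bool(out.loc["x", "panel_positive"])
        assert not bool(out.loc["x", "excluded"])

    def test_all_missing_excluded_not_negative(self):
        out = serum_panel_classify(self._sheet())
        assert bool(out.loc["x", "excluded"])

    def test_partial_markers_still_classified(self):
        out = serum_panel_classify(self._sheet(cea=9.0))
        assert bool(out.loc["x", "panel_positive"])
        assert not bool(out.loc["x", "excluded"])


class TestPrepost:
    def test_no_change_gives_p_one(self):
        drop, t, p, n = prepost_comparison([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert (drop, t, p, n) == (0.0, 0.0, 1.0, 3)

    def test_closed_form_three_pairs(self):
        pre = np.array([0.8, 0.6, 0.9])
        post = pre + np.array([-0.2, -0.1, -0.3])
        drop, t, p, n = prepost_comparison(pre, post)
        assert drop == pytest.approx(-0.2)
        assert t == pytest.approx(-0.2 / (0.1 / np.sqrt(3)), rel=1e-6)
        assert p == pytest.approx(0.0742, abs=2e-3)

    def test_signed_rank_alternative(self):
        pre = np.linspace(0.3, 0.9, 8)
        post = pre - 0.1
        _, _, p, _ = prepost_comparison(pre, post, alternative_test=True)
        assert p < 0.05

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            prepost_comparison([0.5], [0.4])
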