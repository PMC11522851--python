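"""Diagnostic statistics: AMS rule, rank statistics, ROC, agreement."""

import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from noctox.errors import (
    DegenerateGroupingError,
    InputDomainError,
    InsufficientDataError,
)
from noctox.session import LLSRecord
from noctox.stats import (
    auc_mann_whitney,
    bland_altman,
    classify_ams,
    compare_groups,
    exploratory_correlations,
    hodges_lehmann,
    remove_outliers,
    roc_youden,
    youden_indices,
)


class TestClassifyAMS:
    @pytest.mark.parametrize(
        "total,headache,expected",
        [(3, 1, True), (2, 2, False), (5, 0, False), (12, 3, True), (0, 0, False)],
    )
    def test_conjunctive_rule(self, total, headache, expected):
        rec = LLSRecord("P01", "day11", "morning", total, min(headache, total))
        assert classify_ams(rec).is_positive is expected

    def test_rule_gap_flagged(self):
        st_ = classify_ams(LLSRecord("P01", "day11", "morning", 5, 0))
        assert not st_.is_positive and st_.rule_gap

    def test_evening_record_rejected(self):
        with pytest.raises(InputDomainError):
            classify_ams(LLSRecord("P01", "day11", "evening", 5, 2))


class TestRemoveOutliers:
    def test_gross_outlier_removed(self, rng):
        vals = np.concatenate([rng.normal(85, 1, 50), [20.0]])
        kept, removed = remove_outliers(vals)
        assert removed == [20.0]
        assert kept.size == 50

    def test_identical_values_unchanged(self):
        kept, removed = remove_outliers(np.full(10, 85.0))
        assert kept.size == 10 and removed == []

    def test_too_few_values(self):
        with pytest.raises(InputDomainError):
            remove_outliers([1.0, 2.0])


class TestCompareGroups:
    def test_identical_groups(self):
        gc = compare_groups([1, 2, 3], [1, 2, 3])
        assert gc.hl_median_difference == 0.0
        assert gc.p_value == pytest.approx(1.0)
        assert gc.ci95[0] <= 0 <= gc.ci95[1]

    def test_shifted_groups(self):
        gc = compare_groups([10, 11, 12], [1, 2, 3])
        # brute force: median of the 9 pairwise differences
        diffs = sorted(a - b for a in (10, 11, 12) for b in (1, 2, 3))
        assert gc.hl_median_difference == statistics.median(diffs) == 9.0

    @pytest.mark.parametrize("seed", range(10))
    def test_hl_matches_bruteforce(self, seed):
        r = np.random.default_rng(seed)
        pos = r.normal(0, 3, r.integers(3, 25))
        neg = r.normal(1, 3, r.integers(3, 25))
        brute = statistics.median(a - b for a in pos for b in neg)
        assert hodges_lehmann(pos, neg) == pytest.approx(brute)
        gc = compare_groups(pos, neg)
        assert gc.hl_median_difference == pytest.approx(brute)
        assert gc.ci95[0] <= gc.hl_median_difference <= gc.ci95[1]

    def test_empty_group(self):
        with pytest.raises(DegenerateGroupingError):
            compare_groups([], [1, 2])


class TestRoc:
    def test_perfect_separation(self):
        r = roc_youden([7, 8, 9], [1, 2, 3])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.youden_reported == pytest.approx(2.0)
        assert r.cutoff_direction == "above"

    def test_orientation_flip_for_low_scores(self):
        r = roc_youden([1, 2, 3], [7, 8, 9])
        assert r.auc == 1.0
        assert r.cutoff_direction == "below"

    def test_identical_distributions_chance_auc(self):
        r = roc_youden([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.auc == pytest.approx(0.5)

    def test_youden_conventions(self):
        yr, ys = youden_indices(0.667, 0.760)
        assert yr == pytest.approx(1.427)
        assert ys == pytest.approx(0.427)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_u_statistic(self, seed):
        r = np.random.default_rng(seed)
        pos = r.integers(0, 8, r.integers(2, 12)).astype(float)
        neg = r.integers(0, 8, r.integers(2, 12)).astype(float)
        if np.unique(np.concatenate([pos, neg])).size < 2:
            return
        brute = np.mean([
            1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg
        ])
        assert auc_mann_whitney(pos, neg) == pytest.approx(brute)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_auc_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        pos = r.normal(1, 1, 12)
        neg = r.normal(0, 1, 15)
        a1 = roc_youden(pos, neg).auc
        a2 = roc_youden(np.exp(pos / 3), np.exp(neg / 3)).auc
        assert a1 == pytest.approx(a2)

    def test_youden_identity(self, rng):
        pos = rng.normal(1, 1, 30)
        neg = rng.normal(0, 1, 40)
        r = roc_youden(pos, neg)
        assert r.youden_reported - r.youden_standard == pytest.approx(1.0)
        assert 0.5 <= r.auc <= 1.0
        assert r.auc_ci95[0] <= r.auc <= r.auc_ci95[1]

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateGroupingError):
            roc_youden([1, 2], [])
        with pytest.raises(DegenerateGroupingError):
            roc_youden([5, 5], [5, 5])


class TestBlandAltman:
    def test_identity_pairs(self):
        ba = bland_altman([90, 85, 80], [90, 85, 80])
        assert ba.bias == 0.0 and ba.sd_diff == 0.0
        assert ba.loa95 == (0.0, 0.0)

    def test_constant_offset(self):
        ba = bland_altman([90, 85, 80], [85, 80, 75])
        assert ba.bias == pytest.approx(5.0)
        assert ba.sd_diff == 0.0
        assert ba.slope == 0.0

    def test_proportional_difference_recovered(self):
        avgs = np.linspace(84, 100, 9)
        diffs = 0.5 * avgs - 45.0
        ref, tst = avgs + diffs / 2, avgs - diffs / 2
        ba = bland_altman(ref, tst)
        assert ba.slope == pytest.approx(0.5, abs=1e-9)
        assert ba.x_intercept == pytest.approx(90.0, abs=1e-6)
        assert ba.r_squared == pytest.approx(1.0)
        assert ba.loa95[1] - ba.loa95[0] == pytest.approx(2 * 1.96 * ba.sd_diff)

    def test_swap_antisymmetry(self, rng):
        ref = rng.normal(88, 3, 25)
        tst = ref - rng.normal(2, 1, 25)
        a = bland_altman(ref, tst)
        b = bland_altman(tst, ref)
        assert a.bias == pytest.approx(-b.bias)
        assert abs(a.slope) == pytest.approx(abs(b.slope))
        assert a.r_squared == pytest.approx(b.r_squared)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([90, 85], [88, 84])


class TestExploratoryCorrelations:
    def _features(self, values):
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(len(values))],
                "night_label": ["day9"] * len(values),
                "ov_spo2_mean": values,
            }
        )

    def _lls(self, peaks):
        return [
            LLSRecord(f"P{i}", "day11", "morning", int(t), min(int(t), 1))
            for i, t in enumerate(peaks)
        ]

    def test_perfect_linear_relationship(self):
        feats = self._features([90.0, 88.0, 86.0, 84.0])
        lls = self._lls([0, 2, 4, 6])
        out = exploratory_correlations(feats, lls, ["ov_spo2_mean"], ["day9"])
        assert out.iloc[0]["r"] == pytest.approx(-1.0)

    def test_too_few_pairs_not_assessable(self):
        feats = self._features([90.0, 88.0])
        out = exploratory_correlations(feats, self._lls([1, 2]), ["ov_spo2_mean"], ["day9"])
        assert np.isnan(out.iloc[0]["r"]) and out.iloc[0]["n"] == 2

    def test_null_relationship_small_r(self, rng):
        rs = []
        for _ in range(30):
            feats = self._features(rng.normal(88, 2, 18))
            lls = self._lls(rng.integers(0, 7, 18))
            out = exploratory_correlations(feats, lls, ["ov_spo2_mean"], ["day9"])
            rs.append(out.iloc[0]["r"])
        assert abs(np.mean(rs)) < 0.15  # centred on zero under the null
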