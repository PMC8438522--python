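"""Contingency tests, ROC/AUC pair-counting equivalence, DeLong."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6apattern.response_eval import (binarize_response, contingency_test,
                                      delong_compare, response_rate_table,
                                      roc_auc)


def auc_pair_count_oracle(scores, labels):
    """All-pairs Mann-Whitney probability with half-weight ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def delong_components_oracle(scores, labels):
    """Direct V10/V01 structural components by pairwise comparison."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    psi = lambda x, y: 1.0 if x > y else (0.5 if x == y else 0.0)
    v10 = np.array([np.mean([psi(p, n) for n in neg]) for p in pos])
    v01 = np.array([np.mean([psi(p, n) for p in pos]) for n in neg])
    return v10, v01


class TestContingency:
    def test_homogeneous_table_chi2_zero(self):
        stat, p = contingency_test([[10, 10], [10, 10]], method="chi2")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_fisher_diagonal_enumeration(self):
        # [[3,0],[0,3]]: two-sided p = 2 / C(6,3) = 0.1
        _, p = contingency_test([[3, 0], [0, 3]], method="fisher2x2")
        assert p == pytest.approx(2.0 / math.comb(6, 3))

    def test_transpose_invariance(self):
        rng = np.random.default_rng(0)
        table = rng.integers(1, 30, size=(2, 3))
        s1, p1 = contingency_test(table, method="chi2")
        s2, p2 = contingency_test(table.T, method="chi2")
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_auto_picks_fisher_for_sparse_2x2(self):
        stat, p = contingency_test([[2, 1], [1, 3]], method="auto")
        ref_stat, ref_p = contingency_test([[2, 1], [1, 3]], method="fisher2x2")
        assert (stat, p) == (ref_stat, ref_p)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contingency_test([[0, 0], [1, 2]])


class TestRoc:
    def test_perfect_separation(self):
        out = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert out.auc == 1.0

    def test_matches_pair_count_oracle_exactly(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 40))
            scores = rng.integers(0, 8, size=n).astype(float)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            out = roc_auc(scores, labels)
            assert out.auc == pytest.approx(
                auc_pair_count_oracle(scores, labels), abs=1e-12)

    def test_null_mean_auc_half(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(2000):
            scores = rng.normal(size=30)
            labels = np.array([0] * 15 + [1] * 15)
            rng.shuffle(labels)
            aucs.append(roc_auc(scores, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_direction_complement(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=40)  # tie-free
        labels = rng.integers(0, 2, size=40)
        hi = roc_auc(scores, labels, "higher").auc
        lo = roc_auc(scores, labels, "lower").auc
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=25)
        labels = np.r_[np.zeros(12, int), np.ones(13, int)]
        rng.shuffle(labels)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(2.0 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_curve_endpoints_monotone(self):
        rng = np.random.default_rng(4)
        out = roc_auc(rng.normal(size=50), rng.integers(0, 2, size=50))
        curve = out.curve
        assert curve.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert curve.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert (curve["fpr"].diff().dropna() >= 0).all()
        assert (curve["tpr"].diff().dropna() >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1.0, 2.0], [1, 1])


class TestDeLong:
    def test_self_comparison_degenerate(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        auc_a, auc_b, z, p = delong_compare(scores, scores, labels)
        assert auc_a == auc_b
        assert z == 0.0 and p == 1.0

    def test_components_match_direct_oracle(self):
        rng = np.random.default_rng(6)
        from m6apattern.response_eval import _structural_components
        for _ in range(10):
            scores = rng.integers(0, 6, size=25).astype(float)
            labels = np.r_[np.zeros(12, int), np.ones(13, int)]
            v10, v01 = _structural_components(scores, labels)
            o10, o01 = delong_components_oracle(scores, labels)
            np.testing.assert_allclose(v10, o10, atol=1e-10)
            np.testing.assert_allclose(v01, o01, atol=1e-10)

    def test_detects_genuinely_better_score(self):
        rng = np.random.default_rng(7)
        n = 400
        labels = rng.integers(0, 2, size=n)
        good = labels + rng.normal(0, 0.5, n)
        bad = rng.normal(size=n)
        auc_a, auc_b, z, p = delong_compare(good, bad, labels)
        assert auc_a > auc_b and p < 1e-6


class TestResponseTable:
    def test_binarize_recist_collapse(self):
        resp = pd.Series(["CR", "PR", "SD", "PD", None])
        out = binarize_response(resp)
        assert out.tolist()[:4] == [1, 1, 0, 0]
        assert pd.isna(out.iloc[4])

    def test_rate_table_counts(self):
        groups = pd.Series(["high", "high", "low", "low", "low"])
        resp = pd.Series(["CR", "PD", "PR", "CR", "SD"])
        table = response_rate_table(groups, resp)
        assert table.loc["low", "responder"] == 2
        assert table.loc["high", "non_responder"] == 1

    def test_low_score_group_responds_more_on_default_cohort(self, default_cohort):
        """The planted negative response link makes the low-score stratum the
        responsive one (chi-square p < 0.05)."""
        _, clinical, _, truth = default_cohort
        groups = pd.Series(np.where(truth.true_score == truth.true_score.max(),
                                    "high", "low"), index=truth.true_score.index)
        table = response_rate_table(groups, clinical.data["response"])
        rates = table["responder"] / table.sum(axis=1)
        assert rates["low"] > rates["high"]
        _, p = contingency_test(table.to_numpy(), method="chi2")
        assert p < 0.05
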