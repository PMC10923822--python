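"""Evaluation metrics: Jaccard, confusion counts, summary rates, AUC."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctrseg import evalmetrics as em


class TestJaccard:
    def test_identical_masks(self):
        m = np.zeros((8, 8))
        m[2:5, 2:5] = 1
        assert em.jaccard(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((8, 8))
        a[0, 0] = 1
        b = np.zeros((8, 8))
        b[7, 7] = 1
        assert em.jaccard(a, b) == 0.0

    def test_partial_overlap_set_count(self):
        a = np.zeros((8, 8))
        a[0, 0:8] = 1          # 8 px
        b = np.zeros((8, 8))
        b[0, 4:8] = 1
        b[1, 0:4] = 1          # 8 px, overlap 4
        assert em.jaccard(a, b) == pytest.approx(4 / 12)

    def test_both_empty_defined_as_one(self):
        assert em.jaccard(np.zeros((4, 4)), np.zeros((4, 4))) == 1.0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.random((6, 6)) > 0.5
        b = rng.random((6, 6)) > 0.5
        assert em.jaccard(a, b) == em.jaccard(b, a)


class TestConfusion:
    def test_all_correct(self):
        labels = ["cardiomegaly", "normal", "cardiomegaly"]
        c = em.confusion(labels, labels)
        assert c == {"tp": 2, "fn": 0, "tn": 1, "fp": 0}

    def test_fully_swapped(self):
        t = ["cardiomegaly", "normal"]
        p = ["normal", "cardiomegaly"]
        c = em.confusion(t, p)
        assert c["tp"] == 0 and c["tn"] == 0
        assert c["fn"] == 1 and c["fp"] == 1

    def test_hand_tally(self):
        t = ["cardiomegaly", "cardiomegaly", "normal", "normal", "normal",
             "cardiomegaly"]
        p = ["cardiomegaly", "normal", "normal", "cardiomegaly", "normal",
             "cardiomegaly"]
        assert em.confusion(t, p) == {"tp": 2, "fn": 1, "tn": 2, "fp": 1}

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            em.confusion(["big"], ["normal"])


class TestSummaryMetrics:
    def test_detection_study_row(self):
        # counts for a 79-positive / 52-negative assessment set
        rep = em.summary_metrics({"tp": 45, "fn": 34, "tn": 45, "fp": 7})
        r = rep.rounded()
        assert r["sens"] == 56.96
        assert r["spec"] == 86.54
        assert r["gmean"] == 70.21
        assert r["acc"] == 68.70
        assert r["auc"] == 71.75

    def test_balanced_identity(self):
        rep = em.summary_metrics({"tp": 30, "fn": 10, "tn": 30, "fp": 10})
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity + rep.specificity) / 2)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            tp, fn, tn, fp = rng.integers(0, 21, size=4)
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = em.summary_metrics(
                {"tp": int(tp), "fn": int(fn), "tn": int(tn), "fp": int(fp)})
            assert rep.sensitivity == pytest.approx(100 * tp / (tp + fn))
            assert rep.specificity == pytest.approx(100 * tn / (tn + fp))
            assert rep.g_mean == pytest.approx(
                math.sqrt(rep.sensitivity * rep.specificity))
            assert rep.accuracy == pytest.approx(
                100 * (tp + tn) / (tp + fn + tn + fp))

    def test_gmean_bounded_by_arithmetic_mean(self):
        rep = em.summary_metrics({"tp": 5, "fn": 15, "tn": 18, "fp": 2})
        assert rep.g_mean <= (rep.sensitivity + rep.specificity) / 2

    def test_one_class_rates_undefined(self):
        rep = em.summary_metrics({"tp": 0, "fn": 0, "tn": 10, "fp": 2})
        assert math.isnan(rep.sensitivity)
        assert math.isnan(rep.g_mean)


class TestAUC:
    def test_hard_predictor_is_mean_of_rates(self):
        t = ["cardiomegaly"] * 79 + ["normal"] * 52
        p = (["cardiomegaly"] * 45 + ["normal"] * 34
             + ["normal"] * 45 + ["cardiomegaly"] * 7)
        assert em.auc_binary(t, p) == pytest.approx((56.962 + 86.538) / 2,
                                                    abs=0.01)

    def test_perfect_predictor(self):
        t = ["cardiomegaly", "normal", "cardiomegaly"]
        assert em.auc_binary(t, t) == 100.0

    def test_always_positive_predictor(self):
        t = ["cardiomegaly", "normal"]
        p = ["cardiomegaly", "cardiomegaly"]
        assert em.auc_binary(t, p) == 50.0

    def test_scores_perfectly_separated(self):
        t = ["normal"] * 5 + ["cardiomegaly"] * 5
        s = list(range(10))
        assert em.auc_scores(t, s) == 100.0

    def test_scores_all_tied(self):
        t = ["normal", "cardiomegaly"] * 5
        assert em.auc_scores(t, [0.5] * 10) == 50.0

    def test_scores_match_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        t = ["cardiomegaly" if v else "normal"
             for v in rng.integers(0, 2, 10)]
        if len(set(t)) < 2:
            t[0] = "normal"
            t[1] = "cardiomegaly"
        s = rng.random(10)
        pos = [si for ti, si in zip(t, s) if ti == "cardiomegaly"]
        neg = [si for ti, si in zip(t, s) if ti == "normal"]
        conc = sum((p > n) + 0.5 * (p == n)
                   for p, n in itertools.product(pos, neg))
        assert em.auc_scores(t, s) == pytest.approx(
            100 * conc / (len(pos) * len(neg)))

    def test_binary_equals_scores_on_hard_predictions(self):
        t = ["cardiomegaly"] * 6 + ["normal"] * 4
        p = ["cardiomegaly", "normal"] * 5
        as_scores = [1.0 if x == "cardiomegaly" else 0.0 for x in p]
        assert em.auc_binary(t, p) == pytest.approx(em.auc_scores(t, as_scores))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            em.auc_binary(["normal", "normal"], ["normal", "normal"])


class TestRatesToSummary:
    def test_counts_recovered_from_printed_rates(self):
        rep = em.rates_to_summary(56.96, 86.54, 79, 52)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (45, 34, 45, 7)
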