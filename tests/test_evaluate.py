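"""Correlation, regression increment, ROC/AUC, cutoffs, confusion metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piezosleep import (
    BinaryConfusion,
    DomainError,
    MultiLevelConfusion,
    SeverityClass,
    SingularityError,
    UndefinedCorrelationError,
    binary_confusion,
    binary_metrics,
    classify_severity_by_rei,
    incremental_regression,
    multilevel_confusion,
    multilevel_metrics,
    optimal_cutoff,
    pearson_r,
    roc_auc,
    round_display,
)


def brute_force_auc(scores, labels):
    """Pairwise Mann-Whitney counting with ties worth 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(1.0, 11.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])


class TestIncrementalRegression:
    def test_perfect_single_predictor_leaves_nothing_for_fcv(self):
        rng = np.random.default_rng(0)
        rei = rng.uniform(0, 50, 30)
        res = incremental_regression(ahi=rei, rei=rei, fcv=rng.normal(0, 1, 30))
        assert res.multiple_r_base == pytest.approx(1.0, abs=1e-9)
        assert res.p_value > 0.05 or res.partial_f == np.inf  # nothing left to explain

    def test_detects_signal_carried_only_by_fcv(self):
        rng = np.random.default_rng(1)
        n = 200
        rei = rng.uniform(0, 50, n)
        fcv = rng.normal(0, 1, n)
        ahi = rei + 1.0 * fcv + rng.normal(0, 1, n)
        res = incremental_regression(ahi, rei, fcv)
        assert res.p_value < 0.01
        assert res.multiple_r_full > res.multiple_r_base

    def test_collinear_predictors_rejected(self):
        rei = np.arange(10.0)
        with pytest.raises(SingularityError):
            incremental_regression(rei * 2, rei, rei)


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 4], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.ci95 == (1.0, 1.0)

    def test_tied_scores_half_credit(self):
        assert roc_auc([1, 2, 2, 3], [0, 0, 1, 1]).auc == pytest.approx(0.875)

    def test_label_inversion_complements(self):
        assert roc_auc([1, 2, 2, 3], [1, 1, 0, 0]).auc == pytest.approx(0.125)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([1, 2, 3], [1, 1, 1])

    def test_matches_bruteforce_and_trapezoid(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = rng.integers(6, 30)
            scores = rng.integers(0, 8, n).astype(float)
            labels = np.zeros(n, dtype=int)
            labels[rng.permutation(n)[: rng.integers(2, n - 1)]] = 1
            if labels.sum() in (0, n):
                continue
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            trapezoid = np.trapezoid(r.curve[:, 1], r.curve[:, 0])
            assert trapezoid == pytest.approx(r.auc, abs=1e-12)

    def test_ci_brackets_auc_and_curve_is_monotone(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(0, 1, 25), rng.normal(1, 1, 25)])
        labels = np.repeat([0, 1], 25)
        r = roc_auc(scores, labels)
        assert r.ci95[0] <= r.auc <= r.ci95[1]
        assert tuple(r.curve[0]) == (0.0, 0.0) and tuple(r.curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.curve[:, 0]) >= 0)
        assert np.all(np.diff(r.curve[:, 1]) >= 0)


class TestOptimalCutoff:
    def test_midpoint_rule(self):
        assert optimal_cutoff([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(2.5)

    def test_recovers_generating_boundary(self):
        rng = np.random.default_rng(4)
        ahi = rng.uniform(0, 40, 40)
        labels = (ahi >= 15).astype(int)
        rei = ahi + rng.normal(0, 3, 40)
        cutoff = optimal_cutoff(rei, labels)
        assert abs(cutoff - 15.0) <= 3.0

    def test_exhaustive_scan_oracle(self):
        """The returned cutoff attains the best min(sens, spec) found by a
        brute-force scan over all candidate thresholds."""
        rng = np.random.default_rng(5)
        scores = rng.normal(0, 1, 30).round(2)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[:3] = [0, 1, 0]  # both classes present
        cutoff = optimal_cutoff(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]

        def balance(c):
            return min((pos >= c).mean(), (neg < c).mean())

        grid = np.unique(scores)
        best = max(balance((a + b) / 2) for a, b in zip(grid[:-1], grid[1:]))
        assert balance(cutoff) == pytest.approx(best)


class TestBinaryMetrics:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            # (tp, fp, fn, tn) -> sens, spec, acc, ppa, npa (percent, 1 dp)
            ((14, 2, 4, 19), (77.8, 90.5, 84.6, 87.5, 82.6)),
            ((10, 1, 0, 28), (100.0, 96.6, 97.4, 90.9, 100.0)),
            ((14, 2, 2, 21), (87.5, 91.3, 89.7, 87.5, 91.3)),
            ((7, 1, 1, 30), (87.5, 96.8, 94.9, 87.5, 96.8)),
        ],
    )
    def test_reference_tables(self, cells, expected):
        m = binary_metrics(BinaryConfusion(*cells))
        got = tuple(
            round_display(v)
            for v in (m.sensitivity, m.specificity, m.accuracy, m.ppa, m.npa)
        )
        assert got == expected

    def test_empty_positive_class_flags_sensitivity_undefined(self):
        m = binary_metrics(BinaryConfusion(tp=0, fp=0, fn=0, tn=10))
        assert m.sensitivity is None
        assert m.specificity == pytest.approx(100.0)

    def test_all_zero_table_rejected(self):
        with pytest.raises(DomainError):
            binary_metrics(BinaryConfusion(0, 0, 0, 0))

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_accuracy_identity(self, cells):
        tp, fp, fn, tn = cells
        if tp + fp + fn + tn == 0 or tp + fn == 0 or tn + fp == 0:
            return
        m = binary_metrics(BinaryConfusion(tp, fp, fn, tn))
        p, n = tp + fn, tn + fp
        assert m.accuracy == pytest.approx((m.sensitivity * p + m.specificity * n) / (p + n))

    def test_confusion_from_scores(self):
        rei = [5.0, 14.0, 20.0, 2.0]
        ahi = [4.0, 20.0, 10.0, 30.0]
        c = binary_confusion(rei, ahi, rei_cutoff=14.0, ahi_cutoff=15.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)


class TestMultiLevelMetrics:
    def test_training_style_matrix(self):
        m = MultiLevelConfusion(((12, 3, 2, 0), (1, 3, 2, 0), (0, 1, 4, 0), (0, 1, 0, 10)))
        res = multilevel_metrics(m)
        assert round_display(res.accuracy) == 74.4
        assert round(res.off_by_shares[0]) == 70
        assert round(res.off_by_shares[1]) == 30
        assert [round(s) for s in res.per_class_sensitivity] == [92, 38, 50, 100]
        assert [round(s) for s in res.per_class_specificity] == [81, 90, 97, 97]

    def test_test_style_matrix(self):
        m = MultiLevelConfusion(((7, 7, 2, 0), (4, 3, 0, 0), (1, 1, 5, 1), (0, 0, 1, 7)))
        res = multilevel_metrics(m)
        assert round_display(res.accuracy) == 56.4
        assert round(res.off_by_shares[0]) == 82
        assert round(res.off_by_shares[1]) == 18

    def test_diagonal_matrix_perfect(self):
        m = MultiLevelConfusion(tuple(tuple(5 if i == j else 0 for j in range(4)) for i in range(4)))
        res = multilevel_metrics(m)
        assert res.accuracy == 100.0
        assert res.off_by_shares == (0.0, 0.0, 0.0)

    def test_off_by_shares_cover_all_misclassifications(self):
        rng = np.random.default_rng(6)
        m = MultiLevelConfusion(tuple(tuple(int(v) for v in row) for row in rng.integers(0, 9, (4, 4))))
        res = multilevel_metrics(m)
        if m.total > np.trace(m.array):
            assert sum(res.off_by_shares) == pytest.approx(100.0)


class TestClassifyByRei:
    @pytest.mark.parametrize(
        "rei, expected",
        [
            (0.0, SeverityClass.NORMAL),
            (8.9, SeverityClass.NORMAL),
            (9.0, SeverityClass.MILD),
            (13.9, SeverityClass.MILD),
            (14.0, SeverityClass.MODERATE),
            (23.9, SeverityClass.MODERATE),
            (24.0, SeverityClass.SEVERE),
        ],
    )
    def test_banding(self, rei, expected):
        assert classify_severity_by_rei(rei) is expected

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            classify_severity_by_rei(-1.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.floats(min_value=0, max_value=80, allow_nan=False),
        b=st.floats(min_value=0, max_value=80, allow_nan=False),
    )
    def test_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert classify_severity_by_rei(lo) <= classify_severity_by_rei(hi)

    def test_multilevel_confusion_builder(self):
        rei = [2.0, 10.0, 15.0, 30.0]
        ahi = [1.0, 10.0, 20.0, 40.0]
        m = multilevel_confusion(rei, ahi)
        assert np.trace(m.array) == 4
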