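import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from methrisk import (compare_auc, nri_idi, pr_curve, roc_curve,
                      screening_metrics, youden_cutoff)


def mann_whitney_auc(scores, labels, weights=None):
    """Brute-force U-statistic AUC: P(score_case > score_control) + 0.5 ties."""
    w = np.ones(len(labels)) if weights is None else np.asarray(weights, float)
    pos = [(s, wi) for s, l, wi in zip(scores, labels, w) if l == 1]
    neg = [(s, wi) for s, l, wi in zip(scores, labels, w) if l == 0]
    num = den = 0.0
    for (sp, wp), (sn, wn) in itertools.product(pos, neg):
        den += wp * wn
        if sp > sn:
            num += wp * wn
        elif sp == sn:
            num += 0.5 * wp * wn
    return num / den


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)

    def test_chance_level(self, rng):
        y = rng.integers(0, 2, 4000)
        roc = roc_curve(rng.random(4000), y)
        assert abs(roc.auc - 0.5) < 0.03

    def test_auc_equals_mann_whitney(self, rng):
        scores = rng.choice(np.linspace(0, 1, 7), 30)  # with ties
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels), abs=1e-12)

    def test_weighted_auc_equals_weighted_mann_whitney(self, rng):
        scores = rng.random(25)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        w = rng.uniform(0.5, 3.0, 25)
        roc = roc_curve(scores, labels, weights=w)
        assert roc.auc == pytest.approx(mann_whitney_auc(scores, labels, w), abs=1e-12)

    def test_matches_sklearn(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert roc_curve(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


class TestPrCurve:
    def test_precision_definition(self):
        """precision = TP / (TP + FP) at each threshold."""
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0])
        recall, precision = pr_curve(scores, labels)
        assert np.allclose(recall, [0.5, 0.5, 1.0, 1.0])
        assert np.allclose(precision, [1.0, 0.5, 2 / 3, 0.5])


class TestCompareAuc:
    def test_self_comparison_p_one(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        assert compare_auc(scores, scores, labels) == 1.0

    def test_null_type_one_error(self, rng):
        """Independent noise added to a common signal: ~5% rejections."""
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            y = rng.integers(0, 2, 150)
            y[:2] = [0, 1]
            base = y + rng.normal(0, 1.5, 150)
            a = base + rng.normal(0, 0.5, 150)
            b = base + rng.normal(0, 0.5, 150)
            if compare_auc(a, b, y) < 0.05:
                rejections += 1
        assert abs(rejections / n_rep - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_detects_known_auc_gap(self, rng):
        """A real discrimination gap is detected most of the time."""
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            y = rng.integers(0, 2, 750)
            y[:2] = [0, 1]
            good = y + rng.normal(0, 0.8, 750)   # AUC ~ 0.81
            poor = y + rng.normal(0, 2.5, 750)   # AUC ~ 0.61
            if compare_auc(good, poor, y) < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.8


class TestYoudenCutoff:
    def test_matches_brute_force(self, rng):
        scores = rng.random(8)
        labels = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        roc = roc_curve(scores, labels)
        cutoff, sens, spec = youden_cutoff(roc)
        best_j = -np.inf
        for thr in scores:
            pred = scores > thr
            s = (pred & (labels == 1)).sum() / (labels == 1).sum()
            sp = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            best_j = max(best_j, s + sp - 1)
        assert sens + spec - 1 == pytest.approx(best_j, abs=1e-12)

    def test_perfect_scores_lowest_cutoff(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        cutoff, sens, spec = youden_cutoff(roc)
        assert sens == 1.0 and spec == 1.0
        # lowest observed threshold achieving J=1 (inclusive >= semantics)
        assert cutoff == pytest.approx(0.8)

    def test_anti_predictive_warns(self, caplog):
        import logging
        roc = roc_curve([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        with caplog.at_level(logging.WARNING, logger="methrisk.metrics"):
            cutoff, sens, spec = youden_cutoff(roc)
        assert sens + spec - 1 <= 0
        assert "not predictive" in caplog.text


class TestScreeningMetrics:
    def test_cohort_worked_example(self):
        """sens 0.804 / spec 0.728 with 102 events and 650 controls."""
        r = screening_metrics(0.804, 0.728, 102, 650)
        assert (r.tp, r.fn, r.tn, r.fp) == (82, 20, 473, 177)
        assert round(100 * r.ppv, 1) == 31.8
        assert round(100 * r.npv, 1) == 95.9
        assert round(100 * r.accuracy, 1) == 73.8
        assert round(100 * r.prevalence, 1) == 13.6

    def test_perfect_test(self):
        r = screening_metrics(1.0, 1.0, 10, 90)
        assert r.ppv == r.npv == r.accuracy == 1.0

    def test_uninformative_test(self):
        r = screening_metrics(0.5, 0.5, 100, 100)
        assert r.ppv == r.npv == r.accuracy == 0.5

    def test_counts_consistent_with_bayes(self, rng):
        """PPV from the report's own counts agrees with the Bayes-rule value
        within rounding (0.5 percentage points)."""
        for _ in range(20):
            sens = rng.uniform(0.3, 0.99)
            spec = rng.uniform(0.3, 0.99)
            r = screening_metrics(sens, spec, 102, 650)
            assert r.tp + r.fn == 102 and r.tn + r.fp == 650
            ppv_counts = r.tp / (r.tp + r.fp)
            npv_counts = r.tn / (r.tn + r.fn)
            assert abs(ppv_counts - r.ppv) < 0.005 + 0.5 / (r.tp + r.fp)
            assert abs(npv_counts - r.npv) < 0.005 + 0.5 / (r.tn + r.fn)


class TestNriIdi:
    def test_identical_models_zero(self, rng):
        pred = rng.random(30)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        rep = nri_idi(pred, pred, y, 0.5)
        assert rep.nri_categorical == 0 and rep.nri_continuous == 0 and rep.idi == 0

    def test_eight_subject_counting_oracle(self):
        """Hand-countable reclassification moves.

        Events (4): base [0.1, 0.3, 0.6, 0.2], new [0.6, 0.2, 0.7, 0.1]
          with cutoff 0.5: up moves = 1 (0.1->0.6), down = 0 -> NRI_e = 1/4
        Non-events (4): base [0.6, 0.4, 0.1, 0.55], new [0.3, 0.5, 0.2, 0.6]
          down = 1 (0.6->0.3), up = 0 -> NRI_ne = 1/4
        """
        base = np.array([0.1, 0.3, 0.6, 0.2, 0.6, 0.4, 0.1, 0.55])
        new = np.array([0.6, 0.2, 0.7, 0.1, 0.3, 0.5, 0.2, 0.6])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        rep = nri_idi(base, new, y, 0.5)
        assert rep.nri_events == pytest.approx(0.25)
        assert rep.nri_nonevents == pytest.approx(0.25)
        assert rep.nri_categorical == pytest.approx(0.5)
        # continuous: events up {0.6,0.7} (2), down {0.2,0.1} (2) -> 0
        # non-events: down {0.3}, up {0.5,0.2,0.6} (3) -> (1-3)/4 = -0.5
        assert rep.nri_continuous == pytest.approx(0.0 + (1 - 3) / 4)
        # IDI = mean event improvement - mean non-event improvement
        d = new - base
        assert rep.idi == pytest.approx(d[:4].mean() - d[4:].mean())

    def test_component_decomposition_sums(self, rng):
        base = rng.random(40)
        new = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        rep = nri_idi(base, new, y, 0.3)
        assert rep.nri_categorical == pytest.approx(rep.nri_events + rep.nri_nonevents)

    def test_label_swap_negates_continuous_nri(self, rng):
        base = rng.random(40)
        new = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        a = nri_idi(base, new, y, 0.5).nri_continuous
        b = nri_idi(base, new, 1 - y, 0.5).nri_continuous
        assert a == pytest.approx(-b)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            nri_idi([0.1, 0.2], [0.2, 0.3], [0, 0], 0.5)
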