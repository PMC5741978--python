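import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from conftest import random_labels
from ksrmkl import evaluation
from ksrmkl.evaluation import (
    ConfusionCounts,
    confusion,
    cross_validate,
    evaluate_scores,
    make_folds,
    metrics,
    roc_auc,
    run_folds,
    threshold_at_specificity,
    topk_retrieval,
)


class TestConfusion:
    def test_direct_count(self):
        c = confusion(
            np.array([1, 1, -1, -1]), np.array([0.9, 0.2, 0.8, 0.1]), 0.5
        )
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_threshold_below_min(self):
        c = confusion(np.array([1, -1]), np.array([0.2, 0.1]), -5.0)
        assert c.FN == 0 and c.TN == 0

    def test_threshold_above_max(self):
        c = confusion(np.array([1, -1]), np.array([0.2, 0.1]), 5.0)
        assert c.TP == 0 and c.FP == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([]), np.array([]), 0.0)


class TestMetrics:
    def test_sensitivity(self):
        r = metrics(ConfusionCounts(TP=9, TN=0, FP=5, FN=1))
        assert r.Sn == pytest.approx(0.9)

    def test_perfect_prediction(self):
        r = metrics(ConfusionCounts(TP=10, TN=20, FP=0, FN=0))
        assert r.Sn == r.Sp == r.Pre == r.F1 == r.MCC == 1.0

    def test_mcc_frozen_value(self):
        # phi coefficient of TP=45, FN=5, TN=90, FP=10
        r = metrics(ConfusionCounts(TP=45, TN=90, FP=10, FN=5))
        assert r.MCC == pytest.approx(0.7825855808712326, abs=1e-9)

    def test_mcc_equals_phi_coefficient(self, rng):
        """MCC must equal the Pearson correlation of the binary
        label/prediction indicator vectors (phi), checked on random
        confusion tables."""
        for _ in range(200):
            y = random_labels(rng, 40)
            pred = random_labels(rng, 40)
            c = confusion(y, pred.astype(float), 0.5)
            phi_input = np.vstack([(y == 1), (pred == 1)]).astype(float)
            with np.errstate(invalid="ignore"):
                phi = np.corrcoef(phi_input)[0, 1]
            if np.isnan(phi):
                continue
            assert metrics(c).MCC == pytest.approx(phi, abs=1e-12)

    def test_degenerate_denominators_zero(self, caplog):
        with caplog.at_level("WARNING"):
            r = metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=5))
        assert r.Pre == 0.0 and r.F1 == 0.0 and r.MCC == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([1, 1, -1, -1])
        *_, auc = roc_auc(y, np.array([0.9, 0.8, 0.2, 0.1]))
        assert auc == 1.0

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 60))
            y = random_labels(rng, n)
            s = rng.normal(size=n)
            *_, auc = roc_auc(y, s)
            u = mannwhitneyu(s[y == 1], s[y == -1]).statistic
            expected = u / ((y == 1).sum() * (y == -1).sum())
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_null_scores_near_half(self, rng):
        y = np.concatenate([np.ones(1000), -np.ones(1000)])
        *_, auc = roc_auc(y, rng.normal(size=2000))
        assert 0.45 <= auc <= 0.55

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.arange(5.0))


class TestThresholdAtSpecificity:
    def test_enumerated_negatives(self):
        """10 negatives scored 0.0..0.9: the chosen threshold leaves
        exactly one negative above it at target 0.9."""
        y = np.array([-1] * 10 + [1] * 2)
        s = np.concatenate([np.arange(10) / 10, [0.85, 0.95]])
        thr, report = threshold_at_specificity(y, s, 0.9)
        assert report.Sp == pytest.approx(0.9)
        assert (s[y == -1] >= thr).sum() == 1

    def test_extreme_target(self):
        y = np.array([1, 1, -1, -1])
        s = np.array([0.4, 0.9, 0.3, 0.8])
        thr, report = threshold_at_specificity(y, s, 0.999)
        assert report.Sp == 1.0

    def test_separable_full_sensitivity(self):
        y = np.array([-1, -1, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        _, report = threshold_at_specificity(y, s, 0.95)
        assert report.Sn == 1.0 and report.Sp == 1.0

    def test_achieves_target_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(12, 80))
            y = random_labels(rng, n)
            s = rng.normal(size=n)
            target = float(rng.uniform(0.5, 0.99))
            _, report = threshold_at_specificity(y, s, target)
            assert report.Sp >= target

    def test_monotone_tradeoff(self, rng):
        y = random_labels(rng, 200)
        s = rng.normal(size=200) + 0.5 * (y == 1)
        sn = [
            threshold_at_specificity(y, s, t)[1].Sn
            for t in (0.99, 0.95, 0.9, 0.8, 0.6)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(sn, sn[1:]))

    def test_no_negatives_rejected(self):
        with pytest.raises(ValueError, match="no negatives"):
            threshold_at_specificity(np.ones(3), np.arange(3.0), 0.9)


class TestTopkRetrieval:
    def test_all_positives_on_top(self):
        y = np.array([1] * 10 + [-1] * 90)
        s = np.concatenate([np.linspace(2, 3, 10), np.linspace(0, 1, 90)])
        rows = topk_retrieval(y, s, (0.20,))
        assert rows[0]["fraction_of_positives"] == 1.0

    def test_full_list(self):
        y = np.array([1, -1, 1, -1])
        rows = topk_retrieval(y, np.arange(4.0), (1.0,))
        assert rows[0]["TP_in_top"] == 2 and rows[0]["fraction_of_positives"] == 1.0

    def test_random_scores_expected_fraction(self, rng):
        y = np.array([1] * 100 + [-1] * 900)
        fractions = [
            topk_retrieval(y, rng.normal(size=1000), (0.10,))[0][
                "fraction_of_positives"
            ]
            for _ in range(50)
        ]
        assert np.mean(fractions) == pytest.approx(0.10, abs=0.02)

    def test_stable_tie_break(self):
        y = np.array([-1, 1, -1, 1])
        rows = topk_retrieval(y, np.zeros(4), (0.25,))
        # first input wins the tie, and it is a negative
        assert rows[0]["TP_in_top"] == 0

    def test_ceiling_rule(self):
        rows = topk_retrieval(np.array([1, -1, -1]), np.arange(3.0), (0.4,))
        assert rows[0]["n_top"] == 2


class TestCrossValidation:
    def test_fold_partition_and_sizes(self):
        y = np.array([1] * 30 + [-1] * 70)
        folds = make_folds(y, 10, seed=0)
        sizes = np.bincount(folds)
        assert sizes.tolist() == [10] * 10
        # stratification: every fold has 3 positives
        for f in range(10):
            assert (y[folds == f] == 1).sum() == 3

    def test_small_class_rejected(self):
        y = np.array([1] * 4 + [-1] * 50)
        with pytest.raises(ValueError, match="smaller k"):
            make_folds(y, 10, seed=0)

    def test_determinism(self, strong_dataset, strong_views):
        cv1 = cross_validate(strong_dataset, strong_views, ("seq", "func"), k=10, seed=7)
        cv2 = cross_validate(strong_dataset, strong_views, ("seq", "func"), k=10, seed=7)
        assert np.array_equal(cv1.fold_assignments, cv2.fold_assignments)
        assert np.array_equal(cv1.scores, cv2.scores)

    def test_seed_changes_folds(self, strong_dataset, strong_views):
        cv1 = cross_validate(strong_dataset, strong_views, ("seq",), k=5, seed=1)
        cv2 = cross_validate(strong_dataset, strong_views, ("seq",), k=5, seed=2)
        assert not np.array_equal(cv1.fold_assignments, cv2.fold_assignments)

    def test_no_leakage_from_test_labels(self, strong_dataset, strong_views):
        """Flipping the labels of one fold's samples cannot change that
        fold's own out-of-fold scores (they never enter its training)."""
        mats = strong_views.matrices(("seq",))
        y = strong_dataset.labels
        folds = make_folds(y, 5, seed=0)
        scores1, _ = run_folds(mats, y, folds, betas=(1.0, 2.0))
        y_flipped = y.copy()
        y_flipped[folds == 0] *= -1
        scores2, _ = run_folds(mats, y_flipped, folds, betas=(1.0, 2.0))
        assert np.allclose(scores1[folds == 0], scores2[folds == 0])
        # sanity: training on flipped labels did change the other folds
        assert not np.array_equal(scores1[folds != 0], scores2[folds != 0])


def test_evaluate_scores_report_structure(strong_dataset, strong_views):
    cv = cross_validate(strong_dataset, strong_views, ("seq", "func"), k=10, seed=0)
    report = evaluate_scores(strong_dataset.labels, cv.scores)
    assert 0 <= report["auc"] <= 1
    for key in ("0.95", "0.90"):
        assert report["at_specificity"][key]["Sp"] >= float(key)
    assert [row["fraction"] for row in report["topk"]] == [
        0.01, 0.02, 0.05, 0.10, 0.20,
    ]
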