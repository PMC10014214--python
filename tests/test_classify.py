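import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import repurbench as rb
from repurbench.classify import UndefinedMetricError

from conftest import pairwise_auroc, random_relevance

# the ten-drug mock ranking: 3 actives in the top five, 1 in the bottom five
MOCK_TEN_DRUG = rb.RelevanceVector((1, 0, 1, 1, 0, 0, 1, 0, 0, 0))
MOCK_COUNTS = rb.ConfusionCounts(TP=3, FP=2, TN=4, FN=1)


class TestConfusionAtCutoff:
    def test_ten_drug_mock_at_cutoff_five(self):
        assert rb.confusion_at_cutoff(MOCK_TEN_DRUG, 5) == MOCK_COUNTS

    def test_cutoff_equal_to_n(self):
        c = rb.confusion_at_cutoff(MOCK_TEN_DRUG, 10)
        assert c.FN == 0
        assert c.FP == 6  # all inactives called positive

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        rel = random_relevance(rng, 40, 11)
        for cutoff in range(1, 41):
            c = rb.confusion_at_cutoff(rel, cutoff)
            assert c.TP == sum(rel.rel[:cutoff])
            assert c.FN == sum(rel.rel[cutoff:])
            assert c.N == rel.N
            assert c.n_actives == rel.n_actives

    def test_out_of_range_cutoff_rejected(self):
        with pytest.raises(ValueError):
            rb.confusion_at_cutoff(MOCK_TEN_DRUG, 0)

    @given(st.integers(1, 10))
    def test_marginals_conserved_at_every_cutoff(self, cutoff):
        c = rb.confusion_at_cutoff(MOCK_TEN_DRUG, cutoff)
        assert c.TP + c.FN == 4
        assert c.TN + c.FP == 6
        assert c.N == 10


class TestPointMetrics:
    def test_mock_example_metric_values(self):
        c = MOCK_COUNTS
        assert rb.sensitivity(c) == 0.75
        assert rb.specificity(c) == pytest.approx(4 / 6)
        assert rb.fdr(c) == pytest.approx(0.4)
        assert rb.fpr(c) == pytest.approx(2 / 6)
        assert rb.precision(c) == pytest.approx(0.6)
        assert rb.accuracy(c) == pytest.approx(0.7)
        assert rb.f1(c) == pytest.approx(2 / 3)

    def test_perfect_classification(self):
        c = rb.ConfusionCounts(TP=4, FP=0, TN=6, FN=0)
        assert rb.sensitivity(c) == rb.specificity(c) == 1.0
        assert rb.precision(c) == rb.accuracy(c) == rb.f1(c) == 1.0
        assert rb.mcc(c) == pytest.approx(1.0)
        assert rb.fdr(c) == 0.0

    def test_all_positive_prediction_on_balanced_data_has_zero_mcc(self):
        c = rb.ConfusionCounts(TP=5, FP=5, TN=0, FN=0)
        with pytest.raises(UndefinedMetricError):
            rb.mcc(c)  # marginal TN+FN = 0
        c = rb.ConfusionCounts(TP=5, FP=5, TN=1, FN=1)
        # near-no-information classifier: MCC 0 by symmetry
        assert rb.mcc(c) == pytest.approx(0.0)

    def test_f1_is_harmonic_mean_of_precision_and_recall(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            tp, fp, tn, fn = rng.integers(1, 30, size=4)
            c = rb.ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
            p, r = rb.precision(c), rb.sensitivity(c)
            assert rb.f1(c) == pytest.approx(2 * p * r / (p + r))
            assert rb.f1(c) <= min(1.0, (p + r) / 2 + 1e-12)

    def test_undefined_denominators_signal_not_zero(self):
        no_actives = rb.ConfusionCounts(TP=0, FP=3, TN=7, FN=0)
        with pytest.raises(UndefinedMetricError):
            rb.sensitivity(no_actives)
        no_inactives = rb.ConfusionCounts(TP=3, FP=0, TN=0, FN=7)
        with pytest.raises(UndefinedMetricError):
            rb.specificity(no_inactives)
        with pytest.raises(UndefinedMetricError):
            rb.fpr(no_inactives)
        nothing_called = rb.ConfusionCounts(TP=0, FP=0, TN=5, FN=5)
        with pytest.raises(UndefinedMetricError):
            rb.precision(nothing_called)
        with pytest.raises(UndefinedMetricError):
            rb.fdr(nothing_called)

    def test_fdr_one_when_only_false_discoveries(self):
        assert rb.fdr(rb.ConfusionCounts(TP=0, FP=4, TN=2, FN=4)) == 1.0

    def test_accuracy_of_empty_prediction_tracks_inactive_ratio(self):
        # the skewed-standard pathology: calling everything negative looks great
        c = rb.ConfusionCounts(TP=0, FP=0, TN=94, FN=6)
        assert rb.accuracy(c) == pytest.approx(0.94)


class TestRocCurve:
    def test_perfect_ranking_has_unit_area(self):
        rel = rb.RelevanceVector((1, 1, 1, 0, 0, 0))
        assert rb.auroc_trapezoid(rel) == pytest.approx(1.0)

    def test_alternating_ranking(self):
        assert rb.auroc_trapezoid(rb.RelevanceVector((1, 0, 1, 0))) == pytest.approx(0.75)

    def test_equals_pairwise_mann_whitney(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            N = int(rng.integers(3, 60))
            n = int(rng.integers(1, N))
            rel = random_relevance(rng, N, n)
            assert rb.auroc_trapezoid(rel) == pytest.approx(
                pairwise_auroc(rel.active_ranks, N), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(12)
        rel = random_relevance(rng, 50, 9)
        y = np.asarray(rel.rel)
        assert rb.auroc_trapezoid(rel) == pytest.approx(
            roc_auc_score(y, -np.arange(rel.N))
        )

    def test_curve_monotone_with_endpoints(self):
        rng = np.random.default_rng(13)
        rel = random_relevance(rng, 30, 10)
        pts = rb.roc_curve(rel)
        assert pts.shape == (31, 2)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError):
            rb.roc_curve(rb.RelevanceVector((1, 1)))


class TestPrCurve:
    def test_all_actives_first(self):
        assert rb.auprc(rb.RelevanceVector((1, 1, 0, 0))) == pytest.approx(1.0)

    def test_single_active_at_bottom(self):
        N = 7
        rel = rb.RelevanceVector((0,) * (N - 1) + (1,))
        assert rb.auprc(rel) == pytest.approx(1 / N)

    def test_auprc_equals_average_precision_on_binary_data(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            N = int(rng.integers(2, 60))
            rel = random_relevance(rng, N, int(rng.integers(1, N + 1)))
            assert rb.auprc(rel) == pytest.approx(rb.average_precision(rel), abs=1e-12)

    def test_curve_shape(self):
        rel = rb.RelevanceVector((1, 0, 1, 0))
        pts = rb.pr_curve(rel)
        assert pts.shape == (4, 2)
        assert pts[0].tolist() == [0.5, 1.0]

    def test_no_actives_rejected(self):
        with pytest.raises(ValueError):
            rb.pr_curve(rb.RelevanceVector((0, 0)))
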