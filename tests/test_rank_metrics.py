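import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import repurbench as rb
from repurbench.rank_metrics import AlphaValidityWarning, EarlyRecognitionInput

from conftest import pairwise_auroc, random_relevance


@st.composite
def rank_instances(draw, max_n=40):
    N = draw(st.integers(2, max_n))
    n = draw(st.integers(1, N - 1))
    ranks = draw(
        st.sets(st.integers(1, N), min_size=n, max_size=n).map(sorted).map(tuple)
    )
    return EarlyRecognitionInput(ranks, N, alpha=20.0)


class TestMRR:
    def test_perfect_and_hand_values(self):
        assert rb.mean_reciprocal_rank([1, 1, 1]) == 1.0
        assert rb.mean_reciprocal_rank([2, 4]) == 0.375

    def test_none_counts_as_zero(self):
        assert rb.mean_reciprocal_rank([1, None]) == 0.5

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            rb.mean_reciprocal_rank([0])

    def test_random_first_ranks_match_harmonic_average(self):
        rng = np.random.default_rng(1)
        N = 100
        ranks = rng.integers(1, N + 1, size=1000)
        expect = np.mean(1.0 / ranks)
        assert rb.mean_reciprocal_rank(ranks.tolist()) == pytest.approx(expect)


class TestPrecisionAtKAndAP:
    def test_p_at_k_examples(self):
        rel = rb.RelevanceVector((1, 0, 1, 0))
        assert rb.precision_at_k(rel, 2) == 0.5
        assert rb.precision_at_k(rel, 4) == rel.n_actives / rel.N

    def test_p_at_k_matches_brute_count(self):
        rng = np.random.default_rng(2)
        rel = random_relevance(rng, 30, 7)
        for k in range(1, 31):
            assert rb.precision_at_k(rel, k) == sum(rel.rel[:k]) / k

    @pytest.mark.parametrize(
        "rel, expect",
        [((1, 1, 0), 1.0), ((0, 1), 0.5), ((1, 0, 1), (1 + 2 / 3) / 2)],
    )
    def test_ap_hand_values(self, rel, expect):
        assert rb.average_precision(rb.RelevanceVector(rel)) == pytest.approx(expect)

    def test_ap_matches_sklearn(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(3)
        for _ in range(20):
            rel = random_relevance(rng, 25, int(rng.integers(1, 25)))
            y = np.asarray(rel.rel)
            scores = -np.arange(rel.N)  # rank 1 highest score
            assert rb.average_precision(rel) == pytest.approx(
                average_precision_score(y, scores)
            )

    def test_ap_without_actives_rejected_and_map_averages(self):
        with pytest.raises(ValueError):
            rb.average_precision(rb.RelevanceVector((0, 0)))
        rels = [rb.RelevanceVector((1, 0)), rb.RelevanceVector((0, 1))]
        assert rb.mean_average_precision(rels) == pytest.approx(0.75)


class TestEnrichmentFactor:
    def test_forced_values(self):
        inp = EarlyRecognitionInput(tuple(range(1, 6)) + (20, 30, 40, 50, 60), 100)
        assert rb.enrichment_factor(inp, 0.1) == pytest.approx(5.0)
        top = EarlyRecognitionInput(tuple(range(1, 11)), 100)
        assert rb.enrichment_factor(top, 0.1) == pytest.approx(10.0)  # N/n maximum

    def test_empty_top_fraction_rejected(self):
        inp = EarlyRecognitionInput((1,), 100)
        with pytest.raises(ValueError, match="k=0"):
            rb.enrichment_factor(inp, 0.001)

    def test_random_expectation_is_one(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(2000):
            ranks = tuple(sorted(rng.choice(np.arange(1, 101), 10, replace=False)))
            vals.append(rb.enrichment_factor(EarlyRecognitionInput(ranks, 100), 0.1))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se


class TestRIEandBEDROC:
    def test_direct_summation_hand_case(self):
        # N=10, n=1, active at rank 1, alpha=20
        inp = EarlyRecognitionInput((1,), 10, alpha=20.0)
        num = math.exp(-20.0 * 0.1)
        denom = (1 / 10) * (1 - math.exp(-20.0)) / (math.exp(2.0) - 1)
        assert rb.rie(inp) == pytest.approx(num / denom)

    def test_rie_max_is_actives_on_top(self):
        lo, hi = rb.rie_bounds(50, 5, alpha=20.0)
        assert rb.rie(EarlyRecognitionInput(tuple(range(1, 6)), 50)) == pytest.approx(hi)
        assert rb.rie(EarlyRecognitionInput(tuple(range(46, 51)), 50)) == pytest.approx(lo)
        assert lo < 1.0 < hi

    def test_matches_rdkit_reference_exactly(self):
        from rdkit.ML.Scoring import Scoring

        rng = np.random.default_rng(5)
        for _ in range(25):
            N = int(rng.integers(20, 200))
            n = int(rng.integers(1, max(2, N // 10)))
            ranks = tuple(sorted(rng.choice(np.arange(1, N + 1), n, replace=False)))
            inp = EarlyRecognitionInput(ranks, N, alpha=20.0)
            table = [[0.0, 1 if r + 1 in set(ranks) else 0] for r in range(N)]
            assert rb.rie(inp) == pytest.approx(
                Scoring.CalcRIE(table, 1, 20.0), rel=1e-12
            )
            # rdkit normalizes BEDROC with continuous bounds; ours are exact
            # finite-N sums, so the two agree only closely, not identically
            assert rb.bedroc(inp) == pytest.approx(
                Scoring.CalcBEDROC(table, 1, 20.0), abs=5e-3
            )

    def test_mean_rie_is_one_under_random_ranking(self):
        rng = np.random.default_rng(6)
        vals = [
            rb.rie(EarlyRecognitionInput(
                tuple(sorted(rng.choice(np.arange(1, 101), 10, replace=False))), 100))
            for _ in range(2000)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1.0) < 3 * se

    def test_bedroc_bounds_are_exact(self):
        top = EarlyRecognitionInput(tuple(range(1, 11)), 100)
        bottom = EarlyRecognitionInput(tuple(range(91, 101)), 100)
        assert rb.bedroc(top) == pytest.approx(1.0)
        assert rb.bedroc(bottom) == pytest.approx(0.0)

    def test_mean_bedroc_under_random_matches_expectation(self):
        # E[RIE] = 1 implies E[BEDROC] = (1 - RIEmin) / (RIEmax - RIEmin)
        rng = np.random.default_rng(7)
        lo, hi = rb.rie_bounds(100, 10, 20.0)
        expect = (1.0 - lo) / (hi - lo)
        vals = [
            rb.bedroc(EarlyRecognitionInput(
                tuple(sorted(rng.choice(np.arange(1, 101), 10, replace=False))), 100))
            for _ in range(2000)
        ]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expect) < 3 * se

    def test_validity_warning_when_alpha_ra_large(self):
        with pytest.warns(AlphaValidityWarning):
            rb.bedroc(EarlyRecognitionInput(tuple(range(1, 6)), 10, alpha=20.0))

    def test_degenerate_all_actives_rejected(self):
        with pytest.raises(ValueError):
            rb.rie(EarlyRecognitionInput((1, 2), 2))

    @given(rank_instances())
    def test_bedroc_bounded_and_rie_positive(self, inp):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AlphaValidityWarning)
            b = rb.bedroc(inp)
        assert 0.0 <= b <= 1.0
        assert rb.rie(inp) > 0.0


class TestAurocRankFormula:
    def test_hand_case_with_discrete_correction(self):
        inp = EarlyRecognitionInput((1, 2), 10)
        assert rb.auroc_rank_formula(inp) == pytest.approx(0.9375)
        assert rb.auroc_rank_formula(inp, exact=True) == pytest.approx(1.0)

    def test_uniform_quantile_actives_near_half(self):
        inp = EarlyRecognitionInput((10, 30, 50, 70, 90), 100)
        assert rb.auroc_rank_formula(inp, exact=True) == pytest.approx(
            pairwise_auroc(inp.active_ranks, inp.N)
        )
        assert abs(rb.auroc_rank_formula(inp) - 0.5) < 0.01

    def test_exact_form_equals_pairwise_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            N = int(rng.integers(5, 400))
            n = int(rng.integers(1, N))
            ranks = tuple(sorted(rng.choice(np.arange(1, N + 1), n, replace=False)))
            inp = EarlyRecognitionInput(ranks, N)
            assert rb.auroc_rank_formula(inp, exact=True) == pytest.approx(
                pairwise_auroc(ranks, N), abs=1e-12
            )


class TestNDCG:
    def test_single_active_at_rank_one(self):
        rel = rb.RelevanceVector((1, 0, 0))
        assert rb.dcg(rel, 1) == 1.0
        assert rb.ndcg(rel, 1) == 1.0

    def test_hand_evaluation(self):
        rel = rb.RelevanceVector((1, 0, 1))
        assert rb.dcg(rel, 3) == pytest.approx(1.5)
        assert rb.idcg(rel, 3) == pytest.approx(1 + 1 / math.log2(3))
        assert rb.ndcg(rel, 3) == pytest.approx(1.5 / (1 + 1 / math.log2(3)))

    def test_actives_on_top_give_one_at_any_p(self):
        rel = rb.RelevanceVector((1, 1, 1, 0, 0, 0, 0))
        for p in range(1, 8):
            assert rb.ndcg(rel, p) == pytest.approx(1.0)

    def test_no_actives_defined_as_zero(self):
        assert rb.ndcg(rb.RelevanceVector((0, 0)), 2) == 0.0

    def test_graded_relevance_prefers_best_first(self):
        good = rb.RelevanceVector((2, 1, 0))
        flipped = rb.RelevanceVector((1, 2, 0))
        assert rb.ndcg(good, 3) == pytest.approx(1.0)
        assert rb.ndcg(flipped, 3) < 1.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            rb.ndcg(rb.RelevanceVector((1, 0)), 3)

    @given(rank_instances(max_n=25), st.integers(1, 25))
    def test_bounded_in_unit_interval(self, inp, p):
        rel = np.zeros(inp.N, dtype=int)
        rel[np.asarray(inp.active_ranks) - 1] = 1
        v = rb.ndcg(rb.RelevanceVector(tuple(rel)), min(p, inp.N))
        assert 0.0 <= v <= 1.0


class TestPermutationInvariance:
    def test_metrics_ignore_inactive_shuffles_below_actives(self):
        # two lists with identical active positions, inactives permuted
        a = rb.RelevanceVector((0, 1, 0, 0, 1, 0))
        inp = EarlyRecognitionInput.from_relevance(a)
        same = EarlyRecognitionInput((2, 5), 6)
        assert rb.rie(inp) == rb.rie(same)
        assert rb.auroc_rank_formula(inp) == rb.auroc_rank_formula(same)
        assert rb.average_precision(a) == rb.average_precision(
            rb.RelevanceVector((0, 1, 0, 0, 1, 0))
        )
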