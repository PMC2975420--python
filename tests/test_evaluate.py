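import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airnet.evaluate import (
    EvaluationResult,
    aupr,
    auroc,
    average_scores,
    combined_score,
    empirical_pvalues,
    evaluate_network,
    rank_predictions,
)
from airnet.exceptions import ParameterError, UndefinedValueError
from airnet.influence import influence_matrix
from airnet.io import GoldStandard
from conftest import make_discrete
from oracles import sweep_aupr, sweep_auroc


def _gold(positives, universe):
    return GoldStandard(
        frozenset(frozenset(p) for p in positives), frozenset(universe)
    )


def _ranking(labels):
    """Build a strict ranking over synthetic pairs with given relevance."""
    universe = [f"g{i}" for i in range(len(labels) + 1)]
    pairs = [(universe[i], universe[i + 1]) for i in range(len(labels))]
    gold = _gold(
        [pairs[i] for i, lab in enumerate(labels) if lab], universe
    )
    return pairs, gold


class TestRankPredictions:
    def test_sorted_by_abs_v_with_lex_ties(self):
        d = make_discrete(
            {"A": [0, 1, 0, 1], "B": [0, 1, 0, 1], "C": [1, 0, 1, 0]}
        )
        im = influence_matrix(d, keep_tallies=False)
        ranking = rank_predictions(im)
        assert len(ranking) == 3
        vs = [abs(im.value(a, b)) for a, b in ranking]
        assert vs == sorted(vs, reverse=True)

    def test_all_equal_full_lexicographic(self):
        d = make_discrete({"C": [0, 1], "A": [0, 1], "B": [0, 1]})
        ranking = rank_predictions(influence_matrix(d, keep_tallies=False))
        assert ranking == [("A", "B"), ("A", "C"), ("B", "C")]


class TestAurocAupr:
    def test_perfect_ranking(self):
        pairs, gold = _ranking([1, 1, 0, 0])
        assert auroc(pairs, gold) == 1.0
        assert aupr(pairs, gold) == 1.0

    def test_inverted_ranking(self):
        pairs, gold = _ranking([0, 0, 1, 1])
        assert auroc(pairs, gold) == 0.0

    def test_alternating_ranking(self):
        pairs, gold = _ranking([1, 0, 1, 0])
        assert auroc(pairs, gold) == pytest.approx(0.75)
        assert aupr(pairs, gold) == pytest.approx((1 + 2 / 3) / 2)

    def test_single_positive_ranked_first(self):
        pairs, gold = _ranking([1, 0, 0, 0, 0])
        assert aupr(pairs, gold) == 1.0

    def test_degenerate_gold_rejected(self):
        pairs, gold = _ranking([1, 1, 0])
        with pytest.raises(UndefinedValueError):
            auroc(pairs, _gold([], gold.universe))
        all_pos = _gold([tuple(sorted(p)) for p in pairs], gold.universe)
        with pytest.raises(UndefinedValueError):
            auroc(pairs, all_pos)

    def test_tied_scores_trapezoid(self):
        # two positives and two negatives all sharing one score -> 0.5
        pairs, gold = _ranking([1, 0, 1, 0])
        scored = [(p, 1.0) for p in pairs]
        assert auroc(scored, gold) == pytest.approx(0.5)

    @pytest.mark.parametrize(
        "labels",
        [
            list(labels)
            for n in range(2, 9)
            for labels in itertools.product([0, 1], repeat=n)
            if 0 < sum(labels) < n
        ][::7],  # thin the exhaustive set to keep runtime modest
    )
    def test_matches_confusion_sweep_oracle(self, labels):
        pairs, gold = _ranking(labels)
        assert auroc(pairs, gold) == pytest.approx(sweep_auroc(labels))
        assert aupr(pairs, gold) == pytest.approx(sweep_aupr(labels))

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=40, deadline=None)
    def test_reversal_complements_auroc(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 10))
        labels = rng.integers(0, 2, size=n).tolist()
        if not 0 < sum(labels) < n:
            labels[0], labels[-1] = 1, 0
        pairs, gold = _ranking(labels)
        rev_pairs, rev_gold = _ranking(labels[::-1])
        assert auroc(pairs, gold) + auroc(rev_pairs, rev_gold) == pytest.approx(1.0)


class TestEmpiricalPvalues:
    def test_observed_above_all_nulls(self):
        auroc_p, aupr_p = empirical_pvalues(
            1.1, 1.1, n_candidates=20, n_positives=5, n_null=999, seed=0
        )
        assert auroc_p == aupr_p == 1 / 1000

    def test_observed_below_all_nulls(self):
        auroc_p, aupr_p = empirical_pvalues(
            -0.1, -0.1, n_candidates=20, n_positives=5, n_null=99, seed=0
        )
        assert auroc_p == aupr_p == 1.0

    def test_median_observed_near_half(self):
        # the null AUROC distribution is symmetric around 0.5
        n_null = 4000
        auroc_p, _ = empirical_pvalues(
            0.5, 0.0, n_candidates=45, n_positives=10, n_null=n_null, seed=3
        )
        se = math.sqrt(0.25 / n_null)
        assert abs(auroc_p - 0.5) < 3 * se + 1 / n_null

    def test_seed_reproducibility(self):
        a = empirical_pvalues(0.7, 0.3, 45, 10, n_null=500, seed=11)
        b = empirical_pvalues(0.7, 0.3, 45, 10, n_null=500, seed=11)
        assert a == b

    def test_null_auroc_mean_is_half(self):
        from airnet.evaluate import _null_metrics

        rng = np.random.default_rng(5)
        aurocs, _ = _null_metrics(45, 10, 3000, rng)
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.02)

    def test_null_means_match_exact_enumeration(self):
        # exact expectations by enumerating every placement of 2 positives
        # among 6 candidates (all equally likely under a random ranking)
        from airnet.evaluate import _null_metrics

        exact_auroc, exact_aupr = [], []
        for positions in itertools.combinations(range(6), 2):
            labels = [1 if i in positions else 0 for i in range(6)]
            exact_auroc.append(sweep_auroc(labels))
            exact_aupr.append(sweep_aupr(labels))
        rng = np.random.default_rng(8)
        aurocs, auprs = _null_metrics(6, 2, 20_000, rng)
        se_auroc = np.std(exact_auroc) / math.sqrt(20_000)
        se_aupr = np.std(exact_aupr) / math.sqrt(20_000)
        assert np.mean(aurocs) == pytest.approx(
            np.mean(exact_auroc), abs=4 * se_auroc
        )
        assert np.mean(auprs) == pytest.approx(
            np.mean(exact_aupr), abs=4 * se_aupr
        )


class TestCombinedScore:
    @pytest.mark.parametrize(
        "auroc_p,aupr_p,expected",
        [
            (5.0578e-01, 8.5675e-03, 1.1816),
            (5.5198e-02, 4.1550e-05, 2.8198),
            (9.3634e-04, 5.2984e-26, 14.152),
            (1.4694e-05, 1.0263e-71, 37.911),
            (0.1, 0.1, 1.0),
        ],
    )
    def test_published_score_identities(self, auroc_p, aupr_p, expected):
        got = combined_score(auroc_p, aupr_p)
        assert got == pytest.approx(expected, rel=5e-4)

    @pytest.mark.parametrize(
        "auroc_p,aupr_p,expected",
        [
            # every remaining published (AUROC_p, AUPR_p, score) triple
            (2.5279e-01, 2.1759e-03, 1.6298),
            (9.0845e-02, 3.6441e-04, 2.2401),
            (4.9687e-01, 2.6065e-05, 2.4438),
            (7.3901e-01, 6.1865e-06, 2.6700),
            (7.4297e-01, 7.7215e-06, 2.6207),
            (5.0297e-01, 6.8572e-11, 5.2312),
            (4.6923e-01, 4.7395e-08, 3.8264),
            (4.1762e-01, 6.3523e-11, 5.2881),
        ],
    )
    def test_remaining_published_rows(self, auroc_p, aupr_p, expected):
        assert combined_score(auroc_p, aupr_p) == pytest.approx(expected, rel=5e-4)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ParameterError):
            combined_score(0.0, 0.5)


class TestAverageScores:
    def _result(self, auroc_p, aupr_p):
        return EvaluationResult(
            auroc=0.7,
            aupr=0.4,
            auroc_p=auroc_p,
            aupr_p=aupr_p,
            score=combined_score(auroc_p, aupr_p),
            n_null=100,
        )

    def test_single_result_identity(self):
        r = self._result(0.2, 0.01)
        avg = average_scores([r])
        assert avg.auroc_p == r.auroc_p
        assert avg.score == pytest.approx(r.score)

    def test_mean_of_pvalues(self):
        avg = average_scores([self._result(0.2, 0.1), self._result(0.4, 0.3)])
        assert avg.auroc_p == pytest.approx(0.3)
        assert avg.aupr_p == pytest.approx(0.2)
        assert avg.score == pytest.approx(combined_score(0.3, 0.2))

    def test_identical_pvalues_fixed_point(self):
        results = [self._result(0.05, 0.02)] * 5
        assert average_scores(results).score == pytest.approx(
            combined_score(0.05, 0.02)
        )

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            average_scores([])


class TestEvaluateNetwork:
    def test_fields_consistent(self):
        pairs, gold = _ranking([1, 1, 0, 0, 1, 0])
        res = evaluate_network(pairs, gold, n_null=200, seed=1)
        assert res.score == pytest.approx(
            combined_score(res.auroc_p, res.aupr_p)
        )
        assert res.n_null == 200
        assert 0 < res.auroc_p <= 1 and 0 < res.aupr_p <= 1
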