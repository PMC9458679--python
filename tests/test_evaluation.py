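"""AUC/ROC against pair-counting oracles; resampling scheme properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mefv_origins.evaluation import (
    auc,
    bootstrap_evaluate,
    kfold_evaluate,
    rank_countries,
    roc_curve,
    _evaluate_split,
    EvaluationReport,
)
from mefv_origins.logistic_model import FeatureTable


def pair_counting_auc(scores, labels):
    """Independent oracle: exhaustive positive-negative pair comparison."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            wins += p > q
            ties += p == q
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        assert auc([0.3] * 6, [0, 1, 0, 1, 0, 1]) == pytest.approx(0.5)

    def test_perfect_prediction_gives_one(self):
        assert auc([0, 1, 0, 1], [0, 1, 0, 1]) == pytest.approx(1.0)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False).map(lambda v: round(v, 2)),
                st.integers(0, 1),
            ),
            min_size=2,
            max_size=50,
        ).filter(lambda d: len({y for _, y in d}) == 2)
    )
    def test_matches_exhaustive_pair_counting(self, data):
        scores = [s for s, _ in data]
        labels = [y for _, y in data]
        assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        base = auc(scores, labels)
        assert auc(np.exp(5 * scores), labels) == pytest.approx(base)
        assert auc(np.log(scores + 1e-9), labels) == pytest.approx(base)


class TestRoc:
    def test_two_subjects_three_points(self):
        points = roc_curve([0.2, 0.9], [0, 1])
        assert points.shape == (3, 2)
        np.testing.assert_allclose(points, [[0, 0], [0, 1], [1, 1]])

    def test_starts_at_origin_ends_at_one_one_and_is_monotone(self):
        rng = np.random.default_rng(1)
        scores = np.round(rng.random(60), 1)  # force ties
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        pts = roc_curve(scores, labels)
        np.testing.assert_allclose(pts[0], [0, 0])
        np.testing.assert_allclose(pts[-1], [1, 1])
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_trapezoid_area_equals_auc(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(50), 1)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        pts = roc_curve(scores, labels)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc(scores, labels), abs=1e-12)


def _random_feature_table(n=100, p=4, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.random((n, p)), columns=[f"c{j}" for j in range(p)])
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    return FeatureTable(X, y)


class TestKFold:
    def test_folds_partition_the_rows(self):
        table = _random_feature_table(n=100)
        report = kfold_evaluate(table, k=10, seed=0)
        assert report.n_resamples == 10
        # every row scored exactly once across held-out parts
        assert len(report.pooled_labels) == 100
        assert report.skipped == 0

    def test_same_seed_is_deterministic(self):
        table = _random_feature_table(n=120, seed=4)
        a = kfold_evaluate(table, k=10, seed=11)
        b = kfold_evaluate(table, k=10, seed=11)
        assert a.aucs == b.aucs
        pd.testing.assert_frame_equal(a.coef, b.coef)

    def test_permuted_labels_score_near_half(self):
        """Null behavior: with labels carrying no signal, cross-validated
        AUC stays near 0.5."""
        rng = np.random.default_rng(42)
        n = 500
        X = pd.DataFrame(rng.random((n, 5)), columns=list("abcde"))
        y = rng.permutation(np.r_[np.zeros(n // 2), np.ones(n - n // 2)]).astype(int)
        report = kfold_evaluate(FeatureTable(X, y), k=10, seed=0)
        assert 0.4 <= report.mean_auc <= 0.6

    def test_n_smaller_than_k_is_an_error(self):
        with pytest.raises(ValueError, match="at least"):
            kfold_evaluate(_random_feature_table(n=5), k=10)

    def test_stratified_folds_balance_classes(self):
        table = _random_feature_table(n=100, seed=2)
        report = kfold_evaluate(table, k=10, seed=0, stratified=True)
        assert report.skipped == 0 and report.n_resamples == 10


class TestBootstrap:
    def test_mean_out_of_bag_size_matches_expectation(self):
        """E[oob size] = n (1 - 1/n)^n ~ n/e."""
        n, B = 100, 200
        table = _random_feature_table(n=n, seed=1)
        report = bootstrap_evaluate(table, B=B, seed=0)
        assert report.skipped == 0
        mean_oob = len(report.pooled_labels) / B
        expected = n * (1 - 1 / n) ** n  # ~36.6
        sd = np.sqrt(n * (1 - 1 / n) ** n * (1 - (1 - 1 / n) ** n))
        assert abs(mean_oob - expected) < 3 * sd / np.sqrt(B)

    def test_same_seed_is_deterministic(self):
        table = _random_feature_table(n=60, seed=5)
        a = bootstrap_evaluate(table, B=25, seed=3)
        b = bootstrap_evaluate(table, B=25, seed=3)
        assert a.aucs == b.aucs and a.skipped == b.skipped

    def test_degenerate_replicates_are_skipped_and_counted(self):
        table = _random_feature_table(n=30, seed=6)
        n = table.n
        # an all-in-bag replicate has an empty out-of-bag set: skipped
        assert _evaluate_split(table, np.arange(n), np.array([], dtype=int), {}) is None
        # a single-class out-of-bag set is likewise skipped
        pos = np.flatnonzero(table.labels == 1)
        rest = np.setdiff1d(np.arange(n), pos[:1])
        assert (
            _evaluate_split(table, rest, pos[:1], {}) is None
        )
        report = bootstrap_evaluate(table, B=40, seed=0)
        assert len(report.aucs) + report.skipped == 40


class TestRanking:
    def _report(self, coef_rows):
        coef = pd.DataFrame(coef_rows)
        return EvaluationReport(
            scheme="kfold",
            params={},
            seed=0,
            aucs=(0.7,) * len(coef_rows),
            skipped=0,
            coef=coef,
            pooled_scores=np.empty(0),
            pooled_labels=np.empty(0),
        )

    def test_sorting_and_group_ends(self):
        report = self._report(
            [{"(intercept)": 0.1, "sex": 9.0, "A": 2.0, "B": -1.0, "C": 0.5, "D": 0.1, "E": -0.3}]
        )
        ranking = rank_countries(report)
        assert ranking.top(4) == ("A", "C", "D", "E")
        assert ranking.bottom(4) == ("B", "E", "D", "C")
        assert "sex" not in dict(ranking.entries)

    def test_mean_is_over_resamples(self):
        report = self._report([{"A": 1.0, "B": 0.0}, {"A": 0.0, "B": 2.0}])
        ranking = rank_countries(report, exclude=())
        assert dict(ranking.entries) == {"A": 0.5, "B": 1.0}
        assert ranking.top(1) == ("B",)

    def test_ties_break_lexicographically(self):
        report = self._report([{"B": 1.0, "A": 1.0, "C": 1.0}])
        ranking = rank_countries(report, exclude=())
        assert [c for c, _ in ranking.entries] == ["A", "B", "C"]

    def test_zero_successful_resamples_is_an_error(self):
        empty = EvaluationReport(
            "kfold", {}, 0, (), 5, pd.DataFrame(), np.empty(0), np.empty(0)
        )
        with pytest.raises(ValueError, match="no successful"):
            rank_countries(empty)
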