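"""IRLS logistic regression against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from mefv_origins.logistic_model import (
    FeatureTable,
    fit_logistic,
    make_feature_table,
    predict_proba,
)


def _table(x, y, name="x"):
    return FeatureTable(pd.DataFrame({name: x}), np.asarray(y))


def test_label_independent_of_feature_gives_zero_fit():
    fit = fit_logistic(_table([0, 0, 1, 1], [0, 1, 0, 1]), penalty="none")
    assert fit.converged
    assert fit.intercept == pytest.approx(0.0, abs=1e-7)
    assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-7)


def test_unpenalized_fit_matches_closed_form_log_odds():
    """On 2x2-structured data the MLE is the log odds ratio of the table."""
    # x=1: 3 of 4 positive; x=0: 1 of 4 positive
    x = [1, 1, 1, 1, 0, 0, 0, 0]
    y = [1, 1, 1, 0, 1, 0, 0, 0]
    fit = fit_logistic(_table(x, y), penalty="none")
    assert fit.converged
    assert fit.coefficients["x"] == pytest.approx(np.log(9.0), abs=1e-6)
    assert fit.intercept == pytest.approx(np.log(1 / 3), abs=1e-6)


@pytest.mark.parametrize("lam", [0.5, 1.0, 4.0])
@pytest.mark.parametrize("seed", [0, 1])
def test_ridge_fit_matches_brute_force_maximizer(random_table, lam, seed):
    """The IRLS optimum agrees with an independent numerical maximizer of
    the penalized Bernoulli log-likelihood to 1e-6 per coefficient."""
    table = random_table(n=30, p=3, seed=seed, signal=2.0)
    fit = fit_logistic(table, penalty="ridge", lam=lam)
    X = table.features.to_numpy()
    y = table.labels

    def neg_pen_loglik(beta):
        eta = beta[0] + X @ beta[1:]
        return -(y @ eta - np.logaddexp(0, eta).sum()) + 0.5 * lam * beta[1:] @ beta[1:]

    ref = minimize(neg_pen_loglik, np.zeros(4), method="BFGS", tol=1e-12)
    assert fit.intercept == pytest.approx(ref.x[0], abs=1e-6)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.x[1:], atol=1e-6)


def test_ridge_fit_matches_sklearn():
    """Independent cross-check: scikit-learn's L2 logistic regression with
    C = 1/lam solves the same objective."""
    sklearn = pytest.importorskip("sklearn.linear_model")
    rng = np.random.default_rng(7)
    X = pd.DataFrame(rng.random((120, 4)), columns=list("abcd"))
    y = (rng.random(120) < expit(2 * X["a"] - 1)).astype(int)
    fit = fit_logistic(FeatureTable(X, y), penalty="ridge", lam=1.0)
    ref = sklearn.LogisticRegression(C=1.0, tol=1e-10, max_iter=5000)
    ref.fit(X.to_numpy(), y)
    assert fit.intercept == pytest.approx(ref.intercept_[0], abs=1e-5)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), ref.coef_[0], atol=1e-5)


def test_fit_is_invariant_to_row_order(random_table):
    table = random_table(n=50, p=3, seed=3, signal=1.0)
    perm = np.random.default_rng(0).permutation(table.n)
    fit_a = fit_logistic(table)
    fit_b = fit_logistic(table.take(perm))
    assert fit_a.intercept == pytest.approx(fit_b.intercept, abs=1e-9)
    np.testing.assert_allclose(
        fit_a.coefficients.to_numpy(), fit_b.coefficients.to_numpy(), atol=1e-9
    )


def test_perfect_separation_without_penalty_is_flagged():
    with pytest.warns(UserWarning, match="separation"):
        fit = fit_logistic(_table([0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1]), penalty="none")
    assert not fit.converged
    # ridge restores a finite, converged optimum
    assert fit_logistic(_table([0, 0, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1])).converged


def test_single_class_labels_are_an_error():
    with pytest.raises(ValueError, match="single-class"):
        fit_logistic(_table([0, 1, 0], [1, 1, 1]))


def test_constant_column_is_fitted_with_a_warning(random_table):
    table = random_table(n=30, p=2, seed=5)
    X = table.features.assign(flat=0.0)
    with pytest.warns(UserWarning, match="constant"):
        fit = fit_logistic(FeatureTable(X, table.labels))
    base = fit_logistic(table)
    # the all-zero column cannot move any prediction
    np.testing.assert_allclose(
        predict_proba(fit, X), predict_proba(base, table.features), atol=1e-8
    )


class TestPredictProba:
    def test_zero_model_predicts_half(self):
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_logistic(_table([0.0] * 6, [0, 1, 0, 1, 0, 1]), penalty="none")
        probs = predict_proba(fit, pd.DataFrame({"x": [0.0, 0.0]}))
        np.testing.assert_allclose(probs, 0.5, atol=1e-9)

    def test_large_intercept_saturates_to_one(self):
        fit = fit_logistic(_table([0, 1, 0, 1], [0, 1, 1, 0]), penalty="none")
        from mefv_origins.logistic_model import FitResult

        saturated = FitResult(30.0, fit.coefficients * 0, True, 0, "none", 0.0)
        probs = predict_proba(saturated, pd.DataFrame({"x": [0.3]}))
        assert probs[0] == pytest.approx(1.0, abs=1e-9)

    def test_agrees_with_direct_sigmoid_recomputation(self, random_table):
        table = random_table(n=40, p=3, seed=9, signal=1.5)
        fit = fit_logistic(table)
        probs = predict_proba(fit, table.features)
        manual = expit(
            fit.intercept + table.features.to_numpy() @ fit.coefficients.to_numpy()
        )
        np.testing.assert_allclose(probs, manual, atol=1e-12)
        assert ((probs > 0) & (probs < 1)).all()

    def test_feature_mismatch_is_an_error(self, random_table):
        table = random_table(n=20, p=2, seed=1)
        fit = fit_logistic(table)
        with pytest.raises(ValueError, match="do not match"):
            predict_proba(fit, table.features.rename(columns={"f0": "other"}))


def test_make_feature_table_encodes_sex_and_outcome(paper_sim):
    from mefv_origins.genotype_summary import modeling_subset
    from mefv_origins.origin_score import build_matrix, filter_countries

    cohort, _ = paper_sim
    matrix, _ = build_matrix(cohort)
    matrix, _ = filter_countries(matrix)
    sub = modeling_subset(cohort)
    table = make_feature_table(sub, matrix, "M694V", outcome="carrier")
    assert "sex" in table.features.columns
    assert set(np.unique(table.features["sex"])) <= {0.0, 1.0}
    hmz = make_feature_table(sub, matrix, "M694V", outcome="homozygous")
    assert hmz.labels.sum() < table.labels.sum()  # homozygotes are a subset
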