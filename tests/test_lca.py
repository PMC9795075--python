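"""EM correctness, fit indices, model selection and class labeling."""

import numpy as np
import pytest

from pitchlca import (
    LatentClassAnalysis,
    ResponseMatrix,
    fit_indices,
    fit_lca,
    loglikelihood,
    n_parameters,
    select_model,
)
from pitchlca.datasets import load_fit_indices
from pitchlca.lca import aic_delta_report, posterior_entropy

from conftest import random_small_matrix


def brute_force_loglik(Y, cats, priors, probs):
    """Direct summation over classes per observation (linear domain)."""
    total = 0.0
    for i in range(Y.shape[0]):
        like = 0.0
        for r, p in enumerate(priors):
            term = p
            for j in range(Y.shape[1]):
                k = list(cats[j]).index(Y[i, j])
                term *= probs[j][r][k]
            like += term
        total += np.log(like)
    return total


def random_params(rng, J, R, Kj):
    priors = rng.dirichlet(np.ones(R))
    probs = np.zeros((J, R, max(Kj)))
    for j in range(J):
        for r in range(R):
            probs[j, r, :Kj[j]] = rng.dirichlet(np.ones(Kj[j]))
    return priors, probs


class TestLoglikelihood:
    def test_single_class_reduces_to_sum_of_logs(self):
        m = ResponseMatrix([[1, 2], [2, 1]])
        probs = np.zeros((2, 1, 2))
        probs[:, 0, :] = [0.3, 0.7]
        expected = np.log(0.3) + np.log(0.7) + np.log(0.7) + np.log(0.3)
        assert loglikelihood(m, [1.0], probs) == pytest.approx(expected, abs=1e-12)

    def test_two_class_single_item_closed_form(self):
        m = ResponseMatrix(np.array([[1], [2]]))
        probs = np.zeros((1, 2, 2))
        probs[0, 0] = [0.2, 0.8]
        probs[0, 1] = [0.8, 0.2]
        # obs y=1: 0.5*0.2 + 0.5*0.8 = 0.5; obs y=2 symmetric
        ll = loglikelihood(m, [0.5, 0.5], probs)
        assert ll == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_matches_direct_summation_on_100_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            N = rng.integers(2, 7)
            J = rng.integers(1, 4)
            R = rng.integers(1, 4)
            m = random_small_matrix(rng, N=N, J=J, K=int(rng.integers(2, 5)))
            cats = m.column_categories
            priors, probs = random_params(rng, m.J, R, m.Kj)
            fast = loglikelihood(m, priors, probs)
            slow = brute_force_loglik(m.Y, cats, priors, probs)
            assert fast == pytest.approx(slow, abs=1e-12)

    def test_no_underflow_for_tiny_probabilities(self):
        m = ResponseMatrix(np.vstack([np.ones(30, int), np.full(30, 2)]))
        probs = np.zeros((30, 1, 2))
        probs[:, 0, 0] = 1e-300
        probs[:, 0, 1] = 1 - 1e-300
        ll = loglikelihood(m, [1.0], probs)
        assert np.isfinite(ll)
        assert ll == pytest.approx(30 * np.log(1e-300), rel=1e-9)

    def test_dimension_mismatch_raises(self):
        m = ResponseMatrix([[1, 2], [2, 1]])
        with pytest.raises(ValueError):
            loglikelihood(m, [1.0], np.ones((3, 1, 2)))


class TestEMFitting:
    def test_single_class_mle_is_empirical_frequencies(self):
        rng = np.random.default_rng(5)
        m = random_small_matrix(rng, N=40, J=4, K=3)
        fit = fit_lca(m, 1, n_restarts=2, seed=0)
        for j, cat in enumerate(m.column_categories):
            emp = [np.mean(m.Y[:, j] == c) for c in cat]
            assert np.allclose(fit.class_probs_[j, 0, :len(cat)], emp, atol=1e-9)
        assert fit.priors_[0] == pytest.approx(1.0)

    def test_perfectly_separated_patterns_recovered_exactly(self):
        Y = np.vstack([np.tile([1, 2, 1, 2], (10, 1)),
                       np.tile([2, 1, 2, 1], (10, 1))])
        fit = fit_lca(ResponseMatrix(Y), 2, n_restarts=5, seed=1)
        assert np.allclose(fit.priors_, [0.5, 0.5], atol=1e-6)
        # class-conditional probabilities converge to the indicator profiles
        assert np.all(np.max(fit.class_probs_, axis=2) > 1 - 1e-6)
        assert fit.entropy_ == pytest.approx(0.0, abs=1e-6)

    def test_loglik_is_monotone_within_restart(self, small_matrix):
        fit = fit_lca(small_matrix, 3, n_restarts=3, seed=2)
        h = np.array(fit.loglik_history_)
        assert np.all(np.diff(h) >= -1e-9)

    def test_simplex_constraints_hold_after_fit(self, small_matrix):
        fit = fit_lca(small_matrix, 3, n_restarts=3, seed=3)
        assert fit.priors_.sum() == pytest.approx(1.0, abs=1e-12)
        sums = fit.class_probs_.sum(axis=2)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert np.allclose(fit.posterior_.sum(axis=1), 1.0, atol=1e-12)

    def test_canonical_order_is_descending_share(self, small_matrix):
        fit = fit_lca(small_matrix, 3, n_restarts=3, seed=4)
        assert np.all(np.diff(fit.priors_) <= 1e-12)

    def test_reported_loglik_matches_formula_evaluation(self, small_matrix):
        fit = fit_lca(small_matrix, 2, n_restarts=3, seed=5)
        ll = loglikelihood(small_matrix, fit.priors_, fit.class_probs_)
        assert ll == pytest.approx(fit.loglik_, abs=1e-8)

    def test_em_never_beaten_by_random_search_on_enumerable_data(self):
        """All 16 binary datasets with N=2, J=2: the EM optimum dominates
        1,000 random parameter draws."""
        rng = np.random.default_rng(99)
        for bits in range(16):
            Y = np.array([[1 + (bits >> b) % 2 for b in range(2)],
                          [1 + (bits >> (b + 2)) % 2 for b in range(2)]])
            m = ResponseMatrix(Y)
            fit = fit_lca(m, 2, n_restarts=8, seed=bits)
            best_random = -np.inf
            for _ in range(1000):
                priors, probs = random_params(rng, m.J, 2, m.Kj)
                best_random = max(best_random, loglikelihood(m, priors, probs))
            assert fit.loglik_ >= best_random - 1e-9

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ResponseMatrix(np.empty((0, 5), dtype=int))

    def test_more_classes_than_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            fit_lca(ResponseMatrix([[1, 2]]), 2, n_restarts=1, seed=0)

    def test_determinism_under_fixed_seed(self, small_matrix):
        a = fit_lca(small_matrix, 3, n_restarts=4, seed=11)
        b = fit_lca(small_matrix, 3, n_restarts=4, seed=11)
        assert a.loglik_ == b.loglik_
        assert np.array_equal(a.labels_, b.labels_)

    def test_sklearn_get_set_params_roundtrip(self):
        est = LatentClassAnalysis(n_classes=4, random_state=3)
        params = est.get_params()
        est2 = LatentClassAnalysis().set_params(**params)
        assert est2.get_params() == params


class TestFitIndices:
    def test_npar_formula_matches_published_parameter_counts(self):
        # sum_j (Kj - 1) = 77 reproduces the published 2- and 3-class counts
        Kj = [4] * 17 + [3] * 13
        assert sum(k - 1 for k in Kj) == 77
        assert n_parameters(Kj, 2) == 155
        assert n_parameters(Kj, 3) == 233

    def test_aic_bic_arithmetic(self, small_matrix):
        fit = fit_lca(small_matrix, 2, n_restarts=2, seed=6)
        idx = fit_indices(fit)
        assert fit.aic_ == pytest.approx(-2 * fit.loglik_ + 2 * idx["n_parameters"])
        assert fit.bic_ == pytest.approx(
            -2 * fit.loglik_ + idx["n_parameters"] * np.log(small_matrix.N))

    def test_entropy_zero_for_hard_posteriors(self):
        theta = np.eye(3)[[0, 1, 2, 0]]
        assert posterior_entropy(theta) == 0.0

    def test_entropy_maximal_for_uniform_posteriors(self):
        theta = np.full((5, 3), 1 / 3)
        assert posterior_entropy(theta) == pytest.approx(np.log(3))


class TestModelSelection:
    def test_published_table_delta_rule(self):
        report = aic_delta_report(load_fit_indices())
        r3 = report[report.n_classes == 3].iloc[0]
        assert r3["delta_aic"] == 2
        # strict inequality: delta = 2 sits on the boundary, no annotation
        assert not r3["strong_support_more_complex"]
        assert report[report.n_classes == 2]["aic_best"].iloc[0]
        assert report[report.n_classes == 2]["bic_best"].iloc[0]

    def test_delta_three_earns_annotation(self):
        t = load_fit_indices().copy()
        t.loc[t.n_classes == 3, "aic"] = t.loc[t.n_classes == 2, "aic"].iloc[0] + 3
        report = aic_delta_report(t)
        assert report[report.n_classes == 3]["strong_support_more_complex"].iloc[0]

    def test_increasing_bic_prefers_smallest_model(self):
        report = aic_delta_report(load_fit_indices())
        assert report.loc[report["bic_best"], "n_classes"].iloc[0] == 2

    def test_select_model_on_real_fits(self, small_matrix):
        fits = [fit_lca(small_matrix, R, n_restarts=3, seed=R) for R in (2, 3)]
        report = select_model(fits)
        assert list(report["n_classes"]) == [2, 3]
        assert report["aic_best"].sum() == 1

    def test_select_model_rejects_mismatched_fits(self, small_matrix):
        rng = np.random.default_rng(0)
        other = random_small_matrix(rng, N=20, J=5, K=4)
        fits = [fit_lca(small_matrix, 2, n_restarts=2, seed=1),
                fit_lca(other, 3, n_restarts=2, seed=1)]
        with pytest.raises(ValueError, match="different matrices"):
            select_model(fits)


class TestClassAssignment:
    def test_modal_assignment_takes_argmax(self, small_matrix):
        fit = fit_lca(small_matrix, 3, n_restarts=3, seed=7)
        assert np.array_equal(fit.labels_, np.argmax(fit.posterior_, axis=1))

    def test_descriptive_names_follow_profile_thresholds(self, small_matrix):
        fit = fit_lca(small_matrix, 3, n_restarts=10, seed=8)
        assert sorted(fit.class_names_) == ["follower", "opposer", "switcher"]

    def test_permuting_classes_leaves_loglik_unchanged(self, small_matrix):
        fit = fit_lca(small_matrix, 3, n_restarts=3, seed=9)
        perm = [2, 0, 1]
        ll = loglikelihood(small_matrix, fit.priors_[perm],
                           fit.class_probs_[:, perm, :])
        assert ll == pytest.approx(fit.loglik_, abs=1e-9)

    def test_predict_matches_training_labels(self, small_matrix):
        fit = fit_lca(small_matrix, 3, n_restarts=3, seed=10)
        assert np.array_equal(fit.predict(small_matrix), fit.labels_)
        assert fit.score(small_matrix) == pytest.approx(fit.loglik_, abs=1e-8)
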