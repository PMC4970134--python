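"""Underlying probabilistic classifiers: Gaussian NB, softmax
regression, SVM decision values, Platt sigmoid and pairwise coupling."""

import numpy as np
import pytest

from vennose import (ConvergenceError, Dataset, GaussianNaiveBayes,
                     InvalidInputError, SoftmaxRegression, SVMPlatt,
                     pairwise_couple, platt_fit_sigmoid, platt_sigmoid,
                     tune_svm)
from vennose.classifiers import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID


def proba_is_distribution(P):
    return np.all(P >= 0) and np.all(P <= 1) and np.allclose(P.sum(axis=1), 1, atol=1e-9)


class TestGaussianNB:
    def test_symmetric_classes_give_half_half_at_origin(self, rng):
        X = np.concatenate([rng.normal(-2, 1, 400), rng.normal(2, 1, 400)])[:, None]
        y = np.array(["a"] * 400 + ["b"] * 400)
        clf = GaussianNaiveBayes(("a", "b")).fit(X, y)
        p = clf.predict_proba([[0.0]])[0]
        assert p == pytest.approx([0.5, 0.5], abs=0.05)

    def test_identical_densities_return_priors(self, rng):
        X = rng.normal(size=(300, 2))
        y = np.array(["a"] * 100 + ["b"] * 200)
        clf = GaussianNaiveBayes(("a", "b")).fit(X, y)
        p = clf.predict_proba(rng.normal(size=(50, 2)))
        assert np.allclose(p.mean(axis=0), [1 / 3, 2 / 3], atol=0.1)

    def test_fitted_means_close_to_truth(self, rng):
        n = 1000
        X = np.concatenate([rng.normal(0, 1, n), rng.normal(3, 1, n)])[:, None]
        y = np.array([0] * n + [1] * n)
        clf = GaussianNaiveBayes((0, 1)).fit(X, y)
        means = clf.params()["means"]
        assert abs(means[0][0] - 0.0) < 0.15  # ~5 standard errors
        assert abs(means[1][0] - 3.0) < 0.15

    def test_posterior_invariant_to_feature_permutation(self, three_class_data):
        d = three_class_data
        perm = np.array([2, 0, 3, 1])
        a = GaussianNaiveBayes(d.labels).fit(d.X, d.y).predict_proba(d.X[:5])
        b = GaussianNaiveBayes(d.labels).fit(d.X[:, perm], d.y).predict_proba(d.X[:5, perm])
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_distribution_contract(self, three_class_data):
        d = three_class_data
        P = GaussianNaiveBayes(d.labels).fit(d.X, d.y).predict_proba(d.X)
        assert proba_is_distribution(P)


class TestSoftmax:
    def test_zero_parameters_give_uniform(self, three_class_data):
        d = three_class_data
        clf = SoftmaxRegression(d.labels).fit(d.X, d.y)
        clf.theta_ = np.zeros_like(clf.theta_)
        assert np.allclose(clf.predict_proba(d.X[:4]), 1 / 3)

    def test_binary_case_reduces_to_logistic(self, rng):
        X = rng.normal(size=(80, 3))
        y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
        clf = SoftmaxRegression((0, 1), l2=1e-3).fit(X, y)
        X1 = np.hstack([np.ones((10, 1)), X[:10]])
        delta = clf.theta_[1] - clf.theta_[0]
        logistic = 1.0 / (1.0 + np.exp(-X1 @ delta))
        np.testing.assert_allclose(clf.predict_proba(X[:10])[:, 1], logistic, atol=1e-9)

    def test_separable_data_fits_perfectly_with_finite_coefficients(self):
        X = np.array([[-2.0], [-1.5], [-1.0], [1.0], [1.5], [2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = SoftmaxRegression((0, 1), l2=1e-2).fit(X, y)
        assert (clf.predict(X) == y).all()
        assert np.all(np.isfinite(clf.theta_))

    def test_objective_history_is_non_increasing(self, three_class_data):
        d = three_class_data
        clf = SoftmaxRegression(d.labels).fit(d.X, d.y)
        hist = np.array(clf.objective_history_)
        assert np.all(np.diff(hist) <= 1e-9)

    def test_non_convergence_raises_diagnostic_error(self, three_class_data):
        d = three_class_data
        with pytest.raises(ConvergenceError) as err:
            SoftmaxRegression(d.labels, max_iter=1).fit(d.X, d.y)
        assert err.value.gradient_norm is not None

    def test_distribution_contract(self, three_class_data):
        d = three_class_data
        P = SoftmaxRegression(d.labels).fit(d.X, d.y).predict_proba(d.X)
        assert proba_is_distribution(P)


class TestSVMDecisionValues:
    def test_antisymmetry(self, three_class_data):
        d = three_class_data
        F = SVMPlatt(d.labels).fit(d.X, d.y).decision_values(d.X[:6])
        np.testing.assert_allclose(F, -F.transpose(0, 2, 1), atol=1e-12)

    def test_midpoint_of_symmetric_problem_is_on_boundary(self):
        X = np.array([[-1.0, 0.0], [-1.2, 0.3], [-0.8, -0.2],
                      [1.0, 0.0], [1.2, -0.3], [0.8, 0.2]])
        y = np.array([0, 0, 0, 1, 1, 1])
        clf = SVMPlatt((0, 1), C=1.0).fit(X, y)
        f = clf.decision_values([[0.0, 0.0]])[0, 0, 1]
        assert abs(f) < 0.05

    def test_sign_matches_predicted_side_binary(self, rng):
        X = np.vstack([rng.normal(-2, 0.5, (30, 2)), rng.normal(2, 0.5, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        clf = SVMPlatt((0, 1), C=10.0).fit(X, y)
        F = clf.decision_values(X)
        pred = clf.predict(X)
        # positive f_01 must mean "class 0 side"
        assert all((F[n, 0, 1] > 0) == (pred[n] == 0) for n in range(60))


class TestPlattSigmoid:
    def test_symmetric_values_give_near_zero_intercept(self, rng):
        f = np.concatenate([rng.normal(1.5, 0.5, 100), rng.normal(-1.5, 0.5, 100)])
        y = np.array([True] * 100 + [False] * 100)
        A, B = platt_fit_sigmoid(f, y)
        assert abs(B) < 0.2
        assert A < 0  # larger f -> higher probability of the positive class

    def test_value_at_zero_decision(self, rng):
        f = np.concatenate([rng.normal(1, 1, 50), rng.normal(-1, 1, 50)])
        y = np.array([True] * 50 + [False] * 50)
        A, B = platt_fit_sigmoid(f, y)
        assert platt_sigmoid(0.0, A, B) == pytest.approx(1 / (1 + np.exp(B)))

    def test_uninformative_decisions_recover_class_prior(self, rng):
        f = rng.normal(size=400)
        y = rng.random(400) < 0.7  # labels independent of f
        A, B = platt_fit_sigmoid(f, y)
        r = platt_sigmoid(f, A, B)
        assert abs(A) < 0.25
        assert np.all(np.abs(r - y.mean()) < 0.1)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidInputError):
            platt_fit_sigmoid(np.array([1.0, 2.0]), np.array([True, True]))


class TestPairwiseCoupling:
    def test_uniform_pairwise_gives_uniform(self):
        for K in (2, 3, 5):
            r = np.full((K, K), 0.5)
            assert np.allclose(pairwise_couple(r), 1.0 / K, atol=1e-8)

    def test_recovers_generating_distribution(self, rng):
        for K in (2, 3, 4):
            p = rng.dirichlet(np.ones(K) * 2)
            r = np.zeros((K, K))
            for i in range(K):
                for j in range(K):
                    if i != j:
                        r[i, j] = p[i] / (p[i] + p[j])
            np.testing.assert_allclose(pairwise_couple(r), p, atol=1e-6)

    def test_two_class_closed_form(self):
        r = np.array([[0.0, 0.8], [0.2, 0.0]])
        np.testing.assert_allclose(pairwise_couple(r), [0.8, 0.2], atol=1e-8)

    def test_matches_constrained_qp_solver(self, rng):
        """Independent check: scipy SLSQP on the same objective."""
        from scipy.optimize import minimize

        K = 3
        for _ in range(5):
            r = np.zeros((K, K))
            for i in range(K):
                for j in range(i + 1, K):
                    r[i, j] = rng.uniform(0.05, 0.95)
                    r[j, i] = 1.0 - r[i, j]

            def objective(p):
                return 0.5 * sum((r[j, i] * p[i] - r[i, j] * p[j]) ** 2
                                 for i in range(K) for j in range(K) if j != i)

            ref = minimize(objective, np.full(K, 1 / K), method="SLSQP",
                           bounds=[(0, 1)] * K,
                           constraints={"type": "eq", "fun": lambda p: p.sum() - 1},
                           options={"ftol": 1e-14, "maxiter": 500})
            np.testing.assert_allclose(pairwise_couple(r), ref.x, atol=2e-3)

    def test_matches_brute_force_simplex_grid(self, rng):
        """Exhaustive grid over the 2-simplex, step 1e-3."""
        K = 3
        step = 1e-3
        m = int(round(1.0 / step))
        i = np.arange(m + 1)
        p1, p2 = np.meshgrid(i, i, indexing="ij")
        keep = (p1 + p2) <= m
        grid = np.stack([p1[keep], p2[keep], m - p1[keep] - p2[keep]], axis=1) / m
        for _ in range(3):
            r = np.zeros((K, K))
            for a in range(K):
                for b in range(a + 1, K):
                    r[a, b] = rng.uniform(0.05, 0.95)
                    r[b, a] = 1.0 - r[a, b]
            Q = np.zeros((K, K))
            for a in range(K):
                Q[a, a] = sum(r[c, a] ** 2 for c in range(K) if c != a)
                for b in range(K):
                    if b != a:
                        Q[a, b] = -r[b, a] * r[a, b]
            vals = np.einsum("ni,ij,nj->n", grid, Q, grid)
            best = grid[int(np.argmin(vals))]
            np.testing.assert_allclose(pairwise_couple(r), best, atol=2e-3)

    def test_invalid_pairwise_matrix_rejected(self):
        r = np.array([[0.0, 0.9], [0.3, 0.0]])  # 0.9 + 0.3 != 1
        with pytest.raises(InvalidInputError):
            pairwise_couple(r)


class TestSVMPlattEndToEnd:
    def test_coupled_probabilities_are_distributions(self, three_class_data):
        d = three_class_data
        P = SVMPlatt(d.labels).fit(d.X, d.y).predict_proba(d.X)
        assert proba_is_distribution(P)

    def test_agrees_with_sklearn_internal_calibration_on_clean_data(self, separable_data):
        """Cross-check against sklearn's own Platt+coupling chain: on
        well-separated data both must give the same argmax nearly
        everywhere (the sigmoids are fit on different folds, so the
        probabilities themselves differ slightly)."""
        from sklearn.svm import SVC

        d = separable_data
        ours = SVMPlatt(d.labels, C=10.0).fit(d.X, d.y).predict_proba(d.X)
        ref = SVC(C=10.0, probability=True, random_state=0).fit(
            d.X, d.label_indices()).predict_proba(d.X)
        assert (ours.argmax(axis=1) == ref.argmax(axis=1)).mean() >= 0.95


class TestPersistence:
    @pytest.mark.parametrize("kind", ["nb", "softmax"])
    def test_json_roundtrip_preserves_predictions(self, kind, three_class_data, tmp_path):
        from vennose import load_model, make_classifier, save_model

        d = three_class_data
        clf = make_classifier(kind, d.labels).fit(d.X, d.y)
        path = tmp_path / "model.json"
        save_model(clf, path)
        back = load_model(path)
        np.testing.assert_allclose(clf.predict_proba(d.X),
                                   back.predict_proba(d.X), atol=1e-12)

    def test_svm_state_is_not_json_serialisable(self, three_class_data, tmp_path):
        from vennose import save_model

        d = three_class_data
        clf = SVMPlatt(d.labels).fit(d.X, d.y)
        with pytest.raises(InvalidInputError):
            save_model(clf, tmp_path / "m.json")


class TestTuneSVM:
    def test_default_grids_match_protocol(self):
        assert DEFAULT_C_GRID == tuple(2.0 ** k for k in (2, 4, 6, 8, 10, 12, 14))
        assert DEFAULT_GAMMA_GRID == tuple(2.0 ** k for k in (-9, -7, -5, -3, -1))

    def test_single_point_grid_returned(self, three_class_data):
        res = tune_svm(three_class_data, c_grid=(4.0,), gamma_grid=(0.125,))
        assert (res.C, res.gamma) == (4.0, 0.125)

    def test_strictly_better_point_wins(self, separable_data):
        # gamma 1e4 overfits wildly on separable data; 0.125 classifies it
        res = tune_svm(separable_data, c_grid=(16.0,), gamma_grid=(0.125, 1e4))
        assert res.gamma == 0.125

    def test_deterministic_given_seed(self, three_class_data):
        a = tune_svm(three_class_data, c_grid=(4.0, 16.0), gamma_grid=(0.125, 0.5), seed=5)
        b = tune_svm(three_class_data, c_grid=(4.0, 16.0), gamma_grid=(0.125, 0.5), seed=5)
        assert (a.C, a.gamma, a.cv_accuracy) == (b.C, b.gamma, b.cv_accuracy)

    def test_class_smaller_than_folds_rejected(self):
        X = np.arange(12, dtype=float)[:, None]
        y = np.array(["a"] * 9 + ["b"] * 3)
        with pytest.raises(InvalidInputError):
            tune_svm(Dataset(X, y, ("a", "b")), folds=5)
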