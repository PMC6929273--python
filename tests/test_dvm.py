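"""The DVM classifier: neighbor graph, robust solve, residual classification."""

import logging

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.base import clone

from dvmppi import DVMClassifier, predict_batch, similarity_weights, solve_beta
from dvmppi.dvm import NeighborSet, _beta_update, hq_objective


def random_neighbor_set(rng, d=8, k=5):
    cols = rng.normal(size=(d, k))
    labels = rng.integers(0, 2, size=k)
    return NeighborSet(columns=cols, labels=labels)


def two_gaussians(rng, n=200, d=120, sep=6.0):
    """Two spherical unit-sd classes whose means differ by `sep` per dimension."""
    half = n // 2
    mu = np.full(d, sep)
    X = np.vstack(
        [rng.normal(size=(half, d)), mu + rng.normal(size=(n - half, d))]
    )
    y = np.r_[np.zeros(half, dtype=int), np.ones(n - half, dtype=int)]
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestSimilarityWeights:
    def test_identical_columns_weight_one(self):
        c = np.tile(np.array([[1.0], [2.0]]), (1, 2))
        w = similarity_weights(c)
        assert w[0, 1] == pytest.approx(1.0)
        assert w[0, 0] == 0.0  # no self-edges

    def test_orthogonal_columns_weight_zero(self):
        w = similarity_weights(np.eye(2))
        np.testing.assert_allclose(w, 0.0)

    def test_matches_elementwise_oracle(self, rng):
        cols = rng.normal(size=(6, 5))
        w = similarity_weights(cols)
        for p in range(5):
            for q in range(5):
                if p == q:
                    assert w[p, q] == 0.0
                    continue
                cos = cols[:, p] @ cols[:, q] / (
                    np.linalg.norm(cols[:, p]) * np.linalg.norm(cols[:, q])
                )
                assert w[p, q] == pytest.approx(max(cos, 0.0), abs=1e-12)
        assert np.abs(w).max() <= 1.0 + 1e-12

    def test_zero_norm_column_isolated(self, rng):
        cols = rng.normal(size=(4, 3))
        cols[:, 1] = 0.0
        w = similarity_weights(cols)
        np.testing.assert_allclose(w[1, :], 0.0)
        np.testing.assert_allclose(w[:, 1], 0.0)


class TestLaplacian:
    def test_row_sums_zero_symmetric_psd(self, rng):
        for _ in range(10):
            ns = random_neighbor_set(rng, d=7, k=6)
            L = ns.laplacian
            np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-10)
            np.testing.assert_allclose(L, L.T, atol=1e-12)
            assert np.linalg.eigvalsh(L).min() >= -1e-8
            b = rng.normal(size=6)
            assert b @ L @ b >= -1e-10


class TestSolveBeta:
    def test_scalar_ridge_closed_form(self, rng):
        """With one neighbor, gamma=0 and P=I the update is (x'y)/(x'x+delta)."""
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        ns = NeighborSet(columns=x[:, None], labels=np.array([0]))
        delta = 1e-3
        beta = _beta_update(x[:, None], y, np.ones(6), delta, 0.0, ns.laplacian)
        assert beta[0] == pytest.approx((x @ y) / (x @ x + delta), abs=1e-12)

    def test_first_iteration_is_ridge_solution(self, rng):
        """gamma=0, P=I: the initialisation equals (X'X+delta I)^-1 X'y."""
        ns = random_neighbor_set(rng)
        y = rng.normal(size=8)
        delta = 1e-3
        state = solve_beta(y, ns, delta=delta, gamma=0.0, max_iter=1, theta=1e12)
        ridge = np.linalg.solve(
            ns.columns.T @ ns.columns + delta * np.eye(5), ns.columns.T @ y
        )
        # theta -> large keeps P ~ I, so one iteration stays at the ridge point
        np.testing.assert_allclose(state.beta, ridge, atol=1e-8)

    def test_fixed_p_update_matches_numerical_minimizer(self, rng):
        """Closed form vs generic optimizer on the fixed-P quadratic."""
        for _ in range(10):
            d = int(rng.integers(4, 17))
            k = int(rng.integers(2, 11))
            ns = random_neighbor_set(rng, d=d, k=k)
            y = rng.normal(size=d)
            p = rng.uniform(0.05, 1.0, size=d)
            delta, gamma = 1e-3, 1e-4
            beta = _beta_update(ns.columns, y, p, delta, gamma, ns.laplacian)
            X = ns.columns

            def grad(b):
                return 2 * (
                    -X.T @ (p * (y - X @ b)) + delta * b + gamma * ns.laplacian @ b
                )

            res = minimize(
                lambda b: hq_objective(y, X, b, p, delta, gamma, ns.laplacian),
                np.zeros(k),
                jac=grad,
                method="BFGS",
                options={"gtol": 1e-10, "maxiter": 2000},
            )
            np.testing.assert_allclose(beta, res.x, atol=1e-6)

    def test_objective_non_increasing(self, rng):
        for _ in range(25):
            ns = random_neighbor_set(rng, d=10, k=6)
            y = rng.normal(size=10)
            state = solve_beta(y, ns)
            for before, after in state.trace:
                assert after <= before + 1e-9

    def test_weights_in_unit_interval(self, rng):
        ns = random_neighbor_set(rng)
        state = solve_beta(rng.normal(size=8), ns)
        assert ((state.weights > 0) & (state.weights <= 1.0)).all()

    def test_large_theta_recovers_laplacian_ridge(self, rng):
        ns = random_neighbor_set(rng)
        y = rng.normal(size=8)
        delta, gamma = 1e-3, 1e-4
        state = solve_beta(y, ns, delta=delta, gamma=gamma, theta=1e6)
        assert state.weights.min() > 0.999
        direct = np.linalg.solve(
            ns.columns.T @ ns.columns + delta * np.eye(5) + gamma * ns.laplacian,
            ns.columns.T @ y,
        )
        np.testing.assert_allclose(state.beta, direct, atol=1e-4)

    def test_zero_residual_short_circuits(self, rng):
        ns = random_neighbor_set(rng)
        state = solve_beta(np.zeros(8), ns)
        np.testing.assert_allclose(state.weights, 1.0)
        assert state.converged
        np.testing.assert_allclose(state.beta, 0.0, atol=1e-12)


class TestFit:
    def test_stores_standardized_features(self, rng):
        X = rng.normal(loc=3.0, scale=2.5, size=(30, 5))
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        model = DVMClassifier(k=5).fit(X, y)
        np.testing.assert_allclose(model.X_.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(model.X_.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_scale_one(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        model = DVMClassifier(k=5).fit(X, y)
        assert model.scale_[1] == 1.0
        np.testing.assert_allclose(model.X_[:, 1], 0.0)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="2 classes"):
            DVMClassifier().fit(rng.normal(size=(10, 3)), np.zeros(10))

    def test_k_exceeding_n_rejected(self, rng):
        y = np.r_[0, 1, np.zeros(8)]
        with pytest.raises(ValueError, match="lower k"):
            DVMClassifier(k=11).fit(rng.normal(size=(10, 3)), y)

    def test_auto_k_resolution(self, rng):
        y = rng.integers(0, 2, size=300)
        y[:2] = [0, 1]
        model = DVMClassifier().fit(rng.normal(size=(300, 4)), y)
        assert model.k_ == 30  # max(20, ceil(0.1 * 300))


class TestFindNeighbors:
    def test_training_point_is_own_nearest(self, rng):
        X, y = two_gaussians(rng, n=30, d=10)
        model = DVMClassifier(k=1).fit(X, y)
        z = model.X_[4]
        ns = model.find_neighbors(z)
        np.testing.assert_allclose(ns.columns[:, 0], z)

    def test_k_equal_n_returns_all(self, rng):
        X, y = two_gaussians(rng, n=12, d=6)
        model = DVMClassifier(k=12).fit(X, y)
        ns = model.find_neighbors(model.X_[0])
        assert ns.columns.shape == (6, 12)
        assert sorted(ns.labels) == sorted(model.y_)

    def test_matches_brute_force_sort(self, rng):
        X, y = two_gaussians(rng, n=40, d=9)
        model = DVMClassifier(k=7).fit(X, y)
        z = rng.normal(size=9)
        ns = model.find_neighbors(z)
        dists = np.linalg.norm(model.X_ - z, axis=1)
        expect = np.argsort(dists, kind="stable")[:7]
        np.testing.assert_allclose(ns.columns, model.X_[expect].T)

    def test_cosine_metric(self, rng):
        X, y = two_gaussians(rng, n=40, d=9)
        model = DVMClassifier(k=5, neighbor_metric="cosine").fit(X, y)
        z = rng.normal(size=9)
        ns = model.find_neighbors(z)
        cos = model.X_ @ z / (
            np.linalg.norm(model.X_, axis=1) * np.linalg.norm(z)
        )
        expect = np.argsort(1.0 - cos, kind="stable")[:5]
        np.testing.assert_allclose(ns.columns, model.X_[expect].T)


class TestClassify:
    def test_training_point_reconstructs_itself(self, rng):
        X, y = two_gaussians(rng, n=40, d=12)
        model = DVMClassifier(k=10, delta=1e-8, gamma=0.0).fit(X, y)
        i = int(np.where(y == 1)[0][0])
        pred = model.classify(X[i])
        assert pred.label == 1
        assert pred.residuals[1] < 1e-3

    def test_single_class_neighborhood_forces_that_class(self, rng):
        # two tight, far-apart clusters: all k neighbors of a class-1 query
        # are class 1, and the absent class falls back to R = ||y||
        X = np.vstack([rng.normal(size=(10, 5)) * 0.1,
                       100.0 + rng.normal(size=(10, 5)) * 0.1])
        y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        model = DVMClassifier(k=5, standardize=False).fit(X, y)
        pred = model.classify(X[15])
        assert pred.label == 1

    def test_absent_class_residual_is_query_norm(self, rng, caplog):
        X = np.vstack([rng.normal(size=(10, 5)) * 0.1,
                       100.0 + rng.normal(size=(10, 5)) * 0.1])
        y = np.r_[np.zeros(10, dtype=int), np.ones(10, dtype=int)]
        model = DVMClassifier(k=5, standardize=False).fit(X, y)
        with caplog.at_level(logging.DEBUG, logger="dvmppi.dvm"):
            pred = model.classify(X[15])
        z = model._standardize(X[15])
        assert pred.residuals[0] == pytest.approx(np.linalg.norm(z))
        assert "absent among neighbors" in caplog.text

    def test_agrees_with_nearest_centroid_on_separable_data(self, rng):
        X, y = two_gaussians(rng, n=200, d=120, sep=6.0)
        Xtr, ytr, Xte, yte = X[:150], y[:150], X[150:], y[150:]
        model = DVMClassifier().fit(Xtr, ytr)
        pred = model.predict(Xte)
        mu0, mu1 = Xtr[ytr == 0].mean(axis=0), Xtr[ytr == 1].mean(axis=0)
        centroid = (
            np.linalg.norm(Xte - mu1, axis=1) < np.linalg.norm(Xte - mu0, axis=1)
        ).astype(int)
        assert (pred == centroid).mean() >= 0.99

    def test_permuting_training_order_changes_nothing(self, rng):
        X, y = two_gaussians(rng, n=60, d=10, sep=2.0)
        queries = rng.normal(size=(10, 10))
        model = DVMClassifier(k=9).fit(X, y)
        perm = rng.permutation(60)
        model_p = DVMClassifier(k=9).fit(X[perm], y[perm])
        np.testing.assert_allclose(
            model.decision_function(queries), model_p.decision_function(queries)
        )

    def test_margin_sign_matches_prediction(self, rng):
        X, y = two_gaussians(rng, n=80, d=10, sep=3.0)
        model = DVMClassifier().fit(X, y)
        queries = rng.normal(size=(20, 10)) + 1.5
        scores = model.decision_function(queries)
        preds = model.predict(queries)
        assert ((scores > 0) == (preds == 1)).all()

    def test_refit_class_residual_mode(self, rng):
        X, y = two_gaussians(rng, n=100, d=20, sep=6.0)
        a = DVMClassifier(class_residual="refit").fit(X[:80], y[:80])
        b = DVMClassifier(class_residual="slice").fit(X[:80], y[:80])
        assert (a.predict(X[80:]) == y[80:]).mean() >= 0.95
        assert (a.predict(X[80:]) == b.predict(X[80:])).mean() >= 0.9

    def test_dimension_mismatch_names_sample(self, rng):
        X, y = two_gaussians(rng, n=20, d=5)
        model = DVMClassifier(k=5).fit(X, y)
        with pytest.raises(ValueError, match="shape"):
            model.predict(rng.normal(size=(3, 4)))


class TestPredictBatch:
    def test_empty_list(self, rng):
        X, y = two_gaussians(rng, n=20, d=5)
        model = DVMClassifier(k=5).fit(X, y)
        assert predict_batch([], model) == []

    def test_single_sample_equals_classify(self, rng):
        X, y = two_gaussians(rng, n=20, d=5)
        model = DVMClassifier(k=5).fit(X, y)
        q = rng.normal(size=5)
        batch = predict_batch([q], model)
        solo = model.classify(q)
        assert batch[0].label == solo.label
        np.testing.assert_allclose(batch[0].residuals, solo.residuals)

    def test_batch_equals_sequential_loop(self, rng):
        X, y = two_gaussians(rng, n=30, d=6)
        model = DVMClassifier(k=8).fit(X, y)
        queries = rng.normal(size=(6, 6))
        batch = predict_batch(queries, model)
        for q, p in zip(queries, batch):
            solo = model.classify(q)
            assert p.label == solo.label
            np.testing.assert_allclose(p.residuals, solo.residuals)


def test_sklearn_clone_compatible():
    model = DVMClassifier(k=7, delta=1e-2)
    params = clone(model).get_params()
    assert params["k"] == 7 and params["delta"] == 1e-2
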