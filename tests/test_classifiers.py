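"""From-equation classifiers against closed forms, KKT conditions and
independent optimizers."""

import numpy as np
import pytest
from scipy import optimize

from n170trial.classifiers import (
    ConvergenceError,
    DegenerateModelError,
    FisherLDA,
    L1Logit,
    RBFSVM,
    fit_classifier,
    rbf_kernel,
)
from n170trial.evaluation import metric_auc

from conftest import gaussian_cluster_features


class TestFisherLDA:
    def test_one_dimensional_closed_form(self):
        # {0,1} (+) vs {2,3} (-): pooled scatter 0.25, w = -2/0.25 = -8,
        # threshold w*1.5; x=1.4 is nearer the positive-class mean
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([1, 1, -1, -1])
        res = FisherLDA(y, X).fit(shrinkage=0.0)
        assert res.params[0] == pytest.approx(-8.0)
        assert res.threshold == pytest.approx(-12.0)
        assert res.predict([[1.4]])[0] == 1
        assert res.predict([[1.6]])[0] == -1

    def test_identical_class_means_degenerate(self):
        X = np.array([[1.0, 2.0], [3.0, 0.0], [1.0, 2.0], [3.0, 0.0]])
        y = np.array([1, 1, -1, -1])
        with pytest.raises(DegenerateModelError):
            FisherLDA(y, X).fit()

    def test_whitened_data_weight_parallel_to_mean_difference(self):
        rng = np.random.default_rng(0)
        n = 50_000
        delta = np.array([1.0, -0.5, 0.25])
        pos = rng.normal(0, 1, (n, 3)) + delta / 2
        neg = rng.normal(0, 1, (n, 3)) - delta / 2
        X = np.vstack([pos, neg])
        y = np.concatenate([np.ones(n), -np.ones(n)])
        res = FisherLDA(y, X).fit(shrinkage=0.0)
        cos = res.params @ delta / (np.linalg.norm(res.params)
                                    * np.linalg.norm(delta))
        assert cos > 0.99

    def test_direction_recovers_population_discriminant(self):
        # anisotropic covariance: w converges to Sigma^-1 (mu+ - mu-)
        rng = np.random.default_rng(1)
        A = np.array([[2.0, 0.5, 0.0], [0.5, 1.0, 0.3], [0.0, 0.3, 0.5]])
        sigma = A @ A.T
        delta = np.array([1.0, 0.0, -1.0])
        n = 10_000
        z = rng.multivariate_normal(np.zeros(3), sigma, 2 * n)
        X = z + np.concatenate([np.tile(delta / 2, (n, 1)),
                                np.tile(-delta / 2, (n, 1))])
        y = np.concatenate([np.ones(n), -np.ones(n)])
        res = FisherLDA(y, X).fit(shrinkage=0.0)
        target = np.linalg.solve(sigma, delta)
        cos = res.params @ target / (np.linalg.norm(res.params)
                                     * np.linalg.norm(target))
        assert cos > 0.99

    def test_singular_scatter_without_shrinkage_raises(self):
        # rank-deficient features: duplicate column
        X = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([1, 1, -1, -1])
        with pytest.raises(DegenerateModelError):
            FisherLDA(y, X).fit(shrinkage=0.0)
        res = FisherLDA(y, X).fit(shrinkage=0.5)  # regularized path works
        assert np.isfinite(res.params).all()

    def test_auto_shrinkage_within_unit_interval(self):
        X, y = gaussian_cluster_features(n_per_class=20, dim=10, sep=2.0)
        res = FisherLDA(y, X).fit(shrinkage="auto")
        assert 0.0 <= res.shrinkage <= 1.0


class TestL1Logit:
    def test_lambda_at_or_above_max_gives_exact_zero_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6))
        y = np.concatenate([np.ones(25), -np.ones(15)])
        model = L1Logit(y, X)
        lam_max = model.lambda_max()
        for lam in (lam_max, 2 * lam_max):
            res = model.fit(lam)
            assert np.all(res.params == 0.0)
            assert res.intercept == pytest.approx(np.log(25 / 15), abs=1e-4)
            # KKT: at w=0 the loss gradient must lie inside the subgradient box
            from n170trial.classifiers import _logistic_grad
            _, gw = _logistic_grad(res.intercept, res.params, X, y)
            assert np.all(np.abs(gw) <= lam + 1e-10)

    def test_balanced_classes_zero_features(self):
        X = np.zeros((10, 3))
        y = np.concatenate([np.ones(5), -np.ones(5)])
        res = L1Logit(y, X).fit(0.1)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(res.predict_proba(np.zeros((1, 3))), 0.5)

    def test_unregularized_fit_matches_independent_optimizer(self):
        rng = np.random.default_rng(3)
        n, p = 60, 4
        X = rng.normal(size=(n, p))
        true_w = np.array([1.0, -1.0, 0.5, 0.0])
        prob = 1 / (1 + np.exp(-(X @ true_w)))
        y = np.where(rng.random(n) < prob, 1.0, -1.0)
        res = L1Logit(y, X).fit(0.0, tol=1e-12, max_iter=50_000)

        def loss(theta):
            eta = theta[0] + X @ theta[1:]
            return np.mean(np.logaddexp(0.0, -y * eta))

        oracle = optimize.minimize(loss, np.zeros(p + 1), method="BFGS",
                                   options={"gtol": 1e-10})
        assert res.objective_trace[-1] == pytest.approx(oracle.fun, abs=1e-5)

    def test_objective_trace_monotone_nonincreasing(self):
        X, y = gaussian_cluster_features(n_per_class=40, dim=8, sep=1.0, seed=4)
        res = L1Logit(y, X).fit(0.01)
        assert np.all(np.diff(res.objective_trace) <= 1e-15)

    def test_l1_norm_nonincreasing_in_lambda(self):
        X, y = gaussian_cluster_features(n_per_class=40, dim=8, sep=2.0, seed=5)
        model = L1Logit(y, X)
        lam_max = model.lambda_max()
        norms = [np.abs(model.fit(lam).params).sum()
                 for lam in np.geomspace(1e-3 * lam_max, lam_max, 8)]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_sparsity_grows_near_lambda_max(self):
        # two informative features among ten: just below lambda_max only the
        # strongest coordinates activate; at lambda_max the model is empty
        rng = np.random.default_rng(6)
        n = 80
        X = rng.normal(size=(n, 10))
        y = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        X[:, 0] += 1.5 * y
        X[:, 1] += 1.0 * y
        model = L1Logit(y, X)
        lam_max = model.lambda_max()
        just_below = model.fit(0.9 * lam_max)
        at_max = model.fit(lam_max)
        assert at_max.n_nonzero == 0
        assert 1 <= just_below.n_nonzero <= 2
        assert just_below.params[0] != 0.0

    def test_nonfinite_features_rejected(self):
        X = np.array([[np.nan, 1.0], [0.0, 1.0]])
        with pytest.raises(ValueError):
            L1Logit(np.array([1, -1]), X)


def _slsqp_dual_oracle(X, y, C, gamma):
    """Exact small-instance solver for the SVM dual via SLSQP."""
    n = len(y)
    Q = (y[:, None] * y[None, :]) * rbf_kernel(X, X, gamma)

    def neg_dual(a):
        return 0.5 * a @ Q @ a - a.sum()

    def neg_dual_grad(a):
        return Q @ a - np.ones(n)

    res = optimize.minimize(
        neg_dual, np.zeros(n), jac=neg_dual_grad, method="SLSQP",
        bounds=[(0.0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ y,
                     "jac": lambda a: y},
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    assert res.success
    return -res.fun


class TestRBFSVM:
    def test_single_support_vector_decision(self):
        # a model with one SV x1, beta1*y1 = 1, b = 0: f(x1) = sign(K(x1,x1)) = +1
        from n170trial.classifiers import RBFSVMResults
        x1 = np.array([[0.3, -0.2]])
        res = RBFSVMResults(
            model=RBFSVM(np.array([1, -1]), np.vstack([x1, -x1])),
            support_coef=np.array([1.0]), support_vectors=x1,
            support_index=np.array([0]), bias=0.0, C=1.0, gamma=0.7,
            dual_objective=0.0, kkt_gap=0.0, n_iter=0,
        )
        assert res.decision_score(x1)[0] == pytest.approx(1.0)  # K(x,x)=1
        assert res.predict(x1)[0] == 1

    def test_separable_clusters_perfect_training_accuracy(self):
        X, y = gaussian_cluster_features(n_per_class=20, dim=3, sep=8.0, seed=7)
        res = RBFSVM(y, X).fit(C=10.0, gamma=0.1)
        assert np.all(res.predict(X) == y)
        assert res.kkt_gap <= 1e-3

    @pytest.mark.parametrize("seed,C,gamma", [
        (8, 1.0, 0.5), (9, 10.0, 0.1), (10, 0.5, 1.0),
    ])
    def test_dual_objective_matches_qp_oracle(self, seed, C, gamma):
        rng = np.random.default_rng(seed)
        n = 36
        X = rng.normal(size=(n, 3))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=n) > 0, 1.0, -1.0)
        if abs(y.sum()) == n:
            y[0] *= -1
        res = RBFSVM(y, X).fit(C=C, gamma=gamma, tol=1e-6)
        oracle = _slsqp_dual_oracle(X, y, C, gamma)
        assert res.dual_objective == pytest.approx(oracle, abs=1e-3)

    def test_duplicating_rows_with_halved_C_preserves_decision(self):
        X, y = gaussian_cluster_features(n_per_class=15, dim=2, sep=3.0, seed=11)
        grid = np.random.default_rng(12).normal(size=(20, 2)) * 2
        base = RBFSVM(y, X).fit(C=2.0, gamma=0.5, tol=1e-6)
        doubled = RBFSVM(np.tile(y, 2), np.tile(X, (2, 1))).fit(
            C=1.0, gamma=0.5, tol=1e-6)
        assert np.allclose(base.decision_score(grid),
                           doubled.decision_score(grid), atol=5e-3)

    def test_iteration_budget_exhaustion_reports_gap(self):
        X, y = gaussian_cluster_features(n_per_class=25, dim=4, sep=0.5, seed=13)
        with pytest.raises(ConvergenceError) as err:
            RBFSVM(y, X).fit(C=100.0, gamma=1.0, max_iter=3)
        assert err.value.gap is not None and err.value.gap > 0

    def test_invalid_hyperparameters_rejected(self):
        X, y = gaussian_cluster_features(n_per_class=5, dim=2)
        with pytest.raises(ValueError):
            RBFSVM(y, X).fit(C=0.0, gamma=1.0)
        with pytest.raises(ValueError):
            RBFSVM(y, X).fit(C=1.0, gamma=-1.0)


class TestCommonContract:
    @pytest.mark.parametrize("name,hyper", [
        ("lda", {}),
        ("l1lr", {"lam": 0.01}),
        ("rbfsvm", {"C": 5.0, "gamma": 0.2}),
    ])
    def test_predict_is_sign_of_score(self, name, hyper):
        X, y = gaussian_cluster_features(n_per_class=25, dim=4, sep=2.0, seed=14)
        res = fit_classifier(name, X, y, **hyper)
        test = np.random.default_rng(15).normal(size=(30, 4))
        scores = res.decision_score(test)
        assert np.array_equal(res.predict(test), np.where(scores >= 0, 1, -1))

    @pytest.mark.parametrize("name,hyper", [
        ("lda", {}),
        ("l1lr", {"lam": 0.001}),
        ("rbfsvm", {"C": 10.0, "gamma": 0.2}),
    ])
    def test_separable_training_scores_rank_perfectly(self, name, hyper):
        X, y = gaussian_cluster_features(n_per_class=20, dim=3, sep=8.0, seed=16)
        res = fit_classifier(name, X, y, **hyper)
        assert metric_auc(res.decision_score(X), y) == 1.0

    def test_dimension_mismatch_rejected(self):
        X, y = gaussian_cluster_features(n_per_class=10, dim=4)
        res = fit_classifier("lda", X, y)
        with pytest.raises(ValueError):
            res.predict(np.zeros((2, 5)))

    def test_monotone_transform_of_l1lr_scores_preserves_labels(self):
        X, y = gaussian_cluster_features(n_per_class=20, dim=3, sep=2.0, seed=17)
        res = fit_classifier("l1lr", X, y, lam=0.01)
        scores = res.decision_score(X)
        probs = res.predict_proba(X)  # logistic transform of the same scores
        assert np.array_equal(np.sign(scores) >= 0, probs >= 0.5)
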