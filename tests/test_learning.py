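import math

import numpy as np
import pytest
from scipy.optimize import minimize

import espamarkov.learning as learning_mod
from espamarkov import (
    Example1Spec,
    GaussianCentroids,
    GridSpec,
    HyperParams,
    TwoStateChainSpec,
    auc_score,
    eval_loss,
    fit,
    fit_oneshot,
    gen_example1,
    gen_nanopore_toy,
    NanoporeToySpec,
    predict,
    update_lambda,
    update_mu_sigma,
    update_w,
    zscore_rows,
)
from espamarkov.learning import grid_search
from espamarkov.model_core import nll_tensor

from conftest import random_affiliation, random_instance, random_onehot


def likelihood_term(X, gamma, mu, sigma, W, hp):
    ell = nll_tensor(X, np.atleast_2d(mu), np.atleast_2d(sigma))
    return hp.eps_L / X.shape[1] * float(np.einsum("d,kt,dkt->", W, gamma, ell))


class TestMuSigmaStep:
    def test_single_cluster_plain_mean_sd(self):
        X = np.array([[1.0, 3.0]])
        theta = update_mu_sigma(X, np.ones((1, 2)))
        assert theta.mu[0, 0] == pytest.approx(2.0)
        assert theta.sigma[0, 0] == pytest.approx(1.0)

    def test_hard_affiliations_give_per_cluster_stats(self, rng):
        X = rng.normal(size=(2, 30))
        lab = rng.integers(0, 2, 30)
        lab[:2] = [0, 1]
        gamma = np.zeros((2, 30))
        gamma[lab, np.arange(30)] = 1.0
        theta = update_mu_sigma(X, gamma)
        for k in range(2):
            pts = X[:, lab == k]
            np.testing.assert_allclose(theta.mu[:, k], pts.mean(axis=1), atol=1e-12)
            np.testing.assert_allclose(theta.sigma[:, k], pts.std(axis=1), atol=1e-12)

    def test_matches_numeric_minimizer_fuzzy(self, rng):
        """On a fuzzy 5-point instance the analytic (mu, sigma) matches a
        derivative-free minimizer of the likelihood term."""
        X = rng.normal(size=(1, 5))
        gamma = random_affiliation(rng, 2, 5) * 0.8 + 0.1
        gamma /= gamma.sum(axis=0)
        hp = HyperParams(1.0, 0.1, 0.0, 2)
        W = np.ones(1)
        theta = update_mu_sigma(X, gamma)
        f_star = likelihood_term(X, gamma, theta.mu, theta.sigma, W, hp)

        def obj(z):
            mu = z[:2].reshape(1, 2)
            sigma = np.exp(z[2:]).reshape(1, 2)
            return likelihood_term(X, gamma, mu, sigma, W, hp)

        z0 = np.r_[X.mean(), X.mean(), 0.0, 0.0]
        res = minimize(obj, z0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        assert f_star == pytest.approx(res.fun, abs=1e-5)

    def test_empty_cluster_reseeded_with_warning(self, rng):
        X = rng.normal(size=(2, 10))
        gamma = np.zeros((2, 10))
        gamma[0] = 1.0  # cluster 2 empty
        with pytest.warns(UserWarning, match="reseed"):
            theta = update_mu_sigma(X, gamma, rng=rng)
        assert np.isfinite(theta.mu).all()
        assert (theta.sigma > 0).all()


class TestLambdaStep:
    def test_bijective_onehot_gives_identity(self, rng):
        Pi = random_onehot(rng, 3, 20)
        np.testing.assert_allclose(update_lambda(Pi, Pi), np.eye(3), atol=1e-12)

    def test_uniform_affiliation_gives_label_frequencies(self):
        # 4 points, labels (1, 1, 2, 1) -> empirical distribution (0.75, 0.25)
        Pi = np.array([[1.0, 1.0, 0.0, 1.0], [0.0, 0.0, 1.0, 0.0]])
        lam = update_lambda(Pi, np.full((3, 4), 1.0 / 3.0))
        np.testing.assert_allclose(lam, [[0.75] * 3, [0.25] * 3], atol=1e-12)

    def test_columns_always_normalized(self, rng):
        for _ in range(10):
            Pi = random_onehot(rng, 2, 15)
            lam = update_lambda(Pi, random_affiliation(rng, 4, 15))
            np.testing.assert_allclose(lam.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_mass_column_becomes_uniform(self, rng):
        Pi = random_onehot(rng, 2, 6)
        gamma = np.zeros((2, 6))
        gamma[0] = 1.0
        lam = update_lambda(Pi, gamma)
        np.testing.assert_allclose(lam[:, 1], 0.5)


class TestWStep:
    def test_symmetric_errors_give_uniform(self, rng):
        X = np.vstack([rng.normal(size=6)] * 3)  # identical rows
        gamma = random_affiliation(rng, 2, 6)
        theta = update_mu_sigma(X, gamma)
        W = update_w(X, gamma, theta, HyperParams(1.0, 0.1, 0.0, 2))
        np.testing.assert_allclose(W, 1.0 / 3.0, atol=1e-12)

    def test_temperature_limits(self, rng):
        X = rng.normal(size=(3, 10)) * np.array([[0.5], [1.0], [2.0]])
        gamma = random_affiliation(rng, 2, 10)
        theta = update_mu_sigma(X, gamma)
        w_hot = update_w(X, gamma, theta, HyperParams(1.0, 1e6, 0.0, 2))
        np.testing.assert_allclose(w_hot, 1.0 / 3.0, atol=1e-4)
        w_cold = update_w(X, gamma, theta, HyperParams(1.0, 1e-8, 0.0, 2))
        ell = nll_tensor(X, theta.mu, theta.sigma)
        b = np.einsum("kt,dkt->d", gamma, ell)
        expected = np.zeros(3)
        expected[np.argmin(b)] = 1.0
        np.testing.assert_allclose(w_cold, expected, atol=1e-6)

    def test_softmax_reference_value(self, monkeypatch):
        """b = (0, ln 3) at unit temperature gives weights (0.75, 0.25)."""
        captured = {}
        theta = GaussianCentroids(np.zeros((2, 1)), np.ones((2, 1)))
        X = np.zeros((2, 1))
        gamma = np.ones((1, 1))

        def fake_nll(X_, mu_, sigma_):
            return np.array([0.0, math.log(3.0)]).reshape(2, 1, 1)

        monkeypatch.setattr(learning_mod, "nll_tensor", fake_nll)
        W = update_w(X, gamma, theta, HyperParams(1.0, 1.0, 0.0, 1))
        np.testing.assert_allclose(W, [0.75, 0.25], atol=1e-12)

    def test_matches_numeric_constrained_minimizer(self, rng):
        """The softmax solution minimizes likelihood + entropy on the simplex."""
        for _ in range(5):
            X, Pi, gamma, theta, lam, _ = random_instance(rng, D=4, K=2, T=10)
            hp = HyperParams(0.8, 0.07, 0.0, 2)
            W_star = update_w(X, gamma, theta, hp)

            def obj(W):
                lik = likelihood_term(X, gamma, theta.mu, theta.sigma, W, hp)
                ent = hp.eps_E * float(np.sum(W * np.log(np.maximum(W, 1e-300))))
                return lik + ent

            res = minimize(
                obj,
                np.full(4, 0.25),
                method="SLSQP",
                bounds=[(0.0, 1.0)] * 4,
                constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
                options={"maxiter": 500, "ftol": 1e-14},
            )
            assert obj(W_star) == pytest.approx(res.fun, abs=1e-5)


class TestFit:
    def test_total_loss_monotone(self, rng):
        for i in range(5):
            X, Pi, *_ = random_instance(rng, D=3, K=2, T=20)
            hp = HyperParams(1.0, 1e-2, 1e-2, 2)
            m = fit(X, Pi, hp, n_starts=2, seed=i)
            assert (np.diff(m.loss_trace) <= 1e-9).all()

    def test_separable_variances_recovered(self):
        spec = Example1Spec(
            sigma_ratio=4.0, D=1, chain=TwoStateChainSpec(T=500, eps_trans=0.01, seed=3)
        )
        X, Pi, states = gen_example1(spec)
        Xs, _ = zscore_rows(X)
        m = fit(Xs, Pi, HyperParams(1.0, 1e-2, 1e-2, 2), n_starts=5, seed=0)
        pi_hat = m.lam @ m.gamma_train
        assert auc_score(pi_hat[1], states == 2) >= 0.95

    def test_cluster_permutation_invariant_final_loss(self, rng):
        X, Pi, *_ = random_instance(rng, D=2, K=3, T=15, M=2)
        hp = HyperParams(1.0, 1e-2, 1e-2, 3)
        m1 = fit(X, Pi, hp, n_starts=1, seed=4)
        # permuting cluster identities of the solution leaves the loss unchanged
        perm = np.array([2, 0, 1])
        loss_perm = eval_loss(
            X,
            Pi,
            m1.gamma_train[perm],
            GaussianCentroids(m1.theta.mu[:, perm], m1.theta.sigma[:, perm]),
            m1.lam[:, perm],
            m1.W,
            m1.P,
            hp,
        )
        assert loss_perm.total == pytest.approx(m1.loss.total, abs=1e-6)

    def test_input_validation(self, rng):
        X, Pi, *_ = random_instance(rng, D=2, K=2, T=10)
        with pytest.raises(ValueError, match="K=11"):
            fit(X, Pi, HyperParams(1.0, 0.1, 0.1, 11))
        Xbad = X.copy()
        Xbad[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit(Xbad, Pi, HyperParams(1.0, 0.1, 0.1, 2))


class TestPredict:
    def test_identity_classifier_returns_affiliations(self, rng):
        X, Pi, *_ = random_instance(rng, D=2, K=2, T=30)
        m = fit(X, Pi, HyperParams(1.0, 1e-2, 1e-2, 2), n_starts=1, seed=0)
        m.lam = np.eye(2)
        pi_hat, gamma = predict(m, rng.normal(size=(2, 20)))
        np.testing.assert_allclose(pi_hat, gamma, atol=1e-12)

    def test_prediction_columns_stochastic(self, rng):
        X, Pi, *_ = random_instance(rng, D=2, K=3, T=30)
        m = fit(X, Pi, HyperParams(1.0, 1e-2, 1e-2, 3), n_starts=1, seed=0)
        pi_hat, _ = predict(m, rng.normal(size=(2, 25)))
        np.testing.assert_allclose(pi_hat.sum(axis=0), 1.0, atol=1e-8)

    def test_start_independence_on_distinct_likelihoods(self):
        spec = Example1Spec(
            sigma_ratio=4.0, D=1, chain=TwoStateChainSpec(T=300, eps_trans=0.01, seed=9)
        )
        X, Pi, _ = gen_example1(spec)
        m = fit(X, Pi, HyperParams(1.0, 1e-2, 1e-2, 2), n_starts=2, seed=0)
        Xte = gen_example1(
            Example1Spec(sigma_ratio=4.0, D=1, chain=TwoStateChainSpec(T=200, seed=10))
        )[0]
        p1, _ = predict(m, Xte, seed=1)
        p2, _ = predict(m, Xte, seed=2)
        np.testing.assert_allclose(p1, p2, atol=1e-4)

    def test_feature_count_mismatch(self, rng):
        X, Pi, *_ = random_instance(rng, D=3, K=2, T=20)
        m = fit(X, Pi, HyperParams(1.0, 1e-2, 1e-2, 2), n_starts=1, seed=0)
        with pytest.raises(ValueError, match="features"):
            predict(m, rng.normal(size=(2, 10)))


class TestOneShot:
    def test_classification_term_zero_by_construction(self, rng):
        Pi = random_onehot(rng, 2, 40)
        X = rng.normal(size=(1, 40)) * np.where(Pi[0] == 1, 1.0, 3.0)
        model, _ = fit_oneshot(X, Pi, grid=GridSpec(eps_CL=(0.0,), eps_L=(1.0,), eps_E=(1e-2,), K=(2,)))
        # evaluate the KL term with a *positive* classification weight
        hp = HyperParams(1.0, 1e-2, 1e-2, 2)
        loss = eval_loss(X, Pi, model.gamma_train, model.theta, model.lam, model.W, model.P, hp)
        assert loss.classification_term == 0.0
        np.testing.assert_allclose(model.lam, np.eye(2))

    def test_gamma_solve_count_equals_grid_size(self, rng, monkeypatch):
        Pi = random_onehot(rng, 2, 30)
        X = rng.normal(size=(1, 30))
        calls = {"n": 0}
        real = learning_mod.spgqp_solve

        def counting(*args, **kwargs):
            calls["n"] += 1
            return real(*args, **kwargs)

        monkeypatch.setattr(learning_mod, "spgqp_solve", counting)
        grid = GridSpec(eps_CL=(0.0,), eps_L=(1e-2, 1.0, 5.0), eps_E=(1e-3, 1e-1), K=(2,))
        fit_oneshot(X, Pi, grid=grid)
        assert calls["n"] == len(grid.eps_L) * len(grid.eps_E)

    def test_nanopore_cross_sequence_accuracy(self):
        Xtr, Pitr, _ = gen_nanopore_toy(NanoporeToySpec(n_bases=40, seed=11))
        Xte, Pite, _ = gen_nanopore_toy(NanoporeToySpec(n_bases=40, seed=22))
        model, _ = fit_oneshot(Xtr, Pitr)
        pi_hat, _ = predict(model, Xte, seed=0)
        acc = np.mean(np.argmax(pi_hat, axis=0) == np.argmax(Pite, axis=0))
        assert acc >= 0.95

    def test_label_count_must_match_clusters(self, rng):
        Pi = random_onehot(rng, 3, 30)
        X = rng.normal(size=(2, 30))
        with pytest.raises(ValueError, match="bijective"):
            fit_oneshot(X, Pi, P=np.eye(2))

    def test_missing_label_rejected(self, rng):
        Pi = np.zeros((2, 20))
        Pi[0] = 1.0
        with pytest.raises(ValueError, match="label"):
            fit_oneshot(rng.normal(size=(1, 20)), Pi)


class TestStepConditionalOptimality:
    """No random feasible perturbation of an analytic step's output may
    decrease the loss term(s) that the step minimizes."""

    def test_perturbations_never_improve(self, rng):
        X, Pi, gamma, theta, lam, W = random_instance(rng, D=3, K=2, T=15)
        hp = HyperParams(0.9, 0.06, 0.3, 2)
        theta_star = update_mu_sigma(X, gamma)
        lam_star = update_lambda(Pi, gamma)
        W_star = update_w(X, gamma, theta_star, hp)

        f_mu = likelihood_term(X, gamma, theta_star.mu, theta_star.sigma, W_star, hp)
        loss_star = eval_loss(X, Pi, gamma, theta_star, lam_star, W_star, None, hp)
        for _ in range(200):
            mu_p = theta_star.mu + rng.normal(scale=0.05, size=theta_star.mu.shape)
            sig_p = theta_star.sigma * np.exp(rng.normal(scale=0.05, size=theta_star.sigma.shape))
            assert likelihood_term(X, gamma, mu_p, sig_p, W_star, hp) >= f_mu - 1e-12

            lam_p = lam_star + rng.normal(scale=0.05, size=lam_star.shape)
            lam_p = np.clip(lam_p, 1e-9, None)
            lam_p /= lam_p.sum(axis=0)
            loss_p = eval_loss(X, Pi, gamma, theta_star, lam_p, W_star, None, hp)
            assert loss_p.classification_term >= loss_star.classification_term - 1e-12

            W_p = np.clip(W_star + rng.normal(scale=0.05, size=W_star.shape), 1e-12, None)
            W_p /= W_p.sum()
            loss_w = eval_loss(X, Pi, gamma, theta_star, lam_star, W_p, None, hp)
            assert (
                loss_w.likelihood_term + loss_w.entropy_term
                >= loss_star.likelihood_term + loss_star.entropy_term - 1e-12
            )


class TestGridSearch:
    def _dataset(self, seed=0, ratio=3.0, T=240):
        spec = Example1Spec(
            sigma_ratio=ratio,
            D=1,
            chain=TwoStateChainSpec(T=T, eps_trans=0.01, mode="block-dwell", seed=seed),
        )
        return gen_example1(spec)

    def test_singleton_grid_returns_that_model(self):
        X, Pi, _ = self._dataset()
        grid = GridSpec(eps_CL=(1e-2,), eps_L=(1.0,), eps_E=(1e-2,), K=(2,))
        res = grid_search(X, Pi, grid=grid, n_starts=2, seed=0)
        assert len(res.table) == 1
        assert res.best_model.hp == HyperParams(1.0, 1e-2, 1e-2, 2)

    def test_table_has_one_row_per_combination(self):
        X, Pi, _ = self._dataset()
        grid = GridSpec(eps_CL=(1e-3, 1e-2), eps_L=(1e-2, 1.0), eps_E=(1e-2,), K=(2,))
        res = grid_search(X, Pi, grid=grid, n_starts=1, seed=0)
        assert len(res.table) == grid.n == 4

    def test_single_class_split_rejected(self, rng):
        X = rng.normal(size=(1, 60))
        Pi = np.zeros((2, 60))
        Pi[0, :55] = 1.0
        Pi[1, 55:] = 1.0  # test block single-class
        with pytest.raises(ValueError, match="single class"):
            grid_search(X, Pi, grid=GridSpec(eps_CL=(1e-2,), eps_L=(1.0,), eps_E=(1e-2,), K=(2,)))

    def test_separable_data_selected_model_generalizes(self):
        X, Pi, states = self._dataset(seed=5, ratio=4.0, T=360)
        grid = GridSpec(eps_CL=(1e-2,), eps_L=(1e-2, 1.0), eps_E=(1e-2,), K=(2,))
        res = grid_search(X, Pi, grid=grid, n_starts=3, seed=0)
        assert res.test_auc >= 0.9
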