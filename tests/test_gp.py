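"""GP core: closed forms, dense-formula oracles, posterior behavior, NLPD."""

import numpy as np
import pytest

from rxndkl.gp import (
    GaussianProcess,
    GPState,
    KernelParams,
    PredictiveDistribution,
    fit_gp,
    log_marginal_likelihood,
    matern52_gram,
    nlpd,
    posterior_predict,
)
from rxndkl.synthetic import gp_draw_dataset

SQRT5 = np.sqrt(5.0)


def dense_lml(X, y, params):
    """Brute-force oracle: explicit inverse and determinant of Eq.-style LML."""
    K = matern52_gram(X, X, params) + params.noise * np.eye(len(y))
    sign, logdet = np.linalg.slogdet(K)
    assert sign > 0
    return -0.5 * (y @ np.linalg.inv(K) @ y + logdet + len(y) * np.log(2 * np.pi))


def dense_posterior(X, y, params, Xs):
    """Brute-force oracle for the posterior mean/variance (predictive for y*)."""
    K = matern52_gram(X, X, params) + params.noise * np.eye(len(y))
    Ks = matern52_gram(Xs, X, params)
    Kinv = np.linalg.inv(K)
    mean = Ks @ Kinv @ y
    var = params.outputscale + params.noise - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mean, var


class TestKernel:
    def test_zero_distance_gives_outputscale(self):
        p = KernelParams(1.3, 2.5, 0.0)
        K = matern52_gram(np.zeros((1, 3)), np.zeros((1, 3)), p)
        assert K[0, 0] == pytest.approx(2.5)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 4))
        K = matern52_gram(A, A, KernelParams(0.7, 1.2, 0.0))
        np.testing.assert_array_equal(K, K.T)

    def test_value_at_one_lengthscale(self):
        p = KernelParams(2.0, 1.0, 0.0)
        K = matern52_gram(np.array([[0.0]]), np.array([[2.0]]), p)
        expected = (1 + SQRT5 + 5 / 3) * np.exp(-SQRT5)
        assert K[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_width_mismatch_and_nonfinite_rejected(self):
        p = KernelParams()
        with pytest.raises(ValueError):
            matern52_gram(np.zeros((2, 3)), np.zeros((2, 4)), p)
        with pytest.raises(ValueError):
            matern52_gram(np.array([[np.nan]]), np.zeros((1, 1)), p)

    def test_gram_psd_on_random_point_sets(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n, d = rng.integers(2, 15), rng.integers(1, 6)
            X = rng.standard_normal((n, d)) * rng.uniform(0.1, 3)
            K = matern52_gram(X, X, KernelParams(rng.uniform(0.2, 3), rng.uniform(0.1, 2), 0.0))
            assert np.linalg.eigvalsh(K + 1e-8 * np.eye(n)).min() >= 0


class TestLML:
    def test_single_point_unit_variance(self):
        state = GPState(np.zeros((1, 1)), np.zeros(1), KernelParams(1.0, 1.0, 0.0))
        assert log_marginal_likelihood(state) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_two_point_identity_covariance(self):
        # K + noise*I = I via outputscale->0 limit with noise 1: use tiny outputscale
        state = GPState(
            np.array([[0.0], [1e6]]), np.ones(2), KernelParams(1.0, 1e-300, 1.0)
        )
        assert log_marginal_likelihood(state) == pytest.approx(-1 - np.log(2 * np.pi), abs=1e-9)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n, d = rng.integers(2, 21), rng.integers(1, 9)
            X = rng.standard_normal((n, d))
            y = rng.standard_normal(n)
            p = KernelParams(rng.uniform(0.3, 2), rng.uniform(0.3, 2), rng.uniform(0.05, 1))
            state = GPState(X, y, p)
            assert log_marginal_likelihood(state) == pytest.approx(dense_lml(X, y, p), abs=1e-8)


class TestPosterior:
    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n, d = rng.integers(2, 21), rng.integers(1, 9)
            X, Xs = rng.standard_normal((n, d)), rng.standard_normal((5, d))
            y = rng.standard_normal(n)
            p = KernelParams(rng.uniform(0.3, 2), rng.uniform(0.3, 2), rng.uniform(0.05, 1))
            pred = posterior_predict(GPState(X, y, p), Xs)
            mean, var = dense_posterior(X, y, p, Xs)
            np.testing.assert_allclose(pred.mean, mean, atol=1e-8)
            np.testing.assert_allclose(pred.variance, var, atol=1e-8)

    def test_noiseless_interpolation(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(0, 3, (15, 2))
        y = np.sin(X[:, 0]) * np.cos(X[:, 1])
        pred = posterior_predict(GPState(X, y, KernelParams(1.0, 1.0, 1e-12)), X)
        np.testing.assert_allclose(pred.mean, y, atol=1e-4)
        assert pred.variance.max() <= 1e-6

    def test_far_query_reverts_to_prior(self):
        p = KernelParams(0.5, 1.7, 0.3)
        state = GPState(np.zeros((3, 1)), np.array([1.0, 2.0, 3.0]), p)
        pred = posterior_predict(state, np.array([[1e6]]))
        assert pred.mean[0] == pytest.approx(0.0, abs=1e-6)  # prior mean
        assert pred.variance[0] == pytest.approx(p.outputscale + p.noise, abs=1e-6)

    def test_duplicate_training_point_never_increases_variance(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((10, 2))
        y = rng.standard_normal(10)
        p = KernelParams(1.0, 1.0, 0.1)
        v_before = posterior_predict(GPState(X, y, p), X[:1]).variance[0]
        X2 = np.vstack([X, X[:1]])
        y2 = np.append(y, y[0])
        v_after = posterior_predict(GPState(X2, y2, p), X[:1]).variance[0]
        assert v_after <= v_before + 1e-12

    def test_width_mismatch_rejected(self):
        state = GPState(np.zeros((3, 2)), np.zeros(3), KernelParams())
        with pytest.raises(ValueError):
            posterior_predict(state, np.zeros((1, 5)))


class TestFit:
    def test_fit_never_worse_than_init(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 3))
        y = rng.standard_normal(30)
        init = KernelParams(1.0, 1.0, 0.1)
        state = fit_gp(X, y, init=init)
        assert log_marginal_likelihood(state) >= log_marginal_likelihood(GPState(X, y, init)) - 1e-9

    def test_lengthscale_recovery(self):
        """Hyperparameter recovery on data drawn from the prior (small version)."""
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            X = rng.uniform(0, 4, (120, 2))
            y = gp_draw_dataset(X, KernelParams(1.0, 1.0, 0.01), seed=seed)
            state = fit_gp(X, (y - y.mean()) / y.std())
            hits += 0.5 <= state.params.lengthscale <= 2.0
        assert hits >= 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gp(np.zeros((1, 1)), np.zeros(1))
        with pytest.raises(ValueError):
            fit_gp(np.zeros((0, 1)), np.zeros(0))


class TestNLPD:
    def test_standard_normal_at_mode(self):
        pred = PredictiveDistribution(mean=np.zeros(5), variance=np.ones(5))
        assert nlpd(pred, np.zeros(5)) == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_three_sigma_miss(self):
        sigma2 = 0.49
        pred = PredictiveDistribution(mean=np.array([3 * np.sqrt(sigma2)]), variance=np.array([sigma2]))
        expected = 0.5 * np.log(2 * np.pi * sigma2) + 4.5
        assert nlpd(pred, np.zeros(1)) == pytest.approx(expected, abs=1e-12)

    def test_shrinking_variance_at_correct_mean_decreases_nlpd(self):
        values = [
            nlpd(PredictiveDistribution(mean=np.zeros(3), variance=np.full(3, v)), np.zeros(3))
            for v in (1.0, 0.5, 0.1, 0.01)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        mean, var, t = rng.standard_normal(20), rng.uniform(0.1, 2, 20), rng.standard_normal(20)
        perm = rng.permutation(20)
        a = nlpd(PredictiveDistribution(mean=mean, variance=var), t)
        b = nlpd(PredictiveDistribution(mean=mean[perm], variance=var[perm]), t[perm])
        assert a == pytest.approx(b, abs=1e-12)

    def test_sum_mode_is_n_times_mean(self):
        pred = PredictiveDistribution(mean=np.zeros(4), variance=np.ones(4))
        assert nlpd(pred, np.zeros(4), reduce="sum") == pytest.approx(4 * nlpd(pred, np.zeros(4)))

    def test_nonpositive_variance_rejected(self):
        pred = PredictiveDistribution(mean=np.zeros(2), variance=np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            nlpd(pred, np.zeros(2))


class TestModelSurface:
    def test_fit_predict_in_yield_units(self, small_grid_features):
        X, y = small_grid_features
        res = GaussianProcess(X[:60], y[:60]).fit()
        pred = res.predict(X[60:80])
        assert pred.scale_tag == "original"
        assert np.all(pred.variance > 0)
        assert 0 < pred.mean.mean() < 100
        text = res.summary()
        assert "Lengthscale" in text and "Log marginal likelihood" in text

    def test_training_fit_quality(self, small_grid_features):
        X, y = small_grid_features
        res = GaussianProcess(X, y).fit()
        pred = res.predict(X)
        assert np.sqrt(np.mean((pred.mean - y) ** 2)) < np.std(y)

    def test_model_file_round_trip(self, small_grid_features, tmp_path):
        from rxndkl.gp import GPResults

        X, y = small_grid_features
        res = GaussianProcess(X[:40], y[:40]).fit()
        path = tmp_path / "gp_model.npz"
        res.save(path)
        loaded = GPResults.load(path)
        a, b = res.predict(X[40:50]), loaded.predict(X[40:50])
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-10)
        np.testing.assert_allclose(a.variance, b.variance, atol=1e-10)
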