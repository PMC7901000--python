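"""RSS emulator: evidence, prediction, analytic derivatives, potentials."""

import numpy as np
import pytest

from pulsecal.gp import (
    GPPrediction,
    RssEmulator,
    SEKernelHyper,
    TrainingSet,
    potential_exploratory,
    potential_sampling,
)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(3)
    X = rng.uniform(-1, 1, (40, 4))
    y = 8.0 + 2 * np.sin(2 * X[:, 0]) + X[:, 1] ** 2 + 0.5 * X[:, 2] * X[:, 3]
    em = RssEmulator(TrainingSet(X, y))
    em.fit_hyperparameters(rng=0, n_restarts=3)
    return em


class TestEvidence:
    def test_single_point_unit_variance(self):
        em = RssEmulator(
            TrainingSet(np.zeros((1, 1)), np.array([5.0])),
            SEKernelHyper(0.5, np.array([1.0]), 0.5),
        )
        # one standardised target 0 with prior variance v + nugget = 1
        assert em.log_marginal_likelihood() == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_matches_dense_formula(self, fitted):
        X, y = fitted.train.X, fitted.train.targets
        ys = (y - y.mean()) / y.std()
        from pulsecal.gp import _se_kernel

        K = _se_kernel(X, X, fitted.hyper) + fitted.hyper.nugget * np.eye(len(X))
        sign, logdet = np.linalg.slogdet(K)
        direct = (
            -0.5 * ys @ np.linalg.solve(K, ys)
            - 0.5 * logdet
            - 0.5 * len(ys) * np.log(2 * np.pi)
        )
        assert fitted.log_marginal_likelihood() == pytest.approx(direct, rel=1e-9)

    def test_matches_sklearn(self, fitted):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

        X, y = fitted.train.X, fitted.train.targets
        ys = (y - y.mean()) / y.std()
        k = ConstantKernel(fitted.hyper.signal_variance, "fixed") * RBF(
            fitted.hyper.lengthscales, "fixed"
        ) + WhiteKernel(fitted.hyper.nugget, "fixed")
        g = GaussianProcessRegressor(kernel=k, alpha=0.0, optimizer=None).fit(X, ys)
        assert fitted.log_marginal_likelihood() == pytest.approx(
            g.log_marginal_likelihood_value_, rel=1e-8
        )
        x0 = np.array([0.1, -0.2, 0.3, 0.05])
        mu_sk = g.predict(x0[None, :])[0] * y.std() + y.mean()
        assert fitted.predict(x0).mean == pytest.approx(mu_sk, rel=1e-8)

    def test_optimum_beats_restart_initialisations(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (25, 2))
        y = 3.0 + np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        em = RssEmulator(TrainingSet(X, y))
        em.fit_hyperparameters(rng=1, n_restarts=4)
        best = em.log_marginal_likelihood()
        naive = SEKernelHyper(1.0, np.array([1.0, 1.0]), 1e-4)
        assert best >= em.log_marginal_likelihood(naive) - 1e-8


class TestHyperparameterRecovery:
    def test_lengthscales_within_factor_two(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(-1, 1, (60, 2))
        true = SEKernelHyper(1.0, np.array([0.4, 0.9]), 1e-6)
        from pulsecal.gp import _se_kernel

        K = _se_kernel(X, X, true) + 1e-8 * np.eye(60)
        f = np.linalg.cholesky(K) @ rng.standard_normal(60)
        y = f - f.min() + 0.1  # shift into RSS-positive territory
        em = RssEmulator(TrainingSet(X, y))
        em.fit_hyperparameters(rng=2, n_restarts=5)
        ratio = em.hyper.lengthscales / true.lengthscales
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_constant_targets_degenerate_gracefully(self):
        X = np.random.default_rng(0).uniform(-1, 1, (10, 2))
        em = RssEmulator(TrainingSet(X, np.full(10, 3.0)))
        em.fit_hyperparameters(rng=0, n_restarts=2)
        p = em.predict(np.zeros(2))
        assert p.mean == pytest.approx(3.0, abs=1e-6)


class TestPrediction:
    def test_interpolates_training_point(self, fitted):
        x0 = fitted.train.X[7]
        p = fitted.predict(x0)
        assert p.mean == pytest.approx(fitted.train.targets[7], rel=1e-5)
        assert p.variance < 1e-4

    def test_far_field_reverts_to_prior(self, fitted):
        p = fitted.predict(np.full(4, 60.0))
        y = fitted.train.targets
        assert p.mean == pytest.approx(y.mean(), rel=1e-6)
        prior_var = fitted.hyper.signal_variance * y.std() ** 2
        assert p.variance == pytest.approx(prior_var, rel=1e-3)

    def test_batch_matches_scalar(self, fitted):
        rng = np.random.default_rng(2)
        Xq = rng.uniform(-1, 1, (8, 4))
        mu, var = fitted.predict_batch(Xq)
        for i in range(8):
            p = fitted.predict(Xq[i])
            assert mu[i] == pytest.approx(p.mean, rel=1e-9)
            assert var[i] == pytest.approx(p.variance, rel=1e-9, abs=1e-12)


class TestDerivatives:
    @pytest.fixture(scope="class")
    def query(self):
        return np.array([0.1, -0.2, 0.3, 0.05])

    def test_gradient_matches_finite_differences(self, fitted, query):
        h = 1e-4
        pd = fitted.predict_derivatives(query, order=1)
        for i, e in enumerate(np.eye(4)):
            fd = (fitted.predict(query + h * e).mean - fitted.predict(query - h * e).mean) / (2 * h)
            assert pd.gradient[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_variance_gradient_matches_finite_differences(self, fitted, query):
        h = 1e-4
        pd = fitted.predict_derivatives(query, order=1)
        for i, e in enumerate(np.eye(4)):
            fd = (fitted.predict(query + h * e).variance - fitted.predict(query - h * e).variance) / (2 * h)
            assert pd.variance_gradient[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_hessian_matches_finite_differences(self, fitted, query):
        h = 1e-4
        pd = fitted.predict_derivatives(query, order=2)
        for j, e in enumerate(np.eye(4)):
            gp = fitted.predict_derivatives(query + h * e, 1).gradient
            gm = fitted.predict_derivatives(query - h * e, 1).gradient
            fd = (gp - gm) / (2 * h)
            assert np.allclose(pd.hessian[:, j], fd, rtol=1e-5, atol=1e-7)

    def test_third_order_matches_finite_differences(self, fitted, query):
        h = 1e-4
        pd = fitted.predict_derivatives(query, order=3)
        for k, e in enumerate(np.eye(4)):
            Hp = fitted.predict_derivatives(query + h * e, 2).hessian
            Hm = fitted.predict_derivatives(query - h * e, 2).hessian
            fd = (Hp - Hm) / (2 * h)
            assert np.allclose(pd.third[:, :, k], fd, rtol=1e-4, atol=1e-6)

    def test_third_order_fully_symmetric(self, fitted, query):
        T = fitted.predict_derivatives(query, order=3).third
        for perm in [(1, 0, 2), (2, 1, 0), (0, 2, 1)]:
            assert np.max(np.abs(T - np.transpose(T, perm))) < 1e-10

    def test_invalid_order_rejected(self, fitted, query):
        with pytest.raises(ValueError):
            fitted.predict_derivatives(query, order=4)


class TestTrainingSetUpdates:
    def test_add_then_remove_restores_evidence(self, fitted):
        before = fitted.log_marginal_likelihood()
        em = RssEmulator(fitted.train, fitted.hyper)
        em.add_point(np.array([0.9, 0.9, -0.9, 0.2]), 6.0)
        em.remove_point(len(em.train) - 1)
        assert em.log_marginal_likelihood() == pytest.approx(before, abs=1e-8)

    def test_duplicate_add_rejected(self, fitted):
        em = RssEmulator(fitted.train, fitted.hyper)
        with pytest.raises(ValueError):
            em.add_point(fitted.train.X[0], 1.0)

    def test_negative_target_rejected(self, fitted):
        with pytest.raises(ValueError):
            fitted.train.add(np.zeros(4), -1.0)

    def test_variance_shrinks_after_adding_nearby_point(self, fitted):
        x0 = np.array([0.5, 0.5, 0.5, 0.5])
        v_before = fitted.predict(x0).variance
        em = RssEmulator(fitted.train, fitted.hyper)
        em.add_point(x0, 9.0)
        assert em.predict(x0).variance <= v_before + 1e-12


class TestPotentials:
    def test_zero_sd_makes_phases_agree(self):
        pred = GPPrediction(mean=10.0, variance=0.0)
        e = potential_exploratory(pred, 1.0, 5, -2.0)
        s = potential_sampling(pred, 1.0, 5, -2.0)
        assert e == pytest.approx(s)

    def test_uncertainty_lowers_exploratory_potential(self):
        base = potential_exploratory(GPPrediction(10.0, 1.0), 1.0, 0, 0.0)
        more = potential_exploratory(GPPrediction(10.0, 9.0), 1.0, 0, 0.0)
        assert more < base

    def test_exploratory_value(self):
        pred = GPPrediction(mean=10.0, variance=16.0)  # sd = 4
        assert potential_exploratory(pred, 1.0, 0, 0.0) == pytest.approx(3.0)

    def test_sampling_zeroes(self):
        assert potential_sampling(GPPrediction(0.0, 1.0), 1.0, 0, 0.0) == 0.0

    def test_sampling_value(self):
        pred = GPPrediction(mean=14.0, variance=1.0)
        expect = 3.5 + 1.5 * np.log(4 * np.pi) + 1.0
        assert potential_sampling(pred, 2.0, 3, -1.0) == pytest.approx(expect)

    def test_variance_switch(self):
        pred = GPPrediction(mean=10.0, variance=16.0)
        assert potential_exploratory(pred, 1.0, 0, 0.0, use_sd=False) == pytest.approx(-3.0)
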