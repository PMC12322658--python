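"""Gaussian-process surrogate: kernel, marginal likelihood, posterior."""

import numpy as np
import pytest

from optoferm import Condition, GaussianProcess, GPHyperparams
from optoferm.calibration import GPTrainingSet
from optoferm.gp import (
    ParameterSurrogate,
    kernel_matrix,
    log_marginal_likelihood,
    matern52,
)
from optoferm.model import PARAM_NAMES

HYP = GPHyperparams(signal_variance=1.0, length_scales=(1.0, 1.0), noise_variance=0.1)


class TestMatern52:
    def test_zero_distance_gives_signal_variance(self):
        h = GPHyperparams(2.7, (0.3, 4.0), 0.01)
        v = np.array([1.2, -0.5])
        assert matern52(v, v, h) == pytest.approx(2.7)

    def test_unit_distance_closed_form(self):
        # r=1: (1 + sqrt5 + 5/3) * exp(-sqrt5) = 0.52399...
        expected = (1 + np.sqrt(5) + 5 / 3) * np.exp(-np.sqrt(5))
        got = matern52(np.array([1.0, 0.0]), np.array([0.0, 0.0]), HYP)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.5240, abs=5e-5)

    def test_vanishes_at_long_range_and_symmetric(self):
        a, b = np.array([100.0, -50.0]), np.array([0.0, 0.0])
        assert matern52(a, b, HYP) < 1e-10
        assert matern52(a, b, HYP) == matern52(b, a, HYP)

    def test_ard_length_scales_act_per_feature(self):
        h = GPHyperparams(1.0, (1.0, 100.0), 0.01)
        # displacement along the long-length-scale feature barely decorrelates
        near = matern52(np.array([0.0, 5.0]), np.array([0.0, 0.0]), h)
        far = matern52(np.array([5.0, 0.0]), np.array([0.0, 0.0]), h)
        assert near > 0.99
        assert far < 0.1


class TestKernelMatrix:
    def test_single_point(self):
        K = kernel_matrix(np.array([[3.0], [1.0]]), HYP)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(HYP.signal_variance)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        V = rng.normal(size=(2, 5))
        h = GPHyperparams(1.7, (0.8, 2.5), 0.05)
        K = kernel_matrix(V, h)
        for i in range(5):
            for j in range(5):
                assert K[i, j] == pytest.approx(matern52(V[:, i], V[:, j], h), abs=1e-12)

    def test_duplicated_point_factorizes_with_noise(self):
        V = np.array([[1.0, 1.0, 2.0], [0.0, 0.0, 1.0]])  # first two identical
        y = np.array([1.0, 1.1, 2.0])
        # rank-deficient K, but K + noise*I is SPD: LML must evaluate
        val = log_marginal_likelihood(V, y, HYP)
        assert np.isfinite(val)


class TestLogMarginalLikelihood:
    def test_univariate_zero_label(self):
        h = GPHyperparams(0.6, (1.0, 1.0), 0.4)  # total variance 1.0
        V = np.array([[0.0], [0.0]])
        assert log_marginal_likelihood(V, np.array([0.0]), h) == pytest.approx(
            -0.5 * np.log(2 * np.pi), rel=1e-10
        )

    def test_univariate_closed_form(self):
        h = GPHyperparams(1.5, (1.0, 1.0), 0.5)
        y1, s2 = 0.7, 2.0
        expected = -0.5 * y1**2 / s2 - 0.5 * np.log(s2) - 0.5 * np.log(2 * np.pi)
        got = log_marginal_likelihood(np.array([[0.0], [0.0]]), np.array([y1]), h)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_point_order(self):
        rng = np.random.default_rng(3)
        V = rng.normal(size=(2, 6))
        y = rng.normal(size=6)
        perm = rng.permutation(6)
        a = log_marginal_likelihood(V, y, HYP)
        b = log_marginal_likelihood(V[:, perm], y[perm], HYP)
        assert a == pytest.approx(b, rel=1e-12)


def _toy_gp(noise=1e-12, standardize=False):
    gp = GaussianProcess(feature_scale=np.array([1.0, 1.0]), standardize_labels=standardize)
    V = np.array([[0.0, 1.0, 2.5], [0.0, 0.0, 0.0]])
    y = np.array([1.0, 2.0, 1.5])
    h = GPHyperparams(1.0, (1.0, 1.0), noise)
    gp.set_hyperparams(V, y, h)
    return gp, V, y, h


class TestPosterior:
    def test_interpolates_training_labels_at_tiny_noise(self):
        gp, V, y, _ = _toy_gp(noise=1e-12)
        for i in range(V.shape[1]):
            post = gp.predict(V[:, i])
            assert post.mean == pytest.approx(y[i], rel=1e-6)
            assert post.variance == pytest.approx(0.0, abs=1e-6)

    def test_reverts_to_prior_far_from_data(self):
        gp, _, _, h = _toy_gp(noise=0.01)
        post = gp.predict(np.array([500.0, 0.0]))
        assert post.mean == pytest.approx(0.0, abs=1e-8)  # raw zero prior mean
        assert post.variance == pytest.approx(h.signal_variance, rel=1e-6)

    def test_standardized_mode_reverts_to_label_mean(self):
        gp, _, y, _ = _toy_gp(noise=0.01, standardize=True)
        post = gp.predict(np.array([500.0, 0.0]))
        assert post.mean == pytest.approx(float(np.mean(y)), rel=1e-6)

    def test_matches_hand_linear_solve(self):
        gp, V, y, h = _toy_gp(noise=0.3)
        v_star = np.array([1.7, 0.0])
        K = kernel_matrix(V, h) + h.noise_variance * np.eye(3)
        k_star = np.array([matern52(V[:, i], v_star, h) for i in range(3)])
        mean = k_star @ np.linalg.solve(K, y)
        var = h.signal_variance - k_star @ np.linalg.solve(K, k_star)
        post = gp.predict(v_star)
        assert post.mean == pytest.approx(mean, rel=1e-10)
        assert post.variance == pytest.approx(var, rel=1e-8)

    def test_variance_bounded_by_prior(self):
        gp, _, _, h = _toy_gp(noise=0.05)
        for x in np.linspace(-3, 6, 40):
            post = gp.predict(np.array([x, 0.0]))
            assert 0.0 <= post.variance <= h.signal_variance + h.noise_variance + 1e-12

    def test_agrees_with_sklearn_reference(self):
        """Independent oracle: scikit-learn GP with identical fixed
        hyperparameters on a 10-point problem, agreement to 1e-6."""
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import ConstantKernel, Matern

        rng = np.random.default_rng(42)
        V = rng.uniform(0, 3, size=(2, 10))
        y = np.sin(V[0]) + 0.5 * V[1] ** 2
        h = GPHyperparams(2.0, (0.9, 1.4), 0.05)

        gp = GaussianProcess(feature_scale=np.array([1.0, 1.0]), standardize_labels=False)
        gp.set_hyperparams(V, y, h)

        kernel = ConstantKernel(h.signal_variance, "fixed") * Matern(
            length_scale=h.length_scales, length_scale_bounds="fixed", nu=2.5
        )
        ref = GaussianProcessRegressor(kernel=kernel, alpha=h.noise_variance,
                                       optimizer=None).fit(V.T, y)
        X_test = rng.uniform(-1, 4, size=(6, 2))
        mu_ref, std_ref = ref.predict(X_test, return_std=True)
        for k in range(6):
            post = gp.predict(X_test[k])
            assert post.mean == pytest.approx(mu_ref[k], abs=1e-6)
            assert np.sqrt(post.variance) == pytest.approx(std_ref[k], abs=1e-6)


class TestTraining:
    def test_recovers_length_scales_from_gp_draw(self):
        rng = np.random.default_rng(11)
        true = GPHyperparams(1.0, (0.4, 2.0), 1e-6)
        V = rng.uniform(0, 4, size=(2, 30))
        K = kernel_matrix(V, true) + true.noise_variance * np.eye(30)
        y = np.linalg.cholesky(K) @ rng.standard_normal(30)
        gp = GaussianProcess(feature_scale=np.array([1.0, 1.0]), standardize_labels=False)
        gp.fit(V, y, restarts=8, seed=5)
        for est, tru in zip(gp.hyper.length_scales, true.length_scales):
            assert tru / 2 <= est <= tru * 2

    def test_constant_labels_degenerate(self):
        V = np.array([[0.0, 1.0, 2.0, 3.0], [0.0, 1.0, 0.0, 1.0]])
        y = np.full(4, 7.3)
        gp = GaussianProcess().fit(V, y, restarts=4, seed=0)
        post = gp.predict(np.array([1.5, 0.5]))
        assert post.mean == pytest.approx(7.3, rel=1e-6)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        V = rng.uniform(0, 70, size=(2, 12))
        y = rng.uniform(1, 10, size=12)
        a = GaussianProcess().fit(V, y, restarts=4, seed=9)
        b = GaussianProcess().fit(V, y, restarts=4, seed=9)
        assert a.hyper == b.hyper

    def test_prediction_invariant_to_training_order(self):
        rng = np.random.default_rng(4)
        V = rng.uniform(0, 70, size=(2, 10))
        y = rng.uniform(1, 5, size=10)
        perm = rng.permutation(10)
        h = GPHyperparams(1.0, (0.5, 0.5), 0.01)
        a = GaussianProcess().set_hyperparams(V, y, h)
        b = GaussianProcess().set_hyperparams(V[:, perm], y[perm], h)
        v = np.array([33.0, 4.0])
        assert a.predict(v).mean == pytest.approx(b.predict(v).mean, rel=1e-10)
        assert a.predict(v).variance == pytest.approx(b.predict(v).variance, rel=1e-8)


class TestParameterSurrogate:
    def test_interpolates_truth_at_training_conditions(self, truth_surrogate, truth_surface):
        cond = Condition(30.0, 3)
        pred, var = truth_surrogate.predict_params(cond)
        truth = truth_surface.params_at(cond)
        for name in PARAM_NAMES:
            assert getattr(pred, name) == pytest.approx(getattr(truth, name), rel=0.05)
            assert var[name] >= 0.0

    def test_mismatched_feature_matrices_rejected(self, truth_surrogate):
        models = dict(truth_surrogate.models)
        V = np.array([[0.0, 10.0], [1.0, 1.0]])
        rogue = GaussianProcess().set_hyperparams(V, np.array([1.0, 2.0]), HYP)
        models["alpha"] = rogue
        with pytest.raises(ValueError, match="same feature matrix"):
            ParameterSurrogate(models)

    def test_missing_parameter_model_rejected(self, truth_surrogate):
        models = dict(truth_surrogate.models)
        del models["beta"]
        with pytest.raises(ValueError, match="beta"):
            ParameterSurrogate(models)

    def test_nonpositive_mean_floored_with_warning(self, truth_surrogate):
        from optoferm.gp import GPPosterior

        models = dict(truth_surrogate.models)

        class NegativeGP:
            _V = truth_surrogate.models["alpha"]._V
            feature_scale = truth_surrogate.models["alpha"].feature_scale

            def _require_fit(self):
                pass

            def predict(self, v, **kw):
                return GPPosterior(mean=-5.0, variance=1.0)

        models["alpha"] = NegativeGP()
        sur = ParameterSurrogate(models)
        with pytest.warns(UserWarning, match="non-positive"):
            pred, _ = sur.predict_params(Condition(30.0, 3))
        assert pred.alpha == ParameterSurrogate.FLOORS["alpha"]

    def test_persistence_roundtrip_bitexact(self, truth_surrogate, tmp_path):
        path = tmp_path / "surrogate.json"
        truth_surrogate.save(path)
        loaded = ParameterSurrogate.load(path)
        cond = Condition(42.0, 3)
        a, va = truth_surrogate.predict_params(cond)
        b, vb = loaded.predict_params(cond)
        for name in PARAM_NAMES:
            assert getattr(a, name) == getattr(b, name)  # bit-exact
            assert va[name] == vb[name]
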