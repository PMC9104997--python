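"""Deep-kernel GP core: kernel, evidence, gradients, SKI, fit/predict."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from iltox.dkl import (DeepKernelGP, DeepKernelGPResults, GridConfig,
                       KernelHyperparams, NetworkConfig, build_ski_covariance,
                       init_network, lml_and_gradients, log_marginal_likelihood,
                       nn_forward, rbf_kernel, _grid_nodes,
                       _lml_and_gradients_ski)


class TestRBFKernel:
    def test_zero_distance_gives_outputscale(self):
        k = KernelHyperparams(lengthscale=0.7, outputscale=2.5)
        assert rbf_kernel(np.array([1.0, -1.0]), np.array([1.0, -1.0]), k) \
            == pytest.approx(2.5)

    def test_distance_ell_sqrt2_gives_exp_minus_one(self):
        ell = 0.9
        z1 = np.zeros(2)
        z2 = np.array([ell * np.sqrt(2.0), 0.0])
        val = rbf_kernel(z1, z2, KernelHyperparams(ell, 1.0))
        assert val == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_symmetry_and_psd(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((15, 2))
        k = rbf_kernel(z, z, KernelHyperparams(0.5, 1.3))
        np.testing.assert_allclose(k, k.T, rtol=1e-14)
        assert np.linalg.eigvalsh(k).min() > -1e-10


class TestLogMarginalLikelihood:
    def test_scalar_closed_forms(self):
        # n=1, A=[1], y=0: -log(2 pi)/2 ;  n=1, A=[2], y=1: -1/4 - log2/2 - log(2 pi)/2
        assert log_marginal_likelihood(np.array([0.0]), np.array([[0.0]]), 1.0) \
            == pytest.approx(-0.9189385332, abs=1e-9)
        assert log_marginal_likelihood(np.array([1.0]), np.array([[1.0]]), 1.0) \
            == pytest.approx(-0.25 - 0.5 * np.log(2) - 0.9189385332, abs=1e-9)

    def test_matches_mvn_logpdf_oracle(self):
        rng = np.random.default_rng(4)
        n = 20
        b = rng.standard_normal((n, n))
        k = b @ b.T
        y = rng.standard_normal(n)
        sigma2 = 0.3
        expected = multivariate_normal.logpdf(y, mean=np.zeros(n),
                                              cov=k + sigma2 * np.eye(n))
        assert log_marginal_likelihood(y, k, sigma2) == pytest.approx(expected,
                                                                      abs=1e-8)


def _fd_check(fun, x0, analytic, h=1e-5, rtol=1e-4):
    fd = (fun(x0 + h) - fun(x0 - h)) / (2 * h)
    assert analytic == pytest.approx(fd, rel=rtol, abs=1e-8)


class TestGradients:
    """Analytic LML gradients vs central finite differences."""

    @pytest.mark.parametrize("seed", range(20))
    def test_exact_path(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        x = rng.standard_normal((n, 5))
        y = rng.standard_normal(n)
        net = NetworkConfig(layer_sizes=(5, 4, 2))
        weights = init_network(net, seed + 100)
        kern = KernelHyperparams(0.8, 1.3)
        sig2 = 0.3
        lml, g = lml_and_gradients(weights, net, kern, sig2, x, y)

        _fd_check(lambda le: lml_and_gradients(
            weights, net, KernelHyperparams(np.exp(le), 1.3), sig2, x, y)[0],
            np.log(0.8), g["d_log_lengthscale"])
        _fd_check(lambda ls: lml_and_gradients(
            weights, net, KernelHyperparams(0.8, np.exp(ls)), sig2, x, y)[0],
            np.log(1.3), g["d_log_outputscale"])
        _fd_check(lambda lg: lml_and_gradients(
            weights, net, kern, np.exp(lg), x, y)[0],
            np.log(0.3), g["d_log_noise"])

        # a spread of weight coordinates in every layer
        for li in range(len(weights)):
            for arr_i in (0, 1):
                arr = weights[li][arr_i]
                for flat in {0, arr.size // 2, arr.size - 1}:
                    ij = np.unravel_index(flat, arr.shape)

                    def f(v):
                        w2 = [(w.copy(), b.copy()) for w, b in weights]
                        w2[li][arr_i][ij] = v
                        return lml_and_gradients(w2, net, kern, sig2, x, y)[0]

                    _fd_check(f, arr[ij], g["d_weights"][li][arr_i][ij])

    def test_ski_path_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        n = 12
        z = rng.uniform(-1, 1, (n, 2))
        y = rng.standard_normal(n)
        grid = GridConfig(points_per_dim=10, bounds=((-1.5, 1.5), (-1.5, 1.5)))
        kern = KernelHyperparams(0.6, 1.1)
        _, g = _lml_and_gradients_ski(None, None, kern, 0.2, z, y, grid)
        _fd_check(lambda le: _lml_and_gradients_ski(
            None, None, KernelHyperparams(np.exp(le), 1.1), 0.2, z, y, grid)[0],
            np.log(0.6), g["d_log_lengthscale"])
        for i, d in [(0, 0), (5, 1), (11, 0)]:
            def f(v):
                z2 = z.copy()
                z2[i, d] = v
                return _lml_and_gradients_ski(None, None, kern, 0.2, z2, y, grid)[0]
            _fd_check(f, z[i, d], g["d_latent"][i, d])

    def test_noise_gradient_vanishes_at_optimum(self):
        # scalar problem with fixed K=0: optimum sigma^2 = y^2
        y = np.array([1.3, -1.3])
        k = np.zeros((2, 2))
        sig2_opt = float(np.mean(y ** 2))
        h = 1e-6
        up = log_marginal_likelihood(y, k, sig2_opt + h)
        dn = log_marginal_likelihood(y, k, sig2_opt - h)
        assert (up - dn) / (2 * h) == pytest.approx(0.0, abs=1e-6)


class TestNetwork:
    def test_zero_weights_give_zero_latent(self):
        net = NetworkConfig(layer_sizes=(5, 3, 2))
        weights = [(np.zeros((5, 3)), np.zeros(3)), (np.zeros((3, 2)), np.zeros(2))]
        out = nn_forward(weights, net, np.ones(5))
        np.testing.assert_array_equal(out, np.zeros(2))

    def test_single_identity_layer(self):
        net = NetworkConfig(layer_sizes=(2, 2))
        weights = [(np.eye(2), np.zeros(2))]
        x = np.array([0.3, -1.7])
        np.testing.assert_allclose(nn_forward(weights, net, x), x)

    def test_seeded_init_is_deterministic(self):
        net = NetworkConfig(layer_sizes=(5, 4, 2))
        x = np.linspace(-1, 1, 5)
        out1 = nn_forward(init_network(net, 12), net, x)
        out2 = nn_forward(init_network(net, 12), net, x)
        np.testing.assert_array_equal(out1, out2)

    def test_dimension_mismatch_rejected(self):
        net = NetworkConfig(layer_sizes=(5, 4, 2))
        with pytest.raises(ValueError, match="expects 5"):
            nn_forward(init_network(net, 0), net, np.ones(7))


class TestSKI:
    def test_exact_on_grid_nodes(self):
        kern = KernelHyperparams(0.5, 1.2)
        grid = GridConfig(points_per_dim=9, bounds=((-1, 1), (-1, 1)))
        nodes, _ = _grid_nodes(-1, 1, 9)
        z = np.array([[nodes[2], nodes[3]], [nodes[4], nodes[6]],
                      [nodes[3], nodes[3]]])
        w, kuu = build_ski_covariance(z, grid, kern)
        np.testing.assert_allclose(np.asarray((w @ kuu @ w.T).todense()
                                              if hasattr(w @ kuu @ w.T, "todense")
                                              else w @ kuu @ w.T),
                                   rbf_kernel(z, z, kern), atol=1e-12)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        z = rng.uniform(-1, 1, (30, 2))
        w, _ = build_ski_covariance(
            z, GridConfig(points_per_dim=12, bounds=((-1, 1), (-1, 1))),
            KernelHyperparams())
        np.testing.assert_allclose(np.asarray(w.sum(axis=1)).ravel(),
                                   np.ones(30), atol=1e-12)
        assert w.getnnz(axis=1).max() <= 16

    def test_gram_error_decreases_with_grid_size(self):
        rng = np.random.default_rng(1)
        z = rng.uniform(-1, 1, (50, 2))
        kern = KernelHyperparams(0.5, 1.0)
        exact = rbf_kernel(z, z, kern)
        errs = []
        for m in (8, 16, 32, 64):
            w, kuu = build_ski_covariance(
                z, GridConfig(points_per_dim=m, bounds=((-1, 1), (-1, 1))), kern)
            approx = w @ kuu @ w.T
            errs.append(np.linalg.norm(approx - exact) / np.linalg.norm(exact))
        assert all(a > b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-2

    def test_point_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="re-fit the grid bounds"):
            build_ski_covariance(
                np.array([[5.0, 0.0]]),
                GridConfig(points_per_dim=8, bounds=((-1, 1), (-1, 1))),
                KernelHyperparams())


def _gp_closed_form(res, x_train, y_train, x_query):
    """Textbook GP posterior through the fitted latents/hyperparameters."""
    zs = res.latent(x_train)
    qs = res.latent(x_query)
    k = rbf_kernel(zs, zs, res.kernel)
    ks = rbf_kernel(qs, zs, res.kernel)
    a = k + res.noise_variance * np.eye(len(y_train))
    ys = (y_train - res.y_mean) / res.y_sd
    mean = ks @ np.linalg.solve(a, ys) * res.y_sd + res.y_mean
    var = (res.kernel.outputscale
           - np.sum(ks * np.linalg.solve(a, ks.T).T, axis=1)) * res.y_sd ** 2
    return mean, var


@pytest.fixture(scope="module")
def toy_1d():
    rng = np.random.default_rng(8)
    x = np.sort(rng.uniform(-3, 3, (20, 1)), axis=0)
    y = np.sin(x[:, 0]) + 0.1 * rng.standard_normal(20)
    return x, y


@pytest.fixture(scope="module")
def fitted_1d():
    rng = np.random.default_rng(3)
    x = rng.uniform(-2, 2, (25, 1))
    y = 0.5 * x[:, 0] ** 2 + 0.1 * rng.standard_normal(25)
    return DeepKernelGP(y, x, network=None).fit(n_iter=100,
                                                covariance="exact", seed=3)


class TestFitPredict:
    def test_identity_map_matches_closed_form_gp(self, toy_1d):
        x, y = toy_1d
        res = DeepKernelGP(y, x, network=None).fit(
            n_iter=150, covariance="exact", seed=0)
        xq = np.linspace(-3, 3, 9)[:, None]
        dist = res.predict(xq)
        mean_cf, var_cf = _gp_closed_form(res, x, y, xq)
        np.testing.assert_allclose(dist.mean, mean_cf, atol=1e-6)
        np.testing.assert_allclose(dist.latent_sd ** 2, var_cf, atol=1e-6)

    def test_zero_iterations_returns_initialized_model(self, small_features):
        x, y = small_features
        model = DeepKernelGP(y, x)
        res = model.fit(n_iter=0, seed=4)
        assert res.lml_trace.size == 0
        expected = init_network(NetworkConfig(), 4)
        for (w, b), (we, be) in zip(res.weights, expected):
            np.testing.assert_array_equal(w, we)
            np.testing.assert_array_equal(b, be)
        assert res.kernel == KernelHyperparams()
        np.testing.assert_allclose(res.x_mean, x.mean(axis=0))

    def test_fit_is_deterministic(self, small_features):
        x, y = small_features
        r1 = DeepKernelGP(y, x).fit(n_iter=30, seed=2)
        r2 = DeepKernelGP(y, x).fit(n_iter=30, seed=2)
        assert r1.lml_trace[-1] == r2.lml_trace[-1]
        np.testing.assert_array_equal(r1.latent_train, r2.latent_train)

    def test_noise_variance_recovery(self):
        """Data simulated from a known GP: sigma^2 recovered within x2."""
        true = KernelHyperparams(1.0, 1.0)
        sig2_true = 0.04
        estimates = []
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            x = rng.uniform(-3, 3, (100, 1))
            k = rbf_kernel(x, x, true) + sig2_true * np.eye(100)
            y = np.linalg.cholesky(k) @ rng.standard_normal(100)
            res = DeepKernelGP(y, x, network=None).fit(
                n_iter=250, covariance="exact", seed=rep)
            estimates.append(res.noise_variance * res.y_sd ** 2)
        med = np.median(estimates)
        assert sig2_true / 2 <= med <= sig2_true * 2

    def test_interpolation_limit(self, toy_1d):
        # near-zero noise: the posterior mean interpolates the targets
        # (a short lengthscale keeps the Gram numerically well-conditioned)
        x, y = toy_1d
        res = DeepKernelGP(y, x, network=None).fit(
            n_iter=0, covariance="exact", init_noise=1e-8,
            init_kernel=KernelHyperparams(0.15, 1.0))
        np.testing.assert_allclose(res.predict(x).mean, y, atol=1e-4)

    def test_prior_reversion_far_from_data(self, toy_1d):
        x, y = toy_1d
        res = DeepKernelGP(y, x, network=None).fit(
            n_iter=100, covariance="exact", seed=0)
        far = np.array([[1e4]])
        dist = res.predict(far)
        assert dist.mean[0] == pytest.approx(y.mean(), abs=1e-6)
        prior_sd = np.sqrt(res.kernel.outputscale) * res.y_sd
        assert dist.latent_sd[0] == pytest.approx(prior_sd, rel=1e-6)

    def test_predictive_sd_dominates_latent_sd(self, toy_1d):
        x, y = toy_1d
        res = DeepKernelGP(y, x, network=None).fit(n_iter=50,
                                                   covariance="exact", seed=0)
        dist = res.predict(np.linspace(-4, 4, 30)[:, None])
        assert np.all(dist.predictive_sd >= dist.latent_sd)
        assert np.all(dist.latent_sd > 0)

    def test_lml_ascends_on_fixture_data(self, small_features):
        """The exact-covariance evidence climbs under the default optimizer;
        RMSprop's normalized steps allow only small transient dips."""
        x, y = small_features
        res = DeepKernelGP(y, x).fit(n_iter=200, covariance="exact", seed=5)
        steps = np.diff(res.lml_trace)
        assert res.lml_trace[-1] > res.lml_trace[0] + 50
        assert steps.min() > -0.5
        assert np.median(steps) >= 0

    def test_non_finite_input_rejected(self):
        x = np.ones((6, 2))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            DeepKernelGP(np.ones(6), x, network=None)


class TestSampling:
    @pytest.fixture
    def fitted(self, fitted_1d):
        return fitted_1d

    def test_shape_20_samples_15_queries(self, fitted):
        xq = np.linspace(-2, 2, 15)[:, None]
        draws = fitted.sample_posterior(xq, n_samples=20, seed=0)
        assert draws.shape == (20, 15)

    def test_seeded_draws_reproduce(self, fitted):
        xq = np.linspace(-1, 1, 5)[:, None]
        np.testing.assert_array_equal(fitted.sample_posterior(xq, 8, seed=11),
                                      fitted.sample_posterior(xq, 8, seed=11))

    def test_monte_carlo_sd_converges(self, fitted):
        xq = np.array([[0.37]])
        dist = fitted.predict(xq)
        draws = fitted.sample_posterior(xq, n_samples=10_000, seed=1)
        assert draws.std(ddof=1) == pytest.approx(dist.predictive_sd[0],
                                                  rel=0.03)

    def test_sample_moments_match_predict(self, fitted):
        xq = np.linspace(-1.5, 1.5, 4)[:, None]
        dist = fitted.predict(xq)
        draws = fitted.sample_posterior(xq, n_samples=20_000, seed=2)
        np.testing.assert_allclose(draws.mean(axis=0), dist.mean, atol=0.05)


class TestPersistence:
    def test_save_load_round_trip(self, small_features, tmp_path):
        x, y = small_features
        res = DeepKernelGP(y, x).fit(n_iter=20, seed=6)
        path = tmp_path / "model.npz"
        res.save(path)
        loaded = DeepKernelGPResults.load(path)
        xq = x[:5]
        d1, d2 = res.predict(xq), loaded.predict(xq)
        np.testing.assert_allclose(d1.mean, d2.mean, rtol=1e-12)
        np.testing.assert_allclose(d1.predictive_sd, d2.predictive_sd,
                                   rtol=1e-12)

    def test_load_rejects_foreign_archive(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, header='{"format": "other"}')
        with pytest.raises(ValueError, match="not an iltox model"):
            DeepKernelGPResults.load(path)


class TestConfigValidation:
    def test_final_layer_must_be_two_units(self):
        with pytest.raises(ValueError, match="2 units"):
            NetworkConfig(layer_sizes=(310, 16, 3))

    def test_kernel_params_positive(self):
        with pytest.raises(ValueError):
            KernelHyperparams(lengthscale=-1.0)

    def test_grid_needs_four_points(self):
        with pytest.raises(ValueError):
            GridConfig(points_per_dim=3)
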