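"""Wishart-process construction, densities, ELBO, and recovery."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from tvfc import simkit, wishart
from tvfc.datatypes import cov_to_corr
from tvfc.wishart import MaternKernelParams


class TestMatern52:
    def test_zero_distance_gives_variance(self):
        p = MaternKernelParams(variance=2.3, lengthscale=0.5)
        assert np.isclose(wishart.matern52(0.4, 0.4, p), 2.3)

    def test_unit_distance_closed_form(self):
        p = MaternKernelParams(variance=1.0, lengthscale=1.0)
        expected = (1 + math.sqrt(5) + 5 / 3) * math.exp(-math.sqrt(5))
        assert np.isclose(wishart.matern52(0.0, 1.0, p), expected)

    def test_symmetry(self, rng):
        p = MaternKernelParams(variance=0.7, lengthscale=0.2)
        a, b = rng.uniform(0, 1, (2, 100))
        np.testing.assert_allclose(
            wishart.matern52(a, b, p), wishart.matern52(b, a, p)
        )


class TestConstructSigma:
    def test_zero_f_gives_lambda(self):
        out = wishart.construct_sigma(np.eye(2), np.zeros((2, 2)), [0.3, 0.4])
        np.testing.assert_allclose(out, np.diag([0.3, 0.4]))

    def test_rank_one_plus_noise(self):
        f = np.array([[1.0, 0.0], [0.0, 0.0]])
        out = wishart.construct_sigma(np.eye(2), f, [0.1, 0.1])
        expected = np.outer([1, 0], [1, 0]) + 0.1 * np.eye(2)
        np.testing.assert_allclose(out, expected)

    @pytest.mark.parametrize("d", [2, 3])
    def test_wishart_first_moment(self, d, rng):
        # E[A F F^T A^T] = nu A A^T for F with iid standard normal entries
        nu = d
        a = np.tril(rng.standard_normal((d, d)))
        np.fill_diagonal(a, np.abs(np.diag(a)) + 0.5)
        n_draw = 100_000
        f = rng.standard_normal((n_draw, d, nu))
        g = np.matmul(a, f)
        draws = np.matmul(g, g.transpose(0, 2, 1))
        mean = draws.mean(axis=0)
        se = draws.std(axis=0) / np.sqrt(n_draw)
        np.testing.assert_array_less(np.abs(mean - nu * (a @ a.T)), 4 * se)


class TestWishartLogpdf:
    def test_matches_chi_squared_for_d1(self):
        # W_1(1, 1) is chi-squared with 1 dof
        for s in (0.3, 1.0, 2.7):
            ours = wishart.wishart_logpdf([[s]], [[1.0]], 1)
            assert np.isclose(ours, stats.chi2.logpdf(s, df=1))

    def test_density_normalized_d1(self):
        val, _ = integrate.quad(
            lambda s: math.exp(wishart.wishart_logpdf([[s]], [[0.7]], 3)), 0, 80
        )
        assert np.isclose(val, 1.0, atol=1e-6)

    def test_matches_scipy_wishart(self, rng):
        # independent dense implementation as cross-check
        for d, nu in [(2, 3), (3, 5)]:
            v = np.eye(d) + 0.3
            s = stats.wishart.rvs(df=nu, scale=v, random_state=rng)
            assert np.isclose(
                wishart.wishart_logpdf(s, v, nu),
                stats.wishart.logpdf(s, df=nu, scale=v),
            )

    def test_construction_samples_match_density(self, rng):
        # histogram of Eq-style construction draws vs density oracle, D=1:
        # a^2 * chi2_nu scaling of the Wishart
        draws = np.array([
            wishart.construct_sigma(np.eye(1), rng.standard_normal((1, 3)), [0.0]).item()
            for _ in range(4000)
        ])
        # Kolmogorov-Smirnov against chi-squared with 3 dof
        stat, p = stats.kstest(draws, "chi2", args=(3,))
        assert p > 0.01

    def test_non_pd_rejected(self):
        with pytest.raises(ValueError):
            wishart.wishart_logpdf([[-1.0]], [[1.0]], 1)


class TestConditionalLoglik:
    def test_identity_at_origin(self):
        # y = 0, Sigma = I (F = 0, Lambda = 1): loglik = -(D/2) log 2 pi
        val = wishart.conditional_loglik(
            [0.0, 0.0], np.eye(2), np.zeros((2, 2)), [1.0, 1.0]
        )
        assert np.isclose(val, -math.log(2 * math.pi))

    def test_reduces_to_univariate_normal(self):
        y, a, lam = 0.7, 1.3, 0.2
        f = np.array([[0.9]])
        var = (a * 0.9) ** 2 + lam
        assert np.isclose(
            wishart.conditional_loglik([y], [[a]], f, [lam]),
            stats.norm.logpdf(y, scale=math.sqrt(var)),
        )

    def test_matches_dense_gaussian_oracle(self, rng):
        a = np.tril(rng.standard_normal((3, 3))) + 2 * np.eye(3)
        f = rng.standard_normal((3, 3))
        lam = np.abs(rng.standard_normal(3)) + 0.1
        y = rng.standard_normal(3)
        sigma = a @ f @ f.T @ a.T + np.diag(lam)
        expected = stats.multivariate_normal.logpdf(y, mean=np.zeros(3), cov=sigma)
        assert abs(wishart.conditional_loglik(y, a, f, lam) - expected) < 1e-8


def _quadrature_log_marginal(y, x, a, lam, kern, n_quad=50):
    """Tensor Gauss-Hermite log marginal for D=1, nu=1, N=3."""
    from numpy.polynomial.hermite import hermgauss
    from scipy.special import logsumexp

    k = wishart._kernel_matrix(x, x, kern) + 1e-6 * kern.variance * np.eye(3)
    chol = np.linalg.cholesky(k)
    nodes, wts = hermgauss(n_quad)
    u = np.stack(np.meshgrid(nodes, nodes, nodes, indexing="ij"), -1).reshape(-1, 3)
    u = u * math.sqrt(2.0)
    logw = (
        np.stack(np.meshgrid(*([np.log(wts)] * 3), indexing="ij"), -1)
        .reshape(-1, 3).sum(axis=1)
        - 1.5 * math.log(math.pi)
    )
    f = u @ chol.T
    var = a**2 * f**2 + lam
    ll = np.sum(-0.5 * np.log(2 * math.pi * var) - 0.5 * y[:, 0] ** 2 / var, axis=1)
    return float(logsumexp(ll + logw))


class TestElbo:
    def _tiny_model(self, rng, perturb=True):
        x = np.linspace(0, 1, 3)
        y = rng.standard_normal((3, 1))
        model = wishart._init_model(3, 1, wishart.WPConfig(m=3, seed=0))
        if perturb:
            model.params["mu"] += 0.4 * rng.standard_normal(model.params["mu"].shape)
            model.params["lam_raw"][:] = wishart.inv_softplus(0.3)
        return x, y, model

    def test_kl_zero_at_prior(self, rng):
        x, y, model = self._tiny_model(rng, perturb=False)
        ls = wishart._chol_from_raw(model.params["ls_raw"])
        assert np.isclose(wishart._kl_whitened(model.params["mu"], ls), 0.0)

    def test_kl_nonnegative(self, rng):
        for _ in range(20):
            mu = rng.standard_normal((2, 4))
            raw = np.tril(rng.standard_normal((2, 4, 4)))
            ls = wishart._chol_from_raw(raw)
            assert wishart._kl_whitened(mu, ls) >= -1e-10

    def test_elbo_below_quadrature_marginal(self, rng):
        x, y, model = self._tiny_model(rng)
        logz = _quadrature_log_marginal(
            y, x, float(model.a[0, 0]), float(model.lam[0]), model.kernel
        )
        elbo, se = wishart.elbo_estimate(model, x, y, n_mc=100_000, seed=3)
        assert elbo <= logz + 3 * se

    def test_elbo_reproducible_given_seed(self, rng):
        x, y, model = self._tiny_model(rng)
        e1, _ = wishart.elbo_estimate(model, x, y, n_mc=500, seed=4)
        e2, _ = wishart.elbo_estimate(model, x, y, n_mc=500, seed=4)
        assert e1 == e2


class TestCovToCorr:
    def test_diagonal_to_identity(self):
        np.testing.assert_allclose(cov_to_corr(np.diag([4.0, 9.0])), np.eye(2))

    def test_collinear_edge(self):
        out = cov_to_corr(np.array([[4.0, 2.0], [2.0, 1.0]]))
        assert np.isclose(out[0, 1], 1.0)

    def test_correlation_fixed_point(self):
        c = np.array([[1.0, 0.8], [0.8, 1.0]])
        np.testing.assert_allclose(cov_to_corr(c), c)

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            cov_to_corr(np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestFitAndPosterior:
    def test_constant_recovery(self, constant_fit):
        data, truth, model = constant_fit
        post = wishart.posterior_tvfc(model, data.x, n_samples=1000, seed=1)
        edge = post.mean_corr.edge(0, 1)
        assert np.all(np.abs(edge - 0.8) < 0.15)
        assert edge.std() < 0.1

    def test_elbo_improves_over_initialization(self, constant_fit):
        _, _, model = constant_fit
        assert np.mean(model.elbo_trace[-50:]) > model.elbo_trace[0]

    def test_null_recovery_no_spurious_structure(self, bench_wp_config):
        data, _ = simkit.simulate_dataset("null", n=400, seed=8)
        model = wishart.fit_wp(data, bench_wp_config)
        post = wishart.posterior_tvfc(model, data.x, n_samples=1000, seed=1)
        assert np.mean(np.abs(post.mean_corr.edge(0, 1))) < 0.15

    def test_posterior_shape_and_bands(self, constant_fit):
        data, _, model = constant_fit
        post = wishart.posterior_tvfc(model, data.x, n_samples=400, seed=2)
        assert post.mean_corr.n == data.n
        diag = np.diagonal(post.mean_corr.sigmas, axis1=1, axis2=2)
        np.testing.assert_allclose(diag, 1.0)
        assert np.all(post.lower <= post.mean_corr.sigmas + 1e-12)
        assert np.all(post.upper >= post.mean_corr.sigmas - 1e-12)
        assert np.all(np.abs(post.mean_corr.sigmas) <= 1.0)

    def test_imputation_path_between_training_points(self, constant_fit):
        data, _, model = constant_fit
        mid = (data.x[:-1] + data.x[1:]) / 2.0
        post = wishart.posterior_tvfc(model, mid[:50], n_samples=200, seed=3)
        assert np.all(np.isfinite(post.mean_corr.sigmas))
        assert np.all(np.abs(post.mean_corr.edge(0, 1)) <= 1.0)

    def test_lambda_strictly_positive(self, constant_fit):
        _, _, model = constant_fit
        assert np.all(model.lam > 0)

    def test_wp_beats_static_on_smooth_structure(self, bench_wp_config):
        # direction check: on slowly oscillating truth the WP posterior mean
        # tracks while the static estimate cannot
        wins = 0
        for seed in range(3):
            data, truth = simkit.simulate_dataset("periodic_slow", n=400, seed=40 + seed)
            model = wishart.fit_wp(data, bench_wp_config)
            post = wishart.posterior_tvfc(model, data.x, n_samples=500, seed=1)
            wp_rmse = np.sqrt(np.mean((post.mean_corr.edge(0, 1) - truth.edge(0, 1)) ** 2))
            static = np.corrcoef(data.y.T)[0, 1]
            s_rmse = np.sqrt(np.mean((static - truth.edge(0, 1)) ** 2))
            wins += wp_rmse < s_rmse
        assert wins >= 2
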