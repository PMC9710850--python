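import numpy as np
import pytest

from mechlearn import datasets
from mechlearn.datasets import DensityDataset
from mechlearn.gp import (
    GPSurrogate,
    Hyperparameters,
    SurrogateError,
    fit_hyperparameters,
    joint_mean_cov,
    marginal_log_likelihood,
    regularize_covariance,
    sample_joint,
    se_kernel,
    se_kernel_derivatives,
)

HYPER = Hyperparameters(sigma_f=1.0, sigma_n=0.1, ell1=0.7, ell2=0.4)


class TestKernel:
    def test_zero_distance_variance(self):
        h = Hyperparameters(2.0, 0.1, 1.0, 1.0)
        assert se_kernel([0.3, 0.4], [0.3, 0.4], h) == pytest.approx(4.0)

    def test_hand_value(self):
        h = Hyperparameters(1.0, 0.1, 1.0, 1.0)
        assert se_kernel([0.0, 0.0], [1.0, 0.0], h) == pytest.approx(np.exp(-0.5))

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            p, q = rng.random(2), rng.random(2)
            assert se_kernel(p, q, HYPER) == pytest.approx(se_kernel(q, p, HYPER))

    def test_positive_lengthscale_required(self):
        with pytest.raises(ValueError):
            Hyperparameters(1.0, 0.1, -1.0, 1.0)


class TestKernelDerivatives:
    def test_first_derivative_vanishes_at_zero_separation(self):
        assert se_kernel_derivatives([0.2, 0.3], [0.2, 0.3], HYPER, (1, 0, 0, 0)) == 0.0

    def test_mixed_second_derivative_at_zero(self):
        h = Hyperparameters(1.0, 0.1, 1.0, 1.0)
        assert se_kernel_derivatives([0.5, 0.5], [0.5, 0.5], h, (1, 0, 1, 0)) == (
            pytest.approx(1.0)
        )

    def test_mixed_fourth_derivative_at_zero(self):
        h = Hyperparameters(1.0, 0.1, 1.0, 1.0)
        assert se_kernel_derivatives([0.5, 0.5], [0.5, 0.5], h, (2, 0, 2, 0)) == (
            pytest.approx(3.0)
        )

    @pytest.mark.parametrize(
        "order",
        [
            (1, 0, 0, 0), (0, 1, 0, 0), (2, 0, 0, 0), (1, 0, 1, 0),
            (0, 1, 2, 0), (2, 0, 1, 0), (2, 0, 2, 0), (0, 1, 0, 1),
        ],
    )
    def test_matches_finite_differences(self, order):
        """Each analytic mixed partial is the central difference of the
        next-lower analytic derivative (ladder anchored at the kernel)."""
        rng = np.random.default_rng(3)
        p, q = rng.random(2), rng.random(2) + 0.3
        # decrement the first nonzero slot of the order tuple
        slot = next(i for i, c in enumerate(order) if c > 0)
        lower = list(order)
        lower[slot] -= 1
        lower = tuple(lower)
        h = 1e-5
        dp, dq = np.zeros(2), np.zeros(2)
        if slot < 2:
            dp[slot] = h
        else:
            dq[slot - 2] = h
        fd = (
            se_kernel_derivatives(p + dp, q + dq, HYPER, lower)
            - se_kernel_derivatives(p - dp, q - dq, HYPER, lower)
        ) / (2 * h)
        exact = se_kernel_derivatives(p, q, HYPER, order)
        assert fd == pytest.approx(exact, rel=1e-6, abs=1e-9)

    def test_unsupported_order_rejected(self):
        with pytest.raises(NotImplementedError):
            se_kernel_derivatives([0, 0], [1, 1], HYPER, (3, 0, 2, 0))


def make_grid_dataset(field_fn, n=6, m=5):
    positions = np.linspace(0.0, 1.0, n)
    times = np.linspace(0.0, 1.0, m)
    XI, TAU = np.meshgrid(positions, times, indexing="ij")
    return DensityDataset(
        positions, times, field_fn(XI, TAU)[:, :, None], units_state="rescaled"
    )


class TestPosterior:
    def test_shapes(self):
        data = make_grid_dataset(lambda x, t: 1.0 + x * t)
        grid = datasets.unit_interval_grid(data, 4, 3)
        sur = joint_mean_cov(data, HYPER, grid)
        nm = 12
        assert sur.mu.shape == (4 * nm,)
        assert sur.Sigma.shape == (4 * nm, 4 * nm)
        np.testing.assert_allclose(sur.Sigma, sur.Sigma.T)

    def test_constant_field_mean_and_derivatives(self):
        data = make_grid_dataset(lambda x, t: np.full_like(x, 3.0))
        hyper = Hyperparameters(1.0, 1e-4, 0.8, 0.8)
        grid = datasets.unit_interval_grid(data, 5, 5)
        sur = joint_mean_cov(data, hyper, grid)
        nm = 25
        np.testing.assert_allclose(sur.mu[:nm], 3.0, atol=1e-2)
        # first-derivative blocks vanish tightly; the curvature block keeps
        # a small edge artefact from the finite length-scale prior
        np.testing.assert_allclose(sur.mu[nm : 3 * nm], 0.0, atol=5e-2)
        np.testing.assert_allclose(sur.mu[3 * nm :], 0.0, atol=0.3)

    def test_linear_field_spatial_derivative(self):
        a = 2.0
        data = make_grid_dataset(lambda x, t: a * x, n=9, m=4)
        hyper = Hyperparameters(2.0, 1e-4, 0.8, 1.5)
        grid = datasets.unit_interval_grid(data, 7, 3)
        sur = joint_mean_cov(data, hyper, grid)
        nm = 21
        dudxi = sur.mu[2 * nm : 3 * nm]
        np.testing.assert_allclose(dudxi, a, atol=0.05)

    def test_posterior_mean_interpolates_as_noise_vanishes(self):
        data = make_grid_dataset(lambda x, t: np.sin(2 * x) + t, n=5, m=5)
        hyper = Hyperparameters(1.5, 1e-6, 0.6, 0.6)
        grid = datasets.unit_interval_grid(data, 5, 5)
        sur = joint_mean_cov(data, hyper, grid)
        u_grid = sur.mu[:25].reshape(5, 5).T  # space-fastest layout
        np.testing.assert_allclose(u_grid, data.densities[:, :, 0], atol=1e-6)


class TestNugget:
    def test_equal_traces_give_equal_nuggets(self):
        Sigma = np.eye(8)
        out = regularize_covariance(Sigma, eta=1e-3)
        np.testing.assert_allclose(np.diag(out), 1.0 + 1e-3)

    def test_trace_ratio_scaling(self):
        Sigma = np.diag([1.0, 1.0, 4.0, 4.0, 1.0, 1.0, 1.0, 1.0])
        out = regularize_covariance(Sigma, eta=1e-3)
        # block 2 has tr = 8 vs block 1 tr = 2 -> nugget 4x eta
        assert out[2, 2] - Sigma[2, 2] == pytest.approx(4e-3)

    def test_min_eigenvalue_does_not_decrease(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 8))
        Sigma = A @ A.T
        out = regularize_covariance(Sigma, eta=1e-4)
        assert np.linalg.eigvalsh(out).min() >= np.linalg.eigvalsh(Sigma).min()

    def test_degenerate_first_block_rejected(self):
        Sigma = np.zeros((8, 8))
        with pytest.raises(SurrogateError):
            regularize_covariance(Sigma)


class TestSampling:
    @pytest.fixture
    def surrogate(self):
        data = make_grid_dataset(lambda x, t: 1.0 + x + t, n=5, m=4)
        grid = datasets.unit_interval_grid(data, 4, 3)
        return joint_mean_cov(data, HYPER, grid)

    def test_zero_draw_returns_mean(self, surrogate):
        s = sample_joint(surrogate, np.zeros(surrogate.mu.size))
        nm = surrogate.nm
        np.testing.assert_array_equal(s.u_star, surrogate.mu[:nm])
        g = surrogate.grid
        np.testing.assert_allclose(
            s.du_dt, surrogate.mu[nm : 2 * nm] / g.t_width
        )
        np.testing.assert_allclose(
            s.d2u_dx2, surrogate.mu[3 * nm :] / g.x_width**2
        )

    def test_determinism(self, surrogate):
        z = np.random.default_rng(5).standard_normal(surrogate.mu.size)
        s1 = sample_joint(surrogate, z)
        s2 = sample_joint(surrogate, z)
        np.testing.assert_array_equal(s1.u_star, s2.u_star)
        np.testing.assert_array_equal(s1.d2u_dx2, s2.d2u_dx2)

    def test_empirical_covariance_matches_sigma(self, surrogate):
        rng = np.random.default_rng(11)
        nm4 = surrogate.mu.size
        draws = np.array(
            [surrogate.mu + surrogate.chol_L @ rng.standard_normal(nm4) for _ in range(4000)]
        )
        emp = np.cov(draws.T)
        scale = np.sqrt(np.outer(np.diag(surrogate.Sigma), np.diag(surrogate.Sigma)))
        np.testing.assert_allclose(emp / scale, surrogate.Sigma / scale, atol=0.12)

    def test_wrong_length_rejected(self, surrogate):
        with pytest.raises(ValueError):
            sample_joint(surrogate, np.zeros(3))

    def test_save_load_round_trip(self, surrogate, tmp_path):
        path = tmp_path / "surrogate.npz"
        surrogate.save(path)
        back = GPSurrogate.load(path)
        np.testing.assert_array_equal(back.mu, surrogate.mu)
        np.testing.assert_array_equal(back.chol_L, surrogate.chol_L)
        assert back.grid.x_span == surrogate.grid.x_span


class TestHyperparameterFit:
    def test_recovers_known_generator(self):
        """Data simulated from a known GP should be recovered within 25%."""
        true = Hyperparameters(sigma_f=1.0, sigma_n=0.05, ell1=0.3, ell2=0.5)
        n, m = 15, 15  # 225 >= 400 would be slow; moderate grid suffices here
        positions = np.linspace(0, 1, n)
        times = np.linspace(0, 1, m)
        XI, TAU = np.meshgrid(positions, times, indexing="ij")
        X = np.vstack([XI.ravel(), TAU.ravel()])
        from mechlearn.gp import _kernel_block

        K = _kernel_block(X, X, true)
        rng = np.random.default_rng(2)
        L = np.linalg.cholesky(K + 1e-12 * np.eye(n * m))
        field = L @ rng.standard_normal(n * m) + true.sigma_n * rng.standard_normal(n * m)
        data = DensityDataset(
            positions, times, field.reshape(n, m)[:, :, None], units_state="rescaled"
        )
        est = fit_hyperparameters(data, restarts=8, seed=4)
        for name in ("sigma_n", "ell1", "ell2"):
            assert getattr(est, name) == pytest.approx(getattr(true, name), rel=0.35)

    def test_best_of_restarts_dominates(self, smooth_dataset):
        data, _ = smooth_dataset
        best = fit_hyperparameters(data, restarts=4, seed=0)
        single = fit_hyperparameters(data, restarts=1, seed=0)
        assert marginal_log_likelihood(data, best) >= (
            marginal_log_likelihood(data, single) - 1e-6
        )

    def test_restart_count_validated(self, smooth_dataset):
        with pytest.raises(ValueError):
            fit_hyperparameters(smooth_dataset[0], restarts=0)
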