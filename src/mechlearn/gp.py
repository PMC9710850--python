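"""Squared-exponential Gaussian-process surrogate with derivative posteriors.

The observed densities are modelled as ``u = u* + sigma_n z`` with
``u* ~ GP(0, k)`` and the anisotropic squared-exponential kernel

    k(p, q) = sigma_f^2 exp(-(dxi)^2 / (2 ell1^2) - (dtau)^2 / (2 ell2^2)),

over unit-square space-time inputs.  Because differentiation is a linear
operator, the function values and their tau-, xi- and xixi-derivatives on a
test grid are jointly Gaussian with covariances given by mixed partial
derivatives of the kernel; the joint posterior over the stacked vector
(u*, du*/dtau, du*/dxi, d2u*/dxi2) is assembled block-wise from closed-form
kernel derivatives, regularised with block-scaled nuggets, and factorised
once so that bootstrap draws are cheap matrix-vector products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError
from scipy.optimize import minimize
from scipy.stats import qmc

from .datasets import DensityDataset, UnitGrid

# block operators on test points: identity, d/dtau, d/dxi, d2/dxi2
BLOCK_OPS = ((0, 0), (0, 1), (1, 0), (2, 0))
BLOCK_NAMES = ("u", "du_dtau", "du_dxi", "d2u_dxi2")


class GPFitError(RuntimeError):
    """All hyperparameter restarts failed to converge."""


class SurrogateError(RuntimeError):
    """Degenerate or numerically unusable surrogate."""


@dataclass(frozen=True)
class Hyperparameters:
    """SE-kernel hyperparameters (all strictly positive).

    ``sigma_f``/``sigma_n`` are on the density scale of the training data;
    ``ell1``/``ell2`` are length-scales on the unit-interval input scale.
    """

    sigma_f: float
    sigma_n: float
    ell1: float
    ell2: float

    def __post_init__(self) -> None:
        for name in ("sigma_f", "sigma_n", "ell1", "ell2"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_f, self.sigma_n, self.ell1, self.ell2])


def _corr_derivative_factor(s: np.ndarray, ell: float, order: int) -> np.ndarray:
    """d^order/ds^order of exp(-s^2 / (2 ell^2)), orders 0..4."""
    g = np.exp(-0.5 * (s / ell) ** 2)
    il2 = 1.0 / ell**2
    if order == 0:
        return g
    if order == 1:
        return -s * il2 * g
    if order == 2:
        return (s**2 * il2**2 - il2) * g
    if order == 3:
        return (3.0 * s * il2**2 - s**3 * il2**3) * g
    if order == 4:
        return (3.0 * il2**2 - 6.0 * s**2 * il2**3 + s**4 * il2**4) * g
    raise NotImplementedError(f"kernel derivative order {order} not supported")


def se_kernel(p, q, hyper: Hyperparameters) -> float:
    """Squared-exponential covariance between 2-vectors ``p`` and ``q``."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    return float(
        hyper.sigma_f**2
        * _corr_derivative_factor(p[0] - q[0], hyper.ell1, 0)
        * _corr_derivative_factor(p[1] - q[1], hyper.ell2, 0)
    )


def se_kernel_derivatives(p, q, hyper: Hyperparameters, order=(0, 0, 0, 0)) -> float:
    """Mixed partial derivative of the SE kernel.

    ``order = (n_xi_p, n_tau_p, n_xi_q, n_tau_q)`` gives the number of
    derivatives taken with respect to each coordinate of each argument.
    Because the kernel depends only on the separations, a derivative with
    respect to a q-coordinate flips the sign of the corresponding
    s-derivative; the xi and tau factors separate.
    """
    nxp, ntp, nxq, ntq = order
    if nxp + nxq > 4 or ntp + ntq > 4:
        raise NotImplementedError("total derivative order above 4 not supported")
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    sign = (-1.0) ** (nxq + ntq)
    fx = _corr_derivative_factor(p[0] - q[0], hyper.ell1, nxp + nxq)
    ft = _corr_derivative_factor(p[1] - q[1], hyper.ell2, ntp + ntq)
    return float(hyper.sigma_f**2 * sign * fx * ft)


def _kernel_block(P, Q, hyper: Hyperparameters, op_p=(0, 0), op_q=(0, 0)) -> np.ndarray:
    """Cross-covariance matrix between operator-images of the GP.

    ``P``/``Q`` are 2 x a / 2 x b input matrices; ``op_p``/``op_q`` are
    (n_xi, n_tau) derivative orders applied to the first/second argument.
    """
    sx = P[0][:, None] - Q[0][None, :]
    st = P[1][:, None] - Q[1][None, :]
    sign = (-1.0) ** (op_q[0] + op_q[1])
    fx = _corr_derivative_factor(sx, hyper.ell1, op_p[0] + op_q[0])
    ft = _corr_derivative_factor(st, hyper.ell2, op_p[1] + op_q[1])
    return hyper.sigma_f**2 * sign * fx * ft


def marginal_log_likelihood(data: DensityDataset, hyper: Hyperparameters) -> float:
    """Gaussian marginal log-likelihood of the training data."""
    X = data.training_inputs()
    u = data.flatten_observations()
    K = _kernel_block(X, X, hyper)
    A = K + hyper.sigma_n**2 * np.eye(u.size)
    try:
        c = cho_factor(A, lower=True)
    except LinAlgError as exc:  # pragma: no cover - pathological hyperparameters
        raise GPFitError("training covariance not positive definite") from exc
    alpha = cho_solve(c, u)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return float(-0.5 * u @ alpha - 0.5 * logdet - 0.5 * u.size * np.log(2 * np.pi))


def _nll_and_grad(log_theta, u, dx2, dt2, n):
    """Negative marginal log-likelihood and gradient in log-parameters.

    ``dx2``/``dt2`` are precomputed squared separations of the training
    inputs; ``log_theta = log(sigma_f, sigma_n, ell1, ell2)``.
    """
    sigma_f, sigma_n, ell1, ell2 = np.exp(log_theta)
    if not np.all(np.isfinite([sigma_f, sigma_n, ell1, ell2])) or min(ell1, ell2) <= 0:
        return np.inf, np.zeros(4)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore", under="ignore"):
        K = sigma_f**2 * np.exp(-0.5 * dx2 / ell1**2 - 0.5 * dt2 / ell2**2)
    A = K + sigma_n**2 * np.eye(n)
    if not np.all(np.isfinite(A)):
        return np.inf, np.zeros(4)
    try:
        c = cho_factor(A, lower=True)
    except (LinAlgError, ValueError):
        return np.inf, np.zeros(4)
    alpha = cho_solve(c, u)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    nll = 0.5 * u @ alpha + 0.5 * logdet + 0.5 * n * np.log(2 * np.pi)
    Ainv = cho_solve(c, np.eye(n))
    W = np.outer(alpha, alpha) - Ainv  # d logL = 0.5 tr(W dA)
    grads = np.empty(4)
    grads[0] = 0.5 * np.sum(W * (2.0 * K))
    grads[1] = 0.5 * np.trace(W) * 2.0 * sigma_n**2
    grads[2] = 0.5 * np.sum(W * (K * dx2 / ell1**2))
    grads[3] = 0.5 * np.sum(W * (K * dt2 / ell2**2))
    return float(nll), -grads


DEFAULT_RESTARTS = 250


def fit_hyperparameters(
    data: DensityDataset,
    restarts: int = DEFAULT_RESTARTS,
    bounds: dict | None = None,
    seed: int = 0,
    maxiter: int = 200,
) -> Hyperparameters:
    """Maximum-likelihood SE-kernel hyperparameters with multistart.

    Starting points are Latin-hypercube samples from per-parameter boxes
    (defaults: length-scales in [1e-6, 1] on the unit-interval input scale,
    signal and noise SDs in [1e-6, 7 SD(u)]); each start is refined by
    L-BFGS-B on log-parameters with analytic gradients, and the restart
    with the largest marginal likelihood wins.  The optimisation itself is
    unconstrained, so fitted values may leave the sampling box.

    The dataset should already be in rescaled units; inputs are normalised
    internally onto the unit square.
    """
    if restarts < 1:
        raise ValueError("need at least one restart")
    u = data.flatten_observations()
    X = data.training_inputs()
    sd_u = float(np.std(u, ddof=1))
    box = {
        "sigma_f": (1e-6, 7.0 * sd_u),
        "sigma_n": (1e-6, 7.0 * sd_u),
        "ell1": (1e-6, 1.0),
        "ell2": (1e-6, 1.0),
    }
    if bounds:
        box.update(bounds)
    lo = np.array([box[k][0] for k in ("sigma_f", "sigma_n", "ell1", "ell2")])
    hi = np.array([box[k][1] for k in ("sigma_f", "sigma_n", "ell1", "ell2")])

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = qmc.scale(sampler.random(restarts), lo, hi)

    dx2 = (X[0][:, None] - X[0][None, :]) ** 2
    dt2 = (X[1][:, None] - X[1][None, :]) ** 2
    n = u.size

    best = None
    best_nll = np.inf
    failures = []
    for s in starts:
        try:
            res = minimize(
                _nll_and_grad,
                np.log(s),
                args=(u, dx2, dt2, n),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter},
            )
        except (FloatingPointError, OverflowError) as exc:  # pragma: no cover
            failures.append(str(exc))
            continue
        if np.isfinite(res.fun) and res.fun < best_nll:
            best_nll = res.fun
            best = res.x
    if best is None:
        raise GPFitError(
            f"all {restarts} restarts failed; diagnostics: {failures[:5]}"
        )
    sigma_f, sigma_n, ell1, ell2 = np.exp(best)
    return Hyperparameters(sigma_f, sigma_n, ell1, ell2)


DEFAULT_NUGGET = 1e-5


def regularize_covariance(Sigma: np.ndarray, eta: float = DEFAULT_NUGGET) -> np.ndarray:
    """Add block-scaled diagonal nuggets to the 4-block joint covariance.

    The nugget for block i is scaled by the trace ratio tr(Sigma_ii) /
    tr(Sigma_11) so each derivative block receives a jitter commensurate
    with its own magnitude.
    """
    total = Sigma.shape[0]
    if Sigma.shape != (total, total) or total % 4:
        raise ValueError("Sigma must be square with four equal blocks")
    nm = total // 4
    traces = np.array(
        [np.trace(Sigma[i * nm : (i + 1) * nm, i * nm : (i + 1) * nm]) for i in range(4)]
    )
    if traces[0] == 0:
        raise SurrogateError("degenerate surrogate: tr(Sigma_11) = 0")
    etas = eta * traces / traces[0]
    return Sigma + np.diag(np.repeat(etas, nm))


@dataclass(frozen=True)
class GPSurrogate:
    """Fitted GP with the joint derivative posterior on a test grid.

    ``mu`` (length 4nm) and ``Sigma`` (4nm x 4nm, nugget-regularised) are
    ordered as (u*, du*/dtau, du*/dxi, d2u*/dxi2); ``chol_L`` satisfies
    ``L L^T = Sigma`` so a standard-normal draw z yields a surrogate field
    sample ``mu + L z``.
    """

    hyper: Hyperparameters
    train_X: np.ndarray
    train_u: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    chol_L: np.ndarray
    grid: UnitGrid

    @property
    def nm(self) -> int:
        return self.mu.size // 4

    def save(self, path) -> None:
        """Serialise to a single ``.npz`` archive."""
        np.savez_compressed(
            path,
            hyper=self.hyper.as_array(),
            train_X=self.train_X,
            train_u=self.train_u,
            mu=self.mu,
            chol_L=self.chol_L,
            xi=self.grid.xi,
            tau=self.grid.tau,
            x_span=np.array(self.grid.x_span),
            t_span=np.array(self.grid.t_span),
        )

    @classmethod
    def load(cls, path) -> "GPSurrogate":
        with np.load(path) as f:
            hyper = Hyperparameters(*f["hyper"])
            grid = UnitGrid(
                f["xi"], f["tau"], tuple(f["x_span"]), tuple(f["t_span"])
            )
            L = f["chol_L"]
            return cls(
                hyper, f["train_X"], f["train_u"], f["mu"], L @ L.T, L, grid
            )


def joint_mean_cov(
    data: DensityDataset,
    hyper: Hyperparameters,
    grid: UnitGrid,
    eta: float = DEFAULT_NUGGET,
) -> GPSurrogate:
    """Posterior mean and covariance of (u*, du*/dtau, du*/dxi, d2u*/dxi2).

    The covariance is the noise-free posterior (no observation-noise term
    is added back: the surrogate targets the underlying density field, not
    the noisy data), regularised with block nuggets and Cholesky-factorised.
    """
    X = data.training_inputs()
    u = data.flatten_observations()
    Xs = grid.test_inputs()
    nm = Xs.shape[1]

    K = _kernel_block(X, X, hyper)
    A = K + hyper.sigma_n**2 * np.eye(u.size)
    try:
        c = cho_factor(A, lower=True)
    except LinAlgError as exc:
        raise SurrogateError(
            "training covariance K(X,X) + sigma_n^2 I is singular"
        ) from exc

    M = np.vstack([_kernel_block(Xs, X, hyper, op_p=op) for op in BLOCK_OPS])
    mu = M @ cho_solve(c, u)

    Kprior = np.empty((4 * nm, 4 * nm))
    for i, op_i in enumerate(BLOCK_OPS):
        for j, op_j in enumerate(BLOCK_OPS):
            if j < i:
                Kprior[i * nm : (i + 1) * nm, j * nm : (j + 1) * nm] = Kprior[
                    j * nm : (j + 1) * nm, i * nm : (i + 1) * nm
                ].T
            else:
                Kprior[i * nm : (i + 1) * nm, j * nm : (j + 1) * nm] = _kernel_block(
                    Xs, Xs, hyper, op_p=op_i, op_q=op_j
                )
    Sigma = Kprior - M @ cho_solve(c, M.T)
    Sigma = 0.5 * (Sigma + Sigma.T)

    Sigma_reg = regularize_covariance(Sigma, eta)
    L = None
    bump = eta
    for _ in range(6):
        try:
            L = cholesky(Sigma_reg, lower=True)
            break
        except LinAlgError:
            bump *= 10.0
            warnings.warn(
                f"joint covariance not positive definite; increasing nugget to {bump:g}"
            )
            Sigma_reg = regularize_covariance(Sigma, bump)
    if L is None:
        raise SurrogateError("could not factorise the joint covariance")
    return GPSurrogate(hyper, X, u, mu, Sigma_reg, L, grid)


@dataclass(frozen=True)
class FunctionSample:
    """One surrogate draw: field values and derivatives on the test grid.

    Flat arrays of length n*m with space varying fastest; derivatives are
    on the physical (rescaled mm/d) scale, the unit-interval factors
    having been applied exactly once at draw time.
    """

    u_star: np.ndarray
    du_dt: np.ndarray
    du_dx: np.ndarray
    d2u_dx2: np.ndarray
    z: np.ndarray
    grid: UnitGrid

    def as_grid(self, field: np.ndarray) -> np.ndarray:
        """Reshape a flat field to (n, m) with rows = space."""
        return field.reshape(self.grid.m, self.grid.n).T


def sample_joint(surrogate: GPSurrogate, z: np.ndarray) -> FunctionSample:
    """Deterministic surrogate draw ``U = mu + L z`` split into blocks.

    Derivative blocks are rescaled from the unit-interval coordinates to
    the physical spans: d/dt by 1/(t_M - t_1), d/dx by 1/(x_N - x_1), and
    d2/dx2 by 1/(x_N - x_1)^2.
    """
    z = np.asarray(z, float)
    if z.shape != surrogate.mu.shape:
        raise ValueError(f"z must have length {surrogate.mu.size}")
    U = surrogate.mu + surrogate.chol_L @ z
    nm = surrogate.nm
    g = surrogate.grid
    return FunctionSample(
        u_star=U[:nm],
        du_dt=U[nm : 2 * nm] / g.t_width,
        du_dx=U[2 * nm : 3 * nm] / g.x_width,
        d2u_dx2=U[3 * nm : 4 * nm] / g.x_width**2,
        z=z,
        grid=g,
    )
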