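"""Loss functions and per-draw parameter estimation.

Each bootstrap draw supplies a surrogate field sample (density values and
derivatives); the parameters of a candidate mechanism model are estimated
by minimising the sum of two log-losses: a PDE-residual loss that matches
the sampled derivatives to the model's right-hand side, and a generalised
least-squares loss that matches the numerical PDE solution to the
replicate-averaged data, with extra weight on the initial time.  Physically
infeasible parameter vectors (negative delay or diffusivity values, or a
net-negative reaction integral) receive an infinite loss, which the
optimiser treats as a hard barrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from . import fvm
from .datasets import DensityDataset
from .gp import FunctionSample
from .mechanisms import MechanismDomainError, MechanismModel

GAUSS_LEGENDRE_ORDER = 64


class EstimationError(RuntimeError):
    """No feasible starting point, or all optimisations failed."""


class ThresholdError(ValueError):
    """Data thresholding removed every grid point."""


@dataclass(frozen=True)
class ParameterVector:
    """Estimated mechanism parameters with their optimisation scales.

    ``theta`` stacks (alpha, beta, gamma) in the model's fitting units
    (mm, d, density x 1e6); the optimiser works on theta / scales = O(1).
    ``as_raw`` converts to the raw reporting units (um^2/h, h^-1).
    """

    theta: np.ndarray
    model: MechanismModel
    scales: np.ndarray = None
    loss: float = np.nan

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, float))
        scales = self.scales
        if scales is None:
            scales = np.ones_like(self.theta)
        object.__setattr__(self, "scales", np.asarray(scales, float))
        if self.theta.size != self.model.n_params:
            raise ValueError("parameter vector length mismatch")
        if np.any(self.scales == 0) or not np.all(np.isfinite(self.scales)):
            raise ValueError("scales must be finite and non-zero")

    @property
    def alpha(self) -> np.ndarray:
        return self.model.split(self.theta)[0]

    @property
    def beta(self) -> np.ndarray:
        return self.model.split(self.theta)[1]

    @property
    def gamma(self) -> np.ndarray:
        return self.model.split(self.theta)[2]

    def as_raw(self) -> np.ndarray:
        """Parameters on the raw physical scales (um, h)."""
        return self.theta * np.array([s.to_raw for s in self.model.param_specs])

    def as_dict(self, raw: bool = True) -> dict[str, float]:
        values = self.as_raw() if raw else self.theta
        return dict(zip(self.model.param_names, values.tolist()))


@dataclass(frozen=True)
class LossBreakdown:
    """The two loss components and the feasibility verdict."""

    l_pde: float
    l_gls: float
    combined: float
    feasible: bool


@dataclass
class SolverConfig:
    """Numerical settings shared by every loss evaluation of one draw."""

    mesh: fvm.FVMesh
    ic: np.ndarray
    times: np.ndarray
    sigma_n: float
    weights: np.ndarray = None
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self) -> None:
        if self.sigma_n <= 0:
            raise ValueError("sigma_n must be positive")
        if self.weights is None:
            w = np.ones(len(self.times))
            w[0] = 10.0
            self.weights = w
        self.weights = np.asarray(self.weights, float)


def default_weights(m: int, w1: float = 10.0) -> np.ndarray:
    """GLS time weights: w_1 = w1 on the initial profile, 1 afterwards."""
    w = np.ones(m)
    w[0] = w1
    return w


def loss_pde(
    theta: np.ndarray,
    model: MechanismModel,
    sample: FunctionSample,
    mask: np.ndarray | None = None,
) -> float:
    """Mean squared PDE residual of the sampled field.

    The residual at each test-grid point is
    du*/dt - T(t) [dD/du (du*/dx)^2 + D d2u*/dx2 + R(u*)], with the
    mechanisms evaluated at the sampled densities clipped at zero (the
    surrogate can dip below zero where the true density vanishes).
    Non-finite residuals yield an infinite loss.
    """
    grid = sample.grid
    u = np.clip(sample.u_star, 0.0, None)
    t_flat = np.repeat(grid.t_nodes(), grid.n)
    try:
        D, dDdu = model.diffusivity(theta, u)
        R = model.reaction(theta, u)
        T = model.delay(theta, t_flat)
    except MechanismDomainError:
        return np.inf
    with np.errstate(invalid="ignore", over="ignore"):
        residual = sample.du_dt - T * (
            dDdu * sample.du_dx**2 + D * sample.d2u_dx2 + R
        )
    if mask is not None:
        residual = residual[mask]
    if residual.size == 0:
        raise ThresholdError("no grid points left for the PDE loss")
    if not np.all(np.isfinite(residual)):
        return np.inf
    return float(np.mean(residual**2))


def loss_gls(
    theta: np.ndarray,
    model: MechanismModel,
    data: DensityDataset,
    solution: fvm.PDESolution,
    sigma_n: float,
    weights: np.ndarray | None = None,
) -> float:
    """Weighted mean squared standardised data residual.

    Residuals compare the PDE solution (nearest-node extraction at the
    data coordinates) with the replicate-averaged densities, standardised
    by the GP noise SD; time weights default to (10, 1, ..., 1).
    """
    if sigma_n <= 0:
        raise ValueError("sigma_n must be positive")
    if not solution.ok:
        return np.inf
    if weights is None:
        weights = default_weights(data.n_time)
    u_hat = solution.extract(data.positions, data.times)  # (N, M)
    u_bar = data.replicate_average()
    resid2 = ((u_hat - u_bar) / sigma_n) ** 2
    val = float(np.sum(weights[None, :] * resid2) / u_bar.size)
    return val if np.isfinite(val) else np.inf


def reaction_integral(model: MechanismModel, theta: np.ndarray, u_max: float) -> float:
    """Gauss-Legendre approximation of the reaction integral over [0, u_max]."""
    nodes, w = np.polynomial.legendre.leggauss(GAUSS_LEGENDRE_ORDER)
    uu = 0.5 * u_max * (nodes + 1.0)
    return float(0.5 * u_max * np.sum(w * model.reaction(theta, uu)))


def check_feasibility(
    model: MechanismModel, theta: np.ndarray, sample: FunctionSample
) -> bool:
    """Hard physical constraints on a trial parameter vector.

    The delay must be non-negative on the sampled time grid, the
    diffusivity non-negative over the sampled density range, and the
    integral of the reaction over [0, u_max] non-negative.
    """
    u = np.clip(sample.u_star, 0.0, None)
    u_max = float(np.max(u))
    try:
        T = model.delay(theta, sample.grid.t_nodes())
        if np.any(~np.isfinite(T)) or np.any(T < 0):
            return False
        u_range = np.linspace(0.0, u_max, 101)
        D, _ = model.diffusivity(theta, u_range)
        if np.any(~np.isfinite(D)) or np.any(D < 0):
            return False
        integral = reaction_integral(model, theta, u_max)
    except MechanismDomainError:
        return False
    return np.isfinite(integral) and integral >= 0


def combined_loss(
    theta: np.ndarray,
    model: MechanismModel,
    sample: FunctionSample,
    data: DensityDataset,
    config: SolverConfig,
    mask: np.ndarray | None = None,
) -> LossBreakdown:
    """Feasibility-guarded total loss log(L_PDE) + log(L_GLS)."""
    theta = np.asarray(theta, float)
    if not np.all(np.isfinite(theta)) or not check_feasibility(model, theta, sample):
        return LossBreakdown(np.inf, np.inf, np.inf, feasible=False)
    l_pde = loss_pde(theta, model, sample, mask=mask)
    if not np.isfinite(l_pde):
        return LossBreakdown(l_pde, np.inf, np.inf, feasible=False)
    solution = fvm.solve(
        model, theta, config.ic, config.times, config.mesh,
        rtol=config.rtol, atol=config.atol,
    )
    l_gls = loss_gls(theta, model, data, solution, config.sigma_n, config.weights)
    if not np.isfinite(l_gls):
        return LossBreakdown(l_pde, l_gls, np.inf, feasible=False)
    with np.errstate(divide="ignore"):
        combined = float(np.log(l_pde) + np.log(l_gls))
    return LossBreakdown(l_pde, l_gls, combined, feasible=True)


class DrawObjective:
    """Callable combined loss for one bootstrap draw.

    Precomputes the draw's initial condition and grid constants so that
    repeated evaluations inside the optimiser only pay for one PDE solve
    plus vector arithmetic.
    """

    def __init__(
        self,
        model: MechanismModel,
        sample: FunctionSample,
        data: DensityDataset,
        config: SolverConfig,
        mask: np.ndarray | None = None,
    ):
        self.model = model
        self.sample = sample
        self.data = data
        self.config = config
        self.mask = mask
        self.n_evals = 0

    def breakdown(self, theta: np.ndarray) -> LossBreakdown:
        self.n_evals += 1
        return combined_loss(
            theta, self.model, self.sample, self.data, self.config, self.mask
        )

    def __call__(self, theta: np.ndarray) -> float:
        return self.breakdown(theta).combined


def _lhs_starts(model: MechanismModel, n: int, seed: int) -> np.ndarray:
    """Latin-hypercube starting points from the per-parameter boxes."""
    specs = model.param_specs
    sampler = qmc.LatinHypercube(d=len(specs), seed=seed)
    unit = sampler.random(n)
    cols = []
    for j, s in enumerate(specs):
        if s.log:
            cols.append(np.exp(unit[:, j] * (np.log(s.hi) - np.log(s.lo)) + np.log(s.lo)))
        else:
            cols.append(unit[:, j] * (s.hi - s.lo) + s.lo)
    return np.column_stack(cols)


def _minimize_scaled(
    objective: DrawObjective,
    scales: np.ndarray,
    maxfev: int,
    xatol: float = 1e-3,
    fatol: float = 1e-5,
):
    """Nelder-Mead on theta / scales starting from all-ones."""
    fun = lambda phi: objective(phi * scales)
    res = minimize(
        fun,
        np.ones(scales.size),
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol},
    )
    return res.x * scales, float(res.fun)


def estimate_parameters(
    model: MechanismModel,
    sample: FunctionSample,
    data: DensityDataset,
    config: SolverConfig,
    scales: np.ndarray | None = None,
    starts: int = 5,
    seed: int = 0,
    mask: np.ndarray | None = None,
    maxfev_per_param: int = 100,
) -> ParameterVector:
    """Minimise the combined loss for one draw.

    Without ``scales`` (pilot phase) the optimiser is restarted from the
    best ``starts`` feasible Latin-hypercube candidates; each start doubles
    as its own parameter scaling so the search always runs on O(1)
    variables.  With ``scales`` (post-pilot) a single optimisation starts
    from theta = scales, i.e. all-ones in scaled space.
    """
    objective = DrawObjective(model, sample, data, config, mask=mask)
    maxfev = maxfev_per_param * model.n_params

    candidates: list[np.ndarray] = []
    if scales is not None:
        scales = np.asarray(scales, float)
        candidates.append(scales)
    else:
        pool = _lhs_starts(model, max(4 * starts, starts), seed)
        scored = [(objective(c), c) for c in pool]
        scored = [(f, c) for f, c in scored if np.isfinite(f)]
        if not scored:
            raise EstimationError(
                f"no feasible starting point among {len(pool)} candidates "
                f"for {model.label or model.diffusivity_form}"
            )
        scored.sort(key=lambda fc: fc[0])
        candidates.extend(c for _, c in scored[:starts])

    best_theta, best_loss = None, np.inf
    for cand in candidates:
        theta, loss = _minimize_scaled(objective, cand, maxfev)
        if loss < best_loss:
            best_theta, best_loss = theta, loss
    if best_theta is None or not np.isfinite(best_loss):
        raise EstimationError("optimiser failed to find a feasible minimum")
    return ParameterVector(best_theta, model, scales=scales, loss=best_loss)


def pilot_scales(pilot_estimates: list[ParameterVector]) -> np.ndarray:
    """Signed geometric-mean magnitudes of the pilot-phase estimates.

    The sign of each component follows the majority sign across pilot
    draws so that subsequent single-start optimisations begin on the right
    branch; magnitudes are floored at 1e-8.
    """
    thetas = np.array([p.theta for p in pilot_estimates])
    mags = np.exp(np.mean(np.log(np.maximum(np.abs(thetas), 1e-8)), axis=0))
    signs = np.sign(np.sum(np.sign(thetas), axis=0))
    signs[signs == 0] = 1.0
    return signs * np.maximum(mags, 1e-8)


def linear_basis_fit(
    model: MechanismModel,
    sample: FunctionSample,
    mask: np.ndarray | None = None,
) -> ParameterVector:
    """Fast least-squares fit for delay-free models linear in theta.

    When the right-hand side is a linear combination of the parameters
    (constant/porous diffusivity, logistic/Gompertz reaction, no delay),
    the PDE residual stacks into a linear system du*/dt = A theta solved
    directly -- no PDE solve and no data term, so the fit is orders of
    magnitude faster but matches the sampled derivatives only.
    """
    if model.delay_form != "none":
        raise EstimationError("basis-function fit requires a delay-free model")
    if model.diffusivity_form not in ("constant", "porous"):
        raise EstimationError("diffusivity form is not linear in its parameters")
    if model.reaction_form not in ("logistic", "gompertz"):
        raise EstimationError("reaction form is not linear in its parameters")

    u = np.clip(sample.u_star, 0.0, None)
    cols = []
    for k in range(model.n_params):
        e_k = np.zeros(model.n_params)
        e_k[k] = 1.0
        D, dDdu = model.diffusivity(e_k, u)
        R = model.reaction(e_k, u)
        cols.append(dDdu * sample.du_dx**2 + D * sample.d2u_dx2 + R)
    A = np.column_stack(cols)
    y = sample.du_dt
    if mask is not None:
        A, y = A[mask], y[mask]
    theta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < model.n_params:
        warnings.warn(
            "rank-deficient basis design; falling back to the pseudoinverse solution"
        )
    return ParameterVector(theta, model)


def threshold_data(
    sample: FunctionSample,
    delta_u: tuple[float, float] = (0.0, 1.0),
    delta_t: tuple[float, float] = (0.0, 1.0),
) -> np.ndarray:
    """Mask of test-grid points kept for the PDE-residual loss.

    A point survives when its sampled density lies within
    ``[lo, hi] * max(u)`` and its time derivative magnitude within
    ``[lo, hi] * max |du/dt|`` -- discarding points that are (relative to
    the draw) nearly empty, saturated, frozen or exploding.
    """
    for lo, hi in (delta_u, delta_t):
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("thresholds must satisfy 0 <= low < high <= 1")
    u = np.clip(sample.u_star, 0.0, None)
    rate = np.abs(sample.du_dt)
    u_max = np.max(u)
    r_max = np.max(rate)
    if r_max == 0.0 and delta_t[0] > 0.0:
        raise ThresholdError(
            "sample is static in time; a positive rate floor removes everything"
        )
    mask = (
        (u >= delta_u[0] * u_max)
        & (u <= delta_u[1] * u_max)
        & (rate >= delta_t[0] * r_max)
        & (rate <= delta_t[1] * r_max)
    )
    if not mask.any():
        raise ThresholdError("thresholding removed every grid point")
    return mask
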