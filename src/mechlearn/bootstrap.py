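"""Parametric bootstrap over surrogate draws, and ensemble summaries.

Each bootstrap iteration draws a standard-normal vector z, maps it through
the surrogate's Cholesky factor into a density field sample with
derivatives, estimates the mechanism parameters for that sample, and
solves the PDE with the sampled initial condition.  Across B iterations
this yields sampling distributions for parameters, functional forms, PDE
solutions, prediction errors and information criteria.  Draws are keyed by
(seed, b) so that every candidate model can consume the identical z
sequence, which is what makes per-draw model comparisons paired.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from . import fvm, learning
from .datasets import DensityDataset
from .gp import GPSurrogate, sample_joint
from .learning import ParameterVector, SolverConfig
from .mechanisms import MechanismModel
from .selection import aicc

logger = logging.getLogger(__name__)

MAPE_ZETA = 2.2e-16  # machine-precision guard in percentage-error denominators


class EnsembleError(RuntimeError):
    """Too many failed bootstrap draws to summarise."""


def draw_z(seed: int, b: int, size: int) -> np.ndarray:
    """The b-th standard-normal draw of a bootstrap run.

    Deterministic in (seed, b) alone, so parallel execution order and the
    worker count cannot change the ensemble, and different candidate
    models fitted with the same seed consume identical draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, b]))
    return rng.standard_normal(size)


@dataclass(frozen=True)
class BootstrapDraw:
    """One bootstrap iteration's results."""

    index: int
    params: ParameterVector | None
    loss: learning.LossBreakdown | None
    solution_at_data: np.ndarray | None  # (N, M) nearest-node extraction
    solution_values: np.ndarray | None  # (Np, M) full mesh solution
    aicc: float
    ok: bool
    error: str = ""


@dataclass
class BootstrapEnsemble:
    """B bootstrap draws for one candidate model.

    Summaries (intervals, modes, ribbons, MAPE) are computed over the
    successful draws; failed draws are dropped with a logged count, never
    imputed.
    """

    model: MechanismModel
    draws: list[BootstrapDraw]
    data: DensityDataset
    seed: int
    level: float = 0.95

    @property
    def B(self) -> int:
        return len(self.draws)

    @property
    def ok_draws(self) -> list[BootstrapDraw]:
        return [d for d in self.draws if d.ok]

    @property
    def n_failed(self) -> int:
        return self.B - len(self.ok_draws)

    def parameter_samples(self, name: str, raw: bool = True) -> np.ndarray:
        """Bootstrap sample of one parameter (raw physical units by default)."""
        names = self.model.param_names
        if name not in names:
            raise KeyError(f"model has no parameter {name!r}; choose from {names}")
        k = names.index(name)
        vals = [
            (d.params.as_raw() if raw else d.params.theta)[k] for d in self.ok_draws
        ]
        if not vals:
            raise EnsembleError("no successful draws")
        return np.array(vals)

    def aicc_samples(self) -> np.ndarray:
        """AICc per draw; NaN where the draw failed (pairing preserved)."""
        return np.array([d.aicc if d.ok else np.nan for d in self.draws])

    def conf_int(self, raw: bool = True) -> dict[str, tuple[float, float]]:
        return {
            name: confidence_interval(self.parameter_samples(name, raw), self.level)
            for name in self.model.param_names
        }

    def modes(self, raw: bool = True) -> dict[str, float]:
        return {
            name: kde_mode(self.parameter_samples(name, raw))[1]
            for name in self.model.param_names
        }


def run_bootstrap(
    surrogate: GPSurrogate,
    model: MechanismModel,
    data: DensityDataset,
    B: int = 100,
    seed: int = 0,
    mesh: fvm.FVMesh | None = None,
    Np: int = 500,
    pilot: int = 10,
    starts: int = 5,
    ic: str = "sampled",
    threshold: tuple | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    maxfev_per_param: int = 100,
    max_failure_fraction: float = 0.5,
) -> BootstrapEnsemble:
    """Run B bootstrap iterations for one candidate model.

    The first ``pilot`` draws are estimated with ``starts`` Latin-hypercube
    restarts; their estimates fix the parameter scaling used by the
    remaining single-start draws.  ``ic`` selects the initial condition for
    the PDE solves: ``"sampled"`` (clipped t = 0 slice of each draw) or
    ``"spline"`` (linear interpolant of the averaged data).
    ``threshold`` optionally passes ``(delta_u, delta_t)`` fraction pairs
    to :func:`mechlearn.learning.threshold_data`.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap draw")
    if mesh is None:
        mesh = fvm.build_mesh(data.positions[0], data.positions[-1], Np)
    pilot = min(pilot, B)
    u_bar = data.replicate_average()
    spline_profile = fvm.spline_ic(data, mesh) if ic == "spline" else None

    def run_draw(b: int, scales: np.ndarray | None) -> BootstrapDraw:
        z = draw_z(seed, b, surrogate.mu.size)
        sample = sample_joint(surrogate, z)
        try:
            mask = None
            if threshold is not None:
                mask = learning.threshold_data(sample, *threshold)
            ic_vec = (
                spline_profile
                if spline_profile is not None
                else fvm.sampled_ic(sample, mesh)
            )
            config = SolverConfig(
                mesh=mesh,
                ic=ic_vec,
                times=data.times,
                sigma_n=surrogate.hyper.sigma_n,
                rtol=rtol,
                atol=atol,
            )
            params = learning.estimate_parameters(
                model,
                sample,
                data,
                config,
                scales=scales,
                starts=starts,
                seed=seed + 977 * b,
                mask=mask,
                maxfev_per_param=maxfev_per_param,
            )
            loss = learning.combined_loss(
                params.theta, model, sample, data, config, mask=mask
            )
            solution = fvm.solve(
                model, params.theta, ic_vec, data.times, mesh, rtol=rtol, atol=atol
            )
            if not solution.ok:
                raise learning.EstimationError("PDE solve failed at the optimum")
            u_hat = solution.extract(data.positions, data.times)
            crit = aicc(u_hat - u_bar, model.a, model.d, model.r)
        except (learning.EstimationError, learning.ThresholdError) as exc:
            logger.warning("bootstrap draw %d failed: %s", b, exc)
            return BootstrapDraw(b, None, None, None, None, np.nan, False, str(exc))
        return BootstrapDraw(b, params, loss, u_hat, solution.values, crit, True)

    draws: list[BootstrapDraw] = [run_draw(b, None) for b in range(pilot)]
    pilot_ok = [d.params for d in draws if d.ok]
    if not pilot_ok:
        raise EnsembleError("every pilot draw failed; cannot set parameter scales")
    scales = learning.pilot_scales(pilot_ok)
    draws.extend(run_draw(b, scales) for b in range(pilot, B))

    n_failed = sum(not d.ok for d in draws)
    if n_failed:
        logger.info("bootstrap: %d/%d draws failed and were dropped", n_failed, B)
    if n_failed > max_failure_fraction * B:
        details = [d.error for d in draws if not d.ok][:5]
        raise EnsembleError(
            f"{n_failed}/{B} bootstrap draws failed; first errors: {details}"
        )
    return BootstrapEnsemble(model, draws, data, seed)


def confidence_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical quantile interval.

    Quantiles use the standard linear-interpolation definition so
    intervals are reproducible bit-exactly across runs.
    """
    samples = np.asarray(samples, float)
    if samples.size == 0:
        raise ValueError("cannot form an interval from an empty sample")
    tail = 0.5 * (1.0 - level)
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)


def kde_mode(samples: np.ndarray, n_grid: int = 512) -> tuple[np.ndarray, float]:
    """Gaussian-KDE density curve and its mode.

    Uses the Silverman rule-of-thumb bandwidth, evaluates on an
    ``n_grid``-point grid padded by three bandwidths, and breaks argmax
    ties toward the lower value.  A zero-variance sample returns that
    value with a flat-density warning.
    """
    samples = np.asarray(samples, float)
    if samples.size < 2 or np.ptp(samples) == 0:
        warnings.warn("zero-variance sample; kernel density is degenerate")
        value = float(samples[0])
        grid = np.column_stack([np.full(n_grid, value), np.full(n_grid, np.nan)])
        return grid, value
    kde = gaussian_kde(samples, bw_method="silverman")
    bw = kde.factor * samples.std(ddof=1)
    xs = np.linspace(samples.min() - 3 * bw, samples.max() + 3 * bw, n_grid)
    density = kde(xs)
    mode = float(xs[np.argmax(density)])
    return np.column_stack([xs, density]), mode


def functional_ribbon(
    ensemble: BootstrapEnsemble,
    mechanism: str,
    eval_range: tuple[float, float],
    n_points: int = 100,
    level: float = 0.95,
) -> dict[str, np.ndarray]:
    """Pointwise mean and quantile band of a mechanism across draws.

    ``mechanism`` is one of ``"delay"``, ``"diffusivity"``, ``"reaction"``;
    the evaluation range is in time (delay) or density (the others), in
    the model's fitting units.
    """
    lo_v, hi_v = eval_range
    if not hi_v > lo_v:
        raise ValueError("degenerate evaluation range")
    xs = np.linspace(lo_v, hi_v, n_points)
    model = ensemble.model
    curves = []
    for d in ensemble.ok_draws:
        theta = d.params.theta
        if mechanism == "delay":
            curves.append(model.delay(theta, xs))
        elif mechanism == "diffusivity":
            curves.append(model.diffusivity(theta, xs)[0])
        elif mechanism == "reaction":
            curves.append(model.reaction(theta, xs))
        else:
            raise ValueError("mechanism must be delay, diffusivity or reaction")
    curves = np.array(curves)
    tail = 0.5 * (1.0 - level)
    return {
        "grid": xs,
        "mean": curves.mean(axis=0),
        "lo": np.quantile(curves, tail, axis=0),
        "hi": np.quantile(curves, 1.0 - tail, axis=0),
    }


def solution_ribbon(ensemble: BootstrapEnsemble, level: float = 0.95) -> dict:
    """Mean and quantile band of the PDE solutions on the mesh."""
    stack = np.array([d.solution_values for d in ensemble.ok_draws])
    tail = 0.5 * (1.0 - level)
    return {
        "mean": stack.mean(axis=0),
        "lo": np.quantile(stack, tail, axis=0),
        "hi": np.quantile(stack, 1.0 - tail, axis=0),
    }


def mape_interval(
    ensemble: BootstrapEnsemble, data: DensityDataset | None = None, level: float = 0.95
) -> tuple[float, float]:
    """Quantile interval of the per-draw median absolute percentage error.

    Each draw's error compares its PDE solution at the data coordinates
    with the replicate-averaged densities; percentage denominators are
    guarded by machine precision so empty cells cannot divide by zero.
    """
    data = data or ensemble.data
    u_bar = data.replicate_average()
    denom = np.maximum(MAPE_ZETA, u_bar)
    medians = [
        float(np.median(100.0 * np.abs(d.solution_at_data - u_bar) / denom))
        for d in ensemble.ok_draws
    ]
    if not medians:
        raise EnsembleError("no successful draws")
    return confidence_interval(np.array(medians), level)


@dataclass(frozen=True)
class HypothesisTest:
    """A CI-based two-sided test record."""

    parameter: str
    null_value: float
    interval: tuple[float, float]
    level: float
    reject: bool


def ci_hypothesis_test(
    ensemble: BootstrapEnsemble,
    parameter: str,
    null_value: float = 0.0,
    level: float = 0.95,
) -> HypothesisTest:
    """Reject H0: theta = null_value iff it lies outside the closed CI."""
    lo, hi = confidence_interval(ensemble.parameter_samples(parameter), level)
    reject = not (lo <= null_value <= hi)
    return HypothesisTest(parameter, null_value, (lo, hi), level, reject)
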