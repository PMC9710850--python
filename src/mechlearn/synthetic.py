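"""Synthetic scratch-assay data with known generating mechanisms.

Generates density datasets shaped like the scratch-assay experiments the
package targets: a 1900 um imaging window sampled at 50 um columns, five
observation times over two days, three replicates, additive Gaussian noise
of constant variance, and an initial profile that is high near the well
edges and depleted in the scratched centre.  Because the generating model
and parameters are known, these datasets exercise every stage of the
pipeline -- surrogate fitting, parameter estimation, uncertainty intervals
and model selection -- without any experimental downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import fvm
from .datasets import DensityDataset
from .mechanisms import MechanismModel

K_DEFAULT = 1.7e-3  # cells per um^2, the measured confluent density


class GenerationError(RuntimeError):
    pass


def scratch_ic(
    u_edge: float,
    u_mid: float,
    edge_width: float,
    positions: np.ndarray,
) -> np.ndarray:
    """Smooth symmetric scratch profile: plateaus at the edges, a depleted
    centre, and C1 tanh ramps between them.

    ``edge_width`` is the fraction of the domain occupied by each edge
    plateau (0 < edge_width < 0.5); the ramp steepness scales with it.
    """
    if not 0.0 < edge_width < 0.5:
        raise ValueError("edge_width must lie in (0, 0.5)")
    if u_mid < 0 or u_edge < u_mid:
        raise ValueError("need u_edge >= u_mid >= 0")
    x = np.asarray(positions, float)
    s = (x - x[0]) / (x[-1] - x[0])
    slope = edge_width / 4.0
    left = 0.5 * (1.0 - np.tanh((s - edge_width) / slope))
    right = 0.5 * (1.0 + np.tanh((s - (1.0 - edge_width)) / slope))
    return u_mid + (u_edge - u_mid) * (left + right)


@dataclass(frozen=True)
class StudyDesign:
    """A fully specified synthetic experiment.

    All quantities are in raw units (um, h, cells um^-2); ``theta_true``
    stacks (alpha, beta, gamma) for the generating model.
    """

    model: MechanismModel
    theta_true: np.ndarray
    sigma_n: float
    n_space: int = 37
    n_time: int = 5
    replicates: int = 3
    x_span: tuple[float, float] = (75.0, 1875.0)
    t_span: tuple[float, float] = (0.0, 48.0)
    u_edge: float = 0.35 * K_DEFAULT
    u_mid: float = 0.005 * K_DEFAULT
    edge_width: float = 0.3
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_true", np.asarray(self.theta_true, float))
        if self.sigma_n < 0:
            raise ValueError("noise SD must be non-negative")
        if min(self.n_space, self.n_time, self.replicates) < 1:
            raise ValueError("grid shape must be positive")

    def positions(self) -> np.ndarray:
        return np.linspace(*self.x_span, self.n_space)

    def times(self) -> np.ndarray:
        return np.linspace(*self.t_span, self.n_time)

    def theta_true_dict(self) -> dict[str, float]:
        return dict(zip(self.model.param_names, self.theta_true.tolist()))


def generate_study(
    design: StudyDesign, seed: int | None = None, Np: int = 300
) -> DensityDataset:
    """Simulate a noisy dataset from a study design.

    The generating PDE is solved on a fine mesh from the scratch-shaped
    initial profile, sampled at the design's space-time grid by
    nearest-node extraction, and i.i.d. N(0, sigma_n^2) noise is added
    independently per replicate.  Noisy values are kept as drawn (the
    noise model is additive, so small negative densities can occur).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    mesh = fvm.build_mesh(*design.x_span, Np)
    ic = scratch_ic(design.u_edge, design.u_mid, design.edge_width, mesh.nodes)
    times = design.times()
    sol = fvm.solve(design.model, design.theta_true, ic, times, mesh)
    if not sol.ok:
        raise GenerationError("generating PDE solve failed for this design")
    truth = sol.extract(design.positions(), times)  # (N, M)
    noise = rng.normal(0.0, design.sigma_n, size=(design.replicates,) + truth.shape)
    densities = (truth[None, :, :] + noise).transpose(1, 2, 0)
    return DensityDataset(design.positions(), times, densities, units_state="raw")


def study_presets(
    sigma_frac: float = 0.01, K: float = K_DEFAULT
) -> list[StudyDesign]:
    """The two standard recovery studies.

    Study 1: Fisher-Kolmogorov dynamics (no delay, constant diffusivity
    301 um^2 h^-1, logistic proliferation 0.044 h^-1).  Study 2: delayed
    Fisher-Kolmogorov dynamics with logistic delay (-1.5, 0.31 h^-1),
    diffusivity 571 um^2 h^-1 and proliferation 0.081 h^-1.  Both use the
    37 x 5 x 3 scratch-assay grid on [75, 1875] um x [0, 48] h and
    additive noise with SD ``sigma_frac * K``.  The default noise level
    (1% of K) and the scratch profile (edge plateaus near 0.35 K, a
    nearly empty centre, ramps wide enough for the 50 um sampling
    columns to resolve) emulate the low-seeding-density wells whose
    measured t = 0 profile drives the recovery studies; at much larger
    noise the maximum-likelihood GP smooths over the early-time delay
    signature and the delay parameters cease to be identifiable, and
    under-resolved fronts bias the diffusivity downward.
    """
    sigma_n = sigma_frac * K
    fk = MechanismModel("none", "constant", "logistic", K, "Model 1")
    dfk = MechanismModel("logistic", "constant", "logistic", K, "Model 2")
    return [
        StudyDesign(fk, [301.0, 0.044], sigma_n, name="study1-fk"),
        StudyDesign(dfk, [-1.5, 0.31, 571.0, 0.081], sigma_n, name="study2-delayed-fk"),
    ]
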