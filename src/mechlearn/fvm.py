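"""Vertex-centred finite-volume solver for the invasion PDE.

The 1-D conservation equation with zero-flux (no net cell movement)
boundaries is semi-discretised on a uniform node set: each node owns a
control volume bounded by the midpoints to its neighbours (half-volumes at
the domain ends), fluxes across the faces use arithmetic-mean diffusivities
and two-point gradients, and the resulting ODE system is integrated with a
stiff-capable adaptive method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .datasets import DensityDataset
from .mechanisms import MechanismDomainError, MechanismModel


class MeshError(ValueError):
    pass


class _IntegrationAbort(Exception):
    """Internal sentinel: stop the ODE integrator immediately."""


@dataclass(frozen=True)
class FVMesh:
    """Uniform vertex-centred mesh on [a, b].

    End nodes own half control volumes: V_1 = V_Np = dx/2, interior
    V_i = dx, so the volumes partition the interval exactly.
    """

    nodes: np.ndarray
    w_bounds: np.ndarray
    e_bounds: np.ndarray
    volumes: np.ndarray
    dx: float

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


def build_mesh(a: float, b: float, Np: int = 500) -> FVMesh:
    """Equally spaced mesh of ``Np`` nodes with faces and volumes."""
    if Np < 3:
        raise MeshError("need at least 3 mesh nodes")
    if b <= a:
        raise MeshError("domain must satisfy b > a")
    nodes = np.linspace(a, b, Np)
    dx = (b - a) / (Np - 1)
    w = np.empty(Np)
    e = np.empty(Np)
    w[0] = nodes[0]
    w[1:] = 0.5 * (nodes[:-1] + nodes[1:])
    e[:-1] = 0.5 * (nodes[:-1] + nodes[1:])
    e[-1] = nodes[-1]
    volumes = np.full(Np, dx)
    volumes[0] = volumes[-1] = 0.5 * dx
    return FVMesh(nodes, w, e, volumes, dx)


def rhs(
    u: np.ndarray,
    t: float,
    model: MechanismModel,
    theta: np.ndarray,
    mesh: FVMesh,
) -> np.ndarray:
    """Semi-discrete time derivative du/dt at every node.

    Interior nodes use the flux difference
    [(D_i + D_{i+1})(u_{i+1} - u_i) - (D_{i-1} + D_i)(u_i - u_{i-1})] / (2 dx^2);
    boundary nodes see a single interior face (zero-flux outer face).  The
    delay factor multiplies transport and reaction together.
    """
    D, _ = model.diffusivity(theta, u)
    R = model.reaction(theta, u)
    T = float(model.delay(theta, t))
    dx = mesh.dx
    out = np.empty_like(u)
    out[0] = (D[0] + D[1]) * (u[1] - u[0]) / dx**2 + R[0]
    out[-1] = -(D[-2] + D[-1]) * (u[-1] - u[-2]) / dx**2 + R[-1]
    flux = (D[:-1] + D[1:]) * (u[1:] - u[:-1])  # 2 * D_face * du across each face
    out[1:-1] = (flux[1:] - flux[:-1]) / (2.0 * dx**2) + R[1:-1]
    return T * out


@dataclass(frozen=True)
class PDESolution:
    """Densities on the mesh at the requested output times.

    ``ok`` is False when the integrator failed (blow-up, domain error from
    a pathological parameter vector); downstream losses treat such
    solutions as infinitely bad rather than crashing the bootstrap.
    """

    times: np.ndarray
    values: np.ndarray  # (Np, n_times)
    mesh: FVMesh
    params: np.ndarray
    ok: bool = True

    def extract(self, positions: np.ndarray, times: np.ndarray) -> np.ndarray:
        """Solution at arbitrary coordinates by nearest-node lookup.

        Ties between equidistant nodes break toward the lower index.
        Returns an array of shape (len(positions), len(times)).
        """
        ix = _nearest_indices(self.mesh.nodes, np.asarray(positions, float))
        it = _nearest_indices(self.times, np.asarray(times, float))
        return self.values[np.ix_(ix, it)]

    def to_dataframe(self):
        import pandas as pd

        nt = self.times.size
        return pd.DataFrame(
            {
                "position": np.repeat(self.mesh.nodes, nt),
                "time": np.tile(self.times, self.mesh.n_nodes),
                "density": self.values.ravel(),
            }
        )


def _nearest_indices(grid: np.ndarray, targets: np.ndarray) -> np.ndarray:
    d = np.abs(grid[:, None] - targets[None, :])
    return np.argmin(d, axis=0)  # argmin takes the first (lower) index on ties


def solve(
    model: MechanismModel,
    theta: np.ndarray,
    ic: np.ndarray,
    times: np.ndarray,
    mesh: FVMesh,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "LSODA",
) -> PDESolution:
    """Integrate the semi-discrete system and sample at ``times``.

    Never raises on integrator failure: a flagged (``ok=False``) solution
    filled with NaN is returned so callers can map it to an infinite loss.
    """
    theta = np.asarray(theta, float)
    times = np.asarray(times, float)
    ic = np.asarray(ic, float)
    if ic.size != mesh.n_nodes:
        raise MeshError("initial condition length does not match mesh")
    if np.any(np.diff(times) <= 0):
        raise ValueError("output times must be strictly increasing")

    blowup = 1e8 * max(1.0, np.max(np.abs(ic)))

    def f(t, u):
        # abort eagerly on blow-up or domain errors: letting the stiff
        # integrator chase NaNs with ever-smaller steps can stall for
        # minutes on a pathological parameter vector
        if not np.all(np.isfinite(u)) or np.max(np.abs(u)) > blowup:
            raise _IntegrationAbort
        try:
            out = rhs(u, t, model, theta, mesh)
        except (MechanismDomainError, FloatingPointError):
            raise _IntegrationAbort from None
        if not np.all(np.isfinite(out)):
            raise _IntegrationAbort
        return out

    options = {}
    if method == "LSODA":
        # the FV stencil couples nearest neighbours only; telling the
        # integrator the Jacobian is tridiagonal reduces its FD Jacobian
        # cost from Np to 3 rhs evaluations
        options = {"lband": 1, "uband": 1}
    try:
        sol = solve_ivp(
            f,
            (times[0], times[-1]),
            ic,
            t_eval=times,
            method=method,
            rtol=rtol,
            atol=atol,
            **options,
        )
    except (_IntegrationAbort, ValueError, FloatingPointError, OverflowError):
        sol = None
    if sol is None or not sol.success or sol.y.shape[1] != times.size:
        return PDESolution(
            times, np.full((mesh.n_nodes, times.size), np.nan), mesh, theta, ok=False
        )
    values = sol.y
    if not np.all(np.isfinite(values)):
        return PDESolution(times, values, mesh, theta, ok=False)
    return PDESolution(times, values, mesh, theta, ok=True)


def spline_ic(data: DensityDataset, mesh: FVMesh) -> np.ndarray:
    """Linear interpolant of the replicate-averaged t = 0 profile."""
    if not np.isclose(data.times[0], 0.0):
        raise ValueError("dataset does not contain a t = 0 profile")
    x = data.positions
    if mesh.nodes[0] < x[0] - 1e-9 or mesh.nodes[-1] > x[-1] + 1e-9:
        raise ValueError("mesh extends beyond the data range; cannot extrapolate")
    profile = data.replicate_average()[:, 0]
    return np.interp(mesh.nodes, x, profile)


def sampled_ic(sample, mesh: FVMesh) -> np.ndarray:
    """Initial condition from the t = 0 slice of a surrogate draw.

    Negative sampled densities are replaced by zero before the linear
    interpolation onto the mesh.
    """
    grid = sample.grid
    x = grid.x_nodes()
    if mesh.nodes[0] < x[0] - 1e-9 or mesh.nodes[-1] > x[-1] + 1e-9:
        raise ValueError("mesh extends beyond the surrogate grid; cannot extrapolate")
    u0 = np.clip(sample.u_star[: grid.n], 0.0, None)
    return np.interp(mesh.nodes, x, u0)
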