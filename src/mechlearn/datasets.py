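"""Spatiotemporal cell-density datasets: loading, validation, units, grids.

The raw data are tables of column densities from scratch-assay images:
one row per (position, time, replicate) with the measured cell density.
Positions are in micrometres, times in hours, densities in cells per
square micrometre.  For numerical work everything is rescaled to
millimetres / days / (density x 1e6) so that all quantities are O(1)-O(1e3),
and the spatial and temporal coordinates are further normalised onto the
unit square for Gaussian-process fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

# raw -> rescaled unit conversions: um -> mm, h -> d, density x 1e6
X_FACTOR = 1.0e-3
T_FACTOR = 1.0 / 24.0
U_FACTOR = 1.0e6

REQUIRED_COLUMNS = ("position", "time", "density", "replicate")


class DataFormatError(ValueError):
    """Missing columns or malformed rows in a density table."""


class DataValidationError(ValueError):
    """Structurally invalid density data (ragged replicates, NaNs, ...)."""


@dataclass(frozen=True)
class DensityDataset:
    """Cell densities on an ``N x M x Rep`` space-time-replicate grid.

    Parameters
    ----------
    positions : ndarray, shape (N,)
        Strictly increasing spatial coordinates (um raw, mm rescaled).
    times : ndarray, shape (M,)
        Strictly increasing observation times (h raw, d rescaled).
    densities : ndarray, shape (N, M, Rep)
        Cell densities; finite everywhere.
    units_state : {"raw", "rescaled"}
    """

    positions: np.ndarray
    times: np.ndarray
    densities: np.ndarray
    units_state: str = "raw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "densities", np.asarray(self.densities, float))
        if self.densities.ndim != 3:
            raise DataValidationError("densities must be an N x M x Rep array")
        n, m, rep = self.densities.shape
        if self.positions.shape != (n,) or self.times.shape != (m,):
            raise DataValidationError("axis lengths do not match densities shape")
        if rep < 1:
            raise DataValidationError("at least one replicate required")
        if np.any(np.diff(self.positions) <= 0):
            raise DataValidationError("positions must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise DataValidationError("times must be strictly increasing")
        if not np.all(np.isfinite(self.densities)):
            raise DataValidationError("densities contain non-finite values")
        if self.units_state not in ("raw", "rescaled"):
            raise DataValidationError(f"unknown units_state {self.units_state!r}")

    @property
    def n_space(self) -> int:
        return self.positions.size

    @property
    def n_time(self) -> int:
        return self.times.size

    @property
    def replicate_count(self) -> int:
        return self.densities.shape[2]

    @property
    def n_observations(self) -> int:
        return self.densities.size

    def replicate_average(self) -> np.ndarray:
        """Mean density over replicates, shape ``(N, M)``."""
        return self.densities.mean(axis=2)

    def flatten_observations(self) -> np.ndarray:
        """Observation vector with space varying fastest, time-major,
        replicates appended as whole blocks:
        ``(u_111, u_211, ..., u_N11, u_121, ..., u_NM1, u_112, ...)``.
        """
        # densities[i, j, r] -> index r*N*M + j*N + i
        return self.densities.transpose(2, 1, 0).ravel()

    def unflatten_observations(self, u: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`flatten_observations`; returns (N, M, Rep)."""
        n, m, rep = self.densities.shape
        u = np.asarray(u, float)
        if u.size != n * m * rep:
            raise DataValidationError("flat vector length mismatch")
        return u.reshape(rep, m, n).transpose(2, 1, 0)

    def training_inputs(self) -> np.ndarray:
        """Space-time input matrix ``X`` (2 x N*M*Rep) on the unit square.

        Coordinates are normalised by the position/time spans; the column
        ordering matches :meth:`flatten_observations`.
        """
        xi = _normalise(self.positions)
        tau = _normalise(self.times)
        xx = np.tile(np.tile(xi, self.n_time), self.replicate_count)
        tt = np.tile(np.repeat(tau, self.n_space), self.replicate_count)
        return np.vstack([xx, tt])


def _normalise(v: np.ndarray) -> np.ndarray:
    return (v - v[0]) / (v[-1] - v[0])


@dataclass(frozen=True)
class UnitGrid:
    """Equally spaced test grid on the unit square with physical spans.

    ``xi``/``tau`` are the normalised space/time coordinates; the spans are
    kept so derivative samples can be mapped back onto physical scales,
    e.g. d/dt = d/dtau / (t_M - t_1).
    """

    xi: np.ndarray
    tau: np.ndarray
    x_span: tuple[float, float]
    t_span: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "xi", np.asarray(self.xi, float))
        object.__setattr__(self, "tau", np.asarray(self.tau, float))

    @property
    def n(self) -> int:
        return self.xi.size

    @property
    def m(self) -> int:
        return self.tau.size

    @property
    def x_width(self) -> float:
        return self.x_span[1] - self.x_span[0]

    @property
    def t_width(self) -> float:
        return self.t_span[1] - self.t_span[0]

    def test_inputs(self) -> np.ndarray:
        """Test matrix ``X*`` (2 x n*m), space varying fastest."""
        xx = np.tile(self.xi, self.m)
        tt = np.repeat(self.tau, self.n)
        return np.vstack([xx, tt])

    def x_nodes(self) -> np.ndarray:
        """Physical spatial coordinates of the grid columns."""
        return self.x_span[0] + self.xi * self.x_width

    def t_nodes(self) -> np.ndarray:
        """Physical times of the grid rows."""
        return self.t_span[0] + self.tau * self.t_width


def load_density_table(path, delimiter: str | None = None) -> DensityDataset:
    """Read a delimited density table into a validated :class:`DensityDataset`.

    The file must have a header row with columns
    ``position,time,density,replicate``.  Rows are regridded into the
    space-fastest / time-major / replicate-block layout regardless of their
    order in the file.

    Parameters
    ----------
    path : str or path-like
    delimiter : str, optional
        Field delimiter; autodetected (comma/tab/semicolon) when omitted.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing required column(s): {', '.join(missing)}")
    for col in ("position", "time", "density"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DataFormatError(f"non-numeric value in column {col!r} at row {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise DataFormatError(f"missing value in column {col!r} at row {row}")
        df[col] = coerced
    return from_dataframe(df)


def from_dataframe(df: pd.DataFrame) -> DensityDataset:
    """Build a :class:`DensityDataset` from a long-format data frame."""
    positions = np.sort(df["position"].unique())
    times = np.sort(df["time"].unique())
    replicates = sorted(df["replicate"].unique())
    n, m, rep = positions.size, times.size, len(replicates)
    if len(df) != n * m * rep:
        raise DataValidationError(
            f"expected a complete {n} x {m} x {rep} grid "
            f"({n * m * rep} rows), found {len(df)} rows"
        )
    pos_idx = {p: i for i, p in enumerate(positions)}
    t_idx = {t: j for j, t in enumerate(times)}
    r_idx = {r: k for k, r in enumerate(replicates)}
    densities = np.full((n, m, rep), np.nan)
    for row in df.itertuples(index=False):
        densities[pos_idx[row.position], t_idx[row.time], r_idx[row.replicate]] = row.density
    if np.isnan(densities).any():
        raise DataValidationError("replicates do not cover the same (position, time) grid")
    return DensityDataset(positions, times, densities, units_state="raw")


def to_dataframe(data: DensityDataset) -> pd.DataFrame:
    """Long-format table (position, time, density, replicate)."""
    n, m, rep = data.densities.shape
    recs = []
    for k in range(rep):
        for j in range(m):
            for i in range(n):
                recs.append(
                    (data.positions[i], data.times[j], data.densities[i, j, k], k + 1)
                )
    return pd.DataFrame(recs, columns=list(REQUIRED_COLUMNS))


def rescale_units(data: DensityDataset) -> DensityDataset:
    """Convert um/h/(cells um^-2) to mm/d/(density x 1e6).

    The optimisation routines are sensitive to the disparate raw scales
    (x = O(1e3) um, t = O(10) h, u = O(1e-3)); after rescaling all
    quantities are O(1)-O(1e3).
    """
    if data.units_state != "raw":
        raise DataValidationError("dataset already rescaled")
    return DensityDataset(
        data.positions * X_FACTOR,
        data.times * T_FACTOR,
        data.densities * U_FACTOR,
        units_state="rescaled",
    )


def unscale_units(data: DensityDataset) -> DensityDataset:
    """Inverse of :func:`rescale_units`."""
    if data.units_state != "rescaled":
        raise DataValidationError("dataset is not in rescaled units")
    return DensityDataset(
        data.positions / X_FACTOR,
        data.times / T_FACTOR,
        data.densities / U_FACTOR,
        units_state="raw",
    )


def drop_leftmost(data: DensityDataset) -> DensityDataset:
    """Remove the first spatial column from every time and replicate.

    The left-most scratch-assay column density is systematically inflated
    by edge effects and is excluded before fitting.
    """
    if data.n_space < 2:
        raise DataValidationError("cannot drop the sole spatial column")
    return replace(
        data, positions=data.positions[1:], densities=data.densities[1:, :, :]
    )


def unit_interval_grid(data: DensityDataset, n: int = 50, m: int = 50) -> UnitGrid:
    """Equally spaced ``n x m`` test grid on the unit square.

    Stores the physical spans of the dataset so derivatives taken in the
    normalised coordinates can be rescaled back.
    """
    if n < 2 or m < 2:
        raise ValueError("grid needs at least 2 points per axis")
    return UnitGrid(
        xi=np.linspace(0.0, 1.0, n),
        tau=np.linspace(0.0, 1.0, m),
        x_span=(float(data.positions[0]), float(data.positions[-1])),
        t_span=(float(data.times[0]), float(data.times[-1])),
    )
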