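"""Model/Results interface tying the pipeline together.

``InvasionModel`` owns a dataset and a candidate mechanism; ``fit`` runs
the full pipeline (rescale, GP surrogate, bootstrap) and returns an
``InvasionResults`` carrying parameter estimates with uncertainty,
diagnostics and a ``summary()`` table.  ``compare`` fits several candidate
mechanisms on shared surrogate draws and returns the evidence-class
selection matrix alongside the per-model results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bootstrap as bt
from . import datasets, fvm, gp
from .mechanisms import MechanismModel, model_catalog
from .selection import SelectionMatrix, selection_matrix
from .synthetic import K_DEFAULT


class InvasionModel:
    """Mechanism-discovery model for one scratch-assay dataset.

    Parameters
    ----------
    data : DensityDataset or DataFrame
        Raw-unit density observations (um, h, cells um^-2); a long-format
        frame with columns position/time/density/replicate is accepted.
    mechanism : MechanismModel or int
        Candidate (T, D, R) model, or an index 1-5 into the standard
        catalog.
    K : float
        Carrying capacity in raw density units.
    drop_edge : bool
        Remove the left-most spatial column before fitting (recommended
        for real scratch-assay tables whose first column is inflated).
    n_grid : (int, int)
        Surrogate test-grid size (n space x m time points).
    """

    def __init__(
        self,
        data,
        mechanism: MechanismModel | int = 1,
        K: float = K_DEFAULT,
        drop_edge: bool = False,
        n_grid: tuple[int, int] = (50, 50),
        nugget: float = gp.DEFAULT_NUGGET,
    ):
        if isinstance(data, pd.DataFrame):
            data = datasets.from_dataframe(data)
        if data.units_state == "raw":
            if drop_edge:
                data = datasets.drop_leftmost(data)
            data = datasets.rescale_units(data)
        elif drop_edge:
            data = datasets.drop_leftmost(data)
        self.data = data
        self.K_raw = K
        if isinstance(mechanism, int):
            mechanism = model_catalog(K)[mechanism - 1]
        self.mechanism = mechanism.with_K(K * datasets.U_FACTOR)
        self.grid = datasets.unit_interval_grid(data, *n_grid)
        self.nugget = nugget
        self._surrogate: gp.GPSurrogate | None = None

    @classmethod
    def from_file(cls, path, delimiter=None, **kwargs) -> "InvasionModel":
        return cls(datasets.load_density_table(path, delimiter), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "InvasionModel":
        return cls(datasets.from_dataframe(df), **kwargs)

    @property
    def surrogate(self) -> gp.GPSurrogate | None:
        return self._surrogate

    def fit_surrogate(self, restarts: int = 250, seed: int = 0) -> gp.GPSurrogate:
        """Fit the GP and assemble the joint derivative posterior (cached)."""
        hyper = gp.fit_hyperparameters(self.data, restarts=restarts, seed=seed)
        self._surrogate = gp.joint_mean_cov(self.data, hyper, self.grid, self.nugget)
        return self._surrogate

    def use_surrogate(self, surrogate: gp.GPSurrogate) -> None:
        """Share a previously fitted surrogate (e.g. across mechanisms)."""
        self._surrogate = surrogate

    def fit(
        self,
        B: int = 100,
        seed: int = 0,
        restarts: int = 250,
        Np: int = 500,
        **bootstrap_kwargs,
    ) -> "InvasionResults":
        """Run the bootstrap and return results with uncertainty."""
        if self._surrogate is None:
            self.fit_surrogate(restarts=restarts, seed=seed)
        ensemble = bt.run_bootstrap(
            self._surrogate,
            self.mechanism,
            self.data,
            B=B,
            seed=seed,
            Np=Np,
            **bootstrap_kwargs,
        )
        return InvasionResults(self, ensemble)

    def compare(
        self,
        mechanisms: list[MechanismModel] | None = None,
        B: int = 100,
        seed: int = 0,
        restarts: int = 250,
        Np: int = 500,
        **bootstrap_kwargs,
    ) -> "ModelComparison":
        """Fit several candidate mechanisms on shared surrogate draws."""
        if mechanisms is None:
            mechanisms = model_catalog(self.K_raw)
        mechanisms = [m.with_K(self.K_raw * datasets.U_FACTOR) for m in mechanisms]
        if self._surrogate is None:
            self.fit_surrogate(restarts=restarts, seed=seed)
        results = []
        for mech in mechanisms:
            ens = bt.run_bootstrap(
                self._surrogate, mech, self.data, B=B, seed=seed, Np=Np,
                **bootstrap_kwargs,
            )
            results.append(InvasionResults(self, ens))
        labels = [m.label or f"{m.delay_form}/{m.diffusivity_form}" for m in mechanisms]
        aiccs = np.vstack([r.ensemble.aicc_samples() for r in results])
        P = selection_matrix(aiccs, labels)
        return ModelComparison(results, P)


class InvasionResults:
    """Bootstrap estimates, uncertainty and diagnostics for one model.

    Parameter point estimates are the modes of the kernel density
    estimates of the bootstrap samples; intervals are equal-tailed
    percentile intervals.  All reported values are in raw physical units
    (um^2 h^-1 for diffusivities, h^-1 for rates).
    """

    def __init__(self, model: InvasionModel, ensemble: bt.BootstrapEnsemble):
        self.model = model
        self.ensemble = ensemble

    @property
    def mechanism(self) -> MechanismModel:
        return self.ensemble.model

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.ensemble.modes(), name="mode")

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        ci = {
            name: bt.confidence_interval(
                self.ensemble.parameter_samples(name), level
            )
            for name in self.mechanism.param_names
        }
        return pd.DataFrame(ci, index=["lower", "upper"]).T

    def mape_interval(self, level: float = 0.95) -> tuple[float, float]:
        return bt.mape_interval(self.ensemble, level=level)

    def test_null(self, parameter: str, value: float = 0.0, level: float = 0.95):
        return bt.ci_hypothesis_test(self.ensemble, parameter, value, level)

    def parameter_table(self) -> pd.DataFrame:
        ci = self.conf_int()
        ci["mode"] = self.params
        return ci[["lower", "mode", "upper"]]

    def summary(self) -> str:
        mech = self.mechanism
        lines = [
            "Mechanism discovery bootstrap results",
            "=" * 54,
            f"delay: {mech.delay_form}   diffusivity: {mech.diffusivity_form}"
            f"   reaction: {mech.reaction_form}",
            f"draws: {self.ensemble.B} ({self.ensemble.n_failed} failed)   "
            f"level: {self.ensemble.level:.0%}",
            "-" * 54,
            f"{'parameter':<12}{'lower':>12}{'mode':>12}{'upper':>12}",
        ]
        table = self.parameter_table()
        units = {"beta": "um^2/h", "alpha_2": "1/h", "gamma_1": "1/h"}
        for name, row in table.iterrows():
            lines.append(
                f"{name:<12}{row['lower']:>12.4g}{row['mode']:>12.4g}{row['upper']:>12.4g}"
            )
        lo, hi = self.mape_interval()
        lines.append("-" * 54)
        lines.append(f"PDE error (MAPE, %): ({lo:.2f}, {hi:.2f})")
        lines.append(
            "diffusivities in um^2/h; rates in 1/h; exponents dimensionless"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        lo, hi = self.mape_interval()
        return {
            "mechanism": {
                "delay": self.mechanism.delay_form,
                "diffusivity": self.mechanism.diffusivity_form,
                "reaction": self.mechanism.reaction_form,
            },
            "B": self.ensemble.B,
            "failed_draws": self.ensemble.n_failed,
            "modes": self.ensemble.modes(),
            "conf_int": {k: list(v) for k, v in self.ensemble.conf_int().items()},
            "mape_interval": [lo, hi],
        }

    def plot_fit(self, ax=None):
        """Data and bootstrap PDE-solution ribbons against position."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.ensemble.data
        ribbon = bt.solution_ribbon(self.ensemble)
        mesh_x = self.ensemble.ok_draws[0].solution_values.shape[0]
        xs = np.linspace(data.positions[0], data.positions[-1], mesh_x)
        for j, t in enumerate(data.times):
            line, = ax.plot(xs, ribbon["mean"][:, j], label=f"t = {t:g}")
            ax.fill_between(
                xs, ribbon["lo"][:, j], ribbon["hi"][:, j],
                alpha=0.25, color=line.get_color(),
            )
            ax.plot(
                data.positions, data.replicate_average()[:, j], ".",
                color=line.get_color(), ms=4,
            )
        ax.set_xlabel("position")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        return ax

    def plot_density(self, parameter: str, ax=None):
        """Kernel density estimate of one parameter's bootstrap sample."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve, mode = bt.kde_mode(self.ensemble.parameter_samples(parameter))
        ax.plot(curve[:, 0], curve[:, 1])
        ax.axvline(mode, ls="--", color="k", lw=0.8)
        ax.set_xlabel(parameter)
        ax.set_ylabel("density")
        return ax


@dataclass
class ModelComparison:
    """Per-model results plus the evidence-class selection matrix."""

    results: list[InvasionResults]
    selection: SelectionMatrix

    def summary(self) -> str:
        lines = ["Model comparison (evidence-class proportions)", "=" * 54]
        lines.append(self.selection.to_dataframe().round(3).to_string())
        lines.append(f"best model by P(E1): {self.selection.best_model()}")
        return "\n".join(lines)
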