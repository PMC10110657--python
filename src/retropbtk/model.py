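"""Model/Results interface over the estimation machinery.

:class:`PBTKModel` bundles a training dataset with the species parameter
sets and exposes ``fit()`` returning a :class:`PBTKResults` object that
carries posterior modes, credible intervals, convergence diagnostics and
a ``summary()`` table; simulation and plotting hang off both objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import estimation, pbtk
from .dataprep import KineticDataset
from .parameters import PBTKParameterSet, load_parameter_set

__all__ = ["PBTKModel", "PBTKResults"]


class PBTKModel:
    """Whole-body toxicokinetic model bound to a kinetic training dataset.

    Parameters
    ----------
    dataset
        Standardized kinetic observations (nmol); only training-function,
        non-relative records enter the likelihood.
    base_params
        Mapping species id -> :class:`PBTKParameterSet` with all fixed
        (in vitro informed) parameters.
    free
        Names of the parameters estimated from the in vivo data.
    """

    def __init__(self, dataset: KineticDataset, base_params: dict,
                 free: tuple = estimation.DEFAULT_FREE, bounds: dict | None = None):
        self.problem = estimation.EstimationProblem(
            dataset=dataset, base_params=dict(base_params),
            free_names=tuple(free), bounds=dict(bounds or {}))
        self.base_params = dict(base_params)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, species: tuple = ("mouse", "rat"),
                       **kwargs) -> "PBTKModel":
        """Build from a tidy observation table using packaged species configs."""
        params = {s: load_parameter_set(species=s) for s in species}
        physiologies = {s: p.physiology for s, p in params.items()}
        compound = next(iter(params.values())).compound
        dataset = KineticDataset.from_tidy(df, compound, physiologies)
        return cls(dataset, params, **kwargs)

    def loglike(self, theta: np.ndarray) -> float:
        return estimation.log_likelihood(np.asarray(theta, float), self.problem)

    def simulate(self, species: str, doses, t_end: float, **kwargs):
        return pbtk.simulate(self.base_params[species], doses, t_end, **kwargs)

    def fit(self, n_iter: int = 20_000, seeds: tuple = (1, 2, 3),
            **kwargs) -> "PBTKResults":
        """Run the multi-chain DRAM sampler and wrap the result."""
        mcmc = estimation.run_mcmc(self.problem, n_iter=n_iter, seeds=seeds,
                                   **kwargs)
        return PBTKResults(model=self, mcmc=mcmc)


@dataclass
class PBTKResults:
    """Posterior summaries and diagnostics of a fitted model."""

    model: PBTKModel
    mcmc: estimation.McmcResult
    _summary: pd.DataFrame = field(default=None, repr=False)

    @property
    def names(self) -> tuple:
        return self.mcmc.names

    @property
    def params(self) -> dict:
        """Posterior modes per parameter."""
        return dict(self.summary()["mode"])

    @property
    def credible_intervals(self) -> dict:
        s = self.summary()
        return {n: (s.loc[n, "hdi_low"], s.loc[n, "hdi_high"]) for n in s.index}

    def gelman_rubin(self) -> dict:
        return self.mcmc.gelman_rubin()

    def converged(self, threshold: float = 1.1) -> bool:
        return self.mcmc.converged(threshold)

    def summary(self) -> pd.DataFrame:
        """Mode, 95% HDI, Gelman-Rubin statistic and acceptance per parameter."""
        if self._summary is None:
            table = self.mcmc.summary()
            gr = self.gelman_rubin()
            table["gelman_rubin"] = [gr[n] for n in table.index]
            self._summary = table
        return self._summary

    def posterior_parameter_sets(self) -> dict:
        """Species parameter sets updated to the posterior modes."""
        theta = np.array([self.params[n] for n in self.names])
        return self.model.problem.apply(theta)

    def simulate(self, species: str, doses, t_end: float, **kwargs):
        """Simulate at the posterior modes."""
        return pbtk.simulate(self.posterior_parameter_sets()[species],
                             doses, t_end, **kwargs)

    def plot_traces(self, path: str | None = None):
        """Trace plot per parameter (one panel each, chains overlaid)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        d = len(self.names)
        fig, axes = plt.subplots(d, 1, figsize=(7, 1.6 * d), sharex=True)
        for j, (ax, name) in enumerate(zip(np.atleast_1d(axes), self.names)):
            for chain in self.mcmc.chains:
                ax.plot(chain[:, j], lw=0.4)
            ax.set_ylabel(name, fontsize=7)
            ax.axvline(self.mcmc.burn_in, color="k", ls=":", lw=0.6)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def plot_fit(self, species: str, route: str, dose: float, matrix: str,
                 t_end: float, path: str | None = None):
        """Observed vs predicted amount-time profile for one study arm."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        result = self.simulate(species, pbtk.DoseEvent(route, dose, 0.0), t_end)
        states = estimation.MATRIX_STATES[matrix]
        pred = sum(result.states[pbtk.IDX[s]] for s in states)
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(result.time_grid, pred, label="model")
        obs = [(o.time, o.value) for o in self.model.problem.dataset.observations
               if o.species_id == species and o.route == route
               and o.matrix == matrix and np.isclose(o.dose, dose)]
        if obs:
            t, v = zip(*obs)
            ax.plot(t, v, "o", ms=4, label="observed")
        ax.set_xlabel("time (h)")
        ax.set_ylabel(f"{matrix} amount (nmol)")
        ax.set_title(f"{species}, {dose:g} mg/kg {route}")
        ax.legend()
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
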