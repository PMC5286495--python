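"""Model/Results front end over the staged estimator.

`BatchLipidModel` holds one condition's observations and the fit
configuration; `fit()` runs the staged estimation and returns a
`BatchLipidResults` carrying the eight parameter estimates, per-series
R-squared, residuals and convergence metadata, with simulation and
sensitivity analysis hanging off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .estimation import FitConfig, FitResult, fit_staged
from .kinetics import Trajectory, simulate
from .sensitivity import SensitivityReport, perturb_and_score, rank_parameters

__all__ = ["BatchLipidModel", "BatchLipidResults"]


class BatchLipidModel:
    """Batch growth / nitrogen-uptake / lipid-accumulation model for one culture.

    Parameters
    ----------
    data : DataFrame
        Observations with columns ``t_days, replicate, X, N, L`` (N and L may
        contain missing values; those residuals are simply dropped from the
        corresponding stage).
    config : FitConfig, optional
    x0, n0 : float, optional
        Initial biomass and nitrogen; inferred from the t = 0 observations
        when omitted.
    freeze : dict, optional
        Stage-1 parameters held fixed (e.g. vm, KN transferred from a
        previously fitted strain).

    Examples
    --------
    >>> from algalipid import BatchLipidModel, datasets
    >>> obs = datasets.generate(datasets.ha1_design(seed=1))
    >>> one = obs[obs.condition == "HA1_N0_0.6"]
    >>> res = BatchLipidModel(one).fit()
    >>> print(res.summary())           # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, config: FitConfig | None = None,
                 *, x0: float | None = None, n0: float | None = None,
                 freeze: dict | None = None):
        self.data = pd.DataFrame(data).reset_index(drop=True)
        self.config = config or FitConfig()
        self.x0 = x0
        self.n0 = n0
        self.freeze = freeze

    @classmethod
    def from_csv(cls, path, **kwargs) -> "BatchLipidModel":
        from .io import read_observations

        return cls(read_observations(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BatchLipidModel":
        return cls(df, **kwargs)

    def fit(self, seed: int | None = None) -> "BatchLipidResults":
        cfg = self.config if seed is None else FitConfig(
            **{**self.config.__dict__, "seed": seed}
        )
        result = fit_staged(self.data, cfg, x0=self.x0, n0=self.n0, freeze=self.freeze)
        return BatchLipidResults(self, result)


class BatchLipidResults:
    """Estimates and diagnostics of one fitted batch culture."""

    def __init__(self, model: BatchLipidModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit_result.params, dtype=float)

    @property
    def rsquared(self) -> dict:
        return dict(self.fit_result.r_squared)

    @property
    def resid(self) -> dict:
        return {k: np.asarray(v) for k, v in self.fit_result.residuals.items()}

    @property
    def converged(self) -> bool:
        return self.fit_result.converged

    def simulate(self, t_grid=None, **kwargs) -> Trajectory:
        """Simulate the fitted model, by default daily over the observed span."""
        fr = self.fit_result
        if fr.composition is None:
            raise ValueError("composition stage not fitted; cannot simulate lipid")
        if t_grid is None:
            t_end = float(self.model.data["t_days"].max())
            t_grid = np.linspace(0.0, t_end, int(round(t_end)) + 1)
        return simulate(fr.kinetic, fr.composition, fr.state, t_grid, **kwargs)

    def sensitivity(self, horizon: float = 24.0, delta: float = 0.20, **kwargs) -> SensitivityReport:
        """One-at-a-time +/-delta perturbation analysis around the estimates."""
        fr = self.fit_result
        if fr.composition is None:
            raise ValueError("composition stage not fitted")
        return perturb_and_score(fr.kinetic, fr.composition, fr.state, horizon, delta, **kwargs)

    def summary(self) -> str:
        """Plain-text summary table of estimates and goodness of fit."""
        fr = self.fit_result
        lines = [
            "Batch lipid-accumulation kinetics: staged least squares",
            "=" * 56,
            f"{'parameter':<10}{'estimate':>12}  {'unit':<22}{'':>6}",
            "-" * 56,
        ]
        units = {
            "mu_max": "1/day",
            "h0": "dimensionless",
            "vm": "g N/(g dw day)",
            "KN": "g/L",
            "Xmax": "g dw/L",
            "k": "g protein/g N",
            "c": "g carb/g dw",
            "phi": "g N/L",
        }
        for name, value in fr.params.items():
            frozen = "frozen" if name in fr.frozen else ""
            lines.append(f"{name:<10}{value:>12.4g}  {units[name]:<22}{frozen:>6}")
        lines.append("-" * 56)
        lines.append(
            "R^2: " + "  ".join(f"{s}(t) {v:.4f}" for s, v in sorted(fr.r_squared.items()))
        )
        lines.append(
            f"initial condition: X0 = {fr.state.X0:.4g} g dw/L, N0 = {fr.state.N0:.4g} g/L"
        )
        lines.append(
            f"objective {fr.objective:.4g}; converged: {fr.converged}; "
            f"{fr.n_evaluations} model evaluations"
        )
        for w in fr.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def rank_sensitivity(self, **kwargs) -> list[str]:
        return rank_parameters(self.sensitivity(**kwargs))

    def plot_fit(self, ax=None):
        """Quick-look overlay of observations and fitted trajectories."""
        traj = self.simulate()
        ax = traj.plot(ax=ax)
        df = self.model.data
        for col, marker in (("X", "o"), ("N", "s"), ("L", "^")):
            sub = df[["t_days", col]].dropna()
            ax.scatter(sub["t_days"], sub[col], marker=marker, s=12, label=f"{col} obs")
        ax.legend()
        return ax
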