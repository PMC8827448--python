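"""Statsmodels-style model and results objects for conditional copulas.

``CopulaGPModel`` holds a pair of pseudo-observations on the unit square
together with the conditioning variable ``x``; ``fit()`` runs stochastic
variational inference (optionally preceded by WAIC model selection over the
standard ten-element candidate set) and returns a ``CopulaGPResults``
carrying the fitted latent GPs, parameter trajectories with confidence
bands, the WAIC, and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .families import BivariateCopula, Independence, clamp_unit, make_family
from .gp import FitConfig, MixtureGPState, fit_mixture_gp, waic_of_state
from .mixture import MixtureCopula

__all__ = ["CopulaGPModel", "CopulaGPResults"]


class CopulaGPModel:
    """Conditional bivariate copula mixture with GP-varying parameters.

    Parameters
    ----------
    u1, u2 : array-like
        Pseudo-observations in (0, 1), e.g. the output of a probability
        integral transform of the raw variables.
    x : array-like
        Conditioning variable (time, position, ...), same length.
    components : list of BivariateCopula or str, optional
        Mixture components.  If omitted, ``fit`` performs model selection.
    """

    def __init__(self, u1, u2, x, components=None):
        self.u1 = clamp_unit(np.asarray(u1, dtype=float))
        self.u2 = clamp_unit(np.asarray(u2, dtype=float))
        self.x = np.asarray(x, dtype=float)
        if not (len(self.u1) == len(self.u2) == len(self.x)):
            raise ValueError("u1, u2 and x must have equal length")
        if np.any(~np.isfinite(self.x)):
            raise ValueError("x contains non-finite values")
        self.components = None
        if components is not None:
            self.components = [
                make_family(c) if isinstance(c, str) else c for c in components
            ]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, var1: str, var2: str, cond: str = "x", **kw):
        return cls(df[var1].to_numpy(), df[var2].to_numpy(), df[cond].to_numpy(), **kw)

    @property
    def nobs(self) -> int:
        return len(self.x)

    def fit(
        self,
        config: FitConfig | dict | None = None,
        seed=None,
        select: str | None = None,
    ) -> "CopulaGPResults":
        """Fit by SVI; ``select`` in {'greedy', 'heuristic'} chooses components.

        Without ``select``, the components given at construction are fitted
        (defaulting to a single Gaussian copula).
        """
        if isinstance(config, dict):
            config = FitConfig.from_dict(config)
        config = config or FitConfig()
        rng = np.random.default_rng(seed)
        if select is not None:
            from . import selection

            algo = {"greedy": selection.select_greedy, "heuristic": selection.select_heuristic}
            if select not in algo:
                raise ValueError("select must be 'greedy' or 'heuristic'")
            state, waic = algo[select](self.x, self.u1, self.u2, config=config, rng=rng)
            return CopulaGPResults(self, state, config, waic=waic)
        comps = self.components or [make_family("Gaussian")]
        try:
            state = fit_mixture_gp(comps, self.x, self.u1, self.u2, config, rng=rng)
        except FloatingPointError:
            # one restart with a shifted stream, as a divergence guard
            state = fit_mixture_gp(comps, self.x, self.u1, self.u2, config, rng=np.random.default_rng(None if seed is None else seed + 1))
        waic = waic_of_state(
            state, self.x, self.u1, self.u2, S=config.waic_samples, rng=rng
        )
        return CopulaGPResults(self, state, config, waic=waic)


class CopulaGPResults:
    """Results of a conditional copula-GP fit."""

    def __init__(self, model: CopulaGPModel, state: MixtureGPState, config: FitConfig, waic=None):
        self.model = model
        self.state = state
        self.config = config
        self.waic_result = waic
        self.components = state.components

    # -- basic accessors --------------------------------------------------------
    @property
    def waic(self) -> float:
        return self.waic_result.waic if self.waic_result is not None else np.nan

    @property
    def is_independence(self) -> bool:
        return len(self.components) == 1 and isinstance(self.components[0], Independence)

    @property
    def aborted(self) -> bool:
        return self.state.aborted

    # -- prediction --------------------------------------------------------------
    def predict_params(self, x, mode: str = "mean", S: int = 1, seed=None):
        """theta_j(x) and phi_j(x); ``mode='sample'`` gives S posterior draws."""
        return self.state.params_at(np.atleast_1d(np.asarray(x, float)), mode=mode, S=S, rng=seed)

    def conf_int(self, x, z: float = 2.0):
        """Pointwise CI (link of latent mean +/- z posterior sd) per component."""
        return self.state.ci_at(np.atleast_1d(np.asarray(x, float)), z=z)

    def mixture_at(self, x) -> MixtureCopula:
        """The posterior-mean static mixture at given x value(s)."""
        return self.state.mixture_at(np.atleast_1d(np.asarray(x, float)))

    def logpdf(self, x, u1, u2):
        return self.state.logpdf(np.asarray(x, float), u1, u2)

    def sample(self, x, seed=None):
        """One pair per entry of ``x``, drawn at the posterior-mean parameters."""
        x = np.atleast_1d(np.asarray(x, float))
        mix = self.state.mixture_at(x)
        return mix.sample(rng=seed)

    def kendall_tau(self, x):
        """Posterior-mean Kendall tau trajectory (phi-weighted component taus)."""
        x = np.atleast_1d(np.asarray(x, float))
        thetas, phis = self.predict_params(x)
        tau = np.zeros_like(x, dtype=float)
        for j, c in enumerate(self.components):
            tau += phis[j] * np.array([c.kendall_tau(t) for t in thetas[j]])
        return tau

    # -- diagnostics --------------------------------------------------------------
    def r2(self, x_interval, n_bins: int = 20, literal: bool = False):
        from .gof import r2_interval

        return r2_interval(self, self.model.x, self.model.u1, self.model.u2, x_interval, n_bins=n_bins, literal=literal)

    def summary(self) -> str:
        lines = ["Conditional copula mixture (GP-parameterized)"]
        lines.append("=" * 54)
        lines.append(f"{'n obs':<28}{self.model.nobs}")
        lines.append(f"{'components':<28}{', '.join(c.key for c in self.components)}")
        lines.append(f"{'WAIC':<28}{self.waic:.5f}")
        if self.waic_result is not None:
            lines.append(f"{'lppd':<28}{self.waic_result.lppd:.2f}")
            lines.append(f"{'p_waic':<28}{self.waic_result.p_waic:.2f}")
        lines.append(f"{'SVI steps':<28}{self.state.steps}")
        lines.append(f"{'aborted (independence)':<28}{self.state.aborted}")
        if not self.is_independence and self.state.latents:
            xs = np.linspace(self.state.x_lo, self.state.x_hi, 5)
            thetas, phis = self.predict_params(xs)
            lines.append("-" * 54)
            lines.append("posterior-mean parameters on an x grid:")
            lines.append("  x      " + "".join(f"{v:>9.3g}" for v in xs))
            for j, c in enumerate(self.components):
                lines.append(f"  th[{c.key[:10]:<10}]" + "".join(f"{v:>9.3f}" for v in thetas[j]))
                lines.append(f"  phi[{c.key[:10]:<9}]" + "".join(f"{v:>9.3f}" for v in phis[j]))
        return "\n".join(lines)

    def plot_params(self, x=None, ax=None):  # pragma: no cover - thin viz helper
        import matplotlib.pyplot as plt

        if x is None:
            x = np.linspace(self.state.x_lo, self.state.x_hi, 200)
        if ax is None:
            _, ax = plt.subplots()
        thetas, phis = self.predict_params(x)
        lo, hi = self.conf_int(x)
        for j, c in enumerate(self.components):
            (line,) = ax.plot(x, thetas[j], label=f"theta {c.key}")
            ax.fill_between(x, lo[j], hi[j], alpha=0.2, color=line.get_color())
        ax.set_xlabel("x")
        ax.set_ylabel("copula parameter")
        ax.legend()
        return ax
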