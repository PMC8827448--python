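"""Conditional canonical vine (C-vine) models.

An ``m``-dimensional copula is factorized into ``m(m-1)/2`` bivariate
copulas arranged in ``m-1`` trees; in a C-vine each tree has a single pivot
node connected to every edge.  Variables are ordered by descending sum of
absolute pairwise Kendall tau (the pivot of tree 1 is the most globally
dependent variable, e.g. a neuropil/population-activity signal in imaging
data).  Each edge is a conditional copula mixture fitted by WAIC model
selection; edges selected as Independence carry no GP state, contribute
zero to the log-density and are skipped during sampling.  Conditional pair
copulas are taken to depend on their u-conditioners only through the
h-function-transformed arguments (the usual simplifying assumption), while
remaining fully conditional on the external covariate x.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .families import clamp_unit
from .gp import FitConfig, MixtureGPState, fit_mixture_gp, waic_of_state
from .model import CopulaGPModel

__all__ = ["CVine", "CVineResults", "order_variables", "n_pair_copulas"]


def n_pair_copulas(m: int) -> int:
    """Number of pair copulas (edges over all trees) of an m-dimensional vine."""
    return m * (m - 1) // 2


def order_variables(U: np.ndarray) -> np.ndarray:
    """Permutation by descending sum of |Kendall tau| with all other columns.

    Ties break by original column index, so fully independent data keeps the
    identity order.
    """
    U = np.asarray(U)
    m = U.shape[1]
    tau_sum = np.zeros(m)
    for i in range(m):
        for j in range(i + 1, m):
            t = abs(stats.kendalltau(U[:, i], U[:, j]).statistic)
            tau_sum[i] += t
            tau_sum[j] += t
    # stable sort on negated sums preserves index order among ties
    return np.argsort(-np.round(tau_sum, 12), kind="stable")


class CVine:
    """Conditional C-vine copula model over pseudo-observations.

    Parameters
    ----------
    U : (n, m) array
        Pseudo-observations on the unit hypercube (PIT-transformed data).
    x : (n,) array
        Conditioning variable.
    """

    def __init__(self, U, x):
        self.U = clamp_unit(np.asarray(U, dtype=float))
        self.x = np.asarray(x, dtype=float)
        if self.U.ndim != 2 or self.U.shape[1] < 2:
            raise ValueError("U must be (n, m) with m >= 2")
        if self.U.shape[0] != len(self.x):
            raise ValueError("U and x must have equal length")

    @property
    def nobs(self) -> int:
        return self.U.shape[0]

    @property
    def dim(self) -> int:
        return self.U.shape[1]

    def fit(
        self,
        config: FitConfig | dict | None = None,
        seed=None,
        select: str | None = "heuristic",
        components=None,
        order=None,
        truncate: int | None = None,
    ) -> "CVineResults":
        """Sequential tree-wise fit.

        ``select`` chooses per-edge model selection ('heuristic', 'greedy' or
        None to fit fixed ``components`` on every edge); ``truncate`` stops
        fitting above that tree, marking deeper edges Independence.
        """
        from . import selection

        if isinstance(config, dict):
            config = FitConfig.from_dict(config)
        config = config or FitConfig()
        rng = np.random.default_rng(seed)
        m = self.dim
        order = np.asarray(order) if order is not None else order_variables(self.U)
        P = self.U[:, order].copy()
        edges: dict[tuple[int, int], MixtureGPState | None] = {}
        waics: dict[tuple[int, int], float] = {}
        seconds: dict[tuple[int, int], float] = {}
        t_max = (m - 1) if truncate is None else min(truncate, m - 1)
        for t in range(m - 1):
            for j in range(t + 1, m):
                if t >= t_max:
                    edges[(t, j)] = None
                    waics[(t, j)] = 0.0
                    continue
                t0 = time.perf_counter()
                try:
                    if select == "heuristic":
                        state, w = selection.select_heuristic(
                            self.x, P[:, t], P[:, j], config=config, rng=rng
                        )
                    elif select == "greedy":
                        state, w = selection.select_greedy(
                            self.x, P[:, t], P[:, j], config=config, rng=rng
                        )
                    elif select is None:
                        state = fit_mixture_gp(
                            components, self.x, P[:, t], P[:, j], config, rng=rng
                        )
                        w = waic_of_state(
                            state, self.x, P[:, t], P[:, j], S=config.waic_samples, rng=rng
                        )
                        if w.waic > -config.waic_tol:
                            state = None
                    else:
                        raise ValueError("select must be 'heuristic', 'greedy' or None")
                except FloatingPointError:  # edge demoted rather than failing the vine
                    import warnings

                    warnings.warn(f"edge ({t},{j}) fit diverged; demoted to Independence")
                    state, w = None, None
                if state is not None and not state.latents:
                    state = None  # Independence marker carries no GP state
                edges[(t, j)] = state
                waics[(t, j)] = 0.0 if w is None else w.waic
                seconds[(t, j)] = time.perf_counter() - t0
            # pseudo-observations for the next tree
            for j in range(t + 1, m):
                st = edges[(t, j)]
                if st is not None:
                    mix = st.mixture_at(self.x)
                    P[:, j] = clamp_unit(mix.hfun(P[:, t], P[:, j]))
        return CVineResults(self, order, edges, waics, config, fit_seconds=seconds)


@dataclass
class CVineResults:
    """A fitted conditional C-vine: ordered variables and per-edge mixtures."""

    model: CVine
    order: np.ndarray
    edges: dict[tuple[int, int], MixtureGPState | None]
    waics: dict[tuple[int, int], float]
    config: FitConfig
    fit_seconds: dict[tuple[int, int], float] = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.model.dim

    @property
    def n_edges(self) -> int:
        return n_pair_copulas(self.dim)

    @property
    def n_independence(self) -> int:
        return sum(1 for v in self.edges.values() if v is None)

    def edge_families(self) -> dict[tuple[int, int], list[str]]:
        return {
            e: ([] if st is None else [c.key for c in st.components])
            for e, st in self.edges.items()
        }

    # -- density ---------------------------------------------------------------
    def logpdf(self, x, U, per_tree: bool = False):
        """Per-sample log copula density (natural log).

        Independence edges add exactly zero.  With ``per_tree`` the result is
        a (m-1, n) array of per-tree contributions.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        U = clamp_unit(np.asarray(U, dtype=float))
        if U.ndim == 1:
            U = U[None, :]
        m = self.dim
        P = U[:, self.order].copy()
        out = np.zeros((m - 1, U.shape[0]))
        for t in range(m - 1):
            mixes = {}
            for j in range(t + 1, m):
                st = self.edges[(t, j)]
                if st is None:
                    continue
                mix = st.mixture_at(x)
                mixes[j] = mix
                out[t] += mix.logpdf(P[:, t], P[:, j])
            for j in range(t + 1, m):
                st = self.edges[(t, j)]
                if st is not None:
                    P[:, j] = clamp_unit(mixes[j].hfun(P[:, t], P[:, j]))
        return out if per_tree else out.sum(axis=0)

    # -- sampling ----------------------------------------------------------------
    def sample(self, x, seed=None):
        """One m-dimensional sample per entry of ``x`` (posterior-mean params)."""
        return self._sample_impl(x, self.edges, seed)

    def _sample_impl(self, x, edges, seed=None):
        rng = np.random.default_rng(seed)
        x = np.atleast_1d(np.asarray(x, dtype=float))
        n = len(x)
        m = self.dim
        w = rng.uniform(size=(n, m))
        mixes = {
            e: (None if st is None else st.mixture_at(x)) for e, st in edges.items()
        }
        u = np.empty((n, m))
        cond = np.empty((n, m))  # F(u_t | u_0..u_{t-1}) per pivot
        for i in range(m):
            q = clamp_unit(w[:, i])
            for t in range(i - 1, -1, -1):
                mix = mixes[(t, i)]
                if mix is not None:
                    q = clamp_unit(mix.ppcf(cond[:, t], q))
            u[:, i] = q
            c = q.copy()
            for t in range(i):
                mix = mixes[(t, i)]
                if mix is not None:
                    c = clamp_unit(mix.hfun(cond[:, t], c))
            cond[:, i] = c
        inv = np.empty(m, dtype=int)
        inv[self.order] = np.arange(m)
        return u[:, inv]

    # -- information ---------------------------------------------------------------
    def tree_entropies(self, x, n_mc: int = 5000, seed=None) -> np.ndarray:
        """Per-tree copula entropy (bits) by MC over the model's own samples."""
        rng = np.random.default_rng(seed)
        xs = np.asarray(x, dtype=float)
        xi = rng.choice(xs, size=n_mc, replace=True)
        U = self._sample_impl(xi, self.edges, rng)
        per_tree = self.logpdf(xi, U, per_tree=True) / np.log(2.0)
        return -per_tree.mean(axis=1)

    def effective_dim(self, x, coverage: float = 0.9, n_mc: int = 5000, seed=None) -> int:
        """Minimal number of trees capturing ``coverage`` of the total entropy."""
        if not 0 < coverage < 1:
            raise ValueError("coverage must be in (0, 1)")
        H = self.tree_entropies(x, n_mc=n_mc, seed=seed)
        total = float(np.abs(H.sum()))
        if total == 0.0 or self.n_independence == self.n_edges:
            return 0
        cum = np.abs(np.cumsum(H))
        return int(np.searchsorted(cum, coverage * total) + 1)

    # -- posterior draws -------------------------------------------------------------
    def draw(self, seed=None) -> "CVineResults":
        """A functional posterior draw: every edge's latents fixed at one draw."""
        rng = np.random.default_rng(seed)
        drawn = {
            e: (None if st is None else _drawn_state(st, rng))
            for e, st in self.edges.items()
        }
        return CVineResults(
            self.model, self.order, drawn, self.waics, self.config, self.fit_seconds
        )

    def summary(self) -> str:
        lines = [f"Conditional C-vine: m={self.dim}, edges={self.n_edges}"]
        lines.append(f"variable order: {list(self.order)}")
        lines.append(
            f"independence edges: {self.n_independence}/{self.n_edges}"
        )
        for (t, j), st in sorted(self.edges.items()):
            fams = "Independence" if st is None else "+".join(c.key for c in st.components)
            lines.append(f"  tree {t + 1} edge ({t},{j}): {fams}  waic={self.waics[(t, j)]:.4f}")
        return "\n".join(lines)


from .gp import drawn_state as _drawn_state  # noqa: E402  (shared with info)
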