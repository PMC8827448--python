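"""Marginal estimation and the probability integral transform (PIT).

Copula modelling is two-stage ("inference for margins"): marginals first,
then dependence.  Unconditional marginals are empirical CDFs with the
rank/(n+1) convention (outputs strictly inside (0,1), copula densities stay
finite).  Conditional marginals F(y|x) are kernel-weighted conditional
ECDFs: Gaussian weights in x around a grid of nodes (Silverman bandwidth),
a weighted empirical CDF in y at each node, and linear interpolation in
both directions.  The operative contract is that the transformed values
are uniform within every x-stratum; with fewer than 200 samples the
conditional estimate falls back to the unconditional ECDF with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .families import CLAMP_EPS, clamp_unit

__all__ = [
    "ConditionedDataset",
    "ECDFMarginal",
    "ConditionalMarginal",
    "fit_unconditional_ecdf",
    "fit_conditional_marginal",
    "pit",
]

MIN_CONDITIONAL_N = 200


@dataclass
class ConditionedDataset:
    """A covariate vector x with an (n, m) observation matrix Y."""

    x: np.ndarray
    Y: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim == 1:
            self.Y = self.Y[:, None]
        if len(self.x) != len(self.Y):
            raise ValueError("x and Y must have equal length")
        if len(self.x) < 2:
            raise ValueError("need at least two samples")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.Y)):
            bad = np.where(~np.isfinite(self.Y).all(axis=1) | ~np.isfinite(self.x))[0]
            raise ValueError(f"missing/non-finite values in rows {bad[:10].tolist()}")
        if not self.names:
            self.names = [f"y{i}" for i in range(self.Y.shape[1])]

    @property
    def domain(self) -> tuple[float, float]:
        return float(np.min(self.x)), float(np.max(self.x))

    @property
    def m(self) -> int:
        return self.Y.shape[1]


class ECDFMarginal:
    """Unconditional empirical CDF with the rank/(n+1) convention."""

    kind = "empirical-unconditional"

    def __init__(self, y):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("constant column: degenerate marginal")
        self.sorted = np.sort(y)
        self.n = len(y)

    def cdf(self, y, x=None):
        """rank/(n+1) at sample points, linearly interpolated between them."""
        y = np.asarray(y, dtype=float)
        n = self.n
        grid = (np.arange(1, n + 1)) / (n + 1.0)
        u = np.interp(y, self.sorted, grid, left=0.5 / (n + 1), right=1 - 0.5 / (n + 1))
        return clamp_unit(u)

    def ppf(self, q, x=None):
        n = self.n
        grid = (np.arange(1, n + 1)) / (n + 1.0)
        return np.interp(np.asarray(q, dtype=float), grid, self.sorted)


class ConditionalMarginal:
    """Kernel-weighted conditional ECDF F(y | x) on an x-grid."""

    kind = "conditional-kde"

    def __init__(self, x, y, n_nodes: int = 50, bandwidth: float | None = None):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("constant column: degenerate marginal")
        if len(x) < MIN_CONDITIONAL_N:
            warnings.warn(
                f"n={len(x)} < {MIN_CONDITIONAL_N}: falling back to the "
                "unconditional empirical CDF"
            )
            self._fallback = ECDFMarginal(y)
            return
        self._fallback = None
        self.x_lo, self.x_hi = float(np.min(x)), float(np.max(x))
        self.nodes = np.linspace(self.x_lo, self.x_hi, n_nodes)
        sx = np.std(x)
        # widened Silverman factor: CDF estimation tolerates (and a stable
        # conditional ECDF requires) more smoothing than density estimation
        self.bandwidth = bandwidth or max(1.6 * sx * len(x) ** (-1 / 5), 1e-6)
        order = np.argsort(y)
        self.y_sorted = y[order]
        x_sorted_by_y = x[order]
        # per node: normalized cumulative kernel weight along sorted y
        F = np.empty((n_nodes, len(y)))
        for g, node in enumerate(self.nodes):
            w = np.exp(-0.5 * ((x_sorted_by_y - node) / self.bandwidth) ** 2)
            cw = np.cumsum(w)
            tot = cw[-1]
            # midpoint convention keeps values strictly inside (0, 1)
            F[g] = (cw - 0.5 * w) / tot
        self.F = F

    def _locate(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x_lo - 1e-9) or np.any(x > self.x_hi + 1e-9):
            warnings.warn("x outside the training domain: extrapolating marginal")
        pos = np.clip(
            (x - self.x_lo) / max(self.x_hi - self.x_lo, 1e-12), 0.0, 1.0
        ) * (len(self.nodes) - 1)
        idx = np.minimum(pos.astype(int), len(self.nodes) - 2)
        return idx, pos - idx

    def cdf(self, y, x):
        if self._fallback is not None:
            return self._fallback.cdf(y)
        y = np.asarray(y, dtype=float)
        idx, frac = self._locate(x)
        u_lo = _interp_cdf(self.y_sorted, self.F, idx, y)
        u_hi = _interp_cdf(self.y_sorted, self.F, idx + 1, y)
        return clamp_unit(u_lo * (1 - frac) + u_hi * frac)

    def ppf(self, q, x):
        if self._fallback is not None:
            return self._fallback.ppf(q)
        q = np.asarray(q, dtype=float)
        idx, frac = self._locate(x)
        out = np.empty(np.broadcast(q, idx).shape)
        qb, ib, fb = np.broadcast_arrays(q, idx, frac)
        for i in range(out.size):
            Fg = self.F[ib.flat[i]] * (1 - fb.flat[i]) + self.F[ib.flat[i] + 1] * fb.flat[i]
            out.flat[i] = np.interp(qb.flat[i], Fg, self.y_sorted)
        return out


def _interp_cdf(y_sorted, F, node_idx, y):
    """Evaluate the node CDFs at arbitrary y by interpolation along y."""
    if np.ndim(node_idx) == 0:
        return np.interp(y, y_sorted, F[node_idx])
    out = np.empty(np.broadcast(y, node_idx).shape)
    yb, nb = np.broadcast_arrays(y, node_idx)
    for g in np.unique(nb):
        mask = nb == g
        out[mask] = np.interp(yb[mask], y_sorted, F[g])
    return out


def fit_unconditional_ecdf(Y) -> list[ECDFMarginal]:
    """One empirical-CDF marginal per column of Y."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if len(Y) < 2:
        raise ValueError("need at least two samples")
    return [ECDFMarginal(Y[:, i]) for i in range(Y.shape[1])]


def fit_conditional_marginal(x, y, **kw) -> ConditionalMarginal:
    """Conditional marginal F(y|x) for a single variable."""
    return ConditionalMarginal(x, y, **kw)


def pit(x, Y, models) -> np.ndarray:
    """Probability integral transform onto the unit hypercube.

    ``models`` holds one fitted marginal per column; conditional marginals
    use x, unconditional ones ignore it.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] != len(models):
        raise ValueError(f"{Y.shape[1]} columns but {len(models)} marginal models")
    U = np.empty_like(Y)
    for i, m in enumerate(models):
        U[:, i] = m.cdf(Y[:, i], x)
    return U
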