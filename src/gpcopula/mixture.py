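"""Linear copula mixtures and the stick-breaking simplex map.

A mixture ``c(u) = sum_j phi_j c_j(u; theta_j)`` of at most five bivariate
copula components is itself a copula.  Mixing concentrations ``phi`` live on
the simplex and are parameterized by ``M - 1`` unconstrained reals through a
stick-breaking construction whose zero point corresponds to equal weights
``phi_j = 1/M``:

    t_j  = Phi(f_j + Phi^{-1}((M - j - 1) / (M - j))),   j = 0..M-2
    t_{M-1} = 0
    phi_j = (1 - t_j) * prod_{m<j} t_m
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .families import BivariateCopula, Independence, clamp_unit

__all__ = ["stick_break", "stick_break_jacobian", "MixtureCopula", "MAX_COMPONENTS"]

MAX_COMPONENTS = 5


def _offsets(M: int) -> np.ndarray:
    # Phi^{-1}((M-j-1)/(M-j)) for j = 0..M-2
    j = np.arange(M - 1)
    return special.ndtri((M - j - 1.0) / (M - j))


def stick_break(f_tilde) -> np.ndarray:
    """Map ``M-1`` unconstrained reals to an ``M``-point simplex.

    Accepts shape ``(M-1,)`` or ``(..., M-1)``; returns ``(..., M)``.
    ``f_tilde = 0`` yields equal weights ``1/M``.
    """
    f = np.atleast_1d(np.asarray(f_tilde, dtype=float))
    M = f.shape[-1] + 1
    if M == 1:
        return np.ones(f.shape[:-1] + (1,))
    t = special.ndtr(f + _offsets(M))  # (..., M-1)
    t_full = np.concatenate([t, np.zeros(f.shape[:-1] + (1,))], axis=-1)
    cum = np.cumprod(t_full[..., :-1], axis=-1)  # prod_{m<j} t_m for j>=1
    lead = np.ones(f.shape[:-1] + (1,))
    prods = np.concatenate([lead, cum], axis=-1)  # (..., M)
    phi = (1.0 - t_full) * prods
    return phi


def stick_break_jacobian(f_tilde) -> np.ndarray:
    """Jacobian ``d phi_k / d f_j`` with shape ``(..., M, M-1)``."""
    f = np.atleast_1d(np.asarray(f_tilde, dtype=float))
    M = f.shape[-1] + 1
    if M == 1:
        return np.zeros(f.shape[:-1] + (1, 0))
    off = _offsets(M)
    t = special.ndtr(f + off)  # (..., M-1)
    dt = np.exp(-0.5 * (f + off) ** 2) / np.sqrt(2 * np.pi)  # phi pdf
    t_full = np.concatenate([t, np.zeros(f.shape[:-1] + (1,))], axis=-1)
    lead = np.ones(f.shape[:-1] + (1,))
    prods = np.concatenate(
        [lead, np.cumprod(t_full[..., :-1], axis=-1)], axis=-1
    )  # (..., M)
    phi = (1.0 - t_full) * prods
    jac = np.zeros(f.shape[:-1] + (M, M - 1))
    for k in range(M):
        for j in range(M - 1):
            if j < k:
                # phi_k contains factor t_j
                with np.errstate(divide="ignore", invalid="ignore"):
                    val = np.where(t[..., j] > 0, phi[..., k] / t[..., j], 0.0)
                jac[..., k, j] = val * dt[..., j]
            elif j == k:
                jac[..., k, j] = -prods[..., k] * dt[..., j]
    return jac


@dataclass
class MixtureCopula:
    """A static copula mixture: components with fixed parameters and weights.

    ``thetas`` and ``phis`` may be scalar-per-component (a static mixture) or
    arrays of shape ``(M, n)`` describing per-observation parameters (the
    conditional case, one parameter value per input location).
    """

    components: list[BivariateCopula]
    thetas: np.ndarray
    phis: np.ndarray

    def __post_init__(self):
        self.thetas = np.atleast_1d(np.asarray(self.thetas, dtype=float))
        self.phis = np.atleast_1d(np.asarray(self.phis, dtype=float))
        M = len(self.components)
        if M < 1 or M > MAX_COMPONENTS:
            raise ValueError(f"component count must be in 1..{MAX_COMPONENTS}")
        keys = [c.key for c in self.components]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (family, rotation) components")
        if self.thetas.shape[0] != M or self.phis.shape[0] != M:
            raise ValueError("thetas/phis must have one entry per component")
        tot = np.sum(self.phis, axis=0)
        if np.any(np.abs(tot - 1.0) > 1e-6):
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.phis < -1e-12):
            raise ValueError("mixture weights must be nonnegative")

    @property
    def M(self) -> int:
        return len(self.components)

    # -- densities -----------------------------------------------------------
    def logpdf(self, u1, u2):
        return np.log(np.maximum(self.pdf(u1, u2), 1e-300))

    def pdf(self, u1, u2):
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        u2 = clamp_unit(np.asarray(u2, dtype=float))
        out = 0.0
        for j, comp in enumerate(self.components):
            out = out + self.phis[j] * comp.pdf(self.thetas[j], u1, u2)
        return out

    def cdf(self, u1, u2):
        out = 0.0
        for j, comp in enumerate(self.components):
            out = out + self.phis[j] * comp.cdf(self.thetas[j], u1, u2)
        return out

    # -- h-function and inverse ---------------------------------------------
    def hfun(self, u1, u2):
        """phi-weighted conditional CDF ``C(u2|u1)``."""
        out = 0.0
        for j, comp in enumerate(self.components):
            out = out + self.phis[j] * comp.hfun(self.thetas[j], u1, u2)
        return np.clip(out, 0.0, 1.0)

    def ppcf(self, u1, q, tol: float = 1e-9, maxit: int = 60):
        """Invert :meth:`hfun` by bisection (single components short-circuit)."""
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        q = clamp_unit(np.asarray(q, dtype=float), eps=1e-12)
        if self.M == 1:
            return self.components[0].ppcf(self.thetas[0], u1, q)
        lo = np.full(np.broadcast(u1, q).shape, 1e-9)
        hi = 1.0 - lo
        for _ in range(maxit):
            mid = 0.5 * (lo + hi)
            low = self.hfun(u1, mid) < q
            lo = np.where(low, mid, lo)
            hi = np.where(low, hi, mid)
            if np.max(hi - lo) < tol:
                break
        return 0.5 * (lo + hi)

    # -- sampling -------------------------------------------------------------
    def sample(self, n: int | None = None, rng=None):
        """Draw pairs; a categorical component draw then component sampling.

        With per-observation parameters (``thetas`` of shape ``(M, n)``),
        ``n`` defaults to that length and sample ``i`` uses column ``i``.
        """
        rng = np.random.default_rng(rng)
        per_obs = self.thetas.ndim > 1
        if n is None:
            if not per_obs:
                raise ValueError("n is required for a static mixture")
            n = self.thetas.shape[1]
        phis = (
            self.phis
            if not per_obs
            else np.broadcast_to(self.phis[:, None] if self.phis.ndim == 1 else self.phis, (self.M, n))
        )
        u1 = np.empty(n)
        u2 = np.empty(n)
        if per_obs:
            cum = np.cumsum(phis, axis=0)
            r = rng.uniform(size=n)
            comp_idx = np.sum(r[None, :] > cum, axis=0)
            comp_idx = np.minimum(comp_idx, self.M - 1)
        else:
            comp_idx = rng.choice(self.M, size=n, p=self.phis / self.phis.sum())
        # conditional sampling shares the uniform draws across components
        base1 = rng.uniform(size=n)
        q = rng.uniform(size=n)
        for j, comp in enumerate(self.components):
            mask = comp_idx == j
            if not np.any(mask):
                continue
            th = self.thetas[j][mask] if per_obs else self.thetas[j]
            u1[mask] = base1[mask]
            u2[mask] = comp.ppcf(th, clamp_unit(base1[mask]), clamp_unit(q[mask]))
        return clamp_unit(u1), clamp_unit(u2)

    # -- summaries -------------------------------------------------------------
    def kendall_tau(self) -> float:
        """phi-weighted average of component taus (static mixtures only)."""
        if self.thetas.ndim > 1:
            raise ValueError("per-observation mixture; evaluate at a fixed x")
        return float(
            sum(
                self.phis[j] * c.kendall_tau(self.thetas[j])
                for j, c in enumerate(self.components)
            )
        )

    @classmethod
    def independence(cls) -> "MixtureCopula":
        return cls([Independence()], np.array([0.0]), np.array([1.0]))
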