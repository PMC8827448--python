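"""Bivariate parametric copula families.

Four single-parameter families (Gaussian, Frank, Clayton, Gumbel) plus the
Independence copula, with 90/180/270-degree rotations of the asymmetric
families (Clayton, Gumbel).  Each family provides log-density, CDF,
h-function (conditional CDF ``C(u2|u1)``), its inverse (``ppcf``), sampling,
a closed-form Kendall-tau map and the fixed monotone link ("GPLink") from an
unconstrained latent real to the family's parameter domain.

Rotation convention: 90 deg reflects the first coordinate
(``(u1,u2) -> (1-u1,u2)``, tail mass in the upper-left, negative
dependence); 270 deg reflects the second (``(u1,1-u2)``, lower-right);
180 deg reflects both.  Kendall's tau flips sign under 90/270.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, special, stats

__all__ = [
    "CLAMP_EPS",
    "BivariateCopula",
    "Independence",
    "Gaussian",
    "Frank",
    "Clayton",
    "Gumbel",
    "make_family",
    "standard_candidates",
    "clamp_unit",
]

#: observations are clipped to [CLAMP_EPS, 1-CLAMP_EPS] before evaluation
CLAMP_EPS = 1e-6

_ROTATIONS = (0, 90, 180, 270)


def clamp_unit(u, eps: float = CLAMP_EPS):
    """Clip values into the open unit interval used for copula evaluation."""
    return np.clip(u, eps, 1.0 - eps)


class BivariateCopula:
    """Base class: a parametric bivariate copula family with one parameter.

    Subclasses implement the 0-degree form (``_logpdf0``, ``_cdf0``,
    ``_hfun0``, ``_ppcf0``, ``_sample0``); rotations are handled here.
    """

    name: str = "base"
    #: inclusive parameter domain (theta_lo, theta_hi)
    theta_domain: tuple[float, float] = (-np.inf, np.inf)
    nparams: int = 1
    rotatable: bool = False

    def __init__(self, rotation: int = 0):
        if rotation not in _ROTATIONS:
            raise ValueError(f"rotation must be one of {_ROTATIONS}")
        if rotation != 0 and not self.rotatable:
            raise ValueError(f"{self.name} copula does not support rotation")
        self.rotation = rotation

    # -- identity -----------------------------------------------------------
    @property
    def key(self) -> str:
        return self.name if self.rotation == 0 else f"{self.name}{self.rotation}"

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"<{type(self).__name__} rotation={self.rotation}>"

    def __eq__(self, other):
        return (
            isinstance(other, BivariateCopula)
            and self.name == other.name
            and self.rotation == other.rotation
        )

    def __hash__(self):
        return hash((self.name, self.rotation))

    # -- parameter handling -------------------------------------------------
    def check_theta(self, theta):
        lo, hi = self.theta_domain
        th = np.asarray(theta, dtype=float)
        if np.any(th < lo) or np.any(th > hi):
            raise ValueError(
                f"theta outside domain [{lo}, {hi}] for {self.key} copula"
            )
        return th

    def gplink(self, f):
        """Map an unconstrained latent value onto the parameter domain."""
        raise NotImplementedError

    def gplink_deriv(self, f):
        """Derivative of :meth:`gplink` (used by the variational fitter)."""
        raise NotImplementedError

    def kendall_tau(self, theta) -> float:
        tau = self._tau0(self.check_theta(theta))
        if self.rotation in (90, 270):
            tau = -tau
        return tau

    def theta_of_tau(self, tau: float) -> float:
        """Invert the tau map (bisection on the monotone closed form)."""
        target = -tau if self.rotation in (90, 270) else tau
        lo, hi = self.theta_domain
        lo = max(lo, -35.0)
        hi = min(hi, 35.0)
        from scipy.optimize import brentq

        f = lambda th: self._tau0(th) - target
        a, b = lo + 1e-9, hi - 1e-9
        fa, fb = f(a), f(b)
        if fa * fb > 0:
            return a if abs(fa) < abs(fb) else b
        return brentq(f, a, b, xtol=1e-10)

    # -- rotation plumbing ---------------------------------------------------
    def _rotate_in(self, u1, u2):
        if self.rotation == 0:
            return u1, u2
        if self.rotation == 90:
            return 1.0 - u1, u2
        if self.rotation == 180:
            return 1.0 - u1, 1.0 - u2
        return u1, 1.0 - u2  # 270

    # -- public API ----------------------------------------------------------
    def logpdf(self, theta, u1, u2):
        theta = self.check_theta(theta)
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        u2 = clamp_unit(np.asarray(u2, dtype=float))
        a, b = self._rotate_in(u1, u2)
        return self._logpdf0(theta, a, b)

    def pdf(self, theta, u1, u2):
        return np.exp(self.logpdf(theta, u1, u2))

    def cdf(self, theta, u1, u2):
        theta = self.check_theta(theta)
        u1 = np.clip(np.asarray(u1, dtype=float), 0.0, 1.0)
        u2 = np.clip(np.asarray(u2, dtype=float), 0.0, 1.0)
        if self.rotation == 0:
            return self._cdf0(theta, u1, u2)
        if self.rotation == 90:
            return u2 - self._cdf0(theta, 1.0 - u1, u2)
        if self.rotation == 180:
            return u1 + u2 - 1.0 + self._cdf0(theta, 1.0 - u1, 1.0 - u2)
        return u1 - self._cdf0(theta, u1, 1.0 - u2)  # 270

    def hfun(self, theta, u1, u2):
        """Conditional CDF ``C(u2 | u1) = dC/du1``."""
        theta = self.check_theta(theta)
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        u2 = clamp_unit(np.asarray(u2, dtype=float))
        if self.rotation == 0:
            h = self._hfun0(theta, u1, u2)
        elif self.rotation == 90:
            h = self._hfun0(theta, 1.0 - u1, u2)
        elif self.rotation == 180:
            h = 1.0 - self._hfun0(theta, 1.0 - u1, 1.0 - u2)
        else:  # 270
            h = 1.0 - self._hfun0(theta, u1, 1.0 - u2)
        return np.clip(h, 0.0, 1.0)

    def ppcf(self, theta, u1, q):
        """Inverse of :meth:`hfun` in its second argument."""
        theta = self.check_theta(theta)
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        # q is a conditional quantile, not data: clamp only against 0/1
        q = clamp_unit(np.asarray(q, dtype=float), eps=1e-12)
        if self.rotation == 0:
            return self._ppcf0(theta, u1, q)
        if self.rotation == 90:
            return self._ppcf0(theta, 1.0 - u1, q)
        if self.rotation == 180:
            return 1.0 - self._ppcf0(theta, 1.0 - u1, 1.0 - q)
        return 1.0 - self._ppcf0(theta, u1, 1.0 - q)  # 270

    def sample(self, theta, n, rng=None):
        rng = np.random.default_rng(rng)
        u1, u2 = self._sample0(self.check_theta(theta), n, rng)
        if self.rotation == 90:
            u1 = 1.0 - u1
        elif self.rotation == 180:
            u1, u2 = 1.0 - u1, 1.0 - u2
        elif self.rotation == 270:
            u2 = 1.0 - u2
        return clamp_unit(u1), clamp_unit(u2)

    def dlogpdf_dtheta(self, theta, u1, u2):
        """d log c / d theta by central finite difference (robust per family)."""
        th = np.asarray(theta, dtype=float)
        lo, hi = self.theta_domain
        h = 1e-5 * np.maximum(1.0, np.abs(th))
        thp = np.minimum(th + h, hi)
        thm = np.maximum(th - h, lo)
        denom = thp - thm
        denom = np.where(denom == 0, 1.0, denom)
        return (self.logpdf(thp, u1, u2) - self.logpdf(thm, u1, u2)) / denom

    # -- cached evaluation during fitting -------------------------------------
    def fit_evaluator(self, u1, u2):
        """Return ``(logpdf(theta), dlogpdf_dtheta(theta))`` closures with
        the data-dependent transforms (normal scores, logs) precomputed —
        the optimizer evaluates thousands of theta values on fixed data."""
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        u2 = clamp_unit(np.asarray(u2, dtype=float))
        a, b = self._rotate_in(u1, u2)
        pre = self._precompute(a, b)
        lo, hi = self.theta_domain

        def logpdf(theta):
            return self._logpdf_pre(np.asarray(theta, dtype=float), pre)

        def dlogpdf(theta):
            th = np.asarray(theta, dtype=float)
            h = 1e-5 * np.maximum(1.0, np.abs(th))
            thp = np.minimum(th + h, hi)
            thm = np.maximum(th - h, lo)
            denom = np.where(thp - thm == 0, 1.0, thp - thm)
            return (logpdf(thp) - logpdf(thm)) / denom

        return logpdf, dlogpdf

    def _precompute(self, a, b):
        return (a, b)

    def _logpdf_pre(self, theta, pre):
        return self._logpdf0(theta, pre[0], pre[1])

    # -- hooks ----------------------------------------------------------------
    def _logpdf0(self, theta, u1, u2):
        raise NotImplementedError

    def _cdf0(self, theta, u1, u2):
        raise NotImplementedError

    def _hfun0(self, theta, u1, u2):
        raise NotImplementedError

    def _ppcf0(self, theta, u1, q):
        # generic vectorized bisection fallback (hfun monotone in u2)
        return _bisect_ppcf(lambda b: self._hfun0(theta, u1, b), q)

    def _sample0(self, theta, n, rng):
        # conditional (inverse-h) sampling works for every family
        u1 = rng.uniform(size=n)
        q = rng.uniform(size=n)
        th = np.broadcast_to(theta, (n,)) if np.ndim(theta) else theta
        u2 = self._ppcf0(th, clamp_unit(u1), clamp_unit(q))
        return u1, np.asarray(u2)

    def _tau0(self, theta) -> float:
        raise NotImplementedError


def _bisect_ppcf(hfun_of_u2, q, tol: float = 1e-9, maxit: int = 60):
    """Vectorized bisection solving hfun(u2) = q on (0, 1)."""
    q = np.asarray(q, dtype=float)
    lo = np.full_like(q, CLAMP_EPS)
    hi = np.full_like(q, 1.0 - CLAMP_EPS)
    for _ in range(maxit):
        mid = 0.5 * (lo + hi)
        too_low = hfun_of_u2(mid) < q
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Independence
# ---------------------------------------------------------------------------
class Independence(BivariateCopula):
    """Product copula; density 1 on the whole unit square, zero parameters."""

    name = "Independence"
    theta_domain = (0.0, 0.0)
    nparams = 0

    def gplink(self, f):
        return np.zeros_like(np.asarray(f, dtype=float))

    def gplink_deriv(self, f):
        return np.zeros_like(np.asarray(f, dtype=float))

    def _logpdf0(self, theta, u1, u2):
        return np.zeros(np.broadcast(u1, u2).shape)

    def _cdf0(self, theta, u1, u2):
        return u1 * u2

    def _hfun0(self, theta, u1, u2):
        return np.broadcast_arrays(u1, u2)[1].copy()

    def _ppcf0(self, theta, u1, q):
        return np.broadcast_arrays(u1, q)[1].copy()

    def _sample0(self, theta, n, rng):
        return rng.uniform(size=n), rng.uniform(size=n)

    def _tau0(self, theta):
        return 0.0

    def dlogpdf_dtheta(self, theta, u1, u2):
        return np.zeros(np.broadcast(u1, u2).shape)

    def fit_evaluator(self, u1, u2):
        shape = np.broadcast(np.asarray(u1), np.asarray(u2)).shape
        zero = lambda theta: np.zeros(np.broadcast(np.asarray(theta), np.empty(shape)).shape)
        return zero, zero


# ---------------------------------------------------------------------------
# Gaussian
# ---------------------------------------------------------------------------
class Gaussian(BivariateCopula):
    """Gaussian copula, theta = rho in [-1, 1]; link Erf(f/1.4)."""

    name = "Gaussian"
    theta_domain = (-1.0, 1.0)

    _RHO_CAP = 1.0 - 1e-7  # keep the density finite at the comonotone limit

    def gplink(self, f):
        return special.erf(np.asarray(f, dtype=float) / 1.4)

    def gplink_deriv(self, f):
        f = np.asarray(f, dtype=float)
        return (2.0 / (1.4 * np.sqrt(np.pi))) * np.exp(-((f / 1.4) ** 2))

    def _cap(self, theta):
        return np.clip(theta, -self._RHO_CAP, self._RHO_CAP)

    def _logpdf0(self, theta, u1, u2):
        return self._logpdf_pre(theta, self._precompute(u1, u2))

    def _precompute(self, a, b):
        return (special.ndtri(a), special.ndtri(b))

    def _logpdf_pre(self, theta, pre):
        z1, z2 = pre
        r = self._cap(theta)
        om = 1.0 - r * r
        return -0.5 * np.log(om) + (
            2.0 * r * z1 * z2 - r * r * (z1 * z1 + z2 * z2)
        ) / (2.0 * om)

    def fit_evaluator(self, u1, u2):
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        u2 = clamp_unit(np.asarray(u2, dtype=float))
        a, b = self._rotate_in(u1, u2)
        z1, z2 = special.ndtri(a), special.ndtri(b)
        s2 = z1 * z1 + z2 * z2
        z12 = z1 * z2

        def logpdf(theta):
            r = self._cap(np.asarray(theta, dtype=float))
            om = 1.0 - r * r
            return -0.5 * np.log(om) + (2.0 * r * z12 - r * r * s2) / (2.0 * om)

        def dlogpdf(theta):
            r = self._cap(np.asarray(theta, dtype=float))
            om = 1.0 - r * r
            # d/dr of the cached log-density
            return (
                r / om
                + (z12 - r * s2) / om
                + r * (2.0 * r * z12 - r * r * s2) / (om * om)
            )

        return logpdf, dlogpdf

    def _cdf0(self, theta, u1, u2):
        r = float(np.mean(self._cap(theta))) if np.ndim(theta) else float(
            self._cap(theta)
        )
        z1 = special.ndtri(np.clip(u1, CLAMP_EPS, 1 - CLAMP_EPS))
        z2 = special.ndtri(np.clip(u2, CLAMP_EPS, 1 - CLAMP_EPS))
        lo = np.broadcast_arrays(z1, z2)
        pts = np.stack([lo[0].ravel(), lo[1].ravel()], axis=-1)
        cov = np.array([[1.0, r], [r, 1.0]])
        val = stats.multivariate_normal(mean=[0, 0], cov=cov).cdf(pts)
        out = np.asarray(val, dtype=float).reshape(lo[0].shape)
        # honour the boundary conditions exactly
        out = np.where(np.asarray(u1) >= 1.0, np.asarray(u2) * np.ones_like(out), out)
        out = np.where(np.asarray(u2) >= 1.0, np.asarray(u1) * np.ones_like(out), out)
        out = np.where((np.asarray(u1) <= 0.0) | (np.asarray(u2) <= 0.0), 0.0, out)
        return out

    def _hfun0(self, theta, u1, u2):
        r = self._cap(theta)
        z1 = special.ndtri(u1)
        z2 = special.ndtri(u2)
        return special.ndtr((z2 - r * z1) / np.sqrt(1.0 - r * r))

    def _ppcf0(self, theta, u1, q):
        r = self._cap(theta)
        z1 = special.ndtri(u1)
        zq = special.ndtri(q)
        return special.ndtr(zq * np.sqrt(1.0 - r * r) + r * z1)

    def _sample0(self, theta, n, rng):
        r = self._cap(theta)
        z1 = rng.standard_normal(n)
        e = rng.standard_normal(n)
        z2 = r * z1 + np.sqrt(1.0 - r * r) * e
        return special.ndtr(z1), special.ndtr(z2)

    def _tau0(self, theta):
        return 2.0 / np.pi * np.arcsin(np.clip(theta, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Frank
# ---------------------------------------------------------------------------
class Frank(BivariateCopula):
    """Frank copula, theta in (-inf, inf); link 0.1 f + sign(f) (0.1 f)^2."""

    name = "Frank"
    theta_domain = (-np.inf, np.inf)

    _EPS = 1e-4  # below this |theta| the density is expanded around 0
    _THETA_CAP = 35.0

    def gplink(self, f):
        f = np.asarray(f, dtype=float)
        return 0.1 * f + np.sign(f) * (0.1 * f) ** 2

    def gplink_deriv(self, f):
        f = np.asarray(f, dtype=float)
        return 0.1 + 0.02 * np.abs(f)

    def _cap(self, theta):
        return np.clip(theta, -self._THETA_CAP, self._THETA_CAP)

    def _logpdf0(self, theta, u1, u2):
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(np.abs(th) < self._EPS, 1.0, th)
        # denom = e^{-th u1} + e^{-th u2} - e^{-th (u1+u2)} - e^{-th}
        # (no large-term cancellation); computed via a shifted exp-sum
        a1 = -th_safe * u1
        a2 = -th_safe * u2
        a3 = -th_safe * (u1 + u2)
        a4 = -th_safe * np.ones_like(a3)
        m = np.maximum.reduce([a1, a2, a3, a4])
        denom = (
            np.exp(a1 - m) + np.exp(a2 - m) - np.exp(a3 - m) - np.exp(a4 - m)
        )
        log_abs_denom = m + np.log(np.maximum(np.abs(denom), 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (
                np.log(np.abs(th_safe))
                + np.log(np.abs(-np.expm1(-th_safe)))
                - th_safe * (u1 + u2)
                - 2.0 * log_abs_denom
            )
        # series around theta=0: c = 1 + th (1-2u1)(1-2u2)/2 + O(th^2)
        small_arg = np.clip(
            np.asarray(th) * (1.0 - 2.0 * np.asarray(u1)) * (1.0 - 2.0 * np.asarray(u2)) / 2.0,
            -0.5,
            0.5,
        )
        return np.where(np.abs(th) < self._EPS, np.log1p(small_arg), out)

    def _cdf0(self, theta, u1, u2):
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(np.abs(th) < self._EPS, 1.0, th)
        a = np.expm1(-th_safe * u1)
        b = np.expm1(-th_safe * u2)
        g = np.expm1(-th_safe)
        out = -np.log1p(a * b / g) / th_safe
        return np.where(np.abs(th) < self._EPS, np.asarray(u1) * np.asarray(u2), out)

    def _hfun0(self, theta, u1, u2):
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(np.abs(th) < self._EPS, 1.0, th)
        a = np.exp(-th_safe * u1)
        b = np.exp(-th_safe * u2)
        g = np.exp(-th_safe)
        h = a * (b - 1.0) / ((g - 1.0) + (a - 1.0) * (b - 1.0))
        return np.where(np.abs(th) < self._EPS, np.broadcast_arrays(u1, u2)[1], h)

    def _ppcf0(self, theta, u1, q):
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(np.abs(th) < self._EPS, 1.0, th)
        a = np.exp(-th_safe * u1)
        g = np.exp(-th_safe)
        w = q * (g - 1.0) / (a - q * (a - 1.0))
        u2 = -np.log1p(w) / th_safe
        u2 = np.clip(u2, CLAMP_EPS, 1 - CLAMP_EPS)
        return np.where(np.abs(th) < self._EPS, np.broadcast_arrays(u1, q)[1], u2)

    def _tau0(self, theta):
        th = float(theta)
        if abs(th) < self._EPS:
            return th / 9.0  # leading-order expansion of the Debye formula
        d1, _ = integrate.quad(lambda t: t / np.expm1(t), 0.0, abs(th))
        debye = d1 / abs(th)
        tau = 1.0 + 4.0 * (debye - 1.0) / abs(th)
        return tau if th > 0 else -tau


# ---------------------------------------------------------------------------
# Clayton
# ---------------------------------------------------------------------------
class Clayton(BivariateCopula):
    """Clayton copula, theta in [0, inf); lower-tail dependent; link exp(0.2 f)."""

    name = "Clayton"
    theta_domain = (0.0, np.inf)
    rotatable = True

    _EPS = 1e-6
    _THETA_CAP = 35.0  # numerical ceiling; tau = theta/(theta+2) -> .946

    def gplink(self, f):
        return np.exp(0.2 * np.clip(np.asarray(f, dtype=float), -60.0, 17.0))

    def gplink_deriv(self, f):
        return 0.2 * self.gplink(f)

    def _cap(self, theta):
        return np.clip(theta, 0.0, self._THETA_CAP)

    def _logpdf0(self, theta, u1, u2):
        return self._logpdf_pre(theta, self._precompute(u1, u2))

    def _precompute(self, a, b):
        return (np.log(a), np.log(b))

    def _logpdf_pre(self, theta, pre):
        l1, l2 = pre
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(th < self._EPS, 1.0, th)
        # s = u1^-th + u2^-th - 1, computed via logs for stability
        t1 = -th_safe * l1
        t2 = -th_safe * l2
        m = np.maximum(t1, t2)
        s = np.exp(t1 - m) + np.exp(t2 - m) - np.exp(-m)
        log_s = m + np.log(s)
        out = (
            np.log1p(th_safe)
            - (1.0 + th_safe) * (l1 + l2)
            - (2.0 + 1.0 / th_safe) * log_s
        )
        return np.where(th < self._EPS, 0.0, out)

    def fit_evaluator(self, u1, u2):
        u1 = clamp_unit(np.asarray(u1, dtype=float))
        u2 = clamp_unit(np.asarray(u2, dtype=float))
        a, b = self._rotate_in(u1, u2)
        l1, l2 = np.log(a), np.log(b)
        lsum = l1 + l2

        def _parts(theta):
            th = self._cap(np.asarray(theta, dtype=float))
            th_safe = np.where(th < self._EPS, self._EPS, th)
            t1 = -th_safe * l1
            t2 = -th_safe * l2
            m = np.maximum(t1, t2)
            e1 = np.exp(t1 - m)
            e2 = np.exp(t2 - m)
            s = e1 + e2 - np.exp(-m)
            log_s = m + np.log(s)
            return th, th_safe, e1, e2, s, log_s

        def logpdf(theta):
            th, th_safe, e1, e2, s, log_s = _parts(theta)
            out = (
                np.log1p(th_safe) - (1.0 + th_safe) * lsum - (2.0 + 1.0 / th_safe) * log_s
            )
            return np.where(th < self._EPS, 0.0, out)

        def dlogpdf(theta):
            th, th_safe, e1, e2, s, log_s = _parts(theta)
            # ds/dth = -l1 u1^-th - l2 u2^-th (shifted by the same m)
            ds = -(l1 * e1 + l2 * e2)
            out = (
                1.0 / (1.0 + th_safe)
                - lsum
                + log_s / th_safe**2
                - (2.0 + 1.0 / th_safe) * ds / s
            )
            return np.where(th < self._EPS, out, out)

        return logpdf, dlogpdf

    def _cdf0(self, theta, u1, u2):
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(th < self._EPS, 1.0, th)
        u1c = np.clip(u1, CLAMP_EPS, 1.0)
        u2c = np.clip(u2, CLAMP_EPS, 1.0)
        s = u1c ** (-th_safe) + u2c ** (-th_safe) - 1.0
        out = np.maximum(s, CLAMP_EPS) ** (-1.0 / th_safe)
        out = np.where(th < self._EPS, np.asarray(u1) * np.asarray(u2), out)
        return np.where((np.asarray(u1) <= 0) | (np.asarray(u2) <= 0), 0.0, out)

    def _hfun0(self, theta, u1, u2):
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(th < self._EPS, 1.0, th)
        t1 = -th_safe * np.log(u1)
        t2 = -th_safe * np.log(u2)
        m = np.maximum(t1, t2)
        log_s = m + np.log(np.exp(t1 - m) + np.exp(t2 - m) - np.exp(-m))
        # h = u1^{-th-1} * s^{-1/th - 1}
        log_h = (-th_safe - 1.0) * np.log(u1) + (-1.0 / th_safe - 1.0) * log_s
        h = np.exp(log_h)
        return np.where(th < self._EPS, np.broadcast_arrays(u1, u2)[1], h)

    def _ppcf0(self, theta, u1, q):
        th = self._cap(np.asarray(theta, dtype=float))
        th_safe = np.where(th < self._EPS, 1.0, th)
        # u2 = [ (q^{-th/(1+th)} - 1) u1^{-th} + 1 ]^{-1/th}
        lq = np.log(q)
        lu = np.log(u1)
        a = np.exp(-th_safe / (1.0 + th_safe) * lq - th_safe * lu)
        inner = a - np.exp(-th_safe * lu) + 1.0
        u2 = np.exp(-np.log(np.maximum(inner, CLAMP_EPS)) / th_safe)
        u2 = np.clip(u2, CLAMP_EPS, 1 - CLAMP_EPS)
        return np.where(th < self._EPS, np.broadcast_arrays(u1, q)[1], u2)

    def _tau0(self, theta):
        th = float(theta)
        return th / (th + 2.0)


# ---------------------------------------------------------------------------
# Gumbel
# ---------------------------------------------------------------------------
class Gumbel(BivariateCopula):
    """Gumbel copula, theta in [1, inf); upper-tail dependent; link 1+exp(0.1 f)."""

    name = "Gumbel"
    theta_domain = (1.0, np.inf)
    rotatable = True

    _THETA_CAP = 35.0

    def gplink(self, f):
        return 1.0 + np.exp(0.1 * np.clip(np.asarray(f, dtype=float), -60.0, 35.0))

    def gplink_deriv(self, f):
        return 0.1 * np.exp(0.1 * np.clip(np.asarray(f, dtype=float), -60.0, 35.0))

    def _cap(self, theta):
        return np.clip(theta, 1.0, self._THETA_CAP)

    @staticmethod
    def _logw(th, u1, u2):
        """log w with w = (-ln u1)^th + (-ln u2)^th, stably."""
        a = th * np.log(-np.log(u1))
        b = th * np.log(-np.log(u2))
        m = np.maximum(a, b)
        return m + np.log(np.exp(a - m) + np.exp(b - m))

    def _logpdf0(self, theta, u1, u2):
        return self._logpdf_pre(theta, self._precompute(u1, u2))

    def _precompute(self, a, b):
        x = -np.log(a)
        y = -np.log(b)
        return (x, y, np.log(x), np.log(y))

    def _logpdf_pre(self, theta, pre):
        x, y, lx, ly = pre
        th = self._cap(np.asarray(theta, dtype=float))
        a1 = th * lx
        a2 = th * ly
        m = np.maximum(a1, a2)
        logw = m + np.log(np.exp(a1 - m) + np.exp(a2 - m))
        wp = np.exp(logw / th)  # w^{1/th}
        # c = C(u) (u1 u2)^{-1} (xy)^{th-1} w^{1/th - 2} (w^{1/th} + th - 1)
        return (
            -wp
            + x
            + y
            + (th - 1.0) * (lx + ly)
            + (1.0 / th - 2.0) * logw
            + np.log(wp + th - 1.0)
        )

    def _cdf0(self, theta, u1, u2):
        th = self._cap(np.asarray(theta, dtype=float))
        u1c = np.clip(u1, CLAMP_EPS, 1 - 1e-16)
        u2c = np.clip(u2, CLAMP_EPS, 1 - 1e-16)
        out = np.exp(-np.exp(self._logw(th, u1c, u2c) / th))
        out = np.where(np.asarray(u1) >= 1.0, np.asarray(u2) * np.ones_like(out), out)
        out = np.where(np.asarray(u2) >= 1.0, np.asarray(u1) * np.ones_like(out), out)
        return np.where((np.asarray(u1) <= 0) | (np.asarray(u2) <= 0), 0.0, out)

    def _hfun0(self, theta, u1, u2):
        th = self._cap(np.asarray(theta, dtype=float))
        x = -np.log(u1)
        logw = self._logw(th, u1, u2)
        wp = np.exp(logw / th)
        # h = C(u) * x^{th-1} * w^{1/th - 1} / u1
        log_h = -wp + (th - 1.0) * np.log(x) + (1.0 / th - 1.0) * logw + x
        return np.exp(log_h)

    def _tau0(self, theta):
        return 1.0 - 1.0 / float(theta)


# ---------------------------------------------------------------------------
# registry helpers
# ---------------------------------------------------------------------------
_FAMILIES = {
    "Independence": Independence,
    "Gaussian": Gaussian,
    "Frank": Frank,
    "Clayton": Clayton,
    "Gumbel": Gumbel,
}


def make_family(name: str, rotation: int = 0) -> BivariateCopula:
    """Construct a family by name, e.g. ``make_family('Clayton', 90)``.

    Also accepts compact keys like ``'Clayton90'``.
    """
    if name not in _FAMILIES:
        for base in _FAMILIES:
            if name.startswith(base) and name[len(base):].isdigit():
                return _FAMILIES[base](int(name[len(base):]))
        raise KeyError(f"unknown copula family {name!r}")
    return _FAMILIES[name](rotation)


def standard_candidates() -> list[BivariateCopula]:
    """The ten mixture building blocks: Gaussian + Frank + 4xClayton + 4xGumbel."""
    out: list[BivariateCopula] = [Gaussian(), Frank()]
    for rot in _ROTATIONS:
        out.append(Clayton(rot))
    for rot in _ROTATIONS:
        out.append(Gumbel(rot))
    return out
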