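"""Goodness-of-fit: proportion of variance explained for a conditional copula.

Samples from an x-interval are split into 20 equal bins of the first
pseudo-observation u1; in every bin the empirical conditional CDF
``ecdf(u2 | u1 in bin)`` is compared against the model h-function evaluated
at the bin's mean u1 and at the interval's x center of mass, on the grid
``u2 = 0, 0.05, ..., 1``.  The per-bin score is the conventional
variance-explained form

    R^2 = 1 - sum (ecdf - ccdf)^2 / sum (ecdf - 0.5)^2,

averaged over bins into R-bar^2.  A literal variant that sums the squared
pointwise ratio ``((ecdf - ccdf)/(ecdf - 0.5))^2`` is available behind
``literal=True``; it is unbounded below at grid points where the ecdf
crosses 1/2 and is kept only for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["R2Report", "r2_interval"]


@dataclass
class R2Report:
    r2_per_bin: np.ndarray
    r2_mean: float
    x_interval: tuple[float, float]
    x_mu: float
    n_bins: int
    n_samples: int
    u2_grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 21))


def r2_interval(results, x, u1, u2, x_interval, n_bins: int = 20, literal: bool = False) -> R2Report:
    """R-bar^2 of a fitted conditional copula over an x interval.

    ``results`` is a fitted bivariate model exposing ``mixture_at``.
    """
    x = np.asarray(x, dtype=float)
    u1 = np.asarray(u1, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    lo, hi = x_interval
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 20:
        raise ValueError(f"only {mask.sum()} samples in x interval [{lo}, {hi}]")
    xs, a, b = x[mask], u1[mask], u2[mask]
    x_mu = float(np.mean(xs))
    mix = results.mixture_at(np.array([x_mu]))
    grid = np.linspace(0.0, 1.0, 21)  # u2 = 0.05 n, n = 0..20
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    r2s = []
    for i in range(n_bins):
        sel = (a >= edges[i]) & (a < edges[i + 1])
        if not np.any(sel):
            warnings.warn(f"empty u1 bin {i}; skipped")
            continue
        ecdf = np.mean(b[sel][None, :] <= grid[:, None], axis=1)
        u1_bin = float(np.mean(a[sel]))
        ccdf = np.asarray(
            [np.ravel(mix.hfun(np.array([u1_bin]), np.array([g])))[0] for g in grid]
        )
        resid = ecdf - ccdf
        spread = ecdf - 0.5
        if literal:
            ok = np.abs(spread) > 1e-12
            r2 = 1.0 - float(np.sum((resid[ok] / spread[ok]) ** 2))
        else:
            denom = float(np.sum(spread**2))
            r2 = 1.0 - float(np.sum(resid**2)) / denom if denom > 0 else np.nan
        r2s.append(r2)
    r2s = np.asarray(r2s)
    return R2Report(
        r2_per_bin=r2s,
        r2_mean=float(np.nanmean(r2s)),
        x_interval=(float(lo), float(hi)),
        x_mu=x_mu,
        n_bins=n_bins,
        n_samples=int(mask.sum()),
    )
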