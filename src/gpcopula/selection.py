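"""WAIC-based construction of copula mixtures: greedy and heuristic.

Both strategies score candidate models with the Watanabe-Akaike information
criterion and return the Independence model when no candidate beats
``-waic_tol``.  The *greedy* strategy is family-agnostic forward selection
over the ten standard elements (Gaussian, Frank, four Clayton and four
Gumbel rotations); the *heuristic* strategy first screens for independence
with a short-budget Gaussian fit, then orders candidates by empirical tail
diagnostics (excess mass in the four 0.1 x 0.1 corner squares over the 0.01n
independence expectation picks Clayton/Gumbel rotations; the sign of
Kendall's tau orders Gaussian/Frank) and runs the same forward selection
over that short-list.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from .families import (
    BivariateCopula,
    Clayton,
    Frank,
    Gaussian,
    Gumbel,
    Independence,
    standard_candidates,
)
from .gp import FitConfig, MixtureGPState, WaicResult, fit_mixture_gp, waic_of_state
from .mixture import MAX_COMPONENTS, stick_break

__all__ = ["select_greedy", "select_heuristic", "rank_candidates"]


def _independence_state(x) -> MixtureGPState:
    x = np.asarray(x, dtype=float)
    return MixtureGPState([Independence()], [], [], float(np.min(x)), float(np.max(x)))


def _fit_and_score(comps, x, u1, u2, config, rng):
    state = fit_mixture_gp(comps, x, u1, u2, config, rng=rng)
    waic = waic_of_state(state, x, u1, u2, S=config.waic_samples, rng=rng)
    return state, waic


def _prune_degenerate(state, waic, x, u1, u2, config, rng, min_phi=1e-4):
    """Drop components whose weight never exceeds ``min_phi`` and refit once."""
    if state.M <= 1:
        return state, waic
    xs = np.linspace(state.x_lo, state.x_hi, 101)
    _, phis = state.params_at(xs)
    keep = [j for j in range(state.M) if float(np.max(phis[j])) >= min_phi]
    if len(keep) == state.M or not keep:
        return state, waic
    comps = [state.components[j] for j in keep]
    return _fit_and_score(comps, x, u1, u2, config, rng)


def select_greedy(
    x,
    u1,
    u2,
    config: FitConfig | None = None,
    rng=None,
    candidates: list[BivariateCopula] | None = None,
):
    """Forward selection: best single family, then repeated best additions.

    Stops when the best WAIC decrease falls below ``waic_tol`` or the
    mixture reaches five components; returns ``(state, WaicResult)``, the
    Independence model if nothing beats ``-waic_tol``.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(rng)
    candidates = list(candidates) if candidates is not None else standard_candidates()

    singles = {}
    for cand in candidates:
        singles[cand.key] = _fit_and_score([cand], x, u1, u2, config, rng)
    best_key = min(singles, key=lambda k: singles[k][1].waic)
    state, waic = singles[best_key]
    if waic.waic > -config.waic_tol:
        return _independence_state(x), WaicResult(0.0, 0.0, 0.0, config.waic_samples)

    # candidate additions are screened at half the step budget; the
    # accepted model is refit at the full budget before the next round
    trial_cfg = replace(config, max_steps=max(150, config.max_steps // 2))
    current = [c for c in candidates if c.key == best_key]
    while len(current) < MAX_COMPONENTS:
        unused = [c for c in candidates if c not in current]
        if not unused:
            break
        trials = [
            _fit_and_score(current + [c], x, u1, u2, trial_cfg, rng) for c in unused
        ]
        j = int(np.argmin([w.waic for _, w in trials]))
        if waic.waic - trials[j][1].waic < config.waic_tol:
            break
        current = current + [unused[j]]
        state, waic = _fit_and_score(current, x, u1, u2, config, rng)
    state, waic = _prune_degenerate(state, waic, x, u1, u2, config, rng)
    return state, waic


# -- tail diagnostics --------------------------------------------------------
# corner -> (Clayton rotation, Gumbel rotation) whose tail mass sits there
# under this package's rotation convention
_CORNER_MAP = {
    "ll": (Clayton(0), Gumbel(180)),
    "ur": (Clayton(180), Gumbel(0)),
    "lr": (Clayton(90), Gumbel(270)),
    "ul": (Clayton(270), Gumbel(90)),
}


def corner_masses(u1, u2, width: float = 0.1) -> dict[str, float]:
    """Fraction of points in each corner square of side ``width``."""
    u1 = np.asarray(u1)
    u2 = np.asarray(u2)
    n = len(u1)
    return {
        "ll": float(np.sum((u1 < width) & (u2 < width))) / n,
        "ur": float(np.sum((u1 > 1 - width) & (u2 > 1 - width))) / n,
        "lr": float(np.sum((u1 > 1 - width) & (u2 < width))) / n,
        "ul": float(np.sum((u1 < width) & (u2 > 1 - width))) / n,
    }


def rank_candidates(u1, u2, width: float = 0.1) -> list[BivariateCopula]:
    """Tail-diagnostic candidate ordering for the heuristic strategy.

    Corners are ranked by excess mass over the independence expectation
    ``width**2``; each contributes its Clayton rotation then its Gumbel
    rotation.  Gaussian and Frank lead the list (Frank first when the tail
    excesses are weak relative to |tau|, i.e. dependence looks tail-free).
    """
    masses = corner_masses(u1, u2, width)
    expect = width * width
    excess = {k: m - expect for k, m in masses.items()}
    order = sorted(excess, key=lambda k: -excess[k])
    tau = stats.kendalltau(u1, u2).statistic
    # Gaussian and Frank are sign-symmetric; lead with the one whose shape
    # better matches the data (Frank for tail-free dependence).
    max_excess = max(excess.values())
    head = [Frank(), Gaussian()] if (abs(tau) > 0.1 and max_excess < 0.005) else [Gaussian(), Frank()]
    out: list[BivariateCopula] = list(head)
    for corner in order:
        cl, gu = _CORNER_MAP[corner]
        out.extend([cl, gu])
    return out


def _looks_independent(u1, u2, width: float = 0.1, z_crit: float = 4.0) -> bool:
    """Cheap independence diagnostics backing up the Gaussian screen.

    A balanced mixture of opposite-sign components fools a single Gaussian
    fit (net correlation near zero), but leaves corner-mass excess and/or a
    significant Kendall tau; only data passing all diagnostics are declared
    independent.
    """
    u1 = np.asarray(u1)
    n = len(u1)
    expect = width * width
    sd = np.sqrt(expect * (1 - expect) / n)
    for m in corner_masses(u1, u2, width).values():
        if (m - expect) / sd > z_crit:
            return False
    tau = stats.kendalltau(u1, u2)
    return tau.pvalue > 1e-3


def select_heuristic(
    x,
    u1,
    u2,
    config: FitConfig | None = None,
    rng=None,
    screen_steps: int = 200,
    shortlist: int = 6,
):
    """Two-stage selection: quick independence screen, then guided greedy.

    Stage 1 fits a single Gaussian copula with a capped step budget; if its
    WAIC does not beat ``-waic_tol`` the variables are declared independent.
    Stage 2 runs forward selection over the tail-diagnostic-ordered
    short-list of candidates.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(rng)

    screen_cfg = replace(config, max_steps=min(screen_steps, config.max_steps))
    state, waic = _fit_and_score([Gaussian()], x, u1, u2, screen_cfg, rng)
    if waic.waic > -config.waic_tol and _looks_independent(u1, u2):
        return _independence_state(x), WaicResult(0.0, 0.0, 0.0, config.waic_samples)

    ordered = rank_candidates(u1, u2)[:shortlist]
    return select_greedy(x, u1, u2, config=config, rng=rng, candidates=ordered)
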