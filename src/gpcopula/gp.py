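"""Stochastic variational inference for conditional copula mixtures.

Each of the ``2M - 1`` latent functions of an ``M``-component mixture (one
per copula parameter, ``M - 1`` for the stick-breaking weights) is an
independent Gaussian process of the conditioning variable ``x`` with an RBF
kernel and constant mean.  Inducing values live on a regular grid spanning
the (internally standardized) ``x`` domain; latent values at the data are
obtained by linear interpolation from the grid, so inference costs O(n) per
step.  The variational distribution is a full-covariance Gaussian over
*whitened* inducing values (prior N(0, I)); the evidence lower bound

    L = sum_i E_q[log c(u_i | f(x_i))] - KL[q || N(0, I)]

is maximized by Adam with separate learning rates for GP hyperparameters
(``base_lr``) and variational parameters (``var_lr``).  The expectation is a
Monte-Carlo average over a fixed number of functional draws per step; all
likelihood gradients are analytic apart from d log c / d theta, which each
family supplies by a guarded central difference.

A normal prior on the RBF lengthscale (mean 0.5, sd 1.0 on the unit-interval
x scale) discourages the short-lengthscale overfitting minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .families import BivariateCopula, Independence, clamp_unit
from .mixture import MixtureCopula, stick_break, stick_break_jacobian

__all__ = ["FitConfig", "GPLatent", "MixtureGPState", "fit_mixture_gp", "waic_of_state"]

_JITTER = 1e-6
_MIN_PDF = 1e-30


@dataclass
class FitConfig:
    """Hyper-parameters of the bivariate conditional copula fit.

    The first six names and defaults follow the standard published settings
    for this model class; the remainder are implementation-level knobs.
    """

    base_lr: float = 0.05
    var_lr: float = 0.02
    grid_size: int = 60
    waic_tol: float = 0.005
    loss_tol: float = 1e-4
    check_waic: float = 0.005
    max_steps: int = 1500
    mc_draws: int = 10
    waic_samples: int = 100

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _interp_weights(x01: np.ndarray, G: int):
    """Linear interpolation of grid values onto x in [0, 1]."""
    pos = np.clip(x01, 0.0, 1.0) * (G - 1)
    idx = np.minimum(pos.astype(int), G - 2)
    frac = pos - idx
    return idx, frac


def _interp_apply(vals, idx, frac):
    """W @ vals for vals of shape (..., G) -> (..., n)."""
    return vals[..., idx] * (1.0 - frac) + vals[..., idx + 1] * frac


def _interp_adjoint(g, idx, frac, G):
    """W.T @ g for g of shape (S, n) -> (S, G)."""
    S = g.shape[0]
    out = np.zeros((S, G))
    w0 = g * (1.0 - frac)
    w1 = g * frac
    for s in range(S):
        np.add.at(out[s], idx, w0[s])
        np.add.at(out[s], idx + 1, w1[s])
    return out


def _chol_diff(R: np.ndarray, dK: np.ndarray) -> np.ndarray:
    """Forward-mode derivative of the lower Cholesky factor.

    dR = R * Phi(R^{-1} dK R^{-T}), Phi = lower triangle with halved diagonal.
    """
    A = solve_triangular(R, dK, lower=True)
    A = solve_triangular(R, A.T, lower=True).T
    Phi = np.tril(A)
    Phi[np.diag_indices_from(Phi)] *= 0.5
    return R @ Phi


class GPLatent:
    """One latent GP: constant mean, RBF kernel, whitened variational state."""

    def __init__(self, grid_size: int, rng: np.random.Generator):
        self.G = grid_size
        self.grid = np.linspace(0.0, 1.0, grid_size)
        # hyperparameters (trained with base_lr)
        self.mu = 0.0
        self.log_ls = np.log(0.5)
        self.log_scale = 0.0
        # variational parameters over whitened inducing values (var_lr)
        self.m = np.zeros(grid_size)
        self.L_off = np.zeros((grid_size, grid_size))
        # start the variational covariance tighter than the prior: the WAIC
        # computed during training is then dominated by the fit rather than
        # by still-uncontracted posterior spread
        self.L_log_diag = np.full(grid_size, -1.0)
        self._refresh_kernel()

    # -- kernel ----------------------------------------------------------------
    def _refresh_kernel(self):
        ls = np.exp(self.log_ls)
        sc = np.exp(self.log_scale)
        d2 = (self.grid[:, None] - self.grid[None, :]) ** 2
        self.K = sc**2 * np.exp(-0.5 * d2 / ls**2)
        self.dK_dlog_ls = self.K * (d2 / ls**2)
        self.dK_dlog_scale = 2.0 * self.K
        self.R = cholesky(self.K + _JITTER * np.eye(self.G), lower=True)

    @property
    def L(self) -> np.ndarray:
        return np.tril(self.L_off, -1) + np.diag(np.exp(self.L_log_diag))

    # -- draws -------------------------------------------------------------------
    def draw_f(self, idx, frac, eps):
        """Functional draws at the data points; eps has shape (S, G)."""
        v = self.m[None, :] + eps @ self.L.T  # (S, G) whitened draws
        u = v @ self.R.T  # (S, G) inducing values (zero prior mean)
        return self.mu + _interp_apply(u, idx, frac), v

    def f_moments(self, idx, frac):
        """Posterior mean and sd of f at the data points."""
        A = self.R  # (G, G)
        mean_g = A @ self.m
        cov_half = A @ self.L  # (G, G)
        var_g = np.sum(cov_half**2, axis=1)
        cov_adj = np.einsum("ij,ij->i", cov_half[:-1], cov_half[1:])
        mean = self.mu + _interp_apply(mean_g, idx, frac)
        # exact interpolated variance uses adjacent-node covariance
        w0, w1 = (1.0 - frac), frac
        var = (
            w0**2 * var_g[idx]
            + w1**2 * var_g[idx + 1]
            + 2 * w0 * w1 * cov_adj[idx]
        )
        return mean, np.sqrt(np.maximum(var, 0.0))

    def moments_and_A(self, idx, frac):
        """Marginal q(f_i) moments and the interpolated whitening map A = WR."""
        A = self.R[idx] * (1.0 - frac)[:, None] + self.R[idx + 1] * frac[:, None]
        mu_i = self.mu + A @ self.m
        AL = A @ self.L
        sig = np.sqrt(np.sum(AL * AL, axis=1) + 1e-12)
        return mu_i, sig, A, AL

    def backward_gh(self, gmu, gsig, idx, frac, A, AL, sig, grads_out):
        """Gradients of the likelihood term from dLoss/dmu_i and dLoss/dsigma_i."""
        L = self.L
        grads = {"mu": float(np.sum(gmu)), "m": A.T @ gmu}
        c = gsig / sig
        gL = (A.T * c) @ AL  # = A^T diag(c) A L
        gL = np.tril(gL)
        grads["L_off"] = np.tril(gL, -1)
        grads["L_log_diag"] = np.diag(gL) * np.exp(self.L_log_diag)
        for name, dK in (
            ("log_ls", self.dK_dlog_ls),
            ("log_scale", self.dK_dlog_scale),
        ):
            dR = _chol_diff(self.R, dK)
            dA = dR[idx] * (1.0 - frac)[:, None] + dR[idx + 1] * frac[:, None]
            dmu = dA @ self.m
            dsig = np.sum(AL * (dA @ L), axis=1) / sig
            grads[name] = float(gmu @ dmu + gsig @ dsig)
        grads_out.update(grads)
        return grads_out

    # -- objective pieces ---------------------------------------------------------
    def kl(self) -> float:
        Ld = np.exp(self.L_log_diag)
        L = self.L
        return 0.5 * (
            np.sum(L * L) + self.m @ self.m - self.G - 2.0 * np.sum(self.L_log_diag)
        )

    def lengthscale_penalty(self) -> float:
        lam = np.exp(self.log_ls)
        return 0.5 * (lam - 0.5) ** 2

    # -- gradient accumulation ------------------------------------------------------
    def backward(self, g, idx, frac, eps):
        """Gradients of the *likelihood* term given g = dLoss/df (S, n)."""
        S = g.shape[0]
        b = _interp_adjoint(g, idx, frac, self.G)  # (S, G) = W^T g
        v = self.m[None, :] + eps @ self.L.T
        grads = {}
        grads["mu"] = float(np.sum(g) / S)
        bR = b @ self.R  # (S, G): R^T b
        grads["m"] = bR.mean(axis=0)
        gL = (bR[:, :, None] * eps[:, None, :]).mean(axis=0)  # (G, G)
        gL = np.tril(gL)
        grads["L_off"] = np.tril(gL, -1)
        grads["L_log_diag"] = np.diag(gL) * np.exp(self.L_log_diag)
        for name, dK in (
            ("log_ls", self.dK_dlog_ls),
            ("log_scale", self.dK_dlog_scale),
        ):
            dR = _chol_diff(self.R, dK)
            du = v @ dR.T  # (S, G)
            grads[name] = float(np.mean(np.sum(b * du, axis=1), axis=0) * S / S)
        return grads

    def kl_gradients(self, n_scale: float):
        """Gradients of (KL + lengthscale prior)/n."""
        L = self.L
        gL = (L - np.diag(1.0 / np.exp(self.L_log_diag))) / n_scale
        lam = np.exp(self.log_ls)
        return {
            "m": self.m / n_scale,
            "L_off": np.tril(gL, -1),
            "L_log_diag": np.diag(gL) * np.exp(self.L_log_diag),
            "log_ls": (lam - 0.5) * lam / n_scale,
            "mu": 0.0,
            "log_scale": 0.0,
        }


class _Adam:
    def __init__(self, lr: float):
        self.lr = lr
        self.t = 0
        self.state: dict[tuple, tuple] = {}

    def step(self, key, param, grad):
        m, v = self.state.get(key, (np.zeros_like(np.asarray(param, float)), np.zeros_like(np.asarray(param, float))))
        b1, b2, eps = 0.9, 0.999, 1e-8
        m = b1 * m + (1 - b1) * np.asarray(grad, float)
        v = b2 * v + (1 - b2) * np.asarray(grad, float) ** 2
        self.state[key] = (m, v)
        mhat = m / (1 - b1**self.t)
        vhat = v / (1 - b2**self.t)
        return param - self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class MixtureGPState:
    """Fitted state of a conditional copula mixture."""

    components: list[BivariateCopula]
    theta_latents: list[GPLatent]
    stick_latents: list[GPLatent]
    x_lo: float
    x_hi: float
    loss_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    aborted: bool = False
    steps: int = 0

    @property
    def M(self) -> int:
        return len(self.components)

    @property
    def latents(self) -> list[GPLatent]:
        return self.theta_latents + self.stick_latents

    def standardize(self, x):
        span = self.x_hi - self.x_lo
        return (np.asarray(x, dtype=float) - self.x_lo) / (span if span > 0 else 1.0)

    # -- prediction -------------------------------------------------------------
    def params_at(self, x, mode: str = "mean", S: int = 1, rng=None):
        """Copula parameters theta_j(x) and weights phi_j(x).

        ``mode='mean'`` links the posterior-mean latent; ``mode='sample'``
        returns ``S`` functional posterior draws (leading axis S).
        """
        x01 = self.standardize(x)
        n = x01.shape[0]
        G = self.theta_latents[0].G if self.theta_latents else 60
        idx, frac = _interp_weights(x01, G)
        if mode == "mean":
            f_th = np.stack(
                [lat.f_moments(idx, frac)[0] for lat in self.theta_latents]
            )  # (M, n)
            thetas = np.stack(
                [c.gplink(f_th[j]) for j, c in enumerate(self.components)]
            )
            if self.stick_latents:
                f_st = np.stack(
                    [lat.f_moments(idx, frac)[0] for lat in self.stick_latents],
                    axis=-1,
                )  # (n, M-1)
                phis = stick_break(f_st).T  # (M, n)
            else:
                phis = np.ones((1, n))
            return thetas, phis
        if mode != "sample":
            raise ValueError("mode must be 'mean' or 'sample'")
        rng = np.random.default_rng(rng)
        f_th = np.stack(
            [
                lat.draw_f(idx, frac, rng.standard_normal((S, lat.G)))[0]
                for lat in self.theta_latents
            ]
        )  # (M, S, n)
        thetas = np.stack(
            [c.gplink(f_th[j]) for j, c in enumerate(self.components)]
        )  # (M, S, n)
        if self.stick_latents:
            f_st = np.stack(
                [
                    lat.draw_f(idx, frac, rng.standard_normal((S, lat.G)))[0]
                    for lat in self.stick_latents
                ],
                axis=-1,
            )  # (S, n, M-1)
            phis = np.moveaxis(stick_break(f_st), -1, 0)  # (M, S, n)
        else:
            phis = np.ones((1, S, n))
        return thetas, phis

    def mixture_at(self, x, mode: str = "mean", rng=None) -> MixtureCopula:
        thetas, phis = self.params_at(np.atleast_1d(x), mode=mode, S=1, rng=rng)
        if thetas.ndim == 3:
            thetas, phis = thetas[:, 0, :], phis[:, 0, :]
        return MixtureCopula(self.components, thetas, phis)

    def ci_at(self, x, z: float = 2.0):
        """Pointwise CI of each linked parameter: link(mean +/- z sd)."""
        x01 = self.standardize(x)
        G = self.theta_latents[0].G
        idx, frac = _interp_weights(x01, G)
        lo, hi = [], []
        for j, comp in enumerate(self.components):
            mean, sd = self.theta_latents[j].f_moments(idx, frac)
            a, b = comp.gplink(mean - z * sd), comp.gplink(mean + z * sd)
            lo.append(np.minimum(a, b))
            hi.append(np.maximum(a, b))
        return np.stack(lo), np.stack(hi)

    def logpdf(self, x, u1, u2, mode: str = "mean", rng=None):
        mix = self.mixture_at(x, mode=mode, rng=rng)
        return mix.logpdf(u1, u2)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------
def _mixture_loglik_and_grads(state, thetas_f, sticks_f, evals, need_grads=True):
    """Log-density of the mixture and d log c / d f for every latent.

    ``thetas_f``: list of (S, n) latent draws per component;
    ``sticks_f``: (S, n, M-1); ``evals``: cached per-component
    ``(logpdf, dlogpdf)`` closures.  Returns (logp (S,n), grads per latent).
    """
    comps = state.components
    M = len(comps)
    thetas = [c.gplink(thetas_f[j]) for j, c in enumerate(comps)]
    if M > 1:
        phis = np.moveaxis(stick_break(sticks_f), -1, 0)  # (M, S, n)
    else:
        phis = np.ones((1,) + thetas_f[0].shape)
    cj = np.stack(
        [np.exp(evals[j][0](thetas[j])) for j in range(M)]
    )  # (M, S, n)
    p = np.maximum(np.sum(phis * cj, axis=0), _MIN_PDF)
    logp = np.log(p)
    if not need_grads:
        return logp, None, None
    g_theta = []
    for j, c in enumerate(comps):
        if c.nparams == 0:
            g_theta.append(np.zeros_like(p))
            continue
        dlc = evals[j][1](thetas[j])
        g_theta.append(phis[j] * cj[j] * dlc * c.gplink_deriv(thetas_f[j]) / p)
    if M > 1:
        J = stick_break_jacobian(sticks_f)  # (S, n, M, M-1)
        ratio = np.moveaxis(cj / p[None], 0, -1)  # (S, n, M)
        g_stick = np.einsum("snm,snmk->snk", ratio, J)  # (S, n, M-1)
    else:
        g_stick = None
    return logp, g_theta, g_stick


def fit_mixture_gp(
    components: list[BivariateCopula],
    x,
    u1,
    u2,
    config: FitConfig | None = None,
    rng=None,
) -> MixtureGPState:
    """Fit the conditional copula mixture by stochastic variational inference.

    Follows the two-rate Adam schedule with 50-step loss averaging: when the
    averaged loss change drops below ``check_waic`` the WAIC is evaluated
    once and the fit aborts (flagged) if the model is no better than
    Independence; otherwise optimization continues until the change is below
    ``loss_tol`` or ``max_steps`` is reached.
    """
    config = config or FitConfig()
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    u1 = clamp_unit(np.asarray(u1, dtype=float))
    u2 = clamp_unit(np.asarray(u2, dtype=float))
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two observations")

    comps = list(components)
    M = len(comps)
    if M == 1 and isinstance(comps[0], Independence):
        return MixtureGPState(comps, [], [], float(np.min(x)), float(np.max(x)))

    state = MixtureGPState(
        comps,
        [GPLatent(config.grid_size, rng) for _ in range(M)],
        [GPLatent(config.grid_size, rng) for _ in range(M - 1)],
        float(np.min(x)),
        float(np.max(x)),
    )
    x01 = state.standardize(x)
    idx, frac = _interp_weights(x01, config.grid_size)

    opt_base = _Adam(config.base_lr)
    opt_var = _Adam(config.var_lr)
    base_names = ("mu", "log_ls", "log_scale")
    var_names = ("m", "L_off", "L_log_diag")

    losses = []
    checked_waic = False
    next_check = 0
    S = config.mc_draws
    evals = [c.fit_evaluator(u1, u2) for c in comps]
    # single-component models admit a deterministic Gauss-Hermite
    # expectation over the 1-D latent marginal (noise-free gradients)
    use_gh = M == 1 and comps[0].nparams == 1
    if use_gh:
        gh_t, gh_w = np.polynomial.hermite_e.hermegauss(20)
        gh_w = gh_w / gh_w.sum()  # E over N(0,1): f = mu_i + sigma_i t
        comp = comps[0]
        lat = state.theta_latents[0]
        lp_fn, dlp_fn = comp.fit_evaluator(u1, u2)
        for step in range(1, config.max_steps + 1):
            mu_i, sig, A, AL = lat.moments_and_A(idx, frac)
            fsites = mu_i[None, :] + sig[None, :] * gh_t[:, None]  # (K, n)
            thetas = comp.gplink(fsites)
            logp = lp_fn(thetas)
            dlf = dlp_fn(thetas) * comp.gplink_deriv(fsites)
            kl = lat.kl()
            pen = lat.lengthscale_penalty()
            loss = -float(gh_w @ logp.mean(axis=1)) + (kl + pen) / n
            losses.append(loss)
            gmu = -(gh_w @ dlf) / n
            gsig = -((gh_w * gh_t) @ dlf) / n
            grads = lat.backward_gh(gmu, gsig, idx, frac, A, AL, sig, {})
            klg = lat.kl_gradients(n)
            opt_base.t += 1
            opt_var.t += 1
            for nm in base_names + var_names:
                tot = np.clip(
                    np.nan_to_num(grads[nm] + klg[nm], nan=0.0, posinf=1e3, neginf=-1e3),
                    -1e3,
                    1e3,
                )
                opt = opt_base if nm in base_names else opt_var
                setattr(lat, nm, opt.step((id(lat), nm), getattr(lat, nm), tot))
            lat._refresh_kernel()
            if not np.isfinite(loss):
                raise FloatingPointError("loss diverged during copula-GP fit")
            if step % 50 == 0 and step >= 100:
                dloss = float(np.mean(losses[-100:-50]) - np.mean(losses[-50:]))
                if dloss < config.loss_tol:
                    break
                if dloss < config.check_waic and step >= next_check:
                    w = waic_of_state(state, x, u1, u2, S=config.waic_samples, rng=rng)
                    if w.waic > -config.waic_tol:
                        if checked_waic:  # second strike: abort
                            state.aborted = True
                            break
                        checked_waic = True
                        next_check = step + 200  # confirm before aborting
                    else:
                        next_check = config.max_steps + 1  # model is viable
        state.loss_trace = np.asarray(losses)
        state.steps = len(losses)
        return state

    for step in range(1, config.max_steps + 1):
        eps_th = [rng.standard_normal((S, lat.G)) for lat in state.theta_latents]
        eps_st = [rng.standard_normal((S, lat.G)) for lat in state.stick_latents]
        thetas_f, vs_th = [], []
        for lat, e in zip(state.theta_latents, eps_th):
            f, v = lat.draw_f(idx, frac, e)
            thetas_f.append(f)
        sticks_f = None
        if M > 1:
            fs = []
            for lat, e in zip(state.stick_latents, eps_st):
                f, v = lat.draw_f(idx, frac, e)
                fs.append(f)
            sticks_f = np.stack(fs, axis=-1)  # (S, n, M-1)

        logp, g_theta, g_stick = _mixture_loglik_and_grads(
            state, thetas_f, sticks_f, evals
        )
        kl = sum(lat.kl() for lat in state.latents)
        pen = sum(lat.lengthscale_penalty() for lat in state.latents)
        loss = -float(np.mean(logp)) + (kl + pen) / n
        losses.append(loss)

        opt_base.t += 1
        opt_var.t += 1
        def _update(lat, g, eps):
            g = np.nan_to_num(g, nan=0.0, posinf=0.0, neginf=0.0)
            grads = lat.backward(g, idx, frac, eps)
            klg = lat.kl_gradients(n)
            for nm in base_names + var_names:
                tot = np.clip(
                    np.nan_to_num(grads[nm] + klg[nm], nan=0.0, posinf=1e3, neginf=-1e3),
                    -1e3,
                    1e3,
                )
                opt = opt_base if nm in base_names else opt_var
                setattr(lat, nm, opt.step((id(lat), nm), getattr(lat, nm), tot))
            lat._refresh_kernel()

        for j, lat in enumerate(state.theta_latents):
            _update(lat, -g_theta[j] / n, eps_th[j])
        for k, lat in enumerate(state.stick_latents):
            _update(lat, -g_stick[..., k] / n, eps_st[k])

        if not np.isfinite(loss):
            raise FloatingPointError("loss diverged during copula-GP fit")

        if step % 50 == 0 and step >= 100:
            dloss = float(np.mean(losses[-100:-50]) - np.mean(losses[-50:]))
            if dloss < config.loss_tol:
                break
            if dloss < config.check_waic and step >= next_check:
                w = waic_of_state(state, x, u1, u2, S=config.waic_samples, rng=rng)
                if w.waic > -config.waic_tol:
                    if checked_waic:
                        state.aborted = True
                        break
                    checked_waic = True
                    next_check = step + 200
                else:
                    next_check = config.max_steps + 1

    state.loss_trace = np.asarray(losses)
    state.steps = len(losses)
    return state


def drawn_state(state: MixtureGPState, rng) -> MixtureGPState:
    """Clone a state with variational means replaced by one whitened draw.

    The clone's variational covariance is collapsed, so it represents a
    single functional posterior draw usable at arbitrary x.
    """
    import copy

    new = copy.deepcopy(state)
    for lat in new.latents:
        eps = np.random.default_rng(rng).standard_normal(lat.G) if not isinstance(rng, np.random.Generator) else rng.standard_normal(lat.G)
        lat.m = lat.m + lat.L @ eps
        lat.L_off = np.zeros_like(lat.L_off)
        lat.L_log_diag = np.full(lat.G, -20.0)  # degenerate at the draw
    return new


@dataclass
class WaicResult:
    waic: float
    lppd: float
    p_waic: float
    S: int


def waic_of_state(state: MixtureGPState, x, u1, u2, S: int = 100, rng=None) -> WaicResult:
    """Watanabe-Akaike criterion from S functional posterior draws.

    ``waic = -(lppd - p_waic)/n``; zero for the Independence model, negative
    when the fitted dependence predicts better than independence.
    """
    if S < 2:
        raise ValueError("S >= 2 draws are required to estimate p_waic")
    u1 = clamp_unit(np.asarray(u1, dtype=float))
    u2 = clamp_unit(np.asarray(u2, dtype=float))
    n = np.asarray(u1).shape[0]
    if not state.latents:  # Independence: log density identically zero
        return WaicResult(0.0, 0.0, 0.0, S)
    rng = np.random.default_rng(rng)
    x01 = state.standardize(np.asarray(x, dtype=float))
    G = state.latents[0].G
    idx, frac = _interp_weights(x01, G)
    thetas_f = [
        lat.draw_f(idx, frac, rng.standard_normal((S, lat.G)))[0]
        for lat in state.theta_latents
    ]
    sticks_f = None
    if state.M > 1:
        sticks_f = np.stack(
            [
                lat.draw_f(idx, frac, rng.standard_normal((S, lat.G)))[0]
                for lat in state.stick_latents
            ],
            axis=-1,
        )
    evals = [c.fit_evaluator(u1, u2) for c in state.components]
    logp, _, _ = _mixture_loglik_and_grads(
        state, thetas_f, sticks_f, evals, need_grads=False
    )  # (S, n)
    lppd = float(np.sum(np.log(np.maximum(np.mean(np.exp(logp), axis=0), _MIN_PDF))))
    p_waic = float(np.sum(np.var(logp, axis=0, ddof=1)))
    return WaicResult(-(lppd - p_waic) / n, lppd, p_waic, S)
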