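"""Synthetic data generators and ground-truth oracles.

Two groups of generators:

* A two-neuron generalized linear model (GLM) with exponential nonlinearity
  and Poisson spiking, optionally coupled through spike-history filters,
  whose counts are convolved with an exponential calcium kernel -- a toy
  model of two-photon calcium recordings with a repeated-trial structure.
  The uncoupled variant is conditionally independent given the stimulus;
  the coupled variant develops negative, asymmetrically tailed noise
  correlations after the stimulation window.

* Three copula benchmark distributions with known information content:
  an equicorrelated Gaussian with correlation rho(x) = -0.1 + 1.1 x, a
  Student-T with fixed rho = 0.7 and df(x) = exp(5 x) + 1 (all of the
  mutual information lives in the tails), and a "morphed" Gaussian pushed
  through y_i + (prod_j y_j)^(1/N) followed by an empirical PIT, which
  matches none of the parametric families.  Oracles give the conditional
  copula entropy in closed form (Gaussian, Student-T) and the mutual
  information I(x, y) by integration of the true conditional density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "GLMConfig",
    "simulate_glm",
    "glm_dataset",
    "BenchmarkConfig",
    "gen_benchmark",
    "gaussian_copula_entropy",
    "student_copula_entropy",
    "oracle_entropy_curve",
    "oracle_mi",
]

_LOG2 = np.log(2.0)
_RHO_CLIP = 1.0 - 1e-6


# ===========================================================================
# GLM + calcium toy
# ===========================================================================
@dataclass
class GLMConfig:
    """Configuration of the two-neuron GLM/calcium simulator."""

    T: int = 20  # filter length (steps)
    tau_trial: int = 100  # trial length (steps)
    n_trials: int = 100
    base_rate: float = 0.2
    coupled: bool = True
    ca_decay: float = 4.0  # calcium kernel time constant (steps)
    stim_fraction: float = 0.6  # stimulus occupies this leading trial fraction
    peak_rate_factor: float = 10.0  # peak stimulus-driven rate over baseline
    seed: int | None = None

    def coupling_tensor(self) -> np.ndarray:
        """Spike-history filters h[i, j, k] for lags k = -T..-1.

        h11 = -0.1, h12 = 0.4 (t/T)^2, h21 = -0.1 (1 + t/T)^2, h22 = -0.1
        on t in [-T, 0]; the off-diagonal filters vanish when uncoupled.
        """
        t = np.arange(-self.T, 0, dtype=float)  # -T .. -1
        h = np.zeros((2, 2, self.T))
        h[0, 0] = -0.1
        h[1, 1] = -0.1
        if self.coupled:
            h[0, 1] = 0.4 * (t / self.T) ** 2
            h[1, 0] = -0.1 * (1.0 + t / self.T) ** 2
        return h

    def stimulus(self) -> np.ndarray:
        """Smooth unimodal pulse over the first ``stim_fraction`` of the trial.

        Amplitude is scaled so that the peak T-step running sum (the drive
        through the all-ones stimulus filter) raises the rate to
        ``peak_rate_factor`` times baseline.
        """
        t = np.arange(self.tau_trial, dtype=float)
        width = self.stim_fraction * self.tau_trial
        wave = np.where(t < width, np.sin(np.pi * t / width) ** 2, 0.0)
        run = np.convolve(wave, np.ones(self.T), mode="full")[: self.tau_trial]
        scale = np.log(self.peak_rate_factor) / max(run.max(), 1e-12)
        return wave * scale


def simulate_glm(config: GLMConfig | None = None, seed=None):
    """Simulate spike counts and calcium traces from the two-neuron GLM.

    Returns a dict with ``spikes`` and ``calcium`` of shape
    (n_trials, tau_trial, 2), the ``stimulus`` waveform and the within-trial
    ``time`` axis normalized to [0, 1].
    """
    config = config or GLMConfig()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    T, tau, R = config.T, config.tau_trial, config.n_trials
    h = config.coupling_tensor()
    stim = config.stimulus()
    stim_pad = np.concatenate([np.zeros(T), stim])
    spikes = np.zeros((R, tau, 2))
    lam = np.zeros((R, tau, 2))
    for r in range(R):
        y_hist = np.zeros((T, 2))  # rolling history, oldest first
        for t in range(tau):
            drive_stim = stim_pad[t : t + T].sum()  # all-ones stimulus filter
            drive = np.empty(2)
            for i in range(2):
                drive[i] = drive_stim + np.sum(h[i, 0] * y_hist[:, 0]) + np.sum(
                    h[i, 1] * y_hist[:, 1]
                )
            rate = config.base_rate * np.exp(drive)
            if np.any(rate > 1e6):
                raise FloatingPointError(
                    "GLM rate overflow; coupling filters are unstable"
                )
            y = rng.poisson(rate)
            lam[r, t] = rate
            spikes[r, t] = y
            y_hist = np.vstack([y_hist[1:], y[None, :]])
    # causal exponential calcium kernel, unit amplitude per spike
    klen = int(10 * config.ca_decay)
    kernel = np.exp(-np.arange(klen) / config.ca_decay)
    calcium = np.stack(
        [
            np.apply_along_axis(
                lambda s: np.convolve(s, kernel, mode="full")[:tau], 1, spikes[:, :, i]
            )
            for i in range(2)
        ],
        axis=-1,
    )
    return {
        "spikes": spikes,
        "calcium": calcium,
        "rates": lam,
        "stimulus": stim,
        "time": np.arange(tau) / tau,
    }


def glm_dataset(sim: dict, jitter: float = 0.01, seed=None):
    """Flatten a simulation into (x, Y): x = within-trial time, Y = calcium.

    ``jitter`` adds a small uniform measurement perturbation (in units of
    the per-spike fluorescence amplitude).  The noiseless traces are exactly
    discrete early in a trial (convolved Poisson counts), so tie-breaking
    noise is required for the probability integral transform to be uniform;
    it plays the role of the continuous measurement noise of real
    recordings.
    """
    rng = np.random.default_rng(seed)
    calcium = sim["calcium"]
    R, tau, _ = calcium.shape
    x = np.tile(sim["time"], R)
    Y = calcium.reshape(R * tau, 2)
    if jitter > 0:
        Y = Y + jitter * rng.uniform(-0.5, 0.5, Y.shape)
    return x, Y


# ===========================================================================
# benchmark distributions
# ===========================================================================
@dataclass
class BenchmarkConfig:
    kind: str = "gaussian"  # gaussian | student | morphed
    N: int = 2
    n: int = 5000
    seed: int | None = None
    student_rho: float = 0.7

    def __post_init__(self):
        if self.kind not in ("gaussian", "student", "morphed"):
            raise ValueError("kind must be gaussian, student or morphed")
        if self.N < 1:
            raise ValueError("dimension must be >= 1")


def _rho_of_x(x):
    return np.clip(-0.1 + 1.1 * np.asarray(x, dtype=float), None, _RHO_CLIP)


def _df_of_x(x):
    return np.exp(5.0 * np.asarray(x, dtype=float)) + 1.0


def _check_rho(rho, N):
    lo = -1.0 / (N - 1) if N > 1 else -1.0
    if np.any(rho <= lo):
        raise ValueError(f"equicorrelation rho <= {lo} is not positive definite at N={N}")


def _equicorr_normal(rho, N, rng):
    """Samples z ~ N(0, R(rho)) with per-row rho, via the spectral square root."""
    rho = np.atleast_1d(rho)
    _check_rho(rho, N)
    e = rng.standard_normal((len(rho), N))
    if N == 1:
        return e
    ebar = e.mean(axis=1, keepdims=True)
    a = np.sqrt(np.clip(1.0 - rho, 0.0, None))[:, None]
    b = np.sqrt(np.clip(1.0 + (N - 1) * rho, 0.0, None))[:, None]
    return a * (e - ebar) + b * ebar


def gen_benchmark(config: BenchmarkConfig, seed=None):
    """Generate (x, U): x ~ U[0,1] and copula samples with uniform marginals."""
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n, N = config.n, config.N
    x = rng.uniform(0.0, 1.0, n)
    if config.kind == "gaussian":
        z = _equicorr_normal(_rho_of_x(x), N, rng)
        return x, special.ndtr(z)
    if config.kind == "student":
        rho = np.full(n, config.student_rho)
        z = _equicorr_normal(rho, N, rng)
        df = _df_of_x(x)
        w = rng.chisquare(df) / df
        tvals = z / np.sqrt(w)[:, None]
        return x, special.stdtr(df[:, None], tvals)
    # morphed: push Gaussian copula samples through the product transform
    z = _equicorr_normal(_rho_of_x(x), N, rng)
    y = special.ndtr(z)
    ytil = y + np.prod(y, axis=1, keepdims=True) ** (1.0 / N)
    ranks = np.argsort(np.argsort(ytil, axis=0), axis=0) + 1.0
    return x, ranks / (n + 1.0)


# ===========================================================================
# oracles
# ===========================================================================
def gaussian_copula_entropy(rho, N: int) -> np.ndarray:
    """Copula entropy (bits) of the equicorrelated Gaussian: 0.5 log2 det R."""
    rho = np.asarray(rho, dtype=float)
    det = (1.0 - rho) ** (N - 1) * (1.0 + (N - 1) * rho)
    return 0.5 * np.log2(np.maximum(det, 1e-300))


def _mvt_entropy_nats(df, R_logdet: float, d: int):
    """Differential entropy of the d-variate Student-T (nats)."""
    df = np.asarray(df, dtype=float)
    half = (df + d) / 2.0
    return (
        -special.gammaln(half)
        + special.gammaln(df / 2.0)
        + 0.5 * d * np.log(df * np.pi)
        + 0.5 * R_logdet
        + half * (special.digamma(half) - special.digamma(df / 2.0))
    )


def student_copula_entropy(df, rho: float, N: int) -> np.ndarray:
    """Copula entropy (bits) of the equicorrelated Student-T copula.

    Joint multivariate-t entropy minus the N univariate t marginal
    entropies (the closed multivariate-t entropy form).
    """
    det = (1.0 - rho) ** (N - 1) * (1.0 + (N - 1) * rho)
    h_joint = _mvt_entropy_nats(df, np.log(det), N)
    h_marg = _mvt_entropy_nats(df, 0.0, 1)
    return (h_joint - N * h_marg) / _LOG2


def oracle_entropy_curve(config: BenchmarkConfig, x_grid) -> np.ndarray:
    """True conditional copula entropy H_c(u^x | x = t) on a grid (bits)."""
    x_grid = np.asarray(x_grid, dtype=float)
    if config.kind == "gaussian":
        return gaussian_copula_entropy(_rho_of_x(x_grid), config.N)
    if config.kind == "student":
        return student_copula_entropy(_df_of_x(x_grid), config.student_rho, config.N)
    raise ValueError("no conditional-entropy ground truth for the morphed dataset")


# -- true conditional copula log-densities ----------------------------------
def _gauss_cond_logpdf(x, U, N):
    rho = _rho_of_x(x)
    z = special.ndtri(np.clip(U, 1e-12, 1 - 1e-12))
    det = (1.0 - rho) ** (N - 1) * (1.0 + (N - 1) * rho)
    s2 = np.sum(z * z, axis=1)
    s1 = np.sum(z, axis=1)
    quad = (s2 - rho / (1.0 + (N - 1) * rho) * s1 * s1) / (1.0 - rho)
    return -0.5 * np.log(np.maximum(det, 1e-300)) - 0.5 * (quad - s2)


def _student_cond_logpdf(x, U, N, rho):
    df = _df_of_x(x)
    t = special.stdtrit(df[:, None], np.clip(U, 1e-12, 1 - 1e-12))
    det = (1.0 - rho) ** (N - 1) * (1.0 + (N - 1) * rho)
    s2 = np.sum(t * t, axis=1)
    s1 = np.sum(t, axis=1)
    quad = (s2 - rho / (1.0 + (N - 1) * rho) * s1 * s1) / (1.0 - rho)
    half = (df + N) / 2.0
    log_joint = (
        special.gammaln(half)
        - special.gammaln(df / 2.0)
        - 0.5 * N * np.log(df * np.pi)
        - 0.5 * np.log(det)
        - half * np.log1p(quad / df)
    )
    halfm = (df[:, None] + 1.0) / 2.0
    log_marg = (
        special.gammaln(halfm)
        - special.gammaln(df[:, None] / 2.0)
        - 0.5 * np.log(df[:, None] * np.pi)
        - halfm * np.log1p(t * t / df[:, None])
    )
    return log_joint - np.sum(log_marg, axis=1)


def _sample_true(kind, x, N, rho_student, rng):
    if kind == "gaussian":
        z = _equicorr_normal(_rho_of_x(x), N, rng)
        return special.ndtr(z)
    df = _df_of_x(x)
    z = _equicorr_normal(np.full(len(x), rho_student), N, rng)
    w = rng.chisquare(df) / df
    return special.stdtr(df[:, None], z / np.sqrt(w)[:, None])


def oracle_mi(
    config: BenchmarkConfig,
    n_outer: int = 100_000,
    n_x_nodes: int = 128,
    seed: int = 0,
) -> float:
    """True mutual information I(x, y) in bits by integrating the exact
    conditional copula density: outer MC over (x, u) pairs from the true
    model, inner Gauss-Legendre quadrature over x ~ U[0, 1].

    The morphed benchmark shares the Gaussian value (the transform is a
    homeomorphism independent of x).
    """
    kind = "gaussian" if config.kind == "morphed" else config.kind
    N = config.N
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n_outer)
    U = _sample_true(kind, x, N, config.student_rho, rng)
    if kind == "gaussian":
        logc = lambda xv, Uv: _gauss_cond_logpdf(xv, Uv, N)
    else:
        logc = lambda xv, Uv: _student_cond_logpdf(xv, Uv, N, config.student_rho)
    term1 = np.mean(logc(x, U)) / _LOG2
    nodes, weights = np.polynomial.legendre.leggauss(n_x_nodes)
    nodes = 0.5 * (nodes + 1.0)
    weights = 0.5 * weights
    acc = np.zeros(n_outer)
    for xs, w in zip(nodes, weights):
        acc += w * np.exp(logc(np.full(n_outer, xs), U))
    term2 = np.mean(np.log(np.maximum(acc, 1e-300))) / _LOG2
    return float(term1 - term2)
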