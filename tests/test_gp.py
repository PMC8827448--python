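"""Tests of the variational GP copula fitter."""

import numpy as np
import pytest

from gpcopula.families import Gaussian, Independence
from gpcopula.gp import (
    FitConfig,
    GPLatent,
    fit_mixture_gp,
    waic_of_state,
)
from gpcopula.model import CopulaGPModel


def test_config_defaults_match_published_table():
    cfg = FitConfig()
    assert cfg.base_lr == 0.05
    assert cfg.var_lr == 0.02
    assert cfg.grid_size == 60
    assert cfg.waic_tol == 0.005
    assert cfg.loss_tol == 1e-4
    assert cfg.check_waic == 0.005


def test_config_rejects_unknown_keys():
    with pytest.raises(KeyError, match="unknown"):
        FitConfig.from_dict({"base_lr": 0.1, "bogus": 1})


def test_kl_is_zero_when_variational_equals_prior(rng):
    lat = GPLatent(30, rng)
    lat.m = np.zeros(30)
    lat.L_log_diag = np.zeros(30)  # q(u) = N(0, I) = prior
    assert lat.kl() == pytest.approx(0.0, abs=1e-12)
    # the default (tighter) initialization has a small positive KL
    lat2 = GPLatent(30, rng)
    assert lat2.kl() > 0.0


def test_prior_model_predicts_link_of_zero(rng):
    # an unfitted (zero-latent) model: theta = gplink(0), phi = 1/M
    from gpcopula.families import Clayton, Gumbel
    from gpcopula.gp import MixtureGPState

    comps = [Gaussian(), Clayton(), Gumbel()]
    state = MixtureGPState(
        comps,
        [GPLatent(20, rng) for _ in comps],
        [GPLatent(20, rng) for _ in range(2)],
        0.0,
        1.0,
    )
    thetas, phis = state.params_at(np.array([0.2, 0.8]))
    assert np.allclose(phis, 1 / 3)
    assert np.allclose(thetas[0], 0.0)  # Erf(0)
    assert np.allclose(thetas[1], 1.0)  # exp(0)
    assert np.allclose(thetas[2], 2.0)  # 1 + exp(0)


def test_independence_component_has_no_latents():
    x = np.linspace(0, 1, 100)
    state = fit_mixture_gp([Independence()], x, x * 0 + 0.5, x * 0 + 0.5)
    assert state.latents == []
    w = waic_of_state(state, x, np.full(100, 0.3), np.full(100, 0.7))
    assert w.waic == 0.0 and w.lppd == 0.0 and w.p_waic == 0.0


def test_recovers_sinusoidal_gaussian_parameter(rng):
    n = 5000
    x = rng.uniform(0, 1, n)
    fam = Gaussian()
    th_true = fam.gplink(1.5 * np.sin(2 * np.pi * x))
    z1 = rng.standard_normal(n)
    z2 = th_true * z1 + np.sqrt(1 - th_true**2) * rng.standard_normal(n)
    from scipy.special import ndtr

    state = fit_mixture_gp(
        [fam], x, ndtr(z1), ndtr(z2), FitConfig(max_steps=1000, grid_size=48), rng=1
    )
    thetas, _ = state.params_at(x)
    tau_err = (2 / np.pi) * (np.arcsin(thetas[0]) - np.arcsin(th_true))
    assert np.sqrt(np.mean(tau_err**2)) <= 0.1
    assert not state.aborted


def test_independent_data_scores_no_better_than_independence(rng):
    # the fit either aborts via the WAIC check or converges quickly to a
    # model that WAIC cannot distinguish from Independence
    n = 3000
    x = rng.uniform(0, 1, n)
    u1, u2 = rng.uniform(size=n), rng.uniform(size=n)
    state = fit_mixture_gp([Gaussian()], x, u1, u2, FitConfig(max_steps=600), rng=2)
    w = waic_of_state(state, x, u1, u2, rng=3)
    assert state.aborted or w.waic > -0.005
    assert state.steps < 600  # and it stops early either way


def test_waic_requires_at_least_two_draws(gaussian_benchmark_fit):
    x, U, res = gaussian_benchmark_fit
    with pytest.raises(ValueError, match="draws"):
        waic_of_state(res.state, x, U[:, 0], U[:, 1], S=1)


def test_waic_of_well_fit_model_is_negative(gaussian_benchmark_fit):
    x, U, res = gaussian_benchmark_fit
    assert res.waic < -0.005


def test_ci_halfwidth_is_two_posterior_sd(gaussian_benchmark_fit):
    x, U, res = gaussian_benchmark_fit
    xs = np.array([0.5])
    lo, hi = res.conf_int(xs, z=2.0)
    lat = res.state.theta_latents[0]
    from gpcopula.gp import _interp_weights

    idx, frac = _interp_weights(res.state.standardize(xs), lat.G)
    mean, sd = lat.f_moments(idx, frac)
    fam = res.components[0]
    assert lo[0][0] == pytest.approx(fam.gplink(mean - 2 * sd)[0])
    assert hi[0][0] == pytest.approx(fam.gplink(mean + 2 * sd)[0])
    assert lo[0][0] < hi[0][0]


def test_posterior_uncertainty_grows_where_data_are_sparse(rng):
    # x dense on [0, 0.6], sparse on (0.6, 1]
    n_dense, n_sparse = 2800, 100
    x = np.concatenate(
        [rng.uniform(0, 0.6, n_dense), rng.uniform(0.6, 1.0, n_sparse)]
    )
    th = Gaussian().gplink(np.full(x.shape, 0.8))
    z1 = rng.standard_normal(len(x))
    z2 = th * z1 + np.sqrt(1 - th**2) * rng.standard_normal(len(x))
    from scipy.special import ndtr

    state = fit_mixture_gp(
        [Gaussian()], x, ndtr(z1), ndtr(z2), FitConfig(max_steps=500), rng=4
    )
    lo, hi = state.ci_at(np.array([0.3, 0.95]))
    width_dense = hi[0][0] - lo[0][0]
    width_sparse = hi[0][1] - lo[0][1]
    assert width_sparse > width_dense


def test_model_results_roundtrip_summary(gaussian_benchmark_fit):
    x, U, res = gaussian_benchmark_fit
    text = res.summary()
    assert "Gaussian" in text
    assert "WAIC" in text
    tau = res.kendall_tau(np.array([0.9]))
    assert 0.3 < tau[0] < 1.0


def test_sample_mode_draws_differ_and_stay_in_domain(gaussian_benchmark_fit):
    x, U, res = gaussian_benchmark_fit
    th, ph = res.predict_params(np.linspace(0, 1, 11), mode="sample", S=3, seed=0)
    assert th.shape == (1, 3, 11)
    assert np.all(th >= -1) and np.all(th <= 1)
    assert not np.allclose(th[0, 0], th[0, 1])
    assert np.allclose(ph, 1.0)
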