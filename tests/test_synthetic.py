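"""Tests of the synthetic generators and their ground-truth oracles."""

import numpy as np
import pytest
from scipy.stats import kstest

from gpcopula.synthetic import (
    BenchmarkConfig,
    GLMConfig,
    gaussian_copula_entropy,
    gen_benchmark,
    glm_dataset,
    oracle_entropy_curve,
    oracle_mi,
    simulate_glm,
    student_copula_entropy,
)


class TestGLM:
    def test_baseline_rate_without_stimulus_or_history(self):
        sim = simulate_glm(GLMConfig(n_trials=5, coupled=True), seed=0)
        # the first step of every trial has empty history and zero stimulus
        assert np.allclose(sim["rates"][:, 0, :], 0.2)

    def test_coupling_tensor_matches_filter_definitions(self):
        cfg = GLMConfig(coupled=True)
        h = cfg.coupling_tensor()
        t = np.arange(-cfg.T, 0) / cfg.T
        assert np.allclose(h[0, 0], -0.1)
        assert np.allclose(h[1, 1], -0.1)
        assert np.allclose(h[0, 1], 0.4 * t**2)
        assert np.allclose(h[1, 0], -0.1 * (1 + t) ** 2)
        h0 = GLMConfig(coupled=False).coupling_tensor()
        assert np.all(h0[0, 1] == 0) and np.all(h0[1, 0] == 0)

    def test_stimulus_peak_drive_matches_rate_factor(self):
        cfg = GLMConfig()
        stim = cfg.stimulus()
        run = np.convolve(stim, np.ones(cfg.T), mode="full")[: cfg.tau_trial]
        assert run.max() == pytest.approx(np.log(cfg.peak_rate_factor), rel=1e-6)

    def test_seed_determinism(self):
        a = simulate_glm(GLMConfig(n_trials=3), seed=7)
        b = simulate_glm(GLMConfig(n_trials=3), seed=7)
        assert np.array_equal(a["spikes"], b["spikes"])
        assert np.array_equal(a["calcium"], b["calcium"])

    def test_calcium_is_causal_exponential_convolution(self):
        cfg = GLMConfig(n_trials=1, coupled=False)
        sim = simulate_glm(cfg, seed=1)
        spikes = sim["spikes"][0, :, 0]
        kernel = np.exp(-np.arange(int(10 * cfg.ca_decay)) / cfg.ca_decay)
        manual = np.convolve(spikes, kernel, mode="full")[: cfg.tau_trial]
        assert np.allclose(sim["calcium"][0, :, 0], manual)

    def test_rate_overflow_raises(self):
        # a positive self-excitation filter is explosively unstable
        class _Unstable(GLMConfig):
            def coupling_tensor(self):
                return np.full((2, 2, self.T), 0.5)

        with pytest.raises(FloatingPointError, match="unstable|overflow"):
            simulate_glm(_Unstable(n_trials=1), seed=0)

    def test_dataset_shape_and_jitter(self):
        sim = simulate_glm(GLMConfig(n_trials=4), seed=2)
        x, Y = glm_dataset(sim, jitter=0.01, seed=3)
        assert x.shape == (400,) and Y.shape == (400, 2)
        x2, Y2 = glm_dataset(sim, jitter=0.0)
        assert np.allclose(Y2, sim["calcium"].reshape(400, 2))


class TestBenchmarks:
    def test_gaussian_rho_is_clipped_at_comonotone_limit(self, rng):
        x, U = gen_benchmark(BenchmarkConfig("gaussian", 2, 2000), seed=4)
        # x near 1 implies rho near 1: u1 ~ u2 there
        sel = x > 0.98
        assert np.corrcoef(U[sel, 0], U[sel, 1])[0, 1] > 0.95

    def test_student_df_at_domain_ends(self):
        # df = exp(5x) + 1: 2 at x=0, ~149.4 at x=1
        from gpcopula.synthetic import _df_of_x

        assert _df_of_x(0.0) == pytest.approx(2.0)
        assert _df_of_x(1.0) == pytest.approx(np.exp(5) + 1)

    def test_marginals_are_uniform(self):
        for kind in ("gaussian", "student", "morphed"):
            x, U = gen_benchmark(BenchmarkConfig(kind, 3, 4000), seed=5)
            for i in range(3):
                assert kstest(U[:, i], "uniform").pvalue > 0.01, kind

    def test_morphed_single_dimension_is_exactly_uniform(self):
        x, U = gen_benchmark(BenchmarkConfig("morphed", 1, 1000), seed=6)
        # monotone transform + empirical PIT restores exact ranks
        assert np.allclose(np.sort(U[:, 0]), np.arange(1, 1001) / 1001)

    def test_invalid_equicorrelation_raises(self):
        with pytest.raises(ValueError, match="positive definite"):
            gen_benchmark(BenchmarkConfig("gaussian", 12, 100), seed=7)

    def test_generator_determinism(self):
        a = gen_benchmark(BenchmarkConfig("student", 2, 500), seed=8)
        b = gen_benchmark(BenchmarkConfig("student", 2, 500), seed=8)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestOracles:
    def test_gaussian_equicorrelation_determinant_identity(self):
        # N=3, rho=0.5: H = 0.5 log2((1-rho)^2 (1+2 rho)) = -0.5 bits
        assert gaussian_copula_entropy(0.5, 3) == pytest.approx(-0.5)
        assert gaussian_copula_entropy(0.0, 5) == pytest.approx(0.0)

    def test_student_large_df_limit_is_gaussian(self):
        g = gaussian_copula_entropy(0.7, 2)
        s = student_copula_entropy(1e8, 0.7, 2)
        assert s == pytest.approx(g, abs=1e-3)

    def test_entropy_curve_mc_self_consistency(self):
        # MC entropy of many true samples matches the closed form
        from gpcopula.synthetic import _student_cond_logpdf

        x9, U9 = gen_benchmark(BenchmarkConfig("student", 2, 1_000_000), seed=9)
        H_mc = -np.mean(_student_cond_logpdf(x9, U9, 2, 0.7)) / np.log(2)
        H_true = float(np.mean(student_copula_entropy(np.exp(5 * x9) + 1, 0.7, 2)))
        assert H_mc == pytest.approx(H_true, abs=0.01)

    def test_morphed_entropy_oracle_is_unsupported(self):
        with pytest.raises(ValueError, match="morphed"):
            oracle_entropy_curve(BenchmarkConfig("morphed", 2, 100), [0.5])

    def test_morphed_mi_equals_gaussian_mi(self):
        a = oracle_mi(BenchmarkConfig("gaussian", 2, 100), n_outer=20000, seed=3)
        b = oracle_mi(BenchmarkConfig("morphed", 2, 100), n_outer=20000, seed=3)
        assert a == b

    def test_gaussian_mi_oracle_against_ksg(self):
        from gpcopula.info import ksg_mi

        cfg = BenchmarkConfig("gaussian", 2, 8000)
        x, U = gen_benchmark(cfg, seed=10)
        truth = oracle_mi(cfg, n_outer=50000, seed=0)
        assert ksg_mi(x, U, k=4) == pytest.approx(truth, abs=0.05)
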