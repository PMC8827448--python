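"""Tests of the conditional C-vine."""

import numpy as np
import pytest
from scipy.special import ndtr
from scipy.stats import kendalltau, kstest

from gpcopula.families import Gaussian
from gpcopula.gp import FitConfig
from gpcopula.vine import CVine, n_pair_copulas, order_variables

SMALL = FitConfig(max_steps=250, grid_size=30, waic_samples=50)


def _equicorr_samples(rng, n, m, rho):
    R = rho * np.ones((m, m)) + (1 - rho) * np.eye(m)
    Z = rng.standard_normal((n, m)) @ np.linalg.cholesky(R).T
    return ndtr(Z)


class TestOrdering:
    def test_pair_copula_count(self):
        assert n_pair_copulas(109) == 5886
        assert n_pair_copulas(2) == 1
        assert n_pair_copulas(5) == 10

    def test_noisy_copy_pair_leads_and_independent_trails(self, rng):
        n = 1500
        a = rng.uniform(size=n)
        b = ndtr(0.95 * ndtr(a * 0 + rng.standard_normal(n)))  # placeholder
        # var0 ~ noisy copy of var1; var2 independent
        z = rng.standard_normal(n)
        v1 = ndtr(z)
        v0 = ndtr(z + 0.4 * rng.standard_normal(n))
        v2 = rng.uniform(size=n)
        order = order_variables(np.column_stack([v0, v1, v2]))
        assert set(order[:2]) == {0, 1}
        assert order[-1] == 2

    def test_independent_columns_keep_identity_order(self, rng):
        U = rng.uniform(size=(800, 4))
        order = order_variables(U)
        # tau sums are all tiny; the stable tie-break preserves indices
        assert np.all(np.sort(order) == np.arange(4))

    def test_hub_variable_ranked_first(self, rng):
        n = 1500
        hub = rng.standard_normal(n)
        cols = [ndtr(hub)]
        for _ in range(3):
            cols.append(ndtr(0.8 * hub + 0.6 * rng.standard_normal(n)))
        order = order_variables(np.column_stack(cols))
        assert order[0] == 0


class TestFit:
    def test_bivariate_vine_equals_its_single_edge(self, rng):
        n = 2500
        x = rng.uniform(size=n)
        U = _equicorr_samples(rng, n, 2, 0.6)
        res = CVine(U, x).fit(config=SMALL, seed=1, select=None, components=[Gaussian()])
        edge = res.edges[(0, 1)]
        assert edge is not None
        lp_vine = res.logpdf(x, U)
        mix = edge.mixture_at(x)
        o = res.order
        lp_edge = mix.logpdf(U[:, o[0]], U[:, o[1]])
        assert np.max(np.abs(lp_vine - lp_edge)) < 1e-9

    def test_fully_independent_data_gives_all_independence_edges(self, rng):
        n = 1500
        x = rng.uniform(size=n)
        U = rng.uniform(size=(n, 4))
        res = CVine(U, x).fit(config=SMALL, seed=2, select="heuristic")
        assert res.n_independence == res.n_edges
        assert np.allclose(res.logpdf(x, U), 0.0)
        assert res.effective_dim(x, seed=3) == 0

    def test_equicorrelated_fit_recovers_dependence(self, rng):
        n = 3000
        x = rng.uniform(size=n)
        U = _equicorr_samples(rng, n, 4, 0.5)
        res = CVine(U, x).fit(config=SMALL, seed=3, select=None, components=[Gaussian()])
        # all tree-1 edges carry dependence
        m = res.dim
        for j in range(1, m):
            assert res.edges[(0, j)] is not None
        # sampling/evaluation duality: uniform margins, matching pairwise tau
        Us = res.sample(rng.uniform(size=4000), seed=4)
        for i in range(m):
            assert kstest(Us[:, i], "uniform").pvalue > 0.01
        t_data = kendalltau(U[:, 0], U[:, 1]).statistic
        t_samp = kendalltau(Us[:, 0], Us[:, 1]).statistic
        assert t_samp == pytest.approx(t_data, abs=0.05)

    def test_truncation_marks_deep_trees_independent(self, rng):
        n = 1500
        x = rng.uniform(size=n)
        U = _equicorr_samples(rng, n, 4, 0.5)
        res = CVine(U, x).fit(
            config=SMALL, seed=5, select=None, components=[Gaussian()], truncate=1
        )
        assert all(res.edges[(t, j)] is None for t in (1, 2) for j in range(t + 1, 4))
        assert all(res.edges[(0, j)] is not None for j in range(1, 4))

    def test_logpdf_entropy_matches_gaussian_oracle(self, rng):
        # MC mean of -log2 density over own samples ~ copula entropy
        n = 3000
        x = rng.uniform(size=n)
        rho = 0.6
        U = _equicorr_samples(rng, n, 3, rho)
        res = CVine(U, x).fit(config=FitConfig(max_steps=500, grid_size=30, waic_samples=50), seed=6, select=None, components=[Gaussian()])
        xs = rng.uniform(size=8000)
        Us = res.sample(xs, seed=7)
        H = -np.mean(res.logpdf(xs, Us)) / np.log(2)
        det = (1 - rho) ** 2 * (1 + 2 * rho)
        H_true = 0.5 * np.log2(det)
        assert H == pytest.approx(H_true, abs=0.05)

    def test_effective_dim_of_single_tree_dependence(self, rng):
        n = 2000
        x = rng.uniform(size=n)
        # star structure: all dependence through variable 0
        z = rng.standard_normal(n)
        cols = [ndtr(z)]
        for _ in range(3):
            cols.append(ndtr(0.75 * z + np.sqrt(1 - 0.75**2) * rng.standard_normal(n)))
        U = np.column_stack(cols)
        res = CVine(U, x).fit(config=SMALL, seed=8, select="heuristic")
        assert res.effective_dim(x, coverage=0.9, seed=9) <= 2

    def test_posterior_draw_changes_parameters(self, rng):
        n = 1500
        x = rng.uniform(size=n)
        U = _equicorr_samples(rng, n, 2, 0.6)
        res = CVine(U, x).fit(config=SMALL, seed=10, select=None, components=[Gaussian()])
        d1 = res.draw(seed=1)
        d2 = res.draw(seed=2)
        lp1 = d1.logpdf(x[:50], U[:50])
        lp2 = d2.logpdf(x[:50], U[:50])
        assert not np.allclose(lp1, lp2)
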