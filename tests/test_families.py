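"""Unit tests for the bivariate copula families."""

import numpy as np
import pytest
from scipy.stats import kendalltau

from gpcopula.families import (
    Clayton,
    Frank,
    Gaussian,
    Gumbel,
    Independence,
    make_family,
    standard_candidates,
)


def test_standard_candidate_set_has_ten_elements():
    cands = standard_candidates()
    assert len(cands) == 10
    keys = {c.key for c in cands}
    assert "Gaussian" in keys and "Frank" in keys
    assert sum(k.startswith("Clayton") for k in keys) == 4
    assert sum(k.startswith("Gumbel") for k in keys) == 4


def test_independence_density_is_one_everywhere(unit_grid):
    U1, U2 = unit_grid
    ind = Independence()
    assert np.all(ind.pdf(0.0, U1, U2) == 1.0)
    assert ind.cdf(0.0, 0.3, 0.7) == pytest.approx(0.21)
    assert ind.hfun(0.0, 0.3, 0.6) == pytest.approx(0.6)
    assert ind.ppcf(0.0, 0.3, 0.6) == pytest.approx(0.6)


def test_gaussian_zero_parameter_reduces_to_independence(unit_grid):
    U1, U2 = unit_grid
    assert np.allclose(Gaussian().pdf(0.0, U1, U2), 1.0, atol=1e-12)
    assert Gaussian().cdf(0.0, 0.3, 0.7) == pytest.approx(0.21, abs=1e-6)


def test_density_integrates_to_one(family_grid, unit_grid):
    U1, U2 = unit_grid
    for fam, th in family_grid:
        integral = fam.pdf(th, U1, U2).mean()
        assert integral == pytest.approx(1.0, abs=0.01), fam.key


def test_cdf_boundary_conditions(family_grid):
    for fam, th in family_grid:
        assert fam.cdf(th, 1.0, 1.0) == pytest.approx(1.0, abs=1e-6)
        assert fam.cdf(th, 0.0, 0.5) == pytest.approx(0.0, abs=1e-6)
        assert fam.cdf(th, 1.0, 0.4) == pytest.approx(0.4, abs=1e-3)
        assert fam.cdf(th, 0.4, 1.0) == pytest.approx(0.4, abs=1e-3)


def test_hfun_matches_cdf_partial_derivative(family_grid):
    d = 1e-5
    pts = [(0.3, 0.6), (0.7, 0.2), (0.5, 0.5), (0.15, 0.85)]
    for fam, th in family_grid:
        for u1, u2 in pts:
            fd = (fam.cdf(th, u1 + d, u2) - fam.cdf(th, u1 - d, u2)) / (2 * d)
            assert fam.hfun(th, u1, u2) == pytest.approx(fd, abs=1e-4), fam.key


def test_ppcf_inverts_hfun_on_grid(family_grid):
    g = np.linspace(0.05, 0.95, 20)
    U1, U2 = np.meshgrid(g, g)
    for fam, th in family_grid:
        q = fam.hfun(th, U1, U2)
        back = fam.ppcf(th, U1, np.clip(q, 1e-9, 1 - 1e-9))
        assert np.max(np.abs(back - U2)) < 1e-6, fam.key


def test_sampling_reproduces_kendall_tau(family_grid, rng):
    n = 10000
    for fam, th in family_grid:
        u1, u2 = fam.sample(th, n, rng)
        emp = kendalltau(u1, u2).statistic
        assert emp == pytest.approx(fam.kendall_tau(th), abs=3 / np.sqrt(n) * 1.8), fam.key


def test_rotation_density_identities(unit_grid):
    U1, U2 = unit_grid
    for base in (Clayton, Gumbel):
        p0 = base(0).pdf(2.0, U1, U2)
        assert np.allclose(base(180).pdf(2.0, 1 - U1, 1 - U2), p0)
        assert np.allclose(base(90).pdf(2.0, 1 - U1, U2), p0)
        assert np.allclose(base(270).pdf(2.0, U1, 1 - U2), p0)


def test_rotated_clayton_moves_tail_and_flips_tau(rng):
    u1, u2 = Clayton(90).sample(2.0, 20000, rng)
    emp = kendalltau(u1, u2).statistic
    assert emp == pytest.approx(-0.5, abs=0.03)  # tau = -theta/(theta+2)
    # the 0-degree lower tail lands in the lower-right corner; the
    # opposite corner keeps only the ordinary negative-diagonal mass
    corner = np.mean((u1 > 0.9) & (u2 < 0.1))
    opposite = np.mean((u1 < 0.1) & (u2 > 0.9))
    assert corner > 2 * opposite


def test_gplink_table_anchors():
    assert Gaussian().gplink(0.0) == pytest.approx(0.0)  # Erf(0)
    assert Clayton().gplink(0.0) == pytest.approx(1.0)  # exp(0)
    assert Gumbel().gplink(0.0) == pytest.approx(2.0)  # 1 + exp(0)
    assert Frank().gplink(0.0) == pytest.approx(0.0)
    # monotone and inside the domain
    f = np.linspace(-8, 8, 101)
    for fam in (Gaussian(), Frank(), Clayton(), Gumbel()):
        th = fam.gplink(f)
        assert np.all(np.diff(th) >= 0)
        lo, hi = fam.theta_domain
        assert np.all(th >= lo) and np.all(th <= hi)


def test_gplink_derivative_matches_finite_difference():
    f = np.linspace(-4, 4, 41)
    d = 1e-6
    for fam in (Gaussian(), Frank(), Clayton(), Gumbel()):
        fd = (fam.gplink(f + d) - fam.gplink(f - d)) / (2 * d)
        assert np.allclose(fam.gplink_deriv(f), fd, atol=1e-4), fam.name


def test_kendall_tau_closed_forms(rng):
    assert Gaussian().kendall_tau(1.0) == pytest.approx(1.0)
    assert Gumbel().kendall_tau(1.0) == pytest.approx(0.0)  # tau = 1 - 1/theta
    assert Clayton().kendall_tau(2.0) == pytest.approx(0.5)
    # Frank Debye formula vs sampling
    u1, u2 = Frank().sample(5.0, 100_000, rng)
    assert kendalltau(u1, u2).statistic == pytest.approx(
        Frank().kendall_tau(5.0), abs=0.01
    )


def test_theta_outside_domain_raises():
    with pytest.raises(ValueError):
        Gaussian().pdf(1.5, 0.5, 0.5)
    with pytest.raises(ValueError):
        Clayton().pdf(-1.0, 0.5, 0.5)
    with pytest.raises(ValueError):
        Gumbel().pdf(0.5, 0.5, 0.5)


def test_rotation_only_for_asymmetric_families():
    with pytest.raises(ValueError):
        Gaussian(90)
    with pytest.raises(ValueError):
        Frank(180)
    assert make_family("Clayton90").rotation == 90
    assert make_family("Gumbel", 270).key == "Gumbel270"


def test_frank_small_theta_series_is_continuous():
    u = (0.3, 0.8)
    below = Frank().pdf(9e-5, *u)
    above = Frank().pdf(1.1e-4, *u)
    assert below == pytest.approx(above, abs=1e-4)
    assert Frank().pdf(0.0, *u) == pytest.approx(1.0, abs=1e-6)
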