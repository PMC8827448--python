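import numpy as np
import pytest

from gpcopula.families import Clayton, Frank, Gaussian, Gumbel
from gpcopula.gp import FitConfig


@pytest.fixture()
def rng(request):
    """A per-test deterministic generator (independent of execution order)."""
    import zlib

    return np.random.default_rng(zlib.crc32(request.node.nodeid.encode()))


@pytest.fixture(scope="session")
def unit_grid():
    """Midpoint grid on (0,1)^2 for quadrature checks."""
    g = (np.arange(200) + 0.5) / 200
    return np.meshgrid(g, g)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-budget optimization settings for unit tests."""
    return FitConfig(max_steps=300, grid_size=30, waic_samples=50)


@pytest.fixture(scope="session")
def family_grid():
    """(family, theta) pairs covering every family and rotation class."""
    return [
        (Gaussian(), 0.7),
        (Gaussian(), -0.5),
        (Frank(), 5.0),
        (Frank(), -8.0),
        (Clayton(), 2.0),
        (Clayton(90), 2.0),
        (Clayton(180), 4.0),
        (Clayton(270), 1.0),
        (Gumbel(), 2.0),
        (Gumbel(90), 3.0),
        (Gumbel(180), 1.5),
        (Gumbel(270), 2.5),
    ]


@pytest.fixture(scope="session")
def gaussian_benchmark_fit():
    """A fitted single-Gaussian conditional copula on the rho(x) benchmark.

    Shared by information and goodness-of-fit tests to amortize the fit.
    """
    from gpcopula.model import CopulaGPModel
    from gpcopula.synthetic import BenchmarkConfig, gen_benchmark

    x, U = gen_benchmark(BenchmarkConfig("gaussian", 2, 4000), seed=5)
    res = CopulaGPModel(U[:, 0], U[:, 1], x, components=[Gaussian()]).fit(
        config=FitConfig(max_steps=600, grid_size=40), seed=3
    )
    return x, U, res
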