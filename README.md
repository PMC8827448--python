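# gpcopula

Conditional parametric copula mixtures with Gaussian-process parameters,
canonical vines, and Monte-Carlo information estimators — a statistical
toolkit for modelling how the *dependence* between continuous recordings
(neuronal calcium traces, behavioral variables, ...) changes along a
continuous covariate such as time in a trial or position in an
environment.

## The problem

Simultaneously recorded neuronal and behavioral variables have wildly
different marginal statistics, and their *joint* trial-to-trial
variability ("noise correlations") is itself tuned to the stimulus or
task phase.  Copulas separate the two concerns: by Sklar's theorem,

    p(y | x) = c(F_1(y_1|x), ..., F_N(y_N|x) | x) · ∏_i p_i(y_i | x),

the conditional copula density c(·|x) carries exactly the
stimulus-dependent dependence structure, while the conditional marginals
F_i(·|x) absorb single-variable statistics.  `gpcopula` models c(·|x) as
a linear mixture of parametric bivariate families (Gaussian, Frank, and
rotated Clayton/Gumbel for tail dependence),

    c(u | x) = Σ_j φ_j(x) · c_j(u; θ_j(x)),

where every copula parameter θ_j(x) and mixing weight φ_j(x) is a fixed
monotone link of a latent Gaussian process of x.  Mixtures are scored and
assembled by WAIC model selection, composed into conditional C-vines for
N > 2, and used to estimate conditional entropy and mutual information
I(x, y) in bits, with uncertainty propagated from the GP posterior.

## Worked example

Fit a conditional copula to a benchmark dataset whose dependence
strengthens with x (an equicorrelated Gaussian with ρ(x) = −0.1 + 1.1x),
then estimate the mutual information between x and the pair:

```python
import numpy as np
from gpcopula import CopulaGPModel, FitConfig
from gpcopula.synthetic import BenchmarkConfig, gen_benchmark, oracle_mi
from gpcopula import info

x, U = gen_benchmark(BenchmarkConfig("gaussian", N=2, n=5000), seed=11)
model = CopulaGPModel(U[:, 0], U[:, 1], x)
res = model.fit(config=FitConfig(max_steps=2500, grid_size=48), seed=1)
print(res.summary())

est = info.mi_integrated(res, x, n_mc_outer=8000, n_mc_inner=400, S=8, seed=2)
truth = oracle_mi(BenchmarkConfig("gaussian", 2, 5000), n_outer=150_000, seed=0)
print(f"I(x,y) = {est.value:.3f} bits  (truth {truth:.3f})")
```

which prints

```
Conditional copula mixture (GP-parameterized)
======================================================
n obs                       5000
components                  Gaussian
WAIC                        -0.27835
lppd                        1400.33
p_waic                      8.57
SVI steps                   400
aborted (independence)      False
------------------------------------------------------
posterior-mean parameters on an x grid:
  x        0.00019     0.25      0.5     0.75        1
  th[Gaussian  ]   -0.110    0.221    0.476    0.717    0.977
  phi[Gaussian ]    1.000    1.000    1.000    1.000    1.000
I(x,y) = 0.188 bits  (truth 0.206)
```

The fitted ρ(x) tracks the generating line −0.1 + 1.1x, and the nested
Monte-Carlo ("integrated") mutual-information estimate sits slightly
below the exact value — the characteristic small underestimate of the
variational fit near the comonotone edge (see `docs/methods.md`).

For higher dimensions, `CVine(U, x).fit(select="heuristic")` builds a
canonical vine whose every edge is WAIC-selected (independent pairs cost
nothing), and `gpcopula.info` provides conditional entropy, the
integrated and two-model MI estimators, and a KSG baseline.  A thin CLI
(`gpcopula simulate|select|vine|mi|gof`) wraps the same pipeline for
shell use.

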