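# Methods

`gpcopula` models how the dependence structure of multivariate continuous
recordings — typically neuronal calcium traces together with behavioral
variables — changes along a continuous covariate x (time in a trial,
position in an environment, velocity, ...).  This note documents the model,
the inference scheme, the estimators, and the numerical and design choices
a user should know about.

## Model

By Sklar's theorem the conditional joint density factorizes into
conditional marginals and a conditional copula,

    p(y | x) = c(F_1(y_1|x), ..., F_N(y_N|x) | x) * prod_i p_i(y_i | x),

so the copula c(·|x) carries exactly the covariate-dependent dependence
("noise correlations" when x indexes the stimulus) while the marginals
carry single-variable statistics ("stimulus correlations").

**Marginals.**  Unconditional marginals are empirical CDFs with the
rank/(n+1) convention, which keeps pseudo-observations strictly inside
(0,1).  Conditional marginals F(y|x) are Gaussian-kernel-weighted
conditional ECDFs on a grid of x-nodes (bandwidth 1.6·sd(x)·n^(−1/5) by
default — a widened Silverman factor, since CDF estimation tolerates more
smoothing than density estimation — overridable), linearly interpolated in
both x and y.  The operative contract is per-x-stratum uniformity of the
transformed data, which holds when the marginal varies smoothly relative
to the bandwidth; for repeated-trial designs with sharp within-trial
transients (e.g. the GLM calcium toy, which has ~100 samples at each of
100 distinct time points) a narrower explicit bandwidth (~2 time steps) is
the appropriate setting and is what the packaged analyses use.  With fewer
than 200 samples the conditional estimator falls back to the unconditional
ECDF with a warning.  All pseudo-observations are clamped to
[1e−6, 1−1e−6] before copula evaluation; conditional quantiles passed to
inverse h-functions are clamped only at 1e−12, since they are not data.

**Bivariate copula mixtures.**  The building blocks are the Gaussian,
Frank, Clayton and Gumbel single-parameter families, with 90/180/270°
rotations of Clayton and Gumbel (ten elements total).  Rotation
convention: 90° evaluates the base density at (1−u1, u2) — the Clayton
lower tail moves to the lower-right corner and Kendall's τ flips sign;
270° reflects u2 (tail upper-left); 180° reflects both (tail opposite
corner, τ unchanged).  A dependence structure is a linear mixture
c(u|x) = Σ_j φ_j(x) c_j(u; θ_j(x)) with at most M = 5 components and no
duplicate (family, rotation) pairs.

**Latent Gaussian processes.**  Each θ_j(x) is a fixed monotone link
("GPLink") of an unconstrained latent GP:
Erf(f/1.4) for the Gaussian parameter, 0.1f + sign(f)(0.1f)² for Frank,
exp(0.2f) for Clayton, 1 + exp(0.1f) for Gumbel.  The M−1 free mixture
weights come from M−1 further latent GPs through a stick-breaking map
(0-based components j = 0..M−1)

    t_j = Φ(f̃_j + Φ⁻¹((M−j−1)/(M−j))),  t_{M−1} = 0,
    φ_j = (1 − t_j) Π_{m<j} t_m,

whose zero point gives equal weights 1/M, so the standard-normal prior on
the latents is a uniform prior over components.  A mixture therefore has
2M−1 independent latent GPs, each with an RBF kernel (constant mean μ,
lengthscale λ, output scale σ).

## Inference

Inference is stochastic variational with a whitened inducing-value
parameterization: inducing values live on a regular grid of `grid_size`
points spanning the (internally unit-standardized) x domain, latent values
at data locations are linear interpolations of grid values, and the
variational distribution is a full-covariance Gaussian N(m, LLᵀ) over
whitened values with prior N(0, I).  The ELBO

    L = Σ_i E_q [ log c(u_i | f(x_i)) ] − KL[q ‖ N(0, I)]

(per-sample normalized) is maximized by Adam with the standard two rates —
base_lr = 0.05 for (μ, log λ, log σ) and var_lr = 0.02 for (m, L) — and
the published stopping schedule: the loss is averaged over 50-step
windows; when the windowed change drops below check_waic = 0.005 the WAIC
is evaluated and the fit aborts if the model is no better than
Independence (WAIC > −waic_tol = 0.005); otherwise it continues until the
change is below loss_tol = 1e−4 or max_steps.  A N(0.5, 1.0) prior on the
lengthscale (on the unit x scale) penalizes the short-lengthscale
overfitting minimum.  All gradients are analytic — including the Cholesky
forward derivative for kernel hyperparameters and the stick-breaking
Jacobian — with d log c/dθ in closed form for the Gaussian and Clayton
families and by a guarded central difference for Frank and Gumbel.

Two implementation details matter for accuracy and are our own choices:

* **Single-component models use Gauss–Hermite quadrature** (20 sites) for
  the latent expectation, giving fully deterministic gradients; mixtures
  use Monte-Carlo with 10 functional draws per step (the latent space is
  up to 9-dimensional, where quadrature is impractical).
* **The variational covariance is initialized at e⁻¹·I** (slightly
  tighter than the prior) and the independence abort requires two
  consecutive positive WAIC checks 200 steps apart.  With a prior-width
  initialization, a WAIC evaluated mid-training is dominated by the
  not-yet-contracted posterior (large p_waic) and weakly dependent pairs
  are falsely discarded; the tight start plus the confirmation check
  removes those false aborts while leaving truly independent pairs cheap
  to discard.

Even at the ELBO optimum the posterior-mean parameter is shrunk where the
likelihood is extremely informative and the true parameter sits near the
domain edge (e.g. ρ → 1): on the Gaussian benchmark this produces a small
systematic underestimate of mutual information (~0.02 bit at N = 2), which
is the variational-inference bias the estimators inherit.

## Model selection

Model fit is scored by the Watanabe–Akaike information criterion from
S = 100 functional posterior draws:

    lppd  = Σ_i log( (1/S) Σ_s p(u_i | θ^s) )
    p_waic = Σ_i Var_s log p(u_i | θ^s)
    WAIC  = −(lppd − p_waic)/n ,

so WAIC = 0 is exactly the Independence model (density 1) and lower is
better.  *Greedy* selection fits every candidate element singly, keeps the
best, and repeatedly adds the element with the largest WAIC decrease until
the decrease is below waic_tol or M = 5; it returns Independence when no
model beats −waic_tol.  *Heuristic* selection first screens with a
step-capped Gaussian fit backed by cheap independence diagnostics (corner
masses of the four 0.1×0.1 corner squares against the 0.01·n independence
expectation, and a Kendall-τ test — a single Gaussian is blind to balanced
mixtures of opposite-sign components, the diagnostics are not), then runs
the same forward selection over a short-list ordered by those tail
diagnostics (each corner contributes its matching Clayton and Gumbel
rotation; Gaussian/Frank lead).  Components whose weight never exceeds
1e−4 are pruned with one refit.

## C-vines

High dimensions use a canonical vine: variables are ordered by descending
Σ|τ̂| with all others (stable tie-break by column index), each tree has
one pivot node, and pseudo-observations for tree t+1 are h-function
transforms from tree t.  Pair copulas are conditional on x throughout but
independent of their u-conditioners (the usual simplifying assumption).
Edges selected as Independence store no GP state, add zero log-density and
are skipped in sampling (ppcf not called), so cost scales with the number
of non-independent edges.  Optional truncation treats all trees above
`truncate` as Independence.  An effective dimension is the smallest number
of leading trees whose cumulative (MC-estimated) entropy reaches a
coverage fraction (default 0.9) of the total.

## Information estimates

All entropies and mutual informations are in bits.  The conditional
copula entropy at x = t is H_c(t) = −E log₂ c(u|t) by Monte-Carlo over the
model's own samples.  Mutual information between x and the response block:

* *integrated*: I = E_{p(u,x)} log₂ p(u|x) − E_{p(u)} log₂ E_{p(x)} p(u|x),
  with the outer expectation over model samples at empirical x draws and
  the nested inner expectation over x; valid when marginals are
  x-independent.  Under model mismatch this estimator systematically
  underestimates (it never overestimated on any synthetic benchmark).
* *estimated*: I = Σ_i I(x, y_i) + H_c(u) − ∫ H_c(u^x|x=t) p(t) dt, using
  a second, unconditional copula model for p(u); cheaper, no marginal
  assumption, error of either sign.  The marginal terms use a 32-bin
  quantile histogram estimator and are zero for copula benchmarks.

p(x) is always the empirical distribution of the observed x.  Reported
uncertainty is value ± 2·sqrt(SE² + MCtol²), where SE is the spread over
S = 20 GP-posterior functional draws (evaluated at a quarter of the MC
budget) and MCtol the Monte-Carlo standard error of the point estimate.
Defaults: 10,000 outer samples, 1,000 inner x draws.  A plain KSG
k-nearest-neighbour estimator (k = 4, Chebyshev metric) ships as the
non-parametric baseline.

## Goodness of fit

R̄² compares the empirical conditional CDF of u2 given 20 equal-width u1
bins against the model h-function at the bin's mean u1 and the interval's
x center of mass, on the grid u2 = 0, 0.05, ..., 1, using the conventional
variance-explained form 1 − Σ(ecdf−ccdf)²/Σ(ecdf−0.5)², averaged over
bins.  A literal variant that sums squared pointwise ratios is available
behind `literal=True`; it is unbounded below wherever the ecdf crosses 1/2
and is not the default.

## Synthetic data

**GLM calcium toy.**  Two neurons with exponential-nonlinearity Poisson
GLMs: λ_i = 0.2·exp(1ᵀx^{−T:0} + Σ_j h_ij·y_j^{−T:0}), filter length
T = 20 steps, trials of τ = 100 steps, 100 trials.  Coupled variant uses
h11 = h22 = −0.1, h12(t) = 0.4(t/T)² (slow excitation), h21(t) =
−0.1(1+t/T)² (fast inhibition) on t ∈ [−T, 0]; the uncoupled variant zeroes
the off-diagonals.  Counts are convolved with a causal exponential kernel
(4-step decay, unit amplitude) to mimic calcium fluorescence.  The
stimulus waveform is a sin² pulse over the first 60% of the trial scaled
so the peak drive raises the rate 10× over baseline — chosen (the rate
factor especially) so that the coupled variant's conditional dependence is
strong enough to measure (|τ̂| ≈ 0.15), negative, peaks after the stimulus
peak, and shows the asymmetric "active inhibitory + silent excitatory"
upper-left tail; at ~5× the interaction is too weak for the history
filters to transfer trial-to-trial fluctuations.  `glm_dataset` adds a 1%
uniform tie-breaking jitter: the noiseless traces are exactly discrete
early in a trial (convolved counts), which makes a PIT non-uniform; the
jitter plays the role of continuous measurement noise.  These toys emulate
dynamic noise correlations with known mechanism, not realistic calcium
noise, neuropil contamination, or slow drift — passing them shows the
pipeline separates stimulus from noise correlations in clean conditions,
not that it handles real imaging artifacts.

**Benchmarks.**  Three copula datasets with x ~ U[0,1] and uniform
marginals: equicorrelated Gaussian with ρ(x) = −0.1 + 1.1x (clipped at
1−1e−6); Student-T with fixed ρ = 0.7 and df(x) = exp(5x) + 1 (all mutual
information lives in the changing tails); and a "morphed" Gaussian pushed
through ỹ_i = y_i + (Π_j y_j)^{1/N} and an empirical PIT, which matches no
packaged family.  Truth oracles: Gaussian copula entropy ½log₂ det R(x)
with the equicorrelation determinant (1−ρ)^{N−1}(1+(N−1)ρ); Student-T
copula entropy from the closed multivariate-t entropy minus N univariate-t
entropies; I(x,y) by integrating the exact conditional copula density
(outer Monte-Carlo over true (x,u) pairs, inner Gauss–Legendre quadrature
over x).  The morphed dataset shares the Gaussian I(x,y) (the transform is
an x-independent homeomorphism) and has no conditional-entropy truth.

## Problem sizes used in the packaged checks

The test suite and the acceptance script run the study conditions at
sizes chosen for a single CPU: benchmark fits use n = 5000 with a
48-point inducing grid and step budgets of 600–2500; identifiability runs
use n = 2500 with 300-step budgets and the heuristic strategy (the greedy
strategy is spot-checked for agreement); Monte-Carlo integration uses
8000 outer × 400 inner samples with 8 posterior draws.  These budgets
recover single-family parameters to τ-RMSE ≲ 0.02 and leave the
variational shrinkage described above as the dominant error term.

## Known limitations

* Only the C-vine structure is supported; no structure search.
* Discrete or heavily tied variables require tie-breaking noise before
  the PIT (the package does not model discrete margins).
* The integrated MI estimator assumes x-independent marginals; use the
  estimated variant (with its model-mismatch risk) otherwise.
* WAIC comparisons at tolerance 0.005 are themselves Monte-Carlo noisy at
  S = 100 draws; near-ties between similarly shaped families (e.g. Frank
  vs Gaussian) are resolved arbitrarily within tolerance.
* The conditioning covariate is scalar; multi-dimensional conditioning is
  out of scope.
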