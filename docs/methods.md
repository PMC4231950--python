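# Methods

## Model

Counts `x_1, …, x_n`, one per fixed-width genomic bin, are treated as
independent draws from a Poisson mixture: `X | Λ ~ Poisson(Λ)`, `Λ ~ f(λ)`.
The Poisson kernel is kept because repeated sequencing of one library is
Poisson at a site; all genome-wide heterogeneity (mappability, copy number,
library-preparation artifacts) is pushed into the mixing distribution `f`.
The package fits four parametric choices of `f` and the nonparametric MLE.

Independence across bins is an approximation — neighbouring bins share
fragments and local biases — and the model ignores genomic covariates
entirely; it describes the marginal count distribution, not its spatial
arrangement.

## Parametric fits

**Poisson.** `μ̂ = x̄` exactly.

**Negative binomial.** Parametrized by mean μ and dispersion r with variance
μ + μ²/r, i.e. mixing distribution gamma(shape=r, rate=r/μ). The score in μ
vanishes at the sample mean for every r, so μ is set to `x̄` and only the
profiled dispersion is optimized numerically (bounded scalar minimization of
the negative profile log-likelihood over log r, r ∈ [1e−6, 1e6]). For
underdispersed data the dispersion MLE diverges; the fit is returned with
r = 1e6 and the flag `dispersion_capped` rather than failing, since such
data are effectively Poisson.

**Log-normal Poisson.** `log Λ ~ N(μ, σ²)`. Each pmf term is an integral
with no closed form; it is evaluated by mode-centred Gauss–Hermite
quadrature: substituting `λ = exp(μ + σz)` makes the log-integrand strictly
concave in z, its mode is found by damped Newton iteration, and a 60-node
Gauss–Hermite rule is applied after recentring and rescaling at the Laplace
mode. The public `lnp_loglik` re-evaluates at order 100 and raises if the
two disagree beyond 1e−8 relative per term (in practice they agree to
~1e−12). Because the MLE is also intractable, fitting is Bayesian:
a Gaussian random walk Metropolis–Hastings sampler on (μ, log σ⁻²) under
weak priors μ ~ N(0, 10) (variance 10) and σ⁻² ~ Gamma(shape=1, rate=0.1),
with the proposal scale adapted during burn-in toward ≈0.3 acceptance.
Defaults: 20,000 iterations, 5,000 burn-in. The point estimate is the
post-burn-in posterior mean of each sampled parameter (μ and the precision);
with n in the tens of thousands the priors are negligible and this
approximates the MAP/MLE. An acceptance rate outside [0.05, 0.95] is
flagged, not fatal.

**NB-NB mixture.** `Z ~ Bernoulli(τ)`; `X ~ NB(μ₁, r₁)` if Z=0, else
`NB(μ₂, r₂)` — equivalently a two-gamma mixing distribution. Fit by EM:
E-step responsibilities `P(Z=1 | x)`, M-step τ = mean responsibility and a
weighted NB MLE per component (weighted mean for μ, profiled dispersion as
above). Acceleration uses SQUAREM in the squared first-order form of
Varadhan & Roland on the unconstrained parametrization
(logit τ, log μ₁, log r₁, log μ₂, log r₂), with the step length safeguarded
at α ≤ −1 and one stabilizing EM step after each extrapolation; any
extrapolated point that fails to increase the log-likelihood falls back to
the plain double EM step, so the recorded trace is non-decreasing in both
modes. Convergence: relative log-likelihood change < tol (default 1e−8) or
max parameter change < 1e−6; component collapse (τ within tol of 0 or 1) is
flagged `degenerate_to_single_NB`. Components are reordered so μ₁ ≤ μ₂
before return. The default initialization splits the data at the 0.90
empirical quantile and method-of-moments-fits each part (bulk + tail), which
reflects the intended use: a large low-count population plus a small
high-count one. Both EM variants are deterministic; `seed` is accepted for
interface uniformity only.

## NPMLE via the Constrained Newton Method

The NPMLE of `f` is discrete with at most as many support points as distinct
observed values. Each CNM iteration:

1. evaluates the gradient function
   `d(θ*; G) = Σⱼ [Poisson(xⱼ; θ*) / f_G(xⱼ) − 1]` — the directional
   derivative of the log-likelihood toward a point mass at θ* — over a
   candidate grid (observed distinct counts ∪ a geometric grid of
   `grid_size` points spanning [max(1e−3, min positive count)/2,
   2·max+1] ∪ current-support midpoints), polishes every grid local maximum
   by bounded scalar maximization, and adds all polished maximizers with
   d > 0;
2. recomputes the weight MLE for the enlarged fixed support: the weight
   problem is concave, and is solved by multiplicative (EM) preconditioning
   followed by iterated constrained least squares
   `min ‖Sπ − 2·1‖²` on the simplex (S the per-observation likelihood
   gradient matrix, equality handled by a penalty row, non-negativity by
   NNLS, each step safeguarded by a backtracking line search). The EM
   preconditioning matters: the least-squares linearization is untrustworthy
   when the current mixture leaves near-zero mass at an observed count;
3. prunes support points whose weight falls below 1e−10 (exact zero is
   unattainable in floating point) and **consolidates** adjacent support
   points: the likelihood is almost flat in splitting one atom across two
   nearby points, so the closest adjacent pair is merged (weight-averaged
   location, weights re-optimized) whenever the log-likelihood does not
   decrease. Without consolidation the fit carries split atoms that ruin
   the CDF-bounds diagnostic; the convergence scan of the next iteration
   re-certifies optimality of the consolidated support.

Convergence is declared when sup d ≤ `grad_tol`, default `1e−6·n` since the
gradient scales with sample size. Initialization is a single point at the
sample mean. Non-convergence at `max_iter` returns a usable result flagged
`converged=False` — the recovered distribution is often still adequate for
diagnostics. Likelihoods are computed over unique count values with
multiplicities (counts are small integers with heavy ties), which is
mathematically identical to the per-bin sum and much faster.

## Diagnostics

**TV distance** is computed on 0..x_max (x_max = the larger observed
maximum), the shorter pmf zero-extended, with each model's residual tail
mass beyond x_max compared as one extra cell. Comparisons default to the
empirical pmf; the CNM-recovered pmf can be used as the reference instead
(both are plain `Pmf` objects).

**CDF bounds.** If the NPMLE's atoms are viewed as the collapsed mass of a
continuous `f` over an (unknown) partition of [0, ∞), then
`F(θᵢ) ∈ [Σ_{j<i} πⱼ, Σ_{j≤i} πⱼ)` for every i. The check is strict
half-open — equality at the upper edge counts as a violation, so the
discrete NPMLE's own right-continuous CDF fails its own bounds by
construction. The lower bound 0 at the first support point assumes Λ is not
zero-inflated. The check is evaluated only at the NPMLE support points, and
`log(1 − F)` values are returned for survival-scale plotting.

**Zero-inflation scan.** For each ρ in a grid, `round(ρ·n_zeros)` zeros are
removed (ρ > 0) or `round(|ρ|·n_zeros)` appended (ρ < 0) — deterministic,
since zeros are exchangeable — each model is refit and its d_TV against the
adjusted empirical pmf recorded. ρ is dimensionless (a signed fraction of
the existing zero count), symmetric about 0, with ρ = 1 meaning all zeros
removed. NB-NB refits along the scan are warm-started from the unadjusted
fit: a continuation strategy, without which the EM can land in different
local maxima at neighbouring ρ and the curve becomes erratic. Under genuine
zero-inflation ν, a model that fits the non-inflated part well attains its
d_TV minimum near ρ* = ν / (ν + (1 − ν)·p₀), the inflated share of all
zeros. Near ρ = 0 the NB-NB curve can be quite flat, so the argmin should be
read with one-grid-step resolution.

**Blacklist construction.** Posterior membership of the high-count NB
component, `P(Z=1 | x) = τf₂(x) / (τf₂(x) + (1−τ)f₁(x))`, thresholded at
0.5 by default; flagged bins with coordinates are emitted as BED3 with
adjacent bins merged.

## Binning

Coordinates are 0-based half-open (BED) throughout. Reads are points (start
positions); a chromosome of length G is tiled with `G // w` bins of width w
(default 100 bp; trailing partial bin dropped), and any bin overlapping an
excluded region by ≥1 bp is dropped entirely — not truncated — so all
retained bins are directly comparable. Duplicates are retained. Fragment
extension, duplicate removal and mappability correction are out of scope.

## Synthetic data

`simulate_counts` draws from the hierarchical model exactly: an optional
Bernoulli(ν) zero mask first (rates are not drawn for masked bins), then
Λ from the chosen mixing family, then Poisson counts. Defaults used
throughout the tests mirror the regimes of interest: a bulk-plus-tail
gamma-gamma mixture with τ = 0.05, bulk NB(μ=2, r=10) and tail
NB(μ=30, r=0.8) for heavy-tailed background; a single gamma(2, 0.5)
(NB(μ=4, r=2)) for well-behaved overdispersed background; ν = 0.3 for
zero-inflated scenarios. What the generator does *not* emulate: spatial
autocorrelation between bins, mappability structure, GC bias, or enriched
(peak-bearing) signal — so passing tests demonstrate correctness of the
estimators under the assumed marginal model, not robustness to the spatial
structure of real libraries.

## Numerical choices and problem sizes

- NB dispersion bounded in [1e−6, 1e6] everywhere; profile optimizations use
  bounded Brent with xatol 1e−10 on the log scale.
- CNM: support points merged when within 1e−4·(1+θ); weights below 1e−10
  treated as zero; candidate geometric grid of 100 points by default.
- Tests and the acceptance script use n = 5,000 for NPMLE studies,
  n = 50,000–100,000 for NB-NB recovery and scans, and n = 20,000 for the
  MH recovery study — sizes at which the sampling error of every reported
  quantity is small compared to its test tolerance, as established by a
  20-replicate simulation study for the NB-NB parameters.
- All stochastic entry points take an explicit seed; there is no global
  random state.

## Known limitations

- The NPMLE support count L can exceed the handful of atoms a human would
  draw, on heavy-tailed data: far-tail observations each earn a small atom.
  This is the MLE behaving as designed, but L should not be over-interpreted.
- The zero-inflation scan refits the NB-NB by local EM; despite
  warm-starting, alternative local maxima remain possible at extreme ρ.
- The MH sampler adapts only during burn-in and uses a fixed-shape Gaussian
  proposal; heavily multimodal posteriors (not observed for this model) would
  need a better sampler.
- `check_mixing_fit` inherits the no-zero-inflation assumption of the
  bounds; applying it to zero-inflated data biases the first interval.
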