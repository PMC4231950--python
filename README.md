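# binmix

Poisson-mixture modelling of binned sequencing counts — parametric fits,
the nonparametric MLE of the mixing distribution, and model-fit diagnostics
for ChIP-seq background noise.

## The problem

Read counts `x_i` over fixed-width genomic bins of a ChIP-seq input
(untreated control) library are overdispersed: the variance far exceeds the
mean, so a plain Poisson noise model underestimates the null variability and
inflates false-positive peak calls. A flexible way to capture genome-wide
heterogeneity is a Poisson mixture,

```
X_i | Λ_i ~ Poisson(Λ_i),     Λ_i ~ f(λ),
```

where the mixing distribution `f(λ)` describes how the latent per-bin rate
varies across the genome. Different choices of `f` give the familiar count
models:

| count distribution     | parameters     | mixing distribution      |
|------------------------|----------------|--------------------------|
| Poisson                | μ              | point mass at μ          |
| negative binomial (NB) | μ, r           | gamma(shape=r, rate=r/μ) |
| log-normal Poisson     | μ, σ²          | log-normal(μ, σ²)        |
| NB-NB mixture          | τ, μ₁,r₁, μ₂,r₂ | two-gamma mixture        |

(NB is parametrized by mean μ and dispersion r, variance μ + μ²/r.)

`binmix` asks which `f` the data actually support. The maximum-likelihood
estimate of `f` over *all* distributions — the NPMLE — is a discrete
distribution with finitely many support points, computable with the
Constrained Newton Method (CNM). The package uses the NPMLE in three ways:

1. **Distribution recovery** — rebuild the count pmf
   `f̂(x) = Σᵢ πᵢ Poisson(x; θᵢ)` from the fitted support `(θ, π)` and
   compare it with the empirical pmf by Total Variation distance,
   `d_TV(f, g) = ½ Σₓ |f(x) − g(x)|`.
2. **CDF bounds** — any continuous mixing distribution consistent with the
   NPMLE must satisfy `Σ_{j<i} πⱼ ≤ F(θᵢ) < Σ_{j≤i} πⱼ` at every support
   point, a sharp, tuning-free test of a candidate `f`.
3. **Zero-inflation scan** — remove (or add) a fraction of the zero counts,
   refit, and track `d_TV`: a model that only fits well once most zeros are
   deleted is mistaking a heavy right tail for zero-inflation.

On data with a bulk of ordinary bins plus a small population of high-count
artifact bins, the two-component NB mixture (bulk + heavy tail) is typically
the only parametric model that stays inside the CDF bounds and needs no
zero-inflation. Its posterior component memberships also yield a *de novo*
blacklist of artifact-prone regions.

## Worked example

Simulate 50,000 bins of heavy-tailed background (95% bulk NB(μ=2, r=10),
5% artifact tail NB(μ=30, r=0.8)), then fit and diagnose:

```python
import binmix as bm

spec = bm.MixingSpec.gamma_gamma(0.05, shape1=10, rate1=5, shape2=0.8, rate2=0.8/30)
counts = bm.simulate_counts(spec, 50_000, seed=1)

nb = bm.fit_nb(counts)
nbnb = bm.fit_nbnb(counts, seed=1)
res = bm.cnm_fit(counts)

emp = bm.empirical_pmf(counts)
for name, fit in [("Poisson", bm.fit_poisson(counts)), ("NB", nb), ("NB-NB", nbnb)]:
    print(name, bm.tv_distance(bm.model_pmf(fit.params, emp.x_max), emp))

bounds = bm.cdf_bounds(res.mixture)
print(bm.check_mixing_fit(nb.params, bounds).n_violations)
print(bm.check_mixing_fit(nbnb.params, bounds).n_violations)
```

This prints (abridged):

```
NB fit:    mu=3.331 r=0.799  loglik=-116566.3
NB-NB fit: tau=0.0554 mu1=1.989 r1=10.53 mu2=26.20 r2=0.661  loglik=-100775.9
NPMLE: L=17 support points, loglik=-100769.3, converged=True
d_TV(Poisson vs empirical) = 0.3321
d_TV(NB      vs empirical) = 0.2884
d_TV(NB-NB   vs empirical) = 0.0062
CDF bounds, NB: 15 violations (first at support point 2)
CDF bounds, NB-NB: 1 violations (first at support point 13)
bins with P(artifact component) >= 0.5: 0.0358
```

Reading: the single NB is pulled apart by the artifact tail (its fitted
dispersion r=0.80 is far from the bulk's r=10, and d_TV ≈ 0.29), while the
NB-NB mixture recovers the generating parameters, sits within `d_TV ≈ 0.006`
of the data, and respects the NPMLE CDF bounds everywhere except one extreme
support point. About 3.6% of bins are confidently assigned to the artifact
component — the raw material for a blacklist.

A command-line interface mirrors the library
(`binmix simulate | fit | npmle | diagnose | zeroscan | blacklist | bin`);
run `binmix --help`.

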