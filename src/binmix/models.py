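"""Parametric count models for binned sequencing data.

Four models, all Poisson mixtures X | Lambda ~ Poisson(Lambda):

==================  ==========  =========================
count distribution  parameters  mixing distribution
==================  ==========  =========================
Poisson             mu          point mass at mu
Negative binomial   mu, r       gamma(shape=r, rate=r/mu)
Log-normal Poisson  mu, sigma2  log-normal(mu, sigma2)
NB-NB mixture       tau + 2x(mu, r)  gamma-gamma mixture
==================  ==========  =========================

The NB is parametrized by mean mu and dispersion r with variance
mu + mu^2/r, which makes the gamma mixing representation explicit.  The
Poisson and NB fits are exact/numerical MLEs; the log-normal Poisson is fit
by Metropolis-Hastings under weak conjugate-style priors (mu ~ N(0, 10),
precision ~ Gamma(shape=1, rate=0.1)) with the posterior mean as point
estimate; the NB-NB mixture is fit by EM, optionally accelerated with
SQUAREM extrapolation guarded to keep the log-likelihood monotone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Union

import numpy as np
from scipy import optimize, special, stats

from .counts_io import CountVector

logger = logging.getLogger("binmix")

__all__ = [
    "PoissonParams",
    "NBParams",
    "LNPParams",
    "NBNBParams",
    "FitResult",
    "MCMCTrace",
    "QuadratureError",
    "fit_poisson",
    "fit_nb",
    "lnp_loglik",
    "fit_lnp",
    "fit_nbnb",
    "pmf",
    "mixing_cdf",
]

# dispersion bounds for all numerical NB fits; r at _R_MAX is the documented
# "effectively Poisson" cap used for underdispersed data
_R_MIN = 1e-6
_R_MAX = 1e6


@dataclass(frozen=True)
class PoissonParams:
    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


@dataclass(frozen=True)
class NBParams:
    """Negative binomial with mean ``mu`` and dispersion ``r``.

    Variance is ``mu + mu**2 / r``; equivalently the mixing distribution of
    the latent Poisson rate is gamma(shape=r, rate=r/mu).
    """

    mu: float
    r: float

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.r <= 0:
            raise ValueError("mu and r must be > 0")


@dataclass(frozen=True)
class LNPParams:
    """Log-normal Poisson: log(Lambda) ~ N(mu, sigma2)."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


@dataclass(frozen=True)
class NBNBParams:
    """Two-component NB mixture: Z ~ Bernoulli(tau); X ~ NB(comp2) if Z=1.

    Canonical ordering: ``comp1.mu <= comp2.mu`` (component 2 is the
    high-count branch).
    """

    tau: float
    comp1: NBParams
    comp2: NBParams

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")

    def ordered(self) -> "NBNBParams":
        """Return an equivalent parametrization with comp1.mu <= comp2.mu."""
        if self.comp1.mu <= self.comp2.mu:
            return self
        return NBNBParams(tau=1.0 - self.tau, comp1=self.comp2, comp2=self.comp1)


ModelParams = Union[PoissonParams, NBParams, LNPParams, NBNBParams]


@dataclass
class FitResult:
    params: Any
    loglik: float
    converged: bool
    n_iter: int
    trace: np.ndarray | None = None
    flags: tuple[str, ...] = ()
    n_em_evals: int | None = None


@dataclass
class MCMCTrace:
    """Posterior draws of (mu, precision = 1/sigma2) from the LNP sampler."""

    mu: np.ndarray
    precision: np.ndarray
    burn_in: int
    seed: int
    acceptance_rate: float


class QuadratureError(RuntimeError):
    """Raised when the log-normal Poisson quadrature misses its accuracy target."""

    def __init__(self, achieved: float, target: float):
        self.achieved = achieved
        self.target = target
        super().__init__(
            f"quadrature achieved relative accuracy {achieved:.3e} (target {target:.3e})"
        )


def _unique_weighted(counts: CountVector) -> tuple[np.ndarray, np.ndarray]:
    """Distinct count values and their multiplicities (counts tie heavily)."""
    values, weights = np.unique(np.asarray(counts.counts, dtype=np.int64), return_counts=True)
    return values, weights.astype(float)


# ---------------------------------------------------------------------------
# Poisson


def fit_poisson(counts: CountVector) -> FitResult:
    """Poisson MLE: mu-hat is the sample mean, exactly."""
    x = counts.counts
    if x.size == 0:
        raise ValueError("cannot fit an empty count vector")
    mu = float(x.mean())
    values, weights = _unique_weighted(counts)
    ll = float(weights @ stats.poisson.logpmf(values, mu)) if mu > 0 else 0.0
    return FitResult(params=PoissonParams(mu=mu), loglik=ll, converged=True, n_iter=0)


# ---------------------------------------------------------------------------
# Negative binomial


def _nb_logpmf(x: np.ndarray, mu: float, r: float) -> np.ndarray:
    return stats.nbinom.logpmf(x, r, r / (r + mu))


def _weighted_nb_mle(
    values: np.ndarray, weights: np.ndarray
) -> tuple[NBParams, float, bool]:
    """Weighted NB MLE; returns (params, loglik, capped_flag).

    The score in mu vanishes at the weighted mean for every r, so mu is set
    there exactly and only the dispersion is profiled numerically.
    """
    wsum = weights.sum()
    mu = float(weights @ values / wsum)
    if mu <= 0:
        raise ValueError("NB fit requires a positive mean")
    var = float(weights @ (values - mu) ** 2 / wsum)

    def neg_profile(log_r: float) -> float:
        return -float(weights @ _nb_logpmf(values, mu, np.exp(log_r)))

    if var <= mu:
        r = _R_MAX
        capped = True
    else:
        res = optimize.minimize_scalar(
            neg_profile,
            bounds=(np.log(_R_MIN), np.log(_R_MAX)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        r = float(np.exp(res.x))
        capped = r >= _R_MAX * (1 - 1e-6)
    ll = float(weights @ _nb_logpmf(values, mu, r))
    return NBParams(mu=mu, r=r), ll, capped


def fit_nb(counts: CountVector) -> FitResult:
    """NB MLE by numerical optimization of the profiled dispersion.

    For underdispersed data (sample variance <= mean) the dispersion MLE
    diverges; the fit is returned with ``r`` capped at 1e6 and flagged
    ``"dispersion_capped"`` instead of failing.
    """
    if counts.counts.size == 0:
        raise ValueError("cannot fit an empty count vector")
    values, weights = _unique_weighted(counts)
    params, ll, capped = _weighted_nb_mle(values, weights)
    flags = ("dispersion_capped",) if capped else ()
    return FitResult(params=params, loglik=ll, converged=True, n_iter=1, flags=flags)


# ---------------------------------------------------------------------------
# Log-normal Poisson

_GH_ORDER = 60
_GH_ORDER_CHECK = 100
_LNP_ACCURACY_TARGET = 1e-8
_gh_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order not in _gh_cache:
        _gh_cache[order] = np.polynomial.hermite.hermgauss(order)
    return _gh_cache[order]


def _lnp_logpmf(x: np.ndarray, mu: float, sigma2: float, order: int = _GH_ORDER) -> np.ndarray:
    """log P(X = x) under the log-normal Poisson, by mode-centred Gauss-Hermite.

    With lambda = exp(mu + sigma z), z standard normal, each term is
    (2*pi)^{-1/2} * integral of exp(h(z)) dz / x! with
    h(z) = -z^2/2 + x*(mu + sigma*z) - exp(mu + sigma*z).
    h is strictly concave in z, so the integrand is recentred and rescaled at
    its Laplace mode before applying the Gauss-Hermite rule; this keeps the
    rule accurate for any x.
    """
    x = np.asarray(x, dtype=float)
    sigma = np.sqrt(sigma2)

    # Newton iterations for the mode of h (strictly concave; damped steps)
    z = (np.log(x + 0.5) - mu) / sigma
    z = np.clip(z, -40.0, 40.0)
    for _ in range(60):
        e = np.exp(np.clip(mu + sigma * z, -700, 700))
        grad = -z + sigma * x - sigma * e
        hess = -1.0 - sigma2 * e
        step = grad / hess
        step = np.clip(step, -5.0, 5.0)
        z = z - step
        if np.max(np.abs(step)) < 1e-13:
            break
    e = np.exp(mu + sigma * z)
    scale = 1.0 / np.sqrt(1.0 + sigma2 * e)  # Laplace std dev of h at the mode

    t, w = _gh_nodes(order)
    zz = z[:, None] + np.sqrt(2.0) * scale[:, None] * t[None, :]
    expo = np.clip(mu + sigma * zz, -700, 700)
    h = -0.5 * zz**2 + x[:, None] * (mu + sigma * zz) - np.exp(expo)
    h0 = -0.5 * z**2 + x * (mu + sigma * z) - e
    inner = np.einsum("j,ij->i", w, np.exp(h - h0[:, None] + t[None, :] ** 2))
    return (
        h0
        + np.log(np.sqrt(2.0) * scale * inner)
        - 0.5 * np.log(2.0 * np.pi)
        - special.gammaln(x + 1.0)
    )


def lnp_loglik(params: LNPParams, counts: CountVector, *, check: bool = True) -> float:
    """Log-likelihood of the log-normal Poisson model.

    Each term log integral of Poisson(x; lambda) * LogNormal(lambda; mu,
    sigma2) dlambda is evaluated by adaptive Gauss-Hermite quadrature.  When
    ``check`` is true the evaluation is repeated at a higher order and a
    :class:`QuadratureError` is raised if the two disagree beyond 1e-8
    relative per term.
    """
    values, weights = _unique_weighted(counts)
    if values.size == 0:
        return 0.0
    lp = _lnp_logpmf(values, params.mu, params.sigma2, order=_GH_ORDER)
    if check:
        lp_hi = _lnp_logpmf(values, params.mu, params.sigma2, order=_GH_ORDER_CHECK)
        achieved = float(np.max(np.abs(lp - lp_hi)))
        if achieved > _LNP_ACCURACY_TARGET:
            raise QuadratureError(achieved=achieved, target=_LNP_ACCURACY_TARGET)
        lp = lp_hi
    return float(weights @ lp)


def fit_lnp(
    counts: CountVector,
    n_iter: int = 20_000,
    burn_in: int = 5_000,
    *,
    seed: int,
) -> tuple[FitResult, MCMCTrace]:
    """Fit the log-normal Poisson by Metropolis-Hastings.

    Priors: mu ~ N(0, variance 10); precision sigma^-2 ~ Gamma(shape=1,
    rate=0.1).  A Gaussian random walk on (mu, log precision) is adapted
    during burn-in toward ~0.3 acceptance; the point estimate is the
    post-burn-in posterior mean of each sampled parameter (mu and the
    precision), an approximation to the MAP under these weak priors.  An
    empty count vector yields a prior-only chain.
    """
    if not n_iter > burn_in >= 0:
        raise ValueError("need n_iter > burn_in >= 0")
    values, weights = _unique_weighted(counts) if len(counts) else (np.empty(0), np.empty(0))

    def loglik(mu: float, sigma2: float) -> float:
        if values.size == 0:
            return 0.0
        return float(weights @ _lnp_logpmf(values, mu, sigma2))

    def logprior(mu: float, u: float) -> float:
        # u = log precision; Gamma(1, 0.1) density on precision + Jacobian
        return -mu * mu / 20.0 - 0.1 * np.exp(u) + u

    rng = np.random.default_rng(seed)
    mu = float(np.log(values.mean() + 1.0)) if values.size else 0.0
    u = 0.0
    lp = loglik(mu, np.exp(-u)) + logprior(mu, u)
    scale = np.array([0.3, 0.3])
    mus = np.empty(n_iter)
    precs = np.empty(n_iter)
    accepted_post = 0
    window_acc = 0
    window = 200
    for it in range(n_iter):
        prop = np.array([mu, u]) + scale * rng.standard_normal(2)
        lp_prop = loglik(prop[0], np.exp(-prop[1])) + logprior(prop[0], prop[1])
        if np.log(rng.random()) < lp_prop - lp:
            mu, u = float(prop[0]), float(prop[1])
            lp = lp_prop
            window_acc += 1
            if it >= burn_in:
                accepted_post += 1
        mus[it] = mu
        precs[it] = np.exp(u)
        if it < burn_in and (it + 1) % window == 0:
            rate = window_acc / window
            scale *= np.exp(rate - 0.3)  # Robbins-Monro-style adaptation
            scale = np.clip(scale, 1e-3, 10.0)
            window_acc = 0

    post = slice(burn_in, n_iter)
    acc_rate = accepted_post / (n_iter - burn_in)
    mu_hat = float(mus[post].mean())
    prec_hat = float(precs[post].mean())
    params = LNPParams(mu=mu_hat, sigma2=1.0 / prec_hat)
    flags = ()
    if not 0.05 <= acc_rate <= 0.95:
        flags = ("acceptance_rate_outside_[0.05,0.95]",)
        logger.warning("MH acceptance rate %.3f outside [0.05, 0.95]", acc_rate)
    ll = loglik(mu_hat, params.sigma2)
    result = FitResult(params=params, loglik=ll, converged=True, n_iter=n_iter, flags=flags)
    trace = MCMCTrace(
        mu=mus, precision=precs, burn_in=burn_in, seed=seed, acceptance_rate=acc_rate
    )
    return result, trace


# ---------------------------------------------------------------------------
# NB-NB mixture (EM + SQUAREM)


def _nbnb_loglik_terms(values: np.ndarray, p: NBNBParams) -> np.ndarray:
    l1 = _nb_logpmf(values, p.comp1.mu, p.comp1.r)
    l2 = _nb_logpmf(values, p.comp2.mu, p.comp2.r)
    with np.errstate(divide="ignore"):
        a = np.log1p(-p.tau) + l1 if p.tau < 1.0 else np.full_like(l1, -np.inf)
        b = np.log(p.tau) + l2 if p.tau > 0.0 else np.full_like(l2, -np.inf)
    return np.logaddexp(a, b)


def _nbnb_loglik(values: np.ndarray, weights: np.ndarray, p: NBNBParams) -> float:
    return float(weights @ _nbnb_loglik_terms(values, p))


def _responsibilities(values: np.ndarray, p: NBNBParams) -> np.ndarray:
    """P(Z = 1 | x): posterior weight of the high-count component."""
    if p.tau <= 0.0:
        return np.zeros_like(values, dtype=float)
    if p.tau >= 1.0:
        return np.ones_like(values, dtype=float)
    l1 = np.log1p(-p.tau) + _nb_logpmf(values, p.comp1.mu, p.comp1.r)
    l2 = np.log(p.tau) + _nb_logpmf(values, p.comp2.mu, p.comp2.r)
    return special.expit(l2 - l1)


def _em_step(values: np.ndarray, weights: np.ndarray, p: NBNBParams) -> NBNBParams:
    g = _responsibilities(values, p)
    w2 = weights * g
    w1 = weights * (1.0 - g)
    tau = float(w2.sum() / weights.sum())
    comp1 = p.comp1 if w1.sum() <= 0 or (w1 @ values) <= 0 else _weighted_nb_mle(values, w1)[0]
    comp2 = p.comp2 if w2.sum() <= 0 or (w2 @ values) <= 0 else _weighted_nb_mle(values, w2)[0]
    return NBNBParams(tau=tau, comp1=comp1, comp2=comp2)


_TAU_CLIP = 1e-12


def _to_psi(p: NBNBParams) -> np.ndarray:
    tau = np.clip(p.tau, _TAU_CLIP, 1.0 - _TAU_CLIP)
    return np.array(
        [
            special.logit(tau),
            np.log(p.comp1.mu),
            np.log(p.comp1.r),
            np.log(p.comp2.mu),
            np.log(p.comp2.r),
        ]
    )


def _from_psi(psi: np.ndarray) -> NBNBParams:
    r1 = float(np.clip(np.exp(psi[2]), _R_MIN, _R_MAX))
    r2 = float(np.clip(np.exp(psi[4]), _R_MIN, _R_MAX))
    return NBNBParams(
        tau=float(special.expit(psi[0])),
        comp1=NBParams(mu=float(np.exp(psi[1])), r=r1),
        comp2=NBParams(mu=float(np.exp(psi[3])), r=r2),
    )


def _auto_init(values: np.ndarray, weights: np.ndarray) -> NBNBParams:
    """Moment-based start: bulk below the 0.90 quantile, tail above it."""
    counts = np.repeat(values, weights.astype(np.int64))
    q = np.quantile(counts, 0.90)
    hi = counts > q
    if not hi.any() or hi.all():
        order = np.argsort(counts)
        hi = np.zeros(counts.size, dtype=bool)
        hi[order[-max(1, counts.size // 10) :]] = True
    tau = float(hi.mean())

    def mom(xs: np.ndarray) -> NBParams:
        mu = max(float(xs.mean()), 1e-3)
        var = float(xs.var())
        r = mu * mu / (var - mu) if var > mu else 100.0
        return NBParams(mu=mu, r=float(np.clip(r, 1e-3, _R_MAX)))

    return NBNBParams(tau=tau, comp1=mom(counts[~hi]), comp2=mom(counts[hi]))


def fit_nbnb(
    counts: CountVector,
    init: NBNBParams | str = "auto",
    max_iter: int = 2000,
    tol: float = 1e-8,
    accelerate: bool = True,
    seed: int | None = None,
) -> FitResult:
    """Fit the two-component NB mixture by EM, optionally SQUAREM-accelerated.

    The E-step computes responsibilities P(Z_i = 1 | x_i); the M-step refits
    tau as the mean responsibility and each component by weighted NB MLE.
    SQUAREM (squared first-order extrapolation with step-length safeguarding)
    estimates the accumulation of many EM updates in one jump; any
    extrapolated point that fails to increase the log-likelihood is replaced
    by the plain EM step, so the recorded trace is non-decreasing in either
    mode.  Components are reordered so ``comp1.mu <= comp2.mu`` on return.

    ``seed`` is accepted for interface uniformity; the default initialization
    and both EM variants are deterministic.
    """
    x = counts.counts
    if x.size == 0:
        raise ValueError("cannot fit an empty count vector")
    if np.unique(x).size < 2:
        raise ValueError("NB-NB fit requires at least 2 distinct count values")
    values, weights = _unique_weighted(counts)
    p = _auto_init(values, weights) if isinstance(init, str) else init

    ll = _nbnb_loglik(values, weights, p)
    trace = [ll]
    n_em_evals = 0
    converged = False
    n_iter = 0

    def step(q: NBNBParams) -> NBNBParams:
        nonlocal n_em_evals
        n_em_evals += 1
        return _em_step(values, weights, q)

    while n_iter < max_iter:
        n_iter += 1
        if accelerate:
            p1 = step(p)
            p2 = step(p1)
            psi0, psi1, psi2 = _to_psi(p), _to_psi(p1), _to_psi(p2)
            r = psi1 - psi0
            v = (psi2 - psi1) - r
            vnorm = float(np.linalg.norm(v))
            cand = p2
            ll_cand = _nbnb_loglik(values, weights, p2)
            if vnorm > 1e-12:
                alpha = -float(np.linalg.norm(r)) / vnorm
                alpha = min(alpha, -1.0)  # safeguard: never shorter than one EM step
                psi_s = psi0 - 2.0 * alpha * r + alpha * alpha * v
                if np.all(np.isfinite(psi_s)) and np.max(np.abs(psi_s)) < 300:
                    p_s = step(_from_psi(psi_s))  # stabilizing EM step
                    ll_s = _nbnb_loglik(values, weights, p_s)
                    if np.isfinite(ll_s) and ll_s >= ll_cand:
                        cand, ll_cand = p_s, ll_s
            p_new, ll_new = cand, ll_cand
        else:
            p_new = step(p)
            ll_new = _nbnb_loglik(values, weights, p_new)

        param_change = float(np.max(np.abs(_to_psi(p_new) - _to_psi(p))))
        rel_change = abs(ll_new - ll) / (1.0 + abs(ll))
        p, ll = p_new, ll_new
        trace.append(ll)
        if rel_change < tol or param_change < 1e-6:
            converged = True
            break

    flags: tuple[str, ...] = ()
    if p.tau < tol or p.tau > 1.0 - tol:
        flags = ("degenerate_to_single_NB",)
        converged = True
    p = p.ordered()
    return FitResult(
        params=p,
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        trace=np.asarray(trace),
        flags=flags,
        n_em_evals=n_em_evals,
    )


# ---------------------------------------------------------------------------
# pmf / mixing CDF dispatch


def pmf(params: ModelParams, x) -> np.ndarray | float:
    """Count pmf P(X = x) under any of the four models (vectorized in x)."""
    x_arr = np.asarray(x)
    if np.any(x_arr < 0):
        raise ValueError("x must be >= 0")
    if isinstance(params, PoissonParams):
        out = stats.poisson.pmf(x_arr, params.mu)
    elif isinstance(params, NBParams):
        out = stats.nbinom.pmf(x_arr, params.r, params.r / (params.r + params.mu))
    elif isinstance(params, LNPParams):
        out = np.exp(_lnp_logpmf(np.atleast_1d(x_arr).astype(float), params.mu, params.sigma2))
        out = out.reshape(x_arr.shape)
    elif isinstance(params, NBNBParams):
        p1 = stats.nbinom.pmf(x_arr, params.comp1.r, params.comp1.r / (params.comp1.r + params.comp1.mu))
        p2 = stats.nbinom.pmf(x_arr, params.comp2.r, params.comp2.r / (params.comp2.r + params.comp2.mu))
        out = (1.0 - params.tau) * p1 + params.tau * p2
    else:
        raise TypeError(f"unsupported params type {type(params)!r}")
    return out if np.ndim(x) else float(out)


def mixing_cdf(params: ModelParams, lam) -> np.ndarray | float:
    """CDF F(lambda) of the mixing distribution implied by the model.

    Point-mass step for the Poisson (right-continuous), gamma for the NB,
    log-normal for the LNP, and the tau-weighted two-gamma mixture for the
    NB-NB model.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be >= 0")
    if isinstance(params, PoissonParams):
        out = (lam_arr >= params.mu).astype(float)
    elif isinstance(params, NBParams):
        out = stats.gamma.cdf(lam_arr, a=params.r, scale=params.mu / params.r)
    elif isinstance(params, LNPParams):
        out = stats.lognorm.cdf(lam_arr, s=np.sqrt(params.sigma2), scale=np.exp(params.mu))
    elif isinstance(params, NBNBParams):
        g1 = stats.gamma.cdf(lam_arr, a=params.comp1.r, scale=params.comp1.mu / params.comp1.r)
        g2 = stats.gamma.cdf(lam_arr, a=params.comp2.r, scale=params.comp2.mu / params.comp2.r)
        out = (1.0 - params.tau) * g1 + params.tau * g2
    else:
        raise TypeError(f"unsupported params type {type(params)!r}")
    return out if np.ndim(lam) else float(out)
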