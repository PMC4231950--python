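"""Nonparametric MLE of the Poisson mixing distribution (Constrained Newton Method).

For counts x_i drawn from a Poisson mixture X | Lambda ~ Poisson(Lambda),
Lambda ~ f(lambda), the maximum-likelihood estimate of f is a discrete
distribution with finitely many support points — at most as many as there are
distinct observed values.  The CNM algorithm alternates:

1. support expansion — locate maximizers of the gradient function
   d(theta*; G), the directional derivative of the log-likelihood as mass is
   shifted from the current mixture G toward a point mass at theta*, and add
   every maximizer with d > 0;
2. weight update — the exact weight MLE on the fixed support, obtained by
   iterating the constrained least-squares problem
   min || S pi' - 2*1 ||^2 over the probability simplex, where
   S_ji = (d/d pi_i) l_j is the per-observation likelihood gradient;
3. pruning — support points whose weight hits zero are deleted.

At the NPMLE, d(theta*; G) <= 0 for every theta* >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .counts_io import CountVector
from .models import _unique_weighted

__all__ = ["DiscreteMixture", "CNMResult", "gradient_function", "update_weights", "cnm_fit"]

_WEIGHT_PRUNE = 1e-10  # weights below this are treated as exactly zero
_MERGE_RTOL = 1e-4  # support points closer than _MERGE_RTOL*(1+theta) merge


@dataclass(frozen=True)
class DiscreteMixture:
    """Discrete mixing distribution: support ``theta`` with weights ``pi``."""

    theta: np.ndarray
    pi: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if theta.ndim != 1 or theta.shape != pi.shape or theta.size == 0:
            raise ValueError("theta and pi must be equal-length non-empty vectors")
        if np.any(theta < 0):
            raise ValueError("support points must be >= 0")
        if theta.size > 1 and np.any(np.diff(theta) <= 0):
            raise ValueError("theta must be strictly increasing")
        if np.any(pi <= 0):
            raise ValueError("weights must be > 0 (prune zeros before construction)")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "pi", pi)

    @property
    def L(self) -> int:
        return int(self.theta.size)

    def pmf(self, x) -> np.ndarray:
        """Mixture count pmf: sum_i pi_i Poisson(x; theta_i)."""
        x_arr = np.atleast_1d(np.asarray(x))
        mat = stats.poisson.pmf(x_arr[:, None], self.theta[None, :])
        out = mat @ self.pi
        return out if np.ndim(x) else float(out[0])

    def cdf(self, lam) -> np.ndarray | float:
        """Right-continuous CDF of the mixing distribution."""
        lam_arr = np.atleast_1d(np.asarray(lam, dtype=float))
        out = (lam_arr[:, None] >= self.theta[None, :]) @ self.pi
        return out if np.ndim(lam) else float(out[0])


@dataclass
class CNMResult:
    mixture: DiscreteMixture
    loglik: float
    max_gradient: float
    n_iter: int
    converged: bool
    trace: np.ndarray | None = None


def _poisson_pmf_matrix(values: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P[k, i] = Poisson(values_k; theta_i)."""
    return stats.poisson.pmf(values[:, None], theta[None, :])


def gradient_function(theta_star, mixture: DiscreteMixture, counts: CountVector):
    """Directional derivative d(theta*; G) of the log-likelihood.

    d(theta*; G) = sum_j [ Poisson(x_j; theta*) / f_G(x_j) - 1 ], the rate at
    which the log-likelihood increases as probability mass is shifted from
    the current mixture G to a point mass at theta*.  Vectorized in
    ``theta_star``.
    """
    ts = np.atleast_1d(np.asarray(theta_star, dtype=float))
    if np.any(ts < 0):
        raise ValueError("theta_star must be >= 0")
    values, weights = _unique_weighted(counts)
    fg = _poisson_pmf_matrix(values, mixture.theta) @ mixture.pi
    if np.any(fg <= 0):
        bad = values[fg <= 0][0]
        raise ValueError(f"mixture assigns zero probability to observed count {bad}")
    ratio = stats.poisson.pmf(values[:, None], ts[None, :]) / fg[:, None]
    d = weights @ (ratio - 1.0)
    return d if np.ndim(theta_star) else float(d[0])


def _loglik(values: np.ndarray, weights: np.ndarray, theta: np.ndarray, pi: np.ndarray) -> float:
    fg = _poisson_pmf_matrix(values, theta) @ pi
    if np.any(fg <= 0):
        return -np.inf
    return float(weights @ np.log(fg))


def _cn_weight_solve(
    values: np.ndarray, weights: np.ndarray, theta: np.ndarray, max_inner: int = 200
) -> np.ndarray:
    """Weight MLE on fixed support via iterated constrained least squares.

    Each pass linearizes the (concave) weight log-likelihood at the current
    point: rows sqrt(w_j) * P(x_j; theta_i) / f_G(x_j) against target
    2*sqrt(w_j), with the simplex equality handled by an appended penalty row
    and the non-negativity by NNLS.  A backtracking line search keeps the
    log-likelihood non-decreasing; the concavity of the problem makes the
    limit the global weight MLE.
    """
    L = theta.size
    P = _poisson_pmf_matrix(values, theta)
    pi = np.full(L, 1.0 / L)
    wsum = weights.sum()
    # multiplicative (EM) preconditioning: scale-robust, moves the iterate
    # into the region where the least-squares linearization is trustworthy
    ll = _loglik(values, weights, theta, pi)
    for _ in range(500):
        fg = P @ pi
        pi = pi * ((weights / fg) @ P) / wsum
        pi = pi / pi.sum()
        ll_new = _loglik(values, weights, theta, pi)
        if ll_new - ll < 1e-10 * (1.0 + abs(ll_new)):
            ll = ll_new
            break
        ll = ll_new
    sw = np.sqrt(weights)
    for _ in range(max_inner):
        fg = P @ pi
        if np.any(fg <= 0):
            raise RuntimeError("weight solve hit zero mixture probability at an observed count")
        S = (sw / fg)[:, None] * P
        if not np.all(np.isfinite(S)) or np.abs(S).max() > 1e10:
            break  # linearization ill-conditioned; keep the EM solution
        target = 2.0 * sw
        gamma = 1e4 * max(1.0, float(np.abs(S).max()))
        A = np.vstack([S, gamma * np.ones((1, L))])
        b = np.concatenate([target, [gamma]])
        try:
            pi_new, _ = optimize.nnls(A, b)
        except RuntimeError as exc:  # pragma: no cover - nnls rarely fails
            resid = float(np.linalg.norm(A @ pi - b))
            raise RuntimeError(f"constrained least-squares failed (residual {resid:.3e})") from exc
        total = pi_new.sum()
        if total <= 0:
            raise RuntimeError("constrained least-squares returned the zero vector")
        pi_new = pi_new / total
        # backtracking toward pi to guarantee an increase
        t = 1.0
        for _ in range(40):
            cand = (1.0 - t) * pi + t * pi_new
            ll_cand = _loglik(values, weights, theta, cand)
            if ll_cand >= ll:
                break
            t *= 0.5
        else:
            break
        gain = ll_cand - ll
        pi, ll = cand, ll_cand
        if gain < 1e-13 * (1.0 + abs(ll)):
            break
    return pi


def update_weights(theta, counts: CountVector) -> np.ndarray:
    """Exact weight MLE for a fixed support vector ``theta``.

    Returns weights on the probability simplex; entries may be (numerically)
    zero, which the CNM outer loop prunes.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("theta must be nonempty")
    if theta.size > 1 and np.any(np.diff(theta) <= 0):
        raise ValueError("theta must be strictly increasing")
    if theta.size == 1:
        return np.array([1.0])
    values, weights = _unique_weighted(counts)
    pi = _cn_weight_solve(values, weights, theta)
    pi[pi < _WEIGHT_PRUNE] = 0.0
    return pi / pi.sum()


def _candidate_grid(
    values: np.ndarray, theta: np.ndarray, grid_size: int
) -> np.ndarray:
    lo_positive = values[values > 0].min() if np.any(values > 0) else 1.0
    lo = max(1e-3, float(lo_positive)) / 2.0
    hi = 2.0 * float(values.max()) + 1.0
    geo = np.geomspace(lo, min(lo + 1.0, hi), 2) if hi <= lo else np.geomspace(lo, hi, grid_size)
    mid = (theta[:-1] + theta[1:]) / 2.0 if theta.size > 1 else np.empty(0)
    grid = np.unique(np.concatenate([values.astype(float), geo, mid, theta]))
    return grid


def _local_maxima(grid: np.ndarray, d: np.ndarray) -> list[int]:
    idx = []
    for i in range(grid.size):
        left = d[i - 1] if i > 0 else -np.inf
        right = d[i + 1] if i < grid.size - 1 else -np.inf
        if d[i] >= left and d[i] >= right:
            idx.append(i)
    return idx


def cnm_fit(
    counts: CountVector,
    grid_size: int = 100,
    grad_tol: float | None = None,
    max_iter: int = 200,
) -> CNMResult:
    """Compute the NPMLE of the Poisson mixing distribution by CNM.

    The candidate grid for new support points is the union of the observed
    distinct counts, a geometric grid spanning
    [max(1e-3, min positive count)/2, 2*max(count)+1], and midpoints of the
    current support; every local maximum of the gradient function on the grid
    is polished by bounded scalar maximization, and all polished maximizers
    with positive gradient are added.  ``grad_tol`` defaults to 1e-6 * n
    (the gradient scales with sample size).  A run that exhausts ``max_iter``
    is returned with ``converged=False`` — still usable for diagnostics.
    """
    x = counts.counts
    if x.size == 0:
        raise ValueError("cannot fit an empty count vector")
    n = x.size
    if grad_tol is None:
        grad_tol = 1e-6 * n
    values, weights = _unique_weighted(counts)

    theta = np.array([float(x.mean())])
    pi = np.array([1.0])
    ll = _loglik(values, weights, theta, pi)
    trace = [ll]
    converged = False
    max_grad = np.inf
    n_iter = 0

    while n_iter < max_iter:
        n_iter += 1
        fg = _poisson_pmf_matrix(values, theta) @ pi
        # a provisional mixture can underflow to zero mass at extreme counts;
        # floor it so the gradient stays finite (and enormous) there
        wf = weights / np.maximum(fg, 1e-300)
        wsum = weights.sum()

        def d_of(ts: np.ndarray) -> np.ndarray:
            # gradient_function with the current-mixture pmf precomputed
            return wf @ stats.poisson.pmf(values[:, None], np.atleast_1d(ts)[None, :]) - wsum

        grid = _candidate_grid(values, theta, grid_size)
        d = d_of(grid)

        new_points: list[float] = []
        best_d = -np.inf
        for i in _local_maxima(grid, d):
            lo = grid[i - 1] if i > 0 else max(0.0, grid[i] / 2.0)
            hi = grid[i + 1] if i < grid.size - 1 else grid[i] * 2.0 + 1.0
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda t: -float(d_of(np.array([t]))[0]),
                    bounds=(lo, hi),
                    method="bounded",
                    options={"xatol": 1e-10},
                )
                t_best, d_best = float(res.x), float(-res.fun)
            else:
                t_best, d_best = float(grid[i]), float(d[i])
            best_d = max(best_d, d_best)
            if d_best > 0:
                new_points.append(t_best)

        max_grad = max(best_d, float(d.max()))
        if max_grad <= grad_tol:
            converged = True
            break

        theta_new = np.unique(np.concatenate([theta, np.asarray(new_points)]))
        # drop near-duplicates introduced by polishing
        keep = np.concatenate([[True], np.diff(theta_new) > _MERGE_RTOL * (1.0 + theta_new[1:])])
        theta_new = theta_new[keep]

        pi_new = update_weights(theta_new, counts)
        nz = pi_new > 0
        theta, pi = theta_new[nz], pi_new[nz]

        # consolidation: the likelihood is nearly flat in splitting one atom
        # of the mixing distribution across two close support points, so CNM
        # can carry such pairs along indefinitely.  Greedily merge the
        # closest adjacent pair (weight-averaged location, weights
        # re-optimized) while the log-likelihood does not decrease; the
        # convergence scan at the top of the next iteration re-certifies
        # first-order optimality of the consolidated support.
        ll = _loglik(values, weights, theta, pi)
        while theta.size > 1:
            gaps = np.diff(theta) / (1.0 + theta[:-1])
            i = int(np.argmin(gaps))
            theta_m = np.delete(theta, i + 1)
            theta_m[i] = float(np.average(theta[i : i + 2], weights=pi[i : i + 2]))
            pi_m = update_weights(theta_m, counts)
            nz = pi_m > 0
            ll_m = _loglik(values, weights, theta_m[nz], pi_m[nz] / pi_m[nz].sum())
            if ll_m < ll - 1e-9:
                break
            theta, pi, ll = theta_m[nz], pi_m[nz] / pi_m[nz].sum(), ll_m

        trace.append(ll)

    mixture = DiscreteMixture(theta=theta, pi=pi / pi.sum())
    return CNMResult(
        mixture=mixture,
        loglik=_loglik(values, weights, mixture.theta, mixture.pi),
        max_gradient=float(max_grad),
        n_iter=n_iter,
        converged=converged,
        trace=np.asarray(trace),
    )
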