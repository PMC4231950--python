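"""Model-assessment machinery for Poisson-mixture count models.

Five diagnostics, all built around the discrete NPMLE of the mixing
distribution and the Total Variation (TV) distance between pmfs:

- distribution recovery: rebuild the count pmf implied by a discrete mixing
  distribution and compare it with the empirical pmf;
- CDF bounds: any continuous mixing distribution consistent with the NPMLE
  (theta, pi) must have CDF F with
  sum_{j<i} pi_j <= F(theta_i) < sum_{j<=i} pi_j at every support point
  (half-open; the lower bound at the first point is 0, which assumes Lambda
  is not zero-inflated);
- TV distance, d_TV(f, g) = 1/2 * sum_x |f(x) - g(x)|, the goodness-of-fit
  score;
- zero-inflation scan: delete (or add) a proportion of the zero counts,
  refit each model, and watch how d_TV responds — a fit that improves
  markedly as zeros are removed suggests zero-inflation, real or spurious;
- bin classification: posterior membership of the NB-NB high-count
  component, from which a blacklist of artifact-prone regions can be built
  de novo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import models
from .counts_io import CountVector, RegionSet
from .models import ModelParams, NBNBParams
from .npmle import DiscreteMixture

logger = logging.getLogger("binmix")

__all__ = [
    "Pmf",
    "BoundsTable",
    "MixingFitReport",
    "ZeroScanResult",
    "empirical_pmf",
    "recover_pmf",
    "model_pmf",
    "tv_distance",
    "cdf_bounds",
    "check_mixing_fit",
    "zero_scan",
    "classify_bins",
]


@dataclass(frozen=True)
class Pmf:
    """A pmf on 0..x_max plus the probability mass beyond x_max."""

    support: np.ndarray
    probabilities: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=np.int64)
        probs = np.asarray(self.probabilities, dtype=float)
        if support.shape != probs.shape or support.ndim != 1:
            raise ValueError("support and probabilities must be parallel vectors")
        if support.size == 0 or support[0] != 0 or np.any(np.diff(support) != 1):
            raise ValueError("support must be the contiguous integers 0..x_max")
        if np.any(probs < 0) or self.tail_mass < -1e-12:
            raise ValueError("probabilities must be >= 0")
        total = probs.sum() + self.tail_mass
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pmf must sum to 1 (got {total!r})")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probabilities", probs)

    @property
    def x_max(self) -> int:
        return int(self.support[-1])


def empirical_pmf(counts: CountVector) -> Pmf:
    """Relative frequencies on 0..max(count); no tail mass."""
    x = counts.counts
    if x.size == 0:
        raise ValueError("cannot build a pmf from an empty count vector")
    freqs = np.bincount(x) / x.size
    return Pmf(support=np.arange(freqs.size), probabilities=freqs, tail_mass=0.0)


def recover_pmf(mixture: DiscreteMixture, x_max: int) -> Pmf:
    """Count pmf implied by a discrete mixing distribution.

    f-hat(x) = sum_i pi_i * Poisson(x; theta_i) for x = 0..x_max, with the
    remaining model mass reported as ``tail_mass``.
    """
    if x_max < 0:
        raise ValueError("x_max must be >= 0")
    probs = mixture.pmf(np.arange(x_max + 1))
    return Pmf(
        support=np.arange(x_max + 1),
        probabilities=probs,
        tail_mass=max(0.0, 1.0 - float(np.sum(probs))),
    )


def model_pmf(params: ModelParams, x_max: int) -> Pmf:
    """Fitted-model count pmf truncated at x_max, tail mass lumped."""
    if x_max < 0:
        raise ValueError("x_max must be >= 0")
    probs = np.asarray(models.pmf(params, np.arange(x_max + 1)))
    return Pmf(
        support=np.arange(x_max + 1),
        probabilities=probs,
        tail_mass=max(0.0, 1.0 - float(np.sum(probs))),
    )


def tv_distance(f: Pmf, g: Pmf) -> float:
    """Total Variation distance, d_TV = 1/2 sum_x |f(x) - g(x)|.

    The two pmfs are aligned to the longer support (shorter one extended
    with zeros) and the tail masses are compared as one extra cell.
    """
    x_max = max(f.x_max, g.x_max)
    fp = np.zeros(x_max + 1)
    gp = np.zeros(x_max + 1)
    fp[: f.x_max + 1] = f.probabilities
    gp[: g.x_max + 1] = g.probabilities
    return float(0.5 * (np.abs(fp - gp).sum() + abs(f.tail_mass - g.tail_mass)))


@dataclass(frozen=True)
class BoundsTable:
    """Per-support-point interval [lower_i, upper_i) that must contain F(theta_i).

    lower_i = sum_{j<i} pi_j and upper_i = sum_{j<=i} pi_j; consecutive rows
    telescope (lower_i = upper_{i-1}), lower_1 = 0 and upper_L = 1.
    """

    theta: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"theta": self.theta, "lower": self.lower, "upper": self.upper})


def cdf_bounds(mixture: DiscreteMixture) -> BoundsTable:
    """CDF bounds implied by the discrete NPMLE (no zero-inflation assumed)."""
    csum = np.cumsum(mixture.pi)
    lower = np.concatenate([[0.0], csum[:-1]])
    upper = csum.copy()
    upper[-1] = 1.0
    return BoundsTable(theta=mixture.theta.copy(), lower=lower, upper=upper)


@dataclass
class MixingFitReport:
    """Outcome of checking a continuous mixing CDF against the NPMLE bounds."""

    theta: np.ndarray
    cdf_values: np.ndarray
    passed: np.ndarray
    first_violation: int | None
    n_violations: int
    log_survival: np.ndarray  # log(1 - F(theta_i)), the quantity plotted

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta,
                "cdf": self.cdf_values,
                "log_survival": self.log_survival,
                "passed": self.passed,
            }
        )


def check_mixing_fit(params: ModelParams, bounds: BoundsTable) -> MixingFitReport:
    """Check whether a model's mixing CDF respects the NPMLE CDF bounds.

    The check is strict half-open: lower_i <= F(theta_i) < upper_i; equality
    at the upper edge counts as a violation.
    """
    F = np.asarray(models.mixing_cdf(params, bounds.theta))
    passed = (bounds.lower <= F) & (F < bounds.upper)
    violations = np.flatnonzero(~passed)
    with np.errstate(divide="ignore"):
        log_surv = np.log1p(-np.minimum(F, 1.0))
    return MixingFitReport(
        theta=bounds.theta.copy(),
        cdf_values=F,
        passed=passed,
        first_violation=int(violations[0]) if violations.size else None,
        n_violations=int(violations.size),
        log_survival=log_surv,
    )


# ---------------------------------------------------------------------------
# zero-inflation scan

_FITTERS = {
    "poisson": lambda cv, seed, init: models.fit_poisson(cv),
    "nb": lambda cv, seed, init: models.fit_nb(cv),
    "nbnb": lambda cv, seed, init: models.fit_nbnb(cv, init=init or "auto", seed=seed),
}


@dataclass
class ZeroScanResult:
    """One row per (rho, model): fit metadata and the resulting d_TV."""

    table: pd.DataFrame

    def optimum(self, model: str) -> float:
        """rho minimizing d_TV for the given model."""
        sub = self.table[self.table["model"] == model]
        if sub.empty:
            raise KeyError(f"model {model!r} not in scan")
        return float(sub.loc[sub["d_tv"].idxmin(), "rho"])


def _adjust_zeros(x: np.ndarray, rho: float) -> np.ndarray:
    """Deterministically remove (rho > 0) or add (rho < 0) zeros.

    rho is the signed fraction of the existing zero count: rho = 0.4 removes
    round(0.4 * n_zeros) zeros, rho = -0.4 appends round(0.4 * n_zeros)
    additional zeros.  Zeros are exchangeable, so deterministic removal loses
    no generality.
    """
    n_zeros = int((x == 0).sum())
    k = int(round(abs(rho) * n_zeros))
    if rho > 0:
        nonzero = x[x != 0]
        kept_zeros = np.zeros(n_zeros - k, dtype=x.dtype)
        return np.concatenate([kept_zeros, nonzero])
    if rho < 0:
        return np.concatenate([np.zeros(k, dtype=x.dtype), x])
    return x.copy()


def zero_scan(
    counts: CountVector,
    rho_grid,
    model_names=("poisson", "nb", "nbnb"),
    *,
    seed: int = 0,
) -> ZeroScanResult:
    """Scan zero removal/addition fractions, refitting models at each rho.

    For each rho in ``rho_grid`` the zero counts are adjusted (removed for
    rho > 0, duplicated for rho < 0), each requested model is refit, and the
    TV distance between the fitted pmf and the adjusted empirical pmf is
    recorded.  The rho = 0 row reproduces the unadjusted fit exactly.

    The NB-NB refits are warm-started from the unadjusted fit (a
    continuation along the scan path); without this, the EM can land in
    different local maxima at neighbouring rho values and the scan curve
    becomes erratic.
    """
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(rho_grid > 1.0):
        raise ValueError("rho must be <= 1 (cannot remove more zeros than exist)")
    x = counts.counts
    if np.any(rho_grid > 0) and not np.any(x == 0):
        raise ValueError("counts contain no zeros to remove")
    unknown = set(model_names) - set(_FITTERS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}; choose from {sorted(_FITTERS)}")

    base_fits = {name: _FITTERS[name](counts, seed, None) for name in model_names}
    rows = []
    for rho in rho_grid:
        adj = CountVector(counts=_adjust_zeros(x, float(rho)))
        emp = empirical_pmf(adj)
        for name in model_names:
            if rho == 0.0:
                fit = base_fits[name]
            else:
                init = base_fits[name].params if name == "nbnb" else None
                fit = _FITTERS[name](adj, seed, init)
            d_tv = tv_distance(model_pmf(fit.params, emp.x_max), emp)
            rows.append(
                {
                    "rho": float(rho),
                    "model": name,
                    "d_tv": d_tv,
                    "loglik": fit.loglik,
                    "converged": fit.converged,
                    "n_iter": fit.n_iter,
                }
            )
    return ZeroScanResult(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# blacklist construction


def classify_bins(
    fit: NBNBParams, counts: CountVector, threshold: float = 0.5
) -> tuple[np.ndarray, RegionSet]:
    """Posterior membership of the high-count NB component, per bin.

    posterior_i = tau * f2(x_i) / (tau * f2(x_i) + (1 - tau) * f1(x_i)).
    Bins with posterior >= threshold form the blacklist; adjacent flagged
    bins are merged into single intervals.  Without coordinates the
    posteriors are still returned but the RegionSet is empty.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if fit.comp1.mu > fit.comp2.mu:
        raise ValueError("fit must be ordered with comp1.mu <= comp2.mu")
    x = counts.counts
    f1 = np.asarray(models.pmf(fit.comp1, x))
    f2 = np.asarray(models.pmf(fit.comp2, x))
    num = fit.tau * f2
    den = num + (1.0 - fit.tau) * f1
    posterior = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    flagged = posterior >= threshold
    if counts.bin_starts is None or counts.bin_width is None:
        if flagged.any():
            logger.warning("counts carry no coordinates; blacklist left empty")
        return posterior, RegionSet(())
    chrom = counts.chrom if counts.chrom is not None else "."
    width = int(counts.bin_width)
    intervals = [
        (chrom, int(start), int(start) + width)
        for start in counts.bin_starts[flagged]
    ]
    return posterior, RegionSet(tuple(intervals))  # adjacent bins merge on construction
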