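"""Synthetic count generation from Poisson mixtures.

Counts are drawn hierarchically: a latent per-bin rate Lambda is drawn from a
mixing distribution f(lambda), then the count X | Lambda ~ Poisson(Lambda).
Supported mixing families cover everything the modelling code can fit: a
single point mass (plain Poisson counts), a gamma (NB counts), a log-normal
(log-normal Poisson counts), a two-component gamma mixture (NB-NB counts) and
an arbitrary finite discrete distribution (the form the NPMLE takes).

Optional zero-inflation replaces each count with 0 with probability ``nu``
before anything is drawn for that bin.  Every sampler takes an explicit seed;
there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from .counts_io import CountVector

__all__ = ["MixingSpec", "ZeroInflationConfig", "simulate_counts", "nb_mixing_spec"]

_KINDS = ("point", "gamma", "lognormal", "gamma_gamma_mixture", "discrete")


@dataclass(frozen=True)
class MixingSpec:
    """A mixing distribution for the latent Poisson rate Lambda.

    ``kind`` selects the family; ``params`` are kind-specific:

    - ``point``: ``lam`` (>= 0)
    - ``gamma``: ``shape``, ``rate`` (> 0); mixes to NB(mu=shape/rate,
      r=shape) in the mean-dispersion parametrization used package-wide
    - ``lognormal``: ``mu`` (log-scale mean), ``sigma2`` (log-scale variance > 0)
    - ``gamma_gamma_mixture``: ``tau`` in [0,1] plus ``shape1``, ``rate1``,
      ``shape2``, ``rate2``; component 2 is chosen with probability ``tau``
    - ``discrete``: ``theta`` (non-negative support), ``pi`` (weights summing to 1)

    Prefer the classmethod constructors, which name the parameters.
    """

    kind: str
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown mixing kind {self.kind!r}; expected one of {_KINDS}")
        p = dict(self.params)
        object.__setattr__(self, "params", p)
        if self.kind == "point":
            if p["lam"] < 0:
                raise ValueError("point mass lam must be >= 0")
        elif self.kind == "gamma":
            if p["shape"] <= 0 or p["rate"] <= 0:
                raise ValueError("gamma shape and rate must be > 0")
        elif self.kind == "lognormal":
            if p["sigma2"] <= 0:
                raise ValueError("lognormal sigma2 must be > 0")
        elif self.kind == "gamma_gamma_mixture":
            if not 0.0 <= p["tau"] <= 1.0:
                raise ValueError("tau must be in [0, 1]")
            for key in ("shape1", "rate1", "shape2", "rate2"):
                if p[key] <= 0:
                    raise ValueError(f"{key} must be > 0")
        elif self.kind == "discrete":
            theta = np.asarray(p["theta"], dtype=float)
            pi = np.asarray(p["pi"], dtype=float)
            if theta.shape != pi.shape or theta.ndim != 1 or theta.size == 0:
                raise ValueError("theta and pi must be equal-length non-empty vectors")
            if np.any(theta < 0):
                raise ValueError("discrete support must be >= 0")
            if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
                raise ValueError("pi must be non-negative and sum to 1")
            p["theta"], p["pi"] = theta, pi

    @classmethod
    def point(cls, lam: float) -> "MixingSpec":
        return cls("point", {"lam": float(lam)})

    @classmethod
    def gamma(cls, shape: float, rate: float) -> "MixingSpec":
        return cls("gamma", {"shape": float(shape), "rate": float(rate)})

    @classmethod
    def lognormal(cls, mu: float, sigma2: float) -> "MixingSpec":
        return cls("lognormal", {"mu": float(mu), "sigma2": float(sigma2)})

    @classmethod
    def gamma_gamma(
        cls, tau: float, shape1: float, rate1: float, shape2: float, rate2: float
    ) -> "MixingSpec":
        return cls(
            "gamma_gamma_mixture",
            {
                "tau": float(tau),
                "shape1": float(shape1),
                "rate1": float(rate1),
                "shape2": float(shape2),
                "rate2": float(rate2),
            },
        )

    @classmethod
    def discrete(cls, theta, pi) -> "MixingSpec":
        return cls("discrete", {"theta": theta, "pi": pi})

    def draw_rates(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` latent rates Lambda from this mixing distribution."""
        p = self.params
        if self.kind == "point":
            return np.full(size, p["lam"], dtype=float)
        if self.kind == "gamma":
            return rng.gamma(shape=p["shape"], scale=1.0 / p["rate"], size=size)
        if self.kind == "lognormal":
            return rng.lognormal(mean=p["mu"], sigma=np.sqrt(p["sigma2"]), size=size)
        if self.kind == "gamma_gamma_mixture":
            z = rng.random(size) < p["tau"]
            lam = np.empty(size, dtype=float)
            n2 = int(z.sum())
            lam[~z] = rng.gamma(shape=p["shape1"], scale=1.0 / p["rate1"], size=size - n2)
            lam[z] = rng.gamma(shape=p["shape2"], scale=1.0 / p["rate2"], size=n2)
            return lam
        # discrete
        idx = rng.choice(p["theta"].size, size=size, p=p["pi"])
        return p["theta"][idx]


def nb_mixing_spec(mu: float, r: float) -> MixingSpec:
    """Gamma mixing spec equivalent to NB(mu, r): gamma(shape=r, rate=r/mu)."""
    if mu <= 0 or r <= 0:
        raise ValueError("mu and r must be > 0")
    return MixingSpec.gamma(shape=r, rate=r / mu)


@dataclass(frozen=True)
class ZeroInflationConfig:
    """Probability ``nu`` of forcing a bin's count to zero before sampling."""

    nu: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError("nu must be in [0, 1]")


def simulate_counts(
    spec: MixingSpec,
    n: int,
    zi: ZeroInflationConfig | None = None,
    *,
    seed: int,
) -> CountVector:
    """Simulate ``n`` counts: X_i | Lambda_i ~ Poisson(Lambda_i), Lambda_i ~ spec.

    With zero-inflation, each bin is independently zeroed with probability
    ``zi.nu`` first; rates are drawn only for the surviving bins.  Fully
    reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    nu = 0.0 if zi is None else zi.nu
    rng = np.random.default_rng(seed)
    zeroed = rng.random(n) < nu
    m = int((~zeroed).sum())
    counts = np.zeros(n, dtype=np.int64)
    if m:
        lam = spec.draw_rates(rng, m)
        counts[~zeroed] = rng.poisson(lam)
    return CountVector(counts=counts)
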