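"""Priors on the number of mixture components K.

Four families are supported, all with support on the positive integers
(K >= 1):

* ``uniform(lower=1, upper)`` — discrete uniform on ``{1, ..., upper}``.
* ``truncated_poisson(rate)`` — zero-truncated Poisson: a Poisson(rate)
  conditioned on K >= 1.
* ``shifted_geometric(p)`` — ``K - 1 ~ Geom(p)`` counting failures before
  the first success, so ``P(K = 1) = p``.
* ``shifted_bnb(n, a, b)`` — ``K - 1`` follows a beta-negative-binomial
  distribution with shape parameters ``(n, a, b)``.

The parameterizations are pinned by the moment pairs they must reproduce:
uniform(1, 30) has mean 15.5 and variance 74.9; truncated_poisson(3) has
mean ~3.16 and variance ~2.66; shifted_geometric(0.1) has mean 10 and
variance 90; shifted_bnb(1, 4, 3) has mean 2 and variance 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

__all__ = ["PriorK", "uniform_k", "truncated_poisson_k", "shifted_geometric_k",
           "shifted_bnb_k", "point_mass_k", "prior_from_dict"]

_FAMILIES = ("uniform", "truncated_poisson", "shifted_geometric", "shifted_bnb")

#: unbounded supports are enumerated up to cumulative mass 1 - _TAIL_MASS
_TAIL_MASS = 1e-12


@dataclass(frozen=True)
class PriorK:
    """A prior distribution on the number of mixture components ``K >= 1``.

    Parameters
    ----------
    family
        One of ``uniform``, ``truncated_poisson``, ``shifted_geometric``,
        ``shifted_bnb``.
    params
        Family-specific parameters: ``{"lower", "upper"}`` for uniform,
        ``{"rate"}``, ``{"p"}``, or ``{"n", "a", "b"}``.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    support_min: int = 1

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        p = dict(self.params)
        if self.family == "uniform":
            lower, upper = int(p.get("lower", 1)), int(p["upper"])
            if lower < 1 or upper < lower:
                raise ValueError("uniform prior needs 1 <= lower <= upper")
        elif self.family == "truncated_poisson":
            if p["rate"] <= 0:
                raise ValueError("rate must be positive")
        elif self.family == "shifted_geometric":
            if not 0 < p["p"] <= 1:
                raise ValueError("success probability must be in (0, 1]")
        else:
            if min(p["n"], p["a"], p["b"]) <= 0:
                raise ValueError("shape parameters must be positive")
        object.__setattr__(self, "params", p)

    # -- pmf / cdf -----------------------------------------------------
    def pmf(self, k):
        """P(K = k); zero outside the support. Vectorized over ``k``."""
        k = self._check_k(k)
        p = self.params
        if self.family == "uniform":
            dist = stats.randint(p.get("lower", 1), p["upper"] + 1)
            return dist.pmf(k)
        if self.family == "truncated_poisson":
            lam = p["rate"]
            out = stats.poisson(lam).pmf(k) / -np.expm1(-lam)
            return np.where(k >= 1, out, 0.0)
        if self.family == "shifted_geometric":
            # scipy geom counts trials to first success, support {1, 2, ...}
            return stats.geom(p["p"]).pmf(k)
        return stats.betanbinom(p["n"], p["a"], p["b"], loc=1).pmf(k)

    def logpmf(self, k):
        k = self._check_k(k)
        with np.errstate(divide="ignore"):
            return np.log(self.pmf(k))

    def cdf(self, k):
        k = self._check_k(k)
        p = self.params
        if self.family == "uniform":
            return stats.randint(p.get("lower", 1), p["upper"] + 1).cdf(k)
        if self.family == "truncated_poisson":
            lam = p["rate"]
            pois = stats.poisson(lam)
            return np.clip((pois.cdf(k) - pois.pmf(0)) / -np.expm1(-lam), 0.0, 1.0)
        if self.family == "shifted_geometric":
            return stats.geom(p["p"]).cdf(k)
        return stats.betanbinom(p["n"], p["a"], p["b"], loc=1).cdf(k)

    def tail_prob(self, k0: int) -> float:
        """P(K > k0) = 1 - CDF(k0)."""
        if k0 < 1:
            raise ValueError("k0 must be >= 1")
        return float(1.0 - self.cdf(k0))

    # -- moments -------------------------------------------------------
    def moments(self) -> tuple[float, float]:
        """Mean and variance of K (closed form where available)."""
        p = self.params
        if self.family == "uniform":
            lo, hi = p.get("lower", 1), p["upper"]
            m = (lo + hi) / 2.0
            v = ((hi - lo + 1) ** 2 - 1) / 12.0
            return m, v
        if self.family == "truncated_poisson":
            lam = p["rate"]
            m = lam / -np.expm1(-lam)
            # V[K] = m (1 + lam - m) for the zero-truncated Poisson
            return m, m * (1.0 + lam - m)
        if self.family == "shifted_geometric":
            q = p["p"]
            return 1.0 + (1.0 - q) / q, (1.0 - q) / q**2
        d = stats.betanbinom(p["n"], p["a"], p["b"], loc=1)
        return float(d.mean()), float(d.var())

    # -- support handling ----------------------------------------------
    @property
    def bounded(self) -> bool:
        return self.family == "uniform"

    def support_max(self, tail_mass: float = _TAIL_MASS) -> int:
        """Upper enumeration bound: exact for uniform, else the smallest k
        with CDF(k) >= 1 - tail_mass.  Memoized (the generic discrete ppf
        is costly for the heavy-tailed families)."""
        if self.family == "uniform":
            return int(self.params["upper"])
        memo = self.__dict__.setdefault("_supmax_memo", {})
        if tail_mass in memo:
            return memo[tail_mass]
        p = self.params
        if self.family == "truncated_poisson":
            base = stats.poisson(p["rate"])
        elif self.family == "shifted_geometric":
            base = stats.geom(p["p"])
        else:
            base = stats.betanbinom(p["n"], p["a"], p["b"], loc=1)
        k = max(int(base.ppf(1.0 - tail_mass)), 1)
        memo[tail_mass] = k
        return k

    def support(self, tail_mass: float = _TAIL_MASS) -> np.ndarray:
        lo = int(self.params.get("lower", 1)) if self.family == "uniform" else 1
        return np.arange(lo, self.support_max(tail_mass) + 1)

    # -- sampling ------------------------------------------------------
    def sample(self, rng: np.random.Generator, m: int = 1) -> np.ndarray:
        """Draw ``m`` i.i.d. values of K."""
        if m < 1:
            raise ValueError("m must be >= 1")
        p = self.params
        if self.family == "uniform":
            return rng.integers(p.get("lower", 1), p["upper"] + 1, size=m)
        if self.family == "truncated_poisson":
            # inverse-CDF on the zero-truncated scale
            lam = p["rate"]
            u = rng.uniform(stats.poisson(lam).pmf(0), 1.0, size=m)
            return stats.poisson(lam).ppf(u).astype(int)
        if self.family == "shifted_geometric":
            return rng.geometric(p["p"], size=m)
        d = stats.betanbinom(p["n"], p["a"], p["b"], loc=1)
        return d.ppf(rng.uniform(size=m)).astype(int)

    # -- plumbing ------------------------------------------------------
    @staticmethod
    def _check_k(k):
        arr = np.asarray(k)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.mod(arr, 1) == 0):
                raise ValueError("k must be integer")
            arr = arr.astype(int)
        if np.any(arr < 1):
            raise ValueError("k must be >= 1")
        return arr

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    def __repr__(self) -> str:  # compact, config-file friendly
        inner = ", ".join(f"{k}={v:g}" for k, v in self.params.items())
        return f"PriorK({self.family}({inner}))"


# -- convenience constructors ------------------------------------------

def uniform_k(upper: int, lower: int = 1) -> PriorK:
    return PriorK("uniform", {"lower": lower, "upper": upper})


def truncated_poisson_k(rate: float) -> PriorK:
    return PriorK("truncated_poisson", {"rate": rate})


def shifted_geometric_k(p: float) -> PriorK:
    return PriorK("shifted_geometric", {"p": p})


def shifted_bnb_k(n: float, a: float, b: float) -> PriorK:
    return PriorK("shifted_bnb", {"n": n, "a": a, "b": b})


def point_mass_k(k: int) -> PriorK:
    """Degenerate prior P(K = k) = 1, as uniform(k, k)."""
    return PriorK("uniform", {"lower": k, "upper": k})


def prior_from_dict(d: Mapping) -> PriorK:
    """Rebuild a prior from its ``{"family", "params"}`` serialization."""
    return PriorK(d["family"], dict(d["params"]))
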