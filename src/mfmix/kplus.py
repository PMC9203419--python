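"""The number of filled components K+ and its induced prior.

In a mixture of finite mixtures, the number of *data clusters* is the
number K+ of components that actually receive observations.  Its prior is
not specified directly: it is induced jointly by the prior p(K) on the
number of components, the (symmetric) Dirichlet parameter gamma_K on the
weights, and the sample size n.  Given K, the cluster sizes follow a
symmetric Dirichlet-multinomial law, and K+ is the number of non-empty
cells; marginalizing over K ~ p(K) gives the induced prior.

Two computational routes are provided and cross-validated against each
other: an exact dynamic-programming recursion over the
Dirichlet-multinomial occupancy law, and direct Monte-Carlo simulation of
weights and assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .priors import PriorK

__all__ = ["KPlusDistribution", "conditional_kplus_given_K", "induced_prior_kplus"]


@dataclass
class KPlusDistribution:
    """A pmf over the number of filled components ``k_plus >= 1``.

    ``support`` and ``probs`` are aligned arrays; ``n`` is the sample size
    the distribution refers to; ``provenance`` is ``"prior"`` or
    ``"posterior"``; ``meta`` records how it was computed (method, seed,
    Monte-Carlo replications, truncation cap).
    """

    support: np.ndarray
    probs: np.ndarray
    n: int
    provenance: str = "prior"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.support.shape != self.probs.shape:
            raise ValueError("support and probs must align")
        if np.any(self.probs < -1e-15):
            raise ValueError("negative probability")

    def as_dict(self) -> dict[int, float]:
        return {int(k): float(p) for k, p in zip(self.support, self.probs)}

    def pmf(self, k: int) -> float:
        idx = np.nonzero(self.support == k)[0]
        return float(self.probs[idx[0]]) if idx.size else 0.0

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.probs)

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs))

    def mode(self) -> int:
        """Argmax of the pmf; ties broken toward the smallest k_plus."""
        return int(self.support[int(np.argmax(self.probs))])

    def entropy(self) -> float:
        """Shannon entropy in nats over the observed support (0 log 0 = 0)."""
        p = self.probs[self.probs > 0]
        return float(-np.sum(p * np.log(p)))

    def tv_distance(self, other) -> float:
        """Total-variation distance to another pmf over the integers.

        ``other`` may be a KPlusDistribution or any object with
        ``support()``/``pmf()`` in the PriorK style.
        """
        if isinstance(other, KPlusDistribution):
            osup, oprob = other.support, other.probs
        else:
            osup = other.support()
            oprob = other.pmf(osup)
        lo = min(self.support.min(), osup.min())
        hi = max(self.support.max(), osup.max())
        a = np.zeros(hi - lo + 1)
        b = np.zeros(hi - lo + 1)
        a[self.support - lo] = self.probs
        b[osup - lo] = oprob
        return 0.5 * float(np.abs(a - b).sum())


# ---------------------------------------------------------------------
# exact occupancy law via dynamic programming
# ---------------------------------------------------------------------

def _log_occupancy_pmf(K: int, gamma: float, n: int) -> np.ndarray:
    """log P(K+ = j | K, gamma, n) for j = 1..min(K, n).

    Cluster sizes (N_1, ..., N_K) follow the symmetric
    Dirichlet-multinomial law

        P(N) = n!/prod(N_k!) * G(K g)/G(K g + n) * prod G(N_k + g)/G(g),

    so with w(m) = G(m + g) / (G(g) m!) for m >= 1,

        P(K+ = j) = C(K, j) G(K g)/G(K g + n) n! * sum over positive
                    compositions (N_1..N_j) of n of prod w(N_m).

    The composition sum is a j-fold convolution, computed with the terms
    rescaled by w(1) = gamma to keep the recursion in a safe float range.
    """
    jmax = min(K, n)
    m = np.arange(1, n + 1)
    # r(m) = w(m) / w(1) = G(m+g) / (G(1+g) m!)
    log_r = gammaln(m + gamma) - gammaln(1.0 + gamma) - gammaln(m + 1)
    shift = log_r.max()
    r = np.exp(log_r - shift)

    out = np.full(jmax, -np.inf)
    conv = r.copy()  # A'_j(.) for j = 1, scaled by exp(-j*shift)
    base = (gammaln(K * gamma) - gammaln(K * gamma + n) + gammaln(n + 1)
            + gammaln(K + 1))
    for j in range(1, jmax + 1):
        a_n = conv[n - j] if n - j < conv.size else 0.0  # index of total n
        if a_n > 0:
            out[j - 1] = (base - gammaln(j + 1) - gammaln(K - j + 1)
                          + j * (np.log(gamma) + shift) + np.log(a_n))
        if j < jmax:
            conv = np.convolve(conv, r)[: n]
    return out


def conditional_kplus_given_K(
    K: int,
    gamma_K: float,
    n: int,
    method: str = "exact",
    mc_reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> KPlusDistribution:
    """Distribution of the number of non-empty cells when ``n`` draws are
    allocated by a symmetric Dirichlet(``gamma_K``)-multinomial over ``K``
    cells."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if method == "exact":
        logp = _log_occupancy_pmf(K, gamma_K, n)
        p = np.exp(logp - logsumexp(logp))
        meta = {"method": "exact"}
    elif method == "monte_carlo":
        if mc_reps < 1000:
            raise ValueError("mc_reps < 1000 is too noisy to be meaningful")
        rng = np.random.default_rng() if rng is None else rng
        w = rng.dirichlet(np.full(K, gamma_K), size=mc_reps)
        counts = rng.multinomial(n, w)
        kp = (counts > 0).sum(axis=1)
        p = np.bincount(kp, minlength=min(K, n) + 1)[1: min(K, n) + 1] / mc_reps
        meta = {"method": "monte_carlo", "mc_reps": mc_reps}
    else:
        raise ValueError(f"unknown method {method!r}")
    return KPlusDistribution(np.arange(1, min(K, n) + 1), p, n, "prior", meta)


# ---------------------------------------------------------------------
# induced prior, marginalized over K ~ p(K)
# ---------------------------------------------------------------------

def induced_prior_kplus(
    prior_k: PriorK,
    weight_mode: str = "static",
    weight_param: float = 1.0,
    n: int = 82,
    method: str = "exact",
    mc_reps: int = 100_000,
    rng: np.random.Generator | None = None,
) -> KPlusDistribution:
    """Prior on the number of filled components induced by ``p(K)``, the
    Dirichlet weight parameter, and the sample size.

    Parameters
    ----------
    weight_mode
        ``"static"``: gamma_K = ``weight_param`` for every K.
        ``"dynamic"``: gamma_K = ``weight_param`` / K.
    method
        ``"exact"`` marginalizes the DP occupancy pmf over the truncated
        support of ``p(K)``; ``"monte_carlo"`` simulates
        (K, weights, assignments) directly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if weight_param <= 0:
        raise ValueError("weight_param must be positive")
    if weight_mode not in ("static", "dynamic"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    ks = prior_k.support()
    if method == "exact":
        pk = prior_k.pmf(ks)
        jcap = min(int(ks[-1]), n)
        acc = np.zeros(jcap)
        for K, w in zip(ks, pk):
            if w <= 0.0:
                continue
            g = weight_param / K if weight_mode == "dynamic" else weight_param
            logp = _log_occupancy_pmf(int(K), g, n)
            p = np.exp(logp - logsumexp(logp))
            acc[: p.size] += w * p
        acc /= acc.sum()
        meta = {"method": "exact", "k_cap": int(ks[-1])}
        return KPlusDistribution(np.arange(1, jcap + 1), acc, n, "prior", meta)

    if mc_reps < 1000:
        raise ValueError("mc_reps < 1000 is too noisy to be meaningful")
    rng = np.random.default_rng() if rng is None else rng
    kdraws = prior_k.sample(rng, mc_reps)
    counts = np.zeros(min(int(ks[-1]), n) + 1)
    # vectorize within groups of equal K
    for K in np.unique(kdraws):
        reps = int(np.sum(kdraws == K))
        g = weight_param / K if weight_mode == "dynamic" else weight_param
        w = rng.dirichlet(np.full(int(K), g), size=reps)
        c = rng.multinomial(n, w)
        kp = (c > 0).sum(axis=1)
        counts[: kp.max() + 1] += np.bincount(kp, minlength=kp.max() + 1)
    probs = counts[1:] / mc_reps
    meta = {"method": "monte_carlo", "mc_reps": mc_reps, "k_cap": int(ks[-1])}
    return KPlusDistribution(np.arange(1, counts.size), probs, n, "prior", meta)
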