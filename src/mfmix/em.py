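"""Maximum-likelihood EM for univariate Gaussian mixtures with BIC selection.

This is the frequentist baseline against which the Bayesian cluster-number
estimates are compared: fit mixtures with K = 1..K_max components by EM,
under either an equal-variance or an unequal-variance model, and pick K
(and optionally the variance model) by minimizing

    BIC = -2 loglik + p log n,   p = (K - 1) + K + (1 or K).

Initialization uses Ward hierarchical clustering plus random restarts;
EM is run to a relative log-likelihood tolerance with a variance floor
guarding against the usual likelihood singularities at tiny clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.special import logsumexp

__all__ = ["EMFit", "em_fit", "select_K_bic"]

_LOG2PI = float(np.log(2.0 * np.pi))

try:  # optional acceleration; the numpy path is equivalent
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: variance floor, as a fraction of the sample variance
_FLOOR_FRAC = 1e-6


@dataclass
class EMFit:
    """A converged (or stopped) EM fit of a K-component Gaussian mixture."""

    K: int
    variance_model: str
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_iter_used: int
    degenerate: bool = False
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_params(self) -> int:
        return (self.K - 1) + self.K + (1 if self.variance_model == "equal"
                                        else self.K)


def _loglik_matrix(y, w, mu, s2):
    with np.errstate(divide="ignore"):
        return (np.log(w) - 0.5 * (_LOG2PI + np.log(s2))
                - 0.5 * (y[:, None] - mu) ** 2 / s2)


def _bic(loglik: float, K: int, variance_model: str, n: int) -> float:
    p = (K - 1) + K + (1 if variance_model == "equal" else K)
    return -2.0 * loglik + p * np.log(n)


def _init_params(y, K, scheme, rng, link=None):
    """Starting (weights, means, variances) from hard labels."""
    n = y.size
    if scheme == "hclust":
        if link is None:
            link = linkage(y[:, None], method="ward")
        lab = fcluster(link, t=K, criterion="maxclust") - 1
    elif scheme == "random":
        centers = rng.choice(y, size=K, replace=False)
        lab = np.argmin(np.abs(y[:, None] - centers), axis=1)
    else:
        raise ValueError(f"unknown init scheme {scheme!r}")
    w = np.empty(K)
    mu = np.empty(K)
    s2 = np.empty(K)
    overall = max(float(np.var(y)), 1e-12)
    for k in range(K):
        idx = lab == k
        nk = int(idx.sum())
        w[k] = max(nk, 1) / n
        mu[k] = y[idx].mean() if nk else y[rng.integers(n)]
        s2[k] = y[idx].var() if nk > 1 else overall
    w /= w.sum()
    s2 = np.maximum(s2, _FLOOR_FRAC * overall)
    return w, mu, s2


def _em_loop_py(y, w, mu, s2, equal, tol, max_iter, floor):
    """Reference EM loop (mutates w, mu, s2 in place)."""
    n = y.size
    K = w.size
    path = []
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = _loglik_matrix(y, w, mu, s2)
        row = logsumexp(lp, axis=1)
        ll = float(row.sum())
        path.append(ll)
        if ll - ll_old <= tol * abs(ll):
            converged = True
            break
        ll_old = ll
        r = np.exp(lp - row[:, None])
        nk = np.maximum(r.sum(axis=0), 1e-300)
        w[:] = nk / n
        mu[:] = (r * y[:, None]).sum(axis=0) / nk
        dev = (y[:, None] - mu) ** 2
        if equal:
            s2[:] = max((r * dev).sum() / n, floor)
        else:
            s2[:] = np.maximum((r * dev).sum(axis=0) / nk, floor)
    return np.asarray(path), it, converged


if _HAVE_NUMBA:
    @_njit(cache=False)
    def _em_loop_jit(y, w, mu, s2, equal, tol, max_iter, floor):
        n = y.size
        K = w.size
        path = np.empty(max_iter)
        buf = np.empty(K)
        nk = np.empty(K)
        sy = np.empty(K)
        syy = np.empty(K)
        ll_old = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            for k in range(K):
                buf[k] = 0.0  # reused below; zero the accumulators
                nk[k] = 0.0
                sy[k] = 0.0
                syy[k] = 0.0
            logc = np.empty(K)
            for k in range(K):
                logc[k] = np.log(w[k]) - 0.5 * (_LOG2PI + np.log(s2[k]))
            ll = 0.0
            for i in range(n):
                yi = y[i]
                m = -np.inf
                for k in range(K):
                    t = logc[k] - 0.5 * (yi - mu[k]) ** 2 / s2[k]
                    buf[k] = t
                    if t > m:
                        m = t
                s = 0.0
                for k in range(K):
                    buf[k] = np.exp(buf[k] - m)
                    s += buf[k]
                ll += m + np.log(s)
                for k in range(K):
                    r = buf[k] / s
                    nk[k] += r
                    sy[k] += r * yi
                    syy[k] += r * yi * yi
            path[it - 1] = ll
            if ll - ll_old <= tol * abs(ll):
                converged = True
                break
            ll_old = ll
            tot = 0.0
            for k in range(K):
                if nk[k] < 1e-300:
                    nk[k] = 1e-300
                w[k] = nk[k] / n
                mu[k] = sy[k] / nk[k]
                ssq = syy[k] - nk[k] * mu[k] * mu[k]
                if ssq < 0.0:
                    ssq = 0.0
                tot += ssq
                if not equal:
                    s2[k] = max(ssq / nk[k], floor)
            if equal:
                for k in range(K):
                    s2[k] = max(tot / n, floor)
        return path[:it], it, converged


def em_fit(data, K: int, variance_model: str = "unequal",
           init_scheme: str = "hclust", tol: float = 1e-8,
           max_iter: int = 1000, rng=None, _link=None) -> EMFit:
    """Fit a K-component univariate Gaussian mixture by EM.

    ``variance_model`` is ``"equal"`` (one shared variance) or
    ``"unequal"``.  Convergence is declared when the relative
    log-likelihood improvement falls below ``tol``.  A component whose
    variance collapses to the floor marks the fit ``degenerate`` (the fit
    is still returned).  ``K=1`` is solved in closed form.
    """
    y = np.asarray(data, dtype=float).ravel()
    n = y.size
    if K < 1 or n <= K:
        raise ValueError("need K >= 1 and n > K")
    if variance_model not in ("equal", "unequal"):
        raise ValueError(f"unknown variance model {variance_model!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    floor = _FLOOR_FRAC * max(float(np.var(y)), 1e-12)

    if K == 1:
        mu = float(y.mean())
        s2 = max(float(y.var()), floor)
        ll = float(-0.5 * n * (_LOG2PI + np.log(s2)) - 0.5 * n)
        return EMFit(1, variance_model, np.ones(1), np.array([mu]),
                     np.array([s2]), ll, _bic(ll, 1, variance_model, n),
                     True, 0, loglik_path=np.array([ll]))

    w, mu, s2 = _init_params(y, K, init_scheme, rng, link=_link)
    if variance_model == "equal":
        # start inside the constrained parameter set, else the first
        # M-step projection can decrease the likelihood
        s2[:] = max(float(np.dot(w, s2)), floor)
    loop = _em_loop_jit if _HAVE_NUMBA else _em_loop_py
    path, it, converged = loop(y, w, mu, s2, variance_model == "equal",
                               tol, max_iter, floor)
    ll = float(path[-1])
    bic = _bic(ll, K, variance_model, n)
    return EMFit(K, variance_model, w, mu, s2, ll, bic, converged, it,
                 degenerate=bool(np.any(s2 <= floor * (1 + 1e-12))),
                 loglik_path=np.asarray(path))


def select_K_bic(data, K_range=range(1, 16), approach: str = "unequal",
                 restarts: int = 5, rng=None, tol: float = 1e-8,
                 max_iter: int = 1000) -> EMFit:
    """Minimize BIC over K (and, for ``approach="best_of_both"``, over the
    equal/unequal variance models).

    For every (K, model) cell one hierarchical-clustering-initialized fit
    plus ``restarts`` random-restart fits are run and the best
    log-likelihood is kept before the BIC comparison.
    """
    y = np.asarray(data, dtype=float).ravel()
    models = {"equal": ("equal",), "unequal": ("unequal",),
              "best_of_both": ("equal", "unequal")}[approach]
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    link = linkage(y[:, None], method="ward")
    best: EMFit | None = None
    for K in K_range:
        for model in models:
            fits = [em_fit(y, K, model, "hclust", tol, max_iter, rng, _link=link)]
            if K > 1:
                fits += [em_fit(y, K, model, "random", tol, max_iter, rng)
                         for _ in range(restarts)]
            top = max(fits, key=lambda f: f.loglik)
            if best is None or top.bic < best.bic:
                best = top
    return best
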