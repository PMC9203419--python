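"""Telescoping sampler for the univariate Gaussian mixture of finite mixtures.

The model places a prior p(K) on the number of components, a symmetric
Dirichlet(gamma_K) prior on the weights (static: gamma_K = gamma; dynamic:
gamma_K = alpha / K), independent Normal(b0, B0) priors on the component
means and Gamma(c0, C0) priors on the component precisions (rate
parameterization, prior mean c0/C0 for the precision).

One sweep of the sampler consists of five steps:

1. draw the assignments S_i from their categorical full conditional,
   recompute the occupancy counts and relabel so the filled components
   come first;
2. update means and variances of the filled components from their
   conjugate conditionals (precision first, then mean);
3. draw a new K from p(K | partition), a discrete distribution supported
   on K >= K_plus;
4. append K - K_plus empty components with parameters from the prior;
5. draw new weights from the Dirichlet with parameters gamma_K + N_k.

Because K is resampled conditional only on the partition, no
reversible-jump machinery is needed; empty components are born and die
through steps 3-4.  All kernel arithmetic is done in log space with
log-gamma functions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .priors import PriorK

__all__ = [
    "MFMConfig", "MixtureState", "MFMTrace",
    "update_assignments", "count_and_relabel", "update_filled_components",
    "sample_K_given_partition", "step3_log_kernel", "add_empty_components",
    "update_weights", "initial_state", "run_sampler",
]

_LOG2PI = float(np.log(2.0 * np.pi))

try:  # optional acceleration; the numpy path is equivalent
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:
    @_njit(cache=False)
    def _assign_rows(y, a, b, c, u):
        """Row-wise categorical draws with logits a_k + y b_k + y^2 c_k.

        Returns -1 - i if every logit of row i is -inf.  Terms more than
        60 nats below the row maximum are skipped; they cannot move a
        float64 running sum."""
        n = y.size
        K = a.size
        out = np.zeros(n, np.int64)
        buf = np.empty(K)
        for i in range(n):
            yi = y[i]
            y2 = yi * yi
            m = -np.inf
            for k in range(K):
                t = a[k] + yi * b[k] + y2 * c[k]
                buf[k] = t
                if t > m:
                    m = t
            if not np.isfinite(m):
                out[i] = -1 - i
                return out
            s = 0.0
            for k in range(K):
                if buf[k] - m > -60.0:
                    s += np.exp(buf[k] - m)
            target = u[i] * s
            acc = 0.0
            k = 0
            for k in range(K):
                if buf[k] - m > -60.0:
                    acc += np.exp(buf[k] - m)
                    if acc >= target:
                        break
            out[i] = k
        return out


@dataclass(frozen=True)
class MFMConfig:
    """Prior and MCMC configuration for one sampler run.

    ``weight_param`` is gamma for ``weight_mode="static"`` and alpha for
    ``weight_mode="dynamic"``.  ``b0=None`` means "midpoint of the data
    range", resolved when the sampler starts.  ``n_iter`` counts
    post-burn-in sweeps; every ``thinning``-th of them is retained.
    ``K_cap=None`` enumerates K in step 3 up to the point where the prior
    on K has cumulative mass 1 - 1e-12.
    """

    prior_k: PriorK
    weight_mode: str = "static"
    weight_param: float = 1.0
    b0: Optional[float] = None
    B0: float = 630.0
    c0: float = 2.0
    C0: float = 12.5
    n_iter: int = 200_000
    burn_in: int = 10_000
    thinning: int = 4
    K_init: int = 10
    seed: Optional[int] = None
    K_cap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.weight_mode not in ("static", "dynamic"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if self.weight_param <= 0:
            raise ValueError("weight_param must be positive")
        for name in ("B0", "c0", "C0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thinning < 1 or self.K_init < 1:
            raise ValueError("thinning and K_init must be >= 1")

    def gamma_K(self, K: int) -> float:
        """Dirichlet parameter used for a mixture with K components."""
        return self.weight_param / K if self.weight_mode == "dynamic" else self.weight_param

    def k_cap(self) -> int:
        return self.K_cap if self.K_cap is not None else self.prior_k.support_max()

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in (
            "weight_mode", "weight_param", "b0", "B0", "c0", "C0",
            "n_iter", "burn_in", "thinning", "K_init", "seed")}
        d["prior_k"] = self.prior_k.to_dict()
        d["K_cap"] = self.k_cap()
        return d


@dataclass
class MixtureState:
    """Current sampler state.

    ``assignments`` holds 0-based component indices; after
    :func:`count_and_relabel` the filled components occupy slots
    ``0..K_plus-1`` in their original relative order.
    """

    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    assignments: np.ndarray
    counts: np.ndarray
    K_plus: int

    def validate(self, n: int | None = None) -> None:
        assert self.weights.size == self.means.size == self.variances.size == self.K
        assert abs(self.weights.sum() - 1.0) < 1e-10
        assert np.all(self.variances > 0)
        if n is not None:
            assert self.counts.sum() == n
        assert self.K_plus == int(np.sum(self.counts > 0))
        assert self.K >= self.K_plus
        assert np.all(self.counts[: self.K_plus] > 0)
        assert np.all(self.counts[self.K_plus:] == 0)


@dataclass
class TraceRecord:
    """One retained draw: the label-invariant summary of the state."""

    iteration: int
    K: int
    K_plus: int
    filled_counts: tuple


@dataclass
class MFMTrace:
    """Retained draws of a sampler run plus run metadata."""

    iteration: np.ndarray
    K: np.ndarray
    K_plus: np.ndarray
    filled_counts: list
    meta: dict = field(default_factory=dict)
    params: Optional[dict] = None  # filled means/variances/weights per draw

    def __len__(self) -> int:
        return self.iteration.size

    def records(self):
        for i in range(len(self)):
            yield TraceRecord(int(self.iteration[i]), int(self.K[i]),
                              int(self.K_plus[i]), tuple(self.filled_counts[i]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"iteration": self.iteration, "K": self.K,
                             "K_plus": self.K_plus})


# ---------------------------------------------------------------------
# the five steps
# ---------------------------------------------------------------------

def update_assignments(state: MixtureState, data: np.ndarray,
                       rng: np.random.Generator) -> MixtureState:
    """Step 1a: redraw every assignment from
    P(S_i = k) prop. to eta_k N(y_i | mu_k, sigma^2_k), in log space."""
    with np.errstate(divide="ignore"):
        logw = np.log(state.weights)
    # log eta_k N(y|mu_k, s2_k) expanded in y so the n x K matrix is built
    # from two rank-1 updates (K can run into the hundreds for dynamic
    # weights, where most components are empty)
    inv = 1.0 / state.variances
    a = logw - 0.5 * (_LOG2PI + np.log(state.variances)) \
        - 0.5 * state.means**2 * inv
    if _HAVE_NUMBA:
        u = rng.uniform(size=data.size)
        out = _assign_rows(data, a, state.means * inv, -0.5 * inv, u)
        if out.min() < 0:
            i = int(-(out.min()) - 1)
            raise FloatingPointError(
                f"all categorical weights underflowed for observation {i} "
                f"(y={data[i]!r}); state: K={state.K}, "
                f"weights={state.weights}")
        state.assignments = out
        return state
    logp = np.multiply.outer(data, state.means * inv)
    logp += np.multiply.outer(data * data, -0.5 * inv)
    logp += a
    rowmax = logp.max(axis=1)
    finite = np.isfinite(rowmax)
    if not finite.all():
        i = int(np.nonzero(~finite)[0][0])
        raise FloatingPointError(
            f"all categorical weights underflowed for observation {i} "
            f"(y={data[i]!r}); state: K={state.K}, weights={state.weights}")
    # row-wise inverse-CDF draw on the normalized categorical; terms more
    # than 60 nats below the row maximum cannot move a float64 cumsum
    logp -= rowmax[:, None]
    mask = logp > -60.0
    probs = np.zeros_like(logp)
    np.exp(logp, out=probs, where=mask)
    cdf = np.cumsum(probs, axis=1)
    u = rng.uniform(size=data.size) * cdf[:, -1]
    state.assignments = (cdf < u[:, None]).sum(axis=1)
    return state


def count_and_relabel(state: MixtureState) -> MixtureState:
    """Step 1b: recompute occupancy counts, set K_plus, and compact the
    filled components into the leading slots (stable: relative order of
    the filled components is preserved)."""
    counts = np.bincount(state.assignments, minlength=state.K)
    filled = np.nonzero(counts > 0)[0]
    empty = np.nonzero(counts == 0)[0]
    order = np.concatenate([filled, empty])
    inv = np.empty(state.K, dtype=int)
    inv[order] = np.arange(state.K)
    state.weights = state.weights[order]
    state.means = state.means[order]
    state.variances = state.variances[order]
    state.counts = counts[order]
    state.assignments = inv[state.assignments]
    state.K_plus = int(filled.size)
    return state


def update_filled_components(state: MixtureState, data: np.ndarray,
                             config: MFMConfig,
                             rng: np.random.Generator) -> MixtureState:
    """Step 2: conjugate updates for the filled components, precisions
    first (Gamma(c_k, C_k)), then means (Normal(b_k, B_k)) given the new
    precisions."""
    kp = state.K_plus
    if kp < 1 or np.any(state.counts[:kp] == 0):
        raise AssertionError("update_filled_components requires filled slots 0..K_plus-1")
    b0 = config.b0 if config.b0 is not None else 0.5 * (data.min() + data.max())
    nk = state.counts[:kp]
    sumy = np.bincount(state.assignments, weights=data, minlength=state.K)[:kp]
    sq = np.bincount(state.assignments,
                     weights=(data - state.means[state.assignments]) ** 2,
                     minlength=state.K)[:kp]
    ck = config.c0 + 0.5 * nk
    Ck = config.C0 + 0.5 * sq
    prec = rng.gamma(shape=ck, scale=1.0 / Ck)
    Bk = 1.0 / (1.0 / config.B0 + nk * prec)
    bk = Bk * (b0 / config.B0 + prec * sumy)
    state.variances[:kp] = 1.0 / prec
    state.means[:kp] = rng.normal(bk, np.sqrt(Bk))
    return state


def step3_log_kernel(K_values: np.ndarray, K_plus: int,
                     filled_counts: np.ndarray, n: int,
                     config: MFMConfig,
                     log_pk: np.ndarray | None = None) -> np.ndarray:
    """Unnormalized log p(K | partition) over candidate values ``K_values``:

        log K!/(K-K_plus)! + log G(K g_K) - log G(K g_K + n)
        + sum_k [log G(N_k + g_K) - log G(1 + g_K)] + log p(K),

    with n the sample size and g_K the Dirichlet parameter at K."""
    K_values = np.asarray(K_values, dtype=float)
    if log_pk is None:
        log_pk = config.prior_k.logpmf(K_values.astype(int))
    g = config.weight_param / K_values if config.weight_mode == "dynamic" \
        else np.full_like(K_values, config.weight_param)
    kern = gammaln(K_values + 1.0) - gammaln(K_values - K_plus + 1.0)
    kern += gammaln(K_values * g) - gammaln(K_values * g + n)
    kern += (gammaln(filled_counts[:, None] + g[None, :])
             - gammaln(1.0 + g)[None, :]).sum(axis=0)
    return kern + log_pk


def sample_K_given_partition(state: MixtureState, config: MFMConfig,
                             rng: np.random.Generator,
                             _cache: dict | None = None) -> int:
    """Step 3: draw a new K from p(K | partition) on {K_plus, ..., K_cap}."""
    n = int(state.counts.sum())
    kp = state.K_plus
    cap = len(_cache["k_grid"]) if _cache is not None else max(config.k_cap(), kp)
    nk = state.counts[:kp].astype(float)
    if _cache is not None:
        # precomputed tables indexed by K = 1..cap (offset 1)
        sl = slice(kp - 1, cap)
        kern = _cache["lfact"][kp:cap + 1] - _cache["lfact"][: cap - kp + 1]
        kern = kern + _cache["log_pk"][sl]
        if config.weight_mode == "static":
            g = config.weight_param
            kern = kern + _cache["lg_kg"][sl]
            kern = kern + np.sum(gammaln(nk + g) - gammaln(1.0 + g))
        else:
            gvec = config.weight_param / _cache["k_grid"][sl]
            kern = kern + (gammaln(nk[:, None] + gvec[None, :])
                           - gammaln(1.0 + gvec)[None, :]).sum(axis=0)
        kvals = _cache["k_grid"][sl]
    else:
        kvals = np.arange(kp, cap + 1)
        kern = step3_log_kernel(kvals, kp, nk, n, config)
    kern = kern - kern[np.isfinite(kern)].max() if np.isfinite(kern).any() else kern
    with np.errstate(invalid="ignore"):
        w = np.exp(kern)
    w[~np.isfinite(w)] = 0.0
    total = w.sum()
    if not total > 0:
        raise FloatingPointError(
            f"step-3 kernel has zero mass; K_plus={kp}, counts={nk}, "
            f"log-kernel={kern}")
    u = rng.uniform() * total
    return int(kvals[np.searchsorted(np.cumsum(w), u)])


def add_empty_components(state: MixtureState, config: MFMConfig,
                         rng: np.random.Generator, new_K: int,
                         b0: float) -> MixtureState:
    """Step 4: resize to ``new_K`` components; slots K_plus..K-1 get fresh
    parameters from the prior and zero counts."""
    kp = state.K_plus
    n_new = new_K - kp
    state.K = new_K
    state.means = np.concatenate([state.means[:kp],
                                  rng.normal(b0, np.sqrt(config.B0), size=n_new)])
    state.variances = np.concatenate([
        state.variances[:kp],
        1.0 / rng.gamma(shape=config.c0, scale=1.0 / config.C0, size=n_new)])
    state.counts = np.concatenate([state.counts[:kp],
                                   np.zeros(n_new, dtype=int)])
    state.weights = np.concatenate([state.weights[:kp], np.zeros(n_new)])
    return state


def update_weights(state: MixtureState, config: MFMConfig,
                   rng: np.random.Generator) -> MixtureState:
    """Step 5: weights ~ Dirichlet(gamma_K + N_1, ..., gamma_K + N_K) with
    gamma_K evaluated at the current K (drawn as normalized Gammas, which
    is robust for very small concentration parameters)."""
    alpha = config.gamma_K(state.K) + state.counts
    g = rng.gamma(shape=alpha)
    state.weights = g / g.sum()
    return state


# ---------------------------------------------------------------------
# the full run
# ---------------------------------------------------------------------

def initial_state(data: np.ndarray, config: MFMConfig,
                  rng: np.random.Generator) -> MixtureState:
    """Starting state: K_init components with equal weights, variances
    C0/2, and means at the centroids of a k-means fit (10 restarts)."""
    from sklearn.cluster import KMeans

    n = data.size
    # cannot start with more components than observations or than the
    # prior on K can ever support
    K0 = min(config.K_init, n, config.k_cap())
    if K0 > 1:
        km = KMeans(n_clusters=K0, n_init=10,
                    random_state=int(rng.integers(2**31)))
        km.fit(data[:, None])
        means = np.sort(km.cluster_centers_.ravel())
    else:
        means = np.array([float(np.mean(data))])
    return MixtureState(
        K=K0,
        weights=np.full(K0, 1.0 / K0),
        means=means,
        variances=np.full(K0, config.C0 / 2.0),
        assignments=np.zeros(n, dtype=int),
        counts=np.concatenate([[n], np.zeros(K0 - 1, dtype=int)]),
        K_plus=1,
    )


def _step3_cache(config: MFMConfig, n: int) -> dict:
    cap = config.k_cap()
    k_grid = np.arange(1, cap + 1, dtype=float)
    cache = {
        "k_grid": k_grid,
        "lfact": gammaln(np.arange(cap + 1, dtype=float) + 1.0),
        "log_pk": config.prior_k.logpmf(np.arange(1, cap + 1)),
    }
    if config.weight_mode == "static":
        g = config.weight_param
        cache["lg_kg"] = gammaln(k_grid * g) - gammaln(k_grid * g + n)
    return cache


def run_sampler(data, config: MFMConfig, store_params: bool = False,
                validate_every: int = 0) -> MFMTrace:
    """Run the telescoping sampler and return the retained trace.

    Parameters
    ----------
    data
        1-d array of observations.
    store_params
        If True, the filled components' means, variances and weights of
        every retained draw are kept on the trace (``trace.params``).
    validate_every
        If positive, run internal state consistency checks every that
        many sweeps (for tests; slows the run down).
    """
    y = np.asarray(data, dtype=float).ravel()
    if y.size == 0 or not np.all(np.isfinite(y)):
        raise ValueError("data must be non-empty and finite")
    rng = np.random.default_rng(config.seed)
    state = initial_state(y, config, rng)
    b0 = config.b0 if config.b0 is not None else 0.5 * (y.min() + y.max())
    cache = _step3_cache(config, y.size)

    n_keep = (config.n_iter + config.thinning - 1) // config.thinning
    it_out = np.empty(n_keep, dtype=int)
    k_out = np.empty(n_keep, dtype=int)
    kp_out = np.empty(n_keep, dtype=int)
    counts_out: list = []
    params: dict | None = (
        {"means": [], "variances": [], "weights": []} if store_params else None)

    t0 = time.perf_counter()
    kept = 0
    total = config.burn_in + config.n_iter
    for it in range(total):
        update_assignments(state, y, rng)
        count_and_relabel(state)
        update_filled_components(state, y, config, rng)
        new_K = sample_K_given_partition(state, config, rng, _cache=cache)
        add_empty_components(state, config, rng, new_K, b0)
        update_weights(state, config, rng)
        if validate_every and it % validate_every == 0:
            state.validate(y.size)
        post = it - config.burn_in
        if post >= 0 and post % config.thinning == 0:
            it_out[kept] = it
            k_out[kept] = state.K
            kp_out[kept] = state.K_plus
            counts_out.append(tuple(sorted(state.counts[: state.K_plus],
                                           reverse=True)))
            if params is not None:
                params["means"].append(state.means[: state.K_plus].copy())
                params["variances"].append(state.variances[: state.K_plus].copy())
                params["weights"].append(state.weights[: state.K_plus].copy())
            kept += 1

    meta = {"config": config.to_dict(), "seed": config.seed,
            "K_cap": config.k_cap(), "n": int(y.size),
            "runtime_s": time.perf_counter() - t0}
    return MFMTrace(it_out[:kept], k_out[:kept], kp_out[:kept],
                    counts_out, meta, params)
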