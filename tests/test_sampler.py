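"""Telescoping sampler: per-step conditionals, kernel, full-run contracts."""

import math

import numpy as np
import pytest
from scipy import stats

from mfmix.priors import point_mass_k, uniform_k
from mfmix.sampler import (MFMConfig, MixtureState, add_empty_components,
                           count_and_relabel, initial_state, run_sampler,
                           sample_K_given_partition, step3_log_kernel,
                           update_assignments, update_filled_components,
                           update_weights)


def make_state(K, weights, means, variances, assignments):
    assignments = np.asarray(assignments, dtype=int)
    counts = np.bincount(assignments, minlength=K)
    return MixtureState(K=K, weights=np.asarray(weights, float),
                        means=np.asarray(means, float),
                        variances=np.asarray(variances, float),
                        assignments=assignments, counts=counts,
                        K_plus=int((counts > 0).sum()))


BASE_CFG = dict(prior_k=uniform_k(30), weight_mode="static",
                weight_param=1.0, b0=0.0, B0=100.0, c0=2.0, C0=1.0,
                n_iter=100, burn_in=10, thinning=1, K_init=5, seed=0)


# ---------------------------------------------------------------- step 1
def test_assignments_single_component(rng):
    s = make_state(1, [1.0], [0.0], [1.0], np.zeros(10, int))
    update_assignments(s, rng.normal(size=10), rng)
    assert np.all(s.assignments == 0)


def test_assignments_separation_limit(rng):
    s = make_state(2, [0.5, 0.5], [0.0, 100.0], [1.0, 1.0], np.zeros(50, int))
    update_assignments(s, np.zeros(50), rng)
    assert np.all(s.assignments == 0)


def test_assignments_symmetric_components(rng):
    s = make_state(2, [0.5, 0.5], [1.0, 1.0], [2.0, 2.0],
                   np.zeros(20_000, int))
    update_assignments(s, np.ones(20_000), rng)
    frac = s.assignments.mean()
    assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(20_000)


def test_assignments_degenerate_weights_raise(rng):
    s = make_state(2, [0.0, 0.0], [0.0, 1.0], [1.0, 1.0], np.zeros(3, int))
    s.weights = np.zeros(2)  # invalid on purpose
    with pytest.raises(FloatingPointError):
        update_assignments(s, np.zeros(3), rng)


# ------------------------------------------------------- count & relabel
def test_relabel_textbook_partition():
    # S = (2,1,1,2,1,2,1,1,1,1) on K=3 components, 1-based: the third
    # component is empty, so K_plus = 2
    s1 = np.array([2, 1, 1, 2, 1, 2, 1, 1, 1, 1]) - 1
    s = make_state(3, [0.2, 0.3, 0.5], [0., 1., 2.], [1., 1., 1.], s1)
    count_and_relabel(s)
    assert s.K_plus == 2
    groups = [set(np.nonzero(s.assignments == k)[0] + 1) for k in range(2)]
    assert groups == [{2, 3, 5, 7, 8, 9, 10}, {1, 4, 6}]
    # empty component moved last, parameters carried along
    assert s.counts.tolist() == [7, 3, 0]
    assert s.means.tolist() == [0.0, 1.0, 2.0]


def test_relabel_all_in_first_component():
    s = make_state(3, [0.2, 0.3, 0.5], [0., 1., 2.], [1., 1., 1.],
                   np.zeros(6, int))
    count_and_relabel(s)
    assert s.K_plus == 1 and s.counts.tolist() == [6, 0, 0]
    assert s.means.tolist() == [0.0, 1.0, 2.0]


def test_relabel_identity_when_all_filled():
    s = make_state(3, [0.2, 0.3, 0.5], [0., 1., 2.], [1., 1., 1.],
                   np.array([0, 1, 2, 0, 1, 2]))
    before = s.assignments.copy()
    count_and_relabel(s)
    assert np.all(s.assignments == before)
    assert s.means.tolist() == [0.0, 1.0, 2.0]


# ---------------------------------------------------------------- step 2
def test_filled_update_posterior_moments(rng):
    """The precision draw is Gamma(c0 + N_k/2, C0 + 0.5 sum dev^2) and the
    mean draw is Normal(b_k, B_k): check both against their closed-form
    moments by repeated draws from a frozen state."""
    y = rng.normal(2.0, 1.0, size=10)
    cfg = MFMConfig(**BASE_CFG)
    mu0 = 1.5
    precs, mus = [], []
    for _ in range(4000):
        s = make_state(1, [1.0], [mu0], [4.0], np.zeros(10, int))
        update_filled_components(s, y, cfg, rng)
        precs.append(1.0 / s.variances[0])
        mus.append(s.means[0])
    shape = cfg.c0 + 5.0  # c_k = 2 + 10/2 = 7
    rate = cfg.C0 + 0.5 * np.sum((y - mu0) ** 2)
    assert shape == 7.0
    pm = shape / rate
    psd = np.sqrt(shape) / rate
    assert abs(np.mean(precs) - pm) < 4 * psd / np.sqrt(4000)
    # mean-update moments, marginalizing over the drawn precision
    Bk = 1.0 / (1.0 / cfg.B0 + 10 * np.asarray(precs))
    bk = Bk * (cfg.b0 / cfg.B0 + np.asarray(precs) * y.sum())
    assert abs(np.mean(mus) - np.mean(bk)) < 4 * np.std(mus) / np.sqrt(4000)


def test_filled_update_flat_prior_centers_on_cluster_mean(rng):
    y = rng.normal(-3.0, 0.5, size=200)
    cfg = MFMConfig(**{**BASE_CFG, "B0": 1e12})
    draws = []
    for _ in range(2000):
        s = make_state(1, [1.0], [y.mean()], [0.25], np.zeros(200, int))
        update_filled_components(s, y, cfg, rng)
        draws.append(s.means[0])
    se = np.std(draws) / np.sqrt(2000)
    assert abs(np.mean(draws) - y.mean()) < 3 * se


def test_filled_update_rejects_empty_component(rng):
    s = make_state(2, [0.5, 0.5], [0., 1.], [1., 1.], np.zeros(4, int))
    s.K_plus = 2  # claim two filled although component 2 is empty
    with pytest.raises(AssertionError):
        update_filled_components(s, np.zeros(4), MFMConfig(**BASE_CFG), rng)


# ---------------------------------------------------------------- step 3
def direct_kernel(K, K_plus, counts, n, gamma, prior):
    """Literal product evaluation of p(K | partition), no log tricks."""
    val = (math.factorial(K) / math.factorial(K - K_plus)
           * math.gamma(K * gamma) / math.gamma(K * gamma + n)
           * prior.pmf(K))
    for nk in counts:
        val *= math.gamma(nk + gamma) / math.gamma(1 + gamma)
    return val


def test_step3_log_kernel_matches_direct_product():
    prior = uniform_k(15)
    cfg = MFMConfig(**{**BASE_CFG, "prior_k": prior})
    for counts in ([7, 3], [12, 5, 3], [1, 1, 1, 1]):
        counts = np.array(counts, float)
        kp = counts.size
        n = int(counts.sum())
        ks = np.arange(kp, 16)
        kern = step3_log_kernel(ks, kp, counts, n, cfg)
        direct = np.array([direct_kernel(int(K), kp, counts, n, 1.0, prior)
                           for K in ks])
        np.testing.assert_allclose(np.exp(kern), direct, rtol=1e-8)


def test_step3_point_mass_prior():
    cfg = MFMConfig(**{**BASE_CFG, "prior_k": point_mass_k(5)})
    rng = np.random.default_rng(0)
    s = make_state(3, [0.3, 0.3, 0.4], [0., 1., 2.], [1., 1., 1.],
                   np.array([0, 1, 2, 0]))
    assert all(sample_K_given_partition(s, cfg, rng) == 5 for _ in range(20))


def test_step3_sampled_distribution_matches_enumeration(rng):
    """Empirical law of the sampled K vs. brute-force normalization of
    the literal kernel (K_plus=2, n=10, counts (7,3), gamma=1, U(1,30))."""
    prior = uniform_k(30)
    cfg = MFMConfig(**{**BASE_CFG, "prior_k": prior})
    s = make_state(2, [0.7, 0.3], [0., 1.], [1., 1.],
                   np.array([0] * 7 + [1] * 3))
    draws = np.array([sample_K_given_partition(s, cfg, rng)
                      for _ in range(20_000)])
    ks = np.arange(2, 31)
    target = np.array([direct_kernel(int(K), 2, [7, 3], 10, 1.0, prior)
                       for K in ks])
    target /= target.sum()
    obs = np.bincount(draws, minlength=31)[2:]
    keep = target * 20_000 >= 5
    o = np.append(obs[keep], obs[~keep].sum())
    e = np.append(target[keep], target[~keep].sum()) * 20_000
    stat = ((o - e) ** 2 / e).sum()
    assert stats.chi2.sf(stat, df=o.size - 1) > 0.01
    assert draws.min() >= 2  # support constraint K >= K_plus


# ------------------------------------------------------------- steps 4-5
def test_add_empty_components_counts_and_noop(rng):
    cfg = MFMConfig(**BASE_CFG)
    s = make_state(2, [0.6, 0.4], [0., 1.], [1., 1.], np.array([0, 1]))
    add_empty_components(s, cfg, rng, new_K=2, b0=0.0)
    assert s.K == 2 and s.counts.tolist() == [1, 1]
    add_empty_components(s, cfg, rng, new_K=5, b0=0.0)
    assert s.K == 5
    assert s.counts.tolist() == [1, 1, 0, 0, 0]
    assert np.all(s.weights[2:] == 0)


def test_added_parameters_follow_their_priors(rng):
    cfg = MFMConfig(**BASE_CFG)
    mus, precs = [], []
    for _ in range(4000):
        s = make_state(1, [1.0], [0.], [1.], np.zeros(2, int))
        add_empty_components(s, cfg, rng, new_K=3, b0=cfg.b0)
        mus.extend(s.means[1:])
        precs.extend(1.0 / s.variances[1:])
    assert stats.kstest(mus, stats.norm(cfg.b0, np.sqrt(cfg.B0)).cdf
                        ).pvalue > 0.01
    assert stats.kstest(precs, stats.gamma(a=cfg.c0, scale=1 / cfg.C0).cdf
                        ).pvalue > 0.01


def test_weights_single_component(rng):
    cfg = MFMConfig(**BASE_CFG)
    s = make_state(1, [1.0], [0.], [1.], np.zeros(5, int))
    update_weights(s, cfg, rng)
    assert s.weights[0] == pytest.approx(1.0)


def test_weight_mean_for_empty_component(rng):
    # K=2, N=(n,0), gamma=1: eta_2 ~ Beta(1, n+1), mean 1/(n+2)
    cfg = MFMConfig(**BASE_CFG)
    n = 8
    draws = []
    for _ in range(100_000):
        s = make_state(2, [0.5, 0.5], [0., 1.], [1., 1.], np.zeros(n, int))
        update_weights(s, cfg, rng)
        draws.append(s.weights[1])
    mean = 1.0 / (n + 2)
    se = np.sqrt(mean * (1 - mean) / 100_000)  # conservative
    assert abs(np.mean(draws) - mean) < 3 * se


def test_weights_symmetric_dirichlet(rng):
    cfg = MFMConfig(**{**BASE_CFG, "weight_param": 10.0})
    s = make_state(3, np.ones(3) / 3, np.zeros(3), np.ones(3),
                   np.array([], dtype=int))
    s.counts = np.zeros(3, dtype=int)
    s.K_plus = 0
    acc = np.zeros(3)
    reps = 20_000
    for _ in range(reps):
        update_weights(s, cfg, rng)
        acc += s.weights
    sd = np.sqrt((1 / 3) * (2 / 3) / 31)  # Dirichlet(10) marginal sd
    assert np.all(np.abs(acc / reps - 1 / 3) < 3 * sd / np.sqrt(reps))


# ------------------------------------------------------------- full runs
def test_same_seed_reproduces_trace(galaxy_like):
    y, _ = galaxy_like
    cfg = MFMConfig(prior_k=uniform_k(30), weight_param=1.0, B0=630.0,
                    C0=12.5, n_iter=400, burn_in=50, thinning=2, seed=99)
    t1 = run_sampler(y, cfg)
    t2 = run_sampler(y, cfg)
    assert np.array_equal(t1.K, t2.K)
    assert np.array_equal(t1.K_plus, t2.K_plus)
    assert t1.filled_counts == t2.filled_counts


def test_trace_invariants(galaxy_like):
    y, _ = galaxy_like
    cfg = MFMConfig(prior_k=uniform_k(30), weight_param=1.0, B0=630.0,
                    C0=12.5, n_iter=300, burn_in=30, thinning=3, seed=5)
    trace = run_sampler(y, cfg, validate_every=7)
    assert len(trace) == 100
    assert np.all(trace.K >= trace.K_plus)
    assert all(sum(c) == y.size for c in trace.filled_counts)
    assert trace.meta["K_cap"] == 30


def test_run_sampler_input_validation(galaxy_like):
    y, _ = galaxy_like
    cfg = MFMConfig(**BASE_CFG)
    with pytest.raises(ValueError):
        run_sampler(np.array([1.0, np.nan]), cfg)
    with pytest.raises(ValueError):
        run_sampler(np.array([]), cfg)
    with pytest.raises(ValueError):
        MFMConfig(**{**BASE_CFG, "burn_in": 100, "n_iter": 100})


def test_kmeans_initialization_state(galaxy_like):
    y, _ = galaxy_like
    cfg = MFMConfig(**{**BASE_CFG, "K_init": 10, "C0": 5.0})
    s = initial_state(y, cfg, np.random.default_rng(0))
    assert s.K == 10
    assert np.allclose(s.weights, 0.1)
    assert np.allclose(s.variances, 2.5)  # C0 / 2
    s.validate(y.size)


def test_initial_components_capped_by_n_and_prior():
    cfg = MFMConfig(**{**BASE_CFG, "prior_k": point_mass_k(1), "K_init": 10})
    s = initial_state(np.arange(20.0), cfg, np.random.default_rng(0))
    assert s.K == 1
    s2 = initial_state(np.arange(3.0), MFMConfig(**{**BASE_CFG, "K_init": 8}),
                       np.random.default_rng(0))
    assert s2.K == 3


def conjugate_gibbs_oracle(y, cfg, n_draws, seed):
    """Independent single-component Gibbs sampler for the Normal model
    with independent Normal(b0, B0) mean and Gamma(c0, C0) precision."""
    rng = np.random.default_rng(seed)
    n = y.size
    mu, prec = y.mean(), 1.0
    out = np.empty((n_draws, 2))
    for i in range(n_draws):
        prec = rng.gamma(cfg.c0 + n / 2,
                         1.0 / (cfg.C0 + 0.5 * np.sum((y - mu) ** 2)))
        B = 1.0 / (1.0 / cfg.B0 + n * prec)
        mu = rng.normal(B * (cfg.b0 / cfg.B0 + prec * y.sum()), np.sqrt(B))
        out[i] = mu, 1.0 / prec
    return out


def test_point_mass_prior_reduces_to_conjugate_gibbs(rng):
    """With P(K=1)=1 the telescoping sampler is a single-component Gibbs
    sampler; its (mu, sigma^2) draws must match the stand-alone oracle."""
    y = rng.normal(1.0, 2.0, size=150)
    cfg = MFMConfig(prior_k=point_mass_k(1), weight_param=1.0, b0=0.0,
                    B0=25.0, c0=2.0, C0=2.0, n_iter=6000, burn_in=500,
                    thinning=3, K_init=1, seed=314)
    trace = run_sampler(y, cfg, store_params=True)
    assert np.all(trace.K_plus == 1)
    mus = np.array([m[0] for m in trace.params["means"]])
    s2s = np.array([v[0] for v in trace.params["variances"]])
    oracle = conjugate_gibbs_oracle(y, cfg, 2000, seed=2718)
    assert stats.ks_2samp(mus, oracle[:, 0]).pvalue > 0.01
    assert stats.ks_2samp(s2s, oracle[:, 1]).pvalue > 0.01


def test_prior_reproduction_geweke_style():
    """Successive-conditional check: alternating a full sampler sweep with
    regeneration of the data from the current state must leave the prior
    on K invariant (tiny instance: n=5, K <= 10)."""
    from mfmix.sampler import _step3_cache
    prior = uniform_k(10)
    cfg = MFMConfig(prior_k=prior, weight_mode="static", weight_param=1.0,
                    b0=0.0, B0=4.0, c0=2.0, C0=1.0, n_iter=10, burn_in=0,
                    thinning=1, K_init=3, seed=0)
    rng = np.random.default_rng(424242)
    n = 5
    K = int(prior.sample(rng, 1)[0])
    alpha = np.full(K, 1.0)
    g = rng.gamma(alpha)
    state = MixtureState(
        K=K, weights=g / g.sum(), means=rng.normal(0.0, 2.0, K),
        variances=1.0 / rng.gamma(2.0, 0.5, K),
        assignments=np.zeros(n, int), counts=np.zeros(K, int), K_plus=0)
    state.counts[0] = n
    state.K_plus = 1
    cache = _step3_cache(cfg, n)
    y = state.means[0] + np.sqrt(state.variances[0]) * rng.normal(size=n)
    ks = []
    for sweep in range(40_000):
        update_assignments(state, y, rng)
        count_and_relabel(state)
        update_filled_components(state, y, cfg, rng)
        newK = sample_K_given_partition(state, cfg, rng, _cache=cache)
        add_empty_components(state, cfg, rng, newK, b0=0.0)
        update_weights(state, cfg, rng)
        y = (state.means[state.assignments]
             + np.sqrt(state.variances[state.assignments])
             * rng.normal(size=n))
        ks.append(state.K)
    ks = np.asarray(ks[2000:])
    mean, var = prior.moments()
    # effective sample size deflated for chain autocorrelation
    assert abs(ks.mean() - mean) < 4 * np.sqrt(var / (ks.size / 20))
    pk = np.bincount(ks, minlength=11)[1:] / ks.size
    assert np.abs(pk - 0.1).max() < 0.02
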