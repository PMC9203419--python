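# Methods

## Model

`mfmix` fits univariate Gaussian mixtures of finite mixtures (MFM): the
number of components `K` is itself a parameter with prior `p(K)`, the
weights given `K` follow a symmetric Dirichlet with parameter `gamma_K`,
and each component has an independent `N(b0, B0)` prior on its mean and a
`Gamma(c0, C0)` prior on its precision (rate parameterization; prior mean
of the precision is `c0/C0`). The independence prior — rather than the
conjugate normal-gamma coupling — is used so that the spread of a
component's mean does not depend on its variance.

The scientific target is the number of *data clusters* `K+`: the number
of components with at least one observation assigned. A mixture can have
empty components, so the posterior of `K+` (its mode, and its entropy as
a measure of decisiveness) — not the posterior of `K` — answers "how many
clusters are in this sample".

Two weight regimes are supported:

* **static**: `gamma_K = gamma` for every `K`. The effective prior
  sample size `K * gamma` grows with `K`.
* **dynamic**: `gamma_K = alpha / K`. The prior sample size stays
  `alpha`; large-`K` mixtures get very small concentration, which nests
  Dirichlet-process-like behavior and induces sparser `K+`.

## Priors on K

Four families, all on `K >= 1`, with parameterizations pinned by their
moment pairs (checked in the tests):

| family | convention | E[K], V[K] at the canonical parameters |
|---|---|---|
| `uniform(1, B)` | equiprobable on `{1..B}` | 15.5, 74.9 at B = 30 |
| `truncated_poisson(rate)` | *zero-truncated* Poisson, no upper cap | 3.16, 2.66 at rate 3 |
| `shifted_geometric(p)` | `K - 1 ~ Geom(p)` (failures before success), so `P(K=1) = p` | 10, 90 at p = 0.1 |
| `shifted_bnb(n, a, b)` | `K - 1` beta-negative-binomial | 2, 4 at (1, 4, 3) |

Unbounded supports are enumerated up to cumulative mass `1 - 1e-12`
wherever a finite grid is needed (induced-prior marginalization, the
sampler's step-3 support); the cap is recorded in run metadata. For the
simulation-scale design the uniform prior bound is raised to 100; since
`K >= 1` structurally, "uniform up to 100" is read as uniform on
`{1, ..., 100}`.

## Induced prior on K+

Given `K`, the occupancy of the `K` cells after `n` Dirichlet-multinomial
draws determines `K+`. Two routes are implemented and cross-validated:

* **exact**: `P(K+ = j | K) = C(K, j) * G(K g)/G(K g + n) * n! * S_j(n)`
  where `S_j(n)` sums `prod_k G(N_k + g) / (G(g) N_k!)` over positive
  compositions of `n` into `j` parts — a `j`-fold convolution computed by
  dynamic programming, with the terms rescaled by their maximum so the
  recursion stays in normal float range even for `g ~ 1e-6`;
* **monte_carlo**: direct simulation of weights and assignments
  (vectorized within groups of equal `K`); fewer than 1000 replications
  are rejected as meaninglessly noisy.

The induced prior marginalizes the exact kernel over the truncated
support of `p(K)`. The exact recursion is verified in the tests against
full composition enumeration under scipy's Dirichlet-multinomial pmf and
against an assignment-level Polya-urn enumeration at tiny sizes.

## Telescoping sampler

One sweep: (1) categorical assignment updates; relabeling moves filled
components to the leading slots with their relative order preserved
(any stable scheme is valid — all reported summaries are
label-invariant); (2) conjugate updates of filled components, precision
first with `c_k = c0 + N_k/2`, `C_k = C0 + 0.5 * sum (y_i - mu_k)^2`,
then the mean given the new precision with
`B_k = (B0^{-1} + N_k / sigma_k^2)^{-1}`,
`b_k = B_k (b0/B0 + N_k ybar_k / sigma_k^2)`; (3) a draw of `K` from

```
p(K | partition) ∝ K!/(K-K+)! * G(K g_K)/G(K g_K + n)
                   * prod_{k<=K+} G(N_k + g_K)/G(1 + g_K) * p(K)
```

evaluated in log-gamma arithmetic over `K = K+ .. cap` (the `n` in the
Dirichlet-multinomial normalizer is the sample size); (4) fresh
parameters from the prior for the `K - K+` empty components, drawn every
sweep; (5) a Dirichlet weight update with parameters `gamma_K + N_k`,
with `gamma_K` evaluated at the current `K`.

Defaults mirror the standard long-run protocol: 200,000 post-burn-in
sweeps, 10,000 burn-in, thinning 4, 10 initial components with equal
weights, variances `C0/2`, and means at k-means centroids (10 restarts,
seeded from the run seed; the initial component count is truncated to
`min(K_init, n, cap)`). The first operation of a run is the assignment
update. How k-means breaks ties on duplicate data values is
implementation-defined (scikit-learn's behavior).

Numerical choices:

* all density and kernel arithmetic in log space; the categorical
  assignment draw uses row-wise inverse-CDF sampling, skipping terms more
  than 60 nats below the row maximum (such terms cannot change a float64
  cumulative sum, so this is not an approximation in double precision);
  a numba kernel accelerates this when numba is importable, with an
  equivalent numpy path otherwise;
* Dirichlet draws are built from Gamma variates directly, which is
  well-behaved for concentrations as small as `alpha/K ~ 1e-6` (an empty
  component's weight may underflow to exactly zero; its log-weight of
  `-inf` is handled by the log-space assignment step);
* under dynamic weights the conditional of `K` has a heavy right tail
  (the kernel behaves like `K^{K+} p(K)` for large `K`), so with a
  heavy-tailed prior on `K` the sampled `K` routinely reaches the
  hundreds while `K+` stays small — this is correct model behavior, and
  the per-sweep cost scales with the sampled `K`.

## Posterior summaries

`K+` posterior = relative frequencies over retained draws. The mode
breaks ties toward the *smallest* `K+` (the sparser answer; the
convention is ours and propagates into the averaged tables). Entropy is
Shannon entropy in nats over the observed support with `0 log 0 = 0`;
a uniform posterior over 30 values gives `log 30 ≈ 3.40`.

## EM + BIC baseline

Hand-rolled EM for equal- and unequal-variance univariate Gaussian
mixtures: Ward hierarchical-clustering initialization plus 5 random
restarts per `(K, model)`, relative log-likelihood tolerance `1e-8`,
at most 1000 iterations, and a variance floor of `1e-6` times the sample
variance against singleton collapse (a floored component flags the fit
as degenerate rather than raising). Under the equal-variance model the
initial per-cluster variances are pooled so the first constrained M-step
cannot decrease the likelihood. `BIC = -2 loglik + p log n` with
`p = (K-1) + K + 1` (equal) or `(K-1) + 2K` (unequal); selection
minimizes BIC over `K = 1..15` and, optionally, over both variance
models. The reference maximum-likelihood software the baseline emulates
uses its own initialization heuristics, so agreement is claimed at the
level of selected-`K` quantiles over replicates, not per-data-set; the
tests cross-check converged log-likelihoods against scikit-learn's EM.

## Synthetic data

Both benchmark generators produce four clusters with *fixed* sizes
`(5, 55, 30, 10) * scale` (not multinomial draws — a multinomial option
exists but is off by default), shuffled after concatenation:

* `gaussian4`: means (9.5, 20, 24.5, 33), sds (0.25, 1, 1, 0.5) — the
  well-specified case;
* `uniform4`: bounds (9,10), (18,22), (22,27), (32,34) — four clear
  clusters whose shape misspecifies a Gaussian component model.

These emulate a Galaxy-velocity-like sample: small/large/medium/small
groups, one tight low cluster and one tight high cluster. They do not
emulate outliers, skewness, ties from rounding, or multivariate
structure, so passing tests speak to cluster-number recovery under clean
separation, not to robustness on messy real data. The real 82-point
velocity data set is accepted as an ordinary single-column input but is
deliberately not bundled.

## Sensitivity harness

The benchmark design crosses 4 priors on `K` x {static, dynamic} x
Dirichlet parameter {0.01, 1, 10} x `B0` in {6.3, 20, 100, 630} x `C0` in
{0.5, 1, 5, 12.5} (`b0` = data midpoint, `c0 = 2`): 384 cells. The
simulation design restricts `B0` to {6.3, 630} and `C0` to {0.5, 12.5}
(96 cells). Per-cell seeds are derived as `crc32(master_seed | cell_id |
replicate)`, recorded per cell; with an output directory each finished
cell is persisted as JSON and skipped on restart, and a failing cell is
recorded with its error while the run continues. Marginal tables average
the per-cell posterior modes over all other factors; panels order the
priors by `E[K^2] = E[K]^2 + V[K]`.

## Problem sizes used in the checked runs

The test suite runs desk-scale versions chosen to make the qualitative
conclusions reproducible in minutes on one core: 20,000 post-burn-in
sweeps (2,000 burn-in, thinning 4) for single fits; 10 replicates for
the misspecification behavior (static `gamma = 1`, `C0 = 12.5`,
`B0 = 630`, BNB(1,4,3) prior — one representative cell of the regime in
which five clusters are found instead of four); 20 replicates for the
EM + BIC median; a 16-cell reduced design on one misspecified n = 1000
data set for the qualitative marginal orderings (mean estimated clusters
decreasing in `C0`, dynamic below static). Full-length replication runs
use the library defaults via `mfmix experiment`.

## Known limitations

Univariate Gaussian components only; no split–merge or reversible-jump
moves (mixing in `K+` relies on empty-component births, which can be
slow when `gamma` is large and all components stay filled); no
hyperpriors on `C0` or shrinkage priors on the means; no marginal
likelihood estimation; partitions themselves are summarized only through
`K+` (no point-estimate partition or co-clustering matrix).
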