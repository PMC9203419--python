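# mfmix

Bayesian model-based clustering of univariate data with **mixtures of
finite mixtures** (MFM): a finite Gaussian mixture whose number of
components `K` carries its own prior, fitted with a **telescoping Gibbs
sampler**. The package is aimed at statisticians who want to know *how
many data clusters* a sample supports — and how strongly that answer
depends on the prior specification.

## The model

For observations `y_1, ..., y_n`:

```
K               ~ p(K)                       (uniform, zero-truncated Poisson,
                                              shifted geometric, or shifted
                                              beta-negative-binomial)
eta | K         ~ Dirichlet_K(gamma_K)       (static: gamma_K = gamma;
                                              dynamic: gamma_K = alpha / K)
S_i | eta       ~ Categorical(eta)
mu_k            ~ N(b0, B0)                  (independence prior)
sigma_k^{-2}    ~ Gamma(c0, C0)
y_i | S_i = k   ~ N(mu_k, sigma_k^2)
```

The key distinction is between `K`, the number of components, and
`K+`, the number of **filled** components — only those correspond to data
clusters. The sampler alternates (1) assignment updates, (2) conjugate
updates of the filled components, (3) an explicit draw of `K` from
`p(K | partition)` on `{K+, K+ + 1, ...}`, (4) fresh empty components from
the prior, and (5) a Dirichlet weight update. All summaries are
label-invariant, so no label-switching post-processing is needed. The
headline outputs are the posterior of `K+`, its mode (the cluster-number
estimate) and its entropy (how decisive that posterior is).

Also included: the **induced prior on `K+`** implied by `p(K)`, the
Dirichlet parameter and `n` (exact dynamic-programming recursion plus a
Monte-Carlo sampler); an **EM + BIC** maximum-likelihood baseline with
equal/unequal variance models; benchmark **synthetic data generators**
(4-component Gaussian and uniform mixtures with fixed cluster sizes
5/55/30/10 per 100 observations); and a **full-factorial sensitivity
harness** crossing priors on `K`, weight modes, Dirichlet parameters and
the component-prior parameters `B0`, `C0`.

## Worked example

```python
from mfmix import (GAUSSIAN4, MFMConfig, generate, run_sampler,
                   shifted_bnb_k, summarize_trace)

y, _ = generate(GAUSSIAN4.with_scale(10), seed=7)   # n = 1000, 4 clusters

config = MFMConfig(prior_k=shifted_bnb_k(1, 4, 3),
                   weight_mode="dynamic", weight_param=0.01,
                   B0=630.0, C0=12.5,
                   n_iter=20_000, burn_in=2_000, thinning=4, seed=1)
summary = summarize_trace(run_sampler(y, config))
print(summary.pmf.as_dict(), summary.mode, round(summary.entropy, 3))
```

prints

```
{4: 0.998, 5: 0.002} 4 0.016
```

i.e. the posterior of the number of data clusters puts 99.8% of its mass
on the true value 4, the mode-based point estimate is 4, and the entropy
0.016 nats says the posterior is nearly a point mass. The
`examples/` directory holds one short script per capability (priors on
`K`, induced `K+` prior, sampler fit, EM + BIC baseline, sensitivity
design); each prints a small table and a note on how to read it. A thin
CLI mirrors the library: `mfmix simulate | prior-kplus | fit | summarize |
mlfit | experiment`.

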