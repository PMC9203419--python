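"""Maximum-likelihood baseline: EM with BIC selection of K.

Fits univariate Gaussian mixtures for K = 1..15 by EM on one draw of the
4-cluster Gaussian benchmark (n = 1000) and selects K by minimum BIC,
under the unequal-variance and the equal-variance model.
"""

from mfmix import GAUSSIAN4, generate, select_K_bic

y, _ = generate(GAUSSIAN4.with_scale(10), seed=3)

for approach in ("unequal", "equal"):
    fit = select_K_bic(y, range(1, 16), approach, restarts=5, rng=0)
    print(f"{approach:8s} variances: selected K = {fit.K:2d} "
          f"(BIC = {fit.bic:9.2f}, loglik = {fit.loglik:9.2f})")

# The unequal-variance model recovers the true K = 4.  Forcing equal
# variances misfits the narrow and wide clusters and BIC compensates
# with extra components — the classic overestimation of the baseline.
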