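"""The menu of priors on the number of components K.

Prints the mean and variance of each prior and a tail probability, the
quantities that drive how strongly each prior favors few components.
"""

from mfmix import (shifted_bnb_k, shifted_geometric_k, truncated_poisson_k,
                   uniform_k)

priors = [uniform_k(30), truncated_poisson_k(3.0),
          shifted_geometric_k(0.1), shifted_bnb_k(1, 4, 3)]

print(f"{'prior':38s} {'E[K]':>7s} {'V[K]':>7s} {'P(K>10)':>9s}")
for prior in priors:
    mean, var = prior.moments()
    print(f"{str(prior):38s} {mean:7.2f} {var:7.2f} "
          f"{prior.tail_prob(10):9.5f}")

# The uniform prior is flat up to 30 and expects 15.5 components; the
# truncated Poisson concentrates tightly around 3 (P(K > 10) < 0.001);
# the shifted geometric is diffuse; the shifted BNB expects 2 components
# but keeps a heavy tail.  The sampler treats these interchangeably.
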