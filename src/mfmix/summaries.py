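"""Posterior summaries of the number of data clusters.

The headline quantities of a mixture-of-finite-mixtures fit are the
posterior distribution of the number of filled components K+, its mode
(the point estimate of the number of data clusters) and its Shannon
entropy (how concentrated that posterior is; 0 for a point mass, log m
for a uniform distribution over m values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kplus import KPlusDistribution

__all__ = ["PosteriorKPlusSummary", "kplus_posterior", "mode_kplus",
           "entropy", "summarize_trace"]


@dataclass
class PosteriorKPlusSummary:
    pmf: KPlusDistribution
    mode: int
    entropy: float


def kplus_posterior(trace) -> KPlusDistribution:
    """Relative frequencies of K+ over the retained draws.

    ``trace`` may be an MFMTrace or any sequence of integer K+ values.
    """
    kp = np.asarray(getattr(trace, "K_plus", trace), dtype=int)
    if kp.size == 0:
        raise ValueError("empty trace")
    values, counts = np.unique(kp, return_counts=True)
    m = int(kp.size)
    probs = counts / m
    n = getattr(trace, "meta", {}).get("n", 0) if hasattr(trace, "meta") else 0
    return KPlusDistribution(values, probs, n=n, provenance="posterior",
                             meta={"draws": m})


def mode_kplus(pmf: KPlusDistribution) -> int:
    """Posterior mode of K+; ties broken toward the smallest value, which
    favors the sparser clustering.  Tie events are logged."""
    best = pmf.probs.max()
    tied = pmf.support[pmf.probs >= best - 0.0]
    if tied.size > 1:
        logging.getLogger(__name__).info(
            "K+ posterior mode tied among %s; reporting the smallest",
            tied.tolist())
    return int(tied.min())


def entropy(pmf: KPlusDistribution) -> float:
    """Shannon entropy in nats, with 0 log 0 = 0, computed over the
    observed support."""
    return pmf.entropy()


def summarize_trace(trace) -> PosteriorKPlusSummary:
    pmf = kplus_posterior(trace)
    return PosteriorKPlusSummary(pmf, mode_kplus(pmf), entropy(pmf))
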