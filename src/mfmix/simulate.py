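"""Synthetic univariate mixture data with fixed cluster sizes.

The two built-in generating processes emulate a Galaxy-like velocity
sample: four well/moderately separated groups of very unequal sizes
(5, 55, 30, 10 per 100 observations), drawn either from Gaussian
components — the well-specified case for a Gaussian mixture model — or
from uniform components with matching locations, which misspecifies the
component distribution while keeping four clear data clusters.

Cluster sizes are fixed counts, not multinomial draws: every generated
data set contains exactly ``size * scale`` observations per component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DGPSpec", "generate", "paper_dgps", "GAUSSIAN4", "UNIFORM4"]


@dataclass(frozen=True)
class DGPSpec:
    """A univariate mixture data-generating process with fixed cluster sizes.

    ``component_params`` holds one ``(mean, sd)`` pair per component for
    ``family="gaussian"``, or ``(lower, upper)`` bounds for
    ``family="uniform"``.  Component k contributes exactly
    ``cluster_sizes[k] * scale`` observations.
    """

    family: str
    component_params: tuple
    cluster_sizes: tuple
    scale: int = 1
    name: str = ""
    #: draw the cluster sizes from a multinomial instead of fixing them
    random_sizes: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "uniform"):
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.component_params) != len(self.cluster_sizes):
            raise ValueError("one parameter pair per cluster size required")
        if any(s < 1 for s in self.cluster_sizes) or self.scale < 1:
            raise ValueError("cluster sizes and scale must be positive")
        if self.family == "uniform":
            if any(lo >= hi for lo, hi in self.component_params):
                raise ValueError("uniform bounds need lower < upper")
        else:
            if any(sd <= 0 for _, sd in self.component_params):
                raise ValueError("standard deviations must be positive")

    @property
    def n_components(self) -> int:
        return len(self.cluster_sizes)

    @property
    def n(self) -> int:
        return self.scale * int(sum(self.cluster_sizes))

    def with_scale(self, scale: int) -> "DGPSpec":
        from dataclasses import replace
        return replace(self, scale=scale)


def generate(dgp: DGPSpec, seed=None) -> tuple[np.ndarray, np.ndarray]:
    """Draw one data set from ``dgp``.

    Returns ``(data, labels)`` with exactly ``cluster_sizes[k] * scale``
    observations carrying label ``k``; the rows are shuffled jointly so
    ordering carries no cluster information.  ``seed`` may be an int or a
    Generator; the output is deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    sizes = [int(s) * dgp.scale for s in dgp.cluster_sizes]
    if dgp.random_sizes:
        sizes = rng.multinomial(sum(sizes), np.asarray(sizes) / sum(sizes))
    parts, labels = [], []
    for k, (params, m) in enumerate(zip(dgp.component_params, sizes)):
        m = int(m)
        if dgp.family == "gaussian":
            mu, sd = params
            parts.append(rng.normal(mu, sd, size=m))
        else:
            lo, hi = params
            parts.append(rng.uniform(lo, hi, size=m))
        labels.append(np.full(m, k, dtype=int))
    data = np.concatenate(parts)
    lab = np.concatenate(labels)
    perm = rng.permutation(data.size)
    return data[perm], lab[perm]


#: 4-component Gaussian mixture: means {9.5, 20, 24.5, 33},
#: sds {0.25, 1, 1, 0.5}, cluster sizes (5, 55, 30, 10) * scale.
GAUSSIAN4 = DGPSpec(
    family="gaussian",
    component_params=((9.5, 0.25), (20.0, 1.0), (24.5, 1.0), (33.0, 0.5)),
    cluster_sizes=(5, 55, 30, 10),
    name="gaussian4",
)

#: 4-component uniform mixture on {(9,10), (18,22), (22,27), (32,34)},
#: same cluster sizes; misspecified for a Gaussian mixture fit.
UNIFORM4 = DGPSpec(
    family="uniform",
    component_params=((9.0, 10.0), (18.0, 22.0), (22.0, 27.0), (32.0, 34.0)),
    cluster_sizes=(5, 55, 30, 10),
    name="uniform4",
)


def paper_dgps() -> dict[str, DGPSpec]:
    """The two named benchmark generating processes."""
    return {"gaussian4": GAUSSIAN4, "uniform4": UNIFORM4}
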