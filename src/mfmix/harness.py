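"""Full-factorial prior-sensitivity experiments.

A design space crosses priors on K, static/dynamic weight modes, Dirichlet
parameters, and the component-prior parameters B0 and C0 (b0 is always the
data midpoint, c0 is fixed).  Every cell is one sampler run; the summary
kept per cell is the posterior mode of the number of data clusters K+ and
the entropy of its posterior.  Marginal-effect tables average the per-cell
modes over all other factors.

The benchmark design (4 priors x 2 modes x 3 Dirichlet values x 4 B0 x
4 C0 = 384 cells) and the reduced simulation design (B0 in {6.3, 630},
C0 in {0.5, 12.5}, uniform prior bound raised to 100; 96 cells) are
provided as constructors.  Runs are resumable: with ``out_dir`` set, each
finished cell is persisted as a small JSON file and skipped on restart.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .priors import PriorK, shifted_bnb_k, shifted_geometric_k, \
    truncated_poisson_k, uniform_k
from .sampler import MFMConfig, run_sampler
from .simulate import DGPSpec, generate
from .summaries import summarize_trace

__all__ = ["DesignSpace", "CellResult", "galaxy_design", "simulation_design",
           "run_design", "marginal_table", "panel_report", "FAST_MCMC",
           "prior_sort_key"]

#: desk-scale MCMC profile for quick sensitivity scans
FAST_MCMC = {"n_iter": 20_000, "burn_in": 2_000, "thinning": 4}

_FACTOR_COLUMNS = {"mfm_mode": "weight_mode", "weight_param": "weight_param",
                   "priorK": "prior", "B0": "B0", "C0": "C0"}


@dataclass(frozen=True)
class DesignSpace:
    """A full-factorial grid of prior specifications."""

    priors: tuple
    weight_modes: tuple = ("static", "dynamic")
    weight_params: tuple = (0.01, 1.0, 10.0)
    B0_values: tuple = (6.3, 20.0, 100.0, 630.0)
    C0_values: tuple = (0.5, 1.0, 5.0, 12.5)
    c0: float = 2.0

    @property
    def n_cells(self) -> int:
        return (len(self.priors) * len(self.weight_modes)
                * len(self.weight_params) * len(self.B0_values)
                * len(self.C0_values))

    def cells(self):
        """Yield ``(cell_id, prior, mode, weight_param, B0, C0)`` tuples in
        a fixed enumeration order."""
        for prior in self.priors:
            for mode in self.weight_modes:
                for wp in self.weight_params:
                    for B0 in self.B0_values:
                        for C0 in self.C0_values:
                            cid = f"{prior!r}|{mode}|w{wp:g}|B{B0:g}|C{C0:g}"
                            yield cid, prior, mode, wp, B0, C0


def galaxy_design(uniform_upper: int = 30) -> DesignSpace:
    """The 384-cell benchmark design (4 x 2 x 3 x 4 x 4)."""
    return DesignSpace(priors=(uniform_k(uniform_upper),
                               truncated_poisson_k(3.0),
                               shifted_geometric_k(0.1),
                               shifted_bnb_k(1, 4, 3)))


def simulation_design(uniform_upper: int = 100) -> DesignSpace:
    """The reduced 96-cell design used with artificial data: extreme B0
    and C0 values only, uniform prior on K bounded at 100."""
    return DesignSpace(priors=(uniform_k(uniform_upper),
                               truncated_poisson_k(3.0),
                               shifted_geometric_k(0.1),
                               shifted_bnb_k(1, 4, 3)),
                       B0_values=(6.3, 630.0), C0_values=(0.5, 12.5))


@dataclass
class CellResult:
    cell_id: str
    replicate: int
    mode: int
    entropy: float
    seed: int
    error: str = ""


def _cell_seed(master_seed: int, cell_id: str, replicate: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    return zlib.crc32(f"{master_seed}|{cell_id}|{replicate}".encode()) & 0x7FFFFFFF


def _result_path(out_dir: Path, seed: int) -> Path:
    return out_dir / f"cell_{seed:010d}.json"


def run_design(design: DesignSpace, data=None, dgp: DGPSpec | None = None,
               replicates: int = 1, mcmc: dict | None = None,
               master_seed: int = 0, out_dir=None,
               sampler_fn=run_sampler, progress: bool = False) -> pd.DataFrame:
    """Run every design cell (for every replicate) and tabulate the results.

    Either ``data`` (a fixed data vector, analyzed once per cell) or
    ``dgp`` (a generating process, redrawn per replicate with seeds
    derived from ``master_seed``) must be given.  ``mcmc`` overrides
    MFMConfig fields such as ``n_iter``; ``sampler_fn(data, config)`` must
    return an object with a ``K_plus`` draw array (injection point for
    stub samplers in tests).  A failing cell is recorded with its error
    message and the run continues.
    """
    if (data is None) == (dgp is None):
        raise ValueError("give exactly one of data or dgp")
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    mcmc = dict(mcmc or {})
    rows = []
    for rep in range(replicates):
        if dgp is not None:
            y, _ = generate(dgp, seed=_cell_seed(master_seed, "data", rep))
        else:
            y = np.asarray(data, dtype=float).ravel()
        for cid, prior, mode, wp, B0, C0 in design.cells():
            seed = _cell_seed(master_seed, cid, rep)
            cached = None
            if out_dir is not None and _result_path(out_dir, seed).exists():
                cached = json.loads(_result_path(out_dir, seed).read_text())
            if cached is not None:
                res = CellResult(**cached)
            else:
                cfg = MFMConfig(prior_k=prior, weight_mode=mode,
                                weight_param=wp, B0=B0, C0=C0, c0=design.c0,
                                seed=seed, **mcmc)
                try:
                    summary = summarize_trace(sampler_fn(y, cfg))
                    res = CellResult(cid, rep, summary.mode,
                                     summary.entropy, seed)
                except Exception as exc:  # keep going, record the failure
                    res = CellResult(cid, rep, -1, float("nan"), seed,
                                     error=f"{type(exc).__name__}: {exc}")
                if out_dir is not None:
                    _result_path(out_dir, seed).write_text(
                        json.dumps(res.__dict__))
            if progress:
                print(f"[{len(rows) + 1}] {cid} rep {rep}: "
                      f"mode={res.mode}", flush=True)
            rows.append({"cell_id": cid, "prior": repr(prior),
                         "weight_mode": mode, "weight_param": wp,
                         "B0": B0, "C0": C0, "replicate": rep,
                         "mode": res.mode, "entropy": res.entropy,
                         "seed": res.seed, "error": res.error})
    return pd.DataFrame(rows)


def marginal_table(results: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Mean posterior-mode cluster number per level of one design factor,
    averaged over all other factors and replicates."""
    if factor not in _FACTOR_COLUMNS:
        raise ValueError(f"unknown factor {factor!r}; "
                         f"choose from {sorted(_FACTOR_COLUMNS)}")
    if len(results) == 0:
        raise ValueError("empty results")
    ok = results[results["error"] == ""] if "error" in results else results
    col = _FACTOR_COLUMNS[factor]
    counts = ok.groupby(col)["mode"].count()
    if counts.nunique() > 1:
        import warnings
        warnings.warn("results are not a balanced factorial; marginal "
                      "means mix unequal cell counts", stacklevel=2)
    out = ok.groupby(col)["mode"].mean().rename("mean_mode").reset_index()
    return out


def prior_sort_key(prior_repr: str) -> float:
    """Order priors by E[K^2] = E[K]^2 + V[K], the panel ordering."""
    import re
    m = re.match(r"PriorK\((\w+)\((.*)\)\)", prior_repr)
    fam, inner = m.group(1), m.group(2)
    params = dict(kv.split("=") for kv in inner.split(", "))
    pr = PriorK(fam, {k: float(v) for k, v in params.items()})
    mean, var = pr.moments()
    return mean**2 + var


def panel_report(results: pd.DataFrame, out_dir) -> dict:
    """Write per-(mode, Dirichlet-parameter) panels of posterior mode and
    entropy against the prior on K, as CSV plus plot files.

    Returns the paths written.  Panels order the priors by E[K^2]; point
    color encodes B0, fill encodes C0 (filled = large C0).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "results.csv"
    results.to_csv(csv_path, index=False)

    marg = pd.concat({f: marginal_table(results, f).set_index(
        _FACTOR_COLUMNS[f]).squeeze(axis=1) for f in _FACTOR_COLUMNS})
    marg_path = out_dir / "marginals.csv"
    marg.rename("mean_mode").to_csv(marg_path)

    ok = results[results["error"] == ""]
    priors = sorted(ok["prior"].unique(), key=prior_sort_key)
    xpos = {p: i for i, p in enumerate(priors)}
    b0s = sorted(ok["B0"].unique())
    cmap = plt.get_cmap("coolwarm_r")
    paths = {"results": csv_path, "marginals": marg_path}
    for stat in ("mode", "entropy"):
        modes = list(ok["weight_mode"].unique())
        wps = sorted(ok["weight_param"].unique())
        fig, axes = plt.subplots(len(modes), len(wps), squeeze=False,
                                 figsize=(4 * len(wps), 3 * len(modes)),
                                 sharey=True)
        for i, wm in enumerate(modes):
            for j, wp in enumerate(wps):
                ax = axes[i][j]
                sub = ok[(ok["weight_mode"] == wm)
                         & (ok["weight_param"] == wp)]
                for _, row in sub.iterrows():
                    color = cmap(b0s.index(row["B0"]) / max(len(b0s) - 1, 1))
                    filled = row["C0"] >= np.median(ok["C0"].unique())
                    ax.scatter(xpos[row["prior"]]
                               + 0.05 * b0s.index(row["B0"]),
                               row[stat], s=25, facecolor=color if filled
                               else "none", edgecolor=color)
                ax.set_title(f"{wm}, {wp:g}")
                ax.set_xticks(range(len(priors)))
                ax.set_xticklabels([p[7:-1] for p in priors], rotation=30,
                                   fontsize=7)
        fig.suptitle(f"posterior K+ {stat} by prior specification")
        fig.tight_layout()
        p = out_dir / f"panel_{stat}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[stat] = p
    return paths
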