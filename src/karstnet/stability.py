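"""Network stability: robustness to species loss and spectral vulnerability.

Robustness follows the "proportion of species remaining" convention: after
removing a fraction f of nodes at random, surviving nodes left with no
remaining edges count as secondary extinctions, and the curve reports the
mean proportion of nodes still connected. Vulnerability tracks natural
connectivity — the log-average of exponentiated adjacency eigenvalues,

    lambda_bar = ln( (1/N) sum_i exp(lambda_i) ),

a spectral measure of the redundancy of alternative paths — as nodes are
removed one at a time (random order, or by descending current degree in
targeted mode). Curves are Monte-Carlo means over seeded replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._utils import as_rng, derive_seed

__all__ = [
    "StabilityParams",
    "natural_connectivity",
    "robustness_curve",
    "vulnerability_curve",
    "stability_summary",
]


def _default_fractions() -> np.ndarray:
    return np.round(np.arange(0.0, 0.96, 0.05), 10)


@dataclass(frozen=True)
class StabilityParams:
    """Removal-experiment settings.

    ``fractions``: grid of removed-node fractions for robustness (default
    0 to 0.95 in 0.05 steps). ``replicates``: Monte-Carlo repetitions.
    ``mode``: 'random' removal or 'degree-targeted' (hubs first).
    ``secondary_extinction``: count newly isolated survivors as lost.
    """

    fractions: np.ndarray = field(default_factory=_default_fractions)
    replicates: int = 100
    mode: str = "random"
    secondary_extinction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.size and ((frac < 0).any() or (frac >= 1).any()):
            raise ValueError("fractions must lie in [0, 1)")
        object.__setattr__(self, "fractions", frac)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mode not in ("random", "degree-targeted"):
            raise ValueError(f"unknown removal mode {self.mode!r}")


def natural_connectivity(g: nx.Graph) -> float:
    """Natural connectivity of the unweighted adjacency (overflow-safe).

    ln((1/N) sum exp(lambda_i)); exactly 0 for edgeless graphs (all
    eigenvalues zero). Raises for the empty graph.
    """
    N = g.number_of_nodes()
    if N == 0:
        raise ValueError("natural connectivity is undefined for an empty graph")
    if g.number_of_edges() == 0:
        return 0.0
    adj = nx.to_numpy_array(g, weight=None)
    return _nat_conn_from_adjacency(adj)


def _nat_conn_from_adjacency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n == 0:
        raise ValueError("empty adjacency")
    # isolated nodes contribute eigenvalue 0 (exp = 1) each; restrict the
    # eigendecomposition to the non-isolated block for speed
    connected = adj.any(axis=1)
    m = int(connected.sum())
    if m == 0:
        return 0.0
    eig = np.linalg.eigvalsh(adj[np.ix_(connected, connected)])
    return float(logsumexp(np.concatenate([eig, np.zeros(n - m)])) - np.log(n))


def _removal_order(adj: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    """Node-removal order for one replicate (targeted: dynamic degree)."""
    n = adj.shape[0]
    if mode == "random":
        return rng.permutation(n)
    # degree-targeted: repeatedly remove the highest-degree remaining node,
    # ties broken by lowest index (deterministic)
    work = adj.copy()
    alive = np.ones(n, dtype=bool)
    order = np.empty(n, dtype=int)
    for k in range(n):
        deg = work.sum(axis=1)
        deg[~alive] = -1
        pick = int(np.argmax(deg))
        order[k] = pick
        alive[pick] = False
        work[pick, :] = 0.0
        work[:, pick] = 0.0
    return order


def robustness_curve(g: nx.Graph, params: StabilityParams | None = None) -> pd.DataFrame:
    """Mean proportion of species remaining after removing a fraction of nodes.

    For each fraction f: remove round(f N) nodes (uniformly at random, or
    hubs-first in targeted mode); the proportion remaining is the share of
    the original N nodes that survive **and** retain at least one edge
    (secondary-extinction rule; disable via params). Returns a DataFrame with
    columns f, proportion_remaining (mean), sd, replicates.
    """
    params = params or StabilityParams()
    N = g.number_of_nodes()
    if N < 2:
        raise ValueError("robustness needs at least 2 nodes")
    adj = nx.to_numpy_array(g, weight=None).astype(bool)
    reps = 1 if params.mode == "degree-targeted" else params.replicates
    fractions = params.fractions
    values = np.empty((reps, len(fractions)))
    for rep in range(reps):
        rng = as_rng(derive_seed(params.seed, "robustness", rep))
        order = _removal_order(adj.astype(float), params.mode, rng)
        for fi, f in enumerate(fractions):
            k = int(round(f * N))
            alive = np.ones(N, dtype=bool)
            alive[order[:k]] = False
            if params.secondary_extinction:
                deg = adj[np.ix_(alive, alive)].sum(axis=1)
                values[rep, fi] = (deg > 0).sum() / N
            else:
                values[rep, fi] = alive.sum() / N
    return pd.DataFrame(
        {
            "f": fractions,
            "proportion_remaining": values.mean(axis=0),
            "sd": values.std(axis=0, ddof=1) if reps > 1 else np.zeros(len(fractions)),
            "replicates": reps,
        }
    )


def vulnerability_curve(g: nx.Graph, params: StabilityParams | None = None) -> pd.DataFrame:
    """Mean natural connectivity after sequentially removing k = 0..N-1 nodes.

    Each replicate removes nodes one at a time (random order, or by
    descending current degree in targeted mode) and recomputes lambda_bar on
    the remaining subgraph. Returns columns k, natural_connectivity (mean),
    sd, replicates.
    """
    params = params or StabilityParams()
    N = g.number_of_nodes()
    if N < 2:
        raise ValueError("vulnerability needs at least 2 nodes")
    adj = nx.to_numpy_array(g, weight=None)
    reps = 1 if params.mode == "degree-targeted" else params.replicates
    values = np.empty((reps, N))
    for rep in range(reps):
        rng = as_rng(derive_seed(params.seed, "vulnerability", rep))
        if params.mode == "random":
            order = _removal_order(adj, "random", rng)
            alive = np.ones(N, dtype=bool)
            for k in range(N):
                if k > 0:
                    alive[order[k - 1]] = False
                values[rep, k] = _nat_conn_from_adjacency(adj[np.ix_(alive, alive)])
        else:
            # targeted: recompute degrees on the shrinking graph
            work = adj.copy()
            alive = np.ones(N, dtype=bool)
            for k in range(N):
                if k > 0:
                    deg = work.sum(axis=1)
                    deg[~alive] = -1.0
                    pick = int(np.argmax(deg))
                    alive[pick] = False
                    work[pick, :] = 0.0
                    work[:, pick] = 0.0
                values[rep, k] = _nat_conn_from_adjacency(adj[np.ix_(alive, alive)])
    return pd.DataFrame(
        {
            "k": np.arange(N),
            "natural_connectivity": values.mean(axis=0),
            "sd": values.std(axis=0, ddof=1) if reps > 1 else np.zeros(N),
            "replicates": reps,
        }
    )


def stability_summary(
    robustness: pd.DataFrame | None = None,
    vulnerability: pd.DataFrame | None = None,
) -> dict[str, float]:
    """ANOVA-ready scalars from stability curves.

    * ``robustness_auc``: mean of the robustness curve over its fraction grid
      (area under the curve on a uniform grid).
    * ``initial_natural_connectivity``: lambda_bar of the intact network
      (k = 0 point of the vulnerability curve).
    Deterministic given the curves.
    """
    out: dict[str, float] = {}
    if robustness is not None:
        out["robustness_auc"] = float(robustness["proportion_remaining"].mean())
    if vulnerability is not None:
        out["initial_natural_connectivity"] = float(
            vulnerability.loc[vulnerability["k"] == 0, "natural_connectivity"].iloc[0]
        )
    if not out:
        raise ValueError("at least one curve is required")
    return out


def plot_stability(robustness=None, vulnerability=None, ax=None, label=None):
    """Quick matplotlib rendering of stability curves (one panel per curve)."""
    import matplotlib.pyplot as plt

    n_panels = int(robustness is not None) + int(vulnerability is not None)
    if n_panels == 0:
        raise ValueError("nothing to plot")
    if ax is None:
        _, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4), squeeze=False)
        axes = list(axes[0])
    else:
        axes = [ax] if not isinstance(ax, (list, tuple)) else list(ax)
    i = 0
    if robustness is not None:
        axes[i].plot(robustness["f"], robustness["proportion_remaining"], marker="o", label=label)
        axes[i].set_xlabel("proportion of species removed")
        axes[i].set_ylabel("proportion of species remaining")
        i += 1
    if vulnerability is not None:
        axes[i].plot(vulnerability["k"], vulnerability["natural_connectivity"], label=label)
        axes[i].set_xlabel("number of removed nodes")
        axes[i].set_ylabel("natural connectivity")
    return axes
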