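"""Topological properties of co-occurrence (sub-)networks.

Per network: edge and node counts, positive/negative correlation ratios,
graph density, average degree, Newman modularity of a detected community
partition, and *relative modularity* — observed modularity normalised against
the mean modularity of Erdos-Renyi random graphs with the same number of
nodes and edges:

    RM = (Q_obs - mean Q_null) / mean Q_null

Higher edge number, density and average degree indicate denser connectivity
(greater network complexity); RM > 0 indicates more modular structure than
expected for a size-matched random graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._utils import derive_seed

__all__ = [
    "ModularityParams",
    "count_metrics",
    "modularity",
    "detect_communities",
    "relative_modularity",
    "summarize_topology",
]


@dataclass(frozen=True)
class ModularityParams:
    """Null-model settings for relative modularity."""

    null_model_replicates: int = 100
    method: str = "greedy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.null_model_replicates < 1:
            raise ValueError("null_model_replicates must be >= 1")


def count_metrics(g: nx.Graph) -> dict[str, float]:
    """Edge/node counts, sign ratios, density and average degree.

    density = 2E / (N(N-1)), average degree = 2E / N; degenerate graphs
    (N < 2 or E = 0) return zeros rather than errors. Edges without a
    ``sign`` attribute count as positive.
    """
    N = g.number_of_nodes()
    E = g.number_of_edges()
    n_pos = sum(1 for _, _, d in g.edges(data=True) if d.get("sign", "+") == "+")
    return {
        "n_nodes": N,
        "n_nodes_connected": sum(1 for _, deg in g.degree() if deg > 0),
        "n_edges": E,
        "positive_ratio": n_pos / E if E else 0.0,
        "negative_ratio": (E - n_pos) / E if E else 0.0,
        "density": 2.0 * E / (N * (N - 1)) if N >= 2 else 0.0,
        "average_degree": 2.0 * E / N if N >= 1 else 0.0,
    }


def modularity(g: nx.Graph, partition) -> float:
    """Newman modularity Q = sum_c [L_c/E - (k_c/2E)^2] (unweighted).

    ``partition`` is an iterable of node collections that must cover every
    node exactly once. Undefined (raises) for edgeless graphs.
    """
    E = g.number_of_edges()
    if E == 0:
        raise ValueError("modularity is undefined for an edgeless graph")
    communities = [set(c) for c in partition]
    seen: set = set()
    for c in communities:
        if c & seen:
            raise ValueError("partition communities must be disjoint")
        seen |= c
    if seen != set(g.nodes):
        raise ValueError("partition must cover all nodes")
    q = 0.0
    for c in communities:
        intra = sum(1 for u, v in g.edges(c) if u in c and v in c)
        k_c = sum(d for _, d in g.degree(c))
        q += intra / E - (k_c / (2.0 * E)) ** 2
    return q


def detect_communities(g: nx.Graph, seed: int | None = None) -> list[set]:
    """Greedy (agglomerative) modularity-maximising partition.

    Deterministic for a given graph: Clauset-Newman-Moore greedy merging, with
    the returned communities ordered by their lowest node label. ``seed`` is
    accepted for interface uniformity; the algorithm itself is deterministic.
    """
    if g.number_of_edges() == 0:
        raise ValueError("community detection needs at least one edge")
    comms = nx.community.greedy_modularity_communities(g)
    comms = [set(c) for c in comms]
    covered = set().union(*comms) if comms else set()
    comms.extend({n} for n in g.nodes if n not in covered)  # isolated nodes
    return sorted(comms, key=lambda c: min(str(n) for n in c))


def relative_modularity(
    g: nx.Graph, params: ModularityParams | None = None
) -> dict[str, float]:
    """Observed modularity vs an ER(N, E) random-graph null.

    Detects communities on the observed graph and on each of
    ``null_model_replicates`` Erdos-Renyi graphs with matched node and edge
    counts, then returns Q_obs, the null mean, and
    RM = (Q_obs - mean Q_null)/mean Q_null. NaN (with a warning) when the
    null mean is zero.
    """
    params = params or ModularityParams()
    if g.number_of_edges() == 0:
        raise ValueError("relative modularity needs at least one edge")
    q_obs = modularity(g, detect_communities(g))
    N, E = g.number_of_nodes(), g.number_of_edges()
    q_null = np.empty(params.null_model_replicates)
    for rep in range(params.null_model_replicates):
        null = nx.gnm_random_graph(N, E, seed=derive_seed(params.seed, "er-null", rep))
        if null.number_of_edges() == 0:  # pragma: no cover - E >= 1 guaranteed
            q_null[rep] = 0.0
            continue
        q_null[rep] = modularity(null, detect_communities(null))
    mean_null = float(q_null.mean())
    if mean_null == 0.0:
        warnings.warn("null-model mean modularity is zero; RM undefined", RuntimeWarning)
        rm = float("nan")
    else:
        rm = (q_obs - mean_null) / mean_null
    return {
        "modularity": q_obs,
        "null_modularity_mean": mean_null,
        "null_modularity_sd": float(q_null.std(ddof=1)) if len(q_null) > 1 else 0.0,
        "relative_modularity": rm,
    }


def summarize_topology(
    subnetworks: dict[str, nx.Graph],
    metadata: pd.DataFrame | None = None,
    modularity_params: ModularityParams | None = None,
) -> pd.DataFrame:
    """Per-sample topology table, one row per sub-network in input order.

    Joins treatment metadata (W/N/P/block/treatment) when provided, ready for
    downstream factorial ANOVA. Edgeless sub-networks get zero count metrics
    and missing (NaN) modularity fields.
    """
    if not subnetworks:
        raise ValueError("no subnetworks given")
    params = modularity_params or ModularityParams()
    rows = []
    for k, (sample, g) in enumerate(subnetworks.items()):
        row: dict = {"sample_id": sample}
        row.update(count_metrics(g))
        if g.number_of_edges() > 0:
            from dataclasses import replace

            row.update(
                relative_modularity(g, replace(params, seed=derive_seed(params.seed, sample)))
            )
        else:
            row.update(
                {
                    "modularity": np.nan,
                    "null_modularity_mean": np.nan,
                    "null_modularity_sd": np.nan,
                    "relative_modularity": np.nan,
                }
            )
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    if metadata is not None:
        keep = [c for c in ("W", "N", "P", "block", "treatment") if c in metadata.columns]
        df = df.join(metadata[keep])
    return df
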