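"""Co-occurrence network construction from thresholded SparCC correlations.

An edge joins taxa i and j when |rho_ij| >= r_threshold (default 0.6,
inclusive) and the bootstrap pseudo p-value p_ij < p_threshold (default 0.01,
strict). Edges carry the correlation as ``weight`` and its sign as ``sign``
('+'/'-'). Per-sample sub-networks are induced subgraphs on the taxa present
(count > 0) in each sample; isolated nodes are retained.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .otu import OtuTable

__all__ = [
    "build_network",
    "extract_sample_subnetworks",
    "write_network",
    "read_network",
]


def _to_matrix(x, name):
    if isinstance(x, pd.DataFrame):
        return x.to_numpy(), list(x.index)
    arr = np.asarray(x, dtype=float)
    return arr, [f"T{k}" for k in range(arr.shape[0])]


def build_network(
    rho,
    pvals,
    r_threshold: float = 0.6,
    p_threshold: float = 0.01,
    taxon_domains: dict[str, str] | None = None,
) -> nx.Graph:
    """Signed undirected network of robust associations.

    Edge rule: |rho_ij| >= r_threshold AND p_ij < p_threshold (i < j). All
    taxa appear as nodes regardless of degree. Thresholds are stored as graph
    attributes.
    """
    rho_arr, taxa = _to_matrix(rho, "rho")
    p_arr, p_taxa = _to_matrix(pvals, "pvals")
    if rho_arr.shape != p_arr.shape:
        raise ValueError(f"rho shape {rho_arr.shape} != pvals shape {p_arr.shape}")
    if isinstance(rho, pd.DataFrame) and isinstance(pvals, pd.DataFrame):
        if list(rho.index) != list(pvals.index):
            raise ValueError("rho and pvals taxon labels differ")

    g = nx.Graph(r_threshold=float(r_threshold), p_threshold=float(p_threshold))
    domains = taxon_domains or {}
    for t in taxa:
        attrs = {"domain": domains[t]} if t in domains else {}
        g.add_node(t, **attrs)
    ii, jj = np.triu_indices(len(taxa), 1)
    keep = (np.abs(rho_arr[ii, jj]) >= r_threshold) & (p_arr[ii, jj] < p_threshold)
    for i, j in zip(ii[keep], jj[keep]):
        w = float(rho_arr[i, j])
        g.add_edge(taxa[i], taxa[j], weight=w, sign="+" if w >= 0 else "-")
    return g


def extract_sample_subnetworks(
    net: nx.Graph, table: OtuTable, min_count: int = 1
) -> dict[str, nx.Graph]:
    """Per-sample induced subgraphs of the global network.

    A taxon belongs to a sample's sub-network when its count in that sample is
    >= ``min_count`` (default 1, i.e. simple presence); an edge survives when
    both endpoints are present. Isolated present nodes are retained. Returns
    an ordered mapping sample_id -> subgraph.
    """
    missing = [n for n in net.nodes if n not in table.counts.columns]
    if missing:
        raise ValueError(f"network nodes absent from table: {missing[:5]}")
    out: dict[str, nx.Graph] = {}
    nodes = list(net.nodes)
    counts = table.counts[nodes]
    for sample in table.samples:
        present = [n for n in nodes if counts.at[sample, n] >= min_count]
        sub = net.subgraph(present).copy()
        sub.graph["sample_id"] = sample
        out[sample] = sub
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_network(net: nx.Graph, path, fmt: str = "tsv") -> None:
    """Write a network as an edge-list TSV (with a node section, so empty and
    isolated-node graphs round-trip) or as GraphML."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path)
        return
    if fmt != "tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    with open(path, "w") as fh:
        fh.write("#nodes\n")
        for node, attrs in net.nodes(data=True):
            fh.write(f"{node}\t{attrs.get('domain', '')}\n")
        fh.write("#edges\tsource\ttarget\tweight\tsign\n")
        for u, v, attrs in net.edges(data=True):
            weight = attrs.get("weight", 1.0)
            fh.write(f"edge\t{u}\t{v}\t{weight:.12g}\t{attrs.get('sign', '+')}\n")


def read_network(path, fmt: str = "tsv") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt != "tsv":
        raise ValueError(f"unknown network format {fmt!r}")
    g = nx.Graph()
    section = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#nodes"):
                section = "nodes"
                continue
            if line.startswith("#edges"):
                section = "edges"
                continue
            parts = line.split("\t")
            if section == "nodes":
                if len(parts) not in (1, 2):
                    raise ValueError(f"{path}:{lineno}: malformed node line {line!r}")
                node = parts[0]
                if len(parts) == 2 and parts[1]:
                    g.add_node(node, domain=parts[1])
                else:
                    g.add_node(node)
            elif section == "edges":
                if len(parts) != 5 or parts[0] != "edge":
                    raise ValueError(f"{path}:{lineno}: malformed edge line {line!r}")
                _, u, v, w, sign = parts
                try:
                    weight = float(w)
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: bad weight {w!r}") from err
                if sign not in ("+", "-"):
                    raise ValueError(f"{path}:{lineno}: bad sign {sign!r}")
                g.add_edge(u, v, weight=weight, sign=sign)
            else:
                raise ValueError(f"{path}:{lineno}: content before section header")
    return g
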