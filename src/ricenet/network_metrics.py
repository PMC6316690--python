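"""Node- and network-level properties of a signed weighted graph.

Per node: binary degree k_i, weighted degree (sum of signed weights over
binary-adjacent neighbours), the Watts-Strogatz binary clustering
coefficient

    C(i) = sum_j sum_{q != j} a_ij a_iq a_jq / (k_i (k_i - 1)),

and the Onnela signed weighted clustering coefficient

    C_w(i) = sum_j sum_{q != j} |w_ij w_iq w_jq|^{1/3} / (k_i (k_i - 1)),

where the sum runs over ordered pairs of binary-adjacent neighbours that
are themselves adjacent, and k_i is the binary degree.  Since every
|w| <= 1, C_w(i) <= C(i) node-wise on a shared edge set; nodes with
k_i < 2 get clustering 0 by convention so distributions cover the whole
network.  Network level: edge/node counts, hub and end-node counts,
degree assortativity (Newman's edge-endpoint degree correlation),
diameter of the largest component (reported in hops and in traversed
nodes = hops + 1), and a global clustering coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .exceptions import InputError
from .network_build import SignedWeightedGraph


def binary_degree(graph: SignedWeightedGraph) -> np.ndarray:
    return graph.degree()


def weighted_degree(graph: SignedWeightedGraph) -> np.ndarray:
    """Sum of signed correlation weights over binary-adjacent neighbours."""
    return (graph.weights * graph.adjacency).sum(axis=1)


def clustering_binary(graph: SignedWeightedGraph) -> np.ndarray:
    a = graph.adjacency.astype(float)
    k = graph.degree().astype(float)
    triangles = np.einsum("ij,jq,qi->i", a, a, a)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, triangles / denom, 0.0)
    return c


def clustering_onnela(graph: SignedWeightedGraph) -> np.ndarray:
    if np.abs(graph.weights).max(initial=0.0) > 1.0:
        raise InputError("weights must lie in [-1, 1]")
    a = graph.adjacency
    w_hat = np.abs(graph.weights * a) ** (1.0 / 3.0)
    k = graph.degree().astype(float)
    intensity = np.einsum("ij,jq,qi->i", w_hat, w_hat, w_hat)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, intensity / denom, 0.0)
    return c


def degree_assortativity(graph: SignedWeightedGraph) -> float:
    """Pearson correlation of degrees at edge endpoints (both orientations).

    Undefined (NaN, with a warning) when the endpoint degrees have zero
    variance, e.g. on a regular graph.
    """
    adj = graph.adjacency
    ii, jj = np.nonzero(np.triu(adj, 1))
    if ii.size == 0:
        raise InputError("assortativity needs at least one edge")
    deg = graph.degree()
    x = np.concatenate([deg[ii], deg[jj]]).astype(float)
    y = np.concatenate([deg[jj], deg[ii]]).astype(float)
    if x.std() == 0:
        warnings.warn("degree variance over edge endpoints is zero; assortativity undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class DiameterResult:
    """Diameter of the largest connected component.

    ``hops`` counts edges on the longest shortest path; ``nodes``
    (= hops + 1) counts traversed nodes, so either convention of
    reporting path length is available.  ``connected`` flags whether the
    whole graph was covered (a disconnected graph technically has
    infinite diameter; the component restriction is reported instead).
    """

    hops: int
    nodes: int
    connected: bool
    component_size: int


def diameter(graph: SignedWeightedGraph) -> DiameterResult:
    if graph.n_nodes < 2:
        raise InputError("diameter needs at least two nodes")
    adj = graph.adjacency
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels)
    largest = int(sizes.argmax())
    idx = np.nonzero(labels == largest)[0]
    sub = csr_matrix(adj[np.ix_(idx, idx)])
    d = shortest_path(sub, method="D", unweighted=True, directed=False)
    hops = int(d.max()) if idx.size > 1 else 0
    return DiameterResult(
        hops=hops,
        nodes=hops + 1,
        connected=(n_comp == 1),
        component_size=int(idx.size),
    )


def global_clustering(
    graph: SignedWeightedGraph, method: str = "mean_local"
) -> float:
    """Network-level clustering.

    ``mean_local`` (default): arithmetic mean of the binary local
    clustering over nodes with k >= 2.  ``transitivity``: the
    triangle-to-triple ratio, offered as an alternative convention.
    """
    if method == "mean_local":
        k = graph.degree()
        eligible = k >= 2
        if not eligible.any():
            warnings.warn("no node with degree >= 2; global clustering undefined", stacklevel=2)
            return float("nan")
        return float(clustering_binary(graph)[eligible].mean())
    if method == "transitivity":
        a = graph.adjacency.astype(float)
        closed = np.einsum("ij,jq,qi->", a, a, a)
        k = graph.degree().astype(float)
        triples = (k * (k - 1)).sum()
        if triples == 0:
            warnings.warn("no connected triple; transitivity undefined", stacklevel=2)
            return float("nan")
        return float(closed / triples)
    raise InputError(f"unknown global clustering method {method!r}")


def node_metrics(graph: SignedWeightedGraph) -> pd.DataFrame:
    """Per-node metric table (degree, weighted_degree, cc_binary, cc_onnela)."""
    return pd.DataFrame(
        {
            "degree": binary_degree(graph),
            "weighted_degree": weighted_degree(graph),
            "cc_binary": clustering_binary(graph),
            "cc_onnela": clustering_onnela(graph),
        },
        index=pd.Index(graph.nodes, name="gene"),
    )


@dataclass
class NetworkSummary:
    """Network-level property report.

    ``connections_per_node`` is edges/nodes and ``average_degree`` is
    2 * edges/nodes, so the identity average_degree = 2 *
    connections_per_node always holds; hub nodes are those with degree
    above ``hub_threshold`` and end nodes those with degree exactly 1.
    """

    n_nodes: int
    n_edges: int
    connections_per_node: float
    average_degree: float
    n_hub_nodes: int
    n_end_nodes: int
    diameter_hops: int
    diameter_nodes: int
    connected: bool
    degree_assortativity: float
    global_clustering: float
    hub_threshold: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(
    graph: SignedWeightedGraph,
    hub_threshold: int = 200,
    clustering_method: str = "mean_local",
) -> NetworkSummary:
    if graph.n_nodes == 0:
        raise InputError("cannot summarize an empty graph")
    deg = graph.degree()
    n_edges = graph.n_edges
    diam = diameter(graph) if graph.n_nodes >= 2 else DiameterResult(0, 1, True, 1)
    if n_edges > 0:
        assort = degree_assortativity(graph)
    else:
        assort = float("nan")
    return NetworkSummary(
        n_nodes=graph.n_nodes,
        n_edges=n_edges,
        connections_per_node=n_edges / graph.n_nodes,
        average_degree=2.0 * n_edges / graph.n_nodes,
        n_hub_nodes=int((deg > hub_threshold).sum()),
        n_end_nodes=int((deg == 1).sum()),
        diameter_hops=diam.hops,
        diameter_nodes=diam.nodes,
        connected=diam.connected,
        degree_assortativity=assort,
        global_clustering=global_clustering(graph, method=clustering_method),
        hub_threshold=hub_threshold,
    )


def degree_distribution(graph: SignedWeightedGraph) -> pd.DataFrame:
    """Degree histogram as a (degree, count) table; counts sum to n_nodes."""
    values, counts = np.unique(graph.degree(), return_counts=True)
    return pd.DataFrame({"degree": values, "count": counts})


def clustering_distribution(values, n_bins: int = 20) -> pd.DataFrame:
    """Histogram of clustering coefficients over [0, 1] for export/plotting."""
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
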