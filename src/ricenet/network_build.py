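"""Signed weighted co-expression network construction.

One network is built per condition over the shared differential-expression
gene universe: edge weights are Pearson correlations of expression across
all of that condition's samples (seedling and booting stages pooled), the
binary view keeps pairs with ``|r| >= tau`` (default 0.9, inclusive), and
nodes left without any binary edge are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import InputError

_WEIGHT_TOL = 1e-9


@dataclass
class SignedWeightedGraph:
    """Complete signed weighted graph with a thresholded binary view.

    ``weights`` is a dense symmetric matrix of correlations in [-1, 1]
    with a zero diagonal; the binary adjacency is the derived view
    ``|w| >= tau``.  The same object therefore carries both the weighted
    network (for the weighted degree and the Onnela clustering
    coefficient) and the binary network (for degree, binary clustering,
    assortativity and diameter).
    """

    nodes: list[str]
    weights: np.ndarray
    tau: float = 0.9

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise InputError("weight matrix shape does not match node list")
        if len(set(self.nodes)) != len(self.nodes):
            raise InputError("duplicate node ids")
        if not np.allclose(w, w.T, atol=_WEIGHT_TOL):
            raise InputError("weight matrix must be symmetric")
        if np.abs(w).max(initial=0.0) > 1.0 + _WEIGHT_TOL:
            raise InputError("weights are correlations and must lie in [-1, 1]")
        w = np.clip((w + w.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if not 0.0 <= self.tau <= 1.0:
            raise InputError("tau must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def adjacency(self) -> np.ndarray:
        a = np.abs(self.weights) >= self.tau
        np.fill_diagonal(a, False)
        return a

    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def subgraph(self, keep_idx: np.ndarray) -> "SignedWeightedGraph":
        keep_idx = np.asarray(keep_idx)
        nodes = [self.nodes[i] for i in keep_idx]
        return SignedWeightedGraph(
            nodes=nodes, weights=self.weights[np.ix_(keep_idx, keep_idx)], tau=self.tau
        )

    # -- export --------------------------------------------------------------

    def edge_table(self, edges_only: bool = True) -> pd.DataFrame:
        """Long-format pair table (gene_a, gene_b, weight, is_edge)."""
        adj = self.adjacency
        if edges_only:
            ii, jj = np.nonzero(np.triu(adj, 1))
        else:
            ii, jj = np.triu_indices(self.n_nodes, 1)
        return pd.DataFrame(
            {
                "gene_a": [self.nodes[i] for i in ii],
                "gene_b": [self.nodes[j] for j in jj],
                "weight": self.weights[ii, jj],
                "is_edge": adj[ii, jj].astype(int),
            }
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(tau=self.tau)
        g.add_nodes_from(self.nodes)
        adj = self.adjacency
        ii, jj = np.nonzero(np.triu(adj, 1))
        g.add_edges_from(
            (self.nodes[i], self.nodes[j], {"weight": float(self.weights[i, j])})
            for i, j in zip(ii, jj)
        )
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist(self, path, edges_only: bool = True) -> None:
        self.edge_table(edges_only=edges_only).to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "SignedWeightedGraph":
        """Rebuild from a GraphML-style graph (weights only on stored edges)."""
        nodes = list(g.nodes)
        index = {n: i for i, n in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for u, v, data in g.edges(data=True):
            w[index[u], index[v]] = w[index[v], index[u]] = data.get("weight", 1.0)
        return cls(nodes=nodes, weights=w, tau=float(g.graph.get("tau", 0.9)))


def condition_samples(samples: pd.DataFrame, condition: str) -> list[str]:
    """All sample ids of one condition across both stages, in sheet order."""
    ids = list(samples.index[samples["condition"] == condition])
    if not ids:
        raise InputError(f"no samples with condition {condition!r}")
    return ids


def correlation_graph(
    expr: pd.DataFrame, sample_ids, genes=None, tau: float = 0.9
) -> SignedWeightedGraph:
    """Complete signed graph of pairwise Pearson correlations.

    ``expr`` is a genes x samples expression frame (the pipeline passes
    log2-normalized values); correlations are computed over
    ``sample_ids`` only.  Genes with zero variance over those samples
    get all correlations set to 0 (with a warning) since Pearson r is
    undefined for them.
    """
    sample_ids = list(sample_ids)
    if len(sample_ids) < 3:
        raise InputError("need at least three samples to correlate")
    if genes is not None:
        genes = list(genes)
        if len(set(genes)) != len(genes):
            raise InputError("duplicate gene ids in network universe")
        expr = expr.loc[genes]
    x = expr[sample_ids].to_numpy(dtype=float)
    sd = x.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.corrcoef(x)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant-expression gene(s): correlations set to 0",
            stacklevel=2,
        )
        w[constant, :] = 0.0
        w[:, constant] = 0.0
    w = np.clip(np.nan_to_num(w, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return SignedWeightedGraph(nodes=list(expr.index), weights=w, tau=tau)


def apply_threshold(graph: SignedWeightedGraph, tau: float = 0.9) -> SignedWeightedGraph:
    """Recompute the binary view at a new tau; weights untouched (inclusive >=)."""
    return replace(graph, tau=tau)


def drop_isolated(graph: SignedWeightedGraph) -> SignedWeightedGraph:
    """Remove nodes with binary degree zero (only connected nodes remain)."""
    keep = np.nonzero(graph.degree() > 0)[0]
    if keep.size == 0:
        warnings.warn("graph has no edges; result is empty", stacklevel=2)
    return graph.subgraph(keep)
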