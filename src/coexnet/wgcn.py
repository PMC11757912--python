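"""Weighted co-expression network: correlation thresholding, giant component,
edge-to-node weight conversion, and the topological overlap matrix."""
from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .expression import ExpressionMatrix


def correlation_network(matrix: ExpressionMatrix, genes,
                        r_min: float = 0.7, beta: float = 1.0) -> nx.Graph:
    """Graph over ``genes`` with an edge where |Pearson r| >= r_min,
    weighted |r|^beta.  Constant-expression genes are excluded with a warning.
    """
    if not (0.0 < r_min < 1.0):
        raise ValidationError("r_min must lie in (0, 1)")
    if beta < 1.0:
        raise ValidationError("beta must be >= 1")
    genes = [g for g in genes if g in matrix.values.index]
    sub = matrix.values.loc[genes]
    sd = sub.to_numpy(float).std(axis=1)
    constant = [g for g, s in zip(genes, sd) if s == 0]
    if constant:
        warnings.warn(f"excluding {len(constant)} constant-expression genes "
                      "(correlation undefined)", UserWarning)
        genes = [g for g in genes if g not in set(constant)]
        sub = matrix.values.loc[genes]

    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) >= 2:
        r = np.corrcoef(sub.to_numpy(float))
        np.fill_diagonal(r, 0.0)
        ii, jj = np.where(np.triu(np.abs(r) >= r_min, k=1))
        for i, j in zip(ii, jj):
            g.add_edge(genes[i], genes[j], weight=float(np.abs(r[i, j]) ** beta))
    return g


def giant_component(graph: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component; ties broken by
    the component containing the lexicographically smallest node id."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph has no giant component")
    comps = sorted(nx.connected_components(graph),
                   key=lambda c: (-len(c), min(str(n) for n in c)))
    return graph.subgraph(comps[0]).copy()


def node_weights_from_edges(graph: nx.Graph) -> dict:
    """Node weight = sum of incident edge weights (strength); isolated
    nodes get 0.  Also stored on the graph as the 'weight' node attribute."""
    strengths = {v: 0.0 for v in graph.nodes}
    for u, v, w in graph.edges(data="weight", default=1.0):
        strengths[u] += w
        strengths[v] += w
    nx.set_node_attributes(graph, strengths, "weight")
    return strengths


def adjacency(graph: nx.Graph) -> pd.DataFrame:
    """Symmetrized weighted adjacency with sorted node order, zero diagonal."""
    nodes = sorted(graph.nodes, key=str)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    a = 0.5 * (a + a.T)  # guard: already symmetric for undirected input
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=nodes, columns=nodes)


def tom(graph_or_adjacency) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j with k_i = sum_u a_iu; diagonal fixed at 1.  Requires adjacency
    entries in [0, 1].
    """
    if isinstance(graph_or_adjacency, nx.Graph):
        adj = adjacency(graph_or_adjacency)
    else:
        adj = pd.DataFrame(graph_or_adjacency)
        arr = 0.5 * (adj.to_numpy(float) + adj.to_numpy(float).T)
        np.fill_diagonal(arr, 0.0)
        adj = pd.DataFrame(arr, index=adj.index, columns=adj.columns)
    a = adj.to_numpy(float)
    if a.min() < 0 or a.max() > 1 + 1e-9:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [{"node_a": u, "node_b": v, "weight": w}
            for u, v, w in sorted(graph.edges(data="weight", default=1.0))]
    pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
        path, sep="\t", index=False)
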