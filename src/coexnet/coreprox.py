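"""Core-proximity scoring on shortest paths.

Similarities are converted to edge lengths, all-pairs shortest paths are
computed with Dijkstra, and each node j receives

    D_j = (mean SP from noncore to j - mean SP from core to j)
          / (mean SP from all other nodes to j)

so that positive D means the node sits nearer the designated core set.
"""
from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ValidationError

LENGTH_MODES = ("one_minus_sim", "reciprocal")


def edge_lengths(source, mode: str = "one_minus_sim",
                 eps: float = 1e-6) -> nx.Graph:
    """Build a graph with a 'length' attribute from similarities.

    ``source`` is either a graph whose edge weights are similarities, or a
    similarity matrix (DataFrame) whose positive off-diagonal entries become
    edges.  one_minus_sim: length = max(1 - s, eps); reciprocal: 1/s with
    zero-similarity edges dropped (warning).
    """
    if mode not in LENGTH_MODES:
        raise ValidationError(f"unknown length mode {mode!r}")
    g = nx.Graph()
    if isinstance(source, nx.Graph):
        g.add_nodes_from(source.nodes)
        items = [(u, v, w) for u, v, w in source.edges(data="weight", default=1.0)]
    else:
        sim = pd.DataFrame(source)
        nodes = list(sim.index)
        g.add_nodes_from(nodes)
        arr = sim.to_numpy(float)
        items = [(nodes[i], nodes[j], arr[i, j])
                 for i in range(len(nodes)) for j in range(i + 1, len(nodes))
                 if arr[i, j] > 0]
    dropped = 0
    for u, v, s in items:
        if mode == "one_minus_sim":
            g.add_edge(u, v, length=max(1.0 - s, eps))
        else:
            if s <= 0:
                dropped += 1
                continue
            g.add_edge(u, v, length=1.0 / s)
    if dropped:
        warnings.warn(f"dropped {dropped} zero-similarity edges under "
                      "reciprocal lengths", UserWarning)
    return g


def all_pairs_dijkstra(graph: nx.Graph, weight: str = "length") -> pd.DataFrame:
    """Symmetric matrix of Dijkstra shortest-path lengths; unreachable pairs
    are +inf."""
    for u, v, w in graph.edges(data=weight, default=1.0):
        if w < 0:
            raise ValidationError(f"negative edge length on ({u}, {v})")
    nodes = sorted(graph.nodes, key=str)
    index = {v: i for i, v in enumerate(nodes)}
    mat = np.full((len(nodes), len(nodes)), np.inf)
    np.fill_diagonal(mat, 0.0)
    for src, dists in nx.all_pairs_dijkstra_path_length(graph, weight=weight):
        i = index[src]
        for dst, d in dists.items():
            mat[i, index[dst]] = d
    return pd.DataFrame(mat, index=nodes, columns=nodes)


def d_score(sp: pd.DataFrame, core) -> pd.DataFrame:
    """Per-node core-proximity score.

    For each node j the sums run over the other nodes i != j that are
    reachable from j; C and NC are the reachable core / noncore counts after
    excluding j itself.  Nodes with C == 0 or NC == 0 are flagged undefined.
    """
    nodes = list(sp.index)
    core = set(core)
    if not core:
        raise ValidationError("core set is empty")
    if not core < set(nodes):
        raise ValidationError("core must be a proper subset of the nodes")
    is_core = np.array([v in core for v in nodes])
    mat = sp.to_numpy(float)
    rows = []
    for j, node in enumerate(nodes):
        d = mat[:, j]
        usable = np.isfinite(d)
        usable[j] = False
        core_i = usable & is_core
        noncore_i = usable & ~is_core
        c, nc = int(core_i.sum()), int(noncore_i.sum())
        if c == 0 or nc == 0:
            rows.append({"node": node, "d_score": np.nan, "mean_sp_core": np.nan,
                         "mean_sp_noncore": np.nan, "mean_sp_all": np.nan,
                         "is_core": bool(is_core[j]), "defined": False})
            continue
        mean_core = d[core_i].mean()
        mean_noncore = d[noncore_i].mean()
        mean_all = d[usable].mean()
        rows.append({"node": node,
                     "d_score": (mean_noncore - mean_core) / mean_all,
                     "mean_sp_core": mean_core,
                     "mean_sp_noncore": mean_noncore,
                     "mean_sp_all": mean_all,
                     "is_core": bool(is_core[j]), "defined": True})
    return pd.DataFrame(rows).set_index("node")


def core_subnetwork(graph: nx.Graph, dtable: pd.DataFrame
                    ) -> tuple[nx.Graph, dict]:
    """Induced subgraph on core nodes plus nodes with positive D-score.

    Returns the subgraph and counts of core ('seed') nodes and positive-D
    neighbors."""
    core_nodes = set(dtable.index[dtable["is_core"]])
    positive = set(dtable.index[(~dtable["is_core"]) & dtable["defined"]
                                & (dtable["d_score"] > 0)])
    if not positive:
        warnings.warn("no noncore node has positive D-score; returning the "
                      "core-induced subgraph", UserWarning)
    keep = (core_nodes | positive) & set(graph.nodes)
    sub = graph.subgraph(keep).copy()
    counts = {"n_core": len(core_nodes & set(graph.nodes)),
              "n_positive": len(positive & set(graph.nodes)),
              "n_total": sub.number_of_nodes()}
    return sub, counts
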