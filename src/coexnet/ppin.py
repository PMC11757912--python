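"""Interaction-network topology: STRING-dialect parsing, per-node statistics,
whole-network metrics, hub/nonhub classification, and greedy modularity
clustering.

Degree, betweenness, closeness and distances are computed on the unweighted
skeleton.  Betweenness is reported as raw pair counts (each unordered pair
counted once); closeness is (n_comp - 1) / sum of distances within the
connected component, so CC * mean_distance = 1 on any component.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

HUB, NONHUB, OTHER = "hub", "nonhub", "other"

# default classification thresholds
K_HUB = 13
BC_HUB = 63.94
K_NONHUB = 3
BC_NONHUB_DIRECT = 9


def read_string_edges(path, min_combined_score: int = 400,
                      required_channels=None) -> nx.Graph:
    """Read a STRING-dialect TSV into an undirected, deduplicated graph.

    Keeps an edge iff combined_score >= min_combined_score and, when
    ``required_channels`` is given, at least one listed channel score is > 0.
    A-B / B-A duplicates are merged keeping the maximum combined score.
    Edge weight = combined_score / 1000.
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"protein1", "protein2", "combined_score"}
    if not needed.issubset(df.columns):
        raise FormatError(f"edge file lacks required columns "
                          f"{sorted(needed - set(df.columns))}")
    if required_channels:
        missing = [c for c in required_channels if c not in df.columns]
        if missing:
            raise FormatError(f"edge file lacks channel columns {missing}")

    best: dict[tuple, float] = {}
    channel_ok: dict[tuple, bool] = {}
    for row in df.itertuples(index=False):
        a, b = str(row.protein1), str(row.protein2)
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        score = float(row.combined_score)
        ok = True
        if required_channels:
            ok = any(float(getattr(row, c)) > 0 for c in required_channels)
        if key not in best or score > best[key]:
            best[key] = score
            channel_ok[key] = ok
        elif score == best[key]:
            channel_ok[key] = channel_ok[key] or ok

    g = nx.Graph()
    for (a, b), score in best.items():
        if score >= min_combined_score and channel_ok[(a, b)]:
            g.add_edge(a, b, weight=score / 1000.0, combined_score=score)
    return g


def _component_distances(graph: nx.Graph):
    """Yield (component nodes, per-node distance sums, component size)."""
    for comp in nx.connected_components(graph):
        comp = set(comp)
        sums = {}
        for v in comp:
            dists = nx.single_source_shortest_path_length(graph, v)
            sums[v] = sum(d for u, d in dists.items() if u != v)
        yield comp, sums


def node_stats(graph: nx.Graph) -> pd.DataFrame:
    """Per-node degree K, unnormalized betweenness BC, closeness CC and mean
    shortest-path distance, computed per connected component."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    degree = dict(graph.degree)
    bc = nx.betweenness_centrality(graph, normalized=False)
    rows = {}
    for comp, sums, in _component_distances(graph):
        n_comp = len(comp)
        for v in comp:
            if n_comp == 1:
                cc, mean_d, singleton = 0.0, np.nan, True
            else:
                cc = (n_comp - 1) / sums[v]
                mean_d = sums[v] / (n_comp - 1)
                singleton = False
            rows[v] = {"K": degree[v], "BC": bc[v], "CC": cc,
                       "mean_distance": mean_d, "singleton": singleton}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "node"
    return table.sort_index()


def network_metrics(graph: nx.Graph) -> dict:
    """Global transitivity, edge density, mean distance over reachable
    unordered pairs, and diameter (in edges)."""
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    n = graph.number_of_nodes()
    metrics = {
        "n_nodes": n,
        "n_edges": graph.number_of_edges(),
        "transitivity": nx.transitivity(graph),
        "edge_density": (2.0 * graph.number_of_edges() / (n * (n - 1))
                         if n > 1 else 0.0),
    }
    total, pairs, diameter = 0.0, 0, 0
    for comp, sums in _component_distances(graph):
        if len(comp) < 2:
            continue
        total += sum(sums.values()) / 2.0
        pairs += len(comp) * (len(comp) - 1) // 2
        ecc = max(max(nx.single_source_shortest_path_length(graph, v).values())
                  for v in comp)
        diameter = max(diameter, ecc)
    if pairs == 0:
        metrics.update({"mean_distance": np.nan, "diameter": np.nan,
                        "distances_defined": False})
    else:
        metrics.update({"mean_distance": total / pairs, "diameter": diameter,
                        "distances_defined": True})
    return metrics


def classify_from_bounds(k: float, bc: float, k_hub: float = K_HUB,
                         bc_hub: float = BC_HUB, k_nonhub: float = K_NONHUB,
                         bc_nonhub_direct: float = BC_NONHUB_DIRECT) -> str:
    """Label a node from its (K, BC) values alone: hub above both hub
    thresholds, nonhub-eligible within both nonhub bounds, otherwise other.
    (Hub proximity is not checked here; see classify_nodes.)"""
    if k > k_hub and bc > bc_hub:
        return HUB
    if k <= k_nonhub and bc < bc_nonhub_direct:
        return NONHUB
    return OTHER


def classify_nodes(stats: pd.DataFrame, graph: nx.Graph, k_hub: float = K_HUB,
                   bc_hub: float = BC_HUB, k_nonhub: float = K_NONHUB,
                   bc_nonhub_direct: float = BC_NONHUB_DIRECT) -> pd.Series:
    """Hub/nonhub/other labels.

    hub: K > k_hub and BC > bc_hub.  Among the rest, nonhub: either a direct
    neighbor of a hub with K <= k_nonhub and BC < bc_nonhub_direct, or at
    unweighted distance exactly 2 from a hub with K <= k_nonhub and BC == 0.
    """
    k = stats["K"]
    bc = stats["BC"]
    hubs = set(stats.index[(k > k_hub) & (bc > bc_hub)])
    dist1, dist2 = set(), set()
    for h in hubs:
        dist1.update(graph.neighbors(h))
    for v in dist1:
        dist2.update(graph.neighbors(v))
    dist1 -= hubs
    dist2 -= hubs | dist1

    labels = {}
    for v in stats.index:
        if v in hubs:
            labels[v] = HUB
        elif (v in dist1 and k[v] <= k_nonhub and bc[v] < bc_nonhub_direct):
            labels[v] = NONHUB
        elif (v in dist2 and k[v] <= k_nonhub and bc[v] == 0):
            labels[v] = NONHUB
        else:
            labels[v] = OTHER
    return pd.Series(labels, name="label").loc[stats.index]


@dataclass
class Clustering:
    """A partition of the node set with its modularity."""

    assignments: dict
    modularity_q: float
    q_trajectory: list[float] = field(default_factory=list)

    def communities(self) -> list[set]:
        out: dict = {}
        for node, cid in self.assignments.items():
            out.setdefault(cid, set()).add(node)
        return [out[c] for c in sorted(out)]


def modularity(graph: nx.Graph, communities) -> float:
    """Q = sum_c (e_c / m - (d_c / 2m)^2) on the unweighted graph."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for comm in communities:
        comm = set(comm)
        intra = sum(1 for u, v in graph.edges(comm) if u in comm and v in comm)
        deg = sum(d for _, d in graph.degree(comm))
        q += intra / m - (deg / (2.0 * m)) ** 2
    return q


def greedy_modularity_clusters(graph: nx.Graph) -> Clustering:
    """Agglomerative greedy modularity maximization (unweighted).

    Repeatedly merges the connected community pair with the largest positive
    modularity gain; ties are broken by the lexicographically smallest sorted
    pair of community labels (a community's label is its smallest node id).
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("empty graph")
    m = graph.number_of_edges()
    nodes = sorted(graph.nodes, key=str)
    if m == 0:
        assignments = {v: i for i, v in enumerate(nodes)}
        return Clustering(assignments, 0.0, [0.0])

    # community state: label -> members, degree sum, inter-community edges
    members = {v: {v} for v in nodes}
    deg_sum = {v: float(graph.degree(v)) for v in nodes}
    e_between: dict = {v: {} for v in nodes}
    for u, v in graph.edges:
        if u == v:
            continue
        e_between[u][v] = e_between[u].get(v, 0) + 1
        e_between[v][u] = e_between[v].get(u, 0) + 1

    two_m = 2.0 * m
    q = sum(-(d / two_m) ** 2 for d in deg_sum.values())
    trajectory = [q]

    while True:
        best = None  # (dq, (label_lo, label_hi))
        for i in members:
            for j, eij in e_between[i].items():
                if str(j) <= str(i):
                    continue
                dq = eij / m - 2.0 * (deg_sum[i] / two_m) * (deg_sum[j] / two_m)
                key = (dq, tuple(sorted((str(i), str(j)))))
                if best is None or dq > best[0] + 1e-15 or (
                        abs(dq - best[0]) <= 1e-15 and key[1] < best[1]):
                    best = (dq, key[1], (i, j))
        if best is None or best[0] <= 1e-12:
            break
        _, _, (i, j) = best
        keep, drop = (i, j) if str(i) < str(j) else (j, i)
        q += best[0]
        trajectory.append(q)
        members[keep] |= members.pop(drop)
        deg_sum[keep] += deg_sum.pop(drop)
        drop_edges = e_between.pop(drop)
        for other, cnt in drop_edges.items():
            if other == keep:
                continue
            e_between[other].pop(drop, None)
            e_between[keep][other] = e_between[keep].get(other, 0) + cnt
            e_between[other][keep] = e_between[keep][other]
        e_between[keep].pop(drop, None)

    assignments = {}
    for cid, (label, comm) in enumerate(sorted(members.items(),
                                               key=lambda kv: str(kv[0]))):
        for v in comm:
            assignments[v] = cid
    q_final = modularity(graph, members.values())
    return Clustering(assignments, q_final, trajectory)
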