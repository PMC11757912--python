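"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive: Floyd-Warshall for shortest paths,
explicit path enumeration for betweenness, triple enumeration for
transitivity, and exhaustive set-partition search for modularity.  None of
it calls the code paths under test.
"""
from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(nodes, edge_lengths):
    """All-pairs shortest paths.  ``edge_lengths``: {(u, v): length}."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (u, v), w in edge_lengths.items():
        i, j = idx[u], idx[v]
        d[i, j] = min(d[i, j], w)
        d[j, i] = min(d[j, i], w)
    for k in range(n):
        d = np.minimum(d, d[:, k][:, None] + d[k, :][None, :])
    return d


def _unweighted_lengths(graph):
    return {(u, v): 1.0 for u, v in graph.edges}


def unweighted_distances(graph):
    nodes = sorted(graph.nodes, key=str)
    return nodes, floyd_warshall(nodes, _unweighted_lengths(graph))


def brute_betweenness(graph):
    """Unnormalized betweenness by enumerating every shortest path."""
    nodes, d = unweighted_distances(graph)
    idx = {v: i for i, v in enumerate(nodes)}
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        if not math.isfinite(d[idx[s], idx[t]]):
            continue
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(list(path))
                return
            for w in graph.neighbors(u):
                if d[idx[w], idx[t]] == d[idx[u], idx[t]] - 1:
                    extend(path + [w])

        extend([s])
        sigma = len(paths)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / sigma
    return bc


def brute_closeness(graph):
    """(n_comp - 1) / sum of distances, per connected component."""
    nodes, d = unweighted_distances(graph)
    cc = {}
    for i, v in enumerate(nodes):
        reach = [j for j in range(len(nodes)) if j != i and math.isfinite(d[i, j])]
        if not reach:
            cc[v] = 0.0
        else:
            cc[v] = len(reach) / d[i, reach].sum()
    return cc


def brute_transitivity(graph):
    """3 * triangles / connected triples, by enumerating triples."""
    nodes = list(graph.nodes)
    triangles = 0
    triples = 0
    for a, b, c in itertools.combinations(nodes, 3):
        e = {frozenset(p) for p in itertools.combinations((a, b, c), 2)
             if graph.has_edge(*p)}
        if len(e) == 3:
            triangles += 1
        for center in (a, b, c):
            others = [x for x in (a, b, c) if x != center]
            if graph.has_edge(center, others[0]) and graph.has_edge(center, others[1]):
                triples += 1
    return 3.0 * triangles / triples if triples else 0.0


def brute_density(graph):
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    pairs = sum(1 for _ in itertools.combinations(graph.nodes, 2))
    return graph.number_of_edges() / pairs


def brute_distance_metrics(graph):
    """(mean distance over reachable unordered pairs, diameter)."""
    nodes, d = unweighted_distances(graph)
    finite = []
    for i, j in itertools.combinations(range(len(nodes)), 2):
        if math.isfinite(d[i, j]):
            finite.append(d[i, j])
    if not finite:
        return math.nan, math.nan
    return float(np.mean(finite)), float(max(finite))


def direct_modularity(graph, communities):
    """Q by the raw double-sum definition over node pairs."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    label = {}
    for cid, comm in enumerate(communities):
        for v in comm:
            label[v] = cid
    q = 0.0
    for u in graph.nodes:
        for v in graph.nodes:
            if label[u] != label[v]:
                continue
            a = 1.0 if graph.has_edge(u, v) else 0.0
            q += a - graph.degree(u) * graph.degree(v) / (2.0 * m)
    return q / (2.0 * m)


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_by_modularity(graph):
    """Exhaustive max-modularity partition (small graphs only)."""
    best_q, best_part = -math.inf, None
    for part in set_partitions(list(graph.nodes)):
        q = direct_modularity(graph, [set(p) for p in part])
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    return best_q, [set(p) for p in best_part]


def random_graph(rng, n_max=10, p=0.4, weighted=False):
    """A small random undirected graph for oracle comparisons."""
    import networkx as nx

    n = int(rng.integers(2, n_max + 1))
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < p:
            w = float(rng.uniform(0.1, 2.0)) if weighted else 1.0
            g.add_edge(f"n{i}", f"n{j}", weight=w, length=w)
    return g
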