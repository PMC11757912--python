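import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexnet import ppin
from coexnet.exceptions import FormatError, ValidationError
from coexnet.synthetic_data import SimulationConfig, simulate_graph, write_string_edges
from _oracles import (best_partition_by_modularity, brute_betweenness,
                      brute_closeness, brute_density, brute_distance_metrics,
                      brute_transitivity, direct_modularity, random_graph)


def _write_edges(tmp_path, rows, columns=("protein1", "protein2", "combined_score")):
    path = tmp_path / "edges.tsv"
    pd.DataFrame(rows, columns=list(columns)).to_csv(path, sep="\t", index=False)
    return path


class TestReadStringEdges:
    def test_duplicate_rows_merged(self, tmp_path):
        path = _write_edges(tmp_path, [("A", "B", 700), ("B", "A", 700)])
        g = ppin.read_string_edges(path)
        assert g.number_of_edges() == 1
        assert g.edges["A", "B"]["weight"] == pytest.approx(0.7)

    def test_duplicate_keeps_max_score(self, tmp_path):
        path = _write_edges(tmp_path, [("A", "B", 500), ("B", "A", 900)])
        g = ppin.read_string_edges(path)
        assert g.edges["A", "B"]["combined_score"] == 900

    def test_low_score_dropped(self, tmp_path):
        path = _write_edges(tmp_path, [("A", "C", 150)])
        g = ppin.read_string_edges(path, min_combined_score=400)
        assert g.number_of_edges() == 0

    def test_fixture_count_matches_hand_enumeration(self, tmp_path):
        rows = [("A", "B", 700), ("B", "A", 650), ("A", "C", 399),
                ("C", "D", 400), ("D", "C", 200), ("E", "F", 950),
                ("F", "G", 10), ("G", "H", 888), ("H", "G", 888),
                ("A", "D", 401)]
        path = _write_edges(tmp_path, rows)
        g = ppin.read_string_edges(path, min_combined_score=400)
        # hand count after dedup-keeping-max: AB=700, CD=400, EF=950,
        # GH=888, AD=401 pass; AC=399 and FG=10 fail
        assert g.number_of_edges() == 5

    def test_missing_columns_rejected(self, tmp_path):
        path = _write_edges(tmp_path, [("A", "B")], columns=("protein1", "protein2"))
        with pytest.raises(FormatError):
            ppin.read_string_edges(path)

    def test_required_channels(self, tmp_path):
        path = tmp_path / "edges.tsv"
        pd.DataFrame(
            [("A", "B", 500, 0), ("C", "D", 500, 80)],
            columns=["protein1", "protein2", "combined_score", "experimental"],
        ).to_csv(path, sep="\t", index=False)
        g = ppin.read_string_edges(path, required_channels=["experimental"])
        assert list(g.edges) == [("C", "D")]
        with pytest.raises(FormatError):
            ppin.read_string_edges(path, required_channels=["fusion"])

    def test_self_loops_discarded(self, tmp_path):
        path = _write_edges(tmp_path, [("A", "A", 900), ("A", "B", 900)])
        g = ppin.read_string_edges(path)
        assert list(g.edges) == [("A", "B")]


class TestNodeStats:
    def test_path_center(self):
        g = nx.path_graph(["A", "B", "C"])
        stats = ppin.node_stats(g)
        row = stats.loc["B"]
        assert row["K"] == 2
        assert row["BC"] == pytest.approx(1.0)
        assert row["CC"] == pytest.approx(1.0)
        assert row["mean_distance"] == pytest.approx(1.0)

    def test_path_endpoint(self):
        g = nx.path_graph(["A", "B", "C"])
        row = ppin.node_stats(g).loc["A"]
        assert row["K"] == 1
        assert row["BC"] == pytest.approx(0.0)
        assert row["CC"] == pytest.approx(2.0 / 3.0)

    def test_complete_graph(self):
        g = nx.complete_graph(4)
        stats = ppin.node_stats(g)
        assert (stats["BC"] == 0).all()
        assert (stats["CC"] == 1.0).all()

    def test_cc_times_mean_distance_is_one(self):
        rng = np.random.default_rng(0)
        g = random_graph(rng, n_max=10)
        stats = ppin.node_stats(g)
        ok = ~stats["singleton"]
        np.testing.assert_allclose(
            (stats.loc[ok, "CC"] * stats.loc[ok, "mean_distance"]), 1.0)

    def test_singleton_flagged(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b")
        stats = ppin.node_stats(g)
        assert stats.loc["solo", "CC"] == 0.0
        assert stats.loc["solo", "singleton"]

    @pytest.mark.parametrize("seed", range(10))
    def test_bc_cc_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, n_max=8)
        stats = ppin.node_stats(g)
        bc_ref = brute_betweenness(g)
        cc_ref = brute_closeness(g)
        for v in g.nodes:
            assert stats.loc[v, "BC"] == pytest.approx(bc_ref[v], abs=1e-9)
            assert stats.loc[v, "CC"] == pytest.approx(cc_ref[v], abs=1e-9)


class TestNetworkMetrics:
    def test_triangle(self):
        m = ppin.network_metrics(nx.complete_graph(3))
        assert m["transitivity"] == pytest.approx(1.0)
        assert m["edge_density"] == pytest.approx(1.0)
        assert m["mean_distance"] == pytest.approx(1.0)
        assert m["diameter"] == 1

    def test_path_of_four(self):
        m = ppin.network_metrics(nx.path_graph(4))
        assert m["transitivity"] == 0.0
        assert m["edge_density"] == pytest.approx(0.5)
        assert m["mean_distance"] == pytest.approx(10.0 / 6.0)
        assert m["diameter"] == 3

    def test_no_edges_flagged(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        m = ppin.network_metrics(g)
        assert m["edge_density"] == 0.0
        assert not m["distances_defined"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_graph(rng, n_max=10)
        m = ppin.network_metrics(g)
        assert m["transitivity"] == pytest.approx(brute_transitivity(g), abs=1e-12)
        assert m["edge_density"] == pytest.approx(brute_density(g), abs=1e-12)
        mean_ref, diam_ref = brute_distance_metrics(g)
        if m["distances_defined"]:
            assert m["mean_distance"] == pytest.approx(mean_ref, abs=1e-12)
            assert m["diameter"] == diam_ref


class TestClassifyNodes:
    def test_bounds_only_labels(self):
        assert ppin.classify_from_bounds(39, 436.86) == "hub"
        assert ppin.classify_from_bounds(1, 0.0) == "nonhub"
        assert ppin.classify_from_bounds(4, 0.0) == "other"
        # boundary: thresholds are strict for hubs
        assert ppin.classify_from_bounds(13, 100.0) == "other"
        assert ppin.classify_from_bounds(20, 63.94) == "other"
        # nonhub degree bound is inclusive
        assert ppin.classify_from_bounds(3, 1.39) == "nonhub"

    def _hub_graph(self):
        g = nx.Graph()
        hub = "HUB"
        for i in range(20):
            g.add_edge(hub, f"f{i}")
        g.add_edge("direct", hub)
        g.add_edge("indirect", "f0")  # pendant at distance 2, BC = 0
        g.add_edge("mid", "f1")
        g.add_edge("far", "mid")  # distance 3 from hub; mid gets BC > 0
        return g

    def test_graph_classification(self):
        g = self._hub_graph()
        stats = ppin.node_stats(g)
        labels = ppin.classify_nodes(stats, g)
        assert labels["HUB"] == "hub"
        assert labels["direct"] == "nonhub"
        assert labels["indirect"] == "nonhub"
        assert labels["mid"] == "other"  # at distance 2 but BC > 0
        assert labels["far"] == "other"

    def test_labels_partition_nodes(self):
        g = self._hub_graph()
        labels = ppin.classify_nodes(ppin.node_stats(g), g)
        assert set(labels.index) == set(g.nodes)
        assert set(labels.unique()) <= {"hub", "nonhub", "other"}

    def test_planted_graph_recovered(self):
        cfg = SimulationConfig(n_hubs=2, n_nonhubs=6, n_fillers_per_hub=14,
                               seed=21)
        g, gt = simulate_graph(cfg)
        stats = ppin.node_stats(g)
        labels = ppin.classify_nodes(stats, g)
        for h in gt.planted_hubs:
            assert labels[h] == "hub"
        for nh in gt.planted_nonhubs:
            assert labels[nh] == "nonhub"

    def test_round_trip_through_string_file(self, tmp_path):
        cfg = SimulationConfig(n_hubs=2, n_nonhubs=4, seed=33)
        g, gt = simulate_graph(cfg)
        path = tmp_path / "edges.tsv"
        write_string_edges(g, path)
        g2 = ppin.read_string_edges(path, min_combined_score=0)
        assert set(g2.edges) == {tuple(sorted(e)) for e in g.edges} or \
            set(map(frozenset, g2.edges)) == set(map(frozenset, g.edges))


class TestGreedyModularity:
    def test_two_cliques_split(self):
        g = nx.Graph()
        a = ["a1", "a2", "a3", "a4"]
        b = ["b1", "b2", "b3", "b4"]
        for grp in (a, b):
            g.add_edges_from(itertools.combinations(grp, 2))
        g.add_edge("a1", "b1")
        clustering = ppin.greedy_modularity_clusters(g)
        comms = {frozenset(c) for c in clustering.communities()}
        assert comms == {frozenset(a), frozenset(b)}
        # oracle: exhaustive modularity maximization over all partitions
        best_q, best_part = best_partition_by_modularity(g)
        assert {frozenset(c) for c in best_part} == comms
        assert clustering.modularity_q == pytest.approx(best_q, abs=1e-12)

    def test_single_clique_one_cluster(self):
        g = nx.complete_graph(5)
        clustering = ppin.greedy_modularity_clusters(g)
        assert len(set(clustering.assignments.values())) == 1

    def test_q_self_consistent(self):
        rng = np.random.default_rng(5)
        g = random_graph(rng, n_max=12, p=0.3)
        clustering = ppin.greedy_modularity_clusters(g)
        q_direct = direct_modularity(g, clustering.communities())
        assert clustering.modularity_q == pytest.approx(q_direct, abs=1e-12)

    def test_q_matches_networkx_evaluation(self):
        rng = np.random.default_rng(6)
        g = random_graph(rng, n_max=12, p=0.4)
        clustering = ppin.greedy_modularity_clusters(g)
        q_nx = nx.community.modularity(g, clustering.communities())
        assert clustering.modularity_q == pytest.approx(q_nx, abs=1e-12)

    def test_partition_property(self):
        rng = np.random.default_rng(7)
        g = random_graph(rng, n_max=10)
        clustering = ppin.greedy_modularity_clusters(g)
        assert set(clustering.assignments) == set(g.nodes)

    def test_q_never_decreases_along_merges(self):
        rng = np.random.default_rng(8)
        g = random_graph(rng, n_max=12, p=0.3)
        clustering = ppin.greedy_modularity_clusters(g)
        diffs = np.diff(clustering.q_trajectory)
        assert (diffs > 0).all()

    def test_deterministic(self):
        g = nx.karate_club_graph()
        c1 = ppin.greedy_modularity_clusters(g)
        c2 = ppin.greedy_modularity_clusters(g)
        assert c1.assignments == c2.assignments

    def test_empty_graph_rejected(self):
        with pytest.raises(ValidationError):
            ppin.greedy_modularity_clusters(nx.Graph())
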