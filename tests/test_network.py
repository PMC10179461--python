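import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from lncdosage import (
    CentralityConfig,
    build_network,
    centrality_suite,
    maximal_cliques,
    mcc,
    select_hubs,
    summarize_target_regulation,
)
from lncdosage.network import read_sif, write_sif
from lncdosage.targets import TargetPair, cis_targets, trans_targets


def pair(l, t, mode="cis"):
    return TargetPair(lncrna_id=l, target_id=t, mode=mode, distance=0 if mode == "cis" else None)


class TestBuildNetwork:
    def test_star_from_shared_lncrna(self):
        g = build_network([pair("L", "a"), pair("L", "b"), pair("L", "c")])
        assert g.number_of_edges() == 3 and g.degree("L") == 3

    def test_duplicate_cis_trans_pair_single_edge(self):
        g = build_network([pair("L", "a", "cis"), pair("L", "a", "trans")])
        assert g.number_of_edges() == 1

    def test_empty_pairs_empty_graph(self):
        g = build_network([])
        assert g.number_of_nodes() == 0

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError):
            build_network([TargetPair("x", "x", "cis", distance=0)])

    def test_node_kinds_bipartite(self):
        g = build_network([pair("L1", "a"), pair("L2", "a")])
        kinds = nx.get_node_attributes(g, "kind")
        assert kinds == {"L1": "lncRNA", "L2": "lncRNA", "a": "mRNA"}


def brute_force_cliques(g):
    """Exponential oracle: maximal cliques of size >= 2 by subset enumeration."""
    nodes = sorted(g.nodes)
    cliques = []
    for k in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, k):
            if all(g.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    return sorted(
        tuple(sorted(c)) for c in cliques if not any(c < other for other in cliques)
    )


class TestMaximalCliques:
    def test_triangle(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert maximal_cliques(g) == [("a", "b", "c")]

    def test_path(self):
        g = nx.path_graph(["a", "b", "c"])
        assert maximal_cliques(g) == [("a", "b"), ("b", "c")]

    def test_isolated_node_excluded(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b")
        assert maximal_cliques(g) == [("a", "b")]

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_brute_force(self, seed):
        g = nx.gnp_random_graph(12, 0.4, seed=seed)
        assert maximal_cliques(g) == brute_force_cliques(g)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_enumeration(self, seed):
        g = nx.gnp_random_graph(20, 0.3, seed=seed)
        ours = set(maximal_cliques(g))
        ref = {tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= 2}
        assert ours == ref


class TestMcc:
    def test_star_center_equals_leaf_count(self):
        g = nx.star_graph(30)  # center 0, leaves 1..30
        assert mcc(g)[0] == 30

    def test_triangle_nodes_score_two(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert mcc(g) == {"a": 2, "b": 2, "c": 2}

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("x")
        assert mcc(g)["x"] == 0

    def test_equals_degree_on_bipartite_graphs(self, small_dataset):
        """No neighbour-neighbour edges => all maximal cliques are edges."""
        lncs = [g for g in small_dataset.annotation if g.biotype == "lncRNA"]
        coding = [g for g in small_dataset.annotation if g.biotype == "coding"]
        pairs = cis_targets(lncs, coding)
        graph = build_network(pairs)
        scores = mcc(graph)
        assert scores and all(scores[v] == graph.degree(v) for v in graph.nodes)


class TestCentralitySuite:
    def test_p3_hand_values(self):
        g = nx.path_graph(["a", "b", "c"])
        table = centrality_suite(g)
        b = table.loc["b"]
        assert b.Betweenness == 1 and b.Stress == 1
        assert b.Radiality == pytest.approx(2.0)
        assert b.Closeness == pytest.approx(2.0)
        assert b.Eccentricity == pytest.approx(1.0)
        a = table.loc["a"]
        assert a.Radiality == pytest.approx(1.5)
        assert a.Closeness == pytest.approx(1.5)
        assert a.Eccentricity == pytest.approx(0.5)

    def test_lncrna_nodes_have_dmnc_zero_mnc_one(self):
        g = build_network([pair("L", "a"), pair("L", "b"), pair("M", "b"), pair("M", "c")])
        table = centrality_suite(g)
        for v in ("L", "M"):
            assert table.loc[v, "DMNC"] == 0
            assert table.loc[v, "MNC"] == 1

    def test_epc_two_node_closed_form(self):
        g = nx.Graph([("a", "b")])
        config = CentralityConfig(epc_iterations=4000, seed=1)
        table = centrality_suite(g, config)
        # E[size] = 0.5*2 + 0.5*1 = 1.5; SE = sqrt(0.25)/sqrt(K)
        se = 0.5 / math.sqrt(4000)
        assert abs(table.loc["a", "EPC"] - 1.5) < 3 * se

    def test_epc_path_closed_form(self):
        g = nx.path_graph(["a", "b", "c"])
        config = CentralityConfig(epc_iterations=4000, seed=2)
        table = centrality_suite(g, config)
        # center: 0.25*3 + 0.5*2 + 0.25*1 = 2.0 ; end: 0.25*3 + 0.25*2 + 0.5*1 = 1.75
        sd_center = math.sqrt(0.25 * 9 + 0.5 * 4 + 0.25 * 1 - 4.0)
        assert abs(table.loc["b", "EPC"] - 2.0) < 3 * sd_center / math.sqrt(4000)
        sd_end = math.sqrt(0.25 * 9 + 0.25 * 4 + 0.5 * 1 - 1.75**2)
        assert abs(table.loc["a", "EPC"] - 1.75) < 3 * sd_end / math.sqrt(4000)

    def test_isolated_node_row_finite(self):
        g = nx.Graph([("a", "b")])
        g.add_node("solo")
        table = centrality_suite(g)
        row = table.loc["solo"]
        assert row.MCC == 0 and row.Degree == 0 and row.MNC == 0
        assert np.isfinite(row.to_numpy(dtype=float)).all()

    def test_table_column_order_and_sorting(self):
        g = build_network([pair("L", "a"), pair("L", "b"), pair("M", "c")])
        table = centrality_suite(g)
        assert list(table.columns) == [
            "MCC", "DMNC", "MNC", "Degree", "EPC", "Bottleneck",
            "Eccentricity", "Closeness", "Radiality", "Betweenness", "Stress",
        ]
        assert table.index[0] == "L"  # highest MCC first

    def test_determinism_given_seed(self):
        g = nx.gnp_random_graph(15, 0.3, seed=3)
        t1 = centrality_suite(g, CentralityConfig(seed=5))
        t2 = centrality_suite(g, CentralityConfig(seed=5))
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize("seed", range(10))
    def test_metrics_match_independent_oracles(self, seed):
        """Betweenness/stress/closeness/radiality/eccentricity vs brute-force
        path enumeration on random graphs of <= 12 nodes."""
        g = nx.gnp_random_graph(10, 0.35, seed=seed)
        table = centrality_suite(g)
        stress_ref = {v: 0.0 for v in g.nodes}
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            dist = {s: nx.single_source_shortest_path_length(g, s) for s in comp}
            for s, t in itertools.combinations(comp, 2):
                paths = list(nx.all_shortest_paths(g, s, t))
                for v in comp:
                    if v in (s, t):
                        continue
                    stress_ref[v] += sum(1 for p in paths if v in p)
            diam = max(max(d.values()) for d in dist.values())
            n = len(comp)
            for v in comp:
                if n > 1:
                    rad = sum(diam + 1 - dist[v][u] for u in comp if u != v) / (n - 1)
                    assert table.loc[v, "Radiality"] == pytest.approx(rad)
                    assert table.loc[v, "Closeness"] == pytest.approx(
                        sum(1 / dist[v][u] for u in comp if u != v)
                    )
                    assert table.loc[v, "Eccentricity"] == pytest.approx(
                        1 / max(dist[v].values())
                    )
        bet_ref = nx.betweenness_centrality(g, normalized=False)
        for v in g.nodes:
            assert table.loc[v, "Stress"] == pytest.approx(stress_ref[v])
            assert table.loc[v, "Betweenness"] == pytest.approx(bet_ref[v])


class TestSelectHubs:
    def test_threshold_inclusive(self):
        table = pd.DataFrame({"MCC": [31, 30, 29]}, index=["A", "B", "C"])
        hubs, _ = select_hubs(table, min_mcc=30)
        assert hubs == ["A", "B"]

    def test_all_below_threshold(self):
        table = pd.DataFrame({"MCC": [5, 3]}, index=["A", "B"])
        assert select_hubs(table, min_mcc=30)[0] == []

    def test_star_subnetwork_is_whole_star(self):
        g = build_network([pair("L", f"m{i}") for i in range(35)])
        table = centrality_suite(g)
        hubs, sub = select_hubs(table, min_mcc=30, graph=g)
        assert hubs == ["L"]
        assert set(sub.nodes) == set(g.nodes) and sub.number_of_edges() == 35

    def test_only_lncrna_nodes_eligible_with_graph(self):
        # an mRNA shared by many lncRNAs gets a high MCC but is not a hub
        g = build_network([pair(f"L{i}", "shared") for i in range(32)])
        table = centrality_suite(g)
        hubs, _ = select_hubs(table, min_mcc=30, graph=g)
        assert hubs == []


class TestSummarizeTargetRegulation:
    def test_breakdown_sums(self):
        status = {}
        for i in range(41):
            status[f"d{i}"] = {"down"}
        for i in range(26):
            status[f"u{i}"] = {"up"}
        for i in range(7):
            status[f"b{i}"] = {"up", "down"}
        for i in range(73):
            status[f"n{i}"] = {"ns"}
        out = summarize_target_regulation(status)
        assert out == {"n_down": 41, "n_up": 26, "n_both": 7, "n_ns": 73, "total": 147}

    def test_scalar_statuses_accepted(self):
        out = summarize_target_regulation({"a": "up", "b": "ns"})
        assert out["n_up"] == 1 and out["n_ns"] == 1 and out["total"] == 2


class TestSifIO:
    def test_round_trip(self, tmp_path):
        g = build_network([pair("L", "a"), pair("L", "b")])
        g.add_node("solo")
        write_sif(g, tmp_path / "g.sif")
        back = read_sif(tmp_path / "g.sif")
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
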