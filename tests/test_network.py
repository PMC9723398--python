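"""Edge filtering, network building, the centrality battery, hubs and null models."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phosphonet import (
    ConfigError,
    InteractionEdge,
    NetworkModel,
    build_network,
    compute_centralities,
    filter_edges,
    generate_network,
    null_distribution,
    randomize_network,
    select_hubs,
)
from phosphonet.network import MODE_SIGNALING

from _oracles import brute_force_betweenness_stress


def _model(G, mode="ppi_undirected"):
    return NetworkModel(graph=G, mode=mode)


class TestEdgeFiltering:
    def test_experiments_channel_at_threshold(self):
        edge = InteractionEdge("A", "B", experiments=0.20)
        assert filter_edges([edge]) == [edge]
        assert filter_edges([InteractionEdge("A", "B", experiments=0.15)]) != []

    def test_databases_below_threshold_dropped(self):
        assert filter_edges([InteractionEdge("A", "B", databases=0.30)]) == []

    def test_disjunction_over_channels(self):
        edge = InteractionEdge("A", "B", experiments=0.10, databases=0.40)
        assert filter_edges([edge]) == [edge]

    def test_self_loops_and_bad_scores_rejected_at_construction(self):
        with pytest.raises(ConfigError, match="self-loop"):
            InteractionEdge("A", "A")
        with pytest.raises(ConfigError, match="score"):
            InteractionEdge("A", "B", experiments=1.2)


class TestBuildNetwork:
    def test_induced_subgraph_keeps_isolated_dpps(self):
        edges = [
            InteractionEdge("A", "B", experiments=0.9),
            InteractionEdge("A", "D", experiments=0.9),
        ]
        net = build_network(["A", "B", "C"], edges)
        assert set(net.graph.nodes) == {"A", "B", "C"}
        assert set(net.graph.edges) == {("A", "B")}

    def test_edgeless_network_warns(self):
        net = build_network(["A", "B"], [])
        assert net.n_edges == 0
        assert any("edgeless" in w for w in net.warnings)

    def test_signaling_mode_directs_activation_not_docking(self):
        edges = [
            InteractionEdge("A", "B", relation="activation"),
            InteractionEdge("B", "C", relation="docking"),
        ]
        net = build_network(["A", "B", "C"], edges, mode=MODE_SIGNALING)
        assert net.graph.has_edge("A", "B") and not net.graph.has_edge("B", "A")
        assert net.graph.has_edge("B", "C") and net.graph.has_edge("C", "B")

    def test_empty_dpp_list_is_an_error(self):
        with pytest.raises(ConfigError, match="empty"):
            build_network([], [])


class TestCentralities:
    def test_path_graph_betweenness_counts_ordered_pairs(self):
        profiles = compute_centralities(_model(nx.path_graph(["A", "B", "C"])))
        assert profiles.loc["B", "betweenness"] == 2.0
        assert profiles.loc["A", "betweenness"] == 0.0
        assert profiles.loc["B", "stress"] == 2.0

    def test_star_center_betweenness_and_stress(self):
        G = nx.star_graph(3)  # center 0, leaves 1..3
        profiles = compute_centralities(_model(G))
        assert profiles.loc[0, "betweenness"] == 6.0
        assert profiles.loc[0, "stress"] == 6.0
        assert profiles.loc[0, "eigenvector"] == pytest.approx(1.0)

    def test_path_graph_full_battery_hand_values(self):
        profiles = compute_centralities(_model(nx.path_graph(["A", "B", "C"])))
        b = profiles.loc["B"]
        assert b["closeness"] == pytest.approx(1 / 2)
        assert b["eccentricity"] == pytest.approx(1.0)
        # diameter 2, component size 3: ((2+1-1) + (2+1-1)) / 2
        assert b["radiality"] == pytest.approx(2.0)
        # B is strictly closer to the other endpoint than either end is
        assert b["centroid"] == 1.0
        assert b["in_degree"] == b["out_degree"] == 2
        # bridging coefficient of B: (1/2) / (1/1 + 1/1) = 0.25
        assert b["bridging"] == pytest.approx(0.5)
        a = profiles.loc["A"]
        assert a["closeness"] == pytest.approx(1 / 3)
        assert a["eccentricity"] == pytest.approx(1 / 2)
        assert a["bridging"] == 0.0

    def test_isolated_node_scores_zero_without_division_errors(self):
        G = nx.Graph()
        G.add_nodes_from(["A", "B", "C"])
        G.add_edge("A", "B")
        profiles = compute_centralities(_model(G))
        c = profiles.loc["C"]
        for column in ("betweenness", "stress", "closeness", "eccentricity", "radiality", "bridging"):
            assert c[column] == 0.0
        assert c["in_degree"] == 0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            G = nx.gnp_random_graph(8, 0.35, seed=int(rng.integers(2**31)))
            profiles = compute_centralities(_model(G))
            betweenness, stress = brute_force_betweenness_stress(G)
            for v in G:
                assert profiles.loc[v, "betweenness"] == pytest.approx(betweenness[v])
                assert profiles.loc[v, "stress"] == pytest.approx(stress[v])

    def test_directed_mode_matches_brute_force(self):
        G = nx.gnp_random_graph(8, 0.3, seed=5, directed=True)
        profiles = compute_centralities(_model(G, mode=MODE_SIGNALING))
        betweenness, stress = brute_force_betweenness_stress(G)
        for v in G:
            assert profiles.loc[v, "betweenness"] == pytest.approx(betweenness[v])
            assert profiles.loc[v, "stress"] == pytest.approx(stress[v])
        assert (profiles["in_degree"] == [d for _, d in G.in_degree()]).all()

    def test_empty_network_is_an_error(self):
        with pytest.raises(ConfigError, match="empty"):
            compute_centralities(_model(nx.Graph()))


class TestHubSelection:
    def test_strictly_above_mean(self):
        profiles = pd.DataFrame(
            {"betweenness": [10.0, 2.0, 1.0, 1.0]}, index=["a", "b", "c", "d"]
        )
        assert select_hubs(profiles) == {"a"}  # mean 3.5

    def test_uniform_betweenness_yields_no_hubs(self):
        profiles = pd.DataFrame({"betweenness": [4.0, 4.0, 4.0]}, index=list("abc"))
        assert select_hubs(profiles) == set()

    def test_two_node_case(self):
        profiles = pd.DataFrame({"betweenness": [5.0, 1.0]}, index=["a", "b"])
        assert select_hubs(profiles) == {"a"}

    def test_invariant_under_uniform_scaling(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame({"betweenness": rng.uniform(0, 50, 30)})
        scaled = profiles * 17.0
        assert select_hubs(profiles) == select_hubs(scaled)


class TestRandomization:
    def test_triangle_is_rigid(self):
        net = _model(nx.complete_graph(3))
        rewired = randomize_network(net, n_swaps=100, seed=0)
        assert set(rewired.graph.edges) == set(net.graph.edges)

    def test_degree_multiset_conserved_across_seeds(self):
        G = nx.barabasi_albert_graph(40, 2, seed=1)
        net = _model(G)
        original = sorted(d for _, d in G.degree())
        for seed in range(10):
            rewired = randomize_network(net, seed=seed)
            assert sorted(d for _, d in rewired.graph.degree()) == original
            assert not any(u == v for u, v in rewired.graph.edges)

    def test_directed_rewiring_conserves_in_and_out_degrees(self):
        G = nx.gnp_random_graph(20, 0.2, seed=2, directed=True)
        net = _model(G, mode=MODE_SIGNALING)
        rewired = randomize_network(net, seed=4)
        assert sorted(d for _, d in rewired.graph.in_degree()) == sorted(
            d for _, d in G.in_degree()
        )
        assert sorted(d for _, d in rewired.graph.out_degree()) == sorted(
            d for _, d in G.out_degree()
        )

    def test_same_seed_identical_rewiring(self):
        net = _model(nx.barabasi_albert_graph(30, 2, seed=0))
        r1 = randomize_network(net, seed=9)
        r2 = randomize_network(net, seed=9)
        assert set(r1.graph.edges) == set(r2.graph.edges)

    def test_too_small_to_rewire_returns_input_with_warning(self):
        G = nx.Graph([("A", "B")])
        rewired = randomize_network(_model(G), seed=0)
        assert set(rewired.graph.edges) == {("A", "B")}
        assert any("too few edges" in w for w in rewired.warnings)


class TestNullDistribution:
    def test_rigid_triangle_gives_p_one(self):
        net = _model(nx.complete_graph(3))
        result = null_distribution(net, n_random=25, seed=0)
        assert (result.node_stats["empirical_p"] == 1.0).all()
        assert (result.node_stats["null_sd"] == 0.0).all()

    def test_add_one_correction_bounds_p(self):
        edges, truth = generate_network(
            15, model="erdos_renyi", model_params={"p": 0.4}, n_planted_connectors=1, seed=1
        )
        net = build_network(truth.nodes, edges)
        result = null_distribution(net, n_random=99, seed=2)
        p = result.node_stats["empirical_p"]
        assert (p >= 1 / 100).all() and (p <= 1.0).all()

    def test_planted_connector_is_significant(self):
        edges, truth = generate_network(
            21, model="erdos_renyi", model_params={"p": 0.4}, n_planted_connectors=1, seed=7
        )
        net = build_network(truth.nodes, edges)
        result = null_distribution(net, n_random=50, seed=3)
        assert result.node_stats.loc[truth.connectors[0], "empirical_p"] <= 0.05

    def test_replicate_table_is_violin_ready(self):
        net = _model(nx.barabasi_albert_graph(20, 2, seed=0))
        result = null_distribution(net, n_random=10, seed=1)
        assert list(result.replicate_table.columns) == ["replicate", "statistic", "value"]
        assert len(result.replicate_table) == 10
        assert (result.replicate_table["statistic"] == "mean_betweenness").all()
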