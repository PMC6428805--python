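import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from conftest import random_connected_graph
from ppinet import (
    DataError,
    PPINetError,
    betweenness,
    closeness,
    clustering_coefficient,
    compute_node_metrics,
    degree,
    eccentricity,
    eigenvector_centrality,
    global_metrics,
    mean_shortest_path_length,
    small_world_summary,
)


class TestDegree:
    def test_triangle_all_two(self, triangle):
        assert set(degree(triangle).values()) == {2}

    def test_star(self, star5):
        d = degree(star5)
        assert d["HUB"] == 5 and all(d[f"L{i}"] == 1 for i in range(5))

    def test_handshake_identity_on_synthetic_graph(self, bundle):
        d = degree(bundle.network)
        assert sum(d.values()) == 2 * bundle.network.number_of_edges()


class TestBetweenness:
    def test_path_center_carries_all_paths(self, path3):
        bc = betweenness(path3)
        assert bc["B"] == pytest.approx(1.0)
        assert bc["A"] == bc["C"] == 0.0

    def test_star_center_is_one(self, star5):
        bc = betweenness(star5)
        assert bc["HUB"] == pytest.approx(1.0)
        assert all(bc[f"L{i}"] == 0.0 for i in range(5))

    def test_tiny_graph_all_zero(self):
        g = nx.Graph([("A", "B")])
        assert betweenness(g) == {"A": 0.0, "B": 0.0}

    def test_matches_igraph_on_synthetic_graph(self, bundle):
        igraph = pytest.importorskip("igraph")
        g = bundle.network
        nodes = sorted(g.nodes)
        index = {v: i for i, v in enumerate(nodes)}
        ig = igraph.Graph(
            n=len(nodes), edges=[(index[a], index[b]) for a, b in g.edges]
        )
        norm = (len(nodes) - 1) * (len(nodes) - 2) / 2
        expected = {v: b / norm for v, b in zip(nodes, ig.betweenness())}
        ours = betweenness(g)
        assert ours == pytest.approx(expected, abs=1e-10)


class TestCloseness:
    def test_complete_graph_all_one(self, triangle):
        assert set(closeness(triangle).values()) == {1.0}

    def test_path_values(self, path3):
        cc = closeness(path3)
        assert cc["B"] == pytest.approx(1.0)
        assert cc["A"] == pytest.approx(2 / 3)

    def test_disconnected_input_instructs_giant_extraction(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        with pytest.raises(DataError, match="giant component"):
            closeness(g)


class TestEccentricity:
    def test_path_of_five(self):
        g = nx.path_graph(5)
        result = eccentricity(g)
        assert result.center == (2,)
        assert result.radius == 2 and result.diameter == 4

    def test_complete_graph_center_is_everyone(self):
        result = eccentricity(nx.complete_graph(4))
        assert set(result.center) == {0, 1, 2, 3}
        assert set(result.eccentricity.values()) == {1}

    def test_radius_diameter_sandwich_on_synthetic(self, bundle):
        result = eccentricity(bundle.network)
        assert result.radius <= result.diameter <= 2 * result.radius


class TestEigenvector:
    def test_cycle_symmetry_gives_all_ones(self):
        ec = eigenvector_centrality(nx.cycle_graph(6))
        assert all(v == pytest.approx(1.0) for v in ec.values())

    def test_star_center_dominates(self, star5):
        ec = eigenvector_centrality(star5)
        assert ec["HUB"] == 1.0
        assert all(ec[f"L{i}"] < 1.0 for i in range(5))

    def test_matches_dense_eigendecomposition(self, bundle):
        g = random_connected_graph(30, 0.15, seed=4)
        expected = oracles.dense_eigenvector(g)
        assert eigenvector_centrality(g) == pytest.approx(expected, abs=1e-8)

    def test_non_convergence_reports_residual(self, star5):
        with pytest.raises(PPINetError, match="residual"):
            eigenvector_centrality(star5, max_iter=1)


class TestClustering:
    def test_triangle_all_one(self, triangle):
        assert set(clustering_coefficient(triangle).values()) == {1.0}

    def test_star_center_zero(self, star5):
        assert clustering_coefficient(star5)["HUB"] == 0.0

    def test_low_degree_nodes_are_zero(self, path3):
        assert clustering_coefficient(path3)["A"] == 0.0

    def test_matches_triangle_counting_oracle(self, bundle):
        expected = oracles.brute_clustering(bundle.network)
        assert clustering_coefficient(bundle.network) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("seed", range(12))
def test_all_metrics_match_bruteforce_on_tiny_graphs(seed):
    """Exhaustive-enumeration oracles on random graphs of <= 7 nodes."""
    g = random_connected_graph(7, 0.4, seed=seed)
    if g.number_of_nodes() < 3:
        pytest.skip("degenerate draw")
    assert betweenness(g) == pytest.approx(oracles.brute_betweenness(g), abs=1e-8)
    assert closeness(g) == pytest.approx(oracles.brute_closeness(g), abs=1e-8)
    assert eccentricity(g).eccentricity == oracles.brute_eccentricity(g)
    assert clustering_coefficient(g) == pytest.approx(oracles.brute_clustering(g), abs=1e-8)
    assert eigenvector_centrality(g) == pytest.approx(oracles.dense_eigenvector(g), abs=1e-8)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_metrics_invariant_under_relabeling(seed):
    g = random_connected_graph(12, 0.3, seed=seed)
    if g.number_of_nodes() < 4:
        return
    mapping = {v: f"X{v}" for v in g.nodes}
    h = nx.relabel_nodes(g, mapping)
    for fn in (betweenness, closeness, clustering_coefficient):
        original = fn(g)
        relabeled = fn(h)
        assert relabeled == pytest.approx(
            {mapping[v]: x for v, x in original.items()}, abs=1e-10
        )


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_adding_an_edge_never_increases_eccentricity_or_mspl(seed):
    g = random_connected_graph(10, 0.3, seed=seed)
    nodes = sorted(g.nodes)
    if len(nodes) < 4:
        return
    missing = [
        (a, b)
        for i, a in enumerate(nodes)
        for b in nodes[i + 1 :]
        if not g.has_edge(a, b)
    ]
    if not missing:
        return
    before_ecc = eccentricity(g).eccentricity
    before_mspl = mean_shortest_path_length(g)
    g.add_edge(*missing[seed % len(missing)])
    after_ecc = eccentricity(g).eccentricity
    assert all(after_ecc[v] <= before_ecc[v] for v in nodes)
    assert mean_shortest_path_length(g) <= before_mspl + 1e-12


class TestGlobalMetrics:
    def test_complete_graph(self):
        gm = global_metrics(nx.complete_graph(4))
        assert gm.mspl == 1.0 and gm.diameter == 1 and gm.avg_clustering == 1.0

    def test_avg_degree_is_twice_edges_over_nodes(self, bundle):
        gm = global_metrics(bundle.network)
        assert gm.avg_degree == pytest.approx(
            2 * gm.n_edges / gm.n_nodes, abs=1e-12
        )

    def test_sd_uses_sample_denominator(self):
        g = nx.path_graph(4)  # degrees 1,2,2,1
        gm = global_metrics(g)
        assert gm.sd_degree == pytest.approx(np.std([1, 2, 2, 1], ddof=1))

    def test_mspl_matches_all_pairs_bfs_oracle(self, bundle):
        assert global_metrics(bundle.network).mspl == pytest.approx(
            oracles.brute_mspl(bundle.network), abs=1e-10
        )

    def test_center_nodes_attain_radius(self, bundle):
        gm = global_metrics(bundle.network)
        ecc = eccentricity(bundle.network)
        assert all(ecc.eccentricity[v] == gm.radius for v in gm.center)
        assert gm.mspl <= gm.diameter

    def test_disconnected_rejected(self):
        with pytest.raises(DataError):
            global_metrics(nx.Graph([("A", "B"), ("C", "D")]))

    def test_node_metric_rows_are_sorted_and_complete(self, bundle):
        rows = compute_node_metrics(bundle.network)
        assert [m.node for m in rows] == sorted(bundle.network.nodes)
        assert all(m.degree <= len(rows) - 1 for m in rows)


class TestSmallWorld:
    def test_ring_of_cliques_is_highly_clustered(self):
        g = nx.ring_of_cliques(8, 5)
        result = small_world_summary(g, n_random=10, rng_seed=0)
        assert result.clustering_ratio > 3.0

    def test_er_graph_against_itself_is_unremarkable(self):
        g = random_connected_graph(60, 0.12, seed=2)
        result = small_world_summary(g, n_random=30, rng_seed=1)
        assert abs(result.acc_observed - result.acc_random_mean) < max(
            3 * result.acc_random_sd, 0.05
        )
        assert abs(result.mspl_observed - result.mspl_random_mean) < max(
            3 * result.mspl_random_sd, 0.2
        )

    def test_bit_identical_under_fixed_seed(self, bundle):
        a = small_world_summary(bundle.network, n_random=10, rng_seed=5)
        b = small_world_summary(bundle.network, n_random=10, rng_seed=5)
        assert a == b

    def test_too_few_replicates_rejected(self, triangle):
        with pytest.raises(DataError):
            small_world_summary(triangle, n_random=5)
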