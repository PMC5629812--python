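import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import dijkstra

from landconnect.genetics import PopulationMatrixSet
from landconnect.popgraph import (
    conditional_genetic_distance,
    node_connectivity,
    prune_edges,
    read_graphml,
    saturated_graph,
    write_graphml,
)
from oracles import residual_partial_correlation


def _mats_from_centroids(cent: np.ndarray, n_per_site: int = 20) -> PopulationMatrixSet:
    """PopulationMatrixSet built directly from site centroid profiles."""
    k = cent.shape[0]
    centered = cent - cent.mean(axis=0)
    C = centered @ centered.T / (cent.shape[1] - 1)
    d = C.diagonal()
    D = np.maximum(d[:, None] + d[None, :] - 2 * C, 0.0)
    np.fill_diagonal(D, 0.0)
    order = [f"S{i}" for i in range(k)]
    return PopulationMatrixSet(order, C, D, pd.Series(n_per_site, index=order))


def _random_mats(seed: int, k: int = 8, p: int = 60) -> PopulationMatrixSet:
    rng = np.random.default_rng(seed)
    return _mats_from_centroids(rng.standard_normal((k, p)))


class TestSaturatedGraph:
    def test_complete_graph_edge_count_and_weights(self):
        mats = _random_mats(0, k=4)
        g = saturated_graph(mats)
        assert g.number_of_edges() == 6
        for i in range(4):
            for j in range(i + 1, 4):
                assert g[f"S{i}"][f"S{j}"]["weight"] == pytest.approx(mats.D[i, j])

    def test_identical_sites_clamped_with_warning(self):
        cent = np.tile(np.linspace(0, 1, 12), (3, 1))
        mats = _mats_from_centroids(cent)
        with pytest.warns(UserWarning, match="clamped"):
            g = saturated_graph(mats)
        assert all(d["weight"] > 0 for _, _, d in g.edges(data=True))

    def test_node_metadata_attached(self):
        mats = _random_mats(1, k=4)
        meta = pd.DataFrame(
            {"site_id": mats.site_order, "x": [0.0, 1, 2, 3], "y": [5.0, 6, 7, 8],
             "species": ["lynx"] * 4}
        )
        g = saturated_graph(mats, meta)
        assert g.nodes["S2"]["x"] == 2.0
        assert g.nodes["S2"]["n"] == 20


class TestPruneEdges:
    def test_identity_covariance_prunes_everything(self):
        mats = _random_mats(2, k=5)
        pruned = prune_edges(saturated_graph(mats), np.eye(5), n_total=100)
        assert pruned.number_of_edges() == 0
        assert len(pruned.graph["pruning"]) == 10

    def test_monotone_in_alpha(self):
        mats = _random_mats(3, k=8)
        g = saturated_graph(mats)
        edges = {}
        for alpha in (0.01, 0.05, 0.5):
            pruned = prune_edges(g, mats.C, n_total=160, alpha=alpha)
            edges[alpha] = set(map(frozenset, pruned.edges))
        assert edges[0.01] <= edges[0.05] <= edges[0.5]

    def test_alpha_near_one_retains_saturated_graph(self):
        mats = _random_mats(4, k=6)
        g = saturated_graph(mats)
        pruned = prune_edges(g, mats.C, n_total=120, alpha=1.0)
        assert pruned.number_of_edges() == g.number_of_edges()

    def test_chain_conditional_independence_pruned(self):
        """Sites forming a Markov chain 0 - 3 - 2: the indirect (0, 2)
        edge is conditionally independent given site 3 and must be
        dropped, while the direct chain edges survive; agreement checked
        against a regression-residual partial-correlation oracle."""
        rng = np.random.default_rng(12)
        k, p = 6, 300
        cent = rng.standard_normal((k, p))
        cent[3] = cent[0] + 0.4 * rng.standard_normal(p)
        cent[2] = cent[3] + 0.4 * rng.standard_normal(p)
        mats = _mats_from_centroids(cent, n_per_site=20)
        pruned = prune_edges(saturated_graph(mats), mats.C, n_total=120)
        kept = set(map(frozenset, pruned.edges))
        assert frozenset({"S0", "S2"}) not in kept
        assert frozenset({"S0", "S3"}) in kept
        assert frozenset({"S2", "S3"}) in kept
        # oracle on the raw (uncentered, full-rank) site profiles
        assert abs(residual_partial_correlation(cent, 0, 2)) < 0.15
        assert residual_partial_correlation(cent, 0, 3) > 0.5

    def test_record_covers_every_pair(self):
        mats = _random_mats(5, k=7)
        pruned = prune_edges(saturated_graph(mats), mats.C, n_total=140)
        rec = pruned.graph["pruning"]
        assert len(rec) == 21
        assert set(rec.columns) >= {"site_a", "site_b", "weight", "eed", "kept"}


class TestConditionalGeneticDistance:
    def test_path_sum_through_intermediate(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=2.0)
        g.add_edge("B", "C", weight=3.0)
        cgd = conditional_genetic_distance(g)
        f = cgd.to_frame()
        assert f.loc["A", "C"] == pytest.approx(5.0)
        assert f.loc["A", "A"] == 0.0
        assert np.allclose(cgd.values, cgd.values.T)

    def test_matches_independent_dijkstra(self):
        mats = _random_mats(6, k=10)
        pruned = prune_edges(saturated_graph(mats), mats.C, n_total=200)
        cgd = conditional_genetic_distance(pruned)
        adj = nx.to_scipy_sparse_array(pruned, nodelist=cgd.site_order, weight="weight")
        oracle = dijkstra(adj, directed=False)
        np.testing.assert_allclose(cgd.values, oracle, rtol=1e-10)

    def test_disconnected_components_flagged_not_fabricated(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_node("C")
        with pytest.warns(UserWarning, match="components"):
            cgd = conditional_genetic_distance(g)
        assert np.isinf(cgd.to_frame().loc["A", "C"])
        assert not cgd.reachable[0, 2]

    def test_pruning_cannot_shorten_paths(self):
        mats = _random_mats(7, k=9)
        g = saturated_graph(mats)
        sat = conditional_genetic_distance(g).values
        pruned = prune_edges(g, mats.C, n_total=180)
        pr = conditional_genetic_distance(pruned).values
        assert np.all(sat <= pr + 1e-12)


class TestNodeConnectivity:
    def test_average_inverse_edge_weight_arithmetic(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=2.0)
        g.add_edge("A", "C", weight=4.0)
        g.add_edge("B", "C", weight=8.0)
        df = node_connectivity(g).set_index("site_id")
        assert df.loc["A", "mean_inverse_edge_weight"] == pytest.approx(0.375)
        assert df.loc["A", "mean_edge_weight"] == pytest.approx(3.0)

    def test_matches_recomputation_from_edge_list(self):
        mats = _random_mats(8, k=8)
        pruned = prune_edges(saturated_graph(mats), mats.C, n_total=160, alpha=0.5)
        df = node_connectivity(pruned).set_index("site_id")
        for node in pruned.nodes:
            w = [d["weight"] for _, _, d in pruned.edges(node, data=True)]
            if w:
                assert df.loc[node, "mean_inverse_edge_weight"] == pytest.approx(
                    np.mean([1 / x for x in w])
                )
                assert df.loc[node, "degree"] == len(w)

    def test_within_species_zscores_standardized(self):
        mats = _random_mats(9, k=8)
        g = saturated_graph(mats)
        species = {s: ("lynx" if i < 4 else "fisher") for i, s in enumerate(g.nodes)}
        df = node_connectivity(g, species=pd.Series(species))
        for _, sub in df.groupby("species"):
            assert sub["connectivity_z"].mean() == pytest.approx(0.0, abs=1e-10)
            assert sub["connectivity_z"].std(ddof=1) == pytest.approx(1.0)

    def test_jensen_inequality_per_species(self):
        mats = _random_mats(10, k=10)
        g = saturated_graph(mats)
        df = node_connectivity(g)
        for _, sub in df.groupby("species"):
            assert sub["mean_inverse_edge_weight"].mean() >= 1.0 / sub["mean_edge_weight"].mean()

    def test_single_node_species_rejected(self):
        mats = _random_mats(11, k=4)
        g = saturated_graph(mats)
        species = dict(zip(g.nodes, ["lynx", "lynx", "lynx", "marten"]))
        with pytest.raises(ValueError, match="z-score"):
            node_connectivity(g, species=pd.Series(species))

    def test_all_pairs_variant_uses_cgd(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=2.0)
        g.add_edge("B", "C", weight=3.0)
        df = node_connectivity(g, all_pairs_cgd=True).set_index("site_id")
        # for A: cGD to B is 2, to C is 5
        assert df.loc["A", "mean_inverse_edge_weight"] == pytest.approx((0.5 + 0.2) / 2)


class TestGraphml:
    def test_round_trip_nodes_edges_weights(self, tmp_path):
        mats = _random_mats(12, k=6)
        pruned = prune_edges(saturated_graph(mats), mats.C, n_total=120, alpha=0.5)
        path = tmp_path / "g.graphml"
        write_graphml(pruned, path)
        back = read_graphml(path)
        assert set(back.nodes) == set(pruned.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, pruned.edges))
        for u, v, d in pruned.edges(data=True):
            assert back[u][v]["weight"] == pytest.approx(d["weight"])
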