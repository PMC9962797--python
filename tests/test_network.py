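import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mmnet import (
    CorrelationSet,
    FeatureTable,
    GroupDesign,
    atria_rank,
    build_heteronet,
    fruchterman_reingold,
    kegg_support,
    network_specific_metabolites,
)
from mmnet.network import annotate_ranks


def brute_force_pays(graph):
    """Independent pay calculator: explicit loops over the <=2-path rule."""
    nodes = sorted(graph.nodes())
    pays = {}
    for i in nodes:
        total = 1.0  # self-pay
        for j in nodes:
            if j == i:
                continue
            candidates = [0.0]
            if graph.has_edge(i, j):
                candidates.append(graph.edges[i, j]["weight"])
            for k in nodes:
                if k in (i, j):
                    continue
                if graph.has_edge(i, k) and graph.has_edge(k, j):
                    candidates.append(
                        graph.edges[i, k]["weight"] * graph.edges[k, j]["weight"]
                    )
            total += max(candidates, key=abs)
        pays[i] = abs(total)
    return pays


def _corr_set(rows):
    return CorrelationSet(
        pd.DataFrame(
            rows, columns=["feature_a", "feature_b", "layer", "rho", "p", "method"]
        )
    )


class TestAtria:
    def test_triangle_hand_example(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.9)
        g.add_edge("A", "C", weight=0.8)
        g.add_edge("B", "C", weight=0.1)
        pays = brute_force_pays(g)
        # hand computation: B->C via A (0.72) beats the direct 0.1 edge
        assert pays == pytest.approx({"A": 2.7, "B": 2.62, "C": 2.52})
        ranking = atria_rank(g)
        assert ranking.order[0] == "A"
        assert ranking.entries[0][1] == pytest.approx(2.7)
        # ablation removed B-C (it closed a triangle with A): B, C are residual
        assert set(ranking.residual) == {"B", "C"}

    def test_positive_star_hub_first(self):
        g = nx.Graph()
        for i in range(4):
            g.add_edge("hub", f"leaf{i}", weight=1.0)
        pays = brute_force_pays(g)
        assert max(pays, key=lambda n: (pays[n], n)) is not None
        ranking = atria_rank(g)
        assert ranking.order[0] == "hub"

    def test_weighted_star_hub_strictly_dominates(self):
        g = nx.Graph()
        for i in range(4):
            g.add_edge("zhub", f"leaf{i}", weight=0.9)  # hub last lexicographically
        pays = brute_force_pays(g)
        assert pays["zhub"] > max(pays[f"leaf{i}"] for i in range(4))
        assert atria_rank(g).order[0] == "zhub"

    def test_all_negative_star_hub_first(self):
        g = nx.Graph()
        for i in range(4):
            g.add_edge("hub", f"leaf{i}", weight=-1.0)
        # pay uses the magnitude of the summed signed pays: hub |1 - 4| = 3
        assert brute_force_pays(g)["hub"] == pytest.approx(3.0)
        assert atria_rank(g).order[0] == "hub"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_first_extraction_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(8, 0.5, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes()})
        for u, v in g.edges():
            g.edges[u, v]["weight"] = round(float(rng.uniform(-1, 1)), 3)
        pays = brute_force_pays(g)
        best_pay = max(pays.values())
        expected_first = min(n for n, p in pays.items() if p >= best_pay - 1e-9)
        ranking = atria_rank(g)
        if best_pay > 1 + 1e-9:
            assert ranking.order[0] == expected_first
            assert ranking.entries[0][1] == pytest.approx(best_pay)

    def test_ranking_is_duplicate_free_permutation(self):
        rng = np.random.default_rng(10)
        g = nx.gnp_random_graph(12, 0.4, seed=10)
        g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes()})
        for u, v in g.edges():
            g.edges[u, v]["weight"] = float(rng.uniform(-1, 1))
        ranking = atria_rank(g)
        assert sorted(ranking.order) == sorted(g.nodes())
        rounds = [r for _, _, r in ranking.entries if r is not None]
        assert rounds == sorted(rounds) and len(set(rounds)) == len(rounds)

    def test_zero_weight_edges_rank_nothing_beyond_residual(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.0)
        g.add_edge("b", "c", weight=0.0)
        ranking = atria_rank(g)
        assert ranking.residual == ["a", "b", "c"]
        assert all(r is None for _, _, r in ranking.entries)

    def test_isomorphic_relabeling_preserves_ranking(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=0.9)
        g.add_edge("A", "C", weight=0.5)
        g.add_edge("C", "D", weight=-0.7)
        mapping = {"A": "w", "B": "x", "C": "y", "D": "z"}
        h = nx.relabel_nodes(g, mapping)
        order_g = [mapping[n] for n in atria_rank(g).order]
        order_h = atria_rank(h).order
        assert order_g == order_h

    def test_annotate_ranks_writes_contiguous_ranks(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        ranking = atria_rank(g)
        annotate_ranks(g, ranking)
        assert sorted(d["rank"] for _, d in g.nodes(data=True)) == [1, 2]


class TestBuildHeteronet:
    def test_single_significant_pair_gives_two_node_network(self):
        corr = _corr_set([("sp1", "met1", "MT", 0.9, 0.01, "s")])
        g = build_heteronet(corr, group="Chow")
        assert g.number_of_nodes() == 2
        assert g.edges["sp1", "met1"]["weight"] == 0.9
        assert g.nodes["sp1"]["node_type"] == "microbe"
        assert g.nodes["met1"]["node_type"] == "metabolite"

    def test_all_insignificant_gives_empty_network_with_warning(self):
        corr = _corr_set([("sp1", "met1", "MT", 0.9, 0.2, "s")])
        with pytest.warns(UserWarning, match="no admitted edges"):
            g = build_heteronet(corr, group="WD")
        assert g.number_of_nodes() == 0

    def test_nan_rho_records_skipped(self):
        corr = _corr_set(
            [("sp1", "met1", "MT", np.nan, np.nan, "s"),
             ("sp2", "met1", "MT", 0.5, 0.01, "s")]
        )
        g = build_heteronet(corr, group="Chow")
        assert not g.has_node("sp1")

    def test_node_attributes_use_group_means(self, small_microbe_table,
                                             small_metabolite_table, small_design):
        corr = _corr_set([("sp0", "met0", "MT", 0.9, 0.01, "s")])
        g = build_heteronet(
            corr, group="Chow", microbe_table=small_microbe_table,
            metabolite_table=small_metabolite_table, design=small_design,
        )
        expected = small_microbe_table.values.loc[
            "sp0", small_design.samples("Chow")
        ].mean()
        assert g.nodes["sp0"]["mean_abundance"] == pytest.approx(expected)
        assert g.nodes["sp0"]["phylum_or_pathway"] == "Firmicutes"


class TestSpecificMetabolites:
    def _net(self, group, edges):
        g = nx.Graph(group=group)
        for mic, met, w in edges:
            g.add_node(mic, node_type="microbe")
            g.add_node(met, node_type="metabolite")
            g.add_edge(mic, met, weight=w)
        return g

    def test_metabolite_only_in_one_network_is_specific(self):
        nets = {
            "A": self._net("A", [("sp1", "m1", 0.9), ("sp1", "m2", 0.8)]),
            "B": self._net("B", [("sp2", "m2", 0.7)]),
        }
        specific = network_specific_metabolites(nets)
        assert list(specific["A"].index) == ["m1"]
        assert list(specific["B"].index) == []

    def test_shared_metabolite_in_no_specific_set(self):
        nets = {
            "A": self._net("A", [("sp1", "m1", 0.9)]),
            "B": self._net("B", [("sp2", "m1", 0.7)]),
            "C": self._net("C", [("sp3", "m2", 0.5)]),
        }
        specific = network_specific_metabolites(nets)
        assert all("m1" not in frame.index for frame in specific.values())
        assert list(specific["C"].index) == ["m2"]

    def test_specific_sets_pairwise_disjoint(self):
        rng = np.random.default_rng(1)
        nets = {}
        for grp in ("A", "B", "C"):
            edges = [
                (f"sp{i}", f"m{rng.integers(0, 10)}", 0.9) for i in range(5)
            ]
            nets[grp] = self._net(grp, edges)
        specific = network_specific_metabolites(nets)
        sets = [set(f.index) for f in specific.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not (sets[i] & sets[j])

    def test_requires_two_networks(self):
        with pytest.raises(ValueError):
            network_specific_metabolites({"A": nx.Graph()})


class TestKeggSupport:
    def _edge_graph(self, weight):
        g = nx.Graph()
        g.add_edge("spX", "m1", weight=weight)
        return g

    def test_positive_edge_with_shared_pathway_supported(self):
        g = kegg_support(self._edge_graph(0.8), {"spX": {"map00240"}, "m1": {"map00240"}})
        assert g.edges["spX", "m1"]["kegg_supported"] is True

    def test_negative_edge_never_supported(self):
        g = kegg_support(self._edge_graph(-0.8), {"spX": {"map00240"}, "m1": {"map00240"}})
        assert g.edges["spX", "m1"]["kegg_supported"] is False

    def test_disjoint_pathways_not_supported(self):
        g = kegg_support(self._edge_graph(0.8), {"spX": {"map00010"}, "m1": {"map00240"}})
        assert g.edges["spX", "m1"]["kegg_supported"] is False

    def test_malformed_mapping_rows_skipped_with_warning(self, tmp_path):
        from mmnet.network import read_kegg_mapping

        p = tmp_path / "kegg.tsv"
        p.write_text("spX\tmap00240\nbadrow\nm1\tmap00240\n")
        with pytest.warns(UserWarning, match="1 malformed"):
            mapping = read_kegg_mapping(p)
        assert mapping == {"spX": {"map00240"}, "m1": {"map00240"}}


class TestLayout:
    def test_single_node_at_origin(self):
        g = nx.Graph()
        g.add_node("only")
        coords = fruchterman_reingold(g)
        np.testing.assert_allclose(coords["only"], [0.0, 0.0])

    def test_positive_pair_closer_than_isolated_pair(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        g.add_node("c")
        g.add_node("d")
        coords = fruchterman_reingold(g, seed=1)
        d_ab = np.linalg.norm(coords["a"] - coords["b"])
        d_cd = np.linalg.norm(coords["c"] - coords["d"])
        assert d_ab < d_cd

    def test_negative_edge_contributes_no_attraction(self):
        g1 = nx.Graph()
        g1.add_edge("a", "b", weight=-0.9)
        g2 = nx.Graph()
        g2.add_nodes_from(["a", "b"])
        c1 = fruchterman_reingold(g1, seed=2)
        c2 = fruchterman_reingold(g2, seed=2)
        np.testing.assert_allclose(c1["a"], c2["a"])
        np.testing.assert_allclose(c1["b"], c2["b"])

    def test_same_seed_identical_coordinates(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.5)
        g.add_edge("b", "c", weight=0.7)
        c1 = fruchterman_reingold(g, seed=5)
        c2 = fruchterman_reingold(g, seed=5)
        for n in g.nodes():
            np.testing.assert_array_equal(c1[n], c2[n])
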