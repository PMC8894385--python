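"""Candidate intersection, shared targets, MCC, hubs, network, drugs."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from phenoswitch import integrate, synthetic
from phenoswitch.integrate import (
    MirnaNamingError,
    build_network,
    intersect_candidates,
    map_drugs,
    mcc_scores,
    normalize_mirna,
    select_hubs,
    shared_targets,
)


def brute_force_mcc(graph: nx.Graph) -> dict:
    """Independent MCC oracle: enumerate every vertex subset, keep the
    cliques that are maximal, and sum (|C|-1)! per member."""
    nodes = list(graph.nodes)
    cliques = []
    for r in range(2, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(
                graph.has_edge(u, v)
                for u, v in itertools.combinations(subset, 2)
            ):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]
    scores = {v: 0.0 for v in nodes}
    for c in maximal:
        w = math.factorial(len(c) - 1)
        for v in c:
            scores[v] += w
    return scores


class TestIntersection:
    def test_normalization_strips_species_keeps_arm(self):
        assert normalize_mirna("hsa-miR-145-5p") == "mir-145-5p"
        assert normalize_mirna("miR-22-3p") == "mir-22-3p"

    def test_basic_overlap_in_screen_order(self):
        overlap, venn = intersect_candidates(
            ["m-1-3p", "m-2-3p", "m-3-3p"], ["m-2-3p", "m-3-3p", "m-4-3p"]
        )
        assert overlap == ["m-2-3p", "m-3-3p"]
        assert venn == {"screen_only": 1, "de_only": 1, "overlap": 2}

    def test_disjoint_lists_warn(self):
        with pytest.warns(UserWarning, match="disjoint"):
            overlap, _ = intersect_candidates(["m-1-3p"], ["m-2-3p"])
        assert overlap == []

    def test_arm_scheme_mismatch_raises(self):
        with pytest.raises(MirnaNamingError):
            intersect_candidates(["miR-145-5p"], ["hsa-miR-145"])

    def test_six_candidate_scenario(self):
        # screen hits including the classic positive controls intersected
        # with an up-regulated list reproduces a six-miRNA candidate set
        screen_hits = [
            "miR-138-5p", "miR-150-5p", "miR-141-3p", "miR-139-5p",
            "miR-338-3p", "miR-132-3p", "miR-92a-3p", "miR-130a-3p",
            "miR-22-3p", "miR-145-5p",
        ]
        de_up = [
            "hsa-miR-132-3p", "hsa-miR-138-5p", "hsa-miR-141-3p",
            "hsa-miR-145-5p", "hsa-miR-150-5p", "hsa-miR-22-3p",
            "hsa-miR-503-5p",
        ]
        overlap, venn = intersect_candidates(screen_hits, de_up)
        assert venn["overlap"] == 6
        assert "mir-145-5p" in overlap and "mir-22-3p" in overlap


class TestSharedTargets:
    def test_exact_k_grouping(self):
        table = pd.DataFrame(
            {
                "mirna": ["A", "A", "B", "B", "C"],
                "gene": ["g1", "g2", "g1", "g3", "g1"],
            }
        )
        out = shared_targets(table, k_min=3)
        assert list(out.index) == ["g1"]
        assert out.loc["g1", "k"] == 3
        assert out.loc["g1", "mirnas"] == ("A", "B", "C")

    def test_k_min_above_mirna_count_empty(self):
        table = pd.DataFrame({"mirna": ["A"], "gene": ["g1"]})
        assert len(shared_targets(table, k_min=5)) == 0

    def test_k_min_validation(self):
        with pytest.raises(ValueError):
            shared_targets(pd.DataFrame({"mirna": [], "gene": []}), k_min=0)

    def test_strata_sum_to_distinct_genes(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "mirna": rng.choice(list("ABCDEF"), 300),
                "gene": rng.choice([f"g{i}" for i in range(60)], 300),
            }
        )
        out = shared_targets(table, k_min=1)
        assert len(out) == table["gene"].nunique()
        assert out["k"].sum() == len(table[["mirna", "gene"]].drop_duplicates())

    def test_row_order_invariance(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            {
                "mirna": rng.choice(list("ABCD"), 100),
                "gene": rng.choice([f"g{i}" for i in range(25)], 100),
            }
        )
        out1 = shared_targets(table)
        out2 = shared_targets(table.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(
            out1.sort_index(), out2.sort_index()
        )

    def test_planted_fixture_recovery(self):
        universe = tuple(f"G{i:03d}" for i in range(120))
        plan = synthetic.FixturePlan(
            mirnas=tuple(f"mir-{i}" for i in range(1, 7)),
            gene_universe=universe,
            planted_shared={5: ("G000",), 4: ("G001", "G002")},
        )
        targets, _, _ = synthetic.generate_fixtures(plan, seed=0)
        out = shared_targets(targets, k_min=4)
        assert set(out[out["k"] == 5].index) == {"G000"}
        assert set(out[out["k"] == 4].index) == {"G001", "G002"}


class TestMCC:
    def test_triangle(self):
        scores = mcc_scores(nx.complete_graph(3))
        assert all(v == 2.0 for v in scores.values())

    def test_star(self):
        scores = mcc_scores(nx.star_graph(3))
        assert scores[0] == 3.0
        assert scores[1] == scores[2] == scores[3] == 1.0

    def test_path(self):
        scores = mcc_scores(nx.path_graph(3))
        assert scores[1] == 2.0 and scores[0] == scores[2] == 1.0

    def test_isolated_node_scores_zero(self):
        g = nx.Graph()
        g.add_node("lonely")
        g.add_edge("a", "b")
        scores = mcc_scores(g)
        assert scores["lonely"] == 0.0 and scores["a"] == 1.0

    def test_self_loop_rejected(self):
        g = nx.Graph([("a", "a")])
        with pytest.raises(ValueError, match="simple"):
            mcc_scores(g)

    def test_clique_budget_enforced(self):
        with pytest.raises(RuntimeError, match="subgraph"):
            mcc_scores(nx.complete_multipartite_graph(2, 2, 2, 2, 2),
                       max_cliques=3)

    def test_matches_brute_force_on_random_graphs(self):
        """MCC equals subset-enumeration oracle on 200 random graphs of
        at most 10 nodes (exhaustive check)."""
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 11))
            p = float(rng.uniform(0.1, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            assert mcc_scores(g) == brute_force_mcc(g)

    def test_edge_order_invariance(self):
        edges = [("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")]
        g1 = nx.Graph(edges)
        g2 = nx.Graph(edges[::-1])
        assert mcc_scores(g1) == mcc_scores(g2)


class TestSelectHubs:
    def _fixture(self, shared_hub=False):
        universe = tuple(f"G{i:03d}" for i in range(200))
        mirnas = tuple(f"mir-{i}" for i in range(1, 7))
        cliques = []
        cursor = 0
        for i, m in enumerate(mirnas):
            if shared_hub and i == 1:
                genes = (cliques[0][1][0],) + universe[cursor:cursor + 3]
                cursor += 3
            else:
                genes = universe[cursor:cursor + 4]
                cursor += 4
            cliques.append((m, genes))
        plan = synthetic.FixturePlan(
            mirnas=mirnas, gene_universe=universe,
            planted_hub_cliques=tuple(cliques),
        )
        targets, ppi, _ = synthetic.generate_fixtures(plan, seed=8)
        graph = nx.from_pandas_edgelist(ppi, "gene_a", "gene_b")
        return targets, graph, cliques

    def test_planted_clique_members_top_ranked(self):
        universe = tuple(f"G{i:03d}" for i in range(100))
        plan = synthetic.FixturePlan(
            mirnas=("mir-X",), gene_universe=universe,
            planted_hub_cliques=(("mir-X", universe[:4]),),
            n_filler_per_mirna=10,
        )
        targets, ppi, _ = synthetic.generate_fixtures(plan, seed=1)
        graph = nx.from_pandas_edgelist(ppi, "gene_a", "gene_b")
        hubs = select_hubs(targets, graph)
        assert set(hubs.per_mirna_hubs["mir-X"]) <= set(universe[:4])

    def test_disjoint_hub_lists_union_to_eighteen(self):
        targets, graph, _ = self._fixture(shared_hub=False)
        hubs = select_hubs(targets, graph)
        assert len(hubs.hub_set) == 18

    def test_shared_hub_gene_reduces_union_to_seventeen(self):
        targets, graph, _ = self._fixture(shared_hub=True)
        hubs = select_hubs(targets, graph)
        assert len(hubs.hub_set) == 17

    def test_fewer_than_three_targets_warns(self):
        table = pd.DataFrame({"mirna": ["m"], "gene": ["g1"]})
        with pytest.warns(UserWarning, match="only 1"):
            hubs = select_hubs(table, nx.Graph())
        assert hubs.per_mirna_hubs["m"] == ["g1"]


class TestBuildNetwork:
    def test_empty_shared_plus_hubs(self):
        shared = pd.DataFrame(columns=["k", "mirnas"])
        hubs = integrate.HubNetwork(
            per_mirna_hubs={"m": ["g1", "g2", "g3"]},
            mcc={"m": {"g1": 2.0, "g2": 2.0, "g3": 2.0}},
        )
        net = build_network(shared, hubs, nx.Graph())
        assert len(net) == 3
        assert all(d["role"] == "hub" for _, d in net.nodes(data=True))

    def test_gene_in_both_sets_deduplicated(self):
        shared = pd.DataFrame(
            {"k": [4], "mirnas": [("m1", "m2", "m3", "m4")]}, index=["g1"]
        )
        hubs = integrate.HubNetwork(
            per_mirna_hubs={"m1": ["g1"]}, mcc={"m1": {"g1": 6.0}}
        )
        net = build_network(shared, hubs, nx.Graph())
        assert len(net) == 1
        assert net.nodes["g1"]["role"] == "both"

    def test_planted_node_count_arithmetic(self):
        universe = tuple(f"G{i:03d}" for i in range(200))
        mirnas = tuple(f"mir-{i}" for i in range(1, 7))
        plan = synthetic.FixturePlan(
            mirnas=mirnas, gene_universe=universe,
            planted_shared={5: universe[:3], 4: universe[3:19]},
            planted_hub_cliques=tuple(
                (m, universe[19 + 3 * i: 22 + 3 * i])
                for i, m in enumerate(mirnas)
            ),
        )
        targets, ppi, _ = synthetic.generate_fixtures(plan, seed=2)
        graph = nx.from_pandas_edgelist(ppi, "gene_a", "gene_b")
        shared = shared_targets(targets)
        hubs = select_hubs(targets, graph)
        net = build_network(shared, hubs, graph, k_min=4)
        n_shared = (shared["k"] >= 4).sum()
        overlap = len(set(shared[shared["k"] >= 4].index) & set(hubs.hub_set))
        assert len(net) == n_shared + len(hubs.hub_set) - overlap

    def test_induced_edges_only(self):
        shared = pd.DataFrame(columns=["k", "mirnas"])
        hubs = integrate.HubNetwork(
            per_mirna_hubs={"m": ["g1", "g2"]}, mcc={"m": {}}
        )
        g = nx.Graph([("g1", "g2"), ("g1", "x")])
        net = build_network(shared, hubs, g)
        assert set(net.edges) == {("g1", "g2")}


class TestMapDrugs:
    def test_cross_product_of_mirnas_and_drugs(self):
        targets = pd.DataFrame(
            {"mirna": ["m1", "m2"], "gene": ["g1", "g1"]}
        )
        drugs = pd.DataFrame(
            {"drug": ["d1", "d2"], "gene": ["g1", "g1"]}
        )
        triples, coverage = map_drugs(["g1"], drugs, targets)
        assert len(triples) == 4
        assert coverage == 1.0

    def test_no_drugs_zero_coverage(self):
        targets = pd.DataFrame({"mirna": ["m1"], "gene": ["g1"]})
        drugs = pd.DataFrame({"drug": [], "gene": []})
        triples, coverage = map_drugs(["g1"], drugs, targets)
        assert len(triples) == 0 and coverage == 0.0

    def test_fourteen_of_seventeen_hub_coverage(self):
        hub_genes = [f"H{i:02d}" for i in range(17)]
        targets = pd.DataFrame(
            {"mirna": ["m1"] * 17, "gene": hub_genes}
        )
        drugs = pd.DataFrame(
            {"drug": [f"d{i}" for i in range(14)], "gene": hub_genes[:14]}
        )
        _, coverage = map_drugs(hub_genes, drugs, targets,
                                hub_genes=hub_genes)
        assert coverage == pytest.approx(14 / 17)
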