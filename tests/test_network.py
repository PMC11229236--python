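"""Correlation graph, Prim forest, eccentricity, subnetworks, interactions."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

import peachbud as pb
from peachbud import network as net


def _edges(rows):
    return pd.DataFrame(rows, columns=["gene", "hormone", "r", "weight"])


def _nx_graph(edges):
    G = nx.Graph()
    for g, h, r, w in edges.itertuples(index=False):
        G.add_edge(g, h, weight=w)
    return G


class TestTimepointMeans:
    def test_mean_and_invariance(self):
        X = pd.DataFrame([[1, 2, 3, 9]], index=["g"], columns=list("abcd"))
        tp = pd.Series(["T1", "T1", "T1", "T3"], index=list("abcd"))
        m = net.timepoint_means(X, tp, order=("T1", "T3"))
        assert m.loc["g", "T1"] == pytest.approx(2.0)
        assert m.loc["g", "T3"] == pytest.approx(9.0)
        perm = net.timepoint_means(X[list("cbad")], tp, order=("T1", "T3"))
        pd.testing.assert_frame_equal(m, perm)

    def test_missing_timepoint_rejected(self):
        X = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        tp = pd.Series(["T1", "T1"], index=["a", "b"])
        with pytest.raises(ValueError, match="T5"):
            net.timepoint_means(X, tp, order=("T1", "T5"))


class TestPearson:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ((1, 2, 3), (2, 4, 6), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3), (1, 3, 2), 0.5),
        ],
    )
    def test_hand_values(self, x, y, expected):
        assert net.pearson(x, y) == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        assert net.pearson((1, 1, 1), (1, 2, 3)) is None


class TestBuildGraph:
    def test_proportional_profiles_edge_r_one(self):
        gm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["T1", "T3", "T5"])
        hm = pd.DataFrame([[10.0, 20.0, 30.0]], index=["H"], columns=["T1", "T3", "T5"])
        g = net.build_graph(gm, hm, 0.90)
        assert len(g.edges) == 1
        assert g.edges["r"].iloc[0] == pytest.approx(1.0)

    def test_threshold_is_strict(self):
        x = np.array([1.0, 2.0, 3.0])
        xc = (x - x.mean()) / np.linalg.norm(x - x.mean())
        e = np.array([1.0, -2.0, 1.0])
        ec = e / np.linalg.norm(e)
        y = 0.8 * xc + 0.6 * ec  # |r| with x strictly below 0.9? compute it
        r = net.pearson(x, y)
        gm = pd.DataFrame([y], index=["g"], columns=["T1", "T3", "T5"])
        hm = pd.DataFrame([x], index=["H"], columns=["T1", "T3", "T5"])
        # with the threshold set to the achieved |r|, the strict rule drops it
        g = net.build_graph(gm, hm, threshold=abs(r))
        assert len(g.edges) == 0

    def test_threshold_outside_unit_interval_rejected(self):
        gm = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        with pytest.raises(ValueError, match="threshold"):
            net.build_graph(gm, gm, threshold=1.5)

    def test_genes_without_edges_excluded(self):
        gm = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, -2.0, 1.0]], index=["gy", "gn"], columns=list("abc")
        )
        hm = pd.DataFrame([[5.0, 6.0, 7.0]], index=["H"], columns=list("abc"))
        g = net.build_graph(gm, hm, 0.90)
        assert g.genes == ["gy"]


class TestPrim:
    def test_triangle_by_enumeration(self):
        edges = _edges([("a", "b", 0.9, 1.0), ("b", "c", 0.8, 2.0), ("a", "c", 0.7, 3.0)])
        forest = net.minimum_spanning_forest_edges(["a", "b", "c"], edges)
        assert sorted(w for *_, w in forest) == [1.0, 2.0]

    def test_two_components_edge_count(self):
        edges = _edges(
            [
                ("g1", "H1", 0.95, 0.05),
                ("g2", "H1", 0.92, 0.08),
                ("g3", "H2", 0.91, 0.09),
            ]
        )
        nodes = ["H1", "H2", "g1", "g2", "g3"]
        forest = net.minimum_spanning_forest_edges(nodes, edges)
        assert len(forest) == 3  # 5 nodes - 2 components

    def test_tie_break_deterministic_under_reordering(self):
        rows = [
            ("g1", "H1", 0.95, 0.05),
            ("g1", "H2", 0.95, 0.05),
            ("g2", "H1", 0.95, 0.05),
            ("g2", "H2", 0.95, 0.05),
        ]
        nodes = ["H1", "H2", "g1", "g2"]
        ref = net.minimum_spanning_forest_edges(nodes, _edges(rows))
        for perm in ([3, 1, 0, 2], [2, 3, 0, 1]):
            shuffled = _edges([rows[i] for i in perm])
            out = net.minimum_spanning_forest_edges(list(reversed(nodes)), shuffled)
            assert sorted(out) == sorted(ref)

    def test_total_weight_matches_kruskal_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n_h, n_g = rng.integers(2, 5), rng.integers(3, 40)
            rows = [
                (f"g{i}", f"H{j}", r, 1 - abs(r))
                for i in range(n_g)
                for j in range(n_h)
                if rng.random() < 0.4
                for r in [float(rng.uniform(-1, 1))]
            ]
            if not rows:
                continue
            edges = _edges(rows)
            nodes = [f"H{j}" for j in range(n_h)] + [f"g{i}" for i in range(n_g)]
            mine = sum(w for *_, w in net.minimum_spanning_forest_edges(nodes, edges))
            G = _nx_graph(edges)
            G.add_nodes_from(nodes)
            ref = sum(
                d["weight"]
                for *_, d in nx.minimum_spanning_edges(G, algorithm="kruskal", data=True)
            )
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_empty_graph_rejected(self):
        g = net.CorrelationGraph([], [], _edges([]), 0.9)
        with pytest.raises(ValueError, match="empty"):
            net.prim_msf(g)


def _forest_from(rows, hormones):
    edges = _edges(rows)
    nodes = set(edges["gene"]) | set(edges["hormone"])
    genes = sorted(nodes - set(hormones))
    g = net.CorrelationGraph(hormones, genes, edges, 0.9)
    return net.prim_msf(g)


class TestForestStructure:
    def test_path_eccentricity(self):
        f = _forest_from([("b", "a", 0.95, 0.05), ("b", "c", 0.92, 0.08)], ["a", "c"])
        ecc = net.eccentricity(f)
        assert ecc["a"] == 2 and ecc["b"] == 1 and ecc["c"] == 2

    def test_singleton_eccentricity_zero(self):
        f = _forest_from([("g1", "H1", 0.95, 0.05)], ["H1", "H_alone"])
        assert net.eccentricity(f)["H_alone"] == 0

    def test_eccentricity_matches_bfs_oracle_on_random_trees(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            n = int(rng.integers(2, 51))
            T = nx.random_labeled_tree(n, seed=int(rng.integers(10**6)))
            rows = [(f"n{u}", f"n{v}", 1.0, 0.0) for u, v in T.edges]
            f = _forest_from(rows, hormones=[])
            mine = net.eccentricity(f)
            ref = nx.eccentricity(nx.relabel_nodes(T, {u: f"n{u}" for u in T}))
            assert all(mine[k] == ref[k] for k in ref)

    def test_star_sign_accounting(self):
        f = _forest_from(
            [("g1", "H", 0.95, 0.05), ("g2", "H", 0.93, 0.07), ("g3", "H", -0.97, 0.03)],
            ["H"],
        )
        summ = net.subnetwork_summary(f)
        assert summ.loc["H", "n_genes"] == 3
        assert summ.loc["H", "n_direct"] == 2
        assert summ.loc["H", "n_inverse"] == 1

    def test_bridge_gene_flagged_and_in_both(self):
        f = _forest_from(
            [("gb", "H1", 0.95, 0.05), ("gb", "H2", 0.93, 0.07)], ["H1", "H2"]
        )
        assign = net.assign_subnetworks(f)
        assert bool(assign.loc["gb", "is_bridge"])
        assert assign.loc["gb", "hormones"] == "H1|H2"
        both = net.subnetwork_summary(f, count_bridges_in_all=True)
        assert both.loc["H1", "n_genes"] == 1 and both.loc["H2", "n_genes"] == 1
        primary = net.subnetwork_summary(f)
        assert primary["n_genes"].sum() == 1  # counted once in primary mode

    def test_primary_sizes_sum_to_gene_count(self, default_dataset):
        d = default_dataset
        logcpm = pb.cpm_log_transform(d["counts"])
        md = d["metadata"]
        basal = md.index[md["position"] == "basal"]
        gm = net.timepoint_means(
            logcpm[list(basal)], md.loc[basal, "timepoint"], order=("T1", "T3", "T5")
        )
        g = net.build_graph(gm.iloc[:400], d["profiles"].means(), 0.90)
        f = net.prim_msf(g)
        assert net.subnetwork_summary(f)["n_genes"].sum() == len(g.genes)

    def test_removing_non_bridge_gene_preserves_other_assignments(self):
        rng = np.random.default_rng(14)
        rows = [
            (f"g{i}", f"H{j}", r, 1 - abs(r))
            for i in range(30)
            for j in range(3)
            if rng.random() < 0.5
            for r in [float(rng.uniform(-1, 1))]
        ]
        f = _forest_from(rows, [f"H{j}" for j in range(3)])
        assign = net.assign_subnetworks(f)
        victim = assign.index[~assign["is_bridge"]][0]
        rows2 = [r for r in rows if r[0] != victim]
        f2 = _forest_from(rows2, [f"H{j}" for j in range(3)])
        assign2 = net.assign_subnetworks(f2)
        common = assign2.index
        pd.testing.assert_frame_equal(assign.loc[common], assign2)


class TestInteractions:
    def test_sign_rules(self):
        syn = _forest_from(
            [("g", "A", 0.95, 0.05), ("g", "B", 0.92, 0.08)], ["A", "B"]
        )
        calls = net.call_interactions(syn)
        assert len(calls) == 1 and calls[0].verdict == "synergism"
        ant = _forest_from(
            [("g", "A", 0.95, 0.05), ("g", "B", -0.93, 0.07)], ["A", "B"]
        )
        assert net.call_interactions(ant)[0].verdict == "antagonism"

    def test_mixed_verdict(self):
        # g1 bridges A-B concordantly in the forest; g2 bridges A-C in the
        # forest and carries a discordant graph edge to B, so the (A, B)
        # pair collects conflicting sign pairs
        f = _forest_from(
            [
                ("g1", "A", 0.99, 0.01),
                ("g1", "B", 0.98, 0.02),
                ("g2", "A", 0.97, 0.03),
                ("g2", "C", 0.96, 0.04),
                ("g2", "B", -0.91, 0.09),
            ],
            ["A", "B", "C"],
        )
        calls = {(c.hormone_a, c.hormone_b): c.verdict for c in net.call_interactions(f)}
        assert calls[("A", "B")] == "mixed"


class TestExports:
    def test_graphml_readable_by_oracle(self, tmp_path, default_dataset):
        d = default_dataset
        logcpm = pb.cpm_log_transform(d["counts"])
        md = d["metadata"]
        basal = md.index[md["position"] == "basal"]
        gm = net.timepoint_means(
            logcpm[list(basal)], md.loc[basal, "timepoint"], order=("T1", "T3", "T5")
        )
        g = net.build_graph(
            gm.iloc[:200],
            d["profiles"].means(),
            0.90,
            gene_mean_expression=logcpm.mean(axis=1),
        )
        f = net.prim_msf(g)
        net.write_graphml(g, f, tmp_path / "net.graphml")
        G = nx.read_graphml(tmp_path / "net.graphml")
        assert G.number_of_nodes() == len(g.nodes)
        assert G.number_of_edges() == len(g.edges)
        some_gene = g.genes[0]
        assert G.nodes[some_gene]["kind"] == "gene"
        in_forest = [d_["in_forest"] for *_, d_ in G.edges(data=True)]
        assert sum(in_forest) == len(f.edges)

    def test_edge_list_round_trip_columns(self, tmp_path):
        f = _forest_from([("g1", "H1", 0.95, 0.05)], ["H1"])
        net.write_edge_list(f.graph, f, tmp_path / "edges.tsv")
        df = pd.read_csv(tmp_path / "edges.tsv", sep="\t")
        assert list(df.columns) == ["gene", "hormone", "r", "weight", "sign", "in_forest"]
        assert bool(df["in_forest"].iloc[0])
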