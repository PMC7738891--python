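"""Guilt-by-association scoring: weights, distances, curves, AUC scores,
ranking — each checked against independent brute-force oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dcmir import prioritize, synth
from conftest import random_weighted_graph


# ---------------------------------------------------------------------------
# independent oracles (no calls into the code paths they check)
# ---------------------------------------------------------------------------

def floyd_warshall_oracle(G):
    nodes = sorted(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for u, v, d in G.edges(data=True):
        w = d["length"]
        i, j = idx[u], idx[v]
        D[i, j] = min(D[i, j], w)
        D[j, i] = min(D[j, i], w)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return nodes, D


def knode_oracle(G, bins):
    """Direct summation + explicit trapezoid integration."""
    nodes, D = floyd_warshall_oracle(G)
    w = np.array([G.nodes[v]["weight"] for v in nodes])
    p_bar = w.mean()
    finite = D[np.isfinite(D)]
    dmax = finite.max()
    if dmax == 0:
        thresholds = [0.0]
    else:
        thresholds = [dmax * k / bins for k in range(1, bins + 1)]
    scores = {}
    for i, v in enumerate(nodes):
        curve = []
        for s in thresholds:
            acc = 0.0
            for j in range(len(nodes)):
                # same stated tie rule as the pipeline: within 1e-9 of a
                # threshold counts as inside
                if np.isfinite(D[i, j]) and D[i, j] <= s + 1e-9:
                    acc += w[j] - p_bar
            curve.append(2.0 / p_bar * acc)
        if len(thresholds) == 1:
            scores[v] = curve[0]
        else:
            area = 0.0
            for k in range(len(thresholds) - 1):
                area += 0.5 * (curve[k] + curve[k + 1]) * (
                    thresholds[k + 1] - thresholds[k]
                )
            scores[v] = area / (thresholds[-1] - thresholds[0])
    return scores


class TestNodeWeight:
    @pytest.mark.parametrize(
        "p_adj,log2fc,expected",
        [(0.01, 2.0, 4.0), (1.0, 5.0, 0.0), (0.1, -3.0, 3.0)],
    )
    def test_printed_formula(self, p_adj, log2fc, expected):
        assert prioritize.node_weight(p_adj, log2fc) == pytest.approx(
            expected
        )

    def test_missing_p_adj_gives_zero(self):
        assert prioritize.node_weight(float("nan"), 3.0) == 0.0

    def test_tiny_p_clamped(self):
        w = prioritize.node_weight(1e-320, 1.0)
        assert w == pytest.approx(300.0)

    def test_nonpositive_p_rejected(self):
        with pytest.raises(ValueError):
            prioritize.node_weight(0.0, 1.0)


class TestDistances:
    def test_path_graph_additivity(self):
        G = nx.Graph()
        G.add_edge("a", "b", length=0.2)
        G.add_edge("b", "c", length=0.3)
        nodes, D = prioritize.all_shortest_distances(G)
        i, j = nodes.index("a"), nodes.index("c")
        assert D[i, j] == pytest.approx(0.5)

    def test_triangle_detour_beats_direct(self):
        G = nx.Graph()
        G.add_edge("a", "c", length=0.9)
        G.add_edge("a", "b", length=0.2)
        G.add_edge("b", "c", length=0.3)
        nodes, D = prioritize.all_shortest_distances(G)
        assert D[nodes.index("a"), nodes.index("c")] == pytest.approx(0.5)

    def test_unreachable_is_infinite(self):
        G = nx.Graph()
        G.add_edge("a", "b", length=0.1)
        G.add_node("z")
        nodes, D = prioritize.all_shortest_distances(G)
        assert np.isinf(D[nodes.index("a"), nodes.index("z")])

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            G = random_weighted_graph(rng)
            nodes, D = prioritize.all_shortest_distances(G)
            nodes_o, D_o = floyd_warshall_oracle(G)
            assert nodes == nodes_o
            assert np.allclose(D, D_o)


class TestCurvesAndScores:
    def test_uniform_weights_annihilate_curves(self):
        G = nx.path_graph(5)
        for n in G.nodes:
            G.nodes[n]["weight"] = 2.5
            G.nodes[n]["class"] = "protein_coding"
        for u, v in G.edges:
            G.edges[u, v]["length"] = 0.4
        scored = prioritize.score_network(G)
        assert np.allclose(scored["score"], 0.0)

    def test_two_node_hand_example(self):
        # weights (4, 0), one edge of length 0.5, explicit thresholds
        D = np.array([[0.0, 0.5], [0.5, 0.0]])
        weights = np.array([4.0, 0.0])
        curves = prioritize.neighborhood_curves(
            D, weights, np.array([0.5, 1.0])
        )
        # p_bar = 2; both nodes within 0.5: (1)*((4-2)+(0-2)) = 0
        assert np.allclose(curves, 0.0)
        # below the edge length only the self-term contributes
        curves2 = prioritize.neighborhood_curves(
            D, weights, np.array([0.25, 0.5])
        )
        assert curves2[0, 0] == pytest.approx((2 / 2) * (4 - 2))
        assert curves2[1, 0] == pytest.approx((2 / 2) * (0 - 2))

    def test_heavy_neighborhood_dominates_elementwise(self):
        # star around h (heavy leaves) vs star around l (light leaves)
        G = nx.Graph()
        for i in range(3):
            G.add_edge("h", f"hh{i}", length=0.1)
            G.add_edge("l", f"ll{i}", length=0.1)
        G.add_edge("h", "l", length=0.9)
        for n in G.nodes:
            G.nodes[n]["class"] = "protein_coding"
            G.nodes[n]["weight"] = 5.0 if n.startswith("hh") else 0.5
        nodes, D = prioritize.all_shortest_distances(G)
        w = np.array([G.nodes[n]["weight"] for n in nodes])
        thresholds = prioritize.make_thresholds(D, bins=10)
        curves = prioritize.neighborhood_curves(D, w, thresholds)
        hi, li = nodes.index("h"), nodes.index("l")
        assert (curves[hi] >= curves[li] - 1e-12).all()

    def test_constant_curve_scores_its_height(self):
        thresholds = np.linspace(0.1, 1.0, 10)
        assert prioritize.knode_score(
            np.full(10, 3.3), thresholds
        ) == pytest.approx(3.3)
        assert prioritize.knode_score(np.zeros(10), thresholds) == 0.0

    def test_all_zero_weights_warn_and_zero(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        curves = prioritize.neighborhood_curves(
            D, np.zeros(2), np.array([0.3])
        )
        assert np.allclose(curves, 0.0)

    def test_scores_match_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            G = random_weighted_graph(rng)
            scored = prioritize.score_network(G, bins=7)
            expected = knode_oracle(G, bins=7)
            for _, row in scored.iterrows():
                assert row["score"] == pytest.approx(
                    expected[row["node_id"]], abs=1e-10
                )


class TestRanking:
    def make_scores(self, rows):
        return pd.DataFrame(
            rows, columns=["node_id", "class", "weight", "score"]
        )

    def test_classes_ranked_independently(self):
        scores = self.make_scores(
            [("m1", "miRNA", 1.0, 3.0), ("m2", "miRNA", 1.0, 1.0),
             ("g1", "protein_coding", 1.0, 2.0)]
        )
        ranked = prioritize.rank_separately(scores).set_index("node_id")
        assert ranked.loc["m1", "rank_in_class"] == 1
        assert ranked.loc["m2", "rank_in_class"] == 2
        assert ranked.loc["g1", "rank_in_class"] == 1

    def test_score_tie_broken_by_weight(self):
        scores = self.make_scores(
            [("a", "miRNA", 5.0, 2.0), ("b", "miRNA", 1.0, 2.0)]
        )
        ranked = prioritize.rank_separately(scores).set_index("node_id")
        assert ranked.loc["a", "rank_in_class"] == 1

    def test_input_order_irrelevant(self):
        rng = np.random.default_rng(3)
        rows = [(f"n{i}", "miRNA", float(rng.uniform()),
                 float(rng.uniform())) for i in range(10)]
        a = prioritize.rank_separately(self.make_scores(rows))
        b = prioritize.rank_separately(self.make_scores(rows[::-1]))
        am = dict(zip(a["node_id"], a["rank_in_class"]))
        bm = dict(zip(b["node_id"], b["rank_in_class"]))
        assert am == bm

    def test_ranks_are_permutations_within_class(self):
        rng = np.random.default_rng(4)
        rows = [(f"n{i}", "miRNA" if i % 2 else "protein_coding",
                 float(rng.uniform()), float(rng.uniform()))
                for i in range(11)]
        ranked = prioritize.rank_separately(self.make_scores(rows))
        for cls, grp in ranked.groupby("class"):
            assert sorted(grp["rank_in_class"]) == list(
                range(1, len(grp) + 1)
            )


class TestScoreWeightCorrelation:
    def test_proportional_scores_give_unit_correlation(self):
        df = pd.DataFrame(
            {
                "node_id": ["a", "b", "c"],
                "class": ["miRNA"] * 3,
                "weight": [1.0, 2.0, 3.0],
                "score": [2.0, 4.0, 6.0],
            }
        )
        assert prioritize.correlate_score_with_weight(df) == pytest.approx(
            1.0
        )

    def test_constant_scores_report_missing(self):
        df = pd.DataFrame(
            {
                "node_id": ["a", "b", "c"],
                "class": ["miRNA"] * 3,
                "weight": [1.0, 2.0, 3.0],
                "score": [5.0, 5.0, 5.0],
            }
        )
        assert np.isnan(prioritize.correlate_score_with_weight(df))

    def test_too_few_mirnas_report_missing(self):
        df = pd.DataFrame(
            {
                "node_id": ["a"], "class": ["miRNA"],
                "weight": [1.0], "score": [1.0],
            }
        )
        assert np.isnan(prioritize.correlate_score_with_weight(df))

    def test_mostly_positive_on_weight_driven_networks(self):
        positives = 0
        for seed in range(20):
            cfg = synth.SynthConfig(n_genes=120, n_mirnas=12, seed=seed)
            G, _ = synth.generate_priority_network(cfg, kind="mirna_hub")
            scored = prioritize.score_network(G, bins=10)
            corr = prioritize.correlate_score_with_weight(scored)
            positives += corr > 0
        assert positives / 20 >= 0.9


class TestStructuralProperties:
    def test_self_weight_monotonicity(self):
        rng = np.random.default_rng(6)
        G = random_weighted_graph(rng, n_max=10)
        target = sorted(G.nodes)[0]
        scored = prioritize.rank_separately(
            prioritize.score_network(G, bins=10)
        ).set_index("node_id")
        before = scored.loc[target, "rank_in_class"]
        G.nodes[target]["weight"] += 5.0
        after = prioritize.rank_separately(
            prioritize.score_network(G, bins=10)
        ).set_index("node_id").loc[target, "rank_in_class"]
        assert after <= before

    def test_translation_leaves_order_on_complete_uniform_graph(self):
        rng = np.random.default_rng(12)
        G = nx.complete_graph(8)
        for n in G.nodes:
            G.nodes[n]["class"] = "protein_coding"
            G.nodes[n]["weight"] = float(rng.uniform(0.5, 5.0))
        for u, v in G.edges:
            G.edges[u, v]["length"] = 0.5
        order1 = prioritize.rank_separately(
            prioritize.score_network(G, bins=10)
        ).sort_values("rank_in_class")["node_id"].tolist()
        for n in G.nodes:
            G.nodes[n]["weight"] += 10.0
        order2 = prioritize.rank_separately(
            prioritize.score_network(G, bins=10)
        ).sort_values("rank_in_class")["node_id"].tolist()
        assert order1 == order2
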