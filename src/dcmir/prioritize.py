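"""Guilt-by-association node prioritization on regulatory networks.

Each node carries a perturbation weight p_j = -log10(p_adj) * |log2FC|.
For node i, the neighborhood-importance curve evaluates, at each distance
threshold s,

    K_i(s) = (2 / p_bar) * sum_j (p_j - p_bar) * 1[d(i, j) <= s],

where d is the weighted shortest-path distance over edge lengths
1 - |rho|, p_bar the mean weight over the network's nodes, and the sum runs
over every node including i itself (d(i, i) = 0). Thresholds are equally
spaced over (0, max finite distance]; unreachable nodes never satisfy the
indicator. A node's score is the mean height of its curve (trapezoidal area
divided by the threshold range): nodes sitting inside clusters of
high-perturbation nodes score high. miRNAs and protein-coding genes are
ranked separately.

The 2/p_bar constant follows the convention of the clustering-based
association statistic this score derives from; any positive constant leaves
the ranking unchanged.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_BINS = 25
P_ADJ_FLOOR = 1e-300
# a node whose distance falls within this tolerance of a threshold counts as
# inside it; shields the indicator from float jitter between shortest-path
# algorithms (edge lengths are O(1), so 1e-9 is far below any real gap)
DIST_TOL = 1e-9


def node_weight(p_adj: float, log2fc: float) -> float:
    """Perturbation weight -log10(p_adj) * |log2FC|.

    A missing adjusted p-value (feature removed by independent filtering, or
    absent from the DE table) yields weight 0. p_adj is clamped below at
    1e-300 to keep the logarithm finite.
    """
    if p_adj is None or (isinstance(p_adj, float) and np.isnan(p_adj)):
        return 0.0
    if p_adj <= 0.0:
        raise ValueError(f"p_adj must be positive, got {p_adj}")
    if not np.isfinite(log2fc):
        raise ValueError(f"log2fc must be finite, got {log2fc}")
    p = max(float(p_adj), P_ADJ_FLOOR)
    return float(-np.log10(p) * abs(log2fc))


def node_weights(p_adj: pd.Series, log2fc: pd.Series) -> pd.Series:
    """Vectorized perturbation weights (missing p_adj -> 0)."""
    p = p_adj.to_numpy(dtype=float)
    f = log2fc.to_numpy(dtype=float)
    if np.any(p[~np.isnan(p)] <= 0.0):
        raise ValueError("p_adj must be positive where present")
    w = np.where(
        np.isnan(p), 0.0, -np.log10(np.clip(p, P_ADJ_FLOOR, None)) * np.abs(f)
    )
    return pd.Series(w, index=p_adj.index, name="weight")


def all_shortest_distances(
    G: nx.Graph, weight: str = "length", directed: bool = False
) -> tuple[list[str], np.ndarray]:
    """All-pairs weighted shortest-path distances.

    Returns ``(nodes, D)`` with D[i, j] the minimum total edge length from
    node i to node j (+inf if unreachable, 0 on the diagonal). By default
    the graph is viewed as undirected, matching the symmetric,
    association-based reading of the score.
    """
    H = G if (directed or not G.is_directed()) else G.to_undirected(as_view=True)
    nodes = sorted(H.nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    D = np.full((len(nodes), len(nodes)), np.inf)
    for src, dists in nx.all_pairs_dijkstra_path_length(H, weight=weight):
        i = pos[src]
        for dst, d in dists.items():
            D[i, pos[dst]] = d
    np.fill_diagonal(D, 0.0)
    return nodes, D


def make_thresholds(D: np.ndarray, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Equally spaced distance thresholds over (0, max finite distance].

    Degenerate case: if every finite distance is 0 (single node or fully
    coincident nodes) a single zero threshold is returned.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    finite = D[np.isfinite(D)]
    dmax = float(finite.max()) if finite.size else 0.0
    if dmax == 0.0:
        return np.array([0.0])
    return dmax * np.arange(1, bins + 1) / bins


def neighborhood_curves(
    D: np.ndarray, weights: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """K_i(s) for all nodes i and thresholds s (rows = nodes).

    K_i(s) = (2 / p_bar) * sum_j (p_j - p_bar) * 1[d(i,j) <= s]. All-zero
    weights give all-zero curves with a warning (p_bar = 0 is degenerate).
    """
    weights = np.asarray(weights, dtype=float)
    p_bar = weights.mean()
    if p_bar == 0.0:
        log.warning("all node weights are zero; curves are identically zero")
        return np.zeros((D.shape[0], len(thresholds)))
    centered = weights - p_bar
    # indicator (n_nodes, n_nodes, n_thresholds) collapsed via matmul per s
    out = np.empty((D.shape[0], len(thresholds)))
    for k, s in enumerate(thresholds):
        ind = D <= s + DIST_TOL  # infinite distances never satisfy this
        out[:, k] = ind @ centered
    return (2.0 / p_bar) * out


def knode_score(curve: np.ndarray, thresholds: np.ndarray) -> float:
    """Mean height of the neighborhood-importance curve.

    Trapezoidal area over the thresholds divided by the threshold range, so
    scores are comparable across networks with different distance scales.
    A single-threshold (degenerate) curve scores its only value.
    """
    curve = np.asarray(curve, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    if curve.shape != thresholds.shape:
        raise ValueError("curve and thresholds must have the same length")
    span = thresholds[-1] - thresholds[0]
    if span == 0.0:
        return float(curve[0])
    return float(np.trapezoid(curve, thresholds) / span)


def score_network(
    G: nx.Graph, bins: int = DEFAULT_BINS, directed: bool = False
) -> pd.DataFrame:
    """Score every node of a weighted network.

    Node attributes required: ``class`` and ``weight``. Returns a table
    (node_id, class, weight, score) in canonical node order.
    """
    if G.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node_id", "class", "weight", "score"])
    nodes, D = all_shortest_distances(G, directed=directed)
    weights = np.array([G.nodes[n]["weight"] for n in nodes], dtype=float)
    thresholds = make_thresholds(D, bins=bins)
    curves = neighborhood_curves(D, weights, thresholds)
    scores = [knode_score(curves[i], thresholds) for i in range(len(nodes))]
    return pd.DataFrame(
        {
            "node_id": nodes,
            "class": [G.nodes[n]["class"] for n in nodes],
            "weight": weights,
            "score": scores,
        }
    )


def rank_separately(scores: pd.DataFrame) -> pd.DataFrame:
    """Within-class ranks: descending score, ties by descending weight then
    lexicographic id; rank 1 is the top node of its class."""
    out = scores.copy()
    out["rank_in_class"] = 0
    for cls, idx in out.groupby("class").groups.items():
        sub = out.loc[idx]
        order = sub.sort_values(
            by=["score", "weight", "node_id"],
            ascending=[False, False, True],
            kind="mergesort",
        ).index
        out.loc[order, "rank_in_class"] = np.arange(1, len(order) + 1)
    return out


def correlate_score_with_weight(
    scores: pd.DataFrame, cls: str = "miRNA"
) -> float:
    """Pearson correlation between scores and weights within one class.

    Needs >= 3 nodes of the class and non-constant vectors; otherwise NaN
    with a log entry.
    """
    sub = scores[scores["class"] == cls]
    if len(sub) < 3:
        log.info("score-weight correlation: <3 %s nodes", cls)
        return float("nan")
    s = sub["score"].to_numpy(dtype=float)
    w = sub["weight"].to_numpy(dtype=float)
    if np.std(s) == 0.0 or np.std(w) == 0.0:
        log.info("score-weight correlation: degenerate (constant) input")
        return float("nan")
    return float(np.corrcoef(s, w)[0, 1])


def prioritize_networks(
    networks: dict[str, nx.Graph], bins: int = DEFAULT_BINS,
    directed: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank every category network; also report per-category score-weight
    correlation among miRNAs.

    Returns ``(ranking, correlations)``.
    """
    rank_frames = []
    corr_rows = []
    for cat in sorted(networks):
        G = networks[cat]
        scored = score_network(G, bins=bins, directed=directed)
        if scored.empty:
            continue
        ranked = rank_separately(scored)
        ranked.insert(0, "category", cat)
        rank_frames.append(ranked)
        corr_rows.append(
            {
                "category": cat,
                "mirna_score_weight_corr":
                    correlate_score_with_weight(ranked, "miRNA"),
                "n_mirnas": int((ranked["class"] == "miRNA").sum()),
            }
        )
    ranking = (
        pd.concat(rank_frames, ignore_index=True)
        if rank_frames
        else pd.DataFrame(columns=["category", "node_id", "class", "weight",
                                   "score", "rank_in_class"])
    )
    return ranking, pd.DataFrame(corr_rows)
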