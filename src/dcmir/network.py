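"""Regulatory-network reconstruction with correlation sign filtering.

Functional gene-gene interactions (activation, inhibition, co-expression /
complex formation) are merged with miRNA-target edges whose predictions
carry experimental support. Every edge is annotated with the Pearson
correlation of its endpoints' normalized expression across treated-condition
samples; an edge survives only if the correlation sign agrees with its
regulation type — activation positive, inhibition negative, miRNA targeting
negative, co-expression/complex kept regardless. Edge length is 1 - |rho|,
so strongly co-varying partners are close. Per-root-category networks are
vertex-induced subgraphs around the category's pathway genes plus the
significantly DE miRNAs that target them.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

from .prioritize import node_weight
from .synth import PathwayCollection

log = logging.getLogger(__name__)

FUNCTIONAL_TYPES = ("activation", "inhibition", "coexpression_complex")


def directionalize(catalogue: pd.DataFrame) -> pd.DataFrame:
    """Expand bidirectional edges into their two unidirectional constituents.

    Forward edges pass through; duplicate (source, target, type) triples are
    dropped.
    """
    rows = []
    for row in catalogue.itertuples(index=False):
        rows.append((row.source, row.target, row.type))
        if row.direction == "bidirectional":
            rows.append((row.target, row.source, row.type))
    out = pd.DataFrame(rows, columns=["source", "target", "type"])
    out = out.drop_duplicates(ignore_index=True)
    out["direction"] = "forward"
    return out


def intersect_mirna_targets(
    predicted: pd.DataFrame,
    experimental: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Keep predicted (miRNA, gene) pairs with support in >= 1 experimental
    table; provenance lists the supporting tables."""
    pred_pairs = predicted[["mirna", "gene"]].drop_duplicates()
    support: dict[tuple[str, str], list[str]] = {}
    for name in sorted(experimental):
        tab = experimental[name]
        for pair in zip(tab["mirna"], tab["gene"]):
            support.setdefault(pair, []).append(name)
    rows = []
    for pair in zip(pred_pairs["mirna"], pred_pairs["gene"]):
        if pair in support:
            rows.append(
                (pair[0], pair[1], "mirna_target", "forward",
                 ";".join(support[pair]))
            )
    return pd.DataFrame(
        rows, columns=["source", "target", "type", "direction", "provenance"]
    )


def merge_catalogue(
    functional: pd.DataFrame, mirna_edges: pd.DataFrame
) -> pd.DataFrame:
    """Directionalized functional edges plus supported miRNA-target edges."""
    func = directionalize(functional[functional["type"].isin(FUNCTIONAL_TYPES)])
    func["provenance"] = "catalogue"
    cols = ["source", "target", "type", "direction", "provenance"]
    return pd.concat([func[cols], mirna_edges[cols]], ignore_index=True)


def edge_correlations(
    edges: pd.DataFrame,
    norm_expr: pd.DataFrame,
    sheet: pd.DataFrame,
    condition: str = "treated",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of edge endpoints across one condition's samples.

    ``norm_expr`` is the normalized-log expression matrix covering both
    feature classes. Edges with an unmeasured endpoint are dropped with a
    log entry; ``length = 1 - |rho|``.
    """
    samples = sheet.loc[sheet["condition"] == condition, "sample_id"].tolist()
    if len(samples) < min_samples:
        raise ValueError(
            f"need >= {min_samples} {condition} samples, got {len(samples)}"
        )
    expr = norm_expr[samples]
    measured = set(expr.index)

    keep = edges["source"].isin(measured) & edges["target"].isin(measured)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d edges with unmeasured endpoints", n_drop)
    out = edges.loc[keep].copy()

    mat = expr.to_numpy(dtype=float)
    pos = {f: i for i, f in enumerate(expr.index)}
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))

    si = out["source"].map(pos).to_numpy()
    ti = out["target"].map(pos).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (centered[si] * centered[ti]).sum(axis=1) / (norms[si] * norms[ti])
    rho = np.clip(rho, -1.0, 1.0)
    out["rho"] = rho
    out["length"] = 1.0 - np.abs(rho)
    const = ~np.isfinite(rho)
    if const.any():
        log.info("dropping %d edges with constant endpoint expression",
                 int(const.sum()))
        out = out.loc[~const]
    return out


def filter_by_sign(edges: pd.DataFrame) -> pd.DataFrame:
    """Sign-consistency filter.

    activation requires rho > 0; inhibition and mirna_target require
    rho < 0; coexpression_complex is kept regardless. Zero correlation
    carries no sign evidence, so strict inequalities remove it.
    """
    rho = edges["rho"].to_numpy(dtype=float)
    etype = edges["type"]
    keep = (
        ((etype == "activation") & (rho > 0))
        | ((etype == "inhibition") & (rho < 0))
        | ((etype == "mirna_target") & (rho < 0))
        | (etype == "coexpression_complex")
    )
    return edges.loc[keep.to_numpy()].reset_index(drop=True)


def classify_influence(rho: float) -> str:
    """Regulative-influence class of a miRNA-gene correlation.

    strong: rho <= -0.5; weak: -0.5 < rho <= -0.3; none otherwise.
    """
    if rho <= -0.5:
        return "strong"
    if rho <= -0.3:
        return "weak"
    return "none"


def build_category_network(
    category: str,
    collection: PathwayCollection,
    root_map: dict[str, set[str]],
    edges: pd.DataFrame,
    de_genes: pd.DataFrame,
    de_mirnas: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    mirna_alpha: float = 0.05,
) -> nx.Graph:
    """Vertex-induced regulatory network for one root category.

    Nodes are the category's pathway genes present in the DE data plus
    significantly DE miRNAs with >= 1 surviving target edge into those
    genes. Edges are the surviving sign-filtered edges with both endpoints
    in the node set. Node attributes: class, perturbation weight,
    log2fc, p_adj, immune_category, is_TF.
    """
    cat_pathways = [p for p, roots in root_map.items() if category in roots]
    cat_genes: set[str] = set()
    for pid in cat_pathways:
        cat_genes |= collection.sets[pid]
    measured = set(de_genes["feature_id"])
    genes = cat_genes & measured

    sig_mirnas = set(
        de_mirnas.loc[
            de_mirnas["p_adj"].notna() & (de_mirnas["p_adj"] <= mirna_alpha),
            "feature_id",
        ]
    )
    mt = edges[
        (edges["type"] == "mirna_target")
        & edges["source"].isin(sig_mirnas)
        & edges["target"].isin(genes)
    ]
    mirnas = set(mt["source"])

    nodes = genes | mirnas
    G = nx.Graph(category=category)
    if not nodes:
        log.warning("category %s: empty node set", category)
        return G

    de_all = pd.concat([de_genes, de_mirnas], ignore_index=True)
    de_all = de_all.set_index("feature_id")
    ann = None
    if annotations is not None:
        ann = annotations.set_index("feature_id")

    for node in sorted(nodes):
        cls = "miRNA" if node in mirnas else "protein_coding"
        rec = de_all.loc[node] if node in de_all.index else None
        p_adj = float(rec["p_adj"]) if rec is not None and \
            pd.notna(rec["p_adj"]) else np.nan
        log2fc = float(rec["log2fc"]) if rec is not None else np.nan
        attrs = {
            "class": cls,
            "log2fc": log2fc,
            "p_adj": p_adj,
            "weight": node_weight(p_adj, log2fc),
            "immune_category": "none",
            "is_TF": False,
        }
        if ann is not None and node in ann.index:
            attrs["immune_category"] = str(ann.loc[node, "immune_category"])
            attrs["is_TF"] = bool(ann.loc[node, "is_TF"])
        G.add_node(node, **attrs)

    sub = edges[edges["source"].isin(nodes) & edges["target"].isin(nodes)]
    for row in sub.sort_values(["source", "target", "type"]).itertuples(
        index=False
    ):
        # undirected view: keep the strongest |rho| if both directions exist
        if G.has_edge(row.source, row.target):
            if abs(row.rho) <= abs(G.edges[row.source, row.target]["rho"]):
                continue
        G.add_edge(
            row.source, row.target,
            type=row.type, rho=float(row.rho), length=float(row.length),
        )
    return G


def build_all_category_networks(
    collection: PathwayCollection,
    root_map: dict[str, set[str]],
    edges: pd.DataFrame,
    de_genes: pd.DataFrame,
    de_mirnas: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    mirna_alpha: float = 0.05,
) -> dict[str, nx.Graph]:
    categories = sorted(set().union(*root_map.values())) if root_map else []
    return {
        cat: build_category_network(
            cat, collection, root_map, edges, de_genes, de_mirnas,
            annotations=annotations, mirna_alpha=mirna_alpha,
        )
        for cat in categories
    }


def network_to_tables(G: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for TSV export (canonical order)."""
    node_rows = [
        {
            "id": n,
            "class": d.get("class", ""),
            "weight": d.get("weight", np.nan),
            "log2fc": d.get("log2fc", np.nan),
            "p_adj": d.get("p_adj", np.nan),
            "immune_category": d.get("immune_category", "none"),
            "is_TF": d.get("is_TF", False),
        }
        for n, d in sorted(G.nodes(data=True))
    ]
    edge_rows = [
        {
            "source": min(u, v),
            "target": max(u, v),
            "type": d.get("type", ""),
            "rho": d.get("rho", np.nan),
            "length": d.get("length", np.nan),
        }
        for u, v, d in sorted(
            G.edges(data=True), key=lambda e: (min(e[0], e[1]),
                                               max(e[0], e[1]))
        )
    ]
    return (
        pd.DataFrame(node_rows, columns=["id", "class", "weight", "log2fc",
                                         "p_adj", "immune_category", "is_TF"]),
        pd.DataFrame(edge_rows, columns=["source", "target", "type", "rho",
                                         "length"]),
    )


def network_from_tables(nodes: pd.DataFrame, edges: pd.DataFrame,
                        category: str = "") -> nx.Graph:
    G = nx.Graph(category=category)
    for rec in nodes.to_dict("records"):
        G.add_node(
            rec["id"],
            **{
                "class": rec["class"],
                "weight": float(rec["weight"]),
                "log2fc": float(rec["log2fc"]),
                "p_adj": float(rec["p_adj"]),
                "immune_category": rec["immune_category"],
                "is_TF": bool(rec["is_TF"]),
            },
        )
    for row in edges.itertuples(index=False):
        G.add_edge(row.source, row.target, type=row.type,
                   rho=float(row.rho), length=float(row.length))
    return G
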