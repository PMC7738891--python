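"""Summary artifacts: targeting profiles, regulation landscape, candidates.

These are joins and counts over upstream stage outputs — no new statistics
are computed here.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .network import classify_influence
from .synth import PathwayCollection


def _mirna_targets(G: nx.Graph) -> dict[str, set[str]]:
    """miRNA -> set of protein-coding genes with surviving target edges."""
    out: dict[str, set[str]] = {}
    for u, v, d in G.edges(data=True):
        if d.get("type") != "mirna_target":
            continue
        mirna, gene = (u, v) if G.nodes[u].get("class") == "miRNA" else (v, u)
        out.setdefault(mirna, set()).add(gene)
    return out


def targeting_profile(
    networks: dict[str, nx.Graph],
    enrich: pd.DataFrame,
    collection: PathwayCollection,
    root_map: dict[str, set[str]],
) -> pd.DataFrame:
    """Per (miRNA, root category): target count and regulated enriched
    pathways.

    n_targets counts distinct protein-coding genes with surviving edges from
    the miRNA inside the category network; n_enriched_regulated counts the
    category's significantly enriched pathways containing at least one such
    target.
    """
    sig = enrich[enrich["significant"]] if len(enrich) else enrich
    rows = []
    for cat in sorted(networks):
        G = networks[cat]
        cat_sig = [
            p for p in sig["pathway_id"]
            if cat in root_map.get(p, set())
        ] if len(sig) else []
        for mirna, targets in sorted(_mirna_targets(G).items()):
            n_enriched = sum(
                1 for pid in cat_sig
                if collection.sets[pid] & targets
            )
            rows.append(
                {
                    "mirna": mirna,
                    "category": cat,
                    "n_targets": len(targets),
                    "n_enriched_pathways_regulated": n_enriched,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mirna", "category", "n_targets",
                 "n_enriched_pathways_regulated"],
    )


def landscape_matrix(
    G: nx.Graph,
    collection: PathwayCollection,
    root_map: dict[str, set[str]],
    enrich: pd.DataFrame,
    de_genes: pd.DataFrame,
    ranking: pd.DataFrame,
    rho_max: float = -0.3,
) -> pd.DataFrame:
    """Tidy landscape of one category: pathway membership rows plus
    miRNA-influence rows over the DE genes targeted at rho <= rho_max.

    Rows: (row_kind in {pathway, mirna}, row_id, gene, value) where value is
    1.0 for pathway membership and the Pearson rho for miRNA influence.
    Gene annotations (log2fc) and pathway/miRNA annotations (fdr, rank) are
    attached as extra columns.
    """
    category = G.graph.get("category", "")
    sig_de = set(
        de_genes.loc[
            de_genes["p_adj"].notna() & (de_genes["p_adj"] <= 0.05),
            "feature_id",
        ]
    )
    # DE protein-coding genes targeted by a miRNA at rho <= rho_max
    influence = []
    for u, v, d in G.edges(data=True):
        if d.get("type") != "mirna_target":
            continue
        mirna, gene = (u, v) if G.nodes[u].get("class") == "miRNA" else (v, u)
        if gene in sig_de and d["rho"] <= rho_max:
            influence.append((mirna, gene, d["rho"]))
    genes = sorted({g for _, g, _ in influence})

    lfc = de_genes.set_index("feature_id")["log2fc"]
    fdr = (
        enrich.set_index("pathway_id")["fdr"] if len(enrich)
        else pd.Series(dtype=float)
    )
    sig = enrich[enrich["significant"]] if len(enrich) else enrich
    cat_paths = sorted(
        p for p in (sig["pathway_id"] if len(sig) else [])
        if category in root_map.get(p, set())
    )

    mirna_rank = {}
    if len(ranking):
        sub = ranking[(ranking["category"] == category)
                      & (ranking["class"] == "miRNA")]
        mirna_rank = dict(zip(sub["node_id"], sub["rank_in_class"]))

    rows = []
    for pid in cat_paths:
        for gene in genes:
            if gene in collection.sets[pid]:
                rows.append(
                    {
                        "row_kind": "pathway",
                        "row_id": pid,
                        "gene": gene,
                        "value": 1.0,
                        "gene_log2fc": float(lfc.get(gene, np.nan)),
                        "row_fdr": float(fdr.get(pid, np.nan)),
                        "row_rank": np.nan,
                    }
                )
    for mirna, gene, rho in sorted(influence):
        rows.append(
            {
                "row_kind": "mirna",
                "row_id": mirna,
                "gene": gene,
                "value": float(rho),
                "gene_log2fc": float(lfc.get(gene, np.nan)),
                "row_fdr": np.nan,
                "row_rank": float(mirna_rank.get(mirna, np.nan)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["row_kind", "row_id", "gene", "value", "gene_log2fc",
                 "row_fdr", "row_rank"],
    )


def candidate_table(
    networks: dict[str, nx.Graph],
    coop: pd.DataFrame,
    direction_notes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Strong/weak-influence miRNA-gene candidates with cooperativity
    partners.

    One row per surviving miRNA-target edge classified strong or weak
    (rho <= -0.3); partners joins the passing cooperativity records;
    ``direction_notes`` (mirna, note) is passthrough annotation.
    """
    notes = {}
    if direction_notes is not None and len(direction_notes):
        notes = dict(zip(direction_notes["mirna"], direction_notes["note"]))

    partner_map: dict[tuple[str, str], list[str]] = {}
    if len(coop):
        for rec in coop.itertuples(index=False):
            partner_map.setdefault((rec.de_mirna, rec.gene), []).append(
                rec.partner_mirna
            )

    seen = set()
    rows = []
    for cat in sorted(networks):
        G = networks[cat]
        for u, v, d in G.edges(data=True):
            if d.get("type") != "mirna_target":
                continue
            mirna, gene = (u, v) if G.nodes[u].get("class") == "miRNA" \
                else (v, u)
            influence = classify_influence(d["rho"])
            if influence == "none" or (mirna, gene) in seen:
                continue
            seen.add((mirna, gene))
            rows.append(
                {
                    "mirna": mirna,
                    "gene": gene,
                    "influence": influence,
                    "rho": float(d["rho"]),
                    "partners": ";".join(
                        sorted(set(partner_map.get((mirna, gene), [])))
                    ),
                    "mirna_direction_note": notes.get(mirna, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mirna", "gene", "influence", "rho", "partners",
                 "mirna_direction_note"],
    ).sort_values(["mirna", "gene"], ignore_index=True)
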