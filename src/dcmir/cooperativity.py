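"""miRNA cooperativity: pairs predicted to co-repress a shared target.

Two miRNAs binding a transcript in proximity can form an RNA triplex whose
joint repression exceeds either miRNA alone. The pipeline consumes a
precomputed triplex-attribute table (equilibrium concentration in nM,
minimum free energy in kcal/mol) and keeps triplexes with equilibrium
concentration >= 50 nM and MFE <= -25 kcal/mol, both thresholds inclusive.
Candidate records must involve at least one significantly DE miRNA; the
cooperating partner need not itself be DE or in the network — it is
annotation.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

EQ_CONC_MIN_NM = 50.0
MFE_MAX_KCAL = -25.0

TRIPLEX_FIELDS = ["mirna1", "mirna2", "gene", "eq_conc", "mfe"]


def candidate_pairs(
    de_mirnas: set[str], triplex_table: pd.DataFrame
) -> pd.DataFrame:
    """Records where at least one participating miRNA is significantly DE."""
    keep = triplex_table["mirna1"].isin(de_mirnas) | \
        triplex_table["mirna2"].isin(de_mirnas)
    return triplex_table.loc[keep].drop_duplicates(
        subset=TRIPLEX_FIELDS[:3]
    ).reset_index(drop=True)


def filter_triplexes(records: pd.DataFrame) -> pd.DataFrame:
    """Set the ``passes`` flag: eq_conc >= 50 nM and mfe <= -25 kcal/mol.

    Boundary values pass. Records with a missing numeric field are rejected
    (dropped) with a log entry.
    """
    numeric = records[["eq_conc", "mfe"]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = numeric.isna().any(axis=1)
    if bad.any():
        log.warning("rejecting %d triplex records with missing fields",
                    int(bad.sum()))
    out = records.loc[~bad].copy()
    out["eq_conc"] = numeric.loc[~bad, "eq_conc"]
    out["mfe"] = numeric.loc[~bad, "mfe"]
    out["passes"] = (out["eq_conc"] >= EQ_CONC_MIN_NM) & \
        (out["mfe"] <= MFE_MAX_KCAL)
    return out.reset_index(drop=True)


def attach_cooperativity(
    G: nx.Graph, passing_records: pd.DataFrame
) -> pd.DataFrame:
    """Partner lists for each miRNA-target edge of a network.

    For every surviving mirna_target edge (miRNA m, gene g), the partners
    are the other miRNAs of passing triplex records on gene g that include
    m. Records whose gene is not in the network are ignored. Returns tidy
    rows (gene, de_mirna, partner_mirna, eq_conc, mfe); edges without any
    passing record are omitted (empty partner list).
    """
    if "passes" in passing_records.columns:
        passing_records = passing_records[passing_records["passes"]]

    rows = []
    for u, v, d in G.edges(data=True):
        if d.get("type") != "mirna_target":
            continue
        mirna, gene = (u, v) if G.nodes[u].get("class") == "miRNA" else (v, u)
        recs = passing_records[passing_records["gene"] == gene]
        for rec in recs.itertuples(index=False):
            if rec.mirna1 == mirna:
                partner = rec.mirna2
            elif rec.mirna2 == mirna:
                partner = rec.mirna1
            else:
                continue
            rows.append(
                {
                    "gene": gene,
                    "de_mirna": mirna,
                    "partner_mirna": partner,
                    "eq_conc": float(rec.eq_conc),
                    "mfe": float(rec.mfe),
                }
            )
    out = pd.DataFrame(
        rows, columns=["gene", "de_mirna", "partner_mirna", "eq_conc", "mfe"]
    )
    return out.sort_values(
        ["gene", "de_mirna", "partner_mirna"], ignore_index=True
    )
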