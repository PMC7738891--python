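"""Competitive gene-set enrichment over pathway collections.

The per-gene statistic is the weighted log2 fold-change (log2FC divided by
its standard error). Each pathway is tested competitively against the rest
of the measured genes with a two-sample t statistic whose denominator is
inflated by a variance inflation factor VIF = 1 + (m - 1) * rho_bar to
account for inter-gene correlation within the set, in the spirit of
correlation-adjusted competitive gene-set tests. A positive score means the
set's genes tend to sit at the upregulated end of the statistic.

Pathways are organized in a parent-child hierarchy with designated root
categories; each pathway is assigned every root reachable by ascending
parent links.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .synth import PathwayCollection

log = logging.getLogger(__name__)

DEFAULT_RHO_BAR = 0.01
DEFAULT_MIN_SET_SIZE = 5


def gene_statistic(de: pd.DataFrame) -> pd.Series:
    """Weighted log2FC: z = log2fc / se_log2fc.

    Features with zero standard error carry no usable scale and are
    excluded with a warning.
    """
    se = de["se_log2fc"].to_numpy(dtype=float)
    usable = se > 0
    n_drop = int((~usable).sum())
    if n_drop:
        log.warning("excluding %d zero-variance features from the gene "
                    "statistic", n_drop)
    sub = de.loc[usable]
    z = sub["log2fc"].to_numpy(dtype=float) / sub["se_log2fc"].to_numpy(float)
    return pd.Series(z, index=pd.Index(sub["feature_id"], name="feature_id"),
                     name="z")


def map_to_roots(collection: PathwayCollection) -> dict[str, set[str]]:
    """Assign each pathway the root-category names of all reachable roots.

    Roots map to their own category name. Raises on a hierarchy cycle,
    naming the pathways involved.
    """
    parents: dict[str, set[str]] = {}
    for row in collection.hierarchy.itertuples(index=False):
        parents.setdefault(row.child_id, set()).add(row.parent_id)

    root_name = dict(
        zip(collection.roots["pathway_id"], collection.roots["root_name"])
    )

    _check_acyclic(parents)

    cache: dict[str, set[str]] = {}

    def ascend(pid: str) -> set[str]:
        if pid in cache:
            return cache[pid]
        found: set[str] = set()
        if pid in root_name:
            found.add(root_name[pid])
        for par in parents.get(pid, ()):
            found |= ascend(par)
        cache[pid] = found
        return found

    return {pid: ascend(pid) for pid in collection.sets}


def _check_acyclic(parents: dict[str, set[str]]) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}
    stack_path: list[str] = []

    def visit(node: str) -> None:
        color[node] = GREY
        stack_path.append(node)
        for par in parents.get(node, ()):
            c = color.get(par, WHITE)
            if c == GREY:
                cyc = stack_path[stack_path.index(par):] + [par]
                raise ValueError(f"hierarchy cycle: {' -> '.join(cyc)}")
            if c == WHITE:
                visit(par)
        stack_path.pop()
        color[node] = BLACK

    for node in list(parents):
        if color.get(node, WHITE) == WHITE:
            visit(node)


def validate_collection(collection: PathwayCollection) -> dict[str, set[str]]:
    """Root mapping plus the closure check that every pathway reaches a root."""
    roots = map_to_roots(collection)
    orphans = sorted(p for p, r in roots.items() if not r)
    if orphans:
        raise ValueError(f"pathways reach no root category: {orphans[:10]}")
    return roots


def competitive_test(
    stats_by_gene: pd.Series,
    gene_set: set[str],
    rho_bar: float = DEFAULT_RHO_BAR,
) -> tuple[float, float]:
    """Correlation-adjusted two-sample t-test of in-set vs out-of-set genes.

    With rho_bar = 0 this is the ordinary pooled-variance two-sample t-test.
    Returns ``(score, p)`` where score is the t statistic (positive = the
    set tends to be upregulated) and p its two-sided tail from a t
    distribution with M - 2 df.
    """
    z = stats_by_gene.to_numpy(dtype=float)
    in_mask = stats_by_gene.index.isin(gene_set)
    m = int(in_mask.sum())
    M = z.size
    if m == 0 or m >= M:
        raise ValueError(f"set size {m} incompatible with background {M}")
    z_in, z_out = z[in_mask], z[~in_mask]
    delta = z_in.mean() - z_out.mean()
    ss = ((z_in - z_in.mean()) ** 2).sum() + ((z_out - z_out.mean()) ** 2).sum()
    s_p = np.sqrt(ss / (M - 2))
    if s_p == 0.0:
        raise ValueError("pooled standard deviation is zero")
    vif = 1.0 + (m - 1) * rho_bar
    t = delta / (s_p * np.sqrt(vif * (1.0 / m + 1.0 / (M - m))))
    p = 2.0 * stats.t.sf(abs(t), df=M - 2)
    return float(t), float(p)


def enrich_all(
    de: pd.DataFrame,
    collection: PathwayCollection,
    alpha: float = 0.05,
    rho_bar: float = DEFAULT_RHO_BAR,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    exclude_filtered: bool = False,
) -> pd.DataFrame:
    """Competitive test for every pathway, BH-corrected across pathways.

    The background is every feature with a computed statistic; pass
    ``exclude_filtered=True`` to restrict it to features that survived
    independent filtering. Pathways with fewer than ``min_set_size`` genes
    in the background are skipped with a log entry.
    """
    sub = de
    if exclude_filtered:
        sub = de[~de["filtered"].astype(bool)]
    z = gene_statistic(sub)
    root_map = validate_collection(collection)

    rows = []
    for pid in sorted(collection.sets):
        gene_set = collection.sets[pid]
        n_in = int(z.index.isin(gene_set).sum())
        if n_in < min_set_size:
            log.info("skipping %s: only %d genes in data", pid, n_in)
            continue
        if n_in >= z.size:
            log.info("skipping %s: set covers the whole background", pid)
            continue
        score, p = competitive_test(z, gene_set, rho_bar=rho_bar)
        rows.append(
            {
                "pathway_id": pid,
                "roots": ";".join(sorted(root_map[pid])),
                "score": score,
                "p": p,
                "n_genes_in_data": n_in,
            }
        )
    result = pd.DataFrame(
        rows, columns=["pathway_id", "roots", "score", "p", "n_genes_in_data"]
    )
    if len(result):
        result["fdr"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["fdr"] <= alpha
    else:
        result["fdr"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result
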