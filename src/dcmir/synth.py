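"""Synthetic paired-donor RNA-seq data with a planted regulatory network.

The generator emulates the study design the pipeline targets: a small cohort
of donors, each contributing one control and one treated sample; negative
binomial counts for protein-coding genes and miRNAs; a planted set of
differentially expressed features with known log2 fold-changes; and
expression correlations whose signs follow a planted typed interaction
network (activation/co-expression positive, inhibition and miRNA targeting
negative).

Correlations are induced by shared latent Gaussian factors on the log2-mean
scale through a one-step signed graph filter: every feature owns one iid
standard-normal factor per sample, and a feature's latent value mixes its
own factor with its planted neighbours' factors, signed by the edge type.
Shared neighbours make the correlation structure transitive, as in real
co-expression modules; the self-mixing ratio is set so that an edge between
typical-degree nodes attains |rho| ~= corr_strength on the latent scale
(attenuating with node degree and with counting noise).

Everything is deterministic given ``SynthConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io

EDGE_TYPES = ("activation", "inhibition", "coexpression_complex")
# sampling weights for functional (gene-gene) edge types
_EDGE_TYPE_P = (0.5, 0.3, 0.2)

HUB_MIN_TARGETS = 20

# latent-factor scale in log2 units; chosen so that biological (latent)
# variation dominates NB counting noise at the default baseline means while
# keeping paired log2FC estimates usable at n_donors = 7
LATENT_SD = 0.5
DONOR_SD = 0.2


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults emulate the paired seven-donor design: two conditions per donor,
    a planted DE fraction with effect sizes |log2FC| in ``de_log2fc_range``,
    NB dispersion ``alpha`` with variance mu + alpha*mu^2, and a planted
    interaction network of ``network_density`` edges per node whose
    endpoints correlate with target magnitude ``corr_strength``.
    """

    n_genes: int = 200
    n_mirnas: int = 20
    n_donors: int = 7
    frac_de: float = 0.1
    de_log2fc_range: tuple[float, float] = (1.5, 3.0)
    nb_dispersion: float = 0.02
    baseline_mean_range: tuple[float, float] = (50.0, 2000.0)
    network_density: float = 1.5
    corr_strength: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_mirnas <= 0 or self.n_donors <= 0:
            raise ValueError("n_genes, n_mirnas, n_donors must be positive")
        if self.n_donors < 3:
            raise ValueError(
                "n_donors < 3: paired correlations are degenerate"
            )
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        lo, hi = self.de_log2fc_range
        if lo <= 0 or hi < lo:
            raise ValueError("de_log2fc_range must satisfy 0 < min <= max")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        blo, bhi = self.baseline_mean_range
        if blo <= 0 or bhi < blo:
            raise ValueError("baseline_mean_range must satisfy 0 < min <= max")
        if self.network_density <= 0:
            raise ValueError("network_density must be positive")
        if not 0.0 < self.corr_strength < 1.0:
            raise ValueError("corr_strength must lie in (0, 1)")


@dataclass
class GroundTruth:
    """What was planted: DE effects, the interaction network, the hub."""

    de_log2fc: dict[str, float]          # feature id -> planted log2FC
    planted_network: pd.DataFrame        # interaction catalogue
    planted_hub: str                     # miRNA id with >= 20 targets

    @property
    def de_features(self) -> set[str]:
        return set(self.de_log2fc)

    def to_json_dict(self) -> dict:
        return {
            "de_log2fc": self.de_log2fc,
            "planted_hub": self.planted_hub,
            "n_planted_edges": int(len(self.planted_network)),
        }


def gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}-5p" for i in range(1, n + 1)]


def feature_classes(config: SynthConfig) -> pd.Series:
    """Explicit class labels; class is never inferred from the id string."""
    ids = gene_ids(config.n_genes) + mirna_ids(config.n_mirnas)
    classes = ["protein_coding"] * config.n_genes + ["miRNA"] * config.n_mirnas
    return pd.Series(classes, index=pd.Index(ids, name="feature_id"),
                     name="class")


# ---------------------------------------------------------------------------
# interaction catalogue
# ---------------------------------------------------------------------------

def generate_interactions(config: SynthConfig) -> pd.DataFrame:
    """Planted typed interaction catalogue.

    Gene-gene functional edges (activation / inhibition /
    coexpression_complex, a fraction of them bidirectional) plus
    miRNA-target edges. One designated hub miRNA targets at least
    `HUB_MIN_TARGETS` genes. Total edge count is ~ n_genes * density,
    split 70% functional / 30% miRNA targeting, so it is bounded by
    [n_genes, 4 * n_genes] for densities in [1, 4].
    """
    if config.n_genes < HUB_MIN_TARGETS:
        raise ValueError(
            f"need n_genes >= {HUB_MIN_TARGETS} to plant the hub miRNA"
        )
    rng = np.random.default_rng([config.seed, 101])
    genes = gene_ids(config.n_genes)
    mirnas = mirna_ids(config.n_mirnas)

    n_total = int(round(config.n_genes * config.network_density))
    n_func = max(1, int(round(0.7 * n_total)))
    n_mirna_edges = max(HUB_MIN_TARGETS, n_total - n_func)

    rows: list[tuple[str, str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()

    # functional gene-gene edges
    attempts = 0
    while len(rows) < n_func and attempts < 50 * n_func:
        attempts += 1
        i, j = rng.integers(0, config.n_genes, size=2)
        if i == j:
            continue
        etype = EDGE_TYPES[rng.choice(3, p=_EDGE_TYPE_P)]
        key = (genes[i], genes[j], etype)
        if key in seen or (genes[j], genes[i], etype) in seen:
            continue
        seen.add(key)
        if etype == "coexpression_complex":
            direction = "bidirectional"
        else:
            direction = "bidirectional" if rng.random() < 0.15 else "forward"
        rows.append((genes[i], genes[j], etype, direction))

    # miRNA-target edges; the first miRNA is the planted hub
    hub = mirnas[0]
    hub_targets = rng.choice(config.n_genes,
                             size=min(HUB_MIN_TARGETS, config.n_genes),
                             replace=False)
    mt_seen: set[tuple[str, str]] = set()
    for t in hub_targets:
        mt_seen.add((hub, genes[t]))
        rows.append((hub, genes[t], "mirna_target", "forward"))
    n_rest = max(0, n_mirna_edges - len(hub_targets))
    attempts = 0
    while n_rest > 0 and attempts < 50 * n_mirna_edges:
        attempts += 1
        m = mirnas[int(rng.integers(1, config.n_mirnas))] \
            if config.n_mirnas > 1 else hub
        g = genes[int(rng.integers(0, config.n_genes))]
        if (m, g) in mt_seen:
            continue
        mt_seen.add((m, g))
        rows.append((m, g, "mirna_target", "forward"))
        n_rest -= 1

    return pd.DataFrame(rows, columns=io.INTERACTION_COLS)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _select_de_features(config: SynthConfig) -> dict[str, float]:
    """Planted DE features and their signed log2FC (deterministic).

    The hub miRNA is always included when any miRNAs are differentially
    expressed, so that it can enter the reconstructed networks.
    """
    rng = np.random.default_rng([config.seed, 202])
    lo, hi = config.de_log2fc_range
    out: dict[str, float] = {}

    n_de_g = int(round(config.frac_de * config.n_genes))
    n_de_m = int(round(config.frac_de * config.n_mirnas))
    genes = gene_ids(config.n_genes)
    mirnas = mirna_ids(config.n_mirnas)

    de_g = rng.choice(config.n_genes, size=n_de_g, replace=False)
    for i in de_g:
        mag = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out[genes[i]] = sign * mag

    if n_de_m > 0:
        picks = [0]  # the hub
        others = rng.choice(np.arange(1, config.n_mirnas),
                            size=n_de_m - 1, replace=False) \
            if n_de_m > 1 else []
        picks.extend(int(o) for o in others)
        for i in picks:
            mag = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            out[mirnas[i]] = sign * mag
    return out


def _graph_filter(
    features: list[str], catalogue: pd.DataFrame, corr_strength: float
) -> np.ndarray:
    """Row-normalized one-step signed graph filter W.

    Latent values are z = W @ V with V iid standard normal per feature and
    sample: W = r*I + A_signed, rows scaled to unit norm, where A_signed is
    the symmetric adjacency with +1 for activation/co-expression and -1 for
    inhibition/miRNA-target edges. The self-mixing ratio r solves
    2r / (r^2 + dbar) = corr_strength at the mean degree dbar, so an edge
    between typical-degree nodes correlates at ~corr_strength; when no such
    r exists (dense graphs) the magnitude-maximizing r = sqrt(dbar) is used.
    """
    idx = {f: i for i, f in enumerate(features)}
    n = len(features)
    A = np.zeros((n, n))
    for row in catalogue.itertuples(index=False):
        sign = -1.0 if row.type in ("inhibition", "mirna_target") else 1.0
        i, j = idx[row.source], idx[row.target]
        A[i, j] = A[j, i] = sign
    deg = (A != 0).sum(axis=1)
    dbar = deg[deg > 0].mean() if (deg > 0).any() else 1.0
    disc = 1.0 - corr_strength ** 2 * dbar
    if disc > 0:
        r = (1.0 - np.sqrt(disc)) / corr_strength
    else:
        r = np.sqrt(dbar)
    W = r * np.eye(n) + A
    W /= np.sqrt((W ** 2).sum(axis=1))[:, None]
    return W


def generate_counts(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate paired NB counts for genes and miRNAs.

    Returns ``(gene_counts, mirna_counts, sample_sheet, truth)``. Counts are
    feature x sample DataFrames; the sheet has one control and one treated
    sample per donor. Planted DE features have treated means scaled by
    2**log2FC; planted edges induce correlated log2-mean fluctuations with
    the sign of the edge type; a per-feature, per-donor offset shared by the
    donor's two samples makes the paired contrast the informative one.
    """
    catalogue = generate_interactions(config)
    de_map = _select_de_features(config)
    truth = GroundTruth(
        de_log2fc=de_map,
        planted_network=catalogue,
        planted_hub=mirna_ids(config.n_mirnas)[0],
    )

    classes = feature_classes(config)
    features = list(classes.index)
    n_feat = len(features)
    donors = [f"D{d}" for d in range(1, config.n_donors + 1)]
    samples = [f"{d}_{c}" for d in donors for c in ("control", "treated")]
    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "donor": [s.split("_")[0] for s in samples],
            "condition": [s.split("_")[1] for s in samples],
        }
    )

    rng = np.random.default_rng([config.seed, 303])
    blo, bhi = config.baseline_mean_range
    base = np.exp(rng.uniform(np.log(blo), np.log(bhi), size=n_feat))

    W = _graph_filter(features, catalogue, config.corr_strength)
    n_samples = len(samples)
    factors = rng.standard_normal((n_feat, n_samples))
    z = W @ factors                                 # unit-variance latents

    donor_off = rng.normal(0.0, DONOR_SD, size=(n_feat, config.n_donors))
    donor_of_sample = np.repeat(np.arange(config.n_donors), 2)
    treated = np.array([c == "treated" for c in sheet["condition"]])

    lfc = np.array([de_map.get(f, 0.0) for f in features])
    log2_mu = (
        np.log2(base)[:, None]
        + LATENT_SD * z
        + donor_off[:, donor_of_sample]
        + lfc[:, None] * treated[None, :]
    )
    mu = np.power(2.0, log2_mu)

    alpha = config.nb_dispersion
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mu)
    counts = rng.negative_binomial(n_param, p_param)

    mat = pd.DataFrame(counts, index=pd.Index(features, name="feature_id"),
                       columns=samples)
    is_gene = classes == "protein_coding"
    gene_counts = mat.loc[is_gene.values]
    mirna_counts = mat.loc[(~is_gene).values]
    return gene_counts, mirna_counts, sheet, truth


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

ROOT_NAMES = ("immune_system", "signal_transduction", "metabolism")


@dataclass
class PathwayCollection:
    """Gene sets plus a parent-child hierarchy with designated roots."""

    sets: dict[str, set[str]]
    hierarchy: pd.DataFrame           # columns parent_id, child_id
    roots: pd.DataFrame               # columns pathway_id, root_name

    def write(self, outdir: str | Path, prefix: str = "pathways") -> None:
        outdir = Path(outdir)
        io.write_gmt(self.sets, outdir / f"{prefix}.gmt")
        io.write_tsv(self.hierarchy, outdir / f"{prefix}_hierarchy.tsv")
        io.write_tsv(self.roots, outdir / f"{prefix}_roots.tsv")

    @classmethod
    def read(cls, outdir: str | Path,
             prefix: str = "pathways") -> "PathwayCollection":
        outdir = Path(outdir)
        return cls(
            sets=io.read_gmt(outdir / f"{prefix}.gmt"),
            hierarchy=io.read_hierarchy(outdir / f"{prefix}_hierarchy.tsv"),
            roots=io.read_roots(outdir / f"{prefix}_roots.tsv"),
        )


def generate_pathways(
    config: SynthConfig, catalogue: pd.DataFrame | None = None
) -> PathwayCollection:
    """Pathway gene sets with a rooted parent-child hierarchy.

    Guarantees, by construction: every non-root pathway reaches >= 1 root;
    one pathway ("P_multi") has two parents under different roots; one
    pathway ("P_planted") contains the planted upregulated DE genes, for
    enrichment power checks.
    """
    rng = np.random.default_rng([config.seed, 404])
    genes = np.array(gene_ids(config.n_genes))

    root_rows = [(f"R_{name}", name) for name in ROOT_NAMES]
    root_ids = [r[0] for r in root_rows]

    size_lo = min(10, config.n_genes)
    size_hi = min(200, config.n_genes)

    n_pathways = max(6, config.n_genes // 12)
    sets: dict[str, set[str]] = {}
    hier_rows: list[tuple[str, str]] = []

    # roots carry the union of their children; fill at the end
    for rid in root_ids:
        sets[rid] = set()

    pids = [f"P{i:03d}" for i in range(1, n_pathways + 1)]
    for k, pid in enumerate(pids):
        size = int(rng.integers(size_lo, size_hi + 1))
        members = rng.choice(config.n_genes, size=size, replace=False)
        sets[pid] = set(genes[members])
        if k >= 2 and rng.random() < 0.3:
            parent = pids[int(rng.integers(0, k))]
        else:
            parent = root_ids[int(rng.integers(0, len(root_ids)))]
        hier_rows.append((parent, pid))

    # planted-DE pathway under the immune root (upregulated planted genes)
    de_map = _select_de_features(config)
    up = sorted(g for g, f in de_map.items() if g.startswith("G") and f > 0)
    filler = [g for g in genes if g not in up]
    need = max(0, size_lo - len(up))
    planted = set(up) | set(filler[:need])
    if planted:
        sets["P_planted"] = planted
        hier_rows.append((root_ids[0], "P_planted"))
        pids.append("P_planted")

    # multi-parent pathway under two different roots
    members = rng.choice(config.n_genes, size=size_lo, replace=False)
    sets["P_multi"] = set(genes[members])
    hier_rows.append((root_ids[1], "P_multi"))
    hier_rows.append((root_ids[2], "P_multi"))
    pids.append("P_multi")

    for parent, child in hier_rows:
        if parent in root_ids:
            sets[parent] |= sets[child]
    for rid in root_ids:
        if not sets[rid]:
            sets[rid] = set(genes[:size_lo])

    return PathwayCollection(
        sets=sets,
        hierarchy=pd.DataFrame(hier_rows, columns=["parent_id", "child_id"]),
        roots=pd.DataFrame(root_rows, columns=["pathway_id", "root_name"]),
    )


# ---------------------------------------------------------------------------
# miRNA-target evidence tables and triplexes
# ---------------------------------------------------------------------------

def generate_target_evidence(
    config: SynthConfig, catalogue: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Predicted and experimentally supported miRNA-target tables.

    All planted mirna_target edges are predicted; most have support in at
    least one of two experimental tables; a few decoy predictions lack any
    support, to exercise the intersection.
    """
    rng = np.random.default_rng([config.seed, 505])
    mt = catalogue[catalogue["type"] == "mirna_target"]
    pairs = list(zip(mt["source"], mt["target"]))

    genes = gene_ids(config.n_genes)
    mirnas = mirna_ids(config.n_mirnas)
    existing = set(pairs)
    decoys = []
    while len(decoys) < max(3, len(pairs) // 5):
        m = mirnas[int(rng.integers(0, config.n_mirnas))]
        g = genes[int(rng.integers(0, config.n_genes))]
        if (m, g) not in existing:
            existing.add((m, g))
            decoys.append((m, g))

    predicted = pd.DataFrame(pairs + decoys, columns=["mirna", "gene"])
    support = rng.random(len(pairs))
    exp_a = [p for p, u in zip(pairs, support) if u < 0.7]
    exp_b = [p for p, u in zip(pairs, support) if 0.5 < u < 0.95]
    experimental = {
        "assay_a": pd.DataFrame(exp_a, columns=["mirna", "gene"]),
        "assay_b": pd.DataFrame(exp_b, columns=["mirna", "gene"]),
    }
    return predicted, experimental


def generate_triplexes(config: SynthConfig) -> pd.DataFrame:
    """Triplex attribute table with known pass/fail composition.

    Thresholds downstream: equilibrium concentration >= 50 nM and minimum
    free energy <= -25 kcal/mol. The table mixes records passing both,
    failing only one, failing both, and exact-boundary records; the
    generator's own pass count is stored in ``df.attrs['n_pass_expected']``.
    """
    rng = np.random.default_rng([config.seed, 606])
    mirnas = mirna_ids(config.n_mirnas)
    genes = gene_ids(config.n_genes)

    n_records = max(24, 2 * config.n_mirnas)
    rows = []

    def draw(conc_pass: bool, mfe_pass: bool):
        m1, m2 = rng.choice(config.n_mirnas, size=2, replace=False)
        g = genes[int(rng.integers(0, config.n_genes))]
        conc = rng.uniform(50.0, 400.0) if conc_pass else rng.uniform(0.5, 49.9)
        mfe = rng.uniform(-60.0, -25.0) if mfe_pass else rng.uniform(-24.9, -5.0)
        rows.append((mirnas[m1], mirnas[m2], g, conc, mfe))

    quads = [(True, True), (True, False), (False, True), (False, False)]
    for k in range(n_records - 2):
        cp, mp = quads[k % 4]
        draw(cp, mp)
    # exact-boundary records: both thresholds inclusive -> passes; and one
    # failing only the MFE criterion at the concentration boundary
    rows.append((mirnas[0], mirnas[1 % config.n_mirnas],
                 genes[0], 50.0, -25.0))
    rows.append((mirnas[0], mirnas[1 % config.n_mirnas],
                 genes[min(1, config.n_genes - 1)], 50.0, -24.0))

    df = pd.DataFrame(
        rows, columns=["mirna1", "mirna2", "gene", "eq_conc", "mfe"]
    )
    df.attrs["n_pass_expected"] = int(
        ((df["eq_conc"] >= 50.0) & (df["mfe"] <= -25.0)).sum()
    )
    return df


# ---------------------------------------------------------------------------
# annotations and scored networks for prioritization properties
# ---------------------------------------------------------------------------

def generate_annotations(config: SynthConfig) -> pd.DataFrame:
    """Immune-category and TF flags for protein-coding genes."""
    rng = np.random.default_rng([config.seed, 707])
    genes = gene_ids(config.n_genes)
    cats = np.array(["cytokine", "chemokine", "tcr_signalling", "none"])
    cat = cats[rng.choice(4, size=config.n_genes, p=[0.1, 0.1, 0.1, 0.7])]
    is_tf = rng.random(config.n_genes) < 0.1
    return pd.DataFrame(
        {"feature_id": genes, "immune_category": cat, "is_TF": is_tf}
    )


def generate_priority_network(
    config: SynthConfig, kind: str = "mirna_hub"
):
    """A weighted, correlation-annotated network with a planted top node.

    ``kind='mirna_hub'``: the hub miRNA and its >= 20 targets carry elevated
    perturbation weights; every other node draws a small background weight.
    ``kind='gene_control'``: one protein-coding gene gets the maximum
    perturbation and dense strong-correlation connectivity, emulating an
    artificially introduced transcript as an internal positive control.

    Returns ``(graph, planted_id)`` where the graph is an undirected
    networkx graph with node attrs ``class``/``weight`` and edge attrs
    ``rho``/``length``, ready for scoring.
    """
    import networkx as nx

    catalogue = generate_interactions(config)
    rng = np.random.default_rng([config.seed, 808])
    classes = feature_classes(config)

    G = nx.Graph()
    for fid, cls in classes.items():
        G.add_node(fid, **{"class": cls})

    for row in catalogue.itertuples(index=False):
        mag = rng.uniform(0.3, 0.9)
        rho = -mag if row.type in ("inhibition", "mirna_target") else mag
        G.add_edge(row.source, row.target, rho=rho, length=1.0 - abs(rho),
                   type=row.type)

    # background perturbation: mostly weak evidence
    for fid in G.nodes:
        G.nodes[fid]["weight"] = float(rng.exponential(0.3))

    hub = mirna_ids(config.n_mirnas)[0]
    if kind == "mirna_hub":
        G.nodes[hub]["weight"] = float(rng.uniform(6.0, 9.0))
        mt = catalogue[(catalogue["type"] == "mirna_target")
                       & (catalogue["source"] == hub)]
        for g in mt["target"]:
            G.nodes[g]["weight"] = float(rng.uniform(3.0, 8.0))
        planted = hub
    elif kind == "gene_control":
        # emulates an artificially introduced, strongly induced transcript:
        # maximal perturbation inside a tightly co-regulated responder
        # module (dose-driven, hence near-uniform strong correlations)
        # that couples to the background transcriptome through one
        # moderate link
        genes = gene_ids(config.n_genes)
        n_module = max(HUB_MIN_TARGETS, config.n_genes // 8) + 1
        members = [genes[i] for i in
                   rng.choice(config.n_genes, size=n_module, replace=False)]
        planted = members[0]
        for m in members:
            for nb in list(G.neighbors(m)):
                G.remove_edge(m, nb)
        clique_rho = 0.95
        for a in range(n_module):
            for b in range(a + 1, n_module):
                G.add_edge(members[a], members[b], rho=clique_rho,
                           length=1.0 - clique_rho, type="activation")
        others = [g for g in genes if g not in members]
        bridge_to = others[int(rng.integers(0, len(others)))]
        G.add_edge(members[-1], bridge_to, rho=0.4, length=0.6,
                   type="activation")
        for m in members[1:]:
            G.nodes[m]["weight"] = float(rng.uniform(3.0, 8.0))
        weights = [d["weight"] for _, d in G.nodes(data=True)]
        G.nodes[planted]["weight"] = float(max(weights) * 2.0 + 10.0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return G, planted


# ---------------------------------------------------------------------------
# one-call materialization
# ---------------------------------------------------------------------------

def write_all(config: SynthConfig, outdir: str | Path) -> dict[str, str]:
    """Generate every pipeline input and write it under ``outdir``.

    Returns a mapping of artifact name -> file path (all TSV/GMT/JSON).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    gene_counts, mirna_counts, sheet, truth = generate_counts(config)
    collection = generate_pathways(config, truth.planted_network)
    predicted, experimental = generate_target_evidence(
        config, truth.planted_network
    )
    triplexes = generate_triplexes(config)
    annotations = generate_annotations(config)

    paths: dict[str, str] = {}

    def put(name: str, writer, *args) -> None:
        path = outdir / name
        writer(*args, path)
        paths[name.split(".")[0]] = str(path)

    put("gene_counts.tsv", io.write_counts, gene_counts)
    put("mirna_counts.tsv", io.write_counts, mirna_counts)
    put("sample_sheet.tsv", io.write_sample_sheet, sheet)
    put("interactions.tsv", io.write_interactions, truth.planted_network)
    put("predicted_targets.tsv", io.write_tsv, predicted)
    put("experimental_assay_a.tsv", io.write_tsv, experimental["assay_a"])
    put("experimental_assay_b.tsv", io.write_tsv, experimental["assay_b"])
    put("triplexes.tsv", io.write_tsv, triplexes)
    put("annotations.tsv", io.write_tsv, annotations)
    collection.write(outdir)
    paths["pathways"] = str(outdir / "pathways.gmt")
    io.write_json(
        {
            "config": dataclasses.asdict(config),
            "truth": truth.to_json_dict(),
            "triplex_n_pass_expected": triplexes.attrs["n_pass_expected"],
        },
        outdir / "ground_truth.json",
    )
    paths["ground_truth"] = str(outdir / "ground_truth.json")
    return paths
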