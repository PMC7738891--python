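"""Staged pipeline runner with a content-hashed run manifest.

Stages (in order): simulate, de, enrich, network, prioritize, cooperate,
report. Each stage reads the artifacts of earlier stages from the output
directory and writes its own as TSV; a missing upstream artifact raises a
``PipelineError`` naming the stage to run first. ``run_pipeline`` executes
any contiguous prefix and can resume, skipping stages whose outputs already
exist.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import cooperativity as coop_mod
from . import enrichment as enrich_mod
from . import io
from . import network as net_mod
from . import prioritize as prio_mod
from . import report as report_mod
from . import synth
from .de import run_de, significant

log = logging.getLogger(__name__)

STAGES = ["simulate", "de", "enrich", "network", "prioritize", "cooperate",
          "report"]

STAGE_OUTPUTS = {
    "simulate": ["gene_counts.tsv", "mirna_counts.tsv", "sample_sheet.tsv",
                 "interactions.tsv", "predicted_targets.tsv",
                 "experimental_assay_a.tsv", "experimental_assay_b.tsv",
                 "triplexes.tsv", "annotations.tsv", "pathways.gmt",
                 "pathways_hierarchy.tsv", "pathways_roots.tsv",
                 "ground_truth.json"],
    "de": ["de_genes.tsv", "de_mirnas.tsv", "norm_log.tsv"],
    "enrich": ["enrichment.tsv"],
    "network": ["edges_filtered.tsv", "networks/"],
    "prioritize": ["ranking.tsv", "score_weight_correlation.tsv"],
    "cooperate": ["cooperativity.tsv"],
    "report": ["targeting_profile.tsv", "landscape_immune.tsv",
               "candidates.tsv"],
}


class PipelineError(RuntimeError):
    pass


DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "rho_bar": 0.01,
    "bins": 25,
    "rho_threshold": -0.3,
    "pseudocount": 1.0,
    "min_count": 5,
    "synth": {},          # overrides for SynthConfig fields
}


def _merge_config(config: dict | None) -> dict:
    merged = {**DEFAULT_CONFIG, **(config or {})}
    merged["synth"] = {**DEFAULT_CONFIG["synth"],
                       **((config or {}).get("synth") or {})}
    return merged


def _require(outdir: Path, stage: str) -> None:
    for name in STAGE_OUTPUTS[stage]:
        if not (outdir / name).exists():
            raise PipelineError(
                f"missing artifact {name!r}: run stage {stage!r} first"
            )


def _outputs_exist(outdir: Path, stage: str) -> bool:
    return all((outdir / name).exists() for name in STAGE_OUTPUTS[stage])


def stage_simulate(config: dict, outdir: Path) -> dict:
    sc = synth.SynthConfig(seed=config["seed"], **config["synth"])
    synth.write_all(sc, outdir)
    return {"n_genes": sc.n_genes, "n_mirnas": sc.n_mirnas,
            "n_donors": sc.n_donors}


def stage_de(config: dict, outdir: Path) -> dict:
    _require(outdir, "simulate")
    sheet = io.read_sample_sheet(outdir / "sample_sheet.tsv")
    frames = {}
    norm_frames = []
    for kind in ("genes", "mirnas"):
        counts = io.read_counts(outdir / f"{kind[:-1]}_counts.tsv"
                                if kind == "genes"
                                else outdir / "mirna_counts.tsv")
        de, norm_log = run_de(
            counts, sheet, alpha=config["alpha"],
            pseudocount=config["pseudocount"], min_count=config["min_count"],
        )
        io.write_tsv(de, outdir / f"de_{kind}.tsv")
        frames[kind] = de
        norm_frames.append(norm_log)
    norm_all = pd.concat(norm_frames)
    io.write_tsv(norm_all, outdir / "norm_log.tsv", index=True)
    return {
        "n_sig_genes": int(len(significant(frames["genes"], config["alpha"]))),
        "n_sig_mirnas": int(len(significant(frames["mirnas"],
                                            config["alpha"]))),
    }


def stage_enrich(config: dict, outdir: Path) -> dict:
    _require(outdir, "de")
    _require(outdir, "simulate")
    de_genes = io.read_tsv(outdir / "de_genes.tsv")
    collection = synth.PathwayCollection.read(outdir)
    enr = enrich_mod.enrich_all(
        de_genes, collection, alpha=config["alpha"],
        rho_bar=config["rho_bar"],
    )
    io.write_tsv(enr, outdir / "enrichment.tsv")
    return {"n_pathways_tested": int(len(enr)),
            "n_significant": int(enr["significant"].sum()) if len(enr) else 0}


def stage_network(config: dict, outdir: Path) -> dict:
    _require(outdir, "de")
    _require(outdir, "simulate")
    de_genes = io.read_tsv(outdir / "de_genes.tsv")
    de_mirnas = io.read_tsv(outdir / "de_mirnas.tsv")
    sheet = io.read_sample_sheet(outdir / "sample_sheet.tsv")
    norm_log = io.read_tsv(outdir / "norm_log.tsv", index_col="feature_id")
    catalogue = io.read_interactions(outdir / "interactions.tsv")
    predicted = io.read_tsv(outdir / "predicted_targets.tsv")
    experimental = {
        "assay_a": io.read_tsv(outdir / "experimental_assay_a.tsv"),
        "assay_b": io.read_tsv(outdir / "experimental_assay_b.tsv"),
    }
    annotations = io.read_tsv(outdir / "annotations.tsv")
    collection = synth.PathwayCollection.read(outdir)

    mirna_edges = net_mod.intersect_mirna_targets(predicted, experimental)
    merged = net_mod.merge_catalogue(
        catalogue[catalogue["type"] != "mirna_target"], mirna_edges
    )
    with_rho = net_mod.edge_correlations(merged, norm_log, sheet)
    surviving = net_mod.filter_by_sign(with_rho)
    io.write_tsv(surviving, outdir / "edges_filtered.tsv")

    root_map = enrich_mod.validate_collection(collection)
    networks = net_mod.build_all_category_networks(
        collection, root_map, surviving, de_genes, de_mirnas,
        annotations=annotations, mirna_alpha=config["alpha"],
    )
    net_dir = outdir / "networks"
    net_dir.mkdir(exist_ok=True)
    for cat, G in networks.items():
        nodes, edges = net_mod.network_to_tables(G)
        io.write_tsv(nodes, net_dir / f"{cat}_nodes.tsv")
        io.write_tsv(edges, net_dir / f"{cat}_edges.tsv")
    return {
        "n_edges_surviving": int(len(surviving)),
        "network_sizes": {c: G.number_of_nodes()
                          for c, G in networks.items()},
    }


def _load_networks(outdir: Path) -> dict:
    net_dir = outdir / "networks"
    networks = {}
    for node_file in sorted(net_dir.glob("*_nodes.tsv")):
        cat = node_file.name[: -len("_nodes.tsv")]
        nodes = io.read_tsv(node_file)
        edges = io.read_tsv(net_dir / f"{cat}_edges.tsv")
        networks[cat] = net_mod.network_from_tables(nodes, edges, category=cat)
    return networks


def stage_prioritize(config: dict, outdir: Path) -> dict:
    _require(outdir, "network")
    networks = _load_networks(outdir)
    ranking, corr = prio_mod.prioritize_networks(
        networks, bins=config["bins"]
    )
    io.write_tsv(ranking, outdir / "ranking.tsv")
    io.write_tsv(corr, outdir / "score_weight_correlation.tsv")
    return {"n_ranked": int(len(ranking))}


def stage_cooperate(config: dict, outdir: Path) -> dict:
    _require(outdir, "de")
    _require(outdir, "network")
    de_mirnas = io.read_tsv(outdir / "de_mirnas.tsv")
    sig_mirnas = set(significant(de_mirnas, config["alpha"])["feature_id"])
    triplexes = io.read_triplexes(outdir / "triplexes.tsv")
    candidates = coop_mod.candidate_pairs(sig_mirnas, triplexes)
    flagged = coop_mod.filter_triplexes(candidates)
    networks = _load_networks(outdir)
    frames = [
        coop_mod.attach_cooperativity(G, flagged)
        for G in networks.values()
    ]
    coop = (
        pd.concat(frames, ignore_index=True).drop_duplicates(
            ignore_index=True)
        if frames else pd.DataFrame()
    )
    io.write_tsv(coop, outdir / "cooperativity.tsv")
    return {"n_passing": int(flagged["passes"].sum()) if len(flagged) else 0,
            "n_cooperative_edges": int(len(coop))}


def stage_report(config: dict, outdir: Path) -> dict:
    for st in ("simulate", "de", "enrich", "network", "prioritize",
               "cooperate"):
        _require(outdir, st)
    collection = synth.PathwayCollection.read(outdir)
    root_map = enrich_mod.validate_collection(collection)
    networks = _load_networks(outdir)
    enr = io.read_tsv(outdir / "enrichment.tsv")
    de_genes = io.read_tsv(outdir / "de_genes.tsv")
    ranking = io.read_tsv(outdir / "ranking.tsv")
    coop = io.read_tsv(outdir / "cooperativity.tsv")

    profile = report_mod.targeting_profile(networks, enr, collection,
                                           root_map)
    io.write_tsv(profile, outdir / "targeting_profile.tsv")

    immune_cat = "immune_system"
    G = networks.get(immune_cat)
    landscape = (
        report_mod.landscape_matrix(
            G, collection, root_map, enr, de_genes, ranking,
            rho_max=config["rho_threshold"],
        )
        if G is not None
        else pd.DataFrame()
    )
    io.write_tsv(landscape, outdir / "landscape_immune.tsv")

    candidates = report_mod.candidate_table(networks, coop)
    io.write_tsv(candidates, outdir / "candidates.tsv")
    return {"n_profile_rows": int(len(profile)),
            "n_candidates": int(len(candidates))}


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "de": stage_de,
    "enrich": stage_enrich,
    "network": stage_network,
    "prioritize": stage_prioritize,
    "cooperate": stage_cooperate,
    "report": stage_report,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(
    config: dict | None,
    outdir: str | Path,
    stages: list[str] | None = None,
    resume: bool = False,
) -> dict:
    """Run the pipeline (or a prefix of it) and write a manifest.

    With ``resume=True``, stages whose outputs already exist are skipped,
    so deleting one stage's outputs re-runs it and everything after it.
    The manifest records the seed, a config hash, library versions, each
    stage's summary counts, and a sha256 for every output file.
    """
    import networkx
    import numpy
    import scipy

    from . import __version__

    config = _merge_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise PipelineError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in stages]

    stage_info: dict[str, dict] = {}
    for stage in stages:
        if resume and _outputs_exist(outdir, stage):
            log.info("stage %s: outputs present, skipping", stage)
            stage_info[stage] = {"skipped": True}
            continue
        log.info("stage %s: running", stage)
        stage_info[stage] = STAGE_FUNCS[stage](config, outdir)

    files = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json" \
                and p.suffix != ".log":
            files[str(p.relative_to(outdir))] = _sha256(p)

    manifest = {
        "seed": config["seed"],
        "config_hash": _config_hash(config),
        "config": config,
        "versions": {
            "dcmir": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "networkx": networkx.__version__,
        },
        "stages": stage_info,
        "files": files,
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
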