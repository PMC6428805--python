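"""End-to-end orchestration: construct -> giant component -> metrics ->
backbone -> second extension -> annotation -> reports.

A single YAML/dict config drives the run.  Each *variant* names an
evidence-channel set (by default the high-confidence pair
{experimental, database} and the same plus coexpression), and every
variant produces the full artifact bundle.  All outputs are deterministic
for a fixed config + seed: node iteration is lexicographic, the run log
carries no timestamps, and every artifact directory embeds the config
hash and seed in ``manifest.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Sequence

import networkx as nx
import pandas as pd
import yaml

from . import io as graph_io
from .annotate import annotate, attach_membership_attribute, overlap_table
from .backbone import Backbone, compare_backbones, extract_backbone, second_extension
from .construct import (
    DEFAULT_PRIOR,
    DEFAULT_THRESHOLD,
    build_network,
    edge_count_enrichment,
    filter_interactions,
    giant_component,
)
from .errors import ConfigError, DataError, PPINetError
from .topology import GlobalMetrics, compute_node_metrics, global_metrics, small_world_summary

logger = logging.getLogger(__name__)

DEFAULT_VARIANTS = (
    {"name": "core", "channels": ["experimental", "database"]},
    {"name": "coexpression", "channels": ["experimental", "database", "coexpression"]},
)

_KNOWN_KEYS = {
    "interactions", "dialect", "seed_list", "gene_sets", "variants",
    "score_threshold", "combine_prior", "fraction", "seed", "null_density",
    "smallworld_replicates", "strip_species_prefix", "out_dir",
}


def load_config(source: str | Path | dict[str, Any]) -> dict[str, Any]:
    """Load and validate a pipeline config from YAML or a dict."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {source} does not hold a mapping")
    else:
        raw = dict(source)
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    config = {
        "dialect": "string_tsv",
        "variants": [dict(v) for v in DEFAULT_VARIANTS],
        "score_threshold": DEFAULT_THRESHOLD,
        "combine_prior": DEFAULT_PRIOR,
        "fraction": 0.10,
        "seed": 0,
        "null_density": None,
        "smallworld_replicates": 0,
        "strip_species_prefix": False,
        "seed_list": None,
        "gene_sets": None,
        **raw,
    }
    if "interactions" not in config:
        raise ConfigError("config must name an 'interactions' table")
    threshold = config["score_threshold"]
    if not isinstance(threshold, (int, float)) or not 0.0 < threshold <= 1.0:
        raise ConfigError(f"score_threshold must be in (0, 1]: {threshold}")
    if not 0.0 < config["fraction"] <= 1.0:
        raise ConfigError(f"fraction must be in (0, 1]: {config['fraction']}")
    if not 0.0 <= config["combine_prior"] < 1.0:
        raise ConfigError(f"combine_prior must be in [0, 1): {config['combine_prior']}")
    if not config["variants"]:
        raise ConfigError("at least one variant is required")
    for variant in config["variants"]:
        if "name" not in variant or "channels" not in variant or not variant["channels"]:
            raise ConfigError(f"variant needs 'name' and non-empty 'channels': {variant}")
    return config


def config_hash(config: dict[str, Any]) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class VariantReport:
    """Everything computed for one channel-set variant."""

    name: str
    channels: list[str]
    network: nx.Graph
    giant: nx.Graph
    metrics: list
    global_giant: GlobalMetrics
    backbone: Backbone
    extension: nx.Graph
    global_extension: GlobalMetrics | None
    annotations: dict[str, list[str]] | None


@dataclass
class PipelineResult:
    out_dir: Path | None
    config: dict[str, Any]
    variants: dict[str, VariantReport]
    summary: pd.DataFrame
    comparison: Any  # BackboneComparison | None


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PPINetError as err:
        raise type(err)(f"stage {name!r} failed: {err}") from err


def _globals_of(graph: nx.Graph) -> GlobalMetrics:
    # extension networks may be disconnected; summarise their giant component
    if graph.number_of_edges() == 0:
        raise DataError("network has no edges")
    target = graph if nx.is_connected(graph) else giant_component(graph)
    return global_metrics(target)


def summarize_variants(rows: Sequence[tuple[str, GlobalMetrics]]) -> pd.DataFrame:
    """Machine twin of a global-topology comparison table, one row per network."""
    records = [
        {
            "network": name,
            "n_nodes": gm.n_nodes,
            "n_edges": gm.n_edges,
            "avg_degree": round(gm.avg_degree, 2),
            "sd_degree": round(gm.sd_degree, 2),
            "diameter": gm.diameter,
            "radius": gm.radius,
            "mspl": round(gm.mspl, 2),
            "avg_clustering": round(gm.avg_clustering, 3),
        }
        for name, gm in rows
    ]
    return pd.DataFrame(records)


def run_pipeline(
    config: str | Path | dict[str, Any],
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis for every variant and write the report bundle."""
    config = load_config(config)
    out = Path(out_dir) if out_dir is not None else (
        Path(config["out_dir"]) if config.get("out_dir") else None
    )
    log_handler = None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(out / "run.log", mode="w")
        # no timestamps: the bundle must be byte-identical across reruns
        log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logging.getLogger("ppinet").addHandler(log_handler)
        logging.getLogger("ppinet").setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        if log_handler is not None:
            logging.getLogger("ppinet").removeHandler(log_handler)
            log_handler.close()


def _run(config: dict[str, Any], out: Path | None) -> PipelineResult:
    interactions = _stage(
        "read_interactions",
        graph_io.read_interactions,
        config["interactions"],
        dialect=config["dialect"],
        strip_species_prefix=config["strip_species_prefix"],
    )
    gene_sets = (
        _stage("read_gene_sets", graph_io.read_gene_sets, config["gene_sets"])
        if config["gene_sets"]
        else None
    )
    threshold = config["score_threshold"]
    prior = config["combine_prior"]

    reports: dict[str, VariantReport] = {}
    summary_rows: list[tuple[str, GlobalMetrics]] = []
    for variant in config["variants"]:
        name, channels = variant["name"], list(variant["channels"])
        kept = _stage(f"filter[{name}]", filter_interactions,
                      interactions, channels, threshold, prior)
        network = _stage(f"build[{name}]", build_network, kept)
        giant = _stage(f"giant_component[{name}]", giant_component, network)
        logger.info("variant %s: %d/%d interactions kept; giant component %d/%d nodes",
                    name, len(kept), len(interactions),
                    giant.number_of_nodes(), network.number_of_nodes())
        metrics = _stage(f"metrics[{name}]", compute_node_metrics, giant)
        gm = _stage(f"global_metrics[{name}]", global_metrics, giant)
        bb = _stage(f"backbone[{name}]", extract_backbone, giant, metrics,
                    config["fraction"])
        ext = _stage(f"second_extension[{name}]", second_extension,
                     bb.members, interactions, channels, threshold, prior)
        gm_ext = _globals_of(ext) if ext.number_of_edges() else None
        annotations = annotate(ext, gene_sets) if gene_sets else None
        reports[name] = VariantReport(
            name=name, channels=channels, network=network, giant=giant,
            metrics=metrics, global_giant=gm, backbone=bb, extension=ext,
            global_extension=gm_ext, annotations=annotations,
        )
        summary_rows.append((f"{name}/giant", gm))
        if gm_ext is not None:
            summary_rows.append((f"{name}/extension", gm_ext))
        if out is not None:
            _write_variant(out, reports[name], config, gene_sets)

    summary = summarize_variants(summary_rows)
    comparison = None
    if len(reports) >= 2:
        first, second = list(reports.values())[:2]
        comparison = compare_backbones(first.backbone, second.backbone)

    if out is not None:
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        if comparison is not None:
            (out / "backbone_comparison.json").write_text(
                json.dumps(comparison.to_dict(), indent=1, sort_keys=True) + "\n"
            )
        manifest = {
            "config": {k: str(v) if isinstance(v, Path) else v for k, v in config.items()},
            "config_hash": config_hash(config),
            "seed": config["seed"],
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
        )
    return PipelineResult(out_dir=out, config=config, variants=reports,
                          summary=summary, comparison=comparison)


def _write_variant(out: Path, report: VariantReport, config: dict[str, Any],
                   gene_sets) -> None:
    name = report.name
    graph_io.write_graph(report.giant, out / f"network_{name}.graphml", "graphml")
    graph_io.write_graph(report.giant, out / f"network_{name}_edges.tsv", "edge_tsv")
    graph_io.write_node_metrics(report.metrics, out / f"node_metrics_{name}.tsv")

    gm_payload = {"giant": asdict(report.global_giant)}
    if report.global_extension is not None:
        gm_payload["extension"] = asdict(report.global_extension)
    if config["null_density"] is not None:
        enr = edge_count_enrichment(report.giant, config["null_density"],
                                    rng_seed=config["seed"])
        gm_payload["edge_enrichment"] = asdict(enr)
    if config["smallworld_replicates"] >= 10:
        sw = small_world_summary(report.giant, config["smallworld_replicates"],
                                 rng_seed=config["seed"])
        gm_payload["small_world"] = asdict(sw)
    (out / f"global_metrics_{name}.json").write_text(
        json.dumps(gm_payload, indent=1, sort_keys=True) + "\n"
    )

    by_node = {m.node: m for m in report.metrics}
    rows = [
        {"node": v, "degree": by_node[v].degree,
         "betweenness": round(by_node[v].betweenness, 9),
         "role": report.backbone.roles[v]}
        for v in sorted(report.backbone.members,
                        key=lambda v: (-by_node[v].degree, v))
    ]
    pd.DataFrame(rows).to_csv(out / f"backbone_{name}.tsv", sep="\t", index=False)

    extension = report.extension
    if gene_sets:
        extension = attach_membership_attribute(extension.copy(), gene_sets)
    if extension.number_of_nodes():
        graph_io.write_graph(extension, out / f"extension_{name}.graphml", "graphml")
        graph_io.write_graph(extension, out / f"extension_{name}_edges.tsv", "edge_tsv")
    if report.annotations is not None:
        overlap_table(report.annotations).to_csv(
            out / f"pathway_overlap_{name}.tsv", sep="\t", index=False
        )
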