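"""End-to-end orchestration: one config, seeded stages, reproducible artifacts.

A run is described by a single YAML configuration (see :func:`validate_config`)
naming, per receptor, either an input phosphosite table or a synthetic
generation block, plus the comparison design, calling thresholds, a motif
library and the network-analysis settings. Stages execute in order —
normalize -> presence filter -> regulation calls -> set summaries -> motif
counts and percentage ratios -> network build -> centralities -> hubs ->
null model — and every artifact is written under the output directory
together with a manifest (config hash, seed, per-stage counts). Rerunning
with an identical config and seed reproduces identical outputs; per-stage
seeds are derived deterministically from the global seed by hashing the
stage name, so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import differential, io, motifs as motifs_mod, network as network_mod, simulate
from .errors import ConfigError, PipelineError

logger = logging.getLogger("phosphonet")

ALL_STAGES = ("simulate", "differential", "motifs", "network")


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed in [0, 2^31) from the global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class ReceptorSource:
    name: str
    path: str | None = None
    ground_truth: str | None = None
    synthetic: dict | None = None


@dataclass
class NetworkConfig:
    enabled: bool = True
    edges_path: str | None = None
    edges_synthetic: dict = field(default_factory=dict)
    experiments_min: float = 0.15
    databases_min: float = 0.35
    mode: str = network_mod.MODE_PPI
    n_random: int = 100
    n_swaps: int | None = None


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    log_level: str
    thresholds: differential.Thresholds
    comparisons: list
    receptors: list
    motifs_path: str | None
    network: NetworkConfig
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        # hash the scientific content only, not where it is written or logged
        content = {k: v for k, v in self.raw.items() if k not in ("output_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(content, sort_keys=True, default=str).encode()
        ).hexdigest()


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


_DEFAULT_COMPARISONS = [
    {"name": "stim_vs_ctrl", "numerator_condition": "stim", "denominator_condition": "ctrl"}
]


def parse_config(data: dict, base_dir: Path | None = None) -> RunConfig:
    """Build a validated RunConfig from a parsed mapping; unknown keys rejected."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    base_dir = Path(base_dir) if base_dir else Path.cwd()
    _check_keys(
        data,
        {
            "seed",
            "output_dir",
            "log_level",
            "thresholds",
            "comparisons",
            "receptors",
            "motifs",
            "network",
        },
        "configuration root",
    )
    thresholds = differential.Thresholds(**(data.get("thresholds") or {}))
    comparisons = [
        differential.ComparisonDesign(**c) for c in data.get("comparisons", _DEFAULT_COMPARISONS)
    ]
    if not comparisons:
        raise ConfigError("at least one comparison is required")

    receptors_raw = data.get("receptors")
    if not receptors_raw:
        raise ConfigError("configuration must define at least one receptor under 'receptors'")
    receptors = []
    for name, block in receptors_raw.items():
        block = block or {}
        _check_keys(block, {"path", "ground_truth", "synthetic"}, f"receptors.{name}")
        has_path = "path" in block
        has_synthetic = "synthetic" in block
        if has_path == has_synthetic:
            raise ConfigError(
                f"receptors.{name}: exactly one of 'path' or 'synthetic' is required"
            )
        path = block.get("path")
        if path is not None:
            path = str(base_dir / path)
            if not Path(path).exists():
                raise ConfigError(f"receptors.{name}: input file not found: {path}")
        truth_path = block.get("ground_truth")
        if truth_path is not None:
            truth_path = str(base_dir / truth_path)
            if not Path(truth_path).exists():
                raise ConfigError(f"receptors.{name}: ground truth file not found: {truth_path}")
        synthetic = block.get("synthetic")
        if synthetic is not None:
            known = set(simulate.SimulationConfig.__dataclass_fields__) - {"seed"}
            _check_keys(synthetic, known, f"receptors.{name}.synthetic")
        receptors.append(
            ReceptorSource(name=name, path=path, ground_truth=truth_path, synthetic=synthetic)
        )

    motifs_block = data.get("motifs") or {}
    _check_keys(motifs_block, {"path", "builtin"}, "motifs")
    motifs_path = motifs_block.get("path")
    if motifs_path is not None:
        motifs_path = str(base_dir / motifs_path)
        if not Path(motifs_path).exists():
            raise ConfigError(f"motifs.path: file not found: {motifs_path}")

    net_block = data.get("network") or {}
    _check_keys(
        net_block,
        {
            "enabled",
            "edges",
            "experiments_min",
            "databases_min",
            "mode",
            "n_random",
            "n_swaps",
        },
        "network",
    )
    edges_block = net_block.get("edges") or {}
    _check_keys(edges_block, {"path", "synthetic"}, "network.edges")
    edges_synth = edges_block.get("synthetic") or {}
    # the node universe, seed and directedness come from the run itself
    _check_keys(
        edges_synth,
        {"model", "model_params", "n_planted_connectors"},
        "network.edges.synthetic",
    )
    edges_path = edges_block.get("path")
    if edges_path is not None:
        edges_path = str(base_dir / edges_path)
        if not Path(edges_path).exists():
            raise ConfigError(f"network.edges.path: file not found: {edges_path}")
    network = NetworkConfig(
        enabled=bool(net_block.get("enabled", True)),
        edges_path=edges_path,
        edges_synthetic=edges_synth,
        experiments_min=float(net_block.get("experiments_min", 0.15)),
        databases_min=float(net_block.get("databases_min", 0.35)),
        mode=str(net_block.get("mode", network_mod.MODE_PPI)),
        n_random=int(net_block.get("n_random", 100)),
        n_swaps=net_block.get("n_swaps"),
    )

    return RunConfig(
        seed=int(data.get("seed", 0)),
        output_dir=str(base_dir / data.get("output_dir", "phosphonet_out")),
        log_level=str(data.get("log_level", "INFO")),
        thresholds=thresholds,
        comparisons=comparisons,
        receptors=receptors,
        motifs_path=motifs_path,
        network=network,
        raw=data,
    )


def validate_config(path) -> RunConfig:
    """Parse, default and validate a YAML run configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    return parse_config(data, base_dir=path.parent)


@dataclass
class RunReport:
    output_dir: str
    manifest: dict


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, na_rep="", float_format="%.17g")


def _confusion(truth_labels: dict, site_calls: pd.DataFrame) -> dict:
    out: dict = {}
    for comparison, group in site_calls.groupby("comparison"):
        counts: dict = {}
        for _, row in group.iterrows():
            true = truth_labels.get(row["site_id"], "unknown")
            counts[f"{true}->{row['label']}"] = counts.get(f"{true}->{row['label']}", 0) + 1
        out[str(comparison)] = dict(sorted(counts.items()))
    return out


def run_pipeline(config: RunConfig, stages=ALL_STAGES) -> RunReport:
    """Execute the requested stages and write all artifacts plus a manifest."""
    stages = tuple(stages)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "stages": list(stages),
        "thresholds": vars(config.thresholds).copy(),
        "counts": {},
        "artifacts": [],
    }

    def record(path: Path) -> None:
        manifest["artifacts"].append(path.name)

    # --- stage: simulate / load ------------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    truths: dict[str, simulate.GroundTruth | None] = {}
    try:
        for receptor in config.receptors:
            if receptor.synthetic is not None:
                sim_config = simulate.SimulationConfig(
                    **receptor.synthetic, seed=derive_seed(config.seed, f"phospho:{receptor.name}")
                )
                table, truth = simulate.generate_phosphosite_table(sim_config)
                path = out / f"{receptor.name}.phosphosites.tsv"
                io.write_phosphosite_table(table, path)
                record(path)
                truth_path = out / f"{receptor.name}.ground_truth.json"
                io.write_ground_truth(truth, truth_path)
                record(truth_path)
            else:
                table = io.read_phosphosite_table(receptor.path)
                truth = (
                    io.read_ground_truth(receptor.ground_truth) if receptor.ground_truth else None
                )
            tables[receptor.name] = table
            truths[receptor.name] = truth
            manifest["counts"][f"{receptor.name}.n_sites"] = int(len(table))
    except ConfigError as exc:
        raise PipelineError("simulate", str(exc)) from exc
    logger.info("loaded %d receptor table(s)", len(tables))
    if set(stages) <= {"simulate"}:
        _finalize_manifest(manifest, out)
        return RunReport(output_dir=str(out), manifest=manifest)

    # --- stage: differential ---------------------------------------------------
    site_calls: dict[str, pd.DataFrame] = {}
    protein_calls: dict[str, pd.DataFrame] = {}
    if "differential" in stages or "motifs" in stages or "network" in stages:
        try:
            for name, table in tables.items():
                normalized = differential.normalize_ratios(table)
                path = out / f"{name}.normalized.tsv"
                io.write_phosphosite_table(normalized, path)
                record(path)
                sites, proteins = differential.call_sites_and_proteins(
                    normalized, config.comparisons, config.thresholds
                )
                site_calls[name] = sites
                protein_calls[name] = proteins
                _write_tsv(sites, out / f"{name}.site_calls.tsv")
                record(out / f"{name}.site_calls.tsv")
                _write_tsv(proteins, out / f"{name}.protein_calls.tsv")
                record(out / f"{name}.protein_calls.tsv")
                for comparison, group in sites.groupby("comparison"):
                    for label in (
                        differential.LABEL_UP,
                        differential.LABEL_DOWN,
                        differential.LABEL_UNCHANGED,
                        differential.LABEL_NOT_QUANTIFIED,
                    ):
                        manifest["counts"][f"{name}.{comparison}.{label}"] = int(
                            (group["label"] == label).sum()
                        )
                truth = truths[name]
                if truth is not None and truth.site_labels:
                    manifest.setdefault("confusion", {})[name] = _confusion(
                        truth.site_labels, sites
                    )
            if len(site_calls) == 2:
                (name_a, calls_a), (name_b, calls_b) = site_calls.items()
                overlap, kinetics = differential.summarize_sets(
                    calls_a, calls_b, name_a, name_b, id_column="site_id"
                )
                _write_tsv(overlap, out / "overlap_sites.tsv")
                record(out / "overlap_sites.tsv")
                p_overlap, p_kinetics = differential.summarize_sets(
                    protein_calls[name_a],
                    protein_calls[name_b],
                    name_a,
                    name_b,
                    id_column="protein_id",
                )
                _write_tsv(p_overlap, out / "overlap_proteins.tsv")
                record(out / "overlap_proteins.tsv")
                _write_tsv(
                    pd.concat([kinetics, p_kinetics.assign(level="protein")], ignore_index=True),
                    out / "kinetics.tsv",
                )
                record(out / "kinetics.tsv")
        except ConfigError as exc:
            raise PipelineError("differential", str(exc)) from exc
        logger.info("regulation calls complete for %s", sorted(site_calls))

    # --- stage: motifs ---------------------------------------------------------
    if "motifs" in stages:
        try:
            library = (
                io.read_motif_library(config.motifs_path)
                if config.motifs_path
                else motifs_mod.default_motif_library()
            )
            count_tables = {}
            for name, sites in site_calls.items():
                windows_by_group: dict = {}
                window_of = dict(
                    zip(tables[name]["site_id"], tables[name]["sequence_window"])
                )
                for comparison in config.comparisons:
                    mask = (sites["comparison"] == comparison.name) & sites["label"].isin(
                        [differential.LABEL_UP, differential.LABEL_DOWN]
                    )
                    windows_by_group[comparison.name] = [
                        window_of[s] for s in sites.loc[mask, "site_id"]
                    ]
                count_tables[name] = motifs_mod.count_motifs(
                    windows_by_group, library, receptor=name
                )
            counts_frame = pd.concat(
                [t.to_frame() for t in count_tables.values()], ignore_index=True
            )
            _write_tsv(counts_frame, out / "motif_counts.tsv")
            record(out / "motif_counts.tsv")
            if len(count_tables) == 2:
                (table_a, table_b) = count_tables.values()
                shared = [
                    g
                    for g in table_a.groups
                    if g in set(table_b.groups) and table_a.total(g) > 0 and table_b.total(g) > 0
                ]
                if shared:
                    trimmed_a = motifs_mod.MotifCountTable(
                        receptor=table_a.receptor,
                        counts=table_a.counts,
                        totals=table_a.totals,
                        kinases=table_a.kinases,
                        groups=tuple(shared),
                    )
                    trimmed_b = motifs_mod.MotifCountTable(
                        receptor=table_b.receptor,
                        counts=table_b.counts,
                        totals=table_b.totals,
                        kinases=table_b.kinases,
                        groups=tuple(shared),
                    )
                    ratios = motifs_mod.percentage_ratio_table(trimmed_a, trimmed_b)
                    _write_tsv(ratios, out / "motif_percentage_ratios.tsv")
                    record(out / "motif_percentage_ratios.tsv")
                else:
                    logger.warning("no comparison has motif attributions in both receptors")
        except ConfigError as exc:
            raise PipelineError("motifs", str(exc)) from exc

    # --- stage: network --------------------------------------------------------
    if "network" in stages and config.network.enabled:
        try:
            for name, proteins in protein_calls.items():
                dpps = sorted(proteins.loc[proteins["regulated"], "protein_id"].unique())
                manifest["counts"][f"{name}.n_dpps"] = len(dpps)
                if not dpps:
                    logger.warning("receptor %s has no DPPs; skipping network stage", name)
                    continue
                if config.network.edges_path:
                    edges = io.read_edge_table(config.network.edges_path)
                else:
                    universe = sorted(tables[name]["protein_id"].unique())
                    synth = dict(config.network.edges_synthetic)
                    synth.setdefault("model", "scale_free")
                    edges, net_truth = simulate.generate_network(
                        n_nodes=len(universe),
                        node_names=universe,
                        seed=derive_seed(config.seed, f"network:{name}"),
                        signaling=config.network.mode == network_mod.MODE_SIGNALING,
                        **synth,
                    )
                    edge_path = out / f"{name}.edges.tsv"
                    io.write_edge_table(edges, edge_path)
                    record(edge_path)
                kept = network_mod.filter_edges(
                    edges, config.network.experiments_min, config.network.databases_min
                )
                annotations = {
                    row["protein_id"]: row["directions"]
                    for _, row in proteins.iterrows()
                    if row["regulated"]
                }
                model = network_mod.build_network(
                    dpps, kept, mode=config.network.mode, annotations=annotations
                )
                manifest["counts"][f"{name}.network_nodes"] = model.n_nodes
                manifest["counts"][f"{name}.network_edges"] = model.n_edges
                profiles = network_mod.compute_centralities(model)
                hubs = network_mod.select_hubs(profiles)
                profiles = profiles.assign(hub=[v in hubs for v in profiles.index])
                null = network_mod.null_distribution(
                    model,
                    n_random=config.network.n_random,
                    n_swaps=config.network.n_swaps,
                    seed=derive_seed(config.seed, f"null:{name}"),
                )
                profiles = profiles.join(
                    null.node_stats[["null_mean", "null_sd", "empirical_p"]]
                )
                _write_tsv(profiles, out / f"{name}.centralities.tsv", index=True)
                record(out / f"{name}.centralities.tsv")
                hub_frame = profiles.loc[sorted(hubs)].sort_values(
                    "betweenness", ascending=False
                )
                _write_tsv(hub_frame, out / f"{name}.hubs.tsv", index=True)
                record(out / f"{name}.hubs.tsv")
                _write_tsv(null.replicate_table, out / f"{name}.null_betweenness.tsv")
                record(out / f"{name}.null_betweenness.tsv")
                manifest["counts"][f"{name}.n_hubs"] = len(hubs)
                _export_graph(model, out / f"{name}.network", record)
        except ConfigError as exc:
            raise PipelineError("network", str(exc)) from exc

    _finalize_manifest(manifest, out)
    return RunReport(output_dir=str(out), manifest=manifest)


def _export_graph(model: network_mod.NetworkModel, stem: Path, record) -> None:
    graphml = stem.parent / (stem.name + ".graphml")
    nx.write_graphml(model.graph, graphml)
    record(graphml)
    sif = stem.parent / (stem.name + ".sif")
    lines = []
    seen = set()
    for a, b, attrs in model.graph.edges(data=True):
        relation = attrs.get("relation") or "pp"
        key = (a, relation, b) if model.graph.is_directed() else (min(a, b), relation, max(a, b))
        if key in seen:
            continue
        seen.add(key)
        lines.append("\t".join(key))
    for node in model.graph.nodes():
        if model.graph.degree(node) == 0:
            lines.append(node)
    sif.write_text("\n".join(sorted(lines)) + "\n")
    record(sif)


def _finalize_manifest(manifest: dict, out: Path) -> None:
    manifest["artifacts"] = sorted(set(manifest["artifacts"]))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
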