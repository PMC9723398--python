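"""Synthetic SILAC phosphoproteomics tables and interaction networks with ground truth.

Every downstream stage of the pipeline is testable against data generated
here: phosphosite tables with a planted fraction of up/down-regulated sites
under multiplicative lognormal ratio noise, 13-mer sequence windows with
kinase consensus motifs planted into regulated sites, and interaction
networks in which designated connector nodes bridge otherwise unconnected
communities (so their betweenness provably exceeds the graph mean).

Generation is fully seeded and deterministic: the same configuration and
seed reproduce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .motifs import (
    AMINO_ACIDS,
    CENTER_INDEX,
    PADDING,
    PHOSPHOACCEPTORS,
    WINDOW_LENGTH,
    MotifDefinition,
    default_motif_library,
    match_motif,
)
from .network import InteractionEdge

_AA_LIST = sorted(AMINO_ACIDS)
_STY_LIST = sorted(PHOSPHOACCEPTORS)


@dataclass
class SimulationConfig:
    """Conditions for one synthetic phosphosite table.

    ``conditions`` labels the SILAC ratio column groups; conditions in
    ``affected_conditions`` (default: all but the first) carry the planted
    regulation effect, while the remaining conditions center on ratio 1, so a
    comparison of an affected versus the reference condition recovers the
    planted fold change. Noise is multiplicative lognormal (normal on the
    log2 scale with standard deviation ``noise_sigma``); replicate
    measurements drop out independently with probability ``missing_rate``.
    """

    n_sites: int = 200
    n_proteins: int = 60
    n_replicates: int = 3
    frac_up: float = 0.1
    frac_down: float = 0.1
    true_up_ratio: float = 2.0
    true_down_ratio: float = 0.5
    noise_sigma: float = 0.2
    missing_rate: float = 0.1
    motif_library: list = field(default_factory=default_motif_library)
    frac_motif_planted: float = 0.5
    conditions: tuple = ("ctrl", "stim")
    affected_conditions: tuple | None = None
    seed: int = 0
    universe_seed: int | None = None

    def __post_init__(self):
        for name in ("n_sites", "n_proteins", "n_replicates"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer, got {getattr(self, name)}")
        for name in ("frac_up", "frac_down", "frac_motif_planted", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_up + self.frac_down > 1:
            raise ConfigError(
                f"frac_up + frac_down must be <= 1, got {self.frac_up + self.frac_down}"
            )
        if not self.true_up_ratio > 1:
            raise ConfigError(f"true_up_ratio must exceed 1, got {self.true_up_ratio}")
        if not 0 < self.true_down_ratio < 1:
            raise ConfigError(f"true_down_ratio must be in (0, 1), got {self.true_down_ratio}")
        if self.noise_sigma < 0:
            raise ConfigError(f"noise_sigma must be nonnegative, got {self.noise_sigma}")
        if len(self.conditions) < 2:
            raise ConfigError("at least two conditions (reference + affected) are required")
        if self.affected_conditions is None:
            self.affected_conditions = tuple(self.conditions[1:])
        unknown = set(self.affected_conditions) - set(self.conditions)
        if unknown:
            raise ConfigError(f"affected_conditions {sorted(unknown)} not in conditions")


@dataclass
class GroundTruth:
    """Planted truth recorded alongside each synthetic dataset."""

    site_labels: dict | None = None  # site_id -> {up, down, unchanged}
    site_kinase: dict | None = None  # site_id -> kinase name or None
    connectors: list | None = None  # planted high-betweenness node ids
    nodes: list | None = None  # full node universe of a generated network

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _random_window(rng: np.random.Generator) -> list:
    chars = list(rng.choice(_AA_LIST, size=WINDOW_LENGTH))
    chars[CENTER_INDEX] = str(rng.choice(_STY_LIST))
    return chars


def _planted_window(
    motif: MotifDefinition,
    library: Sequence[MotifDefinition],
    rng: np.random.Generator,
    max_tries: int = 500,
) -> str:
    """A window matching exactly one library kinase: the planted one.

    Filler positions are rejection-sampled so the window satisfies the
    planted motif and no other kinase's motif — required for exact
    planted-count recovery. Fails loudly if the library's motifs overlap so
    heavily that no such window exists.
    """
    for _ in range(max_tries):
        chars = _random_window(rng)
        chars[CENTER_INDEX] = str(rng.choice(sorted(motif.center_residues)))
        for offset, allowed in motif.constraints.items():
            chars[CENTER_INDEX + offset] = str(rng.choice(sorted(allowed)))
        window = "".join(chars)
        if all(
            match_motif(window, m) == (m.kinase == motif.kinase) for m in library
        ):
            return window
    raise ConfigError(
        f"could not plant a window matching only {motif.kinase!r}; "
        "motif library entries overlap too strongly"
    )


def generate_phosphosite_table(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate one phosphosite table plus its planted ground truth.

    Site identities, protein assignments, positions and background windows
    are drawn from a "universe" stream (reseedable via ``universe_seed`` so
    two receptors can share a site universe while differing in effects);
    regulation labels, planted motifs, noise and missingness come from the
    ``seed`` stream. Windows of sites near the protein N-terminus are padded
    with ``_``; motif-planted sites are kept away from termini so their full
    window is informative.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rng_universe = (
        np.random.default_rng(cfg.universe_seed) if cfg.universe_seed is not None else rng
    )

    n = cfg.n_sites
    site_ids = [f"S{i:05d}" for i in range(n)]
    protein_ids = [
        f"P{int(k):04d}" for k in rng_universe.integers(0, cfg.n_proteins, size=n)
    ]
    positions = rng_universe.integers(1, 801, size=n)
    windows = [_random_window(rng_universe) for _ in range(n)]

    n_up = int(round(cfg.frac_up * n))
    n_down = int(round(cfg.frac_down * n))
    labels = np.array(["up"] * n_up + ["down"] * n_down + ["unchanged"] * (n - n_up - n_down))
    rng.shuffle(labels)

    regulated = np.flatnonzero(labels != "unchanged")
    n_planted = int(round(cfg.frac_motif_planted * regulated.size))
    planted_idx = rng.choice(regulated, size=n_planted, replace=False) if n_planted else []
    site_kinase: dict = {sid: None for sid in site_ids}
    library = list(cfg.motif_library)
    for i in sorted(planted_idx):
        motif = library[int(rng.integers(0, len(library)))]
        windows[i] = list(_planted_window(motif, library, rng))
        positions[i] = int(rng.integers(7, 795))  # keep planted windows un-truncated
        site_kinase[site_ids[i]] = motif.kinase

    # terminal truncation: pad window positions that fall before residue 1
    window_strings = []
    for i in range(n):
        chars = list(windows[i])
        overhang = CENTER_INDEX - (int(positions[i]) - 1)
        for j in range(max(0, overhang)):
            chars[j] = PADDING
        window_strings.append("".join(chars))
    amino_acids = [w[CENTER_INDEX] for w in window_strings]

    base = {"up": cfg.true_up_ratio, "down": cfg.true_down_ratio, "unchanged": 1.0}
    base_ratio = np.array([base[label] for label in labels])

    data = {
        "site_id": site_ids,
        "protein_id": protein_ids,
        "amino_acid": amino_acids,
        "position": positions,
        "sequence_window": window_strings,
    }
    affected = set(cfg.affected_conditions)
    for condition in cfg.conditions:
        center = base_ratio if condition in affected else np.ones(n)
        for rep in range(1, cfg.n_replicates + 1):
            values = center.astype(float).copy()
            if cfg.noise_sigma > 0:
                values = values * 2.0 ** rng.normal(0.0, cfg.noise_sigma, size=n)
            if cfg.missing_rate > 0:
                values = np.where(rng.random(n) < cfg.missing_rate, np.nan, values)
            data[f"ratio_{condition}_rep{rep}"] = values

    table = pd.DataFrame(data)
    truth = GroundTruth(
        site_labels=dict(zip(site_ids, labels.tolist())),
        site_kinase=site_kinase,
    )
    return table, truth


_SUPPORTED_MODELS = ("erdos_renyi", "scale_free")


def _model_graph(
    n: int, model: str, model_params: dict, rng: np.random.Generator
) -> nx.Graph:
    seed = int(rng.integers(0, 2**31 - 1))
    if model == "erdos_renyi":
        p = float(model_params.get("p", 0.1))
        return nx.gnp_random_graph(n, p, seed=seed)
    if model == "scale_free":
        m = int(model_params.get("m", 2))
        if n <= m:
            return nx.complete_graph(n)
        return nx.barabasi_albert_graph(n, m, seed=seed)
    raise ConfigError(
        f"unknown network model {model!r}; supported models: {', '.join(_SUPPORTED_MODELS)}"
    )


def _connect_components(G: nx.Graph, rng: np.random.Generator) -> None:
    """Chain-link the components of a community so it is internally connected."""
    components = [sorted(c) for c in nx.connected_components(G)]
    components.sort()
    for left, right in zip(components, components[1:]):
        u = left[int(rng.integers(0, len(left)))]
        v = right[int(rng.integers(0, len(right)))]
        G.add_edge(u, v)


def generate_network(
    n_nodes: int,
    model: str = "erdos_renyi",
    model_params: dict | None = None,
    n_planted_connectors: int = 0,
    seed: int = 0,
    node_names: Sequence[str] | None = None,
    signaling: bool = False,
) -> tuple[list[InteractionEdge], GroundTruth]:
    """Generate an interaction edge table with optional planted connector nodes.

    With ``n_planted_connectors = c > 0``, the non-connector nodes are split
    into ``c + 1`` communities, each internally wired by the requested random
    model (and made connected); connector ``i`` is the only bridge between
    communities ``i`` and ``i + 1``, so every shortest path between the two
    sides runs through it and its betweenness exceeds the graph mean by
    construction. Edges carry STRING-like per-channel evidence scores
    (``experiments`` drawn in [0.15, 1] so default evidence filtering keeps
    the planted topology intact; ``databases`` in [0, 1]) and, in signaling
    mode, a random activation/inhibition/docking relation.
    """
    if n_nodes < 3:
        raise ConfigError(f"n_nodes must be >= 3, got {n_nodes}")
    if not 0 <= n_planted_connectors < n_nodes:
        raise ConfigError(
            f"n_planted_connectors must be in [0, n_nodes), got {n_planted_connectors}"
        )
    if model not in _SUPPORTED_MODELS:
        raise ConfigError(
            f"unknown network model {model!r}; supported models: {', '.join(_SUPPORTED_MODELS)}"
        )
    model_params = dict(model_params or {})
    rng = np.random.default_rng(seed)
    if node_names is None:
        node_names = [f"N{i:04d}" for i in range(n_nodes)]
    elif len(node_names) != n_nodes:
        raise ConfigError("node_names length must equal n_nodes")
    node_names = list(node_names)

    c = n_planted_connectors
    connectors = node_names[:c]
    members = node_names[c:]
    G = nx.Graph()
    G.add_nodes_from(node_names)
    if c == 0:
        block = _model_graph(len(members), model, model_params, rng)
        G.add_edges_from(
            (members[u], members[v]) for u, v in sorted(block.edges())
        )
    else:
        communities = [sorted(members[i :: c + 1]) for i in range(c + 1)]
        for community in communities:
            block = _model_graph(len(community), model, model_params, rng)
            H = nx.relabel_nodes(block, dict(enumerate(community)), copy=True)
            _connect_components(H, rng)
            G.add_edges_from(sorted(H.edges()))
        for i, connector in enumerate(connectors):
            for community in (communities[i], communities[i + 1]):
                k = min(3, len(community))
                anchors = rng.choice(len(community), size=k, replace=False)
                for a in sorted(anchors):
                    G.add_edge(connector, community[int(a)])

    relations = ["activation", "inhibition", "docking"]
    edges = []
    for a, b in sorted(tuple(sorted(e)) for e in G.edges()):
        edges.append(
            InteractionEdge(
                node_a=a,
                node_b=b,
                experiments=float(np.round(rng.uniform(0.15, 1.0), 4)),
                databases=float(np.round(rng.uniform(0.0, 1.0), 4)),
                relation=str(rng.choice(relations)) if signaling else None,
            )
        )
    truth = GroundTruth(connectors=list(connectors), nodes=node_names)
    return edges, truth
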