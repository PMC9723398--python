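"""Protein-network topology: evidence filtering, centrality battery, hubs, null models.

Networks are reconstructed over differentially phosphorylated proteins (DPPs)
from STRING-like evidence-scored edge tables (undirected PPI mode) or from
signed directed signaling relations (activation/inhibition directed, docking
undirected). Ten node centralities are computed following the CentiScaPe
definitions; hubs are the nodes whose betweenness strictly exceeds the
network mean; topological significance is assessed against degree-preserving
randomized replicates (double-edge-swap rewiring) with add-one empirical
p-values, and a violin-plot-ready long table of the replicate mean
betweenness distribution.

Conventions fixed for reproducibility: betweenness and stress count ordered
source-target pairs and are unnormalized (hub selection by the above-mean
rule is invariant to this scaling); path-based sums on disconnected graphs
run over reachable nodes only, with isolated nodes scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError

RELATIONS = ("activation", "inhibition", "docking")
MODE_PPI = "ppi_undirected"
MODE_SIGNALING = "signaling_mixed"


@dataclass(frozen=True)
class InteractionEdge:
    """A protein pair with per-channel evidence scores and an optional signed relation.

    ``experiments`` and ``databases`` are STRING-style channel scores in
    [0, 1] (None when the channel is not annotated). ``relation`` is one of
    activation/inhibition (directed node_a -> node_b) or docking
    (undirected), or None for a plain PPI edge.
    """

    node_a: str
    node_b: str
    experiments: float | None = None
    databases: float | None = None
    relation: str | None = None

    def __post_init__(self):
        if self.node_a == self.node_b:
            raise ConfigError(f"self-loop edge rejected: {self.node_a!r}")
        for channel in ("experiments", "databases"):
            score = getattr(self, channel)
            if score is not None and not 0 <= score <= 1:
                raise ConfigError(
                    f"edge {self.node_a}-{self.node_b}: {channel} score {score} outside [0, 1]"
                )
        if self.relation is not None and self.relation not in RELATIONS:
            raise ConfigError(
                f"edge {self.node_a}-{self.node_b}: unknown relation {self.relation!r} "
                f"(expected one of {RELATIONS})"
            )


@dataclass
class NetworkModel:
    """A reconstructed network plus per-node fold-change annotations."""

    graph: nx.Graph | nx.DiGraph
    mode: str = MODE_PPI
    annotations: dict = field(default_factory=dict)
    warnings: tuple = ()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def filter_edges(
    edges: Iterable[InteractionEdge],
    experiments_min: float = 0.15,
    databases_min: float = 0.35,
) -> list[InteractionEdge]:
    """Keep edges supported by either evidence channel at its threshold.

    An edge is retained iff its experiments score is present and
    >= ``experiments_min``, or its databases score is present and
    >= ``databases_min`` (inclusive thresholds; the two channels are
    disjunctive).
    """
    for name, threshold in (("experiments_min", experiments_min), ("databases_min", databases_min)):
        if not 0 <= threshold <= 1:
            raise ConfigError(f"{name} must be in [0, 1], got {threshold}")
    kept = []
    for edge in edges:
        by_experiments = edge.experiments is not None and edge.experiments >= experiments_min
        by_databases = edge.databases is not None and edge.databases >= databases_min
        if by_experiments or by_databases:
            kept.append(edge)
    return kept


def build_network(
    dpp_list: Sequence[str],
    edges: Iterable[InteractionEdge],
    mode: str = MODE_PPI,
    annotations: dict | None = None,
) -> NetworkModel:
    """Induced network on the DPP set.

    Only edges with both endpoints among the differentially phosphorylated
    proteins are kept; DPPs without any surviving interaction remain as
    isolated nodes. In signaling mode activation/inhibition edges are
    directed (node_a -> node_b) and docking edges undirected (both arcs).
    """
    dpps = list(dict.fromkeys(dpp_list))
    if not dpps:
        raise ConfigError("dpp_list is empty; nothing to build a network from")
    if mode not in (MODE_PPI, MODE_SIGNALING):
        raise ConfigError(f"unknown mode {mode!r}")
    node_set = set(dpps)
    warnings: list[str] = []
    if mode == MODE_PPI:
        G: nx.Graph | nx.DiGraph = nx.Graph()
    else:
        G = nx.DiGraph()
    G.add_nodes_from(dpps)
    for edge in edges:
        if edge.node_a not in node_set or edge.node_b not in node_set:
            continue
        relation = edge.relation or ""
        if mode == MODE_PPI or edge.relation in (None, "docking"):
            G.add_edge(edge.node_a, edge.node_b, relation=relation)
            if G.is_directed():
                G.add_edge(edge.node_b, edge.node_a, relation=relation)
        else:  # directed activation / inhibition
            G.add_edge(edge.node_a, edge.node_b, relation=relation)
    if G.number_of_edges() == 0:
        warnings.append("no edges survived filtering; network is edgeless")
    return NetworkModel(
        graph=G, mode=mode, annotations=dict(annotations or {}), warnings=tuple(warnings)
    )


def _shortest_path_data(G, source):
    """BFS from ``source``: visit order, predecessors and path counts sigma."""
    sigma = {source: 1}
    dist = {source: 0}
    preds: dict = {source: []}
    order = [source]
    frontier = [source]
    while frontier:
        nxt = []
        for v in frontier:
            for w in G.successors(v) if G.is_directed() else G.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0
                    preds[w] = []
                    nxt.append(w)
                    order.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        frontier = nxt
    return order, preds, sigma, dist


def _stress_centrality(G) -> dict:
    """Stress: the absolute number of shortest paths through each node
    (ordered source-target pairs, endpoints excluded)."""
    stress = dict.fromkeys(G, 0.0)
    for s in G:
        order, preds, sigma, _ = _shortest_path_data(G, s)
        downstream = dict.fromkeys(order, 0.0)  # shortest paths from v onward
        for w in reversed(order):
            for v in preds[w]:
                downstream[v] += downstream[w] + 1
            if w != s:
                stress[w] += sigma[w] * downstream[w]
    return stress


def _all_pairs_distances(G) -> dict:
    return {v: dict(nx.single_source_shortest_path_length(G, v)) for v in G}


def compute_centralities(network: NetworkModel) -> pd.DataFrame:
    """The ten-centrality battery, one row per node.

    Definitions (CentiScaPe conventions): betweenness and stress over ordered
    pairs, unnormalized; closeness = 1/sum of distances to reachable nodes;
    eccentricity = 1/max distance; radiality = sum of (diameter + 1 - d) over
    reachable nodes, divided by (component size - 1), with the diameter taken
    per weakly-connected component; centroid(v) = min over other nodes w of
    gamma_v(w) - gamma_w(v), where gamma_v(w) counts nodes strictly closer to
    v than to w; eigenvector = principal adjacency eigenvector (on the
    undirected view), scaled to unit maximum; bridging = betweenness times
    the bridging coefficient (1/deg(v)) / sum over neighbors of 1/deg;
    in/out-degree on directed edges (both equal the degree in PPI mode).
    Isolated nodes score 0 on all path-based centralities.
    """
    G = network.graph
    nodes = list(G.nodes())
    if not nodes:
        raise ConfigError("cannot compute centralities of an empty network")
    directed = G.is_directed()

    betweenness = nx.betweenness_centrality(G, normalized=False)
    if not directed:  # count ordered pairs in both modes
        betweenness = {v: 2.0 * b for v, b in betweenness.items()}
    stress = _stress_centrality(G)
    dist = _all_pairs_distances(G)

    undirected_view = G.to_undirected() if directed else G
    components = {frozenset(c) for c in nx.connected_components(undirected_view)}
    comp_of = {v: c for c in components for v in c}
    diameter_of = {}
    for c in components:
        finite = [d for v in c for u, d in dist[v].items() if u in c]
        diameter_of[c] = max(finite) if finite else 0

    closeness, eccentricity, radiality = {}, {}, {}
    for v in nodes:
        reach = {t: d for t, d in dist[v].items() if t != v}
        if not reach:
            closeness[v] = eccentricity[v] = radiality[v] = 0.0
            continue
        total = sum(reach.values())
        closeness[v] = 1.0 / total
        eccentricity[v] = 1.0 / max(reach.values())
        comp = comp_of[v]
        delta = diameter_of[comp]
        n_comp = len(comp)
        radiality[v] = (
            sum(delta + 1 - d for d in reach.values()) / (n_comp - 1) if n_comp > 1 else 0.0
        )

    inf = float("inf")
    dist_to = {
        w: {t: dist[w].get(t, inf) for t in nodes} for w in nodes
    }
    gamma = {
        (v, w): sum(1 for t in nodes if dist_to[v][t] < dist_to[w][t])
        for v in nodes
        for w in nodes
        if v != w
    }
    centroid = {
        v: min((gamma[(v, w)] - gamma[(w, v)] for w in nodes if w != v), default=0.0)
        for v in nodes
    }

    if undirected_view.number_of_edges() == 0:
        eigenvector = dict.fromkeys(nodes, 0.0)
    else:
        A = nx.to_numpy_array(undirected_view, nodelist=nodes)
        eigenvalues, eigenvectors = np.linalg.eigh(A)
        principal = np.abs(eigenvectors[:, int(np.argmax(eigenvalues))])
        principal = principal / principal.max() if principal.max() > 0 else principal
        eigenvector = dict(zip(nodes, principal.tolist()))

    degree = dict(undirected_view.degree())
    bridging = {}
    for v in nodes:
        if degree[v] == 0:
            bridging[v] = 0.0
            continue
        denom = sum(1.0 / degree[u] for u in undirected_view.neighbors(v))
        coefficient = (1.0 / degree[v]) / denom if denom > 0 else 0.0
        bridging[v] = betweenness[v] * coefficient

    if directed:
        in_degree = dict(G.in_degree())
        out_degree = dict(G.out_degree())
    else:
        in_degree = out_degree = dict(G.degree())

    return pd.DataFrame(
        {
            "betweenness": [betweenness[v] for v in nodes],
            "bridging": [bridging[v] for v in nodes],
            "centroid": [float(centroid[v]) for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "eccentricity": [eccentricity[v] for v in nodes],
            "eigenvector": [eigenvector[v] for v in nodes],
            "radiality": [radiality[v] for v in nodes],
            "stress": [stress[v] for v in nodes],
            "in_degree": [in_degree[v] for v in nodes],
            "out_degree": [out_degree[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def select_hubs(profiles: pd.DataFrame) -> set:
    """Hubs: nodes whose betweenness strictly exceeds the network mean betweenness."""
    if profiles.empty:
        raise ConfigError("cannot select hubs from an empty centrality table")
    mean_betweenness = profiles["betweenness"].mean()
    return set(profiles.index[profiles["betweenness"] > mean_betweenness])


def _rewire(G, n_swaps: int, rng: np.random.Generator) -> None:
    """Attempt ``n_swaps`` degree-preserving double edge swaps in place.

    Invalid moves (self-loops, existing edges) are rejected, not retried, so
    the number of attempts is exactly ``n_swaps``.
    """
    directed = G.is_directed()
    edges = list(G.edges())
    m = len(edges)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[int(i)]
        c, d = edges[int(j)]
        if not directed and rng.random() < 0.5:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == d or c == b or G.has_edge(a, d) or G.has_edge(c, b):
            continue
        G.remove_edge(a, b)
        G.remove_edge(c, d)
        G.add_edge(a, d)
        G.add_edge(c, b)
        edges[int(i)] = (a, d)
        edges[int(j)] = (c, b)


def randomize_network(
    network: NetworkModel, n_swaps: int | None = None, seed: int = 0
) -> NetworkModel:
    """Degree-preserving randomization by double edge swaps.

    The degree sequence (in- and out-degree sequences in directed mode) is
    conserved exactly; no self-loops or parallel edges are introduced.
    ``n_swaps`` defaults to 10x the edge count. Networks with fewer than two
    edges cannot be rewired and are returned unchanged with a warning flag.
    """
    G = network.graph.copy()
    if G.number_of_edges() < 2:
        return replace(
            network, graph=G, warnings=network.warnings + ("too few edges to rewire",)
        )
    if n_swaps is None:
        n_swaps = 10 * G.number_of_edges()
    _rewire(G, n_swaps, np.random.default_rng(seed))
    return replace(network, graph=G)


@dataclass
class NullModelResult:
    """Observed-vs-null betweenness statistics from randomized replicates."""

    node_stats: pd.DataFrame  # observed, null_mean, null_sd, empirical_p per node
    replicate_table: pd.DataFrame  # long table: replicate, statistic, value
    n_random: int


def null_distribution(
    network: NetworkModel,
    n_random: int = 1000,
    n_swaps: int | None = None,
    seed: int = 0,
) -> NullModelResult:
    """Betweenness null statistics over degree-preserving randomized replicates.

    For each replicate the network is independently rewired and node
    betweenness recomputed. Returns per-node null mean/SD and the add-one
    empirical p-value ``(1 + #{replicates >= observed}) / (n_random + 1)``,
    plus a violin-plot-ready long table of each replicate's mean betweenness.
    """
    if n_random < 1:
        raise ConfigError(f"n_random must be >= 1, got {n_random}")
    G = network.graph
    nodes = list(G.nodes())
    observed = nx.betweenness_centrality(G, normalized=False)
    if not G.is_directed():
        observed = {v: 2.0 * b for v, b in observed.items()}
    seeds = np.random.SeedSequence(seed).generate_state(n_random) % (2**31 - 1)
    null_values = np.empty((n_random, len(nodes)))
    replicate_rows = []
    for r in range(n_random):
        rewired = randomize_network(network, n_swaps=n_swaps, seed=int(seeds[r]))
        b = nx.betweenness_centrality(rewired.graph, normalized=False)
        if not rewired.graph.is_directed():
            b = {v: 2.0 * x for v, x in b.items()}
        null_values[r] = [b[v] for v in nodes]
        replicate_rows.append(
            {
                "replicate": r,
                "statistic": "mean_betweenness",
                "value": float(np.mean(null_values[r])),
            }
        )
    obs = np.array([observed[v] for v in nodes])
    exceed = (null_values >= obs[None, :]).sum(axis=0)
    node_stats = pd.DataFrame(
        {
            "betweenness_observed": obs,
            "null_mean": null_values.mean(axis=0),
            "null_sd": null_values.std(axis=0, ddof=1) if n_random > 1 else 0.0,
            "empirical_p": (1 + exceed) / (n_random + 1),
        },
        index=pd.Index(nodes, name="node"),
    )
    return NullModelResult(
        node_stats=node_stats,
        replicate_table=pd.DataFrame(replicate_rows),
        n_random=n_random,
    )
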