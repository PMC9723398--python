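"""Independent brute-force oracles for shortest-path centralities.

These enumerate every shortest path explicitly via networkx's path
enumeration and count memberships directly; they share no code with the
package's accumulation-based implementations.
"""

from __future__ import annotations

import itertools

import networkx as nx


def brute_force_betweenness_stress(G) -> tuple[dict, dict]:
    """Betweenness and stress by exhaustive shortest-path enumeration.

    Both count ordered (source, target) pairs; betweenness sums the fraction
    of shortest s-t paths through each interior node, stress the absolute
    number of such paths.
    """
    betweenness = dict.fromkeys(G, 0.0)
    stress = dict.fromkeys(G, 0.0)
    nodes = list(G)
    for s, t in itertools.permutations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(G, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            if through:
                betweenness[v] += through / len(paths)
                stress[v] += through
    return betweenness, stress
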