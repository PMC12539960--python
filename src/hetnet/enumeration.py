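"""Exhaustive small-graph enumeration built on the networkx graph atlas.

The atlas contains every graph on up to seven nodes, which is exactly the
regime where this package needs exhaustive certificates: brute-force oracle
checks, extremal-value denominators (HS', HB) and the compliance battery.
"""

from __future__ import annotations

from functools import lru_cache

import networkx as nx

__all__ = ["all_graphs", "connected_graphs", "graphs_with", "min_max_degree"]

_ATLAS_MAX_N = 7


@lru_cache(maxsize=1)
def _atlas() -> tuple[nx.Graph, ...]:
    # index 0 of the atlas is the empty (0-node) placeholder; drop it
    return tuple(g for g in nx.graph_atlas_g() if g.number_of_nodes() >= 1)


def all_graphs(n: int) -> list[nx.Graph]:
    """Every simple graph on exactly ``n`` nodes (n <= 7), including disconnected."""
    if not 1 <= n <= _ATLAS_MAX_N:
        raise ValueError(f"atlas enumeration covers 1 <= n <= {_ATLAS_MAX_N}, got {n}")
    return [g.copy() for g in _atlas() if g.number_of_nodes() == n]


def connected_graphs(max_n: int, min_n: int = 2) -> list[nx.Graph]:
    """All connected graphs with min_n <= n <= max_n nodes (max_n <= 7)."""
    if max_n > _ATLAS_MAX_N:
        raise ValueError(f"atlas enumeration covers n <= {_ATLAS_MAX_N}, got {max_n}")
    return [
        g.copy()
        for g in _atlas()
        if min_n <= g.number_of_nodes() <= max_n and nx.is_connected(g)
    ]


def graphs_with(n: int, m: int) -> list[nx.Graph]:
    """Every graph with exactly ``n`` nodes and ``m`` edges (n <= 7)."""
    return [g for g in all_graphs(n) if g.number_of_edges() == m]


@lru_cache(maxsize=None)
def min_max_degree(n: int, m: int) -> tuple[int, int]:
    """Smallest and largest attainable maximum degree over all graphs with (n, m).

    Exhaustive over the atlas; used to validate the closed forms
    ceil(2m/n) and min(n-1, m) that the HB measure relies on.
    """
    maxdegs = [max(d for _, d in g.degree()) for g in graphs_with(n, m)]
    if not maxdegs:
        raise ValueError(f"no graphs with n={n}, m={m}")
    return min(maxdegs), max(maxdegs)
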