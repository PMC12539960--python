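"""Network manipulations probing measure behaviour: transfer, addition, replication.

* **Transfer** — a Pigou–Dalton-style rewiring: some pivot node moves one of
  its edges from a higher-degree neighbour to a lower-degree non-neighbour,
  without reversing the two nodes' degree order (gap >= 2).  Heterogeneity
  should strictly decrease.
* **Addition** — all node degrees rise by the same constant c.  Three
  semantics: ``degree_shift`` keeps the edge set and hands evaluators an
  explicit shifted degree map; ``overlay`` realizes the increase as a true
  c-regular edge-disjoint layer on the same nodes; ``rewire`` realizes the
  shifted degree sequence k_i + c as a fresh topology (Havel–Hakimi, with
  seeded degree-preserving randomization), since the principle itself does
  not constrain how the new edges connect.
* **Replication** — disjoint union of x relabelled copies (the degree
  distribution is invariant); the distribution version also supports rational
  factors via pre-scaling of the counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import networkx as nx
import numpy as np

from .graph_core import DegreeDistribution, validate_graph

__all__ = [
    "TransferMove",
    "AdditionResult",
    "enumerate_transfers",
    "apply_transfer",
    "apply_addition",
    "replicate",
    "replicate_distribution",
]


@dataclass(frozen=True)
class TransferMove:
    """Rewire edge (pivot, from_node) to (pivot, to_node).

    Requires the edge to exist, the target edge to be absent, the three nodes
    to be distinct, and degree(from_node) >= degree(to_node) + 2 so the move
    narrows the degree gap without reversing the order.
    """

    pivot: object
    from_node: object
    to_node: object


def _is_admissible(graph: nx.Graph, move: TransferMove) -> bool:
    p, u, v = move.pivot, move.from_node, move.to_node
    return (
        p != u
        and p != v
        and u != v
        and graph.has_edge(p, u)
        and not graph.has_edge(p, v)
        and graph.degree(u) >= graph.degree(v) + 2
    )


def enumerate_transfers(graph: nx.Graph) -> list[TransferMove]:
    """All admissible transfer moves, in deterministic (sorted-label) order."""
    validate_graph(graph)
    deg = dict(graph.degree())
    nodes = sorted(graph.nodes(), key=str)
    moves = []
    for pivot in nodes:
        neighbours = set(graph[pivot])
        for u in sorted(neighbours, key=str):
            for v in nodes:
                if v == pivot or v == u or v in neighbours:
                    continue
                if deg[u] >= deg[v] + 2:
                    moves.append(TransferMove(pivot, u, v))
    return moves


def apply_transfer(graph: nx.Graph, move: TransferMove) -> nx.Graph:
    """New graph with edge (pivot, from) replaced by (pivot, to)."""
    if not _is_admissible(graph, move):
        raise ValueError(f"move {move} is not admissible for this graph")
    out = graph.copy()
    out.remove_edge(move.pivot, move.from_node)
    out.add_edge(move.pivot, move.to_node)
    return out


@dataclass
class AdditionResult:
    """Outcome of a uniform degree addition.

    ``degree_shift``: ``graph`` is the original and ``degrees`` maps each node
    to its shifted degree k_i + c (evaluators accept this override).
    ``overlay``: ``graph`` is a real supergraph whose degrees are k_i + c and
    ``degrees`` is None.
    """

    graph: nx.Graph
    degrees: Mapping | None
    semantics: str
    c: int


class OverlayError(RuntimeError):
    """No c-regular edge-disjoint overlay could be constructed."""


def _overlay_layers(graph: nx.Graph, c: int, seed: int) -> nx.Graph:
    """Add a c-regular edge-disjoint layer; circulant offsets first, random
    perfect matchings as fallback (even n only for odd contributions)."""
    n = graph.number_of_nodes()
    nodes = sorted(graph.nodes(), key=str)
    index = {v: i for i, v in enumerate(nodes)}
    out = graph.copy()
    added = np.zeros(n, dtype=int)

    def layer_edges(offset: int) -> list[tuple]:
        if 2 * offset == n:  # antipodal: degree contribution 1
            return [(nodes[i], nodes[i + offset]) for i in range(offset)]
        return [(nodes[i], nodes[(i + offset) % n]) for i in range(n)]

    remaining = c
    for offset in range(1, n // 2 + 1):
        if remaining == 0:
            break
        contrib = 1 if 2 * offset == n else 2
        if contrib > remaining:
            continue
        edges = layer_edges(offset)
        if any(out.has_edge(a, b) for a, b in edges):
            continue
        out.add_edges_from(edges)
        for a, b in edges:
            added[index[a]] += 1
            added[index[b]] += 1
        remaining -= contrib
    rng = np.random.default_rng(seed)
    attempts = 0
    while remaining > 0 and attempts < 200:
        attempts += 1
        if n % 2 == 1:
            break
        perm = rng.permutation(n)
        matching = [(nodes[perm[2 * i]], nodes[perm[2 * i + 1]]) for i in range(n // 2)]
        if any(out.has_edge(a, b) for a, b in matching):
            continue
        out.add_edges_from(matching)
        for a, b in matching:
            added[index[a]] += 1
            added[index[b]] += 1
        remaining -= 1
    if remaining > 0:
        raise OverlayError(
            f"could not realize a {c}-regular edge-disjoint overlay on n={n} "
            f"(graph too dense or n parity infeasible); use degree_shift "
            f"semantics or a larger graph"
        )
    assert all(a == c for a in added)
    return out


def apply_addition(
    graph: nx.Graph, c: int, semantics: str = "degree_shift", seed: int = 0
) -> AdditionResult:
    """Increase every node degree by the positive integer ``c``."""
    if c < 1:
        raise ValueError("c must be a positive integer")
    validate_graph(graph)
    if semantics == "degree_shift":
        shifted = {v: d + c for v, d in graph.degree()}
        return AdditionResult(graph=graph, degrees=shifted, semantics=semantics, c=c)
    if semantics == "overlay":
        return AdditionResult(
            graph=_overlay_layers(graph, c, seed), degrees=None,
            semantics=semantics, c=c,
        )
    if semantics == "rewire":
        return AdditionResult(
            graph=_rewire_realization(graph, c, seed), degrees=None,
            semantics=semantics, c=c,
        )
    raise ValueError(f"unknown addition semantics {semantics!r}")


def _rewire_realization(graph: nx.Graph, c: int, seed: int) -> nx.Graph:
    """A connected graph with degrees k_i + c, not constrained to contain the
    original edges.  seed=0 is the plain Havel–Hakimi realization; larger
    seeds randomize it with degree-preserving double-edge swaps."""
    from .generators import GenerationError, _connectify, realize_sequence

    n = graph.number_of_nodes()
    shifted = [d + c for _, d in graph.degree()]
    if max(shifted) > n - 1:
        raise OverlayError(
            f"degrees k+{c} exceed n-1={n - 1}; addition is infeasible here"
        )
    try:
        realization = realize_sequence(shifted, connected=True)
    except GenerationError as exc:
        raise OverlayError(str(exc)) from exc
    if seed > 0:
        shuffled = realization.copy()
        try:
            nx.double_edge_swap(
                shuffled,
                nswap=2 * shuffled.number_of_edges(),
                max_tries=100 * shuffled.number_of_edges(),
                seed=int(seed),
            )
        except nx.NetworkXError:
            pass
        except nx.NetworkXAlgorithmError:
            pass
        shuffled = _connectify(shuffled)
        if nx.is_connected(shuffled):
            realization = shuffled
    return realization


def replicate(graph: nx.Graph, x: int) -> nx.Graph:
    """Disjoint union of x relabelled copies (labels get a '#i' suffix)."""
    if x < 2:
        raise ValueError("graph replication needs an integer factor x >= 2")
    validate_graph(graph)
    out = nx.Graph()
    for i in range(x):
        out.add_nodes_from(f"{v}#{i}" for v in graph.nodes())
        out.add_edges_from((f"{u}#{i}", f"{v}#{i}") for u, v in graph.edges())
    return out


def replicate_distribution(
    dist: DegreeDistribution, x: Fraction | int | float
) -> DegreeDistribution:
    """Scale every degree count by rational x > 0, pre-scaling by the smallest
    integer that makes all products integral; P(k) is invariant."""
    x = Fraction(x).limit_denominator(10**9) if not isinstance(x, Fraction) else x
    if x <= 0:
        raise ValueError("replication factor must be positive")
    scaled = {k: nk * x for k, nk in dist.counts.items()}
    denominators = [frac.denominator for frac in scaled.values()]
    lcm = 1
    for d in denominators:
        lcm = lcm * d // np.gcd(lcm, d)
    counts = {k: int(frac * lcm) for k, frac in scaled.items()}
    return DegreeDistribution(n=sum(counts.values()), counts=counts)
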