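"""Graph representation, degree statistics, spectral radius and file I/O.

The universal in-memory container is :class:`networkx.Graph` restricted to
simple undirected graphs: no self-loops, no parallel edges, opaque (string or
integer) node labels.  All loaders and generators in this package validate
those invariants; measures downstream may assume them.

Two plain-text formats are supported.  The edge list (two whitespace-separated
labels per line, ``#`` comments) is the exchange format but cannot represent
isolated nodes; the minimal GML subset (graph/node/edge with id/label) can.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "GraphFormatError",
    "GraphValidationError",
    "GraphStats",
    "DegreeDistribution",
    "load_graph",
    "save_graph",
    "validate_graph",
    "graph_stats",
    "degree_sequence",
    "degree_distribution",
    "spectral_radius",
]


class GraphFormatError(ValueError):
    """A file could not be parsed as the requested graph format."""


class GraphValidationError(ValueError):
    """A graph violates the simple-graph invariants (loops, duplicates...)."""


@dataclass(frozen=True)
class GraphStats:
    """Headline statistics of a graph.

    ``density`` is 2m/(n(n-1)) for n >= 2 and defined as 0 for a single node.
    """

    n: int
    m: int
    density: float
    mean_degree: float
    max_degree: int
    min_degree: int
    connected: bool


@dataclass(frozen=True)
class DegreeDistribution:
    """Empirical degree distribution P(k) = n_k / n.

    ``counts`` maps each occurring degree value k to the number of nodes n_k
    with that degree; ``n`` is the total node count, so probabilities sum to 1.
    """

    n: int
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise GraphValidationError("degree distribution needs n >= 1")
        if sum(self.counts.values()) != self.n:
            raise GraphValidationError(
                f"degree counts sum to {sum(self.counts.values())}, expected n={self.n}"
            )

    def probability(self, k: int) -> float:
        return self.counts.get(k, 0) / self.n

    def probabilities(self) -> dict[int, float]:
        return {k: nk / self.n for k, nk in self.counts.items()}


def validate_graph(graph: nx.Graph) -> nx.Graph:
    """Check simple-graph invariants, returning the graph unchanged."""
    if graph.number_of_nodes() < 1:
        raise GraphValidationError("graph must have at least one node")
    if graph.is_directed() or graph.is_multigraph():
        raise GraphValidationError("only simple undirected graphs are supported")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise GraphValidationError(f"self-loop at node {loops[0][0]!r}")
    return graph


def _parse_edgelist(path: str) -> nx.Graph:
    graph = nx.Graph()
    seen: set[frozenset] = set()
    with open(path, "r", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two whitespace-separated labels, "
                    f"got {len(tokens)} token(s): {line!r}"
                )
            u, v = tokens
            if u == v:
                raise GraphValidationError(f"{path}:{lineno}: self-loop at node {u!r}")
            key = frozenset((u, v))
            if key in seen:
                raise GraphValidationError(
                    f"{path}:{lineno}: duplicate edge between {u!r} and {v!r}"
                )
            seen.add(key)
            graph.add_edge(u, v)
    if graph.number_of_nodes() == 0:
        raise GraphFormatError(f"{path}: no edges found in edge-list file")
    return graph


def load_graph(path: str, format: str = "edgelist") -> nx.Graph:
    """Read a simple undirected graph from ``path``.

    ``format`` is ``"edgelist"`` (two labels per line, '#' comments; node
    labels are strings) or ``"gml"``.  Self-loops and duplicate edges are
    rejected with :class:`GraphValidationError`.
    """
    if format == "edgelist":
        return validate_graph(_parse_edgelist(path))
    if format == "gml":
        try:
            graph = nx.read_gml(path)
        except Exception as exc:  # networkx raises several parse error types
            raise GraphFormatError(f"{path}: GML parse failure: {exc}") from exc
        if graph.is_directed():
            raise GraphValidationError(f"{path}: directed graphs are not supported")
        if graph.is_multigraph():
            graph = nx.Graph(graph)
        return validate_graph(graph)
    raise ValueError(f"unknown format {format!r}; use 'edgelist' or 'gml'")


def save_graph(graph: nx.Graph, path: str, format: str = "edgelist") -> None:
    """Write ``graph`` canonically: endpoints sorted within each edge, lines sorted.

    The edge-list format cannot represent isolated nodes; they are dropped
    with a :class:`UserWarning`.  GML preserves them.
    """
    validate_graph(graph)
    if format == "edgelist":
        isolated = [u for u, d in graph.degree() if d == 0]
        if isolated:
            warnings.warn(
                f"edge-list format drops {len(isolated)} isolated node(s); "
                "use GML to preserve them",
                UserWarning,
                stacklevel=2,
            )
        lines = sorted(
            "{} {}".format(*sorted((str(u), str(v)))) for u, v in graph.edges()
        )
        with open(path, "w", encoding="utf-8") as handle:
            handle.write("\n".join(lines))
            if lines:
                handle.write("\n")
    elif format == "gml":
        nx.write_gml(graph, path, stringizer=str)
    else:
        raise ValueError(f"unknown format {format!r}; use 'edgelist' or 'gml'")


def graph_stats(graph: nx.Graph) -> GraphStats:
    """Node/edge counts, density d_G = 2m/(n(n-1)), degree summary, connectivity."""
    validate_graph(graph)
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    degrees = [d for _, d in graph.degree()]
    density = 2.0 * m / (n * (n - 1)) if n >= 2 else 0.0
    return GraphStats(
        n=n,
        m=m,
        density=density,
        mean_degree=2.0 * m / n,
        max_degree=max(degrees),
        min_degree=min(degrees),
        connected=nx.is_connected(graph) if n >= 1 else True,
    )


def degree_sequence(graph: nx.Graph) -> list[int]:
    """Degrees in node-insertion order (handshake: sums to 2m)."""
    return [d for _, d in graph.degree()]


def degree_distribution(seq: Iterable[int] | nx.Graph) -> DegreeDistribution:
    """Empirical degree distribution from a degree sequence or a graph."""
    if isinstance(seq, nx.Graph):
        seq = degree_sequence(seq)
    degrees = list(int(k) for k in seq)
    if not degrees:
        raise GraphValidationError("empty degree sequence")
    return DegreeDistribution(n=len(degrees), counts=dict(Counter(degrees)))


_DENSE_LIMIT = 500


def spectral_radius(graph: nx.Graph, tol: float = 1e-10) -> float:
    """Largest adjacency eigenvalue ℵ1.

    Dense symmetric eigensolver for n <= 500; Lanczos (ARPACK) above, with the
    requested tolerance.  On connected graphs ℵ1 lies in [mean degree, kmax].
    """
    validate_graph(graph)
    n = graph.number_of_nodes()
    if n == 1:
        return 0.0
    if graph.number_of_edges() == 0:
        return 0.0
    if n <= _DENSE_LIMIT:
        adjacency = nx.to_numpy_array(graph, dtype=float)
        return float(np.linalg.eigvalsh(adjacency)[-1])
    from scipy.sparse.linalg import ArpackNoConvergence, eigsh

    adjacency = nx.to_scipy_sparse_array(graph, dtype=float, format="csr")
    try:
        values = eigsh(adjacency, k=1, which="LA", tol=tol, return_eigenvectors=False)
    except ArpackNoConvergence as exc:
        raise RuntimeError(
            f"spectral radius did not converge at tol={tol} for n={n}"
        ) from exc
    return float(values[0])


def degree_map(graph: nx.Graph) -> dict:
    """Node -> degree mapping (convenience shared by the measure evaluators)."""
    return dict(graph.degree())
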