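"""Seeded graph generators for every family the experiments use.

Random models
-------------
* ``gen_er`` — Erdős–Rényi G(n, p) with p = mean_degree/(n-1).
* ``gen_powerlaw`` — static-fitness power-law sampler (node fitness
  proportional to rank^(-1/(γ-1))) with an exact, ER-matched edge count.
* ``gen_exponential`` — geometric (discrete exponential) degree sequence
  realized by configuration-model matching with degree-preserving repair of
  loops and parallel edges.

Named families
--------------
Stars, wheels, cycles, complete and complete-bipartite graphs, circulant
r-regular graphs, and "completely diverse" graphs: graphs on n nodes whose
degree multiset contains exactly n-1 distinct values, one of them repeated.

All generators consume randomness only through a ``numpy`` Generator seeded
from the ``seed`` argument, so the same seed reproduces the same edge set.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np

from .graph_core import validate_graph

__all__ = [
    "gen_er",
    "gen_powerlaw",
    "gen_exponential",
    "gen_named",
    "gen_diverse",
    "realize_sequence",
    "sample_powerlaw_degrees",
    "diverse_degree_sequence",
]


class GenerationError(RuntimeError):
    """A generator could not realize the requested graph."""


def gen_er(n: int, mean_degree: float, seed: int) -> nx.Graph:
    """G(n, p) with connection probability p = mean_degree/(n-1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= mean_degree <= n - 1:
        raise ValueError(f"mean_degree must lie in [0, n-1]={n - 1}, got {mean_degree}")
    p = mean_degree / (n - 1) if n > 1 else 0.0
    graph = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    return graph


def gen_powerlaw(n: int, gamma: float, target_edges: int, seed: int) -> nx.Graph:
    """Static-fitness power-law graph with exactly ``target_edges`` edges.

    Node i (rank i = 1..n) gets fitness i^(-1/(γ-1)); edge endpoints are drawn
    independently proportional to fitness and accepted if they form a new
    non-loop edge, until the target edge count is reached.  The resulting
    degree distribution has a power-law tail with exponent close to γ.
    """
    if gamma <= 2:
        raise ValueError(f"gamma must exceed 2, got {gamma}")
    max_edges = n * (n - 1) // 2
    if target_edges > max_edges:
        raise GenerationError(
            f"target_edges={target_edges} exceeds maximum {max_edges} for n={n}"
        )
    rng = np.random.default_rng(int(seed))
    ranks = np.arange(1, n + 1, dtype=float)
    fitness = ranks ** (-1.0 / (gamma - 1.0))
    prob = fitness / fitness.sum()
    graph = nx.empty_graph(n)
    edges: set[tuple[int, int]] = set()
    # dense targets would stall a rejection sampler; fall back to weighted
    # sampling without replacement over all pairs in that (untypical) regime
    if target_edges > 0.4 * max_edges:
        pairs = np.array(list(itertools.combinations(range(n), 2)))
        weights = prob[pairs[:, 0]] * prob[pairs[:, 1]]
        chosen = rng.choice(
            len(pairs), size=target_edges, replace=False, p=weights / weights.sum()
        )
        graph.add_edges_from(map(tuple, pairs[chosen]))
        return graph
    while len(edges) < target_edges:
        batch = max(1024, 2 * (target_edges - len(edges)))
        us = rng.choice(n, size=batch, p=prob)
        vs = rng.choice(n, size=batch, p=prob)
        for u, v in zip(us, vs):
            if u == v:
                continue
            edge = (u, v) if u < v else (v, u)
            if edge in edges:
                continue
            edges.add(edge)
            if len(edges) == target_edges:
                break
    graph.add_edges_from(edges)
    return graph


def _repair_configuration(
    n: int, pairs: list[tuple[int, int]], rng: np.random.Generator
) -> set[tuple[int, int]] | None:
    """Turn a stub matching into a simple graph by degree-preserving swaps."""
    good: set[tuple[int, int]] = set()
    defects: list[tuple[int, int]] = []
    for u, v in pairs:
        edge = (u, v) if u < v else (v, u)
        if u == v or edge in good:
            defects.append((u, v))
        else:
            good.add(edge)
    good_list = list(good)
    budget = 200 * max(1, len(defects))
    while defects and budget > 0:
        budget -= 1
        u, v = defects.pop()
        i = rng.integers(len(good_list))
        x, y = good_list[i]
        if rng.integers(2):
            x, y = y, x
        # swap (u,v),(x,y) -> (u,x),(v,y); keep degrees, drop the defect
        e1 = (u, x) if u < x else (x, u)
        e2 = (v, y) if v < y else (y, v)
        if u == x or v == y or e1 in good or e2 in good or e1 == e2:
            defects.append((u, v))
            continue
        good.remove((x, y) if x < y else (y, x))
        good.add(e1)
        good.add(e2)
        good_list[i] = e1
        good_list.append(e2)
        # removing (x,y) may desynchronize good_list; rebuild lazily
        if len(good_list) > 2 * len(good):
            good_list = list(good)
    if defects:
        return None
    return good


def gen_exponential(n: int, mean_degree: float, seed: int) -> nx.Graph:
    """Configuration-model graph with geometric degrees on {1, 2, ...}.

    The geometric law with success probability 1/mean_degree is the discrete
    analogue of an exponential degree distribution.  Parity of the stub count
    is fixed by decrementing one degree above 1; loops and parallel edges
    produced by the matching are repaired by degree-preserving edge swaps.
    """
    if mean_degree < 1:
        raise ValueError("mean_degree must be >= 1")
    rng = np.random.default_rng(int(seed))
    degrees = rng.geometric(1.0 / mean_degree, size=n)
    degrees = np.minimum(degrees, n - 1)
    if degrees.sum() % 2 == 1:
        candidates = np.flatnonzero(degrees > 1)
        target = candidates[-1] if len(candidates) else 0
        degrees[target] -= 1
    stubs = np.repeat(np.arange(n), degrees)
    rng.shuffle(stubs)
    pairs = list(map(tuple, stubs.reshape(-1, 2)))
    edges = _repair_configuration(n, pairs, rng)
    if edges is None:
        raise GenerationError(
            f"configuration matching could not be made simple "
            f"(n={n}, mean_degree={mean_degree}, seed={seed}); "
            "the degree sequence is too dense for a simple realization"
        )
    graph = nx.empty_graph(n)
    graph.add_edges_from(edges)
    return graph


def gen_named(family: str, n: int, **params) -> nx.Graph:
    """Deterministic named families: star, wheel, cycle, complete, regular, ...

    ``regular`` builds a circulant with offsets 1..r/2 (plus the antipodal
    offset n/2 for odd r, which requires even n).  ``complete_bipartite``
    takes part sizes ``a`` and ``b`` (n is ignored if both given).
    """
    if family == "star":
        if n < 2:
            raise ValueError("star needs n >= 2")
        return nx.star_graph(n - 1)
    if family == "wheel":
        if n < 4:
            raise ValueError("wheel needs n >= 4")
        return nx.wheel_graph(n)
    if family == "cycle":
        if n < 3:
            raise ValueError("cycle needs n >= 3")
        return nx.cycle_graph(n)
    if family == "complete":
        return nx.complete_graph(n)
    if family == "complete_bipartite":
        a = params.get("a", n // 2)
        b = params.get("b", n - n // 2)
        return nx.complete_bipartite_graph(a, b)
    if family == "regular":
        r = int(params["r"])
        if r < 0 or r > n - 1:
            raise ValueError(f"degree r={r} infeasible for n={n}")
        if (r * n) % 2 == 1:
            raise ValueError(f"r*n must be even; got r={r}, n={n}")
        offsets = list(range(1, r // 2 + 1))
        if r % 2 == 1:
            offsets.append(n // 2)
        graph = nx.circulant_graph(n, offsets)
        if any(d != r for _, d in graph.degree()):
            raise GenerationError(f"circulant offsets {offsets} did not give {r}-regular")
        return graph
    raise ValueError(f"unknown family {family!r}")


def diverse_degree_sequence(n: int) -> list[int]:
    """Canonical completely diverse degree sequence for 4 <= n <= 7.

    Degree values are the n-1 distinct values {1, ..., n-1} with exactly one
    value duplicated; among the parity-feasible, graphical choices with a
    connected realization, the lexicographically smallest sorted sequence is
    the canonical pick.
    """
    if not 4 <= n <= 7:
        raise ValueError("completely diverse fixtures cover 4 <= n <= 7")
    base = list(range(1, n))
    candidates = []
    for extra in base:
        seq = sorted(base + [extra])
        if sum(seq) % 2 == 0 and nx.is_graphical(seq):
            candidates.append(seq)
    for seq in sorted(candidates):
        try:
            realize_sequence(seq, connected=True)
        except GenerationError:
            continue
        return seq
    raise GenerationError(f"no connected completely diverse sequence for n={n}")


def gen_diverse(n: int) -> nx.Graph:
    """Connected completely diverse graph on n nodes (4 <= n <= 7)."""
    return realize_sequence(diverse_degree_sequence(n), connected=True)


def _erdos_gallai_violation(seq: list[int]) -> str:
    degrees = sorted(seq, reverse=True)
    n = len(degrees)
    if any(d < 0 for d in degrees):
        return "negative degree"
    if sum(degrees) % 2 == 1:
        return f"odd degree sum {sum(degrees)}"
    for k in range(1, n + 1):
        lhs = sum(degrees[:k])
        rhs = k * (k - 1) + sum(min(d, k) for d in degrees[k:])
        if lhs > rhs:
            return (
                f"Erdős–Gallai inequality fails at k={k}: "
                f"sum of top {k} degrees {lhs} > {rhs}"
            )
    return "unknown violation"


def realize_sequence(seq: list[int], connected: bool = False) -> nx.Graph:
    """Simple graph with exactly the requested degrees (Havel–Hakimi).

    With ``connected=True`` a degree-preserving double-edge swap joins
    components when the Havel–Hakimi realization is disconnected.
    """
    seq = [int(d) for d in seq]
    if not nx.is_graphical(seq):
        raise GenerationError(
            f"degree sequence {seq} is not graphical: {_erdos_gallai_violation(seq)}"
        )
    graph = nx.havel_hakimi_graph(seq)
    if connected:
        graph = _connectify(graph)
        if not nx.is_connected(graph):
            raise GenerationError(f"no connected realization found for {seq}")
    return validate_graph(graph)


def _connectify(graph: nx.Graph) -> nx.Graph:
    """Merge components by degree-preserving swaps where possible."""
    graph = graph.copy()
    guard = graph.number_of_nodes() ** 2
    while not nx.is_connected(graph) and guard > 0:
        guard -= 1
        components = [list(c) for c in nx.connected_components(graph)]
        swapped = False
        first = set(components[0])
        edges_first = [e for e in graph.edges() if e[0] in first]
        edges_other = [e for e in graph.edges() if e[0] not in first]
        for (a, b) in edges_first:
            for (c, d) in edges_other:
                if not graph.has_edge(a, c) and not graph.has_edge(b, d):
                    graph.remove_edges_from([(a, b), (c, d)])
                    graph.add_edges_from([(a, c), (b, d)])
                    swapped = True
                    break
            if swapped:
                break
        if not swapped:
            break
    return graph


def sample_powerlaw_degrees(
    n: int, gamma: float, seed: int, kmin: int = 1
) -> np.ndarray:
    """Draw n degrees from the discrete power law P(k) ∝ k^(-γ), k >= kmin.

    Uses the zeta (Zipf) sampler; for kmin > 1 the support is shifted by
    sampling k' >= 1 and adding kmin - 1 to the exceedance ranks is *not*
    distribution-preserving, so kmin > 1 is realized by rejection below kmin.
    """
    if gamma <= 1:
        raise ValueError("gamma must exceed 1 for a normalizable law")
    from scipy.stats import zipf

    rng = np.random.default_rng(int(seed))
    if kmin == 1:
        return zipf.rvs(gamma, size=n, random_state=rng)
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = zipf.rvs(gamma, size=2 * (n - filled), random_state=rng)
        draw = draw[draw >= kmin]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out
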