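"""The heterogeneity-measure framework: three generic classes and the battery.

Measure classes
---------------
* **Global dispersion aggregation** — ``c * Σ_i g(k_i − h(K))``: deviations of
  all degrees from a network statistic h (maximum or mean).  Presets: HHG
  (Høivik–Gleditsch degree centralization), HF (Freeman's normalized version),
  HS (Snijders degree variance), HN (sum of absolute deviations), plus the
  density-normalized centralization HB and the φ-generalized variance.
* **Adjacent pairwise dispersion** — ``c * Σ_{{i,j}∈E} g(f(k_i) − f(k_j))``:
  differences across edges.  Presets: HA (Albertson irregularity) and HE
  (Estrada heterogeneity, f(k) = k^(-1/2)), with HE's normalized variant HE'.
* **Pairwise dispersion** — the same aggregation over all node pairs i < j:
  HAp and HEp.
* **Expected difference** — Gini-style expected absolute degree differences:
  HAED (edge-conditional) and HPED with the HHW (uniform node weights,
  c = 1/(2k̄)) and HL (degree-frequency weights, c = 1/k̄) presets.
* **Special** — HCS (Collatz–Sinogowitz spectral irregularity ℵ1 − k̄) and HJ
  (degree-diversity measure on the degree distribution) with its normalized
  variant HJ'.

Every evaluator accepts an optional ``degrees`` override (node → degree).
This supports the uniform-degree-addition manipulation in its "degree shift"
semantics, where the edge set is kept but all degrees are raised by c.

Conventions for the 12-measure battery (HN HS HF HHG HA HE HAp HEp HAED HPED
HJ HCS) are frozen in the registry; ``evaluate(name, graph)`` dispatches.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .graph_core import (
    DegreeDistribution,
    degree_distribution,
    spectral_radius,
    validate_graph,
)

__all__ = [
    "MeasureError",
    "MeasureSpec",
    "MeasureResult",
    "BATTERY",
    "REGISTRY",
    "evaluate",
    "eval_global_dispersion",
    "eval_adjacent_dispersion",
    "eval_pairwise_dispersion",
    "hhg",
    "hf",
    "hb",
    "hs",
    "hs_phi",
    "hs_normalized",
    "hn",
    "ha",
    "he",
    "he_normalized",
    "hap",
    "hep",
    "haed",
    "hhw",
    "hl",
    "hped",
    "hcs",
    "hj",
    "hj_normalized",
    "randic_index",
    "hhw_from_degrees",
    "mean_absolute_difference",
]


class MeasureError(ValueError):
    """A measure's applicability requirements are violated."""


@dataclass(frozen=True)
class MeasureSpec:
    """Declarative description of a measure's place in the framework."""

    name: str
    mclass: str  # global_dispersion | adjacent_dispersion | pairwise_dispersion
    #              | adjacent_expected | pairwise_expected | special
    c: str  # scaling rule, human-readable
    g: str  # aggregation function
    h: str = ""  # degree statistic (global dispersion only)
    f: str = "identity"  # degree transform (pairwise classes)
    prob: str = ""  # probability convention (expected-difference classes)
    requires: frozenset[str] = frozenset()
    func: Callable | None = field(default=None, compare=False, repr=False)


@dataclass
class MeasureResult:
    name: str
    value: float
    graph_id: str | None = None
    warnings: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# degree helpers

def _degree_array(graph: nx.Graph, degrees: Mapping | None) -> np.ndarray:
    if degrees is None:
        return np.asarray([d for _, d in graph.degree()], dtype=float)
    return np.asarray([degrees[v] for v in graph.nodes()], dtype=float)


def _node_degrees(graph: nx.Graph, degrees: Mapping | None) -> Mapping:
    return dict(graph.degree()) if degrees is None else degrees


def _check_no_isolated(k: np.ndarray, name: str, graph: nx.Graph | None = None,
                       degmap: Mapping | None = None) -> None:
    if np.any(k <= 0):
        node = ""
        if graph is not None and degmap is not None:
            for v in graph.nodes():
                if degmap[v] <= 0:
                    node = f" (node {v!r})"
                    break
        raise MeasureError(
            f"{name} uses the inverse-square-root degree transform and is "
            f"undefined on isolated nodes{node}"
        )


# --------------------------------------------------------------------------
# global dispersion aggregation:  c * Σ_i g(k_i − h(K))

def eval_global_dispersion(
    graph: nx.Graph,
    *,
    c: Callable[[np.ndarray, nx.Graph], float],
    g: Callable[[np.ndarray], np.ndarray],
    h: Callable[[np.ndarray], float],
    degrees: Mapping | None = None,
) -> float:
    """Generic class evaluator; the named presets below fix (c, g, h)."""
    k = _degree_array(graph, degrees)
    return float(c(k, graph) * np.sum(g(k - h(k))))


def hhg(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Degree centralization: Σ_i (kmax − k_i)."""
    k = _degree_array(graph, degrees)
    return float(np.sum(k.max() - k))


def hf(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Freeman's normalized degree centralization: HHG / ((n−1)(n−2)).

    The denominator is the maximum of HHG over all graphs on n nodes,
    attained by stars and wheels; HF therefore equals 1.0 exactly on stars.
    """
    n = graph.number_of_nodes()
    if n < 3:
        raise MeasureError(f"HF is undefined for n < 3 (denominator 0), got n={n}")
    return hhg(graph, degrees) / ((n - 1) * (n - 2))


def hb(graph: nx.Graph) -> MeasureResult:
    """Density-normalized centralization: excess of kmax over its minimum
    attainable value, relative to the maximum attainable excess at this (n, m).

    The minimum attainable maximum degree at (n, m) is ceil(2m/n) and the
    maximum is min(n−1, m).  When the two coincide (null and complete graphs,
    and any other (n, m) that forces kmax) the measure is defined as 0.
    """
    validate_graph(graph)
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    if n < 2:
        raise MeasureError("HB needs n >= 2")
    kmax = max(d for _, d in graph.degree())
    lo = math.ceil(2 * m / n)
    hi = min(n - 1, m)
    warnings: list[str] = []
    if hi == lo:
        warnings.append(
            "maximum degree is forced at this (n, m); degenerate 0/0 defined as 0"
        )
        value = 0.0
    else:
        value = (kmax - lo) / (hi - lo)
    return MeasureResult(name="HB", value=value, warnings=warnings)


def hs(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Snijders degree variance: n^{-1} Σ_i (k_i − k̄)^2."""
    k = _degree_array(graph, degrees)
    return float(np.mean((k - k.mean()) ** 2))


def hs_phi(graph: nx.Graph, phi: Callable[[np.ndarray], np.ndarray],
           degrees: Mapping | None = None) -> float:
    """φ-generalized dispersion n^{-1} Σ φ(k_i) − φ(k̄) for convex
    non-decreasing φ; φ(x) = x² recovers the degree variance."""
    k = _degree_array(graph, degrees)
    return float(np.mean(phi(k)) - float(np.asarray(phi(np.asarray([k.mean()])))[0]))


def _max_variance(n: int, m: int) -> float:
    """Maximum degree variance over all graphs with n nodes and m edges.

    Exhaustive over the atlas for n <= 7.  For larger n the extremal graphs
    consist of a group of high-degree (central) nodes, a group of low-degree
    (peripheral) nodes and at most one intermediate node; the search
    enumerates those group structures, keeps the graphical ones and is
    therefore approximate above n = 7.
    """
    if n <= 7:
        from .enumeration import graphs_with

        best = 0.0
        for candidate in graphs_with(n, m):
            k = np.asarray([d for _, d in candidate.degree()], dtype=float)
            best = max(best, float(np.mean((k - k.mean()) ** 2)))
        return best
    total = 2 * m
    best = 0.0
    for n_central in range(0, n):
        for hi in range(1, n):
            rest = total - n_central * hi
            n_side = n - n_central
            if rest < 0 or n_side == 0:
                continue
            lo, extra = divmod(rest, n_side)
            if lo < 0 or lo > hi:
                continue
            seq = [hi] * n_central + [lo + 1] * extra + [lo] * (n_side - extra)
            if max(seq) > n - 1 or not nx.is_graphical(seq):
                continue
            k = np.asarray(seq, dtype=float)
            best = max(best, float(np.mean((k - k.mean()) ** 2)))
    return best


def hs_normalized(graph: nx.Graph) -> MeasureResult:
    """HS' = HS divided by the maximum variance attainable at the same (n, m)."""
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    numerator = hs(graph)
    denominator = _max_variance(n, m)
    warnings = []
    if n > 7:
        warnings.append("HS' denominator is search-based (approximate) for n > 7")
    if denominator == 0.0:
        warnings.append("(n, m) forces regularity; HS' defined as 0")
        return MeasureResult("HS'", 0.0, warnings=warnings)
    return MeasureResult("HS'", numerator / denominator, warnings=warnings)


def hn(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Σ_i |k_i − k̄| — total absolute deviation from the mean degree."""
    k = _degree_array(graph, degrees)
    return float(np.sum(np.abs(k - k.mean())))


# --------------------------------------------------------------------------
# adjacent pairwise dispersion:  c * Σ_{{i,j}∈E} g(f(k_i) − f(k_j))

def eval_adjacent_dispersion(
    graph: nx.Graph,
    *,
    g: Callable[[float], float],
    f: Callable[[float], float] = lambda x: x,
    c: float = 1.0,
    degrees: Mapping | None = None,
) -> float:
    degmap = _node_degrees(graph, degrees)
    return c * sum(g(f(degmap[u]) - f(degmap[v])) for u, v in graph.edges())


def ha(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Albertson irregularity: Σ over edges of |k_i − k_j|."""
    degmap = _node_degrees(graph, degrees)
    return float(sum(abs(degmap[u] - degmap[v]) for u, v in graph.edges()))


def he(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Estrada heterogeneity: Σ over edges of (k_i^{-1/2} − k_j^{-1/2})^2.

    Undefined on graphs with isolated nodes; on graphs without them it obeys
    the Randić identity HE = n − 2·R_{−1/2}.
    """
    degmap = _node_degrees(graph, degrees)
    k = _degree_array(graph, degrees)
    _check_no_isolated(k, "HE", graph, degmap)
    return float(
        sum(
            (degmap[u] ** -0.5 - degmap[v] ** -0.5) ** 2
            for u, v in graph.edges()
        )
    )


def randic_index(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """R_{−1/2} = Σ over edges of (k_i k_j)^{-1/2}."""
    degmap = _node_degrees(graph, degrees)
    return float(sum((degmap[u] * degmap[v]) ** -0.5 for u, v in graph.edges()))


def he_normalized(graph: nx.Graph) -> float:
    """HE' = (n − 2 R_{−1/2}) / (n − 2 √(n−1)) ∈ [0, 1]; 1 on stars, 0 on
    regular graphs.  Needs n >= 3 and no isolated nodes."""
    n = graph.number_of_nodes()
    if n <= 2:
        raise MeasureError(f"HE' is undefined for n <= 2, got n={n}")
    k = _degree_array(graph, None)
    _check_no_isolated(k, "HE'", graph, dict(graph.degree()))
    return (n - 2.0 * randic_index(graph)) / (n - 2.0 * math.sqrt(n - 1))


# --------------------------------------------------------------------------
# pairwise dispersion:  c * Σ_{i<j} g(f(k_i) − f(k_j))

def eval_pairwise_dispersion(
    graph: nx.Graph,
    *,
    g: Callable[[float], float],
    f: Callable[[float], float] = lambda x: x,
    c: float = 1.0,
    degrees: Mapping | None = None,
) -> float:
    k = _degree_array(graph, degrees)
    n = len(k)
    return c * float(
        sum(g(f(k[i]) - f(k[j])) for i in range(n) for j in range(i + 1, n))
    )


def _pairwise_abs_sum(values: np.ndarray) -> float:
    """Σ_{i<j} |x_i − x_j| in O(n log n) via the sorted-rank identity."""
    x = np.sort(values)
    n = len(x)
    coeff = 2.0 * np.arange(n) - (n - 1)
    return float(np.dot(coeff, x))


def hap(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Adapted Albertson over all node pairs: Σ_{i<j} |k_i − k_j|."""
    return _pairwise_abs_sum(_degree_array(graph, degrees))


def hep(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Adapted Estrada over all node pairs: Σ_{i<j} (k_i^{-1/2} − k_j^{-1/2})^2."""
    k = _degree_array(graph, degrees)
    _check_no_isolated(k, "HEp", graph, _node_degrees(graph, degrees))
    f = k ** -0.5
    n = len(f)
    # Σ_{i<j} (f_i − f_j)^2 = n Σ f² − (Σ f)²
    return float(n * np.sum(f**2) - np.sum(f) ** 2)


# --------------------------------------------------------------------------
# expected difference (Gini-type)

def haed(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Adjacent expected difference.

    The conditional probability that a random existing edge joins degrees
    (k, l) is estimated by the empirical unordered degree-pair frequency among
    the m edges; with scaling c = 1 the measure is
    Σ_edges |k_i − k_j| · freq(pair) = (1/m) Σ_pairs count(k,l)^2 |k − l|.
    """
    m = graph.number_of_edges()
    if m == 0:
        raise MeasureError("HAED is undefined on an empty edge set")
    degmap = _node_degrees(graph, degrees)
    pair_counts: Counter = Counter()
    for u, v in graph.edges():
        a, b = degmap[u], degmap[v]
        pair_counts[(a, b) if a <= b else (b, a)] += 1
    return float(
        sum(cnt * cnt * abs(k - l) for (k, l), cnt in pair_counts.items()) / m
    )


def mean_absolute_difference(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """E|X − Y| for independent X, Y with atoms ``values`` and ``weights``.

    Ordered-pair convention (the i = j diagonal contributes 0).  Uniform
    weights 1/n when ``weights`` is None.  O(n log n) via prefix sums.
    """
    x = np.asarray(values, dtype=float)
    w = (
        np.full(len(x), 1.0 / len(x))
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    order = np.argsort(x, kind="stable")
    x, w = x[order], w[order]
    cw = np.concatenate([[0.0], np.cumsum(w)])[:-1]  # W_{<i}
    cwx = np.concatenate([[0.0], np.cumsum(w * x)])[:-1]  # Σ_{<i} w x
    # Σ_{i<j} w_i w_j (x_j − x_i), doubled for ordered pairs
    return 2.0 * float(np.sum(w * (x * cw - cwx)))


def _degree_weights(k: np.ndarray) -> np.ndarray:
    """Per-node weights P(k_i) = n_{k_i}/n (degree-frequency convention)."""
    values, inverse, counts = np.unique(k, return_inverse=True, return_counts=True)
    return counts[inverse] / len(k)


def hhw_from_degrees(degrees: Sequence[float]) -> float:
    """HHW evaluated directly on a degree sequence (Gini coefficient form)."""
    k = np.asarray(degrees, dtype=float)
    kbar = k.mean()
    if kbar == 0:
        raise MeasureError("HHW is undefined when the mean degree is 0")
    return mean_absolute_difference(k) / (2.0 * kbar)


def hhw(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Hu–Wang degree Gini coefficient:
    (1/(2k̄)) Σ_{i,j∈V} |k_i − k_j| (1/n)(1/n) ∈ [0, 1]."""
    return hhw_from_degrees(_degree_array(graph, degrees))


def hl_from_degrees(degrees: Sequence[float]) -> float:
    k = np.asarray(degrees, dtype=float)
    kbar = k.mean()
    if kbar == 0:
        raise MeasureError("HL is undefined when the mean degree is 0")
    w = _degree_weights(k)
    return mean_absolute_difference(k, w) / kbar


def hl(graph: nx.Graph, degrees: Mapping | None = None) -> float:
    """Liu et al. relative mean absolute difference with degree-frequency
    weights P(k) = n_k/n attached to each node term: (1/k̄) Σ_{i,j∈V}
    |k_i − k_j| P(k_i) P(k_j), ordered node pairs."""
    return hl_from_degrees(_degree_array(graph, degrees))


def hped(graph: nx.Graph, preset: str = "HL", degrees: Mapping | None = None) -> float:
    """Pairwise expected difference; the battery preset is the HL convention."""
    if preset.upper() == "HL" or preset.upper() == "HPED":
        return hl(graph, degrees)
    if preset.upper() == "HHW":
        return hhw(graph, degrees)
    raise ValueError(f"unknown HPED preset {preset!r}; use 'HL' or 'HHW'")


# --------------------------------------------------------------------------
# special measures

def hcs(graph: nx.Graph, tol: float = 1e-10) -> float:
    """Collatz–Sinogowitz spectral irregularity ℵ1 − k̄.

    Zero iff the graph is regular; requires a connected graph (the k̄ <= ℵ1
    bound underpinning non-negativity holds for connected graphs).
    """
    validate_graph(graph)
    if not nx.is_connected(graph):
        raise MeasureError("HCS requires a connected graph")
    kbar = 2.0 * graph.number_of_edges() / graph.number_of_nodes()
    return spectral_radius(graph, tol=tol) - kbar


def hj(
    source: nx.Graph | DegreeDistribution,
    degrees: Mapping | None = None,
) -> float:
    """Degree-diversity measure: (1/n) Σ_{k: P(k)>0} (1 − P(k))^2.

    Zero for a single degree value (regular graphs); maximal for completely
    diverse degree multisets, where it equals 1 − 3/n + (n+2)/n^3.
    """
    if isinstance(source, DegreeDistribution):
        dist = source
    elif degrees is not None:
        dist = degree_distribution([degrees[v] for v in source.nodes()])
    else:
        dist = degree_distribution(source)
    n = dist.n
    return sum((1.0 - nk / n) ** 2 for nk in dist.counts.values()) / n


def hj_distribution_form(
    source: nx.Graph | DegreeDistribution,
    degrees: Mapping | None = None,
) -> float:
    """Degree diversity as a pure functional of the distribution:
    Σ_{k: P(k)>0} (1 − P(k))^2 (i.e. n · HJ).

    Dropping the per-node scaling makes the value depend on P alone, so it is
    invariant under network replication — the behaviour the diversity view of
    heterogeneity requires — while ranking graphs identically to HJ at any
    fixed n.  This is the battery convention for the "HJ" entry.
    """
    if isinstance(source, DegreeDistribution):
        dist = source
    elif degrees is not None:
        dist = degree_distribution([degrees[v] for v in source.nodes()])
    else:
        dist = degree_distribution(source)
    return dist.n * hj(dist)


def hj_normalized(
    source: nx.Graph | DegreeDistribution, exact_denominator: bool = True
) -> float:
    """HJ' = HJ normalized by the complete-heterogeneity value.

    The exact denominator 1 − 3/n + (n+2)/n^3 guarantees HJ' ∈ [0, 1] with 1
    attained by completely diverse degree multisets; ``exact_denominator=False``
    uses the large-n approximation 1 − 3/n instead.
    """
    dist = source if isinstance(source, DegreeDistribution) else degree_distribution(source)
    n = dist.n
    if n < 4:
        raise MeasureError(f"HJ' normalization needs n >= 4, got n={n}")
    if exact_denominator:
        denom = 1.0 - 3.0 / n + (n + 2.0) / n**3
    else:
        denom = 1.0 - 3.0 / n
    return hj(dist) / denom


# --------------------------------------------------------------------------
# registry and dispatcher

BATTERY: tuple[str, ...] = (
    "HN", "HS", "HF", "HHG", "HA", "HE",
    "HAp", "HEp", "HAED", "HPED", "HJ", "HCS",
)

REGISTRY: dict[str, MeasureSpec] = {
    spec.name: spec
    for spec in [
        MeasureSpec("HN", "global_dispersion", c="1", g="absolute", h="mean", func=hn),
        MeasureSpec("HS", "global_dispersion", c="1/n", g="square", h="mean", func=hs),
        MeasureSpec("HF", "global_dispersion", c="1/((n-1)(n-2))", g="identity",
                    h="max", requires=frozenset({"n_ge_3"}), func=hf),
        MeasureSpec("HHG", "global_dispersion", c="1", g="identity", h="max", func=hhg),
        MeasureSpec("HA", "adjacent_dispersion", c="1", g="absolute", func=ha),
        MeasureSpec("HE", "adjacent_dispersion", c="1", g="square",
                    f="inverse_sqrt", requires=frozenset({"no_isolated_nodes"}),
                    func=he),
        MeasureSpec("HAp", "pairwise_dispersion", c="1", g="absolute", func=hap),
        MeasureSpec("HEp", "pairwise_dispersion", c="1", g="square",
                    f="inverse_sqrt", requires=frozenset({"no_isolated_nodes"}),
                    func=hep),
        MeasureSpec("HAED", "adjacent_expected", c="1", g="absolute",
                    prob="edge-empirical", func=haed),
        MeasureSpec("HPED", "pairwise_expected", c="1/mean_degree", g="absolute",
                    prob="degree-frequency", func=hl),
        MeasureSpec("HHW", "pairwise_expected", c="1/(2 mean_degree)", g="absolute",
                    prob="uniform-node", func=hhw),
        MeasureSpec("HJ", "special", c="1", g="square", prob="degree-frequency",
                    func=hj_distribution_form),
        MeasureSpec("HCS", "special", c="1", g="identity",
                    requires=frozenset({"connected"}), func=hcs),
        MeasureSpec("HB", "global_dispersion", c="density-normalized", g="identity",
                    h="max", func=lambda graph, degrees=None: hb(graph).value),
        MeasureSpec("HE'", "adjacent_dispersion", c="1/(n-2*sqrt(n-1))", g="square",
                    f="inverse_sqrt",
                    requires=frozenset({"no_isolated_nodes", "n_ge_3"}),
                    func=lambda graph, degrees=None: he_normalized(graph)),
    ]
}

# measures that can take a shifted degree map (degree-shift addition semantics)
DEGREE_SHIFT_CAPABLE: frozenset[str] = frozenset(
    {"HN", "HS", "HF", "HHG", "HA", "HE", "HAp", "HEp", "HPED", "HHW", "HJ"}
)


def evaluate(
    name: str,
    graph: nx.Graph,
    degrees: Mapping | None = None,
    graph_id: str | None = None,
) -> MeasureResult:
    """Evaluate a registered measure under the frozen battery conventions."""
    spec = REGISTRY.get(name)
    if spec is None:
        raise KeyError(
            f"unknown measure {name!r}; available: {', '.join(sorted(REGISTRY))}"
        )
    if degrees is not None and name not in DEGREE_SHIFT_CAPABLE:
        raise MeasureError(f"{name} does not support an explicit degree override")
    if name in ("HCS", "HB", "HE'"):
        value = spec.func(graph)
    else:
        value = spec.func(graph, degrees)
    return MeasureResult(name=name, value=float(value), graph_id=graph_id)


def registry_export() -> dict:
    """JSON-ready description of the registered measures."""
    return {
        name: {
            "class": spec.mclass,
            "c": spec.c,
            "g": spec.g,
            "h": spec.h,
            "f": spec.f,
            "prob": spec.prob,
            "requires": sorted(spec.requires),
        }
        for name, spec in REGISTRY.items()
    }
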