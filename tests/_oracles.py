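"""Naive brute-force reference implementations of every battery measure.

Each function recomputes a measure by direct summation over nodes, node
pairs or edges (and a dense eigensolver for the spectral measure), staying
deliberately independent of the optimized evaluators it is used to check.
"""

import networkx as nx
import numpy as np


def brute(name: str, graph: nx.Graph) -> float:
    k = {v: graph.degree(v) for v in graph.nodes()}
    ks = list(k.values())
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    mean = sum(ks) / n
    kmax = max(ks)
    if name == "HN":
        return sum(abs(x - mean) for x in ks)
    if name == "HS":
        return sum((x - mean) ** 2 for x in ks) / n
    if name == "HHG":
        return sum(kmax - x for x in ks)
    if name == "HF":
        return sum(kmax - x for x in ks) / ((n - 1) * (n - 2))
    if name == "HA":
        return sum(abs(k[u] - k[v]) for u, v in graph.edges())
    if name == "HE":
        return sum((k[u] ** -0.5 - k[v] ** -0.5) ** 2 for u, v in graph.edges())
    nodes = list(graph.nodes())
    if name == "HAp":
        return sum(
            abs(k[u] - k[v]) for i, u in enumerate(nodes) for v in nodes[i + 1 :]
        )
    if name == "HEp":
        return sum(
            (k[u] ** -0.5 - k[v] ** -0.5) ** 2
            for i, u in enumerate(nodes)
            for v in nodes[i + 1 :]
        )
    if name == "HAED":
        from collections import Counter

        pairs = Counter(tuple(sorted((k[u], k[v]))) for u, v in graph.edges())
        return sum(
            abs(a - b) * cnt * (cnt / m) for (a, b), cnt in pairs.items()
        )
    if name == "HPED":
        from collections import Counter

        freq = Counter(ks)
        p = {d: c / n for d, c in freq.items()}
        total = sum(
            abs(k[u] - k[v]) * p[k[u]] * p[k[v]] for u in nodes for v in nodes
        )
        return total / mean
    if name == "HJ":
        from collections import Counter

        freq = Counter(ks)
        return sum((1 - c / n) ** 2 for c in freq.values())
    if name == "HCS":
        return float(np.linalg.eigvalsh(nx.to_numpy_array(graph)).max()) - mean
    raise KeyError(name)
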