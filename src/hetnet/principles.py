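"""Principle-compliance engine for heterogeneity measures.

Three behavioural principles are checked for every measure of the battery:

* **transfer** — every admissible transfer rewiring must *strictly* decrease
  the measure (a no-change outcome is a violation);
* **addition** — raising every degree by the same constant must not increase
  the measure, under per-measure addition semantics (see below);
* **replication** — a disjoint union of x copies must leave the measure
  unchanged; a measure that cannot evaluate the replicated (disconnected)
  graph fails with that error as its witness.

A "pass" verdict is universally quantified over a finite battery: the default
battery is every connected graph on up to six nodes (exhaustive, via the
graph atlas), the committed witness fixtures, and 200 seeded random graphs on
up to twelve nodes.  Passing certifies that no violation was found on that
battery; failing carries a concrete witness that replays to the same values.

Addition semantics per measure: most measures compare against an explicit
shifted degree map on the unchanged edge set (``degree_shift``).  HAED sees a
true c-regular edge-disjoint ``overlay`` because its edge-conditional
probabilities react to the newly formed edges.  HCS sees a ``rewire``
re-realization of the shifted degree sequence: a supergraph overlay can never
raise the spectral radius by more than c, so the only reading under which the
principle is informative for HCS lets the new edges connect freely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np

from .enumeration import connected_graphs
from .manipulations import (
    OverlayError,
    TransferMove,
    apply_addition,
    apply_transfer,
    enumerate_transfers,
    replicate,
)
from .measures import BATTERY, MeasureError, evaluate

__all__ = [
    "PRINCIPLES",
    "ADDITION_SEMANTICS",
    "Witness",
    "ComplianceVerdict",
    "ComplianceMatrix",
    "witness_fixtures",
    "default_battery",
    "check_transfer",
    "check_addition",
    "check_replication",
    "compliance_matrix",
    "replay_witness",
]

PRINCIPLES: tuple[str, ...] = ("transfer", "addition", "replication")

ADDITION_SEMANTICS: dict[str, str] = {
    **{name: "degree_shift" for name in BATTERY},
    "HAED": "overlay",
    "HCS": "rewire",
}

#: double-edge-swap randomization seeds tried per graph for rewire additions
REWIRE_SEEDS: tuple[int, ...] = tuple(range(16))

TOL = 1e-9


@dataclass(frozen=True)
class Witness:
    """A concrete violation: graph, manipulation, before/after values."""

    nodes: tuple
    edges: tuple
    manipulation: str  # "transfer" | "addition" | "replication"
    params: dict
    before: float | None
    after: float | None
    error: str | None = None

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def to_json(self) -> dict:
        return {
            "nodes": [str(v) for v in self.nodes],
            "edges": [[str(u), str(v)] for u, v in self.edges],
            "manipulation": self.manipulation,
            "params": {k: str(v) for k, v in self.params.items()},
            "before": self.before,
            "after": self.after,
            "error": self.error,
        }


@dataclass
class ComplianceVerdict:
    measure: str
    principle: str
    passed: bool
    witness: Witness | None = None
    graphs_examined: int = 0
    cases_examined: int = 0
    skipped: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "measure": self.measure,
            "principle": self.principle,
            "pass": self.passed,
            "witness": self.witness.to_json() if self.witness else None,
            "graphs_examined": self.graphs_examined,
            "cases_examined": self.cases_examined,
            "skipped": len(self.skipped),
        }


@dataclass
class ComplianceMatrix:
    """measure x principle verdicts with summary tallies."""

    verdicts: dict[tuple[str, str], ComplianceVerdict]
    measures: tuple[str, ...]

    def verdict(self, measure: str, principle: str) -> ComplianceVerdict:
        return self.verdicts[(measure, principle)]

    def row(self, measure: str) -> dict[str, bool]:
        return {p: self.verdicts[(measure, p)].passed for p in PRINCIPLES}

    def passing_all(self) -> list[str]:
        return [m for m in self.measures if all(self.row(m).values())]

    def passing_none(self) -> list[str]:
        return [m for m in self.measures if not any(self.row(m).values())]

    def principle_pass_count(self, principle: str) -> int:
        return sum(self.verdicts[(m, principle)].passed for m in self.measures)

    def to_json(self) -> dict:
        return {
            "verdicts": [v.to_json() for v in self.verdicts.values()],
            "summary": {
                "passing_all_three": self.passing_all(),
                "passing_none": self.passing_none(),
                "per_principle_pass_counts": {
                    p: self.principle_pass_count(p) for p in PRINCIPLES
                },
            },
        }

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_json(), handle, indent=2)


# --------------------------------------------------------------------------
# battery assembly

def witness_fixtures() -> list[nx.Graph]:
    """The committed curated witness graphs (searched stand-ins for the
    counter-example networks that exist only as figures)."""
    graphs = []
    root = resources.files("hetnet").joinpath("data/witnesses")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if not entry.name.endswith(".edgelist"):
            continue
        g = nx.Graph()
        for line in entry.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split()
            g.add_edge(u, v)
        g.graph["fixture"] = entry.name
        graphs.append(g)
    return graphs


def random_battery(n_graphs: int = 200, max_n: int = 12, seed: int = 2024) -> list[nx.Graph]:
    rng = np.random.default_rng(seed)
    graphs = []
    while len(graphs) < n_graphs:
        n = int(rng.integers(4, max_n + 1))
        p = float(rng.uniform(0.2, 0.7))
        graphs.append(nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31))))
    return graphs


def default_battery(seed: int = 2024, n_random: int = 200) -> list[nx.Graph]:
    """Curated fixtures first (cheap short-circuits), then exhaustive
    connected graphs on <= 6 nodes, then seeded random graphs on <= 12."""
    return witness_fixtures() + connected_graphs(6) + random_battery(n_random, seed=seed)


# --------------------------------------------------------------------------
# generic machinery

def _safe_value(measure: str, graph: nx.Graph, degrees=None) -> float | None:
    try:
        return evaluate(measure, graph, degrees=degrees).value
    except MeasureError:
        return None


def _graph_key(graph: nx.Graph) -> str:
    return graph.graph.get("fixture", f"n={graph.number_of_nodes()},m={graph.number_of_edges()}")


def _make_witness(graph, manipulation, params, before, after, error=None) -> Witness:
    return Witness(
        nodes=tuple(graph.nodes()),
        edges=tuple(tuple(e) for e in graph.edges()),
        manipulation=manipulation,
        params=params,
        before=before,
        after=after,
        error=error,
    )


def check_transfer(
    measure: str, battery: list[nx.Graph], tol: float = TOL
) -> ComplianceVerdict:
    """Pass iff every admissible move on every battery graph strictly
    decreases the measure; the first violation becomes the witness."""
    verdict = ComplianceVerdict(measure=measure, principle="transfer", passed=True)
    for graph in battery:
        before = _safe_value(measure, graph)
        if before is None:
            verdict.skipped.append(_graph_key(graph))
            continue
        verdict.graphs_examined += 1
        for move in enumerate_transfers(graph):
            verdict.cases_examined += 1
            after = _safe_value(measure, apply_transfer(graph, move))
            if after is None:
                continue
            if not (before - after > tol):  # strict decrease required
                verdict.passed = False
                verdict.witness = _make_witness(
                    graph, "transfer",
                    {"pivot": move.pivot, "from_node": move.from_node,
                     "to_node": move.to_node},
                    before, after,
                )
                return verdict
    return verdict


def _addition_values(measure: str, graph: nx.Graph, c: int):
    """Yield (params, after-value) for each addition realization tried."""
    semantics = ADDITION_SEMANTICS[measure]
    if semantics == "degree_shift":
        result = apply_addition(graph, c, "degree_shift")
        yield {"semantics": semantics, "c": c}, _safe_value(
            measure, result.graph, degrees=result.degrees
        )
    elif semantics == "overlay":
        result = apply_addition(graph, c, "overlay", seed=0)
        yield {"semantics": semantics, "c": c, "seed": 0}, _safe_value(
            measure, result.graph
        )
    elif semantics == "rewire":
        for seed in REWIRE_SEEDS:
            result = apply_addition(graph, c, "rewire", seed=seed)
            yield {"semantics": semantics, "c": c, "seed": seed}, _safe_value(
                measure, result.graph
            )
    else:  # pragma: no cover
        raise ValueError(semantics)


def check_addition(
    measure: str,
    battery: list[nx.Graph],
    c_values: tuple[int, ...] = (1, 2),
    tol: float = TOL,
) -> ComplianceVerdict:
    """Pass iff no addition realization increases the measure (no-change is
    allowed); infeasible overlays/rewires are skipped with a log entry."""
    verdict = ComplianceVerdict(measure=measure, principle="addition", passed=True)
    for graph in battery:
        before = _safe_value(measure, graph)
        if before is None:
            verdict.skipped.append(_graph_key(graph))
            continue
        verdict.graphs_examined += 1
        for c in c_values:
            try:
                for params, after in _addition_values(measure, graph, c):
                    verdict.cases_examined += 1
                    if after is None:
                        continue
                    if after > before + tol:
                        verdict.passed = False
                        verdict.witness = _make_witness(
                            graph, "addition", params, before, after
                        )
                        return verdict
            except OverlayError as exc:
                verdict.skipped.append(f"{_graph_key(graph)} c={c}: {exc}")
    return verdict


def check_replication(
    measure: str,
    battery: list[nx.Graph],
    factors: tuple[int, ...] = (2, 3),
    tol: float = TOL,
) -> ComplianceVerdict:
    """Pass iff value(replicate(G, x)) == value(G) within tol; a measure that
    errors on the replicated (disconnected) graph fails with that error."""
    verdict = ComplianceVerdict(measure=measure, principle="replication", passed=True)
    for graph in battery:
        before = _safe_value(measure, graph)
        if before is None:
            verdict.skipped.append(_graph_key(graph))
            continue
        verdict.graphs_examined += 1
        for x in factors:
            verdict.cases_examined += 1
            replicated = replicate(graph, x)
            try:
                after = evaluate(measure, replicated).value
            except MeasureError as exc:
                verdict.passed = False
                verdict.witness = _make_witness(
                    graph, "replication", {"x": x}, before, None, error=str(exc)
                )
                return verdict
            if abs(after - before) > tol:
                verdict.passed = False
                verdict.witness = _make_witness(
                    graph, "replication", {"x": x}, before, after
                )
                return verdict
    return verdict


_CHECKS = {
    "transfer": check_transfer,
    "addition": check_addition,
    "replication": check_replication,
}


def compliance_matrix(
    measures: tuple[str, ...] = BATTERY,
    battery: list[nx.Graph] | None = None,
) -> ComplianceMatrix:
    """Full measure x principle verdict matrix over the battery."""
    if battery is None:
        battery = default_battery()
    verdicts = {}
    for measure in measures:
        for principle, checker in _CHECKS.items():
            verdicts[(measure, principle)] = checker(measure, battery)
    return ComplianceMatrix(verdicts=verdicts, measures=tuple(measures))


def replay_witness(measure: str, witness: Witness) -> tuple[float | None, float | None]:
    """Recompute a witness's before/after values from its stored graph."""
    graph = witness.graph()
    before = _safe_value(measure, graph)
    if witness.manipulation == "transfer":
        move = TransferMove(
            witness.params["pivot"], witness.params["from_node"],
            witness.params["to_node"],
        )
        after = _safe_value(measure, apply_transfer(graph, move))
    elif witness.manipulation == "addition":
        result = apply_addition(
            graph, int(witness.params["c"]), witness.params["semantics"],
            seed=int(witness.params.get("seed", 0)),
        )
        after = _safe_value(measure, result.graph, degrees=result.degrees)
    elif witness.manipulation == "replication":
        try:
            after = evaluate(measure, replicate(graph, int(witness.params["x"]))).value
        except MeasureError:
            after = None
    else:  # pragma: no cover
        raise ValueError(witness.manipulation)
    return before, after
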