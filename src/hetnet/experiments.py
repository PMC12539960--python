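"""Scaled reproductions of the three empirical studies.

* **Model sweep** — Erdős–Rényi versus power-law graphs over a grid of mean
  degrees (and degree exponents for the power law), evaluating the measure
  battery on every draw.  Desk scale uses n = 10^4 nodes and 5 replicates per
  cell; the full design (n = 10^5, mean degrees 2–50, γ ∈ {4, 3, 2.5, 2.2},
  100 replicates) is available through the config.
* **Regular-graph zero suite** — every battery measure must vanish on every
  regular family supplied (cycles, circulants, complete graphs).
* **Star–diverse comparison** — the battery evaluated on the smallest
  non-trivial star and completely diverse graphs (orders 4–7), min–max
  normalized per measure.

Outputs are tidy pandas DataFrames (one row per graph x measure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .generators import gen_diverse, gen_er, gen_named, gen_powerlaw
from .graph_core import graph_stats
from .measures import BATTERY, MeasureError, evaluate

__all__ = [
    "SweepConfig",
    "run_model_sweep",
    "minmax_normalize",
    "regular_zero_suite",
    "star_diverse_comparison",
]

_FULL = dict(n=100_000, mean_degrees=(2, 5, 10, 20, 50), runs=100)
_DESK = dict(n=10_000, mean_degrees=(2, 10, 50), runs=5)


@dataclass
class SweepConfig:
    """Design of the ER/power-law sweep.

    ``scale="desk"`` (default) keeps runtimes in minutes on one core;
    ``scale="full"`` mirrors the original design.  Explicit field values
    override the scale presets.
    """

    scale: str = "desk"
    n: int | None = None
    mean_degrees: tuple[float, ...] | None = None
    gammas: tuple[float, ...] = (4.0, 3.0, 2.5, 2.2)
    runs: int | None = None
    seed: int = 1
    measures: tuple[str, ...] = BATTERY

    def __post_init__(self) -> None:
        preset = _DESK if self.scale == "desk" else _FULL
        if self.scale not in ("desk", "full"):
            raise ValueError(f"scale must be 'desk' or 'full', got {self.scale!r}")
        if self.n is None:
            self.n = preset["n"]
        if self.mean_degrees is None:
            self.mean_degrees = tuple(preset["mean_degrees"])
        if self.runs is None:
            self.runs = preset["runs"]


def _eval_cell(measure: str, graph: nx.Graph) -> float:
    """Battery evaluation with the sweep's applicability conventions: on a
    disconnected draw HCS is computed on the largest connected component, and
    the inverse-square-root measures (HE, HEp) drop isolated nodes; both
    restrictions are logged as warnings."""
    try:
        return evaluate(measure, graph).value
    except MeasureError:
        if measure == "HCS":
            component = max(nx.connected_components(graph), key=len)
            warnings.warn(
                "HCS evaluated on the largest connected component "
                f"({len(component)}/{graph.number_of_nodes()} nodes)",
                UserWarning,
                stacklevel=2,
            )
            return evaluate(measure, graph.subgraph(component).copy()).value
        if measure in ("HE", "HEp", "HE'"):
            keep = [v for v, d in graph.degree() if d > 0]
            warnings.warn(
                f"{measure} evaluated on the {len(keep)} non-isolated nodes "
                f"(of {graph.number_of_nodes()})",
                UserWarning,
                stacklevel=2,
            )
            return evaluate(measure, graph.subgraph(keep).copy()).value
        raise


def run_model_sweep(config: SweepConfig | None = None) -> pd.DataFrame:
    """Long-form table (model, gamma, mean_degree, replicate, measure, value,
    normalized) for the ER/power-law experiment; deterministic given the seed.

    Power-law draws are edge-matched to the paired ER draw of the same cell
    so both models have identical density.
    """
    config = config or SweepConfig()
    rows = []
    seed_stream = np.random.default_rng(config.seed)
    for lam in config.mean_degrees:
        for run in range(config.runs):
            run_seed = int(seed_stream.integers(2**31))
            er = gen_er(config.n, lam, seed=run_seed)
            m_target = er.number_of_edges()
            draws = [("ER", None, er)]
            for gamma in config.gammas:
                draws.append(
                    ("PL", gamma,
                     gen_powerlaw(config.n, gamma, m_target, seed=run_seed))
                )
            for model, gamma, graph in draws:
                for measure in config.measures:
                    rows.append(
                        {
                            "model": model,
                            "gamma": gamma,
                            "mean_degree": lam,
                            "replicate": run,
                            "measure": measure,
                            "value": _eval_cell(measure, graph),
                        }
                    )
    result = pd.DataFrame(rows)
    return minmax_normalize(result)


def minmax_normalize(
    table: pd.DataFrame, value_col: str = "value", by: str = "measure"
) -> pd.DataFrame:
    """Append a ``normalized`` column: (v − min)/(max − min) within each
    measure across the whole table; a constant column maps to 0 with a warning."""
    table = table.copy()

    def _scale(group: pd.Series) -> pd.Series:
        lo, hi = group.min(), group.max()
        if hi == lo:
            warnings.warn(
                "constant value column during min-max normalization; "
                "normalized values set to 0",
                UserWarning,
                stacklevel=2,
            )
            return pd.Series(0.0, index=group.index)
        return (group - lo) / (hi - lo)

    table["normalized"] = table.groupby(by, group_keys=False)[value_col].apply(_scale)
    return table


DEFAULT_REGULAR_FAMILIES: tuple[tuple[str, dict], ...] = (
    ("C5", {"family": "cycle", "n": 5}),
    ("C8", {"family": "cycle", "n": 8}),
    ("3-regular n=8", {"family": "regular", "n": 8, "r": 3}),
    ("K6", {"family": "complete", "n": 6}),
)


def regular_zero_suite(
    measures: tuple[str, ...] = BATTERY,
    families: tuple[tuple[str, dict], ...] = DEFAULT_REGULAR_FAMILIES,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Evaluate every measure on every regular family and assert |value| <= tol.

    Raises AssertionError naming the first offending (measure, graph) pair;
    returns the full table when all pass.
    """
    rows = []
    for label, spec in families:
        graph = gen_named(**spec)
        for measure in measures:
            value = evaluate(measure, graph).value
            rows.append({"graph": label, "measure": measure, "value": value})
            assert abs(value) <= tol, (
                f"regular-graph zero violated: {measure}({label}) = {value!r}"
            )
    return pd.DataFrame(rows)


def star_diverse_comparison(
    measures: tuple[str, ...] = BATTERY, sizes: tuple[int, ...] = (4, 5, 6, 7)
) -> pd.DataFrame:
    """Battery values on stars versus completely diverse graphs of orders
    4..7, min-max normalized per measure across the whole comparison.

    Column labels carry (n) for stars and (n, m) for diverse graphs together
    with the density, since diverse fixtures are denser than stars.
    """
    rows = []
    for n in sizes:
        for kind in ("diverse", "star"):
            graph = gen_diverse(n) if kind == "diverse" else gen_named("star", n=n)
            stats = graph_stats(graph)
            label = f"{kind}({stats.n},{stats.m})"
            for measure in measures:
                rows.append(
                    {
                        "graph": label,
                        "kind": kind,
                        "n": stats.n,
                        "m": stats.m,
                        "density": stats.density,
                        "measure": measure,
                        "value": evaluate(measure, graph).value,
                    }
                )
    return minmax_normalize(pd.DataFrame(rows))
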