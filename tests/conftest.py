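"""Shared small-graph fixtures.

D4 is the 4-node graph with edges {12, 23, 34, 24} and degree sequence
(1, 3, 2, 2) — the running worked example: it is completely diverse, so it
doubles as the smallest maximal-diversity fixture.
"""

import networkx as nx
import pytest


@pytest.fixture
def star4() -> nx.Graph:
    return nx.star_graph(3)  # 4 nodes: hub 0 + 3 leaves


@pytest.fixture
def cycle4() -> nx.Graph:
    return nx.cycle_graph(4)


@pytest.fixture
def cycle6() -> nx.Graph:
    return nx.cycle_graph(6)


@pytest.fixture
def d4() -> nx.Graph:
    return nx.Graph([(1, 2), (2, 3), (3, 4), (2, 4)])


@pytest.fixture
def k4() -> nx.Graph:
    return nx.complete_graph(4)
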