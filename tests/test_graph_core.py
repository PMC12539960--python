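"""Graph container, statistics, spectral radius and I/O round trips."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hetnet.graph_core import (
    GraphFormatError,
    GraphValidationError,
    degree_distribution,
    degree_sequence,
    graph_stats,
    load_graph,
    save_graph,
    spectral_radius,
)


class TestLoadSave:
    def test_edgelist_star(self, tmp_path):
        path = tmp_path / "s4.edgelist"
        path.write_text("1 2\n1 3\n1 4\n")
        graph = load_graph(str(path))
        assert graph.number_of_nodes() == 4
        assert graph.number_of_edges() == 3
        assert sorted(d for _, d in graph.degree()) == [1, 1, 1, 3]

    def test_comments_and_blank_lines_skipped(self, tmp_path):
        path = tmp_path / "g.edgelist"
        path.write_text("# a star\n\n1 2\n1 3\n")
        assert load_graph(str(path)).number_of_edges() == 2

    def test_duplicate_edge_rejected(self, tmp_path):
        path = tmp_path / "dup.edgelist"
        path.write_text("1 2\n2 1\n")
        with pytest.raises(GraphValidationError, match="duplicate"):
            load_graph(str(path))

    def test_self_loop_rejected(self, tmp_path):
        path = tmp_path / "loop.edgelist"
        path.write_text("1 1\n")
        with pytest.raises(GraphValidationError, match="self-loop"):
            load_graph(str(path))

    def test_malformed_line_names_lineno(self, tmp_path):
        path = tmp_path / "bad.edgelist"
        path.write_text("1 2\n1 2 3\n")
        with pytest.raises(GraphFormatError, match=":2"):
            load_graph(str(path))

    def test_round_trip_er_draw(self, tmp_path):
        graph = nx.gnp_random_graph(50, 0.2, seed=7)
        graph = nx.relabel_nodes(graph, str)
        graph.remove_nodes_from([v for v, d in graph.degree() if d == 0])
        path = tmp_path / "er.edgelist"
        save_graph(graph, str(path))
        again = load_graph(str(path))
        assert set(map(frozenset, again.edges())) == set(map(frozenset, graph.edges()))

    def test_canonical_output_is_byte_stable(self, tmp_path, star4):
        p1, p2 = tmp_path / "a", tmp_path / "b"
        save_graph(star4, str(p1))
        save_graph(nx.Graph(list(reversed(list(star4.edges())))), str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_edgelist_warns_on_isolated_nodes(self, tmp_path):
        graph = nx.Graph()
        graph.add_nodes_from([1, 2, 3])
        graph.add_edge(1, 2)
        with pytest.warns(UserWarning, match="isolated"):
            save_graph(graph, str(tmp_path / "iso.edgelist"))

    def test_gml_preserves_isolated_nodes(self, tmp_path):
        graph = nx.Graph()
        graph.add_nodes_from(["a", "b", "c"])
        path = tmp_path / "g.gml"
        save_graph(graph, str(path), format="gml")
        assert load_graph(str(path), format="gml").number_of_nodes() == 3

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_round_trip_is_identity_on_edge_sets(self, tmp_path_factory, seed):
        graph = nx.gnp_random_graph(12, 0.4, seed=seed)
        graph.remove_nodes_from([v for v, d in graph.degree() if d == 0])
        if graph.number_of_edges() == 0:
            return
        path = tmp_path_factory.mktemp("rt") / "g.edgelist"
        save_graph(graph, str(path))
        again = load_graph(str(path))
        assert {frozenset(map(str, e)) for e in graph.edges()} == set(
            map(frozenset, again.edges())
        )


class TestStats:
    def test_complete_graph(self, k4):
        stats = graph_stats(k4)
        assert (stats.n, stats.m, stats.density, stats.mean_degree) == (4, 6, 1.0, 3.0)

    def test_star(self, star4):
        stats = graph_stats(star4)
        assert stats.density == pytest.approx(0.5)
        assert stats.mean_degree == pytest.approx(1.5)
        assert stats.max_degree == 3 and stats.connected

    def test_two_disjoint_triangles(self):
        graph = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        stats = graph_stats(graph)
        assert not stats.connected
        assert stats.density == pytest.approx(0.4)

    def test_degree_sequence_and_distribution(self, star4, cycle4, d4):
        assert sorted(degree_sequence(star4)) == [1, 1, 1, 3]
        assert degree_distribution(star4).counts == {1: 3, 3: 1}
        assert degree_distribution(cycle4).counts == {2: 4}
        assert degree_distribution(d4).counts == {1: 1, 2: 2, 3: 1}
        dist = degree_distribution(d4)
        assert sum(dist.probabilities().values()) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_handshake(self, seed):
        graph = nx.gnp_random_graph(15, 0.3, seed=seed)
        assert sum(degree_sequence(graph)) == 2 * graph.number_of_edges()


class TestSpectralRadius:
    @pytest.mark.parametrize(
        "graph_factory, expected",
        [
            (lambda: nx.complete_graph(4), 3.0),
            (lambda: nx.cycle_graph(4), 2.0),
            (lambda: nx.star_graph(3), math.sqrt(3)),
            (lambda: nx.star_graph(24), math.sqrt(24)),
        ],
    )
    def test_closed_forms(self, graph_factory, expected):
        assert spectral_radius(graph_factory()) == pytest.approx(expected, abs=1e-9)

    def test_matches_dense_oracle_and_sandwich(self):
        for seed in range(10):
            graph = nx.gnp_random_graph(30, 0.25, seed=seed)
            if not nx.is_connected(graph):
                continue
            rho = spectral_radius(graph)
            dense = np.linalg.eigvalsh(nx.to_numpy_array(graph)).max()
            assert rho == pytest.approx(dense, abs=1e-9)
            degrees = [d for _, d in graph.degree()]
            assert np.mean(degrees) - 1e-9 <= rho <= max(degrees) + 1e-9

    def test_large_sparse_path(self):
        # above the dense cutoff; path eigenvalue 2 cos(pi/(n+1))
        n = 600
        rho = spectral_radius(nx.path_graph(n), tol=1e-10)
        assert rho == pytest.approx(2 * math.cos(math.pi / (n + 1)), abs=1e-8)
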