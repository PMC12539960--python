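"""Measure values frozen from hand computation, algebraic identities, and
brute-force oracle equivalence on exhaustively enumerated small graphs."""

import math

import networkx as nx
import numpy as np
import pytest

from hetnet import measures as M
from hetnet.enumeration import connected_graphs, min_max_degree
from hetnet.graph_core import degree_distribution

SQRT3 = math.sqrt(3)


class TestGlobalDispersion:
    def test_hand_values_star(self, star4):
        assert M.hhg(star4) == 6.0
        assert M.hf(star4) == 1.0
        assert M.hs(star4) == pytest.approx(0.75)
        assert M.hn(star4) == pytest.approx(3.0)

    def test_regular_graphs_are_zero(self, cycle4):
        for fn in (M.hhg, M.hf, M.hs, M.hn):
            assert fn(cycle4) == 0.0

    def test_hand_values_d4(self, d4):
        assert M.hs(d4) == pytest.approx(0.5)
        assert M.hn(d4) == pytest.approx(2.0)
        assert M.hhg(d4) == pytest.approx(4.0)
        assert M.hf(d4) == pytest.approx(2.0 / 3.0)

    def test_hf_rejects_tiny_graphs(self):
        with pytest.raises(M.MeasureError):
            M.hf(nx.path_graph(2))

    def test_hf_is_scaled_hhg_everywhere(self):
        for graph in connected_graphs(6, min_n=3):
            n = graph.number_of_nodes()
            assert M.hf(graph) == pytest.approx(
                M.hhg(graph) / ((n - 1) * (n - 2)), abs=1e-12
            )

    def test_variance_two_forms_agree(self):
        # n^{-1} sum (k - mean)^2  ==  n^{-1} sum k^2 - mean^2
        for graph in connected_graphs(6):
            k = np.array([d for _, d in graph.degree()], dtype=float)
            alt = np.mean(k**2) - np.mean(k) ** 2
            assert M.hs(graph) == pytest.approx(alt, abs=1e-9)

    def test_phi_square_recovers_variance(self, d4):
        assert M.hs_phi(d4, lambda x: x**2) == pytest.approx(M.hs(d4), abs=1e-12)

    def test_hs_normalized(self, cycle4, star4):
        assert M.hs_normalized(cycle4).value == 0.0
        # stars maximize the variance among 4-node 3-edge graphs
        assert M.hs_normalized(star4).value == pytest.approx(1.0)

    def test_hs_normalized_large_n_search(self):
        # 10-node star: the search-based denominator keeps HS' within [0, 1]
        result = M.hs_normalized(nx.star_graph(9))
        assert 0.0 < result.value <= 1.0
        assert any("approximate" in w for w in result.warnings)


class TestHB:
    def test_extreme_conventions(self, k4, star4):
        assert M.hb(k4).value == 0.0
        assert M.hb(k4).warnings  # degenerate 0/0 convention recorded
        assert M.hb(star4).value == 1.0
        assert M.hb(nx.cycle_graph(5)).value == 0.0

    def test_bounds_validated_by_enumeration(self):
        # the closed forms ceil(2m/n) and min(n-1, m) must match exhaustive
        # enumeration of attainable maximum degrees
        for n in range(2, 7):
            for m in range(0, n * (n - 1) // 2 + 1):
                lo, hi = min_max_degree(n, m)
                assert lo == math.ceil(2 * m / n)
                assert hi == min(n - 1, m)

    def test_in_unit_interval_on_battery(self):
        for graph in connected_graphs(6):
            assert 0.0 <= M.hb(graph).value <= 1.0


class TestAdjacentDispersion:
    def test_ha_hand_values(self, star4, cycle4, d4):
        assert M.ha(star4) == 6.0
        assert M.ha(cycle4) == 0.0
        assert M.ha(d4) == 4.0

    def test_he_star_closed_form(self, star4):
        assert M.he(star4) == pytest.approx(4 - 2 * SQRT3, abs=1e-12)

    def test_he_randic_identity_d4(self, d4):
        randic = M.randic_index(d4)
        assert randic == pytest.approx(1.8938468, abs=1e-6)
        assert M.he(d4) == pytest.approx(4 - 2 * randic, abs=1e-9)

    def test_he_rejects_isolated_nodes(self):
        graph = nx.Graph()
        graph.add_nodes_from([1, 2, 3])
        graph.add_edge(1, 2)
        with pytest.raises(M.MeasureError, match="isolated"):
            M.he(graph)

    @pytest.mark.parametrize("n", [4, 10, 25, 50])
    def test_he_normalized_star_is_one(self, n):
        assert M.he_normalized(nx.star_graph(n - 1)) == pytest.approx(1.0, abs=1e-9)

    def test_he_normalized_values(self, d4):
        assert M.he_normalized(nx.cycle_graph(8)) == 0.0
        assert M.he_normalized(d4) == pytest.approx(0.2123063 / (4 - 2 * SQRT3), abs=1e-6)

    def test_he_normalized_needs_three_nodes(self):
        with pytest.raises(M.MeasureError):
            M.he_normalized(nx.path_graph(2))


class TestPairwiseDispersion:
    def test_hand_values(self, star4, cycle4, d4):
        assert M.hap(d4) == 6.0
        assert M.hap(star4) == 6.0
        assert M.hap(cycle4) == 0.0
        assert M.hep(cycle4) == 0.0

    def test_sorted_formula_equals_double_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            k = rng.integers(1, 20, size=rng.integers(2, 30)).astype(float)
            brute = sum(
                abs(k[i] - k[j]) for i in range(len(k)) for j in range(i + 1, len(k))
            )
            assert M._pairwise_abs_sum(k) == pytest.approx(brute, abs=1e-9)


class TestExpectedDifference:
    def test_haed_hand_values(self, star4, cycle6, d4):
        assert M.haed(star4) == pytest.approx(6.0)
        assert M.haed(cycle6) == 0.0
        assert M.haed(d4) == pytest.approx(1.5)

    def test_haed_needs_edges(self):
        empty = nx.empty_graph(3)
        with pytest.raises(M.MeasureError):
            M.haed(empty)

    def test_hhw_hand_value_and_regular_zero(self, star4, cycle6):
        assert M.hhw(star4) == pytest.approx(0.25)
        assert M.hhw(cycle6) == 0.0
        assert M.hl(cycle6) == 0.0

    def test_hl_hand_value(self, d4):
        assert M.hl(d4) == pytest.approx(0.625)

    def test_hped_presets(self, d4):
        assert M.hped(d4, "HL") == M.hl(d4)
        assert M.hped(d4, "HHW") == M.hhw(d4)

    def test_mean_absolute_difference_weighted(self):
        # two atoms 0 and 1 with probabilities p and 1-p: E|X-Y| = 2p(1-p)
        assert M.mean_absolute_difference([0, 1], [0.3, 0.7]) == pytest.approx(0.42)

    def test_hhw_in_unit_interval_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            graph = nx.gnp_random_graph(
                int(rng.integers(3, 30)), float(rng.uniform(0.1, 0.9)),
                seed=int(rng.integers(2**31)),
            )
            if graph.number_of_edges() == 0:
                continue
            assert 0.0 <= M.hhw(graph) <= 1.0


class TestSpecialMeasures:
    def test_hcs_values(self, cycle4, star4, d4):
        assert M.hcs(cycle4) == pytest.approx(0.0, abs=1e-9)
        assert M.hcs(star4) == pytest.approx(SQRT3 - 1.5, abs=1e-9)
        assert M.hcs(d4) == pytest.approx(0.1700865, abs=1e-6)

    def test_hcs_rejects_disconnected(self):
        graph = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
        with pytest.raises(M.MeasureError, match="connected"):
            M.hcs(graph)

    def test_hcs_nonnegative_on_connected_battery(self):
        for graph in connected_graphs(6):
            assert M.hcs(graph) >= -1e-9

    def test_hj_hand_values(self, cycle4, star4, d4):
        assert M.hj(cycle4) == 0.0
        assert M.hj(d4) == pytest.approx(0.34375)
        assert M.hj(star4) == pytest.approx(0.15625)

    def test_hj_complete_diversity_normalizes_to_one(self, d4):
        # D4 is completely diverse: J equals 1 - 3/n + (n+2)/n^3 exactly
        assert M.hj(d4) == pytest.approx(1 - 3 / 4 + 6 / 64, abs=1e-12)
        assert M.hj_normalized(d4) == pytest.approx(1.0, abs=1e-12)

    def test_hj_printed_denominator_variant(self, star4, d4):
        assert M.hj_normalized(star4) == pytest.approx(0.4545454, abs=1e-6)
        # the printed asymptotic denominator exceeds 1 at small n
        assert M.hj_normalized(d4, exact_denominator=False) > 1.0

    def test_hj_accepts_distribution_input(self, d4):
        dist = degree_distribution(d4)
        assert M.hj(dist) == M.hj(d4)

    def test_hj_distribution_form_is_scale_free(self, d4):
        dist = degree_distribution(d4)
        doubled = degree_distribution([1, 3, 2, 2, 1, 3, 2, 2])
        assert M.hj_distribution_form(dist) == pytest.approx(
            M.hj_distribution_form(doubled), abs=1e-12
        )

    def test_hj_normalized_in_unit_interval(self):
        for graph in connected_graphs(6, min_n=4):
            assert 0.0 <= M.hj_normalized(graph) <= 1.0 + 1e-12


class TestDispatcher:
    def test_all_battery_measures_zero_on_cycle(self, cycle6):
        for name in M.BATTERY:
            assert abs(M.evaluate(name, cycle6).value) <= 1e-9

    def test_unknown_measure_lists_registry(self, cycle6):
        with pytest.raises(KeyError, match="HS"):
            M.evaluate("nope", cycle6)

    def test_requirement_violation_propagates(self):
        graph = nx.disjoint_union(nx.cycle_graph(3), nx.cycle_graph(3))
        with pytest.raises(M.MeasureError):
            M.evaluate("HCS", graph)

    def test_hf_star_battery(self):
        assert M.evaluate("HF", nx.star_graph(6)).value == 1.0

    def test_registry_export_shape(self):
        exported = M.registry_export()
        assert set(M.BATTERY) <= set(exported)
        assert exported["HS"]["class"] == "global_dispersion"


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately independent of the library evaluators

from _oracles import brute


@pytest.mark.parametrize("name", M.BATTERY)
def test_oracle_equivalence_exhaustive_n7(name):
    """Every evaluator equals a naive brute-force sum on all connected
    graphs with up to 7 nodes."""
    for graph in connected_graphs(7, min_n=3):
        assert M.evaluate(name, graph).value == pytest.approx(
            brute(name, graph), abs=1e-9
        )


def test_randic_identity_on_random_graphs():
    """HE = n - 2 R_{-1/2} on graphs without isolated nodes."""
    rng = np.random.default_rng(11)
    checked = 0
    while checked < 100:
        graph = nx.gnp_random_graph(
            int(rng.integers(4, 40)), float(rng.uniform(0.15, 0.8)),
            seed=int(rng.integers(2**31)),
        )
        if any(d == 0 for _, d in graph.degree()):
            continue
        checked += 1
        n = graph.number_of_nodes()
        assert M.he(graph) == pytest.approx(
            n - 2 * M.randic_index(graph), abs=1e-9
        )
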