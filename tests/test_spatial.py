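"""Spatial statistics: lengths, length classes, curves, breakdowns, regions."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormdev.config import LengthClassifier
from wormdev.connectome import Connection
from wormdev.spatial import (
    appearance_curves,
    circuit_curves,
    class_counts,
    classify_length,
    connection_length,
    degree_length_correlations,
    electrically_coupled_fraction,
    region_connectivity,
    synapse_breakdown,
)

from conftest import make_connectome


class TestConnectionLength:
    def test_three_four_five_triangle(self):
        c = make_connectome(
            [("A", 0.0, {"ap": 0.0}), ("B", 0.0, {"ap": 0.3, "dv": 0.04})],
            [("A", "B")],
        )
        # A at (0,0,0.05) midline? both midline: z=0; dv 0 vs 0.04 -> dy 0.04, dx 0.3
        d = connection_length(c, c.connections[0])
        assert d == pytest.approx((0.3**2 + 0.04**2) ** 0.5)

    def test_identical_positions_zero_and_symmetry(self):
        c = make_connectome(
            [("A", 0.0, {"ap": 0.5}), ("B", 0.0, {"ap": 0.5}), ("C", 0.0, {"ap": 0.9})],
            [("A", "B"), ("A", "C")],
        )
        assert connection_length(c, c.connections[0]) == 0.0
        assert connection_length(c, Connection("A", "C")) == connection_length(
            c, Connection("C", "A")
        )


class TestClassifyLength:
    @pytest.mark.parametrize(
        "d, expected",
        [
            (0.20, "short"),
            (0.50, "medium"),
            (1.00, "long"),
            (0.36, "medium"),  # short bound is exclusive
            (0.84, "long"),  # long bound is inclusive
            (5.0, "long"),  # beyond the last bin is still long
            (0.0, "short"),
        ],
    )
    def test_boundaries(self, d, expected):
        assert classify_length(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_length(-0.1)

    @given(st.floats(0, 3, allow_nan=False), st.floats(0, 3, allow_nan=False))
    def test_monotone_class_order(self, d1, d2):
        order = {"short": 0, "medium": 1, "long": 2}
        a, b = sorted((d1, d2))
        assert order[classify_length(a)] <= order[classify_length(b)]

    def test_class_counts_conserve_total(self, default_synthetic):
        c, _ = default_synthetic
        counts = class_counts(c)
        assert sum(counts.values()) == c.n_connections


class TestAppearanceCurves:
    def test_single_pair_step_curve(self):
        c = make_connectome(
            [("A", 300.0, {"ap": 0.0}), ("B", 900.0, {"ap": 0.1})],
            [("A", "B")],
        )
        curves = appearance_curves(c, stage_times=[800.0, 2000.0])
        assert curves["short"].percentages == (0.0, 100.0)

    def test_final_stage_everything_present(self, default_synthetic):
        c, _ = default_synthetic
        curves = appearance_curves(c, stage_times=[350, 800, 2700])
        for curve in curves.values():
            assert curve.percentages[-1] == 100.0
            assert list(curve.percentages) == sorted(curve.percentages)

    def test_class_with_no_pairs_omitted(self):
        c = make_connectome(
            [("A", 0.0, {"ap": 0.0}), ("B", 0.0, {"ap": 0.1})], [("A", "B")]
        )
        curves = appearance_curves(c, stage_times=[100.0])
        assert set(curves) == {"short"}


class TestSynapseBreakdown:
    def test_hand_counted_contingency(self):
        c = make_connectome(
            [
                ("A", 100.0, {"ap": 0.0}),
                ("B", 200.0, {"ap": 0.1}),
                ("C", 300.0, {"ap": 1.0}),
                ("D", 900.0, {"ap": 1.1}),
            ],
            [
                ("A", "B", "gap", "bi"),  # gap / short / early
                ("B", "D", "gap", "bi"),  # gap / long (1.0) / late
                ("C", "D", "chemical", "uni"),  # chem / short / late (D born 900)
                ("A", "C", "combination", "bi"),  # comb / long / early
            ],
        )
        counts = synapse_breakdown(c, hatch_time=840.0)
        assert counts[("gap", "short", "early")] == 1
        assert counts[("gap", "long", "late")] == 1
        assert counts[("chemical", "short", "late")] == 1
        assert counts[("combination", "long", "early")] == 1
        assert sum(counts.values()) == c.n_connections
        # electrically coupled = gap + combination; both long links qualify
        assert electrically_coupled_fraction(counts, "long") == 1.0

    def test_all_chemical_zeroes_other_kinds(self, triangle_connectome):
        counts = synapse_breakdown(triangle_connectome)
        assert all(
            v == 0 for (k, _, _), v in counts.items() if k in ("gap", "combination")
        )

    def test_partition_property(self, default_synthetic):
        c, _ = default_synthetic
        counts = synapse_breakdown(c)
        assert sum(counts.values()) == c.n_connections


class TestRegionConnectivity:
    def test_endpoint_weighted_example(self):
        c = make_connectome(
            [
                ("a", 0.0, {"region": "head"}),
                ("b", 0.0, {"region": "head"}),
                ("c", 0.0, {"region": "tail"}),
            ],
            [("a", "b"), ("a", "c")],
        )
        frac = region_connectivity(c)
        assert frac["head"] == pytest.approx(2 / 3)
        assert frac["tail"] == 0.0

    def test_single_region_is_one(self, triangle_connectome):
        # triangle fixture has no regions; rebuild with one
        c = make_connectome(
            [("A", 0.0, {"region": "head"}), ("B", 0.0, {"region": "head"})],
            [("A", "B")],
        )
        assert region_connectivity(c) == {"head": 1.0}

    def test_bipartite_regions_are_zero(self):
        c = make_connectome(
            [
                ("h1", 0.0, {"region": "head"}),
                ("h2", 0.0, {"region": "head"}),
                ("t1", 0.0, {"region": "tail"}),
                ("t2", 0.0, {"region": "tail"}),
            ],
            [("h1", "t1"), ("h2", "t2")],
        )
        frac = region_connectivity(c)
        assert frac["head"] == 0.0 and frac["tail"] == 0.0


class TestCircuitCurves:
    def test_pair_spanning_two_circuits_counts_in_both(self):
        c = make_connectome(
            [
                ("A", 100.0, {"circuits": frozenset({"X"})}),
                ("B", 900.0, {"circuits": frozenset({"Y"})}),
                ("C", 100.0, {"circuits": frozenset({"X"})}),
            ],
            [("A", "B"), ("A", "C")],
        )
        curves = circuit_curves(c, stage_times=[500.0, 1000.0])
        assert curves["X"].adult_count == 2  # A-B spans X and Y; A-C within X
        assert curves["Y"].adult_count == 1
        assert curves["X"].percentages == (50.0, 100.0)

    def test_single_circuit_matches_all_pairs_curve(self, default_synthetic):
        c, _ = default_synthetic
        curves = circuit_curves(c)
        assert sum(cv.adult_count for cv in curves.values()) >= c.n_connections


class TestDegreeLengthCorrelations:
    def test_zero_variance_raises(self):
        c = make_connectome(
            [("A", 0.0, {"ap": 0.0}), ("B", 0.0, {"ap": 0.1}), ("C", 0.0, {"ap": 0.2})],
            [("A", "B"), ("B", "C"), ("A", "C")],
        )
        with pytest.raises(ValueError, match="variance"):
            degree_length_correlations(c)  # everything short

    def test_null_simulation_centered_near_zero(self):
        import numpy as np

        from wormdev.synthetic import GeneratorConfig, generate_connectome

        rs_s, rs_l = [], []
        for seed in range(20):
            # uniform edge placement (no distance decay, no biases) makes the
            # length class of a link independent of its endpoints' degrees
            c, _ = generate_connectome(
                GeneratorConfig(
                    n_neurons=200,
                    n_connections=2000,
                    hub_early_bias=0.0,
                    long_range_early_bias=0.0,
                    distance_decay_mm=1e9,
                    seed=seed,
                )
            )
            r_s, r_l = degree_length_correlations(c)
            rs_s.append(r_s)
            rs_l.append(r_l)
        assert abs(np.mean(rs_s)) < 0.1
        assert abs(np.mean(rs_l)) < 0.1
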