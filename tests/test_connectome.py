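"""Data model: coordinate lifting, degrees, staging, exclusions, I/O."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from wormdev.config import SpatialConfig
from wormdev.connectome import Connection, Connectome, Neuron, lift_to_3d
from wormdev.io import (
    LoadError,
    export_graphml,
    load_connectome,
    load_neuron_table,
    write_connectome,
)

from conftest import make_connectome, make_neuron

CFG = SpatialConfig()


class TestLiftTo3d:
    @pytest.mark.parametrize(
        "dv, side, expected_z",
        [
            (0.05, "midline", 0.0),  # on the dorsal line: z forced to zero
            (0.0, "left", 0.05),  # equator: |z| = r, left positive
            (0.0, "right", -0.05),
            (0.03, "right", -0.04),  # 3-4-5 circle cross-section
            (-0.03, "left", 0.04),
        ],
    )
    def test_circle_cross_section(self, dv, side, expected_z):
        x, y, z = lift_to_3d((1.0, dv), side, CFG)
        assert x == 1.0 and y == dv
        assert z == pytest.approx(expected_z, abs=1e-12)

    def test_overshoot_is_clamped_to_surface(self):
        _, _, z = lift_to_3d((0.0, 0.2), "left", CFG)
        assert z == 0.0

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            lift_to_3d((float("nan"), 0.0), "left", CFG)

    @given(
        dv=st.floats(-0.05, 0.05),
        side=st.sampled_from(["left", "right"]),
    )
    def test_point_lies_on_the_cylinder(self, dv, side):
        _, y, z = lift_to_3d((0.3, dv), side, CFG)
        assert y * y + z * z == pytest.approx(CFG.body_radius**2, abs=1e-9)
        if z != 0:  # z = 0 on the dorsal/ventral lines carries no side sign
            assert (z > 0) == (side == "left")


class TestDegree:
    def test_uni_and_bi_arc_counting(self):
        # 2 uni outgoing + 1 bi link -> degree 4 (bi counts in + out)
        c = make_connectome(
            [("H", 0.0), ("A", 0.0), ("B", 0.0), ("C", 0.0)],
            [("H", "A"), ("H", "B"), ("H", "C", "gap", "bi")],
        )
        assert c.degree("H") == 4
        assert c.degree("A") == 1 and c.degree("C") == 2

    def test_isolated_neuron_and_unknown_id(self):
        c = make_connectome([("A", 0.0)], [])
        assert c.degree("A") == 0
        with pytest.raises(KeyError):
            c.degree("nope")

    def test_handshake_identity(self, default_synthetic):
        c, _ = default_synthetic
        arcs = sum(2 if conn.directedness == "bi" else 1 for conn in c.connections)
        assert sum(c.degrees().values()) == 2 * arcs


class TestStageNetwork:
    def test_chain_cutoff(self):
        c = make_connectome(
            [("A", 100.0), ("B", 200.0), ("C", 300.0)],
            [("A", "B"), ("B", "C")],
        )
        staged = c.stage_network(250.0)
        assert set(staged.neurons) == {"A", "B"}
        assert staged.n_connections == 1

    def test_empty_and_full_extremes(self, triangle_connectome):
        assert triangle_connectome.stage_network(50.0).n_neurons == 0
        full = triangle_connectome.stage_network(400.0)  # inclusive cutoff
        assert full.n_neurons == 3 and full.n_connections == 3

    @given(
        t1=st.floats(0, 3000),
        t2=st.floats(0, 3000),
    )
    def test_monotone_in_time(self, t1, t2):
        c = make_connectome(
            [("A", 100.0), ("B", 840.0), ("C", 2000.0), ("D", 500.0)],
            [("A", "B"), ("B", "C"), ("A", "D"), ("C", "D")],
        )
        s, t = sorted((t1, t2))
        early, late = c.stage_network(s), c.stage_network(t)
        assert set(early.neurons) <= set(late.neurons)
        assert {x.key() for x in early.connections} <= {x.key() for x in late.connections}


class TestExclusions:
    def _with_loops(self):
        neurons = [make_neuron(n, 0.0) for n in "ABCDE"]
        conns = [
            Connection("A", "B"),
            Connection("A", "C"),
            Connection("D", "E"),
            Connection("B", "B", "chemical", "bi"),
        ]
        return Connectome(neurons, conns, allow_self_loops=True)

    def test_removes_neuron_with_incident_edges(self):
        c = self._with_loops().apply_exclusions({"A"})
        assert set(c.neurons) == set("BCDE")
        assert c.n_connections == 1  # A-B, A-C gone; self-loop gone too

    def test_removes_self_loops(self):
        c = self._with_loops().apply_exclusions()
        assert c.n_neurons == 5
        assert c.n_connections == 3

    def test_idempotent_and_identity_on_clean_input(self, triangle_connectome):
        once = triangle_connectome.apply_exclusions()
        assert once == triangle_connectome
        assert once.apply_exclusions({"Z"}) == once  # absent id only warns


class TestValidation:
    def test_gap_junction_must_be_bidirectional(self):
        with pytest.raises(ValueError):
            Connection("A", "B", "gap", "uni")

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="unknown neuron"):
            Connectome([make_neuron("A", 0.0)], [Connection("A", "B")])

    def test_self_loop_rejected_by_default(self):
        with pytest.raises(ValueError, match="self-loop"):
            Connectome(
                [make_neuron("A", 0.0)], [Connection("A", "A", "chemical", "bi")]
            )

    def test_asymmetric_bilateral_annotation_rejected(self):
        with pytest.raises(ValueError, match="asymmetric"):
            Connectome(
                [
                    make_neuron("AVAL", 0.0, bilateral_partner="AVAR"),
                    make_neuron("AVAR", 0.0),
                ],
                [],
            )


class TestIO:
    def test_loader_parses_rows_and_lifts_coordinates(self, tmp_path):
        p = tmp_path / "n.csv"
        p.write_text(
            "id,ap_mm,dv_mm,side,birth_time_min\n"
            "AVAL,0.1,0.0,left,290\n"
            "AVAR,0.1,0.0,right,295\n"
            "RID,0.2,0.05,midline,350\n"
        )
        neurons = load_neuron_table(p, CFG)
        assert len(neurons) == 3
        by_id = {n.id: n for n in neurons}
        assert by_id["AVAL"].birth_time == 290
        assert by_id["AVAL"].position3d[2] == pytest.approx(0.05)
        assert by_id["AVAR"].position3d[2] == pytest.approx(-0.05)
        assert by_id["RID"].position3d[2] == 0.0

    def test_duplicate_id_names_the_offender(self, tmp_path):
        p = tmp_path / "n.csv"
        p.write_text(
            "id,ap_mm,dv_mm,side,birth_time_min\nAVAL,0,0,left,1\nAVAL,0,0,left,2\n"
        )
        with pytest.raises(LoadError, match="AVAL"):
            load_neuron_table(p, CFG)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "n.csv"
        p.write_text("id,ap_mm,side,birth_time_min\nA,0,left,1\n")
        with pytest.raises(LoadError, match="dv_mm"):
            load_neuron_table(p, CFG)

    def test_non_numeric_value_reports_line(self, tmp_path):
        p = tmp_path / "n.csv"
        p.write_text("id,ap_mm,dv_mm,side,birth_time_min\nA,0,0,left,1\nB,x,0,left,2\n")
        with pytest.raises(LoadError, match="line 3"):
            load_neuron_table(p, CFG)

    def test_round_trip_is_identity(self, tmp_path, default_synthetic):
        c, _ = default_synthetic
        paths = write_connectome(c, tmp_path)
        reloaded = load_connectome(paths["neurons"], paths["edges"], config=c.config)
        assert reloaded == c

    def test_duplicate_edges_collapse_to_combination(self, tmp_path):
        ncsv = tmp_path / "n.csv"
        ncsv.write_text(
            "id,ap_mm,dv_mm,side,birth_time_min\nA,0,0,left,1\nB,0.1,0,left,2\n"
        )
        ecsv = tmp_path / "e.csv"
        ecsv.write_text(
            "pre,post,synapse_kind,directedness\n"
            "A,B,gap,bi\nA,B,chemical,uni\n"
        )
        c = load_connectome(ncsv, ecsv)
        assert c.n_connections == 1
        (conn,) = c.connections
        assert conn.synapse_kind == "combination" and conn.directedness == "bi"

    def test_graphml_export_carries_node_attributes(self, tmp_path, triangle_connectome):
        import networkx as nx

        out = tmp_path / "net.graphml"
        export_graphml(triangle_connectome, out)
        g = nx.read_graphml(out)
        assert g.nodes["A"]["birth_time_min"] == 100.0
        assert g.number_of_nodes() == 3
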