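"""Network data model, I/O, synthetic generators, and geometry statistics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import hapsim as hs
from hapsim.network import (InflowBoundary, NetworkParseError,
                            NetworkValidationError, Node, VesselNetwork,
                            VesselSegment, _point_segment_distance)


def _two_node_net(flow=10.0, volume=2e-3, pO2=40.0):
    nodes = [Node(0, (50.0, 50.0, 0.0)), Node(1, (50.0, 50.0, 200.0))]
    segs = [VesselSegment(0, 0, 1, 5.0, flow)]
    return VesselNetwork(nodes, segs, [InflowBoundary(0, pO2, 50.0, 0.0)], volume)


class TestValidation:
    def test_minimal_network_validates(self):
        _two_node_net().validate()

    def test_flow_conservation_violation_names_node(self):
        nodes = [Node(0, (0.0, 0, 0)), Node(1, (100.0, 0, 0)), Node(2, (200.0, 0, 0))]
        segs = [VesselSegment(0, 0, 1, 4.0, 10.0), VesselSegment(1, 1, 2, 4.0, 7.0)]
        net = VesselNetwork(nodes, segs, [InflowBoundary(0, 40, 50)], 1e-3)
        with pytest.raises(NetworkValidationError, match="node 1"):
            net.validate()

    def test_inflow_node_must_feed_exactly_one_segment(self):
        nodes = [Node(0, (0.0, 0, 0)), Node(1, (100.0, 0, 0)), Node(2, (0.0, 50, 0))]
        segs = [VesselSegment(0, 0, 1, 4.0, 5.0), VesselSegment(1, 0, 2, 4.0, 5.0)]
        net = VesselNetwork(nodes, segs, [InflowBoundary(0, 40, 50)], 1e-3)
        with pytest.raises(NetworkValidationError, match="inflow node"):
            net.validate()

    def test_bifurcation_with_conserved_flow_is_valid(self):
        nodes = [Node(0, (0.0, 0, 0)), Node(1, (100.0, 0, 0)),
                 Node(2, (200.0, 50, 0)), Node(3, (200.0, -50, 0))]
        segs = [VesselSegment(0, 0, 1, 4.0, 10.0),
                VesselSegment(1, 1, 2, 3.0, 6.0),
                VesselSegment(2, 1, 3, 3.0, 4.0)]
        net = VesselNetwork(nodes, segs, [InflowBoundary(0, 40, 50)], 1e-3)
        net.validate()
        assert net.total_inflow() == 10.0

    def test_empty_network_rejected(self, tmp_path):
        net = VesselNetwork([Node(0, (0, 0, 0))], [], [], 1e-3)
        with pytest.raises(NetworkValidationError):
            hs.save_network(net, tmp_path / "bad.txt")


class TestFileIO:
    def test_round_trip_identity(self, tmp_path):
        net = _two_node_net()
        p = tmp_path / "net.txt"
        hs.save_network(net, p)
        loaded = hs.load_network(p)
        assert loaded.nodes == net.nodes
        assert loaded.segments == net.segments
        assert loaded.inflow_boundaries == net.inflow_boundaries
        assert loaded.region_volume_mm3 == net.region_volume_mm3
        # second round trip is bit-identical on disk
        p2 = tmp_path / "net2.txt"
        hs.save_network(loaded, p2)
        assert p.read_text() == p2.read_text()

    def test_generated_tumor_network_round_trips(self, small_tumor, tmp_path):
        net, _ = small_tumor
        p = tmp_path / "tumor.txt"
        hs.save_network(net, p)
        loaded = hs.load_network(p)
        assert loaded.segments == net.segments
        assert loaded.nodes == net.nodes

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("#HEADER\n{\"region_volume_mm3\": 1e-3}\n#NODES\n"
                     "id\tx_um\ty_um\tz_um\n0\tnot_a_number\t0\t0\n")
        with pytest.raises(NetworkParseError, match="line 5"):
            hs.load_network(p)

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "noheader.txt"
        p.write_text("#NODES\nid\tx_um\ty_um\tz_um\n")
        with pytest.raises(NetworkParseError, match="header"):
            hs.load_network(p)


class TestKroghGenerator:
    def test_volume_arithmetic(self):
        net, dom = hs.generate_krogh(5.0, 100.0, 200.0, flow=10.0)
        assert net.region_volume_mm3 == pytest.approx(2e-3)
        assert len(net.segments) == 1
        assert dom.box == (100.0, 100.0, 200.0)

    def test_zero_flow_is_valid(self):
        net, _ = hs.generate_krogh(5.0, 100.0, 200.0, flow=0.0)
        net.validate()

    def test_fat_vessel_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            hs.generate_krogh(60.0, 100.0, 200.0, flow=10.0)

    def test_cylindrical_mask_volume(self):
        net, dom = hs.generate_krogh(0.5, 100.0, 100.0, flow=10.0, n_xy=21,
                                     cylindrical_mask=True)
        dom.check_volume_consistency(net)


class TestDistanceField:
    def test_zero_on_vessel_axis_voxels(self, krogh):
        net, dom = krogh
        d = hs.distance_to_nearest_vessel(net, dom)
        c = dom.shape[0] // 2
        assert d.values[c, c, 0] == 0.0 or d.values[c, c, 0] < dom.h

    def test_krogh_radial_closed_form(self, krogh):
        net, dom = krogh
        d = hs.distance_to_nearest_vessel(net, dom)
        r = net.segments[0].radius
        centers = dom.voxel_centers().reshape(*dom.shape, 3)
        expect = np.hypot(centers[..., 0] - 50.0, centers[..., 1] - 50.0) - r
        expect = np.maximum(expect, 0.0)
        act = dom.active_mask
        assert np.allclose(d.values[act], expect[act], atol=1e-9)

    def test_brute_force_oracle_on_random_network(self, small_tumor):
        net, dom = small_tumor
        d = hs.distance_to_nearest_vessel(net, dom)
        rng = np.random.default_rng(0)
        centers = dom.voxel_centers()
        flat = d.values.ravel()
        for idx in rng.choice(len(centers), size=100, replace=False):
            p = centers[idx]
            best = min(
                float(_point_segment_distance(
                    p[None, :], net.node(s.start_node).xyz,
                    net.node(s.end_node).xyz)[0]) - s.radius
                for s in net.segments)
            assert flat[idx] == pytest.approx(max(best, 0.0), abs=1e-9)


class TestPerfusion:
    @pytest.mark.parametrize("q,v,expect", [
        (40.0, 0.12, 333), (75.0, 0.091, 824), (0.0, 0.12, 0)])
    def test_perfusion_per_volume(self, q, v, expect):
        net = _two_node_net(flow=q, volume=v)
        assert round(hs.perfusion_per_volume(net)) == expect

    def test_generated_network_matches_target_within_1pct(self, small_tumor):
        net, _ = small_tumor
        assert hs.perfusion_per_volume(net) == pytest.approx(333.0, rel=0.01)


class TestSyntheticGenerators:
    def test_tumor_has_far_voxels_normal_does_not(self, small_tumor, small_normal):
        tnet, tdom = small_tumor
        nnet, ndom = small_normal
        dt = hs.distance_to_nearest_vessel(tnet, tdom).active_values()
        dn = hs.distance_to_nearest_vessel(nnet, ndom).active_values()
        assert (dt > 50.0).mean() >= 0.10
        assert dn.max() <= 50.0

    def test_determinism_same_seed(self):
        a, _ = hs.generate_tumor_like(seed=7, box=(300.0, 250.0, 100.0),
                                      n_vessels=5)
        b, _ = hs.generate_tumor_like(seed=7, box=(300.0, 250.0, 100.0),
                                      n_vessels=5)
        assert a.nodes == b.nodes and a.segments == b.segments

    def test_different_seed_differs(self):
        a, _ = hs.generate_tumor_like(seed=7, box=(300.0, 250.0, 100.0),
                                      n_vessels=5)
        b, _ = hs.generate_tumor_like(seed=8, box=(300.0, 250.0, 100.0),
                                      n_vessels=5)
        assert a.nodes != b.nodes

    def test_infeasible_targets_error(self):
        with pytest.raises(NetworkValidationError, match="attempts"):
            # one vessel cannot keep every voxel within 30 μm
            hs.generate_tumor_like(seed=1, box=(300.0, 250.0, 100.0),
                                   n_vessels=1, target_max_vessel_distance=30.0,
                                   max_attempts=5)

    def test_flow_conservation_of_generated_networks(self, small_tumor,
                                                     small_normal):
        for net in (small_tumor[0], small_normal[0]):
            net.validate(flow_rtol=1e-12)


class TestScalarField:
    def test_survival_probability_bounds_enforced(self, krogh):
        _, dom = krogh
        bad = np.full(dom.shape, 1.5)
        with pytest.raises(ValueError):
            hs.ScalarField(dom, bad, "survival_probability")

    def test_field_io_round_trip(self, krogh, tmp_path):
        net, dom = krogh
        d = hs.distance_to_nearest_vessel(net, dom)
        from hapsim.network import load_field, save_field
        save_field(d, tmp_path / "d.tsv")
        back = load_field(tmp_path / "d.tsv")
        act = dom.active_mask
        assert np.array_equal(back.values[act], d.values[act])
        assert back.quantity == d.quantity


@given(st.floats(0, 300), st.floats(0, 300), st.floats(0, 300))
def test_point_segment_distance_triangle_bound(x, y, z):
    """Distance to a segment is never more than distance to either endpoint."""
    p = np.array([[x, y, z]])
    a, b = np.array([10.0, 20.0, 30.0]), np.array([200.0, 150.0, 80.0])
    d = _point_segment_distance(p, a, b)[0]
    assert d <= np.linalg.norm(p[0] - a) + 1e-9
    assert d <= np.linalg.norm(p[0] - b) + 1e-9
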