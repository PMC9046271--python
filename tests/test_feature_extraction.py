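import igraph as ig
import numpy as np
import pytest

from vasculometry import (
    BinaryVolume,
    analyze_volume,
    extract_segments,
    measure_segments,
    network_report,
    reduced_graph,
    segment_length,
    segment_tortuosity,
    segments_to_dataframe,
)
from vasculometry.phantoms import arc_phantom, bifurcation_phantom, tube_phantom


def simple_graph(coords, edges, radii=None):
    g = ig.Graph(n=len(coords), edges=edges, directed=False)
    g.vs["coord"] = [tuple(c) for c in coords]
    g.vs["radius"] = list(radii) if radii is not None else [1.0] * len(coords)
    return g


class TestExtractSegments:
    def test_branchless_path_is_one_segment(self):
        g = simple_graph([(0, 0, i) for i in range(5)], [(i, i + 1) for i in range(4)])
        segs = extract_segments(g)
        assert len(segs) == 1
        assert len(segs[0].vertex_path) == 5
        assert segs[0].boundary == ()

    def test_y_graph_three_segments_bounded_by_branchpoint(self):
        # star center 0 with three 3-vertex arms
        coords = [(0, 5, 5)]
        edges = []
        for a, (dy, dx) in enumerate([(1, 0), (-1, 0), (0, 1)]):
            base = len(coords)
            coords += [(0, 5 + dy * k, 5 + dx * k) for k in range(1, 4)]
            edges += [(0, base), (base, base + 1), (base + 1, base + 2)]
        g = simple_graph(coords, edges)
        segs = extract_segments(g)
        assert len(segs) == 3
        for s in segs:
            assert s.boundary == (0,)

    def test_empty_graph_yields_no_segments(self):
        assert extract_segments(simple_graph([], [])) == []


class TestSegmentLength:
    def test_two_points_use_the_chord(self):
        assert segment_length([(0, 0, 0), (0, 3, 4)], (1, 1, 1)) == pytest.approx(5.0)

    def test_collinear_points_give_exact_line_length(self):
        coords = [(0, 0, i) for i in range(11)]
        assert segment_length(coords, (1, 1, 1)) == pytest.approx(10.0, abs=1e-6)

    def test_resolution_scales_length(self):
        coords = [(0, 0, i) for i in range(11)]
        assert segment_length(coords, (1, 1, 2.5)) == pytest.approx(25.0, abs=1e-6)

    def test_semicircle_sample_points_near_analytic_arc_length(self):
        theta = np.linspace(0, np.pi, 41)
        coords = [(0, 20 * np.sin(t), 20 * np.cos(t)) for t in theta]
        length = segment_length(coords, (1, 1, 1))
        assert length == pytest.approx(20 * np.pi, rel=0.02)

    def test_single_point_has_zero_length(self):
        assert segment_length([(1, 2, 3)], (1, 1, 1)) == 0.0


class TestTortuosity:
    def test_straight_segment_is_unity(self):
        assert segment_tortuosity(10.0, (0, 0, 0), (0, 0, 10)) == pytest.approx(1.0)

    def test_semicircle_is_half_pi(self):
        theta = np.linspace(0, np.pi, 41)
        coords = [(0, 20 * np.sin(t), 20 * np.cos(t)) for t in theta]
        length = segment_length(coords, (1, 1, 1))
        tort = segment_tortuosity(length, coords[0], coords[-1])
        assert tort == pytest.approx(np.pi / 2, rel=0.02)

    def test_closed_loop_is_undefined(self):
        assert segment_tortuosity(5.0, (1, 1, 1), (1, 1, 1)) is None


class TestMeasuredFeatures:
    def test_surface_and_volume_identities(self):
        vol, _ = tube_phantom()
        res = analyze_volume(vol)
        for s in res.segments:
            assert s.surface_area == pytest.approx(2 * np.pi * s.radius_mean * s.length)
            assert s.volume == pytest.approx(np.pi * s.radius_mean**2 * s.length)
            assert s.radius_min <= s.radius_mean <= s.radius_max
            if s.tortuosity is not None:
                assert s.tortuosity >= 1.0 - 1e-6

    def test_tube_phantom_geometry_recovery(self):
        vol, gt = tube_phantom(radius=3.0, length=40.0)
        res = analyze_volume(vol)
        assert len(res.segments) == 1
        s = res.segments[0]
        assert s.tortuosity == pytest.approx(1.0, abs=1e-6)
        assert s.length == pytest.approx(40.0, rel=0.05)
        assert abs(s.radius_mean - 3.0) <= 1.0

    def test_arc_phantom_tortuosity(self):
        vol, gt = arc_phantom(arc_radius=20.0, span_degrees=180.0)
        res = analyze_volume(vol)
        assert len(res.segments) == 1
        tort = res.segments[0].tortuosity
        assert tort == pytest.approx(np.pi / 2, rel=0.02)

    def test_loop_tortuosity_excluded(self):
        # a 26-connected diamond loop of degree-2 vertices
        coords = [(0, 1, 0), (0, 0, 1), (0, 1, 2), (0, 2, 1)]
        edges = [(0, 1), (1, 2), (2, 3), (3, 0)]
        g = simple_graph(coords, edges)
        segs = measure_segments(g, extract_segments(g), (1, 1, 1))
        assert len(segs) == 1
        assert segs[0].is_loop
        assert segs[0].tortuosity is None


class TestNetworkReport:
    def test_y_phantom_counts(self):
        vol, _ = bifurcation_phantom()
        res = analyze_volume(vol)
        rep = res.report
        assert rep.branchpoint_count == 1
        assert rep.endpoint_count == 3
        assert rep.segment_count == 3

    def test_partitioning_is_segments_per_unit_length(self):
        vol, _ = tube_phantom()
        rep = analyze_volume(vol).report
        assert rep.segment_partitioning == pytest.approx(
            rep.segment_count / rep.total_length
        )

    def test_bin_counts_sum_to_segment_count(self):
        vol, _ = bifurcation_phantom()
        rep = analyze_volume(vol).report
        assert rep.bin_counts.sum() == rep.segment_count
        assert rep.total_length == pytest.approx(sum(s.length for s in rep.segments))
        assert rep.total_volume == pytest.approx(sum(s.volume for s in rep.segments))

    def test_empty_graph_report_is_all_zeros(self):
        g = simple_graph([], [])
        vol = BinaryVolume(np.zeros((3, 3, 3)))
        rep = network_report(g, [], vol)
        assert rep.segment_count == 0
        assert rep.total_length == 0.0
        assert rep.segment_partitioning == 0.0
        assert rep.area_fraction == 0.0

    def test_custom_bin_edges_respected(self):
        vol, _ = bifurcation_phantom()
        res = analyze_volume(vol, bin_edges=[0.0, 2.0, 4.0, 10.0])
        assert len(res.report.bin_counts) == 3
        assert res.report.bin_counts.sum() == res.report.segment_count


class TestExports:
    def test_segment_dataframe_row_per_segment(self):
        vol, _ = bifurcation_phantom()
        res = analyze_volume(vol)
        df = segments_to_dataframe(res.segments, bin_edges=res.report.bin_edges)
        assert len(df) == 3
        assert {"length", "tortuosity", "radius_mean", "surface_area"} <= set(df.columns)

    def test_reduced_graph_topology_and_attributes(self, tmp_path):
        vol, _ = bifurcation_phantom()
        res = analyze_volume(vol)
        rg = reduced_graph(res.graph, res.segments)
        assert rg.vcount() == 4  # 1 branchpoint + 3 endpoints
        assert rg.ecount() == 3
        assert all(";" in a or " " in a for a in rg.es["path_coordinates"])
        rg.write_graphml(str(tmp_path / "net.graphml"))
        back = ig.Graph.Read_GraphML(str(tmp_path / "net.graphml"))
        assert back.ecount() == 3
        assert back.es["length"] == pytest.approx(rg.es["length"])
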