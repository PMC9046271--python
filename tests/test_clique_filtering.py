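import igraph as ig
import numpy as np
import pytest

from vasculometry import (
    analyze_volume,
    benchmark_branchpoints,
    build_graph,
    detect_clique_clusters,
    estimate_radii,
    filter_class1,
    filter_class2,
    filter_class3,
    filter_cliques,
    skeletonize,
    weight_clique_candidates,
)
from vasculometry.clique_filtering import CliqueCluster
from vasculometry.phantoms import (
    bifurcation_phantom,
    branchpoint_label_volume,
    crossing_phantom,
    random_phantom,
)


def graph_with(n, edges, radii=None, coords=None):
    g = ig.Graph(n=n, edges=edges, directed=False)
    g.vs["radius"] = list(radii) if radii is not None else [1.0] * n
    g.vs["coord"] = coords if coords is not None else [(0, 0, i) for i in range(n)]
    return g


def branchpoint_count(g):
    return int(np.sum(np.asarray(g.degree()) > 2))


class TestWeights:
    def test_parent_vertex_outweighs_children(self):
        # triangle 0-1-2; v0 has two outside neighbors of radius 3,
        # v1/v2 one outside neighbor of radius 1 each
        g = graph_with(
            7,
            [(0, 1), (0, 2), (1, 2), (0, 3), (0, 4), (1, 5), (2, 6)],
            radii=[3, 1, 1, 3, 3, 1, 1],
        )
        w = weight_clique_candidates(g, [0, 1, 2])
        assert w == {0: 6.0, 1: 2.0, 2: 2.0}

    def test_equal_radii_tie(self):
        g = graph_with(6, [(0, 1), (0, 2), (1, 2), (0, 3), (1, 4), (2, 5)])
        w = weight_clique_candidates(g, [0, 1, 2])
        assert len(set(w.values())) == 1

    def test_no_outside_neighbors_falls_back_to_own_radius(self):
        g = graph_with(3, [(0, 1), (0, 2), (1, 2)], radii=[2.0, 1.0, 1.0])
        w = weight_clique_candidates(g, [0, 1, 2])
        assert w[0] == 2.0


class TestClass1:
    def test_junction_triangle_resolves_to_one_branchpoint(self):
        vol, gt = bifurcation_phantom()
        skel = skeletonize(vol)
        g = build_graph(skel, estimate_radii(vol, skel))
        before = branchpoint_count(g)
        filtered = filter_class1(g)
        assert branchpoint_count(filtered) <= before
        full = filter_cliques(g)
        assert branchpoint_count(full) == 1

    def test_graph_without_branchpoints_unchanged(self):
        g = graph_with(4, [(0, 1), (1, 2), (2, 3)])
        filtered = filter_class1(g)
        assert filtered.ecount() == 3
        assert filtered.vcount() == 4

    def test_two_disjoint_triangles_each_lose_one_edge(self):
        # pendants push every triangle vertex above degree 2
        edges = [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]
        pendants = [(0, 6), (1, 7), (2, 8), (3, 9), (4, 10), (5, 11)]
        g = graph_with(12, edges + pendants)
        filtered = filter_class1(g)
        assert filtered.ecount() == len(edges) + len(pendants) - 2
        assert len(filtered.connected_components()) == len(g.connected_components())


class TestClass2:
    def test_blob_merges_to_mean_radius_vertex(self):
        # K5 blob, radii [1,1,2,2,4]; 3 external targets
        blob_edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        ext = [(0, 5), (2, 6), (4, 7)]
        g = graph_with(8, blob_edges + ext, radii=[1, 1, 2, 2, 4, 1, 1, 1])
        cluster = CliqueCluster((0, 1, 2, 3, 4), 2, (5, 6, 7))
        out = filter_class2(g, cluster)
        assert out.vcount() == 4  # 3 targets + merged vertex
        merged = out.vs[out.vcount() - 1]
        assert merged["radius"] == pytest.approx(2.0)
        assert out.degree(out.vcount() - 1) == 3
        assert 1 <= merged["radius"] <= 4  # within cluster radius range
        assert len(out.connected_components()) == len(g.connected_components())

    def test_two_vertex_cluster_degenerate_merge(self):
        g = graph_with(4, [(0, 1), (0, 2), (1, 3)])
        cluster = CliqueCluster((0, 1), 2, (2, 3))
        out = filter_class2(g, cluster)
        assert out.vcount() == 3
        assert len(out.connected_components()) == 1

    def test_cluster_with_no_targets_leaves_isolated_vertex(self):
        g = graph_with(3, [(0, 1), (0, 2), (1, 2)])
        cluster = CliqueCluster((0, 1, 2), 2, ())
        out = filter_class2(g, cluster)
        assert out.vcount() == 1
        assert out.degree(0) == 0


class TestClass3:
    def make_bar_cluster(self, n=60):
        # overlapping triangles i-(i+1)-(i+2) along x; pendant at each end
        edges = [(i, i + 1) for i in range(n - 1)] + [(i, i + 2) for i in range(n - 2)]
        edges += [(0, n), (n - 1, n + 1)]
        coords = [(5, 5, i) for i in range(n)] + [(5, 6, 0), (5, 6, n - 1)]
        return graph_with(n + 2, edges, coords=coords)

    def test_sliding_window_collapses_bar_to_path(self):
        g = self.make_bar_cluster(60)
        clusters = detect_clique_clusters(g)
        assert len(clusters) == 1
        assert clusters[0].cluster_class == 3
        out = filter_class3(g, clusters[0], window_length=10)
        # 6 window vertices + 2 pendants
        assert out.vcount() == 8
        assert len(out.connected_components()) == 1
        # window chain is a path: new vertices have degree <= 3
        degs = out.degree()
        assert max(degs) <= 3

    def test_short_cluster_single_window_acts_as_class2(self):
        g = self.make_bar_cluster(6)
        clusters = detect_clique_clusters(g)
        cluster = CliqueCluster(clusters[0].vertex_ids, 3, clusters[0].external_targets)
        out = filter_class3(g, cluster, window_length=10)
        assert out.vcount() == 3  # one merged vertex + 2 pendants


class TestFilterCliques:
    def test_clean_path_graph_unchanged(self):
        g = graph_with(5, [(i, i + 1) for i in range(4)])
        out = filter_cliques(g)
        assert out.vcount() == 5 and out.ecount() == 4

    def test_y_junction_phantom_single_branchpoint(self):
        vol, gt = bifurcation_phantom()
        res = analyze_volume(vol)
        assert res.report.branchpoint_count == gt.branchpoint_count == 1
        assert res.report.endpoint_count == gt.endpoint_count == 3

    def test_crossing_phantom_bounded_overcount(self):
        vol, _ = crossing_phantom()
        skel = skeletonize(vol)
        g = build_graph(skel, estimate_radii(vol, skel))
        out = filter_cliques(g)
        assert branchpoint_count(out) <= 2
        assert len(out.connected_components()) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_structural_invariants_on_random_phantoms(self, seed):
        vol, _ = random_phantom(seed)
        skel = skeletonize(vol)
        g = build_graph(skel, estimate_radii(vol, skel))
        out = filter_cliques(g)
        assert len(out.connected_components()) == len(g.connected_components())
        assert branchpoint_count(out) <= branchpoint_count(g)
        # no 3-clique remains among branchpoint candidates
        assert detect_clique_clusters(out) == []


class TestBenchmark:
    def test_bifurcation_benchmark_is_exact(self):
        vol, gt = bifurcation_phantom()
        labels = branchpoint_label_volume(gt, vol.shape)
        result = benchmark_branchpoints(vol, labels)
        assert result["ground_truth_branchpoints"] == 1
        assert result["predicted_branchpoints"] == 1
        assert result["accuracy_percent"] == pytest.approx(100.0)
        assert result["error_percent"] == pytest.approx(0.0)
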