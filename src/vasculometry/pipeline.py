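"""End-to-end analysis orchestration shared by the CLI and ROI analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .clique_filtering import DEFAULT_WINDOW_LENGTH, filter_cliques
from .feature_extraction import (
    NetworkReport,
    SegmentRecord,
    extract_segments,
    measure_segments,
    network_report,
)
from .graph_construction import VesselGraph, build_graph
from .pruning import prune_graph
from .radius_estimation import build_medt_lut, estimate_radii
from .skeletonization import SkeletonPointSet, skeletonize
from .volume_io import BinaryVolume

__all__ = ["AnalysisResult", "analyze_volume"]

log = logging.getLogger("vasculometry")


@dataclass
class AnalysisResult:
    skeleton: SkeletonPointSet
    graph: VesselGraph
    pruned_volume: BinaryVolume
    segments: list[SegmentRecord]
    report: NetworkReport
    stage_counts: dict


def analyze_volume(
    volume: BinaryVolume,
    isolated_filter_length: float = 10.0,
    endpoint_prune_length: float = 5.0,
    bin_edges=None,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    spline_samples: int | None = None,
) -> AnalysisResult:
    """Run the full pipeline on a loaded binary volume.

    Stages: skeletonize -> mEDT radii -> 26-connectivity graph ->
    clique filtering -> length pruning -> segment/network features.
    Default prune lengths are 10 / 5 physical units (the most common
    analysis settings for this pipeline).
    """
    counts: dict = {}
    skeleton = skeletonize(volume)
    counts["centerline_points"] = len(skeleton)
    log.info("skeletonization: %d centerline points", len(skeleton))

    lut = build_medt_lut(volume.resolution)
    radii = estimate_radii(volume, skeleton, lut)

    graph = build_graph(skeleton, radii)
    counts["edges"] = graph.ecount()
    log.info("graph construction: %d vertices, %d edges", graph.vcount(), graph.ecount())

    filtered = filter_cliques(graph, window_length=window_length)
    counts["clique_vertices_resolved"] = graph.vcount() - filtered.vcount() if (
        filtered.vcount() <= graph.vcount()
    ) else 0
    counts["clique_edges_removed"] = max(0, graph.ecount() - filtered.ecount())
    log.info(
        "clique filtering: %d -> %d vertices, %d -> %d edges",
        graph.vcount(), filtered.vcount(), graph.ecount(), filtered.ecount(),
    )

    pruned, pruned_volume = prune_graph(
        filtered, volume, isolated_filter_length, endpoint_prune_length
    )
    counts["pruned_vertices"] = filtered.vcount() - pruned.vcount()
    log.info("pruning: removed %d vertices", counts["pruned_vertices"])

    segments = extract_segments(pruned)
    measure_segments(pruned, segments, volume.resolution, samples=spline_samples)
    report = network_report(pruned, segments, pruned_volume, bin_edges=bin_edges)
    counts["segments"] = len(segments)
    log.info(
        "features: %d segments, %d branchpoints, %d endpoints",
        len(segments), report.branchpoint_count, report.endpoint_count,
    )
    return AnalysisResult(
        skeleton=skeleton,
        graph=pruned,
        pruned_volume=pruned_volume,
        segments=segments,
        report=report,
        stage_counts=counts,
    )
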