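"""ROI-wise analysis against an annotation volume.

An annotation volume (integer atlas IDs, or an RGB series where each
region has a distinct color) is bound to the vasculature volume through
a region-selection spec mapping ROI names to sets of identifiers.
Selected ROIs are processed in bins of up to 254 regions: within a bin
the ROIs get labels 1..255 (0 is background), the labels are cast onto
the vasculature's foreground voxels, and the labeled volume is cached
on disk as a memory-mappable NumPy file.  Each ROI's vasculature is
then extracted as a standalone binary volume (global voxel coordinates
preserved) and run through the full pipeline; per-ROI graphs are merged
into one main graph by disjoint union.

Because ROI extraction precedes skeletonization, vessels crossing an
annotation boundary become disconnected and contribute extra endpoints
in both adjoining ROIs — a documented boundary effect traded for the
large memory savings of per-region processing.
"""

from __future__ import annotations

import json
import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path

import igraph as ig
import numpy as np

from .feature_extraction import NetworkReport, network_report
from .graph_construction import VesselGraph
from .volume_io import BinaryVolume

__all__ = [
    "AnnotationSpec",
    "ROI_BIN_SIZE",
    "bin_rois",
    "label_vasculature",
    "analyze_rois",
]

log = logging.getLogger("vasculometry")

ROI_BIN_SIZE = 254  # labels 1..255 per pass; 0 is background


@dataclass
class AnnotationSpec:
    """ROI selection: ordered ``(name, identifiers)`` entries.

    Identifiers are either integer atlas IDs or ``(r, g, b)`` triples
    (matched by exact 8-bit equality).  ID sets must be pairwise
    disjoint and non-empty.
    """

    roi_entries: list

    def __post_init__(self) -> None:
        seen: set = set()
        for name, ids in self.roi_entries:
            ids = list(ids)
            if not ids:
                raise ValueError(f"ROI {name!r} has no identifiers")
            for i in ids:
                key = tuple(i) if isinstance(i, (list, tuple)) else int(i)
                if key in seen:
                    raise ValueError(f"identifier {key} appears in more than one ROI")
                seen.add(key)

    @property
    def is_rgb(self) -> bool:
        first = self.roi_entries[0][1][0]
        return isinstance(first, (list, tuple))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnnotationSpec":
        """Load ``{"rois": {name: [id, ...] | [[r,g,b], ...]}}``.

        Allen-style structure-graph files can be reduced to this format
        by mapping each selected structure name to its ID list.
        """
        payload = json.loads(Path(path).read_text())
        rois = payload["rois"] if "rois" in payload else payload
        return cls(roi_entries=[(name, list(ids)) for name, ids in rois.items()])


def bin_rois(spec: AnnotationSpec) -> list[list[tuple[str, list, int]]]:
    """Partition ROIs, in order, into bins of at most 254; within each bin
    the entries get consecutive labels starting at 1."""
    bins: list[list[tuple[str, list, int]]] = []
    for start in range(0, len(spec.roi_entries), ROI_BIN_SIZE):
        chunk = spec.roi_entries[start : start + ROI_BIN_SIZE]
        bins.append(
            [(name, list(ids), lab) for lab, (name, ids) in enumerate(chunk, start=1)]
        )
    return bins


def _encode(annotation: np.ndarray) -> np.ndarray:
    """Pack an RGB annotation into a single integer channel; pass IDs through."""
    if annotation.ndim == 4 and annotation.shape[-1] in (3, 4):
        a = annotation[..., :3].astype(np.int64)
        return a[..., 0] * 65536 + a[..., 1] * 256 + a[..., 2]
    return annotation.astype(np.int64)


def _encode_id(identifier) -> int:
    if isinstance(identifier, (list, tuple)):
        r, g, b = identifier
        return int(r) * 65536 + int(g) * 256 + int(b)
    return int(identifier)


def label_vasculature(
    volume: BinaryVolume,
    annotation_volume: np.ndarray,
    bin_entries: list[tuple[str, list, int]],
    cache_path: str | Path | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Cast one bin's ROI labels onto the vasculature foreground.

    Returns the labeled uint8 volume (memory-mapped if ``cache_path`` is
    given) and each ROI's physical volume (annotation voxel count times
    the voxel volume).  Annotation IDs absent from the volume are
    counted and logged, not fatal.
    """
    ann = _encode(np.asarray(annotation_volume))
    if volume.data.ndim == 3 and ann.ndim == 2:
        ann = ann[np.newaxis, ...]
    if ann.shape != volume.data.shape:
        raise ValueError(
            f"annotation shape {ann.shape} != vasculature shape {volume.data.shape}"
        )
    if cache_path is not None:
        labels = np.lib.format.open_memmap(
            Path(cache_path), mode="w+", dtype=np.uint8, shape=volume.data.shape
        )
        labels[:] = 0
    else:
        labels = np.zeros(volume.data.shape, dtype=np.uint8)
    roi_volumes: dict[str, float] = {}
    missing = 0
    for name, ids, lab in bin_entries:
        mask = np.isin(ann, [_encode_id(i) for i in ids])
        count = int(mask.sum())
        if count == 0:
            missing += 1
        roi_volumes[name] = count * volume.voxel_volume
        labels[mask & (volume.data == 1)] = lab
    if missing:
        log.warning("%d ROI(s) have no matching voxels in the annotation volume", missing)
    if labels.max() == 0:
        log.warning("no vasculature voxels fall inside the selected ROIs")
    return labels, roi_volumes


def analyze_rois(
    volume: BinaryVolume,
    annotation_volume: np.ndarray,
    spec: AnnotationSpec,
    isolated_filter_length: float = 10.0,
    endpoint_prune_length: float = 5.0,
    cache_dir: str | Path | None = None,
    keep_cache: bool = False,
    **analysis_kwargs,
) -> tuple[dict[str, NetworkReport], VesselGraph, dict[str, float]]:
    """Analyze every selected ROI separately and merge the graphs.

    Returns ``(reports by ROI name, merged graph, ROI physical volumes)``.
    Empty ROIs produce zero-valued reports.  Global voxel coordinates are
    preserved throughout, so the merged graph is spatially coherent.
    """
    from .pipeline import analyze_volume

    if not spec.roi_entries:
        raise ValueError("annotation spec selects no ROIs")
    reports: dict[str, NetworkReport] = {}
    roi_volumes: dict[str, float] = {}
    graphs: list[VesselGraph] = []
    tmpdir = None
    if cache_dir is None:
        tmpdir = tempfile.TemporaryDirectory(prefix="vasculometry-cache-")
        cache_dir = tmpdir.name
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    try:
        for b, entries in enumerate(bin_rois(spec)):
            cache_path = cache_dir / f"labeled_bin{b}.npy"
            labels, vols = label_vasculature(volume, annotation_volume, entries, cache_path)
            roi_volumes.update(vols)
            labels = np.lib.format.open_memmap(cache_path, mode="r")
            for name, _ids, lab in entries:
                sub = BinaryVolume(
                    np.ascontiguousarray(labels == lab).astype(np.uint8),
                    volume.resolution,
                    ndim_original=volume.ndim_original,
                )
                if sub.foreground_count() == 0:
                    empty = ig.Graph(n=0, directed=False)
                    empty.vs["coord"] = []
                    empty.vs["radius"] = []
                    reports[name] = network_report(empty, [], sub)
                    log.info("ROI %s: empty, zero report", name)
                    continue
                result = analyze_volume(
                    sub,
                    isolated_filter_length=isolated_filter_length,
                    endpoint_prune_length=endpoint_prune_length,
                    **analysis_kwargs,
                )
                reports[name] = result.report
                g = result.graph
                g.vs["roi"] = [name] * g.vcount()
                graphs.append(g)
            if not keep_cache:
                del labels
                cache_path.unlink(missing_ok=True)
    finally:
        if tmpdir is not None and not keep_cache:
            tmpdir.cleanup()
    if graphs:
        merged = ig.disjoint_union(graphs)
    else:
        merged = ig.Graph(n=0, directed=False)
    return reports, merged, roi_volumes
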