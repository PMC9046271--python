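"""Undirected centerline graph construction from skeleton coordinates.

One graph vertex per centerline point (index order = lexicographic
coordinate emission order), each carrying ``coord`` and ``radius``
attributes.  Edges connect 26-adjacent centerline points.  Scanning
only the half of the 26-neighborhood oriented towards
``(z_max, y_max, x_max)`` — 13 offsets — visits every unordered voxel
pair exactly once, so no parallel edges or self-loops can arise.

Graphs are ``igraph.Graph`` objects throughout the pipeline.
"""

from __future__ import annotations

import itertools

import igraph as ig
import numpy as np

from .radius_estimation import RadiusMap
from .skeletonization import SkeletonPointSet

__all__ = [
    "VesselGraph",
    "HALF_NEIGHBORHOOD",
    "build_graph",
    "classify_vertices",
    "vertex_coords",
    "vertex_radii",
]

VesselGraph = ig.Graph

# The (z, y, x) offsets with positive lexicographic orientation: exactly one
# of {o, -o} for every nonzero offset of the 26-neighborhood.
HALF_NEIGHBORHOOD: tuple[tuple[int, int, int], ...] = tuple(
    o
    for o in itertools.product((-1, 0, 1), repeat=3)
    if o > (0, 0, 0)
)
assert len(HALF_NEIGHBORHOOD) == 13


def build_graph(skeleton: SkeletonPointSet, radii: RadiusMap) -> VesselGraph:
    """Build the undirected vessel graph over the centerline points.

    Vertex ``i`` carries ``skeleton.coords[i]`` and ``radii.radii[i]``.
    The connected components of the graph equal the 26-connected
    components of the skeleton mask.
    """
    coords = skeleton.coords
    if len(radii.radii) != len(coords):
        raise ValueError(
            f"radii length {len(radii.radii)} != skeleton point count {len(coords)}"
        )
    n = len(coords)
    g = ig.Graph(n=n, directed=False)
    g.vs["coord"] = [tuple(int(c) for c in p) for p in coords]
    g.vs["radius"] = [float(r) for r in radii.radii]
    if n == 0:
        return g

    # spatial hash: voxel coordinate -> vertex index
    index = {tuple(p): i for i, p in enumerate(map(tuple, coords))}
    edges: list[tuple[int, int]] = []
    for i, p in enumerate(coords):
        for off in HALF_NEIGHBORHOOD:
            j = index.get((int(p[0]) + off[0], int(p[1]) + off[1], int(p[2]) + off[2]))
            if j is not None:
                edges.append((i, j))
    g.add_edges(edges)
    return g


def classify_vertices(graph: VesselGraph) -> np.ndarray:
    """Label every vertex ``endpoint`` (degree <= 1), ``path`` (degree 2)
    or ``branchpoint`` (degree > 2).

    Isolated vertices count as endpoints; they are removed downstream by
    the isolated-segment length filter.
    """
    deg = np.asarray(graph.degree())
    labels = np.full(graph.vcount(), "path", dtype=object)
    labels[deg <= 1] = "endpoint"
    labels[deg > 2] = "branchpoint"
    return labels


def vertex_coords(graph: VesselGraph) -> np.ndarray:
    """All vertex coordinates as an ``(n, 3)`` integer array."""
    if graph.vcount() == 0:
        return np.empty((0, 3), dtype=np.int64)
    return np.asarray(graph.vs["coord"], dtype=np.int64)


def vertex_radii(graph: VesselGraph) -> np.ndarray:
    if graph.vcount() == 0:
        return np.empty(0, dtype=np.float64)
    return np.asarray(graph.vs["radius"], dtype=np.float64)
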