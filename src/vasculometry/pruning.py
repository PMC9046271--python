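"""Length-based removal of isolated segments and short endpoint spurs.

After clique filtering, connected components that contain no
branchpoint ("isolated segments") shorter than a user-defined physical
length are deleted, as are endpoint spurs (segments bounded by one
endpoint and one branchpoint) shorter than a second user-defined
length.  The retained branchpoint's degree is re-evaluated implicitly
by the deletion; vertices lying on a path between two branchpoints are
never pruned.  Removed vertices' voxels are also cleared from a copy of
the volume so exported volumes match the graph.

Lengths here are straight-chained edge Euclidean lengths in physical
units (splines are reserved for feature extraction); endpoint-spur
lengths include the edge to the bounding branchpoint.  Pruning is a
single pass — recursive pruning could erode real vessels.
"""

from __future__ import annotations

import numpy as np

from .graph_construction import VesselGraph
from .volume_io import BinaryVolume

__all__ = ["prune_graph"]


def _edge_length(g: VesselGraph, eid: int, res: np.ndarray) -> float:
    e = g.es[eid]
    a = np.asarray(g.vs[e.source]["coord"], dtype=np.float64)
    b = np.asarray(g.vs[e.target]["coord"], dtype=np.float64)
    return float(np.linalg.norm((a - b) * res))


def prune_graph(
    graph: VesselGraph,
    volume: BinaryVolume,
    isolated_filter_length: float,
    endpoint_prune_length: float,
) -> tuple[VesselGraph, BinaryVolume]:
    """Prune short isolated segments and endpoint spurs (single pass).

    Parameters are physical lengths in the units of ``volume.resolution``;
    a segment is removed when its chained length is strictly below the
    relevant threshold, so thresholds of 0 are a no-op.  Returns a
    filtered graph copy and a volume copy with the pruned vertices'
    voxels cleared.
    """
    if isolated_filter_length < 0 or endpoint_prune_length < 0:
        raise ValueError("prune lengths must be non-negative")
    g = graph.copy()
    vol = volume.copy()
    res = np.asarray(volume.resolution, dtype=np.float64)
    deg = np.asarray(g.degree())
    branch = set(np.flatnonzero(deg > 2).tolist())
    others = [v for v in range(g.vcount()) if v not in branch]
    if not others:
        return g, vol
    sub = g.induced_subgraph(others)
    to_delete: list[int] = []
    for comp in sub.connected_components():
        ids = [others[i] for i in comp]
        id_set = set(ids)
        attached = {
            u for v in ids for u in g.neighbors(v) if u in branch
        }
        # chained length: edges inside the component plus attachment edges
        length = 0.0
        for v in ids:
            for eid in g.incident(v):
                e = g.es[eid]
                u = e.target if e.source == v else e.source
                if u in id_set and u < v:
                    length += _edge_length(g, eid, res)
                elif u in attached:
                    length += _edge_length(g, eid, res)
        if not attached:
            if length < isolated_filter_length:
                to_delete.extend(ids)
        elif len(attached) == 1 and any(deg[v] <= 1 for v in ids):
            if length < endpoint_prune_length:
                to_delete.extend(ids)
    if to_delete:
        coords = np.asarray([g.vs[v]["coord"] for v in to_delete], dtype=np.int64)
        vol.data[coords[:, 0], coords[:, 1], coords[:, 2]] = 0
        g.delete_vertices(to_delete)
    return g, vol
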