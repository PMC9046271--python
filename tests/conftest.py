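import numpy as np
import pytest

from vasculometry import BinaryVolume


@pytest.fixture
def straight_line_volume():
    """A 1-voxel-thick, 20-voxel straight vessel along x at 1 unit^3."""
    data = np.zeros((5, 5, 24), dtype=np.uint8)
    data[2, 2, 2:22] = 1
    return BinaryVolume(data, (1.0, 1.0, 1.0))


@pytest.fixture
def solid_cylinder_volume():
    """Solid x-axis cylinder, radius 3 vx, length 40 vx (flat caps)."""
    data = np.zeros((16, 16, 48), dtype=np.uint8)
    zz, yy = np.mgrid[0:16, 0:16]
    disk = (zz - 8) ** 2 + (yy - 8) ** 2 <= 9
    data[:, :, 4:44] = disk[:, :, np.newaxis]
    return BinaryVolume(data, (1.0, 1.0, 1.0))


def brute_force_medt_radius(volume, point, resolution=None):
    """Independent oracle: corrected distance from ``point`` to EVERY
    background voxel; mean of the 4 smallest."""
    res = np.asarray(resolution if resolution is not None else volume.resolution)
    bg = np.argwhere(volume.data == 0)
    deltas = np.abs(bg - np.asarray(point))
    scaled = deltas * res
    dist = np.sqrt((scaled**2).sum(axis=1))
    axial = (deltas != 0).sum(axis=1) == 1
    axis = (deltas[axial] != 0).argmax(axis=1)
    dist[axial] -= 0.5 * res[axis]
    return float(np.sort(dist)[:4].mean())


def brute_force_edges(coords):
    """Independent oracle: all-pairs 26-adjacency (Chebyshev distance 1)."""
    coords = np.asarray(coords)
    edges = set()
    for i in range(len(coords)):
        d = np.abs(coords - coords[i]).max(axis=1)
        for j in np.flatnonzero(d == 1):
            if j > i:
                edges.add((i, int(j)))
    return edges
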