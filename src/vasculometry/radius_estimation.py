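"""Centerline radius estimation with the modified Euclidean distance transform.

Classic EDT-based radius estimates measure from the centerline voxel
center to the *center* of the nearest background voxel, which
overestimates small vessels: a one-voxel-thick vessel at 1 μm³
resolution reads as radius 1 μm instead of the putative 0.5 μm.  The
modified EDT (mEDT) measures instead to the *face* of background voxels
that are reachable from the centerline point by purely face-to-face
steps, subtracting half a voxel unit along that axis; diagonally
situated background voxels keep the plain Euclidean distance.

Operationally, a background voxel at absolute delta ``(dz, dy, dx)``
from a centerline point contributes the corrected distance

    d * r_a - r_a / 2        if exactly one delta component ``d`` is
                             nonzero (along axis ``a``), else
    sqrt(sum_i (d_i * r_i)^2)

where ``r`` is the per-axis resolution.  These values are precomputed
into a lookup table keyed by the absolute delta triple.

Rather than transforming the whole image, an expanding Chebyshev-shell
box search runs around each centerline point until at least four
background voxels are found; the mean of the four smallest corrected
distances is the point's radius (averaging four guards against surface
divots and bubbles).  After the fourth neighbor is found the box grows
one safety shell, and then keeps growing while a later shell could
still hold a smaller corrected distance, so the result is exactly the
mean of the four smallest corrected distances over all background
voxels in the volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .skeletonization import SkeletonPointSet
from .volume_io import BinaryVolume

__all__ = [
    "MedtLut",
    "RadiusMap",
    "build_medt_lut",
    "corrected_distances",
    "estimate_point_radius",
    "estimate_radii",
    "uncorrected_radii",
    "classic_edt_radii",
]


def corrected_distances(deltas: np.ndarray, resolution) -> np.ndarray:
    """mEDT-corrected physical distances for absolute integer delta triples.

    ``deltas`` is ``(m, 3)`` in ``(z, y, x)`` axis order, matching
    ``resolution``.  Purely axial deltas (exactly one nonzero
    component) get the half-unit face correction; all others are plain
    Euclidean.
    """
    deltas = np.atleast_2d(np.abs(np.asarray(deltas, dtype=np.int64)))
    res = np.asarray(resolution, dtype=np.float64)
    scaled = deltas * res
    dist = np.sqrt((scaled * scaled).sum(axis=1))
    nonzero = deltas != 0
    axial = nonzero.sum(axis=1) == 1
    if axial.any():
        axis = nonzero[axial].argmax(axis=1)
        dist[axial] -= 0.5 * res[axis]
    return dist


@dataclass
class MedtLut:
    """Precomputed corrected-distance table keyed by absolute coordinate deltas.

    ``table[dz, dy, dx]`` holds the corrected physical distance for the
    absolute delta triple; deltas beyond ``max_delta`` are computed on
    the fly with the same rule, so vessel size is unbounded.
    """

    table: np.ndarray
    resolution: tuple[float, float, float]
    max_delta: int

    def lookup(self, deltas: np.ndarray) -> np.ndarray:
        """Corrected distances for ``(m, 3)`` absolute delta triples."""
        deltas = np.atleast_2d(np.abs(np.asarray(deltas, dtype=np.int64)))
        out = np.empty(len(deltas), dtype=np.float64)
        small = (deltas <= self.max_delta).all(axis=1)
        if small.any():
            idx = deltas[small]
            out[small] = self.table[idx[:, 0], idx[:, 1], idx[:, 2]]
        if not small.all():
            out[~small] = corrected_distances(deltas[~small], self.resolution)
        return out

    def __getitem__(self, delta) -> float:
        return float(self.lookup(np.asarray(delta)[np.newaxis, :])[0])


def build_medt_lut(resolution, max_delta: int = 64) -> MedtLut:
    """Build the mEDT lookup table for a per-axis ``(z, y, x)`` resolution."""
    res = tuple(float(r) for r in resolution)
    if len(res) != 3 or not all(np.isfinite(r) and r > 0 for r in res):
        raise ValueError(f"resolution must be 3 positive finite values, got {resolution}")
    if max_delta < 1:
        raise ValueError("max_delta must be >= 1")
    n = max_delta + 1
    grid = np.indices((n, n, n)).reshape(3, -1).T
    table = corrected_distances(grid, res).reshape(n, n, n)
    return MedtLut(table=table, resolution=res, max_delta=max_delta)


@dataclass
class RadiusMap:
    """Per-centerline-point radii, index-aligned with a skeleton's coords."""

    radii: np.ndarray

    def __len__(self) -> int:
        return len(self.radii)


def _shell_min_distance(shell: int, resolution) -> float:
    """Smallest corrected distance any voxel in Chebyshev shell ``shell`` can have."""
    r_min = min(resolution)
    return shell * r_min - 0.5 * r_min


def estimate_point_radius(
    volume: BinaryVolume, point, lut: MedtLut, _warn: bool = True
) -> float:
    """mEDT radius at one centerline voxel.

    Expands a box around ``point`` shell by shell until at least four
    background voxels are inside, grows one further safety shell, then
    keeps growing while a later shell could still contain a smaller
    corrected distance.  Returns the mean of the four smallest corrected
    distances.  If the whole volume holds fewer than four background
    voxels, all available distances are averaged and a warning is
    emitted.
    """
    data = volume.data
    shape = data.shape
    z, y, x = (int(c) for c in point)
    max_shell = max(
        z, shape[0] - 1 - z, y, shape[1] - 1 - y, x, shape[2] - 1 - x
    )
    found = np.empty((0, 3), dtype=np.int64)
    stop_shell: int | None = None
    k = 0
    while k <= max_shell:
        k += 1
        lo = (max(z - k, 0), max(y - k, 0), max(x - k, 0))
        hi = (min(z + k, shape[0] - 1), min(y + k, shape[1] - 1), min(x + k, shape[2] - 1))
        box = data[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
        if (box == 0).any():
            bg = np.argwhere(box == 0) + lo
            found = bg
        if stop_shell is None and len(found) >= 4:
            stop_shell = k + 1  # safety shell: nearer voxels can sit one shell out
        if stop_shell is not None and k >= stop_shell:
            deltas = np.abs(found - (z, y, x))
            dists = lut.lookup(deltas)
            fourth = np.partition(dists, 3)[3]
            # exactness guard: stop only when no unseen shell can beat the
            # current 4th-smallest corrected distance
            if _shell_min_distance(k + 1, lut.resolution) >= fourth or k >= max_shell:
                return float(np.sort(dists)[:4].mean())
    if len(found) == 0:
        raise ValueError("volume contains no background voxels; radius undefined")
    if _warn:
        warnings.warn(
            f"only {len(found)} background voxels available; "
            "averaging all corrected distances",
            stacklevel=2,
        )
    dists = lut.lookup(np.abs(found - (z, y, x)))
    return float(np.sort(dists)[: min(4, len(dists))].mean())


def estimate_radii(
    volume: BinaryVolume, skeleton: SkeletonPointSet, lut: MedtLut | None = None
) -> RadiusMap:
    """mEDT radii for every centerline point, index-aligned with the skeleton.

    Per-point problems (e.g. volumes with almost no background) are
    reported as warnings; the batch never aborts.
    """
    if lut is None:
        lut = build_medt_lut(volume.resolution)
    n = len(skeleton)
    radii = np.empty(n, dtype=np.float64)
    for i, point in enumerate(skeleton.coords):
        try:
            radii[i] = estimate_point_radius(volume, point, lut, _warn=(i == 0))
        except ValueError as exc:
            warnings.warn(f"radius undefined at point {tuple(point)}: {exc}", stacklevel=2)
            radii[i] = np.nan
    return RadiusMap(radii=radii)


@dataclass
class _PlainEuclideanLut:
    """Drop-in LUT that skips the half-unit correction (comparison only)."""

    resolution: tuple[float, float, float]

    def lookup(self, deltas: np.ndarray) -> np.ndarray:
        deltas = np.atleast_2d(np.abs(np.asarray(deltas, dtype=np.int64)))
        scaled = deltas * np.asarray(self.resolution, dtype=np.float64)
        return np.sqrt((scaled * scaled).sum(axis=1))


def uncorrected_radii(volume: BinaryVolume, skeleton: SkeletonPointSet) -> RadiusMap:
    """Same expanding-box 4-lowest averaging, but with plain center-to-center
    Euclidean distances.  Upper-bounds the mEDT radius at every point, which
    exposes the axial overestimation bias the face correction removes."""
    lut = _PlainEuclideanLut(resolution=volume.resolution)
    radii = np.empty(len(skeleton), dtype=np.float64)
    for i, point in enumerate(skeleton.coords):
        radii[i] = estimate_point_radius(volume, point, lut, _warn=(i == 0))
    return RadiusMap(radii=radii)


def classic_edt_radii(volume: BinaryVolume, skeleton: SkeletonPointSet) -> RadiusMap:
    """Uncorrected EDT-to-background-center radii, for comparison with mEDT.

    Distance from each centerline voxel center to the nearest background
    voxel *center* (the approach of whole-image EDT pipelines); always an
    upper bound on the mEDT radius.
    """
    edt = ndimage.distance_transform_edt(
        volume.data, sampling=volume.resolution
    )
    c = skeleton.coords
    return RadiusMap(radii=edt[c[:, 0], c[:, 1], c[:, 2]].astype(np.float64))
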