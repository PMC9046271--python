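"""Synthetic vascular phantoms with exact analytic ground truth.

Every pipeline stage is testable without external data: phantoms are
built from tube, arc and bifurcation primitives rasterized with a
center-in-tube rule — a voxel is foreground iff its center lies within
the primitive's tube radius of the centerline curve (no antialiasing:
binary input is the pipeline's contract).  Each rendered phantom
carries a ground-truth record with the analytic branchpoint/endpoint
counts, per-primitive centerline lengths and tortuosities, and the
branchpoint positions (from which marker-sphere label volumes for the
branchpoint benchmark can be rendered).

Optional noise emulates imperfect segmentations: surface divots (random
surface voxels removed) and hole punching (small interior cavities),
both off by default and fully seeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume_io import BinaryVolume

__all__ = [
    "Tube",
    "Arc",
    "Bifurcation",
    "PhantomSpec",
    "GroundTruth",
    "render",
    "spec_from_json",
    "tube_phantom",
    "arc_phantom",
    "bifurcation_phantom",
    "crossing_phantom",
    "random_phantom",
    "branchpoint_label_volume",
    "benchmark_phantoms",
]


@dataclass
class Tube:
    """Straight cylinder from ``start`` to ``end`` (voxel coords, (z,y,x))."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float


@dataclass
class Arc:
    """Circular arc of ``radius`` around ``center`` in the plane spanned by
    two of the axes, swept from ``theta0`` to ``theta1`` (radians), with a
    tube of ``tube_radius`` around it."""

    center: tuple[float, float, float]
    radius: float
    theta0: float
    theta1: float
    tube_radius: float
    plane: tuple[int, int] = (1, 2)  # (y, x) plane by default


@dataclass
class Bifurcation:
    """Three straight arms radiating from a common root (a Y-junction)."""

    root: tuple[float, float, float]
    directions: tuple  # three direction vectors
    lengths: tuple[float, float, float]
    radii: tuple[float, float, float]


@dataclass
class GroundTruth:
    """Analytic expectations for a rendered phantom."""

    branchpoint_count: int
    endpoint_count: int
    branchpoint_coords: list
    segment_lengths: list
    segment_tortuosities: list

    @property
    def total_length(self) -> float:
        return float(sum(self.segment_lengths))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.__dict__, indent=2, default=list))
        return path


@dataclass
class PhantomSpec:
    """Declarative phantom: primitives + shape + noise options + seed."""

    shape: tuple[int, int, int]
    primitives: list
    resolution: tuple[float, float, float] = (1.0, 1.0, 1.0)
    divot_fraction: float = 0.0
    hole_count: int = 0
    hole_radius: float = 1.5
    seed: int = 0


def _tube_mask(shape, start, end, radius) -> np.ndarray:
    start = np.asarray(start, dtype=np.float64)
    end = np.asarray(end, dtype=np.float64)
    lo = np.maximum(np.floor(np.minimum(start, end) - radius - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(np.maximum(start, end) + radius + 1).astype(int) + 1,
        np.asarray(shape),
    )
    mask = np.zeros(shape, dtype=bool)
    grids = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(np.float64)
    d = end - start
    dd = float(d @ d)
    if dd == 0:
        dist = np.sqrt(((grids - start.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    else:
        t = np.clip(
            ((grids[0] - start[0]) * d[0] + (grids[1] - start[1]) * d[1]
             + (grids[2] - start[2]) * d[2]) / dd, 0.0, 1.0,
        )
        closest = start.reshape(3, 1, 1, 1) + t[np.newaxis] * d.reshape(3, 1, 1, 1)
        dist = np.sqrt(((grids - closest) ** 2).sum(axis=0))
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = dist <= radius
    return mask


def _polyline_mask(shape, points, radius) -> np.ndarray:
    """Union of tubes over consecutive polyline points (for curved primitives)."""
    from scipy.spatial import cKDTree

    points = np.asarray(points, dtype=np.float64)
    lo = np.maximum(np.floor(points.min(axis=0) - radius - 1).astype(int), 0)
    hi = np.minimum(
        np.ceil(points.max(axis=0) + radius + 1).astype(int) + 1, np.asarray(shape)
    )
    grids = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].reshape(3, -1).T
    tree = cKDTree(points)
    dist, _ = tree.query(grids.astype(np.float64), k=1)
    mask = np.zeros(shape, dtype=bool)
    sub = (dist <= radius).reshape(hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2])
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
    return mask


def _arc_points(arc: Arc, step: float = 0.05) -> np.ndarray:
    n = max(8, int(abs(arc.theta1 - arc.theta0) * arc.radius / step))
    thetas = np.linspace(arc.theta0, arc.theta1, n)
    pts = np.tile(np.asarray(arc.center, dtype=np.float64), (n, 1))
    a, b = arc.plane
    pts[:, a] += arc.radius * np.cos(thetas)
    pts[:, b] += arc.radius * np.sin(thetas)
    return pts


def _check_bounds(shape, points, radius, margin: int = 2) -> None:
    points = np.asarray(points, dtype=np.float64)
    lo = points.min(axis=0) - radius
    hi = points.max(axis=0) + radius
    if (lo < margin).any() or (hi > np.asarray(shape) - 1 - margin).any():
        raise ValueError(
            f"primitive (extent {lo}..{hi}) does not fit shape {shape} "
            f"with a {margin}-voxel margin"
        )


def render(spec: PhantomSpec) -> tuple[BinaryVolume, GroundTruth]:
    """Rasterize a phantom spec; deterministic for a given seed."""
    data = np.zeros(spec.shape, dtype=bool)
    bp_coords: list = []
    lengths: list[float] = []
    torts: list[float] = []
    n_endpoints = 0
    for prim in spec.primitives:
        if isinstance(prim, Tube):
            _check_bounds(spec.shape, [prim.start, prim.end], prim.radius)
            data |= _tube_mask(spec.shape, prim.start, prim.end, prim.radius)
            lengths.append(
                float(np.linalg.norm(np.subtract(prim.end, prim.start)))
            )
            torts.append(1.0)
            n_endpoints += 2
        elif isinstance(prim, Arc):
            pts = _arc_points(prim)
            _check_bounds(spec.shape, pts, prim.tube_radius)
            data |= _polyline_mask(spec.shape, pts, prim.tube_radius)
            span = abs(prim.theta1 - prim.theta0)
            arc_len = prim.radius * span
            chord = 2.0 * prim.radius * np.sin(span / 2.0)
            lengths.append(float(arc_len))
            torts.append(float(arc_len / chord) if chord > 0 else float("inf"))
            n_endpoints += 2
        elif isinstance(prim, Bifurcation):
            root = np.asarray(prim.root, dtype=np.float64)
            for direction, length, radius in zip(
                prim.directions, prim.lengths, prim.radii
            ):
                d = np.asarray(direction, dtype=np.float64)
                d = d / np.linalg.norm(d)
                end = root + d * length
                _check_bounds(spec.shape, [root, end], radius)
                data |= _tube_mask(spec.shape, root, end, radius)
                lengths.append(float(length))
                torts.append(1.0)
            bp_coords.append([float(c) for c in root])
            n_endpoints += 3
        else:
            raise TypeError(f"unknown primitive {type(prim)!r}")

    rng = np.random.default_rng(spec.seed)
    if spec.divot_fraction > 0:
        eroded = ndimage.binary_erosion(data)
        surface = np.argwhere(data & ~eroded)
        k = int(len(surface) * spec.divot_fraction)
        if k:
            pick = rng.choice(len(surface), size=k, replace=False)
            sel = surface[pick]
            data[sel[:, 0], sel[:, 1], sel[:, 2]] = False
    if spec.hole_count > 0:
        interior = np.argwhere(ndimage.binary_erosion(data, iterations=2))
        if len(interior):
            pick = rng.choice(len(interior), size=min(spec.hole_count, len(interior)))
            for center in interior[pick]:
                zz, yy, xx = np.mgrid[
                    0 : spec.shape[0], 0 : spec.shape[1], 0 : spec.shape[2]
                ]
                hole = (
                    (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
                ) <= spec.hole_radius**2
                data &= ~hole

    gt = GroundTruth(
        branchpoint_count=len(bp_coords),
        endpoint_count=n_endpoints,
        branchpoint_coords=bp_coords,
        segment_lengths=lengths,
        segment_tortuosities=torts,
    )
    return BinaryVolume(data, spec.resolution), gt


def spec_from_json(path: str | Path) -> PhantomSpec:
    """Load a phantom spec from JSON.

    Schema::

        {"shape": [z, y, x], "resolution": [rz, ry, rx], "seed": 0,
         "divot_fraction": 0.0, "hole_count": 0, "hole_radius": 1.5,
         "primitives": [
           {"type": "tube", "start": [..], "end": [..], "radius": 2.0},
           {"type": "arc", "center": [..], "radius": 10, "theta0": 0,
            "theta1": 3.14, "tube_radius": 2, "plane": [1, 2]},
           {"type": "bifurcation", "root": [..], "directions": [[..] x3],
            "lengths": [..], "radii": [..]}]}
    """
    payload = json.loads(Path(path).read_text())
    prims: list = []
    for p in payload["primitives"]:
        kind = p.pop("type")
        if kind == "tube":
            prims.append(Tube(tuple(p["start"]), tuple(p["end"]), float(p["radius"])))
        elif kind == "arc":
            prims.append(
                Arc(
                    tuple(p["center"]), float(p["radius"]), float(p["theta0"]),
                    float(p["theta1"]), float(p["tube_radius"]),
                    tuple(p.get("plane", (1, 2))),
                )
            )
        elif kind == "bifurcation":
            prims.append(
                Bifurcation(
                    tuple(p["root"]),
                    tuple(tuple(d) for d in p["directions"]),
                    tuple(p["lengths"]), tuple(p["radii"]),
                )
            )
        else:
            raise ValueError(f"unknown primitive type {kind!r}")
    return PhantomSpec(
        shape=tuple(payload["shape"]),
        primitives=prims,
        resolution=tuple(payload.get("resolution", (1.0, 1.0, 1.0))),
        divot_fraction=float(payload.get("divot_fraction", 0.0)),
        hole_count=int(payload.get("hole_count", 0)),
        hole_radius=float(payload.get("hole_radius", 1.5)),
        seed=int(payload.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# convenience constructors

def tube_phantom(
    radius: float = 3.0, length: float = 40.0, margin: int = 8, resolution=(1.0, 1.0, 1.0)
) -> tuple[BinaryVolume, GroundTruth]:
    """A straight x-axis tube with spherical caps inside a snug volume."""
    r = int(np.ceil(radius))
    side = 2 * (r + margin) + 1
    c = r + margin
    shape = (side, side, int(length) + 2 * (r + margin) + 1)
    spec = PhantomSpec(
        shape=shape,
        primitives=[Tube((c, c, c), (c, c, c + length), radius)],
        resolution=resolution,
    )
    return render(spec)


def arc_phantom(
    arc_radius: float = 20.0,
    span_degrees: float = 180.0,
    tube_radius: float = 2.0,
    margin: int = 8,
    resolution=(1.0, 1.0, 1.0),
) -> tuple[BinaryVolume, GroundTruth]:
    """A circular arc (default: a semicircle of radius 20) in the y–x plane."""
    pad = int(np.ceil(arc_radius + tube_radius)) + margin
    center = (margin + int(np.ceil(tube_radius)), pad, pad)
    shape = (2 * center[0] + 1, 2 * pad + 1, 2 * pad + 1)
    spec = PhantomSpec(
        shape=shape,
        primitives=[
            Arc(center, arc_radius, 0.0, np.deg2rad(span_degrees), tube_radius)
        ],
        resolution=resolution,
    )
    return render(spec)


def bifurcation_phantom(
    arm_length: float = 16.0,
    radii=(3.0, 2.0, 2.0),
    spread_degrees: float = 40.0,
    resolution=(1.0, 1.0, 1.0),
) -> tuple[BinaryVolume, GroundTruth]:
    """A symmetric Y-junction: a parent arm down -x and two children at
    ±spread from +x, all in the y–x plane."""
    a = np.deg2rad(spread_degrees)
    directions = (
        (0.0, 0.0, -1.0),
        (0.0, np.sin(a), np.cos(a)),
        (0.0, -np.sin(a), np.cos(a)),
    )
    pad = int(np.ceil(arm_length + max(radii))) + 4
    root = (int(np.ceil(max(radii))) + 4, pad, pad)
    shape = (2 * root[0] + 1, 2 * pad + 1, 2 * pad + 1)
    spec = PhantomSpec(
        shape=shape,
        primitives=[
            Bifurcation(root, directions, (arm_length,) * 3, tuple(radii))
        ],
        resolution=resolution,
    )
    return render(spec)


def crossing_phantom(
    arm_length: float = 18.0,
    radius: float = 2.0,
    tilt_degrees: float = 60.0,
    resolution=(1.0, 1.0, 1.0),
) -> tuple[BinaryVolume, GroundTruth]:
    """Two straight tubes crossing at a common center point (an X-junction,
    ground truth: one degree-4 branchpoint, four endpoints)."""
    pad = int(np.ceil(arm_length + radius)) + 4
    c = pad
    a = np.deg2rad(tilt_degrees)
    shape = (2 * pad + 1, 2 * pad + 1, 2 * pad + 1)
    d1 = np.array([0.0, 0.0, 1.0])
    d2 = np.array([0.0, np.sin(a), np.cos(a)])
    center = np.array([c, c, c], dtype=float)
    spec = PhantomSpec(
        shape=shape,
        primitives=[
            Tube(tuple(center - d1 * arm_length), tuple(center + d1 * arm_length), radius),
            Tube(tuple(center - d2 * arm_length), tuple(center + d2 * arm_length), radius),
        ],
        resolution=resolution,
    )
    vol, gt = render(spec)
    gt = GroundTruth(
        branchpoint_count=1,
        endpoint_count=4,
        branchpoint_coords=[[float(c)] * 3],
        segment_lengths=[2.0 * arm_length] * 2,
        segment_tortuosities=[1.0, 1.0],
    )
    return vol, gt


def random_phantom(
    seed: int, shape=(40, 40, 40), n_primitives: int | None = None
) -> tuple[BinaryVolume, GroundTruth]:
    """A random mix of tubes and arcs (possibly disjoint) for property tests."""
    rng = np.random.default_rng(seed)
    if n_primitives is None:
        n_primitives = int(rng.integers(1, 4))
    prims: list = []
    lo, hi = 8, min(shape) - 9
    arc_room = hi - lo > 18  # arcs need clearance for radius + tube
    for _ in range(n_primitives):
        if rng.random() < 0.7 or not arc_room:
            start = rng.uniform(lo, hi, size=3)
            end = rng.uniform(lo, hi, size=3)
            while np.linalg.norm(end - start) < 10:
                end = rng.uniform(lo, hi, size=3)
            prims.append(Tube(tuple(start), tuple(end), float(rng.uniform(1.5, 3.0))))
        else:
            center = rng.uniform(lo + 9, hi - 9, size=3)
            r = float(rng.uniform(5.0, 7.0))
            t0 = float(rng.uniform(0, np.pi))
            prims.append(
                Arc(tuple(center), r, t0, t0 + float(rng.uniform(1.0, np.pi)),
                    float(rng.uniform(1.5, 2.5)))
            )
    spec = PhantomSpec(shape=shape, primitives=prims, seed=seed)
    return render(spec)


def branchpoint_label_volume(
    gt: GroundTruth, shape, sphere_radius: float = 3.0, resolution=(1.0, 1.0, 1.0)
) -> BinaryVolume:
    """Marker spheres around each ground-truth branchpoint (the benchmark's
    label-volume convention: one sphere per true branchpoint)."""
    data = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
    for c in gt.branchpoint_coords:
        data |= (
            (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        ) <= sphere_radius**2
    return BinaryVolume(data, resolution)


def benchmark_phantoms(n: int = 50, seed: int = 0):
    """Yield ``(volume, ground_truth)`` junction phantoms for the
    branchpoint-count benchmark: 4 of every 5 are Y-bifurcations with
    randomized spread, arm length and radii (the dominant junction type in
    vascular networks), every 5th is an X-crossing."""
    rng = np.random.default_rng(seed)
    for i in range(n):
        if i % 5 == 4:
            yield crossing_phantom(
                arm_length=float(rng.uniform(14, 18)),
                radius=float(rng.uniform(1.5, 2.5)),
                tilt_degrees=float(rng.uniform(45, 90)),
            )
        else:
            yield bifurcation_phantom(
                arm_length=float(rng.uniform(13, 17)),
                radii=(
                    float(rng.uniform(2.0, 3.0)),
                    float(rng.uniform(1.5, 2.5)),
                    float(rng.uniform(1.5, 2.5)),
                ),
                spread_degrees=float(rng.uniform(30, 55)),
            )
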