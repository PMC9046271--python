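# Methods

This note documents the models, conventions and numerical choices
behind `vasculometry`, what the synthetic phantoms do and do not
exercise, and the known limitations of the approach.

## Data model and conventions

All volumes are contiguous `uint8` arrays of {0, 1} indexed `(z, y, x)`
with a per-axis physical resolution stored in the same order; 2D images
are padded to a single z slice with unit z resolution, which makes the
pixel neighborhoods (N₄/N₈) emerge from the voxel ones (N₆/N₂₆) without
special cases. Any nonzero input value is foreground — the pipeline
requires pre-segmented data and deliberately exposes no threshold.
NIfTI affines are ignored; the user-supplied resolution is
authoritative, because orientation metadata in segmentation exports is
frequently wrong and the analysis is orientation-invariant anyway.

## Skeletonization

Centerlines come from the Lee–Kashyap–Chu 6-subiteration medial-axis
parallel thinning (via `skimage.morphology.skeletonize`), which
preserves the Euler characteristic and hence the 26-connected component
count. The volume is zero-padded by one voxel before thinning and
cropped after, so border voxels see full neighborhoods. Skeleton
coordinates are emitted in lexicographic `(z, y, x)` order; this fixes
vertex indexing, tie-breaks and output ordering across runs.

Thinning erodes tube ends by roughly one radius: a spherically-capped
cylinder of length 40 and radius 3 yields a centerline of ≈ 38 voxels.
Reported lengths of open-ended segments are therefore biased short by
up to one radius per free end; junction-to-junction segments do not
suffer this because boundary branchpoint coordinates are appended
before length measurement.

## Modified EDT radii

The corrected distance from a centerline voxel c to a background voxel
b with absolute delta d = |c − b| is

* `d·r_a − r_a/2` when exactly one component of d is nonzero (axis *a*),
  i.e. the distance to the voxel *face* for purely axial offsets;
* the plain Euclidean `sqrt(Σ (d_i·r_i)²)` for every other offset.

Distances are served from a precomputed lookup table over absolute
deltas (default up to 64 per axis); larger deltas are computed on the
fly with the same rule, so vessel size is unbounded. The per-point
estimate is the mean of the **four** smallest corrected distances —
fixed, not a parameter — which buffers single-voxel surface defects.

The expanding-box search grows Chebyshev shells until ≥ 4 background
voxels are inside, then one further safety shell, and then continues
while a later shell could still contain a distance below the current
4th-smallest (a shell at Chebyshev k can contribute at minimum
`k·r_min − r_min/2`). The final guard makes the search *exactly*
equivalent to scanning every background voxel in the volume — a single
safety shell alone does not guarantee this under anisotropy or grazing
geometry, and the equivalence is what the oracle tests assert. The
guard triggers rarely, so the cost stays proportional to the local
vessel size. Boxes are clipped at the volume boundary; if the whole
volume holds fewer than four background voxels, all available distances
are averaged and a warning is emitted.

A radius can never fall below `r_min/2` (the smallest possible
corrected distance), which is also the putative radius of a
one-voxel-thick vessel — the worked example the correction exists for.

## Graph construction and branchpoint filtering

One vertex per centerline point, indexed in emission order; edges from
a spatial-hash lookup over the 13 positively-oriented offsets of the
26-neighborhood, visiting each unordered pair once (no parallel edges
or self-loops by construction). Branchpoint = degree > 2, endpoint =
degree ≤ 1 (isolated vertices count as endpoints and are later removed
by the length filters).

Clique filtering operates only on the subgraph induced by degree > 2
vertices — spurious branchpoints are by definition branchpoint
candidates, and this keeps maximal-clique enumeration cheap. Weights
are `radius(v) + mean(radius of v's neighbors outside the clique)`
(own radius alone if no outside neighbors): vertices attached to the
larger parent vessel outweigh the children, so deleting the edge
between the two lowest-weighted members keeps the junction at the
parent. Ties are broken toward the lowest vertex indices, for
determinism. Pass 1 repeats up to 5 sweeps since a removal can expose a
new 3-clique. Pass 2 groups the remaining clique members (maximal
cliques of any size ≥ 3) into connected clusters: clusters under 50
vertices collapse to a single vertex at the rounded centroid with the
cluster's mean radius, wired to all external projection targets;
clusters of 50+ vertices are scanned with a 10-voxel sliding window
(configurable) along their longest bounding-box axis, each window
collapsed the same way and consecutive windows chained. Both collapse
rules keep the merged radius inside the cluster's [min, max] and
preserve the component count; the whole filter runs up to 3 rounds in
case merges create new cliques.

What the filter cannot fix: two residual degree-3 vertices joined by a
short degree-2 bridge (the skeleton of two *obliquely* crossing tubes
is genuinely H-shaped). These are not cliques, and merging them would
require a distance-based heuristic foreign to the clique model; an
X-crossing may therefore report 2 branchpoints where centerline
geometry says 1. The junction-phantom benchmark quantifies this: all
bifurcations resolve exactly; oblique crossings overcount by one.

## Pruning

Components of the branchpoint-removed graph attached to no branchpoint
("isolated segments") shorter than the isolated-filter length, and
spurs attached to exactly one branchpoint and ending in an endpoint
shorter than the endpoint-prune length, are deleted (strict
comparison, so 0 disables). Lengths here are chained straight-line edge
lengths including the attachment edge — splines would be wasted before
filtering. Pruning is a single pass (recursion could erode real
vessels) and never touches a vertex on a branchpoint-to-branchpoint
path; pruned vertices' voxels are also cleared from a copy of the
volume. Defaults are 10 and 5 physical units.

## Segment features

Segment paths are ordered end-to-end; adjoining branchpoint
coordinates are appended before measurement (radius statistics use
interior vertices only — junction radii reflect the junction). Length
follows a clamped uniform B-spline of degree `min(3, n−1)` whose
*control points* are the physically scaled path coordinates, evaluated
at `max(2, 2n)` parameters and summed as a polyline. Using control
points rather than interpolation smooths the voxel staircase (an
interpolating spline would inflate lengths by chasing lattice jitter);
a clamped spline still starts and ends exactly at the path ends, so the
arc-chord tortuosity is ≥ 1 up to spline tolerance (1e−6). Closed loops
have zero chord; their tortuosity is undefined, excluded from averages
and counted in the report. Surface area and volume use the
open-cylinder identities `2π·r̄·L` and `π·r̄²·L`. Radius bins default to
unit-width bins in the dataset's physical units, with configurable
edges; bin counts always sum to the segment count.

## ROI analysis

Selected ROIs are processed in bins of 254 (labels 1–255 per pass, 0 =
background), the labels cast onto foreground voxels, and the labeled
volume cached as a memory-mappable `.npy` (removed after the run unless
kept). Each ROI's voxels become a standalone binary volume — global
coordinates preserved — and run through the full pipeline; per-ROI
graphs are merged by disjoint union. Extracting ROIs *before*
skeletonization is a deliberate trade: it bounds memory by region size
but disconnects vessels at ROI boundaries, inflating endpoint counts
near borders. RGB annotations match by exact 8-bit triple equality.

## Phantoms

Phantoms rasterize tube/arc/bifurcation primitives with a center-in
rule (foreground iff the voxel center is within the tube radius of the
centerline curve; spherical end caps follow automatically) and carry
analytic ground truth: branchpoint/endpoint counts and positions,
per-primitive lengths and tortuosities. Noise options — seeded surface
divots and interior hole punching — are off by default. Rendering is
deterministic per seed.

The junction benchmark is 50 phantoms per run: 4 of every 5 a
Y-bifurcation with randomized spread (30–55°), arm length (13–17 vx)
and radii (1.5–3 vx), every 5th an X-crossing at 45–90°; these sizes
keep the whole benchmark under a minute on one CPU while leaving every
junction several radii away from volume borders. Phantoms emulate
*shape*, not realism: no radius taper, no contrast artifacts, no
anisotropic blur, no densely packed capillary beds. Passing phantom
tests therefore validates the geometry and graph machinery, not
robustness to real segmentation noise. Discretization caveats: tubes
thinner than ~2 voxels rasterize with >10% volume excess (a radius-1.5
disk covers 9 lattice centers against an area of 7.1), and
lattice-aligned half-integer radii (e.g. 2.5) are the worst case for
the center-in rule; the renderer volume checks use radii 2–3.

## Numerical and degenerate-input choices

* Resolution components must be positive and finite; zero/negative
  values are rejected at construction.
* Empty volumes skeletonize to an empty point set; empty graphs
  produce all-zero reports with partitioning 0 by convention.
* Per-point radius failures (no background) warn and yield NaN rather
  than aborting a batch.
* Merged-vertex coordinates are centroids rounded to the nearest voxel
  (graph coordinates stay integral for downstream spline lengths).
* All randomness (phantom geometry, noise) flows from explicit seeds;
  repeated runs with identical inputs produce byte-identical CSVs.

## Limitations

* Segment lengths at free vessel ends are underestimated by up to one
  radius (thinning erosion).
* Oblique X-crossings can report one extra branchpoint (H-skeleton,
  see above).
* No intensity information is used: centerlines are not re-centered
  and radii not refined against grayscale data; input quality bounds
  output quality.
* Vessels crossing ROI boundaries are cut before skeletonization and
  counted as two shorter segments with extra endpoints.
* Directed (artery→vein) hierarchies, mesh rendering and statistical
  group comparisons are out of scope; the exported graph and tables
  feed such analyses downstream.
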