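# Methods

This note documents the models, conventions and numerical choices behind
`seedhull`, in the order the pipeline runs.

## Camera and rig model

The camera is a distortion-free pinhole with five intrinsic parameters:
focal scale factors α_u, α_v (pixels), skew s_uv, and principal point
(u₀, v₀). World coordinates are millimetres; the calibration board plane
defines the world frame (z_w = 0, corner (r, c) at (c·pitch, r·pitch, 0)).
Radial/tangential lens distortion is deliberately out of scope: the rig
works at a single fixed focus and short working distance, and the model
keeps every quantity linear.

Corner detection finds saddle points of the Gaussian-smoothed intensity
(σ = 1.5 px): the response −det(H) = I_xy² − I_xx·I_yy peaks at
checkerboard corners, the strongest rows×cols peaks are kept (interior
black/white saddles respond ~4× more strongly than board-edge junctions
against a mid-grey background), and each peak is refined by Newton steps
on the interpolated gradient/Hessian. Grid ordering is recovered by
fitting a homography from grid indices to the four extreme detections and
assigning predictions to detections by nearest neighbour; the canonical
origin is the extreme corner nearest the image top-left, with the more
horizontal board edge taken as the column direction. On rendered imagery
the detector localises corners to well under 0.1 px.

Intrinsics come from planar (homography-based) calibration over ≥ 3 board
orientations: the closed-form absolute-conic solution initialises a joint
Levenberg–Marquardt refinement of the five intrinsics and all poses.
Per-view poses for known intrinsics use the standard plane-to-image
homography decomposition plus reprojection refinement.

## Rotation axis

Each board corner traces a circle about the turntable axis. A direct
sphere fit to such points is rank-deficient (the points are coplanar, so
every sphere centred anywhere on the axis through the circle centre fits
equally well); the implementation instead fits the least-squares plane,
projects into it, fits a 2D circle (Kasa algebraic fit, then geometric
refinement of centre/radius), and lifts the centre back to 3D. The centre
is the same quantity the sphere fit targets, without the degeneracy.

The axis point is the centroid of the circle centres and the axis
direction the dominant eigenvector of their scatter matrix (principal-
component regression). Sign convention: non-negative dot product with the
camera "up" direction (image −v), ties broken toward +z. A warning is
raised when the top two scatter eigenvalues are within a configurable
ratio (default 0.8) — the centres are then nearly isotropic and the
direction poorly determined. Axis and poses are fitted sequentially, not
bundle-adjusted; on rendered imagery the axis is recovered to ~0.01° and
the contract only needs 0.5° under 0.1 px corner noise.

Virtual views compose the base pose with rotations about the axis
(x → Q(x − m) + m in the camera frame); the defaults are the reference
rig's 40 views at 9°. For seed sequences the world frame is taken to be
the camera frame (identity base pose).

## Silhouettes

Binarization uses Otsu's threshold with polarity chosen so the
smaller-area class is foreground; masks are hole-filled and reduced to
the largest connected component before carving, because the hull
intersection needs one solid silhouette per view.

Nozzle removal scans rows from the top edge and marks the first row whose
foreground count grows by at least `change_fraction` (default 0.30,
a tunable — the effective jump at a seed shoulder is far larger) relative
to the previous row, *after* at least three near-constant rows. The
stability run distinguishes the constant-width nozzle shaft from the
naturally steep width growth at a bare seed apex; without it every convex
apex would trigger a false cut. Rows above the detected row are cleared.
If no row qualifies the mask is returned unchanged with a
`no_intersection` flag and a warning. An optional cross-view consensus
replaces per-view rows with their median over all views.

## Voxel carving

A voxel is occupied iff its centre projects inside the silhouette in
every view; voxels projecting outside any image are outside. The grid is
cubic and auto-sized from the silhouettes (centroid-ray triangulation of
two well-separated views for the centre; the largest back-projected
silhouette extent, padded 5%, for the side), 128³ by default.

Point-in-silhouette lookup samples the nearest mask pixel. Two half-pixel
quantisations (mask raster, nearest-pixel rounding) each bite inward, and
the intersection over 40 views accumulates the worst case, so by default
each mask is dilated by one pixel before carving. This keeps the discrete
hull conservative — on analytic fixtures zero true-interior voxels are
lost and the volume bias is positive and small, provided the pixel
footprint is well below the voxel pitch (the synthetic rigs use ~3–6 px
per voxel; the reference camera's 4912×3684 sensor is far finer still).
The raw predicate is available (`dilate_masks=0`) and is what the
reprojection-exactness property is asserted on.

Occupied voxels split into *surface* (≥ 1 face-adjacent outside
neighbour) and *inside* (6-connectivity erosion).

## Meshing

Marching cubes runs at iso-level 0.5 on the zero-padded occupancy. The
{0,1} field is box-filtered over one voxel first: marching cubes on raw
binary data produces a corner-cut staircase whose area overestimates a
smooth surface by ~9% at 128³, while the filtered field converges to
within ~1–2%. Since the surface-area trait is a first-class output, the
filter is the default; if smoothing would erase the occupancy entirely
(hulls a voxel or two wide) the raw field is contoured instead, and
`smooth=False` gives the unfiltered surface. Meshes are watertight by
construction and re-oriented outward if the signed volume is negative.

## Traits

The canonical seed frame is the principal-axis frame of the occupied
voxel centres: eigenvectors of the covariance sorted by decreasing
eigenvalue map to x = length, y = width, z = thickness; signs are fixed
by making each axis' largest-magnitude component positive and the frame
right-handed. For isotropic bodies (a sphere) any orthonormal frame is
acceptable and the solver's deterministic ordering is used.

Extents, the shadow outline and the transverse section are measured on
the interpolated mesh rather than on raw voxel cell counts: mesh vertices
localise the surface sub-voxel, which the J-index tolerance (±0.02 on a
quantity near 0.785) and the 2% rigid-rotation invariance of the trait
set require at 128³. Specifically:

- **L, W, D**: per-axis spans of the mesh vertices in the canonical frame
  (a single raw voxel still spans one spacing). The grid-based variant
  (centre range + one spacing) remains available.
- **V**: trapezoidal integration of voxel cross-section areas (slice
  count × spacing²) at one-spacing stations along the length axis, with
  the station spacing scaled to the length extent — the slice count
  defaults to the voxel layers, i.e. "sufficiently small intervals".
- **A, R**: the mesh's orthographic shadow along thickness, rasterised at
  a quarter of the voxel pitch, traced subpixel; A is the shoelace area
  and R = 4πA/P² of the same outline. The printed trait-table roundness
  formula is literally a perimeter; the isoperimetric quotient is the
  only standard normalisation making it unitless in (0, 1].
- **A_C**: the largest transverse mesh cross-section, located by the
  voxel slice profile's argmax and refined over ±1 station; this outline
  is the heart-shaped curve for creased grains. Fallback for degenerate
  meshes: the subpixel outline of the argmax voxel slice.
- **J = A_C/(W·D)**, guarded against zero extents.

Contours of binary rasters are traced on a lightly Gaussian-smoothed
field (σ = 1 px) to suppress the marching-squares staircase bias in
perimeters; components under 16 px fall back to the raw trace (a single
pixel yields its diamond boundary).

## Variation statistics

- **PCV** uses the sample SD (n−1), the convention of published summary
  tables; it is scale-invariant and reported in percent.
- **Nested ANOVA** is computed from definitional sums of squares (among
  groups / varieties within groups / seeds within varieties), which
  partition the total exactly; F statistics put each effect over the
  residual mean square and are flagged NaN when the residual is zero.
  No multiple-testing correction is applied; significance is starred at
  P < 0.01. The decomposition handles unbalanced tables.
- **GVF** is read as
  100·sqrt(|Var(P₁)+Var(P₂)−Var(F)|)/(mean(P₁)+mean(P₂)) with population
  (1/N) variances: the summed parental variance plays the role of the
  variance of a sum of independent parental draws, the 1/N is absorbed
  into the variance operator, and the absolute value guards the root when
  offspring variance exceeds the parental sum. Among the readings the
  ambiguous printed operator order admits, this is the one that lands in
  the few-percent range on panel-scale inputs, matching the published
  magnitudes. Per-variety averages are plain means over the nine traits.
- **Clustering** standardises traits per column and delegates to
  scikit-learn (k-means, agglomerative, DBSCAN); precision is scored
  after Hungarian matching of clusters to true batches, so it is
  invariant to label permutations. DBSCAN noise points form their own
  unmatched bin.

## Synthetic fixtures

Seed solids are superellipsoids |x/a|^m + |y/b|^m + |z/c|^m ≤ 1 (defaults
a, b, c = 3.3, 1.6, 1.4 mm, m = 2 — wheat-grain scale) minus an optional
groove: a cylinder along the length axis whose radius is set from the
groove's surface width and depth. Renders are exact for m = 2 (analytic
ray-quadric intersection; the groove case stays exact because a chord of
a convex cylinder lies inside it iff its endpoints do) and fall back to
ray sampling (160 steps inside the bounding sphere) otherwise. Reference
volumes come from a 256³ midpoint rule.

The germplasm simulator draws independent Gaussian traits per seed. Its
default design mirrors the reference study: 15 varieties (2 parents, 6 +
7 offspring in two cross batches), 30 seeds each, with pooled per-trait
means/SDs at panel scale (volume 28.77 ± 6.45 mm³ etc.). Variance
structure per trait with pooled SD σ: variety means are N(mean, (0.6σ)²);
parents carry within-variance B/2 each and ordinary offspring (1−ρ)B with
B = 0.5714σ² and ρ = 0.1, so the pooled SD reproduces σ in expectation
and ordinary offspring land at GVF ≈ 1–3%; one divergent variety gets
(1+κ)B with κ = 4, pinning it to the top of the GVF ranking. Trait
correlations default to zero (published summaries constrain only
marginals); all draws hang off one explicit seed.

What the generator does *not* emulate: trait correlations, non-Gaussian
tails, measurement error structure, batch-level mean separation between
the two crosses (so clustering the simulated batches scores near chance,
unlike real panels), lighting/texture effects, and any genetics beyond a
variance shift. Passing tests therefore demonstrate correctness of the
computations and recoverability under the stated noise model — not field
performance.

## Problem sizes and determinism

The test battery renders boards at 480² px and seeds at 800–1200² px,
carves at 32³–128³, and runs the simulation checks at 200–500 replicates;
the full-scale accuracy check uses the reference conditions (40 views at
9°, 128³). Everything is deterministic given the explicit seeds; the
pipeline writes CSVs with fixed float formatting so identical runs are
byte-identical.

## Known limitations

- The visual hull cannot recover concavities: the ventral groove runs
  along the rotation axis, so carved cross-sections are near-convex and
  the creased-seed J index and volume are biased toward the convex hull.
  Groove-sensitive conclusions need the direct voxelisation path (or a
  different sensor); the creased-geometry unit tests use it.
- The conservative one-pixel guard band trades a small positive volume
  bias for guaranteed containment; it assumes pixels are finer than
  voxels, which any sensible rig satisfies.
- No lens distortion, rolling shutter or exposure modelling; one seed per
  scene; the nozzle must enter from the top edge.
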