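"""Shape-from-silhouette voxel carving and isosurface extraction.

A voxel is occupied iff its centre projects inside the silhouette in every
view — the discrete visual hull, which always contains the true object.
Occupied voxels are partitioned into *surface* (at least one face-adjacent
outside neighbour) and *inside*; a watertight triangle mesh is extracted
from the occupancy field by marching cubes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .calibration import ProjectionMatrix, decompose_projection
from .errors import EmptyHull, EmptySilhouetteWarning
from .silhouette import SilhouetteMask

__all__ = ["VoxelGrid", "carve", "mesh_from_grid", "grid_from_predicate", "estimate_grid"]

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class VoxelGrid:
    """Regular isotropic voxel lattice with boolean occupancy.

    ``origin`` is the world position (mm) of the centre of voxel (0, 0, 0);
    ``spacing`` the voxel edge length in mm.  Surface/inside labels are
    derived from the occupancy: a surface voxel is occupied with at least
    one face-adjacent unoccupied (or out-of-grid) neighbour.
    """

    origin: np.ndarray
    spacing: float
    occupancy: np.ndarray  # bool, (nx, ny, nz)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def inside(self) -> np.ndarray:
        return ndimage.binary_erosion(
            self.occupancy, structure=_FACE_STRUCTURE, border_value=0
        )

    @property
    def surface(self) -> np.ndarray:
        return self.occupancy & ~self.inside

    def states(self) -> np.ndarray:
        """Per-voxel label: 0 = outside, 1 = surface, 2 = inside."""
        out = np.zeros(self.dims, dtype=np.uint8)
        out[self.surface] = 1
        out[self.inside] = 2
        return out

    def occupied_points(self) -> np.ndarray:
        """World coordinates (mm) of occupied voxel centres, (N, 3)."""
        idx = np.argwhere(self.occupancy)
        return self.origin + idx * self.spacing

    def voxel_volume(self) -> float:
        """Occupied-voxel-count volume in mm^3."""
        return self.n_occupied * self.spacing**3


def _as_mask_arrays(masks) -> list[np.ndarray]:
    return [
        m.mask if isinstance(m, SilhouetteMask) else np.asarray(m, dtype=bool)
        for m in masks
    ]


def _ray(P: ProjectionMatrix, uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    intr, pose = decompose_projection(P)
    C = -pose.R.T @ pose.T
    d = pose.R.T @ np.linalg.solve(intr.K, np.array([uv[0], uv[1], 1.0]))
    return C, d / np.linalg.norm(d)


def estimate_grid(
    masks, projections: list[ProjectionMatrix], resolution: int = 128, margin: float = 0.05
) -> VoxelGrid:
    """Auto-size a cubic voxel grid from the silhouettes.

    The grid centre comes from triangulating the silhouette-centroid rays of
    two well-separated views; the cube side from the largest back-projected
    silhouette extent, padded by ``margin``.
    """
    arrs = _as_mask_arrays(masks)
    i0, i1 = 0, max(1, len(arrs) // 4)
    rays = []
    for i in (i0, i1):
        ys, xs = np.nonzero(arrs[i])
        rays.append(_ray(projections[i], np.array([xs.mean(), ys.mean()])))
    (C0, d0), (C1, d1) = rays
    # closest point between the two centroid rays
    w = C0 - C1
    a, b, c = d0 @ d0, d0 @ d1, d1 @ d1
    d, e = d0 @ w, d1 @ w
    den = a * c - b * b
    if abs(den) < 1e-12:
        t0, t1 = -d / a, 0.0
    else:
        t0 = (b * e - c * d) / den
        t1 = (a * e - b * d) / den
    center = 0.5 * (C0 + t0 * d0 + C1 + t1 * d1)

    side = 0.0
    for arr, P in zip(arrs, projections):
        ys, xs = np.nonzero(arr)
        if len(xs) == 0:
            continue
        intr, _ = decompose_projection(P)
        _, depth = P.project(center[None, :])
        ext_px = max(np.ptp(xs), np.ptp(ys)) + 1
        side = max(side, ext_px * float(depth[0]) / min(intr.alpha_u, intr.alpha_v))
    if side == 0:
        raise EmptyHull("all silhouettes are empty")
    side *= 1.0 + margin
    spacing = side / resolution
    origin = center - side / 2.0 + spacing / 2.0
    return VoxelGrid(
        origin=origin, spacing=spacing, occupancy=np.zeros((resolution,) * 3, dtype=bool)
    )


def carve(
    masks,
    projections: list[ProjectionMatrix],
    grid: VoxelGrid | None = None,
    resolution: int = 128,
    chunk_voxels: int = 500_000,
    dilate_masks: int = 1,
) -> VoxelGrid:
    """Carve the visual hull of the seed from its silhouettes.

    Each voxel centre is projected through every view's 3x4 matrix and kept
    only if the nearest mask pixel is foreground in all of them (voxels
    projecting outside an image are discarded).  When ``grid`` is omitted it
    is auto-sized with :func:`estimate_grid` at ``resolution``.

    ``dilate_masks`` dilates each silhouette by that many pixels before
    carving (default 1).  This keeps the discrete hull conservative: the
    nearest-pixel lookup and the pixel raster each quantise by half a pixel,
    and without the dilation the intersection over many views systematically
    bites into the true body.  Set it to 0 for the raw predicate.
    """
    if len(projections) < 2:
        raise ValueError("carving needs at least 2 views")
    arrs = _as_mask_arrays(masks)
    if len(arrs) != len(projections):
        raise ValueError("masks and projections must align")
    if any(not a.any() for a in arrs):
        warnings.warn(
            "at least one silhouette is empty; the hull is empty",
            EmptySilhouetteWarning,
            stacklevel=2,
        )
        raise EmptyHull("empty silhouette forces an empty intersection")
    if grid is None:
        grid = estimate_grid(arrs, projections, resolution)
    if dilate_masks > 0:
        arrs = [
            ndimage.binary_dilation(a, iterations=dilate_masks, structure=np.ones((3, 3), bool))
            for a in arrs
        ]

    nx, ny, nz = grid.dims
    n = nx * ny * nz
    occ = np.zeros(n, dtype=bool)
    Ps = [p.P for p in projections]
    for start in range(0, n, chunk_voxels):
        stop = min(start + chunk_voxels, n)
        flat = np.arange(start, stop)
        idx = np.stack(np.unravel_index(flat, grid.dims), axis=1).astype(float)
        pts = grid.origin + idx * grid.spacing
        alive = np.ones(stop - start, dtype=bool)
        homo = np.column_stack([pts, np.ones(len(pts))])
        for P, arr in zip(Ps, arrs):
            if not alive.any():
                break
            h = homo[alive] @ P.T
            z = h[:, 2]
            ok = z > 0
            u = np.full(len(h), -1.0)
            v = np.full(len(h), -1.0)
            u[ok] = h[ok, 0] / z[ok]
            v[ok] = h[ok, 1] / z[ok]
            ui = np.rint(u).astype(int)
            vi = np.rint(v).astype(int)
            Himg, Wimg = arr.shape
            ok &= (ui >= 0) & (ui < Wimg) & (vi >= 0) & (vi < Himg)
            hit = np.zeros(len(h), dtype=bool)
            hit[ok] = arr[vi[ok], ui[ok]]
            alive[alive] = hit
        occ[start:stop] = alive
    occ = occ.reshape(grid.dims)
    if not occ.any():
        raise EmptyHull("no voxel survived carving")
    return VoxelGrid(origin=grid.origin, spacing=grid.spacing, occupancy=occ)


def grid_from_predicate(
    inside_fn, center: np.ndarray, side: float, resolution: int = 128
) -> VoxelGrid:
    """Voxelize an implicit solid directly (reference grids for testing)."""
    spacing = side / resolution
    origin = np.asarray(center, float) - side / 2.0 + spacing / 2.0
    ax = np.arange(resolution)
    I, J, K = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = origin + np.stack([I.ravel(), J.ravel(), K.ravel()], axis=1) * spacing
    occ = np.zeros(resolution**3, dtype=bool)
    step = 2_000_000
    for s in range(0, len(pts), step):
        occ[s : s + step] = inside_fn(pts[s : s + step])
    return VoxelGrid(origin=origin, spacing=spacing, occupancy=occ.reshape((resolution,) * 3))


def mesh_from_grid(grid: VoxelGrid, smooth: bool = True) -> trimesh.Trimesh:
    """Marching-cubes isosurface of the occupancy field at level 0.5.

    The occupancy is zero-padded so the surface closes at the grid boundary.
    With ``smooth`` (default) the {0,1} field is box-filtered over one voxel
    before contouring, which removes the voxel staircase and makes surface
    areas converge to the smooth-body value; if smoothing would erase the
    occupancy entirely (tiny hulls) the raw field is contoured instead.
    The returned mesh is watertight and outward-oriented, in mm.
    """
    if grid.n_occupied == 0:
        raise EmptyHull("grid has no occupied voxel")
    raw = np.pad(grid.occupancy.astype(float), 1)
    field = ndimage.uniform_filter(raw, size=3) if smooth else raw
    if field.max() <= 0.5:
        field = raw
    s = grid.spacing
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=(s, s, s))
    verts = verts + grid.origin - s  # undo the one-voxel pad
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh
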