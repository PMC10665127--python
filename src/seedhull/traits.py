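"""Nine multidimensional seed traits from a carved grid and mesh.

Traits are measured in a canonical seed frame: the principal axes of the
occupied-voxel point set, ordered by decreasing spread, define x (length),
y (width) and z (thickness).  The traits are

* L, W, D — per-axis extents (mm),
* S — surface area, the Heron-formula sum over mesh triangles (mm^2),
* V — volume by trapezoidal integration of equal-interval cross-section
  areas along the length axis (mm^3),
* A — maximum projection area, the orthographic shadow along thickness (mm^2),
* R — roundness of the shadow outline, 4*pi*area/perimeter^2 in (0, 1],
* A_C — cardioid-derived area, the largest transverse (width x thickness)
  cross-section; heart-shaped for creased seeds (mm^2),
* J — index of adjustment, A_C normalised by the W x D rectangle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .errors import DegenerateOutline, EmptyHull, InsufficientSlices
from .silhouette import silhouette_contour
from .visual_hull import VoxelGrid

__all__ = [
    "CanonicalFrame",
    "SliceProfile",
    "SeedTraits",
    "canonical_frame",
    "extents",
    "surface_area",
    "slice_profile",
    "volume_slices",
    "max_projection_area",
    "projection_outline",
    "polygon_area",
    "mesh_shadow_outline",
    "mesh_section_area",
    "cardioid_area",
    "j_index",
    "roundness",
    "measure_all",
]


@dataclass(frozen=True)
class CanonicalFrame:
    """Rigid map into the seed frame: ``q = (p - centroid) @ axes``.

    ``axes`` columns are the principal directions (length, width, thickness).
    """

    centroid: np.ndarray
    axes: np.ndarray  # (3, 3), columns = canonical x, y, z in world coords

    def transform(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.centroid) @ self.axes


@dataclass(frozen=True)
class SliceProfile:
    """Cross-section areas at equally spaced stations along one axis."""

    axis: int
    areas: np.ndarray  # (n,), mm^2
    positions: np.ndarray  # (n,), slice centres, mm

    @property
    def n(self) -> int:
        return len(self.areas)


@dataclass(frozen=True)
class SeedTraits:
    length: float  # L, mm
    width: float  # W, mm
    thickness: float  # D, mm
    surface_area: float  # S, mm^2
    volume: float  # V, mm^3
    projection_area: float  # A, mm^2
    roundness: float  # R, dimensionless
    cardioid_area: float  # A_C, mm^2
    j_index: float  # J, dimensionless

    def as_dict(self) -> dict[str, float]:
        return {
            "length": self.length,
            "width": self.width,
            "thickness": self.thickness,
            "surface_area": self.surface_area,
            "volume": self.volume,
            "projection_area": self.projection_area,
            "roundness": self.roundness,
            "cardioid_area": self.cardioid_area,
            "j_index": self.j_index,
        }


def canonical_frame(grid: VoxelGrid) -> CanonicalFrame:
    """Principal-axis frame of the occupied voxels.

    Axes are covariance eigenvectors sorted by decreasing eigenvalue; signs
    are fixed by making each axis' largest-magnitude component positive and
    the frame right-handed (z flipped last if needed).  For isotropic bodies
    the eigenvector order is the solver's deterministic tie-break.
    """
    if grid.n_occupied == 0:
        raise EmptyHull("grid has no occupied voxel")
    pts = grid.occupied_points()
    centroid = pts.mean(axis=0)
    X = pts - centroid
    cov = X.T @ X / len(X)
    w, V = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    axes = V[:, order]
    for k in range(3):
        if axes[np.argmax(np.abs(axes[:, k])), k] < 0:
            axes[:, k] = -axes[:, k]
    if np.linalg.det(axes) < 0:
        axes[:, 2] = -axes[:, 2]
    return CanonicalFrame(centroid=centroid, axes=axes)


def extents(canonical_points: np.ndarray, spacing: float) -> tuple[float, float, float]:
    """(L, W, D): per-axis max - min over the voxel extents.

    Each occupied voxel extends ``spacing/2`` beyond its centre, so one
    spacing is added to the centre range; a single voxel spans one spacing.
    """
    pts = np.asarray(canonical_points, dtype=float)
    if pts.size == 0:
        raise EmptyHull("no points")
    span = np.ptp(pts, axis=0) + spacing
    return float(span[0]), float(span[1]), float(span[2])


def surface_area(mesh: trimesh.Trimesh) -> float:
    """Heron-formula surface area: sum of sqrt(l(l-a)(l-b)(l-c)) over faces.

    Degenerate (zero-area) faces contribute zero.
    """
    tri = mesh.triangles
    a = np.linalg.norm(tri[:, 0] - tri[:, 1], axis=1)
    b = np.linalg.norm(tri[:, 1] - tri[:, 2], axis=1)
    c = np.linalg.norm(tri[:, 2] - tri[:, 0], axis=1)
    l = (a + b + c) / 2.0
    sq = np.clip(l * (l - a) * (l - b) * (l - c), 0.0, None)
    return float(np.sqrt(sq).sum())


def slice_profile(
    canonical_points: np.ndarray, spacing: float, axis: int = 0
) -> SliceProfile:
    """Cross-section areas of the voxel cloud at one-spacing intervals.

    Each slice's area is its voxel count times ``spacing**2``.
    """
    pts = np.asarray(canonical_points, dtype=float)
    if pts.size == 0:
        raise EmptyHull("no points")
    x = pts[:, axis]
    lo = x.min()
    idx = np.floor((x - lo) / spacing + 0.5).astype(int)
    n = idx.max() + 1
    counts = np.bincount(idx, minlength=n)
    areas = counts * spacing**2
    positions = lo + np.arange(n) * spacing
    return SliceProfile(axis=axis, areas=areas, positions=positions)


def volume_slices(profile: SliceProfile, length_extent: float) -> float:
    """Trapezoidal slice integration: V = [extent/n] * sum((A_i + A_{i+1})/2)."""
    if profile.n < 2:
        raise InsufficientSlices("volume integration needs >= 2 slices")
    dx = length_extent / (profile.n - 1)
    return float(np.trapezoid(profile.areas, dx=dx))


def _column_cells(pts2d: np.ndarray, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    lo = pts2d.min(axis=0)
    ij = np.floor((pts2d - lo) / spacing + 0.5).astype(int)
    return np.unique(ij, axis=0), lo


def max_projection_area(canonical_points: np.ndarray, spacing: float) -> float:
    """Orthographic shadow area along the thickness axis (mm^2)."""
    pts = np.asarray(canonical_points, dtype=float)
    if pts.size == 0:
        raise EmptyHull("no points")
    cells, _ = _column_cells(pts[:, :2], spacing)
    return float(len(cells) * spacing**2)


def _cells_outline(pts2d: np.ndarray, spacing: float) -> np.ndarray:
    """Subpixel outline polygon (same units as the input) of a 2D cell set."""
    cells, lo = _column_cells(pts2d, spacing)
    shape = cells.max(axis=0) + 1
    img = np.zeros(shape[::-1], dtype=bool)  # rows = second coord
    img[cells[:, 1], cells[:, 0]] = True
    poly_px = silhouette_contour(img)
    return lo + poly_px * spacing


def projection_outline(canonical_points: np.ndarray, spacing: float) -> np.ndarray:
    """Closed outline polygon (mm) of the length x width shadow."""
    pts = np.asarray(canonical_points, dtype=float)
    return _cells_outline(pts[:, :2], spacing)


def polygon_area(outline: np.ndarray) -> float:
    """Shoelace area of a closed polygon."""
    poly = np.asarray(outline, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def cardioid_area(canonical_points: np.ndarray, spacing: float) -> float:
    """Largest transverse (width x thickness) cross-section area (mm^2).

    For a creased seed the corresponding outline is the heart-shaped curve;
    the ventral groove removes area from this section, which is what the
    J index then quantifies.
    """
    pts = np.asarray(canonical_points, dtype=float)
    if pts.size == 0:
        raise EmptyHull("no points")
    return float(slice_profile(pts, spacing, axis=0).areas.max())


def j_index(a_c: float, width: float, thickness: float) -> float:
    """J = A_C / (W * D)."""
    if width <= 0 or thickness <= 0:
        raise ZeroDivisionError("width and thickness must be positive")
    return float(a_c / (width * thickness))


def roundness(outline: np.ndarray) -> float:
    """Isoperimetric roundness of a closed polygon: 4*pi*A / P^2.

    The perimeter P is the wraparound sum of edge lengths; 1 for a circle.
    """
    poly = np.asarray(outline, dtype=float)
    if poly.ndim != 2 or len(poly) < 3:
        raise DegenerateOutline("outline needs >= 3 vertices")
    d = np.roll(poly, -1, axis=0) - poly
    perimeter = float(np.linalg.norm(d, axis=1).sum())
    if perimeter <= 0:
        raise DegenerateOutline("outline has zero perimeter")
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(4.0 * np.pi * area / perimeter**2)


def mesh_shadow_outline(
    mesh_points: np.ndarray, faces: np.ndarray, spacing: float
) -> np.ndarray:
    """Outline polygon (mm) of the mesh's orthographic shadow along z.

    The projected triangles are rasterised at a quarter of the voxel pitch
    and the boundary traced subpixel, so the shadow is consistent under
    rigid rotations of the body (no voxel-lattice alignment effects).
    """
    from skimage.draw import polygon as _fill_polygon

    p2 = np.asarray(mesh_points, dtype=float)[:, :2]
    lo = p2.min(axis=0) - spacing
    pitch = spacing / 4.0
    pix = (p2 - lo) / pitch
    W = int(np.ceil(pix[:, 0].max())) + 2
    H = int(np.ceil(pix[:, 1].max())) + 2
    img = np.zeros((H, W), dtype=bool)
    for f in faces:
        rr, cc = _fill_polygon(pix[f, 1], pix[f, 0], img.shape)
        img[rr, cc] = True
    return lo + silhouette_contour(img) * pitch


def mesh_section_area(mesh: trimesh.Trimesh, x: float) -> float | None:
    """Area of the mesh cross-section by the plane {first axis = x}."""
    sec = mesh.section(plane_origin=[x, 0.0, 0.0], plane_normal=[1.0, 0.0, 0.0])
    if sec is None:
        return None
    planar, _ = sec.to_2D()
    return float(planar.area)


def measure_all(grid: VoxelGrid, mesh: trimesh.Trimesh) -> SeedTraits:
    """All nine traits for one seed from its carved grid and mesh.

    The canonical frame comes from the voxel cloud; extents, shadow area,
    roundness and the cardioid section are measured on the (sub-voxel
    interpolated) mesh surface, which converges faster than raw cell counts
    and is insensitive to how the body sits in the voxel lattice.  The
    volume integrates voxel cross-section areas along the length axis.
    """
    frame = canonical_frame(grid)
    pts = frame.transform(grid.occupied_points())
    s = grid.spacing
    mesh_pts = frame.transform(mesh.vertices)
    mesh_c = trimesh.Trimesh(vertices=mesh_pts, faces=mesh.faces, process=False)
    span = np.ptp(mesh_pts, axis=0)
    L, W, D = float(span[0]), float(span[1]), float(span[2])
    S = surface_area(mesh)
    profile = slice_profile(pts, s, axis=0)
    V = volume_slices(profile, L) if profile.n >= 2 else grid.voxel_volume()
    outline = mesh_shadow_outline(mesh_pts, mesh.faces, s)
    A = polygon_area(outline)
    R = roundness(outline)
    # cardioid-derived area: largest transverse mesh section, seeded by the
    # voxel profile's argmax station
    best = int(np.argmax(profile.areas))
    candidates = [
        mesh_section_area(mesh_c, profile.positions[best] + k * s) for k in (-1, 0, 1)
    ]
    candidates = [a for a in candidates if a is not None]
    if candidates:
        A_C = max(candidates)
    else:
        in_slice = np.abs(pts[:, 0] - profile.positions[best]) <= s / 2
        A_C = polygon_area(_cells_outline(pts[in_slice][:, 1:], s))
    J = j_index(A_C, W, D)
    return SeedTraits(
        length=L,
        width=W,
        thickness=D,
        surface_area=S,
        volume=V,
        projection_area=A,
        roundness=R,
        cardioid_area=A_C,
        j_index=J,
    )
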