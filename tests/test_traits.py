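"""The nine seed traits: canonical frame, extents, areas, volume, roundness."""

import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from seedhull.errors import DegenerateOutline, EmptyHull, InsufficientSlices
from seedhull.synthetic import SeedSolidSpec, make_seed_solid
from seedhull.traits import (
    SliceProfile,
    canonical_frame,
    cardioid_area,
    extents,
    j_index,
    max_projection_area,
    measure_all,
    polygon_area,
    projection_outline,
    roundness,
    slice_profile,
    surface_area,
    volume_slices,
)
from seedhull.visual_hull import VoxelGrid, grid_from_predicate, mesh_from_grid

SEMI = (3.3, 1.6, 1.4)


@pytest.fixture(scope="module")
def ellipsoid_ref_grid():
    solid = make_seed_solid(SeedSolidSpec(semi_axes=SEMI))
    return grid_from_predicate(solid.inside, np.zeros(3), side=7.2, resolution=128)


class TestCanonicalFrame:
    def test_axis_aligned_ellipsoid_gives_identity_frame(self, ellipsoid_ref_grid):
        frame = canonical_frame(ellipsoid_ref_grid)
        assert np.allclose(np.abs(frame.axes), np.eye(3), atol=1e-6)

    def test_prerotated_ellipsoid_frame_recovers_rotation(self):
        R = Rotation.from_rotvec([0.4, -0.3, 0.6]).as_matrix()
        solid = make_seed_solid(SeedSolidSpec(semi_axes=SEMI, R=R))
        grid = grid_from_predicate(solid.inside, np.zeros(3), side=8.0, resolution=96)
        frame = canonical_frame(grid)
        for k in range(3):
            ang = np.degrees(np.arccos(np.clip(abs(frame.axes[:, k] @ R[:, k]), -1, 1)))
            assert ang < 1.0

    def test_sphere_accepts_any_orthonormal_frame(self):
        solid = make_seed_solid(SeedSolidSpec(semi_axes=(1.5, 1.5, 1.5)))
        grid = grid_from_predicate(solid.inside, np.zeros(3), side=3.4, resolution=64)
        frame = canonical_frame(grid)
        assert np.allclose(frame.axes.T @ frame.axes, np.eye(3), atol=1e-9)
        assert np.linalg.det(frame.axes) == pytest.approx(1.0)

    def test_empty_grid_raises(self):
        grid = VoxelGrid(origin=np.zeros(3), spacing=0.1, occupancy=np.zeros((3, 3, 3), bool))
        with pytest.raises(EmptyHull):
            canonical_frame(grid)


class TestExtents:
    def test_ellipsoid_extents(self, ellipsoid_ref_grid):
        frame = canonical_frame(ellipsoid_ref_grid)
        pts = frame.transform(ellipsoid_ref_grid.occupied_points())
        L, W, D = extents(pts, ellipsoid_ref_grid.spacing)
        tol = 2 * ellipsoid_ref_grid.spacing
        assert abs(L - 6.6) < tol and abs(W - 3.2) < tol and abs(D - 2.8) < tol

    def test_unit_cube(self):
        grid = grid_from_predicate(
            lambda p: (np.abs(p) <= 0.5).all(axis=1), np.zeros(3), side=1.3, resolution=64
        )
        L, W, D = extents(grid.occupied_points(), grid.spacing)
        tol = 2 * grid.spacing
        assert abs(L - 1) < tol and abs(W - 1) < tol and abs(D - 1) < tol

    def test_single_voxel_spans_one_spacing(self):
        pts = np.array([[0.3, 0.4, 0.5]])
        assert extents(pts, 0.07) == pytest.approx((0.07, 0.07, 0.07))


class TestSurfaceArea:
    def test_unit_cube_is_six(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        assert surface_area(box) == pytest.approx(6.0, abs=1e-12)

    def test_icosphere_matches_4pi(self):
        sph = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        assert surface_area(sph) == pytest.approx(4 * np.pi, rel=0.01)

    def test_degenerate_face_contributes_zero(self):
        box = trimesh.creation.box(extents=(1, 1, 1))
        v = np.vstack([box.vertices, box.vertices[0]])
        f = np.vstack([box.faces, [0, 1, len(v) - 1]])  # zero-area sliver
        degen = trimesh.Trimesh(vertices=v, faces=f, process=False)
        assert surface_area(degen) == pytest.approx(surface_area(box), abs=1e-12)

    def test_heron_matches_cross_product_area(self, ellipsoid_mesh):
        assert surface_area(ellipsoid_mesh) == pytest.approx(ellipsoid_mesh.area, rel=1e-9)


class TestVolume:
    def test_cylinder_constant_sections_exact(self):
        prof = SliceProfile(axis=0, areas=np.full(50, np.pi * 4.0), positions=np.linspace(0, 10, 50))
        assert volume_slices(prof, 10.0) == pytest.approx(np.pi * 4.0 * 10.0)

    def test_sphere_analytic_slices(self):
        z = np.linspace(-1, 1, 200)
        prof = SliceProfile(axis=0, areas=np.pi * (1 - z**2), positions=z)
        assert volume_slices(prof, 2.0) == pytest.approx(4 * np.pi / 3, rel=0.005)

    def test_slices_agree_with_voxel_count(self, ellipsoid_ref_grid):
        frame = canonical_frame(ellipsoid_ref_grid)
        pts = frame.transform(ellipsoid_ref_grid.occupied_points())
        prof = slice_profile(pts, ellipsoid_ref_grid.spacing, axis=0)
        L = extents(pts, ellipsoid_ref_grid.spacing)[0]
        v = volume_slices(prof, L)
        assert v == pytest.approx(ellipsoid_ref_grid.voxel_volume(), rel=0.02)

    def test_single_slice_raises(self):
        prof = SliceProfile(axis=0, areas=np.array([1.0]), positions=np.array([0.0]))
        with pytest.raises(InsufficientSlices):
            volume_slices(prof, 1.0)


class TestProjectionAreas:
    def test_cube_shadow(self):
        grid = grid_from_predicate(
            lambda p: (np.abs(p) <= 0.5).all(axis=1), np.zeros(3), side=1.3, resolution=64
        )
        A = max_projection_area(grid.occupied_points(), grid.spacing)
        assert A == pytest.approx(1.0, rel=2 * 2 * grid.spacing)

    def test_ellipsoid_shadow_matches_pi_ab(self, ellipsoid_ref_grid):
        frame = canonical_frame(ellipsoid_ref_grid)
        pts = frame.transform(ellipsoid_ref_grid.occupied_points())
        A = polygon_area(projection_outline(pts, ellipsoid_ref_grid.spacing))
        assert A == pytest.approx(np.pi * SEMI[0] * SEMI[1], rel=0.03)

    def test_shadow_bounded_by_length_width(self, ellipsoid_ref_grid):
        frame = canonical_frame(ellipsoid_ref_grid)
        pts = frame.transform(ellipsoid_ref_grid.occupied_points())
        s = ellipsoid_ref_grid.spacing
        L, W, _ = extents(pts, s)
        assert max_projection_area(pts, s) <= L * W + 1e-9

    def test_ellipsoid_transverse_section_matches_pi_bc(self, ellipsoid_ref_grid):
        frame = canonical_frame(ellipsoid_ref_grid)
        pts = frame.transform(ellipsoid_ref_grid.occupied_points())
        A_C = cardioid_area(pts, ellipsoid_ref_grid.spacing)
        assert A_C == pytest.approx(np.pi * SEMI[1] * SEMI[2], rel=0.03)

    def test_crease_strictly_reduces_cardioid_area(self):
        plain = make_seed_solid(SeedSolidSpec(semi_axes=SEMI))
        creased = make_seed_solid(
            SeedSolidSpec(semi_axes=SEMI, crease_depth=0.5, crease_width=1.1)
        )
        gp = grid_from_predicate(plain.inside, np.zeros(3), side=7.2, resolution=96)
        gc = grid_from_predicate(creased.inside, np.zeros(3), side=7.2, resolution=96)
        ap = cardioid_area(gp.occupied_points() - gp.origin, gp.spacing)
        ac = cardioid_area(gc.occupied_points() - gc.origin, gc.spacing)
        assert ac < ap - 2 * gp.spacing**2


class TestJIndexAndRoundness:
    def test_inscribed_ellipse_gives_pi_over_4(self):
        assert j_index(np.pi * 1.6 * 1.4, 3.2, 2.8) == pytest.approx(np.pi / 4)

    def test_panel_scale_arithmetic(self):
        # A_C = 7.29 mm^2, W = 3.23 mm, D = 2.83 mm -> J ~ 0.797
        J = j_index(7.29, 3.23, 2.83)
        assert J == pytest.approx(0.797, abs=0.001)
        assert J == pytest.approx(0.79, abs=0.01)

    def test_full_rectangle_gives_one(self):
        assert j_index(3.2 * 2.8, 3.2, 2.8) == pytest.approx(1.0)

    def test_zero_width_guard(self):
        with pytest.raises(ZeroDivisionError):
            j_index(1.0, 0.0, 1.0)

    def test_circle_roundness_is_one(self):
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        poly = np.column_stack([np.cos(th), np.sin(th)])
        assert roundness(poly) == pytest.approx(1.0, rel=0.01)

    def test_square_roundness_is_pi_over_4(self):
        poly = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        assert roundness(poly) == pytest.approx(np.pi / 4)

    def test_ellipse_roundness_matches_numeric_perimeter_oracle(self):
        a, b = 2.0, 1.0
        th = np.linspace(0, 2 * np.pi, 5000, endpoint=False)
        poly = np.column_stack([a * np.cos(th), b * np.sin(th)])
        # independent oracle: dense numeric arc length + exact area
        th_f = np.linspace(0, 2 * np.pi, 200001)
        dx = -a * np.sin(th_f)
        dy = b * np.cos(th_f)
        P = np.trapezoid(np.hypot(dx, dy), th_f)
        expected = 4 * np.pi * (np.pi * a * b) / P**2
        assert roundness(poly) == pytest.approx(expected, rel=0.01)

    def test_degenerate_outline_raises(self):
        with pytest.raises(DegenerateOutline):
            roundness(np.array([[0.0, 0], [1, 1]]))


class TestMeasureAll:
    def test_carved_ellipsoid_traits(self, ellipsoid_grid, ellipsoid_mesh):
        tr = measure_all(ellipsoid_grid, ellipsoid_mesh)
        a, b, c = SEMI
        s = ellipsoid_grid.spacing
        assert tr.length == pytest.approx(2 * a, abs=2 * s)
        assert tr.width == pytest.approx(2 * b, abs=2 * s)
        assert tr.thickness == pytest.approx(2 * c, abs=2 * s)
        assert tr.volume == pytest.approx(4 / 3 * np.pi * a * b * c, rel=0.05)
        assert tr.projection_area == pytest.approx(np.pi * a * b, rel=0.05)
        assert tr.cardioid_area == pytest.approx(np.pi * b * c, rel=0.05)
        assert tr.j_index == pytest.approx(np.pi / 4, abs=0.03)
        # type invariants
        assert tr.length >= tr.width >= tr.thickness > 0
        assert tr.volume <= tr.length * tr.width * tr.thickness
        assert 0 < tr.j_index <= 1
        assert 0 < tr.roundness <= 1

    def test_sphere_symmetry(self):
        solid = make_seed_solid(SeedSolidSpec(semi_axes=(1.5, 1.5, 1.5)))
        grid = grid_from_predicate(solid.inside, np.zeros(3), side=3.4, resolution=96)
        tr = measure_all(grid, mesh_from_grid(grid))
        assert tr.length == pytest.approx(tr.width, rel=0.02)
        assert tr.width == pytest.approx(tr.thickness, rel=0.02)
        assert tr.j_index == pytest.approx(np.pi / 4, abs=0.02)
        assert tr.roundness == pytest.approx(1.0, abs=0.03)

    def test_crease_lowers_j_index_only(self):
        plain = make_seed_solid(SeedSolidSpec(semi_axes=SEMI))
        creased = make_seed_solid(
            SeedSolidSpec(semi_axes=SEMI, crease_depth=0.5, crease_width=1.1)
        )
        gp = grid_from_predicate(plain.inside, np.zeros(3), side=7.2, resolution=96)
        gc = grid_from_predicate(creased.inside, np.zeros(3), side=7.2, resolution=96)
        tp = measure_all(gp, mesh_from_grid(gp))
        tc = measure_all(gc, mesh_from_grid(gc))
        assert tc.j_index < tp.j_index
        assert tc.length == pytest.approx(tp.length, rel=0.02)
        assert tc.width == pytest.approx(tp.width, rel=0.02)

    def test_rigid_rotation_invariance(self):
        R = Rotation.from_rotvec([0.3, 0.5, -0.2]).as_matrix()
        plain = make_seed_solid(SeedSolidSpec(semi_axes=SEMI))
        rot = make_seed_solid(SeedSolidSpec(semi_axes=SEMI, R=R))
        g0 = grid_from_predicate(plain.inside, np.zeros(3), side=8.0, resolution=96)
        g1 = grid_from_predicate(rot.inside, np.zeros(3), side=8.0, resolution=96)
        t0 = measure_all(g0, mesh_from_grid(g0)).as_dict()
        t1 = measure_all(g1, mesh_from_grid(g1)).as_dict()
        for k in t0:
            assert t1[k] == pytest.approx(t0[k], rel=0.02), k
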