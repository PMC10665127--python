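"""Reconstruct a creased wheat-like seed and measure its nine traits.

Builds a synthetic seed (6.6 x 3.2 x 2.8 mm superellipsoid with a ventral
groove) hanging on the rotation axis, renders 40 silhouettes at 9-degree
steps, carves the visual hull at 128^3 voxels, extracts the marching-cubes
mesh, and prints the nine traits.  The final block contrasts the hull
measurement with a direct voxelisation of the true solid: the groove is a
concavity running along the rotation axis, so silhouettes cannot recover
its depth — the hull's cross-sections are near-convex and its volume and
J index sit above the true creased values.  That gap is the method's known
blind spot, not a bug.
"""

import numpy as np

from seedhull.calibration import RigidPose, axis_aligned_rotation, generate_virtual_views
from seedhull.synthetic import default_rig, make_wheat_like_solid, render_silhouettes
from seedhull.traits import measure_all
from seedhull.visual_hull import carve, grid_from_predicate, mesh_from_grid

intrinsics, _, axis = default_rig(image_size=(960, 960), alpha=5000, depth=50.0)
base = RigidPose(R=np.eye(3), T=np.zeros(3))  # seed world frame == camera frame

solid = make_wheat_like_solid(R=axis_aligned_rotation(axis.direction), t=axis.point)
projections = generate_virtual_views(base, axis, intrinsics, step_deg=9.0, n_views=40)
masks = render_silhouettes(solid, projections, (960, 960))

grid = carve(masks, projections, resolution=128)
mesh = mesh_from_grid(grid)
traits = measure_all(grid, mesh)

print(f"carved voxels: {grid.n_occupied} at {grid.spacing:.4f} mm spacing")
for name, value, unit in [
    ("length L", traits.length, "mm"),
    ("width W", traits.width, "mm"),
    ("thickness D", traits.thickness, "mm"),
    ("surface area S", traits.surface_area, "mm^2"),
    ("volume V", traits.volume, "mm^3"),
    ("projection area A", traits.projection_area, "mm^2"),
    ("roundness R", traits.roundness, ""),
    ("cardioid area A_C", traits.cardioid_area, "mm^2"),
    ("J index", traits.j_index, ""),
]:
    print(f"  {name:<18s} {value:8.3f} {unit}")
print(f"reference solid volume: {solid.reference_volume():.3f} mm^3 "
      f"(hull excess {(traits.volume / solid.reference_volume() - 1) * 100:+.1f}%)")

# ground truth by direct voxelisation of the implicit solid (no imaging)
ref = grid_from_predicate(solid.inside, solid.center, side=7.3, resolution=128)
ref_traits = measure_all(ref, mesh_from_grid(ref))
print(f"true-solid J index:     {ref_traits.j_index:.3f}  vs hull J {traits.j_index:.3f} "
      "(silhouettes cannot see into the groove)")
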