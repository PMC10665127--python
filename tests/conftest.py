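"""Shared synthetic fixtures: a small rig, rendered boards, a carved ellipsoid.

Everything is generated at test time with fixed seeds; heavier artefacts
(rendered silhouettes, carved grids) are session-scoped and reused.
"""

import numpy as np
import pytest

from seedhull.calibration import (
    BoardSpec,
    RigidPose,
    axis_aligned_rotation,
    detect_corners,
    generate_virtual_views,
    rotate_pose,
)
from seedhull.synthetic import (
    SeedSolidSpec,
    default_rig,
    make_seed_solid,
    render_checkerboard,
    render_silhouettes,
)
from seedhull.visual_hull import carve, mesh_from_grid

SEMI_AXES = (3.3, 1.6, 1.4)
IMAGE = (800, 800)
N_VIEWS = 40
STEP_DEG = 9.0


@pytest.fixture(scope="session")
def board():
    return BoardSpec()


@pytest.fixture(scope="session")
def rig(board):
    """Intrinsics, tilted base board pose and turntable axis for board views."""
    return default_rig(image_size=(480, 480), alpha=2600, depth=32.0, board=board)


@pytest.fixture(scope="session")
def board_image(rig, board):
    intr, base_pose, _ = rig
    return render_checkerboard(board, base_pose, intr, (480, 480))


@pytest.fixture(scope="session")
def board_sequence(rig, board):
    """Nine rotated board views: (images, ground-truth corner sets)."""
    intr, base_pose, axis = rig
    imgs, gts = [], []
    for k in range(9):
        img, gt = render_checkerboard(board, rotate_pose(base_pose, axis, k * 9.0), intr, (480, 480))
        imgs.append(img)
        gts.append(gt)
    return imgs, gts


@pytest.fixture(scope="session")
def detected_sequence(board_sequence, board):
    imgs, _ = board_sequence
    return [detect_corners(img, board) for img in imgs]


@pytest.fixture(scope="session")
def seed_rig():
    """Seed-view rig: world frame == camera frame, 40 views over a turn."""
    intr, _, axis = default_rig(image_size=IMAGE, alpha=4000, depth=50.0)
    base = RigidPose(R=np.eye(3), T=np.zeros(3))
    projections = generate_virtual_views(base, axis, intr, STEP_DEG, N_VIEWS)
    return intr, axis, projections


@pytest.fixture(scope="session")
def ellipsoid_solid(seed_rig):
    _, axis, _ = seed_rig
    return make_seed_solid(
        SeedSolidSpec(
            semi_axes=SEMI_AXES, R=axis_aligned_rotation(axis.direction), t=axis.point
        )
    )


@pytest.fixture(scope="session")
def ellipsoid_masks(seed_rig, ellipsoid_solid):
    _, _, projections = seed_rig
    return render_silhouettes(ellipsoid_solid, projections, IMAGE)


@pytest.fixture(scope="session")
def ellipsoid_grid(seed_rig, ellipsoid_masks):
    _, _, projections = seed_rig
    return carve(ellipsoid_masks, projections, resolution=64)


@pytest.fixture(scope="session")
def ellipsoid_mesh(ellipsoid_grid):
    return mesh_from_grid(ellipsoid_grid)


@pytest.fixture(scope="session")
def germplasm_table():
    from seedhull.synthetic import default_germplasm_spec, simulate_germplasm

    return simulate_germplasm(default_germplasm_spec(seed=11))
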