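"""Synthetic fixtures with analytic ground truth.

Every input the pipeline consumes can be generated here:

* parametric seed solids (superellipsoids with an optional ventral groove)
  carrying an ``inside`` predicate and a high-resolution reference volume,
* binary silhouettes of a solid rendered under known projection matrices
  (ray sampling against the inside predicate),
* anti-aliased checkerboard images with ground-truth corner projections,
* corner trajectories of a rotating board (optionally with pixel noise),
* simulated per-variety germplasm trait tables with known means/SDs.

The germplasm generator's default conditions mirror the reference study:
15 varieties (2 parents, 13 offspring in two cross batches), 30 seeds per
variety, and pooled per-trait means/SDs on the scale of a real wheat panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .calibration import (
    BoardSpec,
    CornerTrajectory,
    Intrinsics,
    ProjectionMatrix,
    RigidPose,
    RotationAxis,
    board_points,
    build_projection,
    decompose_projection,
    estimate_board_pose,
    fit_homography,
    generate_virtual_views,
    rotate_pose,
)
from .errors import InvalidSpec, OutOfFrustum

__all__ = [
    "SeedSolidSpec",
    "SeedSolid",
    "make_seed_solid",
    "make_wheat_like_solid",
    "render_silhouettes",
    "render_seed_images",
    "render_checkerboard",
    "simulate_corner_trajectories",
    "default_rig",
    "TRAIT_COLUMNS",
    "TRAIT_SUMMARY",
    "VarietySpec",
    "GermplasmSimSpec",
    "default_germplasm_spec",
    "simulate_germplasm",
]


# ---------------------------------------------------------------------------
# seed solids
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedSolidSpec:
    """Superellipsoid seed body with an optional ventral groove.

    The implicit body is ``(|x/a|^m + |y/b|^m + |z/c|^m) <= 1`` in the solid
    frame (x = length, y = width, z = thickness, all mm), minus a cylindrical
    groove of depth ``crease_depth`` and surface width ``crease_width``
    running along the length axis on the +z side — the wheat crease.
    ``R``/``t`` pose the solid frame in the world frame.
    """

    semi_axes: tuple[float, float, float] = (3.3, 1.6, 1.4)
    exponent: float = 2.0
    crease_depth: float = 0.0
    crease_width: float = 1.0
    R: np.ndarray = field(default_factory=lambda: np.eye(3))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        a, b, c = self.semi_axes
        if not (a >= b >= c > 0):
            raise InvalidSpec("semi-axes must satisfy a >= b >= c > 0")
        if self.exponent < 1:
            raise InvalidSpec("superellipsoid exponent must be >= 1")
        if self.crease_depth < 0 or self.crease_depth >= c:
            if self.crease_depth != 0:
                raise InvalidSpec("crease_depth must lie in [0, c)")
        if self.crease_depth > 0 and self.crease_width <= 0:
            raise InvalidSpec("crease_width must be positive")
        object.__setattr__(self, "R", np.asarray(self.R, dtype=float))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))


class SeedSolid:
    """Implicit seed solid with a vectorised inside test."""

    def __init__(self, spec: SeedSolidSpec):
        self.spec = spec
        a, b, c = spec.semi_axes
        self._radius = float(np.linalg.norm([a, b, c]))
        if spec.crease_depth > 0:
            d, w = spec.crease_depth, spec.crease_width
            self._rc = (w * w / 4.0 + d * d) / (2.0 * d)  # groove cylinder radius
            self._z0 = c + self._rc - d
        else:
            self._rc = None
        self._ref_volume: float | None = None

    @property
    def center(self) -> np.ndarray:
        """Solid-frame origin in world coordinates."""
        return self.spec.t

    @property
    def bounding_radius(self) -> float:
        """Radius of a world-frame bounding sphere around ``center``."""
        return self._radius

    def ray_intersects(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray | None:
        """Exact ray-hit test for exponent-2 (ellipsoid) bodies.

        Returns a boolean array (one per unit direction) or ``None`` when no
        closed form applies and the caller must fall back to ray sampling.
        The groove case is exact too: the groove cylinder is convex, so the
        ellipsoid chord lies entirely inside it iff both chord endpoints do.
        """
        if self.spec.exponent != 2.0:
            return None
        ax = np.asarray(self.spec.semi_axes)
        o_s = (origin - self.spec.t) @ self.spec.R  # solid frame
        d_s = dirs @ self.spec.R
        o = o_s / ax
        d = d_s / ax
        a = (d * d).sum(axis=1)
        b = d @ o
        c = o @ o - 1.0
        disc = b * b - a * c
        hit = disc >= 0
        sq = np.sqrt(np.clip(disc, 0, None))
        t0 = (-b - sq) / a
        t1 = (-b + sq) / a
        hit &= t1 > 0  # intersection must be in front of the camera
        if self._rc is not None:
            def in_groove(t):
                p = o_s[None, :] + t[:, None] * d_s
                return p[:, 1] ** 2 + (p[:, 2] - self._z0) ** 2 < self._rc**2

            hit &= ~(in_groove(t0) & in_groove(t1))
        return hit

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boolean inside test for (N, 3) world points."""
        p = (np.asarray(points, dtype=float) - self.spec.t) @ self.spec.R
        a, b, c = self.spec.semi_axes
        m = self.spec.exponent
        f = (
            np.abs(p[..., 0] / a) ** m
            + np.abs(p[..., 1] / b) ** m
            + np.abs(p[..., 2] / c) ** m
        )
        ins = f <= 1.0
        if self._rc is not None:
            groove = p[..., 1] ** 2 + (p[..., 2] - self._z0) ** 2 < self._rc**2
            ins &= ~groove
        return ins

    def reference_volume(self, n: int = 256) -> float:
        """Midpoint-rule volume over the solid-frame bounding box (mm^3)."""
        if self._ref_volume is None:
            a, b, c = self.spec.semi_axes
            xs = (np.arange(n) + 0.5) / n * 2 * a - a
            ys = (np.arange(n) + 0.5) / n * 2 * b - b
            zs = (np.arange(n) + 0.5) / n * 2 * c - c
            cell = (2 * a / n) * (2 * b / n) * (2 * c / n)
            count = 0
            # slab-wise to bound memory
            Y, Z = np.meshgrid(ys, zs, indexing="ij")
            base = np.stack([Y.ravel(), Z.ravel()], axis=1)
            solid_frame = SeedSolid(
                SeedSolidSpec(
                    semi_axes=self.spec.semi_axes,
                    exponent=self.spec.exponent,
                    crease_depth=self.spec.crease_depth,
                    crease_width=self.spec.crease_width,
                )
            )
            for x in xs:
                pts = np.column_stack([np.full(len(base), x), base])
                count += int(solid_frame.inside(pts).sum())
            self._ref_volume = count * cell
        return self._ref_volume


def make_seed_solid(spec: SeedSolidSpec) -> SeedSolid:
    """Instantiate a solid from its spec (validates the spec)."""
    return SeedSolid(spec)


def make_wheat_like_solid(
    R: np.ndarray | None = None, t: np.ndarray | None = None, creased: bool = True
) -> SeedSolid:
    """A wheat-grain-like fixture: 6.6 x 3.2 x 2.8 mm with a ventral groove."""
    return SeedSolid(
        SeedSolidSpec(
            semi_axes=(3.3, 1.6, 1.4),
            exponent=2.0,
            crease_depth=0.5 if creased else 0.0,
            crease_width=1.1,
            R=np.eye(3) if R is None else R,
            t=np.zeros(3) if t is None else t,
        )
    )


# ---------------------------------------------------------------------------
# silhouette rendering (ray sampling)
# ---------------------------------------------------------------------------


def _view_rays(P: ProjectionMatrix):
    intr, pose = decompose_projection(P)
    Kinv = np.linalg.inv(intr.K)
    C = -pose.R.T @ pose.T
    return C, pose.R.T @ Kinv


def render_silhouettes(
    solid: SeedSolid,
    projections: list[ProjectionMatrix],
    image_size: tuple[int, int],
    n_steps: int = 160,
) -> list[np.ndarray]:
    """Binary silhouettes of the solid under each projection.

    A pixel is foreground iff samples along its camera ray hit the solid's
    inside predicate; the boundary is accurate to about one pixel.  Rays are
    restricted to the projection of the solid's bounding sphere.

    Raises :class:`OutOfFrustum` if the bounding sphere does not project
    fully inside the image in some view.
    """
    H, W = image_size
    masks = []
    for P in projections:
        C, M = _view_rays(P)
        uv_c, depth_c = P.project(solid.center[None, :])
        (uc, vc), depth = uv_c[0], depth_c[0]
        if depth <= 0:
            raise OutOfFrustum("solid is behind the camera")
        intr, _ = decompose_projection(P)
        r_px = solid.bounding_radius * max(intr.alpha_u, intr.alpha_v) / depth
        u0i, u1i = int(np.floor(uc - r_px)), int(np.ceil(uc + r_px)) + 1
        v0i, v1i = int(np.floor(vc - r_px)), int(np.ceil(vc + r_px)) + 1
        if u0i < 0 or v0i < 0 or u1i > W or v1i > H:
            raise OutOfFrustum("solid does not project fully inside the image")

        mask = np.zeros((H, W), dtype=bool)
        us = np.arange(u0i, u1i, dtype=float)
        sc, rb = solid.center, solid.bounding_radius
        chunk = max(1, int(2e7 / max(len(us) * n_steps, 1)))
        for v_start in range(v0i, v1i, chunk):
            vs = np.arange(v_start, min(v_start + chunk, v1i), dtype=float)
            uu, vv = np.meshgrid(us, vs)
            pix = np.stack([uu.ravel(), vv.ravel(), np.ones(uu.size)], axis=0)
            d = (M @ pix).T  # ray directions, (n, 3)
            dn = d / np.linalg.norm(d, axis=1, keepdims=True)
            exact = solid.ray_intersects(C, dn)
            if exact is not None:
                mask[int(vs[0]) : int(vs[-1]) + 1, u0i:u1i] = exact.reshape(
                    len(vs), len(us)
                )
                continue
            # intersect with the bounding sphere for the sampling interval
            oc = C - sc
            b = dn @ oc
            disc = b * b - (oc @ oc - rb * rb)
            hit = disc > 0
            if not hit.any():
                continue
            sq = np.sqrt(disc[hit])
            t0 = -b[hit] - sq
            t1 = -b[hit] + sq
            frac = np.linspace(0.0, 1.0, n_steps, dtype=np.float32)
            ts = t0[:, None].astype(np.float32) + (t1 - t0)[:, None].astype(
                np.float32
            ) * frac[None, :]
            pts = C[None, None, :].astype(np.float32) + ts[..., None] * dn[hit][
                :, None, :
            ].astype(np.float32)
            ins = solid.inside(pts.reshape(-1, 3)).reshape(ts.shape).any(axis=1)
            sub = np.zeros(uu.size, dtype=bool)
            sub[hit] = ins
            mask[int(vs[0]) : int(vs[-1]) + 1, u0i:u1i] = sub.reshape(len(vs), len(us))
        masks.append(mask)
    return masks


def render_seed_images(
    solid: SeedSolid,
    projections: list[ProjectionMatrix],
    image_size: tuple[int, int],
    nozzle_width_px: int = 8,
    background: float = 0.12,
    foreground: float = 0.85,
    nozzle_value: float = 0.80,
    n_steps: int = 160,
) -> list[np.ndarray]:
    """Grayscale seed views: bright seed on dark background plus a bright
    suction-nozzle bar entering from the top edge down to the seed apex."""
    masks = render_silhouettes(solid, projections, image_size, n_steps=n_steps)
    images = []
    for mask in masks:
        img = np.full(mask.shape, background, dtype=float)
        img[mask] = foreground
        rows = np.flatnonzero(mask.any(axis=1))
        if len(rows):
            top = rows[0]
            cols = np.flatnonzero(mask[top])
            cc = int(round(cols.mean()))
            half = max(1, nozzle_width_px // 2)
            img[: top + 2, max(0, cc - half) : cc + half] = nozzle_value
        images.append(img)
    return images


# ---------------------------------------------------------------------------
# checkerboard rendering
# ---------------------------------------------------------------------------


def render_checkerboard(
    board: BoardSpec,
    pose: RigidPose,
    intrinsics: Intrinsics,
    image_size: tuple[int, int],
    supersample: int = 3,
    dark: float = 0.08,
    light: float = 0.92,
    background: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Anti-aliased two-tone checkerboard image plus ground-truth corners.

    Interior corner (r, c) sits at world (c*pitch, r*pitch, 0); the squares
    extend one pitch beyond the interior grid on every side.  Returns
    (image, corners) with corners (rows*cols, 2) row-major, matching
    :func:`seedhull.calibration.detect_corners` ordering from the top-left.
    """
    H, W = image_size
    P = build_projection(intrinsics, pose)
    corners, depth = P.project(board_points(board))
    if (depth <= 0).any():
        raise OutOfFrustum("board is behind the camera")
    if (
        corners[:, 0].min() < 2
        or corners[:, 1].min() < 2
        or corners[:, 0].max() > W - 3
        or corners[:, 1].max() > H - 3
    ):
        raise OutOfFrustum("board does not project fully inside the image")

    # pixel -> board-plane homography
    Hmat = intrinsics.K @ np.column_stack([pose.R[:, 0], pose.R[:, 1], pose.T])
    Hinv = np.linalg.inv(Hmat)
    off = (np.arange(supersample) + 0.5) / supersample - 0.5
    img = np.zeros((H, W), dtype=float)
    vs = np.arange(H, dtype=float)
    us = np.arange(W, dtype=float)
    p = board.pitch
    for dv in off:
        for du in off:
            uu, vv = np.meshgrid(us + du, vs + dv)
            w = Hinv[2, 0] * uu + Hinv[2, 1] * vv + Hinv[2, 2]
            x = (Hinv[0, 0] * uu + Hinv[0, 1] * vv + Hinv[0, 2]) / w
            y = (Hinv[1, 0] * uu + Hinv[1, 1] * vv + Hinv[1, 2]) / w
            on_board = (
                (x >= -p)
                & (x <= board.cols * p)
                & (y >= -p)
                & (y <= board.rows * p)
            )
            parity = (np.floor(x / p) + np.floor(y / p)) % 2
            tone = np.where(parity == 0, dark, light)
            img += np.where(on_board, tone, background)
    img /= supersample**2
    return img, corners


# ---------------------------------------------------------------------------
# turntable trajectories
# ---------------------------------------------------------------------------


def default_rig(
    image_size: tuple[int, int] = (640, 640),
    alpha: float | None = None,
    depth: float = 50.0,
    board: BoardSpec | None = None,
) -> tuple[Intrinsics, RigidPose, RotationAxis]:
    """A plausible synthetic rig: camera ~50 mm from a near-vertical axis.

    Returns intrinsics, a tilted base board pose centred on the axis point,
    and the turntable axis (mostly along -y in the camera frame, i.e. image
    up, with a small skew).  When ``alpha`` is omitted it scales with the
    image width so a wheat-sized seed at the axis fills most of the frame."""
    H, W = image_size
    if alpha is None:
        alpha = 6.0 * W
    intr = Intrinsics(alpha_u=alpha, alpha_v=alpha, u0=W / 2.0, v0=H / 2.0)
    board = board or BoardSpec()
    axis_dir = np.array([0.06, -1.0, 0.09])
    axis_dir /= np.linalg.norm(axis_dir)
    axis = RotationAxis(
        point=np.array([0.15, -0.1, depth]),
        direction=axis_dir,
        eigenvalues=np.array([1.0, 0.0, 0.0]),
        n_centers=0,
    )
    R = Rotation.from_rotvec([0.35, 0.25, 0.1]).as_matrix()
    center = np.array(
        [(board.cols - 1) * board.pitch / 2.0, (board.rows - 1) * board.pitch / 2.0, 0.0]
    )
    T = axis.point - R @ center
    return intr, RigidPose(R=R, T=T), axis


def simulate_corner_trajectories(
    board: BoardSpec,
    intrinsics: Intrinsics,
    base_pose: RigidPose,
    axis: RotationAxis,
    n_views: int = 9,
    step_deg: float = 9.0,
    pixel_noise: float = 0.0,
    n_corners: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[CornerTrajectory]:
    """Camera-frame trajectories of board corners over the rotation steps.

    With ``pixel_noise = 0`` the trajectories are the exact rotated corner
    positions.  Otherwise corners are projected, perturbed by isotropic
    Gaussian pixel noise, the board pose is re-estimated per view, and the
    trajectories are rebuilt from the noisy poses — the same path real
    imagery takes.
    """
    rng = rng or np.random.default_rng(0)
    world = board_points(board)
    poses = [rotate_pose(base_pose, axis, k * step_deg) for k in range(n_views)]
    if pixel_noise > 0:
        est = []
        for pose in poses:
            uv, _ = build_projection(intrinsics, pose).project(world)
            uv = uv + rng.normal(scale=pixel_noise, size=uv.shape)
            est.append(estimate_board_pose(uv, board, intrinsics))
        poses = est
    cam = np.stack([pose.apply(world) for pose in poses], axis=0)  # (views, corners, 3)
    ids = [(r, c) for r in range(board.rows) for c in range(board.cols)]
    n_corners = n_corners or len(ids)
    keep = np.linspace(0, len(ids) - 1, n_corners).round().astype(int)
    return [CornerTrajectory(corner_id=ids[j], points=cam[:, j]) for j in keep]


# ---------------------------------------------------------------------------
# germplasm trait-table simulation
# ---------------------------------------------------------------------------

TRAIT_COLUMNS = [
    "length",
    "width",
    "thickness",
    "surface_area",
    "volume",
    "projection_area",
    "roundness",
    "cardioid_area",
    "j_index",
]

#: pooled per-trait (mean, SD) on the scale of a real wheat panel (mm-based
#: units); these define the generator's default study conditions.
TRAIT_SUMMARY = {
    "length": (6.67, 0.44),
    "width": (3.23, 0.31),
    "thickness": (2.83, 0.24),
    "surface_area": (52.36, 7.54),
    "volume": (28.77, 6.45),
    "projection_area": (16.45, 2.41),
    "roundness": (0.61, 0.04),
    "cardioid_area": (7.29, 1.24),
    "j_index": (0.79, 0.03),
}


@dataclass(frozen=True)
class VarietySpec:
    name: str
    group: str  # 'parents', 'cross_1', 'cross_2'
    role: str  # 'parent' | 'offspring'
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sds.values()):
            raise InvalidSpec("trait SDs must be non-negative")


@dataclass(frozen=True)
class GermplasmSimSpec:
    varieties: tuple[VarietySpec, ...]
    seeds_per_variety: int = 30
    random_seed: int = 0
    divergent: str | None = None  # variety carrying the largest variance shift

    def __post_init__(self) -> None:
        if self.seeds_per_variety < 2:
            raise InvalidSpec("need >= 2 seeds per variety")
        if not self.varieties:
            raise InvalidSpec("need at least one variety")


def default_germplasm_spec(
    seed: int = 0,
    seeds_per_variety: int = 30,
    divergent: str = "F9",
    kappa: float = 4.0,
    rho: float = 0.1,
) -> GermplasmSimSpec:
    """Default 15-variety design: 2 parents + 13 offspring in two batches.

    Variance structure per trait with pooled SD ``sigma`` (from
    :data:`TRAIT_SUMMARY`): variety means are N(mean, (0.6 sigma)^2); each
    parent's within-variety variance is B/2 and ordinary offspring get
    (1 - rho) B where B = 0.5714 sigma^2, so the pooled SD reproduces the
    panel-scale SD in expectation.  One divergent offspring variety gets
    (1 + kappa) B — the largest parent-to-offspring variance shift — so its
    genetic variation factor dominates by construction.
    """
    rng = np.random.default_rng(seed)
    names = ["P1", "P2"] + [f"F{i}" for i in range(1, 14)]
    varieties = []
    for name in names:
        if name in ("P1", "P2"):
            group, role = "parents", "parent"
        elif int(name[1:]) <= 6:
            group, role = "cross_1", "offspring"
        else:
            group, role = "cross_2", "offspring"
        means, sds = {}, {}
        for trait, (mu, sigma) in TRAIT_SUMMARY.items():
            B = 0.5714 * sigma**2
            means[trait] = float(rng.normal(mu, 0.6 * sigma))
            if role == "parent":
                var = B / 2.0
            elif name == divergent:
                var = (1.0 + kappa) * B
            else:
                var = (1.0 - rho) * B
            sds[trait] = float(np.sqrt(var))
        varieties.append(VarietySpec(name=name, group=group, role=role, means=means, sds=sds))
    return GermplasmSimSpec(
        varieties=tuple(varieties),
        seeds_per_variety=seeds_per_variety,
        random_seed=seed,
        divergent=divergent,
    )


def simulate_germplasm(spec: GermplasmSimSpec) -> pd.DataFrame:
    """Draw a trait table honouring the spec; deterministic given its seed.

    Returns a DataFrame with seed_id, variety, group, role and the nine
    trait columns; traits are independent Gaussians per seed.
    """
    rng = np.random.default_rng(spec.random_seed)
    rows = []
    for var in spec.varieties:
        draws = {
            trait: rng.normal(var.means[trait], var.sds[trait], size=spec.seeds_per_variety)
            for trait in TRAIT_COLUMNS
        }
        for j in range(spec.seeds_per_variety):
            row = {
                "seed_id": f"{var.name}_{j:03d}",
                "variety": var.name,
                "group": var.group,
                "role": var.role,
            }
            row.update({trait: draws[trait][j] for trait in TRAIT_COLUMNS})
            rows.append(row)
    return pd.DataFrame(rows)
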