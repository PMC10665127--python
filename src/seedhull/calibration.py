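"""Turntable rig calibration.

The seed sits on a suction nozzle that a stepper motor rotates in fixed
angular steps in front of a fixed camera.  Calibrating the rig means
recovering, once per rig:

* the pinhole intrinsics ``K`` (focal scale factors, skew, principal point),
* the board pose per calibration view,
* the turntable rotation axis in the camera frame, fitted from the circular
  trajectories that checkerboard corners trace while the board rotates, and
* one virtual projection matrix ``P = K [R|T]`` per seed view, obtained by
  composing the base pose with rotations about the fitted axis.

All world/board coordinates are in millimetres; the board plane defines the
world frame (``z_w = 0``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.linalg import rq
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, cKDTree
from scipy.spatial.transform import Rotation

from .errors import (
    AmbiguousOrdering,
    DegenerateConfiguration,
    DegenerateTrajectory,
    IllConditionedAxisWarning,
    InsufficientCenters,
    InvalidIntrinsics,
    NoBoardFound,
)

__all__ = [
    "BoardSpec",
    "Intrinsics",
    "RigidPose",
    "ProjectionMatrix",
    "CornerTrajectory",
    "CircleFit",
    "RotationAxis",
    "CalibrationResult",
    "board_points",
    "detect_corners",
    "estimate_board_pose",
    "calibrate_intrinsics",
    "fit_trajectory_center",
    "fit_rotation_axis",
    "build_projection",
    "decompose_projection",
    "camera_center",
    "axis_aligned_rotation",
    "rotate_pose",
    "generate_virtual_views",
    "calibrate_rig",
    "fit_homography",
    "apply_homography",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoardSpec:
    """Checkerboard described by its interior-corner grid.

    The reference rig uses a 9 x 9 grid of interior corners with a
    corner-to-corner pitch of 0.5 mm.
    """

    rows: int = 9
    cols: int = 9
    pitch: float = 0.5  # mm, corner-to-corner

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("board needs at least 2x2 interior corners")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")

    @property
    def n_corners(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole intrinsic parameters.

    ``alpha_u = f/dx`` and ``alpha_v = f/dy`` are the focal scale factors in
    pixels, ``s_uv`` the skew term, ``(u0, v0)`` the principal point.  The
    physical focal length ``f`` (mm) is optional metadata; only the pixel
    scale factors are observable from images.
    """

    alpha_u: float
    alpha_v: float
    u0: float
    v0: float
    s_uv: float = 0.0
    f: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_u <= 0 or self.alpha_v <= 0:
            raise InvalidIntrinsics(
                f"focal scale factors must be positive, got "
                f"alpha_u={self.alpha_u}, alpha_v={self.alpha_v}"
            )

    @property
    def dx(self) -> float | None:
        """Pixel pitch (mm/px) along u, if ``f`` is known."""
        return None if self.f is None else self.f / self.alpha_u

    @property
    def dy(self) -> float | None:
        return None if self.f is None else self.f / self.alpha_v

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [
                [self.alpha_u, self.s_uv, self.u0],
                [0.0, self.alpha_v, self.v0],
                [0.0, 0.0, 1.0],
            ]
        )


@dataclass(frozen=True)
class RigidPose:
    """World -> camera rigid transform ``x_c = R x_w + T`` (mm)."""

    R: np.ndarray
    T: np.ndarray
    residual: float | None = None  # mean reprojection residual (px), if fitted

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        T = np.asarray(self.T, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise ValueError("R must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("R is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("R must be a proper rotation (det=+1)")
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "T", T)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 3) world points into the camera frame."""
        return np.asarray(points, dtype=float) @ self.R.T + self.T


@dataclass(frozen=True)
class ProjectionMatrix:
    """3x4 pinhole projection ``P = K [R|T]`` mapping mm to pixels."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (3, 4):
            raise ValueError("P must be 3x4")
        if np.linalg.matrix_rank(P) < 3:
            raise ValueError("P must have rank 3")
        object.__setattr__(self, "P", P)

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project (N, 3) world points; returns (N, 2) pixels and (N,) depths."""
        pts = np.asarray(points, dtype=float)
        h = pts @ self.P[:, :3].T + self.P[:, 3]
        z = h[..., 2]
        uv = h[..., :2] / z[..., None]
        return uv, z


@dataclass(frozen=True)
class CornerTrajectory:
    """Positions of one board corner in the camera frame across rotation steps."""

    corner_id: tuple[int, int]
    points: np.ndarray  # (n_steps, 3), mm

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class CircleFit:
    """3D circle fitted to a corner trajectory."""

    center: np.ndarray  # (3,), mm
    radius: float  # mm
    plane_normal: np.ndarray  # unit (3,)
    rms_residual: float  # mm, in-plane radial RMS


@dataclass(frozen=True)
class RotationAxis:
    """Turntable axis: a point and a unit direction in the camera frame."""

    point: np.ndarray  # centroid of circle centers, mm
    direction: np.ndarray  # unit vector, sign-fixed
    eigenvalues: np.ndarray  # covariance eigenvalues, descending
    n_centers: int


# ---------------------------------------------------------------------------
# board geometry / homographies
# ---------------------------------------------------------------------------


def board_points(board: BoardSpec) -> np.ndarray:
    """World coordinates of the interior corners, row-major, z_w = 0.

    Corner (r, c) sits at (c*pitch, r*pitch, 0).
    """
    r, c = np.meshgrid(np.arange(board.rows), np.arange(board.cols), indexing="ij")
    xy = np.stack([c.ravel() * board.pitch, r.ravel() * board.pitch], axis=1)
    return np.column_stack([xy, np.zeros(len(xy))])


def _normalise_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hartley normalisation: similarity T with centroid 0, mean norm sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2.0) / max(d, 1e-12)
    T = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])
    pn = (pts - centroid) * s
    return pn, T


def fit_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform homography mapping (N,2) src -> dst points."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if len(src) < 4:
        raise DegenerateConfiguration("homography needs >= 4 correspondences")
    sn, Ts = _normalise_points(src)
    dn, Td = _normalise_points(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    x, y = sn[:, 0], sn[:, 1]
    u, v = dn[:, 0], dn[:, 1]
    A[0::2, 0] = x
    A[0::2, 1] = y
    A[0::2, 2] = 1
    A[0::2, 6] = -u * x
    A[0::2, 7] = -u * y
    A[0::2, 8] = -u
    A[1::2, 3] = x
    A[1::2, 4] = y
    A[1::2, 5] = 1
    A[1::2, 6] = -v * x
    A[1::2, 7] = -v * y
    A[1::2, 8] = -v
    _, s, Vt = np.linalg.svd(A)
    if s[-2] < 1e-12 * s[0]:
        raise DegenerateConfiguration("degenerate correspondences for homography")
    H = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    h = np.asarray(pts, dtype=float) @ H[:2, :2].T + H[:2, 2]
    w = np.asarray(pts, dtype=float) @ H[2, :2] + H[2, 2]
    return h / w[:, None]


# ---------------------------------------------------------------------------
# corner detection
# ---------------------------------------------------------------------------


def _saddle_refine(pts: np.ndarray, derivs: dict[str, np.ndarray]) -> np.ndarray:
    """Newton refinement of saddle points of the smoothed intensity.

    A checkerboard corner is a saddle of the (Gaussian-smoothed) intensity
    surface; two Newton steps on the interpolated gradient/Hessian localise
    it to well below 0.1 px on clean imagery.
    """
    out = pts.astype(float).copy()
    shape = derivs["Ix"].shape
    for _ in range(3):
        coords = np.stack([out[:, 1], out[:, 0]])  # (row, col)
        vals = {
            k: ndimage.map_coordinates(v, coords, order=1, mode="nearest")
            for k, v in derivs.items()
        }
        g = np.stack([vals["Ix"], vals["Iy"]], axis=1)
        H = np.stack(
            [
                np.stack([vals["Ixx"], vals["Ixy"]], axis=1),
                np.stack([vals["Ixy"], vals["Iyy"]], axis=1),
            ],
            axis=1,
        )
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
        ok = np.abs(det) > 1e-12
        step = np.zeros_like(g)
        Hi = H[ok]
        step[ok] = np.linalg.solve(Hi, g[ok][..., None])[..., 0]
        step = np.clip(step, -1.0, 1.0)
        out[:, 0] = np.clip(out[:, 0] - step[:, 0], 0, shape[1] - 1)
        out[:, 1] = np.clip(out[:, 1] - step[:, 1], 0, shape[0] - 1)
    return out


def _quad_corners(pts: np.ndarray) -> np.ndarray:
    """Four extreme corners of a point grid, ordered as a cycle."""
    hull = pts[ConvexHull(pts).vertices]
    centroid = pts.mean(axis=0)
    q0 = hull[np.argmax(np.linalg.norm(hull - centroid, axis=1))]
    q1 = hull[np.argmax(np.linalg.norm(hull - q0, axis=1))]
    d = q1 - q0
    n = np.array([-d[1], d[0]]) / np.linalg.norm(d)
    signed = (hull - q0) @ n
    if signed.max() <= 1e-9 or signed.min() >= -1e-9:
        raise AmbiguousOrdering("detected points are degenerate (no quadrilateral)")
    q2 = hull[np.argmax(signed)]
    q3 = hull[np.argmin(signed)]
    quad = np.array([q0, q2, q1, q3])  # cycle around the board
    # start the cycle at the corner nearest the image origin (top-left)
    start = int(np.argmin(np.linalg.norm(quad, axis=1)))
    return np.roll(quad, -start, axis=0)


def detect_corners(
    image: np.ndarray, board: BoardSpec, sigma: float = 1.5
) -> np.ndarray:
    """Detect and canonically order the interior checkerboard corners.

    Returns an (rows*cols, 2) array of subpixel (u, v) pixel coordinates,
    row-major from a deterministically chosen origin corner (the extreme
    corner nearest the image top-left).

    Raises
    ------
    NoBoardFound
        if fewer saddle points than interior corners survive filtering.
    AmbiguousOrdering
        if the grid topology cannot be recovered from the detections.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2D array")
    if np.ptp(img) < 1e-9:
        raise NoBoardFound("image has a single tone; no saddle points exist")
    img = (img - img.min()) / np.ptp(img)

    derivs = {
        "Ix": ndimage.gaussian_filter(img, sigma, order=(0, 1)),
        "Iy": ndimage.gaussian_filter(img, sigma, order=(1, 0)),
        "Ixx": ndimage.gaussian_filter(img, sigma, order=(0, 2)),
        "Iyy": ndimage.gaussian_filter(img, sigma, order=(2, 0)),
        "Ixy": ndimage.gaussian_filter(img, sigma, order=(1, 1)),
    }
    # saddle response: -det(Hessian), large and positive at corner saddles
    resp = derivs["Ixy"] ** 2 - derivs["Ixx"] * derivs["Iyy"]
    rmax = resp.max()
    if rmax <= 1e-8:
        raise NoBoardFound("no saddle points found")

    from skimage.feature import peak_local_max

    peaks = peak_local_max(resp, min_distance=3, threshold_abs=0.15 * rmax)
    if len(peaks) < board.n_corners:
        raise NoBoardFound(
            f"found {len(peaks)} saddle points, need {board.n_corners}"
        )
    # keep the strongest n: interior black/white saddles respond ~4x more
    # strongly than board-edge junctions against the background
    strength = resp[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(strength)[::-1][: board.n_corners]
    pts = peaks[order][:, ::-1].astype(float)  # (u, v)

    pts = _saddle_refine(pts, derivs)

    # grid recovery: homography from grid indices to the 4 extreme corners,
    # then nearest-detection assignment, refined once with all matches
    quad = _quad_corners(pts)
    e01 = quad[1] - quad[0]
    e03 = quad[3] - quad[0]
    # column direction = the more horizontal edge at the origin corner
    if abs(e01[0]) * abs(e03[1]) >= abs(e03[0]) * abs(e01[1]):
        grid_corners = np.array(
            [[0, 0], [board.cols - 1, 0], [board.cols - 1, board.rows - 1], [0, board.rows - 1]],
            dtype=float,
        )
    else:
        grid_corners = np.array(
            [[0, 0], [0, board.rows - 1], [board.cols - 1, board.rows - 1], [board.cols - 1, 0]],
            dtype=float,
        )
    cc, rr = np.meshgrid(np.arange(board.cols), np.arange(board.rows))
    grid = np.stack([cc.ravel(), rr.ravel()], axis=1).astype(float)  # (c, r)

    H = fit_homography(grid_corners, quad)
    tree = cKDTree(pts)
    span = np.linalg.norm(quad[1] - quad[0])
    tol = span / (max(board.rows, board.cols) - 1) / 2.5
    for _ in range(2):
        pred = apply_homography(H, grid)
        dist, idx = tree.query(pred)
        if len(np.unique(idx)) != board.n_corners or dist.max() > tol:
            raise AmbiguousOrdering("could not assign detections to the corner grid")
        H = fit_homography(grid, pts[idx])
    return pts[idx]


# ---------------------------------------------------------------------------
# pose estimation and planar intrinsics calibration
# ---------------------------------------------------------------------------


def _rotation_from_two_columns(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    M = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(M)
    return U @ np.diag([1.0, 1.0, np.linalg.det(U @ Vt)]) @ Vt


def estimate_board_pose(
    image_points: np.ndarray,
    board: BoardSpec,
    intrinsics: Intrinsics,
    refine: bool = True,
) -> RigidPose:
    """Planar pose (PnP) of the board from its ordered corner pixels.

    Closed-form initialisation from the board-plane homography followed by
    Levenberg-Marquardt reprojection refinement.
    """
    pix = np.asarray(image_points, dtype=float)
    world = board_points(board)[: len(pix)]
    if len(pix) < 4:
        raise DegenerateConfiguration("pose estimation needs >= 4 points")
    c = pix - pix.mean(axis=0)
    if np.linalg.svd(c, compute_uv=False)[1] < 1e-9 * max(np.linalg.norm(c), 1.0):
        raise DegenerateConfiguration("image points are collinear")

    H = fit_homography(world[:, :2], pix)
    B = np.linalg.solve(intrinsics.K, H)
    lam = 1.0 / np.linalg.norm(B[:, 0])
    if B[2, 2] * lam < 0:  # board must be in front of the camera
        lam = -lam
    R = _rotation_from_two_columns(lam * B[:, 0], lam * B[:, 1])
    T = lam * B[:, 2]

    if refine:
        K = intrinsics.K

        def resid(p):
            Rm = Rotation.from_rotvec(p[:3]).as_matrix()
            cam = world @ Rm.T + p[3:]
            h = cam @ K.T
            return (h[:, :2] / h[:, 2:3] - pix).ravel()

        p0 = np.concatenate([Rotation.from_matrix(R).as_rotvec(), T])
        sol = least_squares(resid, p0, method="lm")
        R = Rotation.from_rotvec(sol.x[:3]).as_matrix()
        T = sol.x[3:]
        mean_res = float(np.mean(np.linalg.norm(sol.fun.reshape(-1, 2), axis=1)))
    else:
        uv, _ = ProjectionMatrix(intrinsics.K @ np.column_stack([R, T])).project(world)
        mean_res = float(np.mean(np.linalg.norm(uv - pix, axis=1)))
    return RigidPose(R=R, T=T, residual=mean_res)


def calibrate_intrinsics(
    corner_sets: list[np.ndarray], board: BoardSpec, refine: bool = True
) -> tuple[Intrinsics, list[RigidPose]]:
    """Planar (Zhang-style) calibration from >= 3 board views.

    Closed-form solution of the absolute-conic constraints from the per-view
    homographies, optionally followed by joint nonlinear refinement of the
    five intrinsic parameters and all poses.
    """
    if len(corner_sets) < 3:
        raise DegenerateConfiguration("intrinsics calibration needs >= 3 views")
    world = board_points(board)
    Hs = [fit_homography(world[:, :2], np.asarray(p, float)) for p in corner_sets]

    def v_ij(H, i, j):
        return np.array(
            [
                H[0, i] * H[0, j],
                H[0, i] * H[1, j] + H[1, i] * H[0, j],
                H[1, i] * H[1, j],
                H[2, i] * H[0, j] + H[0, i] * H[2, j],
                H[2, i] * H[1, j] + H[1, i] * H[2, j],
                H[2, i] * H[2, j],
            ]
        )

    V = []
    for H in Hs:
        V.append(v_ij(H, 0, 1))
        V.append(v_ij(H, 0, 0) - v_ij(H, 1, 1))
    V = np.asarray(V)
    b = np.linalg.svd(V)[2][-1]
    B11, B12, B22, B13, B23, B33 = b
    den = B11 * B22 - B12**2
    if den <= 0 or B11 <= 0:
        # sign ambiguity of the null vector
        b = -b
        B11, B12, B22, B13, B23, B33 = b
        den = B11 * B22 - B12**2
    if den <= 0 or B11 <= 0:
        raise DegenerateConfiguration("degenerate view set for planar calibration")
    v0 = (B12 * B13 - B11 * B23) / den
    lam = B33 - (B13**2 + v0 * (B12 * B13 - B11 * B23)) / B11
    if lam / B11 <= 0:
        raise DegenerateConfiguration("calibration produced non-positive focal scale")
    alpha_u = np.sqrt(lam / B11)
    alpha_v = np.sqrt(lam * B11 / den)
    s_uv = -B12 * alpha_u**2 * alpha_v / lam
    u0 = s_uv * v0 / alpha_v - B13 * alpha_u**2 / lam

    intr = Intrinsics(alpha_u=alpha_u, alpha_v=alpha_v, u0=u0, v0=v0, s_uv=s_uv)
    poses = [estimate_board_pose(p, board, intr) for p in corner_sets]

    if refine:
        pix_all = [np.asarray(p, float) for p in corner_sets]

        def resid(p):
            intr_p = p[:5]
            K = np.array(
                [[intr_p[0], intr_p[2], intr_p[3]], [0, intr_p[1], intr_p[4]], [0, 0, 1]]
            )
            out = []
            for i, pix in enumerate(pix_all):
                q = p[5 + 6 * i : 11 + 6 * i]
                Rm = Rotation.from_rotvec(q[:3]).as_matrix()
                cam = world @ Rm.T + q[3:]
                h = cam @ K.T
                out.append((h[:, :2] / h[:, 2:3] - pix).ravel())
            return np.concatenate(out)

        p0 = [alpha_u, alpha_v, s_uv, u0, v0]
        for pose in poses:
            p0.extend(Rotation.from_matrix(pose.R).as_rotvec())
            p0.extend(pose.T)
        sol = least_squares(resid, np.array(p0), method="lm")
        au, av, s, u0, v0 = sol.x[:5]
        intr = Intrinsics(alpha_u=au, alpha_v=av, u0=u0, v0=v0, s_uv=s)
        poses = []
        n_pts = len(world)
        res = sol.fun.reshape(-1, 2)
        for i in range(len(pix_all)):
            q = sol.x[5 + 6 * i : 11 + 6 * i]
            r_i = res[i * n_pts : (i + 1) * n_pts]
            poses.append(
                RigidPose(
                    R=Rotation.from_rotvec(q[:3]).as_matrix(),
                    T=q[3:],
                    residual=float(np.mean(np.linalg.norm(r_i, axis=1))),
                )
            )
    return intr, poses


# ---------------------------------------------------------------------------
# trajectory circle fit and axis fit
# ---------------------------------------------------------------------------


def fit_trajectory_center(trajectory: CornerTrajectory | np.ndarray) -> CircleFit:
    """Fit a 3D circle to a corner trajectory.

    The points of one rotating corner lie on a circle whose centre sits on
    the turntable axis.  The fit projects the points onto their best
    least-squares plane, fits a 2D circle there (algebraic initialisation,
    geometric refinement), and lifts the centre back to 3D.
    """
    pts = (
        trajectory.points
        if isinstance(trajectory, CornerTrajectory)
        else np.asarray(trajectory, dtype=float)
    )
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise DegenerateTrajectory("circle fit needs >= 3 3D points")
    centroid = pts.mean(axis=0)
    X = pts - centroid
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    scale = max(s[0], 1e-300)
    if s[1] <= 1e-9 * scale:
        raise DegenerateTrajectory("trajectory points are collinear")
    e1, e2, normal = Vt[0], Vt[1], Vt[2]
    xy = X @ np.column_stack([e1, e2])

    # Kasa algebraic fit: x^2 + y^2 = 2ax + 2by + c
    A = np.column_stack([2 * xy, np.ones(len(xy))])
    rhs = (xy**2).sum(axis=1)
    (a, bcoef, c), *_ = np.linalg.lstsq(A, rhs, rcond=None)
    center2d = np.array([a, bcoef])

    def resid(p):
        r = np.linalg.norm(xy - p, axis=1)
        return r - r.mean()

    sol = least_squares(resid, center2d, method="lm")
    center2d = sol.x
    r = np.linalg.norm(xy - center2d, axis=1)
    radius = float(r.mean())
    rms = float(np.sqrt(np.mean((r - radius) ** 2)))
    center3d = centroid + center2d[0] * e1 + center2d[1] * e2
    # deterministic normal sign: largest-magnitude component positive
    if normal[np.argmax(np.abs(normal))] < 0:
        normal = -normal
    return CircleFit(center=center3d, radius=radius, plane_normal=normal, rms_residual=rms)


def fit_rotation_axis(
    centers: np.ndarray | list[np.ndarray],
    ill_conditioned_ratio: float = 0.8,
    up: tuple[float, float, float] = (0.0, -1.0, 0.0),
) -> RotationAxis:
    """Fit the turntable axis to circle centres by principal-component regression.

    The axis passes through the centroid of the centres; its direction is the
    eigenvector of the centres' scatter (covariance) matrix with the largest
    eigenvalue.  The direction sign is fixed to have a non-negative dot
    product with the camera "up" direction (image -v), ties broken toward +z.
    """
    X = np.atleast_2d(np.asarray(centers, dtype=float))
    if X.shape[0] < 2 or len(np.unique(X, axis=0)) < 2:
        raise InsufficientCenters("axis fit needs >= 2 distinct centers")
    m = X.mean(axis=0)
    Lam = (X - m).T @ (X - m)  # scatter matrix (summed outer products)
    w, V = np.linalg.eigh(Lam)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    d = V[:, order[0]]
    if w[1] >= ill_conditioned_ratio * max(w[0], 1e-300):
        warnings.warn(
            "circle centers are nearly isotropic; axis direction is poorly "
            f"determined (eigenvalue ratio {w[1] / w[0]:.3f})",
            IllConditionedAxisWarning,
            stacklevel=2,
        )
    dot = float(d @ np.asarray(up, dtype=float))
    if abs(dot) > 1e-12:
        d = d * np.sign(dot)
    elif d[2] < 0:
        d = -d
    return RotationAxis(point=m, direction=d / np.linalg.norm(d), eigenvalues=w, n_centers=len(X))


# ---------------------------------------------------------------------------
# projections and virtual views
# ---------------------------------------------------------------------------


def build_projection(intrinsics: Intrinsics, pose: RigidPose) -> ProjectionMatrix:
    """Assemble ``P = K [R|T]``."""
    if intrinsics.alpha_u <= 0 or intrinsics.alpha_v <= 0:
        raise InvalidIntrinsics("alpha_u and alpha_v must be positive")
    return ProjectionMatrix(intrinsics.K @ np.column_stack([pose.R, pose.T]))


def decompose_projection(P: ProjectionMatrix | np.ndarray) -> tuple[Intrinsics, RigidPose]:
    """RQ-decompose a projection matrix back into ``K`` and ``[R|T]``."""
    M = P.P if isinstance(P, ProjectionMatrix) else np.asarray(P, dtype=float)
    K, R = rq(M[:, :3])
    D = np.diag(np.sign(np.diag(K)))
    K, R = K @ D, D @ R
    t = np.linalg.solve(K, M[:, 3])
    if np.linalg.det(R) < 0:
        R, t = -R, -t
    K = K / K[2, 2]
    intr = Intrinsics(alpha_u=K[0, 0], alpha_v=K[1, 1], u0=K[0, 2], v0=K[1, 2], s_uv=K[0, 1])
    return intr, RigidPose(R=R, T=t)


def camera_center(P: ProjectionMatrix | np.ndarray) -> np.ndarray:
    """Camera centre in world coordinates."""
    _, pose = decompose_projection(P)
    return -pose.R.T @ pose.T


def axis_aligned_rotation(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix mapping the +x axis onto a given unit direction."""
    n = np.asarray(direction, dtype=float)
    n = n / np.linalg.norm(n)
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, n)
    s = np.linalg.norm(v)
    c = float(x @ n)
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    V = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + V + V @ V * ((1 - c) / s**2)


def rotate_pose(pose: RigidPose, axis: RotationAxis, angle_deg: float) -> RigidPose:
    """Pose after the object rotates by ``angle_deg`` about the axis.

    The rig rotates the object while the camera stays fixed; in the camera
    frame that composes the base pose with the rotation
    ``x -> Q (x - m) + m`` about the axis (point ``m``, direction ``n``).
    """
    Q = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis.direction).as_matrix()
    return RigidPose(R=Q @ pose.R, T=Q @ (pose.T - axis.point) + axis.point)


def generate_virtual_views(
    base_pose: RigidPose,
    axis: RotationAxis,
    intrinsics: Intrinsics,
    step_deg: float = 9.0,
    n_views: int = 40,
) -> list[ProjectionMatrix]:
    """Projection matrices for ``n_views`` rotation steps of ``step_deg``.

    The reference rig takes 40 images at 9-degree intervals (one full turn).
    View ``k`` corresponds to rotation by ``k * step_deg`` about the axis;
    any point on the axis projects to the same pixel in every view.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    return [
        build_projection(intrinsics, rotate_pose(base_pose, axis, k * step_deg))
        for k in range(n_views)
    ]


# ---------------------------------------------------------------------------
# calibration result I/O
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Full rig calibration: intrinsics, board poses, axis and virtual views."""

    intrinsics: Intrinsics
    poses: list[RigidPose]
    axis: RotationAxis
    step_deg: float
    n_views: int
    projections: list[ProjectionMatrix] = field(default_factory=list)
    circle_rms: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        i = self.intrinsics
        return {
            "intrinsics": {
                "alpha_u": i.alpha_u,
                "alpha_v": i.alpha_v,
                "u0": i.u0,
                "v0": i.v0,
                "s_uv": i.s_uv,
                "f": i.f,
            },
            "poses": [
                {"R": p.R.tolist(), "T": p.T.tolist(), "residual": p.residual}
                for p in self.poses
            ],
            "axis": {
                "point": self.axis.point.tolist(),
                "direction": self.axis.direction.tolist(),
                "eigenvalues": self.axis.eigenvalues.tolist(),
                "n_centers": self.axis.n_centers,
            },
            "step_deg": self.step_deg,
            "n_views": self.n_views,
            "projections": [p.P.ravel().tolist() for p in self.projections],
            "circle_rms": list(self.circle_rms),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResult":
        intr = Intrinsics(**d["intrinsics"])
        poses = [
            RigidPose(R=np.array(p["R"]), T=np.array(p["T"]), residual=p.get("residual"))
            for p in d["poses"]
        ]
        ax = d["axis"]
        axis = RotationAxis(
            point=np.array(ax["point"]),
            direction=np.array(ax["direction"]),
            eigenvalues=np.array(ax["eigenvalues"]),
            n_centers=ax["n_centers"],
        )
        projections = [ProjectionMatrix(np.array(p).reshape(3, 4)) for p in d["projections"]]
        return cls(
            intrinsics=intr,
            poses=poses,
            axis=axis,
            step_deg=d["step_deg"],
            n_views=d["n_views"],
            projections=projections,
            circle_rms=d.get("circle_rms", []),
        )

    @classmethod
    def load(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def calibrate_rig(
    corner_sets: list[np.ndarray],
    board: BoardSpec,
    step_deg: float = 9.0,
    n_views: int = 40,
) -> CalibrationResult:
    """End-to-end rig calibration from per-view detected corner sets.

    Estimates intrinsics and per-view poses (planar calibration), builds one
    trajectory per corner across the rotation steps, fits a circle per
    trajectory and the rotation axis to the circle centres, then generates
    the virtual seed-view projection matrices from the first board pose.
    """
    intr, poses = calibrate_intrinsics(corner_sets, board)
    world = board_points(board)
    traj = np.stack([world @ p.R.T + p.T for p in poses], axis=0)  # (views, corners, 3)
    fits = [fit_trajectory_center(traj[:, j]) for j in range(traj.shape[1])]
    axis = fit_rotation_axis(np.array([f.center for f in fits]))
    projections = generate_virtual_views(poses[0], axis, intr, step_deg, n_views)
    return CalibrationResult(
        intrinsics=intr,
        poses=poses,
        axis=axis,
        step_deg=step_deg,
        n_views=n_views,
        projections=projections,
        circle_rms=[f.rms_residual for f in fits],
    )
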