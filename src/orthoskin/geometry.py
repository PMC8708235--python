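"""Coordinate systems and closed-form projection math.

Four coordinate systems tie the scanning rig together:

* **DCS** — depth-scanner coordinate system, one per acquisition; the scanner
  looks along +Z toward the rotation axis.
* **OCS** — object coordinate system; origin on the floor, Y up along the
  rotation axis of the arm, Z toward the front of the subject.
* **CCS** — camera coordinate system of a high-resolution camera; +Z is the
  optical axis pointing at the subject.
* **VCS** — virtual orthographic camera frame used for orthorectification;
  anchored at a surface point V, optical axis antiparallel to the surface
  normal.

Angles are radians internally (degrees only at config boundaries); lengths are
meters; image coordinates are 0-based pixels, origin at the top-left pixel
center, x right, y down.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidPose",
    "CameraCalib",
    "VirtualFrame",
    "BarycentricWeights",
    "GeometryError",
    "NonPositiveDepthError",
    "DegenerateTriangleError",
    "rot_y",
    "dcs_to_ocs",
    "ocs_to_dcs",
    "ocs_to_ccs",
    "camera_center_ocs",
    "project_pinhole",
    "triangle_normal",
    "build_virtual_frame",
    "ocs_to_vcs",
    "vcs_to_ocs",
    "ortho_project",
    "ortho_unproject",
    "barycentric_point",
]

TWO_PI = 2.0 * np.pi


class GeometryError(ValueError):
    """Base class for geometric precondition violations."""


class NonPositiveDepthError(GeometryError):
    """A point at or behind the camera plane cannot be projected."""


class DegenerateTriangleError(GeometryError):
    """Triangle with (near-)collinear vertices has no defined normal."""


@dataclass(frozen=True)
class RigidPose:
    """Pose of a device mounted on the rotating arm.

    Parameters
    ----------
    alpha : float
        Arm rotation angle in radians, normalized to [0, 2*pi).
    h : float
        Device height above the floor, meters.
    r : float
        Device distance to the rotation axis, meters (>= 0; zero collapses
        the device onto the rotation axis, useful for unit checks).
    """

    alpha: float
    h: float
    r: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise GeometryError(f"device radius must be non-negative, got {self.r}")
        object.__setattr__(self, "alpha", float(self.alpha) % TWO_PI)

    @classmethod
    def from_degrees(cls, alpha_deg: float, h: float, r: float) -> "RigidPose":
        return cls(np.deg2rad(alpha_deg), h, r)

    @property
    def alpha_deg(self) -> float:
        return float(np.rad2deg(self.alpha))

    def device_center_ocs(self) -> np.ndarray:
        """OCS position of the device origin (inverse of the pose translation)."""
        return rot_y(self.alpha) @ np.array([0.0, self.h, -self.r])


@dataclass(frozen=True)
class CameraCalib:
    """Intrinsic calibration of one high-resolution camera.

    ``Q`` (3x3) and ``T`` (3-vector, meters) absorb mounting imperfections and
    act in 3D camera space; ``d`` is the pinhole constant converting lateral
    meters at depth z into pixels via 1/(d*z); ``principal_point`` is in
    pixels; ``image_size`` is (width, height).
    """

    Q: np.ndarray
    T: np.ndarray
    d: float
    principal_point: np.ndarray
    image_size: tuple[int, int]

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float).reshape(3, 3)
        T = np.asarray(self.T, dtype=float).reshape(3)
        pp = np.asarray(self.principal_point, dtype=float).reshape(2)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "principal_point", pp)
        object.__setattr__(self, "image_size", (int(self.image_size[0]), int(self.image_size[1])))
        if abs(np.linalg.det(Q)) < 1e-12:
            raise GeometryError("calibration matrix Q must be invertible")
        if not self.d > 0:
            raise GeometryError(f"pinhole constant d must be positive, got {self.d}")
        w, h = self.image_size
        if not (0 <= pp[0] <= w - 1 and 0 <= pp[1] <= h - 1):
            raise GeometryError("principal point must lie inside the image bounds")

    @classmethod
    def ideal(cls, d: float, image_size: tuple[int, int]) -> "CameraCalib":
        """Perfectly mounted camera: Q = I, T = 0, principal point at center."""
        w, h = image_size
        return cls(np.eye(3), np.zeros(3), d, ((w - 1) / 2.0, (h - 1) / 2.0), (w, h))


@dataclass(frozen=True)
class VirtualFrame:
    """Virtual orthographic camera anchored at surface point V.

    ``G`` stacks the VCS axes X, Y, Z as rows; Z is antiparallel to the
    outward surface normal, X is horizontal (zero OCS-Y component).  ``s`` is
    the orthographic scale in pixels per meter.
    """

    V: np.ndarray
    G: np.ndarray
    s: float

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float).reshape(3)
        G = np.asarray(self.G, dtype=float).reshape(3, 3)
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "G", G)
        if not self.s > 0:
            raise GeometryError(f"scale must be positive, got {self.s}")
        if not np.allclose(G @ G.T, np.eye(3), atol=1e-9):
            raise GeometryError("G must be orthonormal")
        if abs(G[0, 1]) > 1e-9:
            raise GeometryError("X axis of the virtual frame must be horizontal")

    @property
    def normal(self) -> np.ndarray:
        """Outward surface normal at V (= -Z row)."""
        return -self.G[2]


@dataclass(frozen=True)
class BarycentricWeights:
    """Non-negative triangle weights (r, g, b), not necessarily normalized."""

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        if min(self.r, self.g, self.b) < 0:
            raise GeometryError("barycentric weights must be non-negative")
        if self.r + self.g + self.b <= 0:
            raise GeometryError("barycentric weights must not all be zero")

    def normalized(self) -> tuple[float, float, float]:
        t = self.r + self.g + self.b
        return (self.r / t, self.g / t, self.b / t)


def rot_y(alpha: float) -> np.ndarray:
    """Rotation matrix about the OCS Y axis used by the DCS->OCS transform."""
    c, s = np.cos(alpha), np.sin(alpha)
    return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])


def dcs_to_ocs(points: np.ndarray, pose: RigidPose) -> np.ndarray:
    """Transform depth-scanner points into the object frame.

    The point is first translated by the device offset (up by h, back by r
    along Z) and then rotated about the vertical axis by the arm angle:
    ``p_OCS = R_y(alpha) @ (p_DCS + [0, h, -r])``.
    """
    p = np.asarray(points, dtype=float)
    offset = np.array([0.0, pose.h, -pose.r])
    return (p + offset) @ rot_y(pose.alpha).T


def ocs_to_dcs(points: np.ndarray, pose: RigidPose) -> np.ndarray:
    """Inverse of :func:`dcs_to_ocs`."""
    p = np.asarray(points, dtype=float)
    offset = np.array([0.0, pose.h, -pose.r])
    return p @ rot_y(pose.alpha) - offset


def ocs_to_ccs(points: np.ndarray, pose: RigidPose, calib: CameraCalib) -> np.ndarray:
    """Transform object-frame points into a camera frame.

    ``p_CCS = Q @ (R_y(-alpha) @ p_OCS - [0, h, -r]) + T``; with Q = I, T = 0
    this exactly inverts :func:`dcs_to_ocs` for a device at the same pose.
    """
    p = np.asarray(points, dtype=float)
    offset = np.array([0.0, pose.h, -pose.r])
    centered = p @ rot_y(pose.alpha) - offset  # R_y(-alpha) = R_y(alpha).T
    return centered @ calib.Q.T + calib.T


def camera_center_ocs(pose: RigidPose, calib: CameraCalib) -> np.ndarray:
    """OCS position of the camera projection center (p_CCS = 0)."""
    # Solve Q (R p - o) + T = 0  ->  p = R^T (o - Q^{-1} T)
    o = np.array([0.0, pose.h, -pose.r])
    return rot_y(pose.alpha) @ (o - np.linalg.solve(calib.Q, calib.T))


def project_pinhole(points_ccs: np.ndarray, calib: CameraCalib) -> np.ndarray:
    """Central projection of CCS points onto the image plane (pixels).

    ``[x_t, y_t] = [x, y] / (d * z) + principal_point``; raises
    :class:`NonPositiveDepthError` for points at or behind the camera.
    """
    p = np.asarray(points_ccs, dtype=float)
    z = p[..., 2]
    if np.any(z <= 0):
        raise NonPositiveDepthError("point(s) at or behind the camera plane (z_CCS <= 0)")
    return p[..., :2] / (calib.d * z[..., None]) + calib.principal_point


def triangle_normal(A: np.ndarray, B: np.ndarray, C: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Unit normal of triangle (A, B, C) following the winding orientation.

    Direction of (B-A) x (C-A), renormalized to unit length so the virtual
    frame built from it is orthonormal for any triangle shape.
    """
    A = np.asarray(A, dtype=float)
    n = np.cross(np.asarray(B, dtype=float) - A, np.asarray(C, dtype=float) - A)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm <= tol):
        raise DegenerateTriangleError("degenerate triangle: cross product norm below tolerance")
    return n / norm


def build_virtual_frame(
    n: np.ndarray, V: np.ndarray, s: float, tol: float = 1e-12
) -> VirtualFrame:
    """Construct the orthorectification frame at surface point V.

    Z points into the surface (antiparallel to the outward unit normal n);
    X is the horizontal direction ``[g_zz, 0, -g_zx] / sqrt(g_zz^2 + g_zx^2)``;
    Y completes the right-handed triad as X x Z.  When n is (anti)parallel to
    the OCS Y axis the horizontal direction is undefined and X falls back to
    (1, 0, 0).
    """
    n = np.asarray(n, dtype=float).reshape(3)
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise GeometryError("normal must be unit length")
    Z = -n
    denom = Z[2] ** 2 + Z[0] ** 2
    if denom < tol:
        X = np.array([1.0, 0.0, 0.0])
    else:
        X = np.array([Z[2], 0.0, -Z[0]]) / np.sqrt(denom)
    Y = np.cross(X, Z)
    G = np.vstack([X, Y, Z])
    return VirtualFrame(np.asarray(V, dtype=float).reshape(3), G, s)


def ocs_to_vcs(points: np.ndarray, frame: VirtualFrame) -> np.ndarray:
    """``p_VCS = G @ (p_OCS - V)``."""
    p = np.asarray(points, dtype=float)
    return (p - frame.V) @ frame.G.T


def vcs_to_ocs(points: np.ndarray, frame: VirtualFrame) -> np.ndarray:
    """Inverse of :func:`ocs_to_vcs` (G is orthonormal, so G^-1 = G^T)."""
    p = np.asarray(points, dtype=float)
    return p @ frame.G + frame.V


def ortho_project(points_vcs: np.ndarray, s: float) -> np.ndarray:
    """Orthographic projection: ``[x_g, y_g] = s * [x_VCS, y_VCS]``."""
    if not s > 0:
        raise GeometryError("scale must be positive")
    p = np.asarray(points_vcs, dtype=float)
    return s * p[..., :2]


def ortho_unproject(xg_yg: np.ndarray, frame: VirtualFrame) -> np.ndarray:
    """Map ortho-image coordinates back onto the tangent plane at V.

    ``p_OCS = (x_g * X + y_g * Y) / s + V`` — the orthographic inverse has no
    depth, so the reconstructed point lies on the plane through V spanned by
    the X and Y axes of the frame.
    """
    q = np.asarray(xg_yg, dtype=float)
    return (q[..., 0:1] * frame.G[0] + q[..., 1:2] * frame.G[1]) / frame.s + frame.V


def barycentric_point(
    w: BarycentricWeights | tuple[float, float, float],
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
) -> np.ndarray:
    """Vertex combination ``(r*A + g*B + b*C) / (r+g+b)``.

    This is how a picked pixel's color shades decode into a surface point:
    the three color components are proportional to the barycentric weights of
    the pixel within its triangle.
    """
    if not isinstance(w, BarycentricWeights):
        w = BarycentricWeights(*w)
    r, g, b = w.r, w.g, w.b
    A, B, C = (np.asarray(v, dtype=float) for v in (A, B, C))
    return (r * A + g * B + b * C) / (r + g + b)
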