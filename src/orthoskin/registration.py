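"""Rigid registration of sequential scans: pairwise ICP plus loop closure.

The arm acquires clouds at 45-degree stops, so consecutive clouds overlap and
can be registered pairwise with point-to-point ICP.  Pairwise chains
accumulate drift around the full turn; a pose-graph optimization over the
cycle (8 sequential edges plus the closing edge) distributes the loop-closure
error so the composed loop transform is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .pointcloud import PointCloud

__all__ = [
    "ICPResult",
    "NoCorrespondenceError",
    "apply_transform",
    "make_transform",
    "transform_error",
    "icp_register",
    "close_loop",
    "accumulate_poses",
]


class NoCorrespondenceError(RuntimeError):
    """No point pairs within the correspondence distance — clouds do not overlap."""


@dataclass(frozen=True)
class ICPResult:
    transform: np.ndarray  # 4x4, maps source points into the target frame
    rms: float
    iterations: int
    correspondences: int


def make_transform(R: np.ndarray, t: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = R
    T[:3, 3] = np.asarray(t, dtype=float).reshape(3)
    return T


def apply_transform(points: np.ndarray, T: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    return p @ T[:3, :3].T + T[:3, 3]


def transform_error(T: np.ndarray, T_ref: np.ndarray = None) -> tuple[float, float]:
    """(rotation error in degrees, translation error in meters) between transforms."""
    if T_ref is not None:
        T = np.linalg.inv(T_ref) @ T
    ang = np.linalg.norm(Rotation.from_matrix(T[:3, :3]).as_rotvec())
    return float(np.rad2deg(ang)), float(np.linalg.norm(T[:3, 3]))


def _best_fit_rigid(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares rigid transform mapping src onto dst (Kabsch/Umeyama)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    S = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ S @ U.T
    return make_transform(R, cd - R @ cs)


def _plane_step(
    moved: np.ndarray, q: np.ndarray, n: np.ndarray, max_trans: float = np.inf
) -> np.ndarray:
    """One linearized point-to-plane alignment step (damped 6x6 solve).

    Smooth scenes leave near-null directions (e.g. sliding along a cylinder
    axis when almost all correspondence normals are radial); light Tikhonov
    damping keeps those directions from exploding on noise while barely
    touching well-constrained ones, and the translation per step is capped so
    weakly-constrained modes cannot jump beyond the correspondence radius.
    """
    b = np.einsum("ij,ij->i", n, q - moved)
    A = np.hstack([np.cross(moved, n), n])
    AtA = A.T @ A
    lam = 1e-4 * np.trace(AtA) / 6.0
    x = np.linalg.solve(AtA + lam * np.eye(6), A.T @ b)
    t_norm = np.linalg.norm(x[3:])
    if t_norm > max_trans:
        x = x * (max_trans / t_norm)
    step = np.eye(4)
    step[:3, :3] = Rotation.from_rotvec(x[:3]).as_matrix()
    step[:3, 3] = x[3:]
    return step


def icp_register(
    source: PointCloud | np.ndarray,
    target: PointCloud | np.ndarray,
    init: np.ndarray | None = None,
    max_corr_dist: float = 0.02,
    max_iterations: int = 50,
    tolerance: float = 1e-6,
    metric: str = "point_to_point",
    normal_reject_deg: float | None = None,
) -> ICPResult:
    """ICP refining the rigid transform source -> target.

    Correspondences are nearest neighbors within ``max_corr_dist``; each
    iteration solves for the rigid motion and stops when the relative RMS
    change drops below ``tolerance``.  With ``metric="point_to_point"`` the
    step is the closed-form (Kabsch) alignment of matched pairs; with
    ``metric="point_to_plane"`` it is the linearized minimization of
    distances to the target's local tangent planes, which converges far below
    the sample spacing on smooth surfaces where pure point pairing stalls on
    tangential (sliding) modes.  The target must carry normals for the plane
    metric; otherwise they are estimated from 10 nearest neighbors.
    When ``normal_reject_deg`` is set, correspondences whose source and
    target normals disagree by more than that angle are discarded; this
    suppresses the bogus pairings that partial overlap produces near coverage
    boundaries (both clouds must carry normals; orientation sign is ignored).
    The reported RMS is always the point-to-point residual of the matched
    correspondences.
    """
    if metric not in ("point_to_point", "point_to_plane"):
        raise ValueError(f"unknown metric {metric!r}")
    src = source.points if isinstance(source, PointCloud) else np.asarray(source, dtype=float)
    dst = target.points if isinstance(target, PointCloud) else np.asarray(target, dtype=float)
    normals = target.normals if isinstance(target, PointCloud) else None
    src_normals = source.normals if isinstance(source, PointCloud) else None
    T = np.eye(4) if init is None else np.asarray(init, dtype=float).copy()
    tree = cKDTree(dst)
    if normals is None and (metric == "point_to_plane" or normal_reject_deg is not None):
        normals = _pca_normals(dst, tree)
    if src_normals is None and normal_reject_deg is not None:
        src_normals = _pca_normals(src, cKDTree(src))
    cos_lim = None if normal_reject_deg is None else float(np.cos(np.deg2rad(normal_reject_deg)))
    prev_rms = np.inf
    rms = np.inf
    it = 0
    for it in range(1, max_iterations + 1):
        moved = apply_transform(src, T)
        dists, nbr = tree.query(moved, distance_upper_bound=max_corr_dist)
        mask = np.isfinite(dists)
        if cos_lim is not None:
            n_moved = src_normals @ T[:3, :3].T
            n_tgt = normals[np.where(mask, nbr, 0)]
            mask &= np.abs(np.einsum("ij,ij->i", n_moved, n_tgt)) > cos_lim
        n_corr = int(mask.sum())
        if n_corr < 6:
            raise NoCorrespondenceError(
                f"only {n_corr} correspondences within {max_corr_dist} m"
            )
        rms = float(np.sqrt(np.mean(dists[mask] ** 2)))
        if metric == "point_to_point":
            step = _best_fit_rigid(moved[mask], dst[nbr[mask]])
        else:
            step = _plane_step(
                moved[mask], dst[nbr[mask]], normals[nbr[mask]], max_trans=0.5 * max_corr_dist
            )
        T = step @ T
        if prev_rms - rms <= tolerance * max(prev_rms, 1e-30):
            break
        prev_rms = rms
    # final residual under the returned transform
    dists, _ = tree.query(apply_transform(src, T), distance_upper_bound=max_corr_dist)
    mask = np.isfinite(dists)
    if mask.any():
        rms = float(np.sqrt(np.mean(dists[mask] ** 2)))
    return ICPResult(T, rms, it, int(mask.sum()))


def _pca_normals(points: np.ndarray, tree: cKDTree, k: int = 10) -> np.ndarray:
    """Unoriented local plane normals (orientation is irrelevant for the
    point-to-plane residual, which is squared)."""
    _, nbr = tree.query(points, k=k)
    nbrs = points[nbr]
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    return vecs[:, :, 0]


def _edge_residual(Ti: np.ndarray, Tj: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """6-vector mismatch of edge measurement Z against absolute poses (Ti, Tj)."""
    E = np.linalg.inv(Z) @ np.linalg.inv(Ti) @ Tj
    return np.concatenate([Rotation.from_matrix(E[:3, :3]).as_rotvec(), E[:3, 3]])


def close_loop(pairwise: list[np.ndarray]) -> list[np.ndarray]:
    """Distribute cycle-closure error over a ring of pairwise transforms.

    ``pairwise[i]`` maps the frame of view ``(i+1) mod n`` into the frame of
    view ``i``; the last entry closes the ring.  Absolute poses (first view
    fixed at identity) are optimized by least squares on rotation-vector +
    translation parameters so every edge, including the closing one, is
    honored; corrected edges ``X_i^{-1} X_{i+1}`` are returned and compose to
    the identity exactly.
    """
    n = len(pairwise)
    if n < 2:
        return [np.asarray(T, dtype=float).copy() for T in pairwise]
    Z = [np.asarray(T, dtype=float) for T in pairwise]

    # Initial absolute poses by chaining all but the closing edge.
    X0 = [np.eye(4)]
    for i in range(n - 1):
        X0.append(X0[-1] @ Z[i])

    def pack(X: list[np.ndarray]) -> np.ndarray:
        out = []
        for T in X[1:]:
            out.append(Rotation.from_matrix(T[:3, :3]).as_rotvec())
            out.append(T[:3, 3])
        return np.concatenate(out)

    def unpack(x: np.ndarray) -> list[np.ndarray]:
        X = [np.eye(4)]
        for i in range(n - 1):
            rv = x[6 * i : 6 * i + 3]
            t = x[6 * i + 3 : 6 * i + 6]
            T = np.eye(4)
            T[:3, :3] = Rotation.from_rotvec(rv).as_matrix()
            T[:3, 3] = t
            X.append(T)
        return X

    def residuals(x: np.ndarray) -> np.ndarray:
        X = unpack(x)
        res = []
        for i in range(n):
            j = (i + 1) % n
            res.append(_edge_residual(X[i], X[j], Z[i]))
        return np.concatenate(res)

    sol = least_squares(residuals, pack(X0), method="lm", xtol=1e-14, ftol=1e-14)
    X = unpack(sol.x)
    corrected = []
    for i in range(n):
        j = (i + 1) % n
        corrected.append(np.linalg.inv(X[i]) @ X[j])
    return corrected


def accumulate_poses(pairwise: list[np.ndarray]) -> list[np.ndarray]:
    """Absolute pose of each view (first view = identity) by chaining edges."""
    X = [np.eye(4)]
    for T in pairwise[:-1]:
        X.append(X[-1] @ np.asarray(T, dtype=float))
    return X
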