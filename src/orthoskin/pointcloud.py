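"""Point-cloud containers and per-cloud processing stages.

A scan session yields one cloud per depth-scanner stop; each cloud passes
through cropping to the subject box, voxel-grid downsampling, normal
estimation, statistical outlier removal and moving-least-squares smoothing
before surface reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidPose, dcs_to_ocs

__all__ = [
    "PointCloud",
    "SubjectBounds",
    "EmptyCropWarning",
    "crop_to_subject",
    "voxel_downsample",
    "estimate_normals",
    "remove_outliers",
    "mls_smooth",
]


class EmptyCropWarning(UserWarning):
    """The crop box contained no points — bounds are probably mis-set."""


@dataclass(frozen=True)
class PointCloud:
    """N x 3 points (meters) with optional unit normals and acquisition pose.

    ``frame`` declares the coordinate system the points live in ("dcs" or
    "ocs"); ``pose`` is the rigid pose of the acquiring scanner when known.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    pose: RigidPose | None = None
    frame: str = "ocs"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "points", pts)
        if not np.all(np.isfinite(pts)):
            raise ValueError("point coordinates must be finite")
        if self.normals is not None:
            nrm = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if nrm.shape != pts.shape:
                raise ValueError("normals must match points in shape")
            lengths = np.linalg.norm(nrm, axis=1)
            if not np.allclose(lengths, 1.0, atol=1e-6):
                raise ValueError("normals must be unit length")
            object.__setattr__(self, "normals", nrm)
        if self.frame not in ("dcs", "ocs"):
            raise ValueError(f"unknown frame {self.frame!r}")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask_or_index: np.ndarray) -> "PointCloud":
        """Subset of the cloud, preserving order and per-point normals."""
        nrm = None if self.normals is None else self.normals[mask_or_index]
        return replace(self, points=self.points[mask_or_index], normals=nrm)

    def to_ocs(self) -> "PointCloud":
        """Apply the nominal device pose to move a DCS cloud into the OCS."""
        if self.frame == "ocs":
            return self
        if self.pose is None:
            raise ValueError("cannot transform to OCS without a pose")
        return replace(self, points=dcs_to_ocs(self.points, self.pose), frame="ocs")


@dataclass(frozen=True)
class SubjectBounds:
    """Closed axis-aligned box in the OCS delimiting the scanned subject."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.minimum, dtype=float).reshape(3)
        hi = np.asarray(self.maximum, dtype=float).reshape(3)
        if not np.all(lo < hi):
            raise ValueError("bounds must satisfy min < max per axis")
        object.__setattr__(self, "minimum", lo)
        object.__setattr__(self, "maximum", hi)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return np.all((p >= self.minimum) & (p <= self.maximum), axis=-1)


def crop_to_subject(cloud: PointCloud, bounds: SubjectBounds) -> PointCloud:
    """Keep only points inside the subject box (closed: boundary points stay)."""
    if cloud.frame != "ocs":
        raise ValueError("crop expects a cloud in the OCS")
    mask = bounds.contains(cloud.points)
    if not mask.any():
        warnings.warn("crop box contains no points", EmptyCropWarning, stacklevel=2)
    return cloud.select(mask)


def voxel_downsample(cloud: PointCloud, voxel: float) -> PointCloud:
    """Replace each occupied voxel by the mean of its member points.

    Voxel indices are ``floor(coordinate / voxel)`` against the global origin,
    so points exactly on a voxel boundary land in the upper cell of the floor
    convention deterministically.  Normals, when present, are averaged and
    renormalized.
    """
    if not voxel > 0:
        raise ValueError("voxel edge length must be positive")
    if len(cloud) == 0:
        return cloud
    idx = np.floor(cloud.points / voxel).astype(np.int64)
    # Order voxels by first appearance so output order is deterministic.
    _, first, inverse = np.unique(idx, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    groups = rank[inverse]
    n_vox = len(order)
    counts = np.bincount(groups, minlength=n_vox).astype(float)
    pts = np.zeros((n_vox, 3))
    for a in range(3):
        pts[:, a] = np.bincount(groups, weights=cloud.points[:, a], minlength=n_vox)
    pts /= counts[:, None]
    normals = None
    if cloud.normals is not None:
        normals = np.zeros((n_vox, 3))
        for a in range(3):
            normals[:, a] = np.bincount(groups, weights=cloud.normals[:, a], minlength=n_vox)
        lengths = np.linalg.norm(normals, axis=1, keepdims=True)
        lengths[lengths == 0] = 1.0
        normals /= lengths
    return replace(cloud, points=pts, normals=normals)


def estimate_normals(cloud: PointCloud, k: int = 30, viewpoint: np.ndarray | None = None) -> PointCloud:
    """Per-point normals from covariance analysis of the k nearest neighbors.

    The normal is the eigenvector with the smallest eigenvalue of the local
    covariance, sign-flipped to point toward ``viewpoint`` (the scanner
    position) so normals are consistently outward-oriented.
    """
    if k < 3:
        raise ValueError("need k >= 3 neighbors for covariance analysis")
    if len(cloud) < k:
        raise ValueError(f"cloud has {len(cloud)} points, need at least k={k}")
    if viewpoint is None:
        if cloud.pose is None:
            raise ValueError("viewpoint required when the cloud has no pose")
        viewpoint = cloud.pose.device_center_ocs()
    viewpoint = np.asarray(viewpoint, dtype=float).reshape(3)

    tree = cKDTree(cloud.points)
    _, nbr = tree.query(cloud.points, k=k)
    nbrs = cloud.points[nbr]  # (N, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    # eigh returns ascending eigenvalues: column 0 is the smallest-axis direction
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]
    flip = np.einsum("ni,ni->n", normals, viewpoint - cloud.points) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return replace(cloud, normals=normals)


def remove_outliers(cloud: PointCloud, k: int = 20, std_mult: float = 1.0) -> PointCloud:
    """Statistical outlier removal.

    Point i is discarded when its mean distance to its k nearest neighbors
    exceeds ``mu + std_mult * sigma``, where mu and sigma summarize those mean
    distances over the whole cloud.  ``std_mult = 1`` keeps the threshold at
    one standard deviation above the average neighborhood spacing.
    """
    if k < 1:
        raise ValueError("need at least one neighbor")
    n = len(cloud)
    if n <= k:
        return cloud
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)  # first hit is the point itself
    mean_dist = dists[:, 1:].mean(axis=1)
    mu, sigma = mean_dist.mean(), mean_dist.std()
    return cloud.select(mean_dist <= mu + std_mult * sigma)


def mls_smooth(cloud: PointCloud, radius: float = 0.05, order: int = 2) -> PointCloud:
    """Moving-least-squares projection of each point onto a local polynomial fit.

    For every point, neighbors within ``radius`` define a local plane (PCA);
    a bivariate polynomial of the given order is fit to the neighbor heights
    over that plane by weighted least squares (Gaussian weight, bandwidth
    radius/2), and the point is moved onto the fitted surface at its own
    in-plane location.  Double-wall artifacts and depth-noise waviness
    collapse onto the local mid-surface; isolated points (no other neighbor in
    range) pass through unchanged.  The default 5 cm radius matches the
    neighborhood size used when smoothing full-body scans.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    if order not in (1, 2, 3):
        raise ValueError("polynomial order must be 1, 2 or 3")
    pts = cloud.points
    n = len(pts)
    if n == 0:
        return cloud
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, radius)
    # exponents of the bivariate monomials u^i v^j with i + j <= order
    exps = [(i, j) for total in range(order + 1) for i in range(total + 1) for j in (total - i,)]
    h2 = (radius / 2.0) ** 2
    out = pts.copy()
    for idx in range(n):
        nbr = neighborhoods[idx]
        if len(nbr) < len(exps) + 1:
            continue
        local = pts[nbr]
        center = local.mean(axis=0)
        q = local - center
        w = np.exp(-np.einsum("ij,ij->i", q, q) / h2)
        cov = (q * w[:, None]).T @ q / w.sum()
        _, vecs = np.linalg.eigh(cov)
        normal, e1, e2 = vecs[:, 0], vecs[:, 1], vecs[:, 2]
        u, v, height = q @ e1, q @ e2, q @ normal
        A = np.stack([u**i * v**j for i, j in exps], axis=1)
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(A * sw[:, None], height * sw, rcond=None)
        p_local = pts[idx] - center
        pu, pv = p_local @ e1, p_local @ e2
        fitted = sum(c * pu**i * pv**j for c, (i, j) in zip(coef, exps))
        out[idx] = center + pu * e1 + pv * e2 + fitted * normal
    return replace(cloud, points=out)
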