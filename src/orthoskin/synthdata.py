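"""Synthetic scan sessions: phantom body, printed markers, virtual cameras.

Real whole-body scans are sensitive medical data, so every algorithm in this
package is exercised against a fully synthetic stand-in: a body-like phantom
(an elliptic cylinder torso capped by hemi-ellipsoids, optional arm cylinders
for occlusions) carrying round calibration markers of known diameter inside
rectangular tags.  The phantom's texture is an analytic function of the
surface point — markers are painted at their true geodesic size on the
developable cylinder chart, never resampled from a raster — so every
generated photograph and depth scan carries its own exact ground truth.

Cameras and depth scanners share one geometry core (the same rigid-pose and
pinhole model), so a marker's position in a photograph and in a scan agree by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.interpolate import interp1d
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .geometry import CameraCalib, RigidPose, dcs_to_ocs, ocs_to_dcs
from .pointcloud import PointCloud
from .registration import apply_transform
from .render import CameraView, render_mosaic, render_shaded

__all__ = [
    "MarkerSpec",
    "ArmSpec",
    "PhantomSpec",
    "Phantom",
    "ScanSession",
    "build_phantom",
    "virtual_photograph",
    "virtual_depth_scan",
    "generate_session",
    "perturb_session",
    "default_camera_calib",
    "default_scanner_calib",
]

SKIN_COLOR = (0.85, 0.65, 0.55)
TAG_COLOR = (0.98, 0.98, 0.98)
MARKER_COLOR = (0.05, 0.05, 0.05)


@dataclass(frozen=True)
class MarkerSpec:
    """A printed marker: black disk of ``diameter_mm`` centered in a
    rectangular tag, positioned on the torso chart at arc length ``u`` (m,
    along the circumference from theta=0) and height ``v`` (m)."""

    u: float
    v: float
    diameter_mm: float = 20.0
    tag_mm: tuple[float, float] = (32.0, 32.0)


@dataclass(frozen=True)
class ArmSpec:
    """A vertical occluder cylinder (stand-in for an arm) at (x, z)."""

    center_x: float
    center_z: float
    radius: float = 0.045
    y_range: tuple[float, float] = (0.7, 1.5)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the synthetic subject.

    The torso is an elliptic cylinder with horizontal semi-axes
    ``semi_axes = (a, b)`` (meters, along OCS X and Z), spanning
    ``y_range`` vertically, closed by hemi-ellipsoidal caps of vertical
    semi-axis ``cap_height``.  All cylinders are developable, so the
    (arc length, height) chart is isometric and geodesic marker disks are
    exact chart disks.
    """

    semi_axes: tuple[float, float] = (0.16, 0.11)
    y_range: tuple[float, float] = (0.5, 1.5)
    cap_height: float = 0.12
    markers: tuple[MarkerSpec, ...] = ()
    arms: tuple[ArmSpec, ...] = ()
    segments: int = 144
    rings_per_meter: int = 72

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0 or self.cap_height <= 0:
            raise ValueError("phantom semi-axes and cap height must be positive")
        if not self.y_range[0] < self.y_range[1]:
            raise ValueError("invalid torso height range")
        for m in self.markers:
            if m.diameter_mm <= 0:
                raise ValueError("marker diameter must be positive")


class Phantom:
    """Built phantom: watertight mesh + analytic chart and texture function."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        a, b = spec.semi_axes
        theta = np.linspace(0.0, 2.0 * np.pi, 4096)
        ds = np.sqrt((a * np.sin(theta)) ** 2 + (b * np.cos(theta)) ** 2)
        arclen = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(theta))])
        self.circumference = float(arclen[-1])
        self._theta_to_u = interp1d(theta, arclen)
        self._u_to_theta = interp1d(arclen, theta)
        self._check_markers()
        self.mesh = self._build_mesh()

    # ----- chart -----

    def surface_point(self, u: float, v: float) -> np.ndarray:
        """OCS point of chart coordinates (arc length u, height v) on the torso."""
        a, b = self.spec.semi_axes
        th = float(self._u_to_theta(u % self.circumference))
        return np.array([a * np.cos(th), v, b * np.sin(th)])

    def surface_normal(self, u: float, v: float) -> np.ndarray:
        """Outward unit normal on the cylindrical band at chart (u, v)."""
        a, b = self.spec.semi_axes
        th = float(self._u_to_theta(u % self.circumference))
        n = np.array([b * np.cos(th), 0.0, a * np.sin(th)])
        return n / np.linalg.norm(n)

    def chart_coords(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(u, v) chart coordinates of OCS points (projected to the torso)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        a, b = self.spec.semi_axes
        th = np.arctan2(p[:, 2] / b, p[:, 0] / a) % (2.0 * np.pi)
        return self._theta_to_u(th), p[:, 1]

    def marker_center(self, i: int) -> np.ndarray:
        m = self.spec.markers[i]
        return self.surface_point(m.u, m.v)

    def marker_normal(self, i: int) -> np.ndarray:
        m = self.spec.markers[i]
        return self.surface_normal(m.u, m.v)

    def tag_corners(self, i: int) -> np.ndarray:
        """OCS corners of marker i's tag, ordered around the rectangle."""
        m = self.spec.markers[i]
        tw, th = m.tag_mm[0] / 1000.0, m.tag_mm[1] / 1000.0
        offsets = [(-tw / 2, -th / 2), (tw / 2, -th / 2), (tw / 2, th / 2), (-tw / 2, th / 2)]
        return np.array([self.surface_point(m.u + du, m.v + dv) for du, dv in offsets])

    def tag_corners_chart(self, i: int) -> np.ndarray:
        m = self.spec.markers[i]
        tw, th = m.tag_mm[0] / 1000.0, m.tag_mm[1] / 1000.0
        return np.array(
            [
                (m.u - tw / 2, m.v - th / 2),
                (m.u + tw / 2, m.v - th / 2),
                (m.u + tw / 2, m.v + th / 2),
                (m.u - tw / 2, m.v + th / 2),
            ]
        )

    # ----- texture -----

    def texture(self, points: np.ndarray) -> np.ndarray:
        """Analytic surface color at OCS points: skin, tag or marker disk."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        colors = np.tile(np.asarray(SKIN_COLOR), (len(p), 1))
        on_band = (p[:, 1] >= self.spec.y_range[0]) & (p[:, 1] <= self.spec.y_range[1])
        for arm in self.spec.arms:
            d2 = (p[:, 0] - arm.center_x) ** 2 + (p[:, 2] - arm.center_z) ** 2
            on_band &= d2 > (1.3 * arm.radius) ** 2
        if not on_band.any():
            return colors
        u, v = self.chart_coords(p[on_band])
        sub = np.tile(np.asarray(SKIN_COLOR), (int(on_band.sum()), 1))
        L = self.circumference
        for m in self.spec.markers:
            du = (u - m.u + L / 2) % L - L / 2
            dv = v - m.v
            tw, th = m.tag_mm[0] / 1000.0, m.tag_mm[1] / 1000.0
            in_tag = (np.abs(du) <= tw / 2) & (np.abs(dv) <= th / 2)
            sub[in_tag] = TAG_COLOR
            r = m.diameter_mm / 2000.0
            in_disk = du**2 + dv**2 <= r**2
            sub[in_disk] = MARKER_COLOR
        colors[on_band] = sub
        return colors

    # ----- placement helper -----

    def place_marker_at_tilt(
        self,
        pose: RigidPose,
        tilt_deg: float,
        v: float,
        diameter_mm: float = 20.0,
        tag_mm: tuple[float, float] = (32.0, 32.0),
    ) -> MarkerSpec:
        """Marker whose normal makes ``tilt_deg`` with the view direction of a camera.

        The marker sits at height ``v``; its chart position is solved so the
        angle between the outward surface normal and the direction toward the
        camera at ``pose`` equals the requested tilt.  Deterministic
        (bracketed root find, offsets on the +u side of the facing point).
        """
        cam = pose.device_center_ocs()

        def tilt_at(u: float) -> float:
            pnt = self.surface_point(u, v)
            n = self.surface_normal(u, v)
            d = cam - pnt
            d = d / np.linalg.norm(d)
            return float(np.degrees(np.arccos(np.clip(n @ d, -1.0, 1.0))))

        # facing point: minimize tilt over the circumference (coarse + refine)
        us = np.linspace(0.0, self.circumference, 720, endpoint=False)
        u0 = us[int(np.argmin([tilt_at(u) for u in us]))]
        if tilt_at(u0) >= tilt_deg:
            u_star = u0
        else:
            hi = self.circumference / 4.0
            u_star = brentq(lambda du: tilt_at(u0 + du) - tilt_deg, 0.0, hi, xtol=1e-9)
            u_star = u0 + u_star
        return MarkerSpec(u=u_star % self.circumference, v=v, diameter_mm=diameter_mm, tag_mm=tag_mm)

    # ----- mesh construction -----

    def _check_markers(self) -> None:
        L = self.circumference
        specs = self.spec.markers
        for i in range(len(specs)):
            for j in range(i + 1, len(specs)):
                du = abs((specs[i].u - specs[j].u + L / 2) % L - L / 2)
                dv = abs(specs[i].v - specs[j].v)
                reach_u = (specs[i].tag_mm[0] + specs[j].tag_mm[0]) / 2000.0
                reach_v = (specs[i].tag_mm[1] + specs[j].tag_mm[1]) / 2000.0
                if du < reach_u and dv < reach_v:
                    raise ValueError(f"markers {i} and {j} overlap")

    def _build_mesh(self) -> trimesh.Trimesh:
        spec = self.spec
        a, b = spec.semi_axes
        y0, y1 = spec.y_range
        mesh = _capped_cylinder_mesh(
            a, b, y0, y1, spec.cap_height, spec.segments, spec.rings_per_meter
        )
        parts = [mesh]
        for arm in spec.arms:
            am = _capped_cylinder_mesh(
                arm.radius, arm.radius, arm.y_range[0], arm.y_range[1], arm.radius,
                max(32, spec.segments // 4), spec.rings_per_meter,
            )
            am.apply_translation([arm.center_x, 0.0, arm.center_z])
            parts.append(am)
        return trimesh.util.concatenate(parts) if len(parts) > 1 else mesh


def _capped_cylinder_mesh(
    a: float, b: float, y0: float, y1: float, cap: float, segments: int, rings_per_meter: int
) -> trimesh.Trimesh:
    """Watertight elliptic cylinder with hemi-ellipsoid caps, outward winding."""
    theta = np.linspace(0.0, 2.0 * np.pi, segments, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    n_cap = max(6, segments // 8)
    rings: list[np.ndarray] = []
    verts = [np.array([0.0, y0 - cap, 0.0])]  # bottom pole (index 0)
    cap_phis = np.linspace(np.pi / 2, 0.0, n_cap + 1)[1:]  # pole-adjacent .. equator
    for p in cap_phis:
        scale = np.cos(p)
        y = y0 - cap * np.sin(p)
        ring = np.stack([a * scale * cos_t, np.full(segments, y), b * scale * sin_t], axis=1)
        rings.append(ring)
    n_side = max(2, int(round((y1 - y0) * rings_per_meter)))
    for y in np.linspace(y0, y1, n_side + 1)[1:-1]:
        rings.append(np.stack([a * cos_t, np.full(segments, y), b * sin_t], axis=1))
    for p in cap_phis[::-1]:
        scale = np.cos(p)
        y = y1 + cap * np.sin(p)
        rings.append(np.stack([a * scale * cos_t, np.full(segments, y), b * scale * sin_t], axis=1))
    ring_start = []
    for ring in rings:
        ring_start.append(len(verts))
        verts.extend(ring)
    top_pole = len(verts)
    verts.append(np.array([0.0, y1 + cap, 0.0]))

    faces: list[tuple[int, int, int]] = []
    s0 = ring_start[0]
    for j in range(segments):
        jn = (j + 1) % segments
        faces.append((0, s0 + jn, s0 + j))
    for r in range(len(rings) - 1):
        lo, hi = ring_start[r], ring_start[r + 1]
        for j in range(segments):
            jn = (j + 1) % segments
            faces.append((lo + j, lo + jn, hi + j))
            faces.append((hi + j, lo + jn, hi + jn))
    sl = ring_start[-1]
    for j in range(segments):
        jn = (j + 1) % segments
        faces.append((top_pole, sl + j, sl + jn))
    mesh = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)
    trimesh.repair.fix_normals(mesh)
    if mesh.is_watertight and mesh.volume < 0:
        mesh.invert()
    return mesh


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Construct the phantom mesh and its analytic texture from a spec."""
    return Phantom(spec)


def default_camera_calib(image_size: tuple[int, int] = (1280, 960), d: float = 2.5e-4) -> CameraCalib:
    """High-resolution camera intrinsics: a 2 cm marker spans ~120 px at 0.65 m."""
    return CameraCalib.ideal(d, image_size)


def default_scanner_calib(image_size: tuple[int, int] = (424, 240), d: float = 4.5e-3) -> CameraCalib:
    """Depth-scanner intrinsics: ~87-degree horizontal field of view at half
    the native resolution of a RealSense-class structured-light scanner."""
    return CameraCalib.ideal(d, image_size)


def virtual_photograph(
    phantom: Phantom, pose: RigidPose, calib: CameraCalib | None = None, view_id: int = 0
) -> CameraView:
    """Render a high-resolution photograph of the phantom from a camera stop."""
    calib = calib or default_camera_calib()
    view = CameraView(pose=pose, calib=calib, view_id=view_id)
    img = render_shaded(phantom.mesh, view, phantom.texture)
    return CameraView(pose=pose, calib=calib, image=img, view_id=view_id)


def virtual_depth_scan(
    phantom: Phantom,
    pose: RigidPose,
    calib: CameraCalib | None = None,
    noise_sigma: float = 0.002,
    dropout: float = 0.0,
    rng: np.random.Generator | int | None = None,
    clutter: int = 0,
    clutter_box: tuple[float, float] = (1.2, 2.4),
) -> PointCloud:
    """Simulate one depth scan: raycast depth map -> noisy DCS point cloud.

    Depth is rendered through the shared pinhole geometry, perturbed along
    each viewing ray by Gaussian noise of ``noise_sigma`` (meters), thinned by
    the ``dropout`` fraction, and optionally mixed with background clutter
    points outside the subject region.  The DCS equals the CCS of an ideally
    mounted device at the same pose, so points come straight from the camera
    frame.  Fully reproducible given an integer seed or seeded generator.
    """
    if noise_sigma < 0 or not (0 <= dropout < 1):
        raise ValueError("invalid noise or dropout")
    calib = calib or default_scanner_calib()
    rng = np.random.default_rng(rng)
    buffers = render_mosaic(phantom.mesh, CameraView(pose=pose, calib=calib))
    h, w = buffers.shape
    z = buffers.depth_buffer
    mask = np.isfinite(z)
    ys, xs = np.nonzero(mask)
    depth = z[mask]
    x_ccs = (xs - calib.principal_point[0]) * calib.d * depth
    y_ccs = (ys - calib.principal_point[1]) * calib.d * depth
    pts = np.stack([x_ccs, y_ccs, depth], axis=1)
    if noise_sigma > 0:
        factor = (depth + rng.normal(0.0, noise_sigma, size=len(depth))) / depth
        pts = pts * factor[:, None]
    if dropout > 0:
        keep = rng.random(len(pts)) >= dropout
        pts = pts[keep]
    if clutter > 0:
        # background points behind/off the subject, removed later by cropping
        radius, height = clutter_box
        cx = rng.uniform(-radius, radius, clutter)
        cy = rng.uniform(0.0, height, clutter)
        cz = rng.uniform(1.5, 3.0, clutter)
        pts = np.vstack([pts, np.stack([cx, cy, cz], axis=1)])
    return PointCloud(points=pts, pose=pose, frame="dcs")


@dataclass
class ScanSession:
    """One full turn of the arm with complete ground truth.

    ``views`` are camera stops (one per camera height and angle), ``clouds``
    the depth scans in DCS; ``perturbations`` are OCS-level rigid errors
    applied per scan angle (identity when unperturbed); ``phantom`` carries
    the exact surface and marker geometry.
    """

    phantom: Phantom
    views: list[CameraView]
    clouds: list[PointCloud]
    angles_deg: np.ndarray
    perturbations: list[np.ndarray] = field(default_factory=list)

    def cloud_angle_index(self, i: int) -> int:
        """Index into ``angles_deg``/``perturbations`` for cloud i."""
        return i % len(self.angles_deg)


def generate_session(
    phantom: Phantom,
    n_angles: int = 8,
    camera_heights: tuple[float, ...] = (0.6, 0.9, 1.2, 1.5),
    scanner_heights: tuple[float, ...] = (0.6, 1.0, 1.4),
    camera_radius: float = 0.8,
    scanner_radius: float = 0.9,
    camera_calib: CameraCalib | None = None,
    scanner_calib: CameraCalib | None = None,
    noise_sigma: float = 0.002,
    dropout: float = 0.0,
    seed: int | None = 0,
    render_images: bool = True,
) -> ScanSession:
    """Generate a complete synthetic scan session.

    The arm stops at ``n_angles`` equal steps over the full turn (default 8
    stops of 45 degrees); at each stop every camera takes a photograph and
    every scanner acquires a noisy depth cloud.  The default rig mirrors a
    prototype with four cameras and three depth scanners on the arm.
    ``render_images=False`` skips the photographs when only geometry is
    needed.
    """
    rng = np.random.default_rng(seed)
    angles = np.arange(n_angles) * (360.0 / n_angles)
    views: list[CameraView] = []
    clouds: list[PointCloud] = []
    vid = 0
    for alpha in angles:
        for h in camera_heights:
            pose = RigidPose.from_degrees(alpha, h, camera_radius)
            if render_images:
                views.append(virtual_photograph(phantom, pose, camera_calib, view_id=vid))
            else:
                views.append(
                    CameraView(pose=pose, calib=camera_calib or default_camera_calib(), view_id=vid)
                )
            vid += 1
    for alpha in angles:
        for h in scanner_heights:
            pose = RigidPose.from_degrees(alpha, h, scanner_radius)
            clouds.append(
                virtual_depth_scan(
                    phantom, pose, scanner_calib, noise_sigma=noise_sigma, dropout=dropout, rng=rng
                )
            )
    identity = [np.eye(4) for _ in range(n_angles)]
    return ScanSession(phantom, views, clouds, angles, identity)


def perturb_session(
    session: ScanSession, max_rot_deg: float, max_trans_m: float, seed: int = 0
) -> ScanSession:
    """Inject per-angle rigid pose errors into a session's depth scans.

    All scanners at one arm stop share the arm's pose error, so one random
    rigid motion (rotation angle <= ``max_rot_deg`` about a uniform axis,
    translation <= ``max_trans_m``) is drawn per stop and applied to the
    OCS-mapped points of that stop's clouds before mapping them back to DCS.
    The first stop is left exact to anchor the reference frame.  The injected
    transforms are recorded for registration-recovery checks.
    """
    if max_rot_deg < 0 or max_trans_m < 0:
        raise ValueError("perturbation bounds must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(session.angles_deg)
    perts = []
    for i in range(n):
        if i == 0 or (max_rot_deg == 0 and max_trans_m == 0):
            perts.append(np.eye(4))
            continue
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = np.deg2rad(rng.uniform(0.0, max_rot_deg))
        R = Rotation.from_rotvec(axis * ang).as_matrix()
        t = rng.normal(size=3)
        t = t / np.linalg.norm(t) * rng.uniform(0.0, max_trans_m)
        T = np.eye(4)
        T[:3, :3] = R
        T[:3, 3] = t
        perts.append(T)
    new_clouds = []
    for i, cloud in enumerate(session.clouds):
        T = perts[session.cloud_angle_index(i)]
        ocs = dcs_to_ocs(cloud.points, cloud.pose)
        moved = apply_transform(ocs, T)
        new_clouds.append(PointCloud(points=ocs_to_dcs(moved, cloud.pose), pose=cloud.pose, frame="dcs"))
    return ScanSession(session.phantom, session.views, new_clouds, session.angles_deg, perts)
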