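"""Deterministic software rasterizer for triangle identification buffers.

Rendering here is an identification device, not visualization: the mosaic
render assigns every pixel the id of the nearest front-facing triangle under
its center (encoded as a unique 24-bit color), and the companion barycentric
buffer stores the perspective-correct weights of the pixel center within that
triangle.  Together they let any pixel of a rendered or photographed view be
mapped back to an exact 3D point on the mesh surface (mouse picking), and
they drive the per-triangle visibility and texture-assignment decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from PIL import Image

from .geometry import (
    CameraCalib,
    RigidPose,
    VirtualFrame,
    ocs_to_ccs,
    ocs_to_vcs,
)

__all__ = [
    "CameraView",
    "RenderBuffers",
    "render_mosaic",
    "render_shaded",
    "surface_points",
    "encode_index",
    "decode_index",
    "save_buffers",
    "load_buffers",
]

_NEAR_PLANE = 1e-6


@dataclass(frozen=True)
class CameraView:
    """One high-resolution camera stop: pose, calibration and (optionally) its image."""

    pose: RigidPose
    calib: CameraCalib
    image: np.ndarray | None = None
    view_id: int = 0

    @property
    def image_size(self) -> tuple[int, int]:
        return self.calib.image_size


@dataclass
class RenderBuffers:
    """Index mosaic + barycentric + depth buffers for one viewpoint.

    ``index_image`` holds triangle_index + 1 (0 = background); ``bary_image``
    holds the three normalized weights; ``depth_buffer`` is z in the viewing
    frame (camera z or VCS z), +inf on background.
    """

    index_image: np.ndarray
    bary_image: np.ndarray
    depth_buffer: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.index_image.shape


def encode_index(index_image: np.ndarray) -> np.ndarray:
    """Triangle ids to 24-bit RGB: id = R + 256*G + 65536*B."""
    idx = np.asarray(index_image, dtype=np.uint32)
    rgb = np.empty(idx.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = idx & 0xFF
    rgb[..., 1] = (idx >> 8) & 0xFF
    rgb[..., 2] = (idx >> 16) & 0xFF
    return rgb


def decode_index(rgb: np.ndarray) -> np.ndarray:
    """Inverse of :func:`encode_index`."""
    rgb = np.asarray(rgb)
    return (
        rgb[..., 0].astype(np.uint32)
        + (rgb[..., 1].astype(np.uint32) << 8)
        + (rgb[..., 2].astype(np.uint32) << 16)
    )


def _project_view(mesh: trimesh.Trimesh, view: CameraView) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex image xy and camera z for a perspective view (no depth guard)."""
    ccs = ocs_to_ccs(mesh.vertices, view.pose, view.calib)
    z = ccs[:, 2]
    safe_z = np.where(z > _NEAR_PLANE, z, np.nan)
    xy = ccs[:, :2] / (view.calib.d * safe_z[:, None]) + view.calib.principal_point
    return xy, z


def _project_frame(
    mesh: trimesh.Trimesh, frame: VirtualFrame, image_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Orthographic projection through a virtual frame; image centered on V."""
    w, h = image_size
    vcs = ocs_to_vcs(mesh.vertices, frame)
    xy = frame.s * vcs[:, :2] + np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    return xy, vcs[:, 2]


def _front_facing_perspective(mesh: trimesh.Trimesh, view: CameraView) -> np.ndarray:
    """A triangle faces the camera when its normal points back toward the center."""
    ccs = ocs_to_ccs(mesh.vertices, view.pose, view.calib)
    a, b, c = (ccs[mesh.faces[:, i]] for i in range(3))
    n = np.cross(b - a, c - a)
    return np.einsum("ij,ij->i", n, a) < 0


def _front_facing_ortho(mesh: trimesh.Trimesh, frame: VirtualFrame) -> np.ndarray:
    # viewer looks along +Z_VCS; front faces have normals with negative VCS z
    n_vcs = mesh.face_normals @ frame.G.T
    return n_vcs[:, 2] < 0


def _rasterize(
    tri_xy: np.ndarray,
    tri_z: np.ndarray,
    face_ids: np.ndarray,
    image_size: tuple[int, int],
    perspective: bool,
) -> RenderBuffers:
    """Z-buffered scan conversion of pre-projected triangles.

    Pixels belong to a triangle when their center lies inside the projected
    triangle (boundary inclusive); overlaps resolve nearest-first, ties to the
    lower triangle id because triangles are processed in ascending id order
    with a strict depth test.
    """
    w, h = image_size
    index = np.zeros((h, w), dtype=np.uint32)
    bary = np.zeros((h, w, 3), dtype=np.float64)
    depth = np.full((h, w), np.inf)
    for t in range(len(face_ids)):
        xy = tri_xy[t]
        if not np.all(np.isfinite(xy)):
            continue
        x0 = max(0, int(np.ceil(xy[:, 0].min())))
        x1 = min(w - 1, int(np.floor(xy[:, 0].max())))
        y0 = max(0, int(np.ceil(xy[:, 1].min())))
        y1 = min(h - 1, int(np.floor(xy[:, 1].max())))
        if x0 > x1 or y0 > y1:
            continue
        area2 = (xy[1, 0] - xy[0, 0]) * (xy[2, 1] - xy[0, 1]) - (xy[1, 1] - xy[0, 1]) * (
            xy[2, 0] - xy[0, 0]
        )
        if area2 == 0.0:
            continue
        px, py = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        lam = np.empty(px.shape + (3,))
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            lam[..., i] = (
                (xy[k, 0] - xy[j, 0]) * (py - xy[j, 1]) - (xy[k, 1] - xy[j, 1]) * (px - xy[j, 0])
            ) / area2
        inside = np.all(lam >= 0.0, axis=-1)
        if not inside.any():
            continue
        z = tri_z[t]
        if perspective:
            inv_z = lam / z[None, None, :]
            denom = inv_z.sum(axis=-1)
            z_pix = 1.0 / denom
            weights = inv_z / denom[..., None]
        else:
            z_pix = lam @ z
            weights = lam
        sub_depth = depth[y0 : y1 + 1, x0 : x1 + 1]
        win = inside & (z_pix < sub_depth)
        if not win.any():
            continue
        sub_depth[win] = z_pix[win]
        index[y0 : y1 + 1, x0 : x1 + 1][win] = face_ids[t] + 1
        bary[y0 : y1 + 1, x0 : x1 + 1][win] = weights[win]
    return RenderBuffers(index, bary, depth)


def render_mosaic(
    mesh: trimesh.Trimesh,
    view: CameraView | VirtualFrame,
    image_size: tuple[int, int] | None = None,
    perspective_correct: bool = True,
) -> RenderBuffers:
    """Render the triangle-id mosaic and barycentric buffers for a viewpoint.

    Back-facing triangles are culled; occlusions resolve through the z-buffer,
    so the index at a pixel identifies the triangle actually visible there.
    ``perspective_correct=False`` switches the barycentric interpolation to
    screen-space linear (for fidelity experiments only).
    """
    if len(mesh.faces) == 0:
        raise ValueError("cannot render an empty mesh")
    if isinstance(view, VirtualFrame):
        if image_size is None:
            raise ValueError("image_size is required for a virtual-frame render")
        xy, z = _project_frame(mesh, view, image_size)
        front = _front_facing_ortho(mesh, view)
        persp = False
    else:
        image_size = image_size or view.image_size
        xy, z = _project_view(mesh, view)
        front = _front_facing_perspective(mesh, view)
        persp = perspective_correct
        front &= np.all(z[mesh.faces] > _NEAR_PLANE, axis=1)
    face_ids = np.flatnonzero(front)
    tri_xy = xy[mesh.faces[face_ids]]
    tri_z = z[mesh.faces[face_ids]]
    return _rasterize(tri_xy, tri_z, face_ids, image_size, perspective=persp)


def surface_points(buffers: RenderBuffers, mesh: trimesh.Trimesh) -> tuple[np.ndarray, np.ndarray]:
    """3D surface point for every foreground pixel (mask, points array).

    Returns a boolean foreground mask of the buffer shape and an (M, 3) array
    of OCS points for the True pixels in row-major order, each the barycentric
    combination of its triangle's vertices.
    """
    mask = buffers.index_image > 0
    tri = buffers.index_image[mask].astype(np.int64) - 1
    wts = buffers.bary_image[mask]
    verts = mesh.vertices[mesh.faces[tri]]  # (M, 3, 3)
    pts = np.einsum("mk,mki->mi", wts, verts)
    return mask, pts


def render_shaded(
    mesh: trimesh.Trimesh,
    view: CameraView | VirtualFrame,
    texture_fn,
    image_size: tuple[int, int] | None = None,
    background: tuple[int, int, int] = (0, 0, 0),
) -> np.ndarray:
    """Render an 8-bit color image by evaluating a surface texture function.

    ``texture_fn`` maps an (M, 3) array of OCS surface points to (M, 3) float
    colors in [0, 1]; it is evaluated at the perspective-correct surface point
    under each foreground pixel.  Used to synthesize virtual photographs.
    """
    buffers = render_mosaic(mesh, view, image_size=image_size)
    h, w = buffers.shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = np.asarray(background, dtype=np.uint8)
    mask, pts = surface_points(buffers, mesh)
    if len(pts):
        colors = np.clip(np.asarray(texture_fn(pts), dtype=float), 0.0, 1.0)
        img[mask] = np.round(colors * 255.0).astype(np.uint8)
    return img


def save_buffers(buffers: RenderBuffers, prefix: str) -> list[str]:
    """Export buffers as PNG: 24-bit RGB index mosaic plus three 16-bit
    grayscale channels for the barycentric weights (8-bit quantization would
    dominate the picking error budget).  Returns the written paths."""
    paths = []
    p = f"{prefix}_index.png"
    Image.fromarray(encode_index(buffers.index_image)).save(p)
    paths.append(p)
    for ch, name in enumerate("rgb"):
        q = np.round(np.clip(buffers.bary_image[..., ch], 0.0, 1.0) * 65535.0).astype(np.uint16)
        p = f"{prefix}_bary_{name}.png"
        Image.fromarray(q).save(p)
        paths.append(p)
    return paths


def load_buffers(prefix: str) -> RenderBuffers:
    """Reload PNG-exported buffers (depth is not persisted; restored as +inf/0)."""
    index = decode_index(np.array(Image.open(f"{prefix}_index.png")))
    bary = np.stack(
        [np.array(Image.open(f"{prefix}_bary_{c}.png")).astype(np.float64) / 65535.0 for c in "rgb"],
        axis=-1,
    )
    depth = np.where(index > 0, 0.0, np.inf)
    return RenderBuffers(index, bary, depth)
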