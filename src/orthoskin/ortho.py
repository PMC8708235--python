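"""Local orthorectification of skin-image patches.

A nevus imaged at an angle and at an arbitrary distance appears sheared and
scaled.  Given the surface point V under the nevus and the triangle normal
there, a virtual orthographic camera is erected on the tangent plane; every
pixel of the output patch is carried from the tangent plane through the rigid
camera transform and the pinhole projection into the source photograph, where
the color is interpolated (inverse mapping).  The result has a uniform
physical scale (pixels per millimeter), so sizes, areas and proportions can
be measured directly.

The tangent plane is a local planar approximation of the skin; curvature
error grows with patch size, so patches default to a few centimeters across.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from PIL import Image
from scipy.ndimage import map_coordinates

from .geometry import (
    VirtualFrame,
    build_virtual_frame,
    ocs_to_ccs,
    ortho_unproject,
    triangle_normal,
)
from .render import CameraView, RenderBuffers

__all__ = ["OrthoPatch", "orthorectify", "patch_grid", "source_coordinates", "save_patch"]

DEFAULT_PATCH_MM = 40.0


class AnchorError(ValueError):
    """The anchor triangle has no usable source view."""


@dataclass
class OrthoPatch:
    """Orthorectified raster with physical scale.

    ``scale`` is pixels per millimeter; the center pixel maps to the anchor
    point V of ``frame``; ``valid_mask`` flags pixels whose source sample was
    on-image and on the rendered surface.
    """

    image: np.ndarray
    scale: float
    frame: VirtualFrame
    source_view: int
    valid_mask: np.ndarray
    anchor_triangle: int = -1

    @property
    def size_mm(self) -> tuple[float, float]:
        h, w = self.image.shape[:2]
        return (w / self.scale, h / self.scale)


def patch_grid(size: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Ortho-image coordinates (x_g, y_g) of every patch pixel center.

    The patch center — pixel ((W-1)/2, (H-1)/2), between pixels for even
    sizes — corresponds to (0, 0) and hence to the anchor point V.
    """
    w, h = size
    xs = np.arange(w) - (w - 1) / 2.0
    ys = np.arange(h) - (h - 1) / 2.0
    return np.meshgrid(xs, ys)


def source_coordinates(
    frame: VirtualFrame, view: CameraView, size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Source-image (x_t, y_t) for each patch pixel, plus a front-of-camera mask.

    This is the inverse-mapping chain on its own: tangent-plane unprojection,
    rigid transform into the camera, pinhole projection.  Exposed separately
    so the mapping can be validated against a closed-form plane homography.
    """
    xg, yg = patch_grid(size)
    pts = ortho_unproject(np.stack([xg, yg], axis=-1), frame)
    ccs = ocs_to_ccs(pts.reshape(-1, 3), view.pose, view.calib).reshape(pts.shape)
    z = ccs[..., 2]
    in_front = z > 1e-9
    safe_z = np.where(in_front, z, np.nan)
    xt = ccs[..., 0] / (view.calib.d * safe_z) + view.calib.principal_point[0]
    yt = ccs[..., 1] / (view.calib.d * safe_z) + view.calib.principal_point[1]
    return xt, yt, in_front


def orthorectify(
    view: CameraView,
    mesh: trimesh.Trimesh,
    anchor: tuple[int, np.ndarray],
    s_px_per_mm: float = 10.0,
    size: tuple[int, int] | None = None,
    mosaic: RenderBuffers | None = None,
    interpolation: str = "bilinear",
) -> OrthoPatch:
    """Resample a patch around a surface point into frontal view at true scale.

    ``anchor`` is (triangle id, V) — typically the result of picking a nevus
    center; ``view`` must carry the photograph assigned to that triangle.
    The virtual frame uses the anchor triangle's outward normal; the whole
    patch is resampled from this single view.  When the view's mosaic render
    is supplied, samples falling on background (off the rendered surface,
    e.g. past the silhouette) are masked invalid instead of extrapolated.
    ``s_px_per_mm`` sets the output resolution; the patch spans
    (W/s) x (H/s) mm.
    """
    if view.image is None:
        raise AnchorError("source view carries no image")
    if interpolation not in ("bilinear", "bicubic"):
        raise ValueError("interpolation must be 'bilinear' or 'bicubic'")
    tri_id, V = anchor
    if size is None:
        px = int(round(DEFAULT_PATCH_MM * s_px_per_mm))
        size = (px, px)
    n = triangle_normal(*mesh.vertices[mesh.faces[tri_id]])
    frame = build_virtual_frame(n, V, s_px_per_mm * 1000.0)
    xt, yt, in_front = source_coordinates(frame, view, size)

    img = np.asarray(view.image, dtype=float)
    if img.ndim == 2:
        img = img[..., None]
    h_src, w_src = img.shape[:2]
    valid = (
        in_front & (xt >= 0) & (xt <= w_src - 1) & (yt >= 0) & (yt <= h_src - 1)
    )
    if mosaic is not None:
        xi = np.clip(np.round(np.where(valid, xt, 0)).astype(int), 0, w_src - 1)
        yi = np.clip(np.round(np.where(valid, yt, 0)).astype(int), 0, h_src - 1)
        valid &= mosaic.index_image[yi, xi] > 0
    order = 1 if interpolation == "bilinear" else 3
    coords = np.stack([np.where(valid, yt, 0.0), np.where(valid, xt, 0.0)])
    out = np.stack(
        [map_coordinates(img[..., c], coords, order=order, mode="nearest") for c in range(img.shape[2])],
        axis=-1,
    )
    out[~valid] = 0.0
    if np.issubdtype(np.asarray(view.image).dtype, np.integer):
        out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    if not valid.any():
        import warnings

        warnings.warn("orthorectified patch is fully invalid", stacklevel=2)
    return OrthoPatch(
        image=out.squeeze(),
        scale=s_px_per_mm,
        frame=frame,
        source_view=view.view_id,
        valid_mask=valid,
        anchor_triangle=int(tri_id),
    )


def save_patch(patch: OrthoPatch, prefix: str | Path) -> tuple[str, str]:
    """Write the patch PNG and a JSON sidecar with its geometry."""
    prefix = str(prefix)
    png = prefix + ".png"
    Image.fromarray(patch.image).save(png)
    meta = {
        "V": patch.frame.V.tolist(),
        "n": patch.frame.normal.tolist(),
        "G": patch.frame.G.tolist(),
        "s_px_per_mm": patch.scale,
        "source_view": patch.source_view,
        "anchor_triangle": patch.anchor_triangle,
    }
    sidecar = prefix + ".json"
    Path(sidecar).write_text(json.dumps(meta, indent=2))
    return png, sidecar
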