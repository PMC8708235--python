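"""Per-triangle source-image selection and surface picking.

Every mesh triangle should be textured from the photograph that shows it
best.  A triangle is a candidate for a view only if it passes the mosaic
visibility test there (its projected footprint actually shows its own id,
i.e. it is front-facing, on-image and unoccluded); among candidate views the
one with the largest projected area wins, which favors the closest,
most frontal camera — the highest effective resolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .geometry import BarycentricWeights, barycentric_point, ocs_to_ccs
from .render import CameraView, RenderBuffers, render_mosaic

__all__ = [
    "PickError",
    "PickResult",
    "TextureAssignment",
    "visibility_test",
    "assign_textures",
    "pick",
    "save_assignment",
    "load_assignment",
    "export_textured_obj",
]

NO_VIEW = -1


class PickError(ValueError):
    """Picked pixel lies on the background — no surface under the cursor."""


@dataclass(frozen=True)
class PickResult:
    triangle_id: int
    weights: BarycentricWeights
    point: np.ndarray  # OCS


@dataclass
class TextureAssignment:
    """Per-triangle best view and texture coordinates.

    ``view_ids[t]`` is the winning view id or ``NO_VIEW``; ``uv[t]`` the
    projected triangle corners in that view (pixels); ``areas[t]`` the
    projected area in px^2.  Texture coordinates live per corner because
    adjacent triangles may be textured from different views.
    """

    view_ids: np.ndarray
    uv: np.ndarray
    areas: np.ndarray

    def __len__(self) -> int:
        return len(self.view_ids)

    @property
    def assigned_fraction(self) -> float:
        return float(np.mean(self.view_ids != NO_VIEW))


_EDGE_INSET = 0.25  # pull edge samples toward the centroid so that, after
# rounding to pixel centers, they stay inside their own triangle instead of
# leaking into the neighbor sharing the edge


def _sample_points(projected: np.ndarray) -> np.ndarray:
    """Centroid plus the three (inset) edge midpoints of a projected triangle."""
    a, b, c = projected
    centroid = (a + b + c) / 3.0
    mids = np.array([(a + b) / 2.0, (b + c) / 2.0, (c + a) / 2.0])
    mids = centroid + (1.0 - _EDGE_INSET) * (mids - centroid)
    return np.vstack([centroid[None, :], mids])


def _visible_mask(tri_xy: np.ndarray, mosaic: RenderBuffers) -> np.ndarray:
    """Vectorized mosaic visibility for (T, 3, 2) projected triangles."""
    h, w = mosaic.shape
    a, b, c = tri_xy[:, 0], tri_xy[:, 1], tri_xy[:, 2]
    centroid = (a + b + c) / 3.0
    mids = np.stack([(a + b) / 2.0, (b + c) / 2.0, (c + a) / 2.0], axis=1)
    mids = centroid[:, None, :] + (1.0 - _EDGE_INSET) * (mids - centroid[:, None, :])
    samples = np.concatenate([centroid[:, None, :], mids], axis=1)  # (T, 4, 2)
    finite = np.all(np.isfinite(samples), axis=(1, 2))
    pts = np.round(np.where(np.isfinite(samples), samples, -1.0)).astype(int)
    inb = (
        (pts[..., 0] >= 0) & (pts[..., 0] < w) & (pts[..., 1] >= 0) & (pts[..., 1] < h)
    ).all(axis=1) & finite
    ok = np.zeros(len(tri_xy), dtype=bool)
    if inb.any():
        sel = np.flatnonzero(inb)
        ids = mosaic.index_image[pts[sel][..., 1], pts[sel][..., 0]]
        ok[sel] = np.all(ids == (sel[:, None] + 1), axis=1)
    return ok


def visibility_test(triangle_id: int, projected: np.ndarray, mosaic: RenderBuffers) -> bool:
    """True iff the mosaic shows this triangle's own id at its interior samples.

    Samples are the centroid and the three edge midpoints of the projected
    triangle, rounded to the nearest pixel; all four must be on-image and
    carry the triangle's id.  A mismatch means the triangle is occluded,
    back-facing or off-image in this view, so its texture must not come from
    here.
    """
    h, w = mosaic.shape
    pts = np.round(_sample_points(np.asarray(projected, dtype=float))).astype(int)
    if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] >= w) or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] >= h):
        return False
    return bool(np.all(mosaic.index_image[pts[:, 1], pts[:, 0]] == triangle_id + 1))


def _projected_vertices(mesh: trimesh.Trimesh, view: CameraView) -> tuple[np.ndarray, np.ndarray]:
    ccs = ocs_to_ccs(mesh.vertices, view.pose, view.calib)
    z = ccs[:, 2]
    safe = np.where(z > 1e-9, z, np.nan)
    xy = ccs[:, :2] / (view.calib.d * safe[:, None]) + view.calib.principal_point
    return xy, z


def assign_textures(
    mesh: trimesh.Trimesh,
    views: list[CameraView],
    mosaics: list[RenderBuffers] | None = None,
) -> TextureAssignment:
    """Assign to each triangle the visible view with the largest projected area.

    Pre-rendered mosaics may be passed to avoid re-rendering; otherwise each
    view's mosaic is rendered here.  Area ties break to the lowest view id,
    making the assignment deterministic and independent of view-list order.
    """
    if not views:
        raise ValueError("at least one view is required")
    n_tri = len(mesh.faces)
    best_area = np.zeros(n_tri)
    best_view = np.full(n_tri, NO_VIEW, dtype=int)
    best_uv = np.full((n_tri, 3, 2), np.nan)
    order = np.argsort([v.view_id for v in views], kind="stable")
    for k in order:
        view = views[k]
        mosaic = mosaics[k] if mosaics is not None else render_mosaic(mesh, view)
        xy, _ = _projected_vertices(mesh, view)
        tri_xy = xy[mesh.faces]
        a, b, c = tri_xy[:, 0], tri_xy[:, 1], tri_xy[:, 2]
        area = 0.5 * np.abs(
            (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
        )
        visible = _visible_mask(tri_xy, mosaic)
        # strict > plus ascending view-id scan = lowest id wins ties
        better = visible & np.isfinite(area) & (area > best_area)
        best_area[better] = area[better]
        best_view[better] = view.view_id
        best_uv[better] = tri_xy[better]
    return TextureAssignment(best_view, best_uv, best_area)


def pick(
    pixel: tuple[float, float], buffers: RenderBuffers, mesh: trimesh.Trimesh
) -> PickResult:
    """Map an image pixel back to the mesh surface (mouse picking).

    The triangle id is decoded from the index mosaic at the pixel, the
    barycentric weights are read from the shaded buffer, and the surface
    point is their weighted combination of the triangle's vertices.
    """
    x, y = int(round(pixel[0])), int(round(pixel[1]))
    h, w = buffers.shape
    if not (0 <= x < w and 0 <= y < h):
        raise PickError(f"pixel ({pixel[0]}, {pixel[1]}) outside the image")
    idx = int(buffers.index_image[y, x])
    if idx == 0:
        raise PickError("no surface under cursor (background pixel)")
    tri = idx - 1
    weights = BarycentricWeights(*buffers.bary_image[y, x])
    A, B, C = mesh.vertices[mesh.faces[tri]]
    return PickResult(tri, weights, barycentric_point(weights, A, B, C))


def save_assignment(assignment: TextureAssignment, path: str | Path) -> None:
    records = []
    for t in range(len(assignment)):
        v = int(assignment.view_ids[t])
        rec = {"triangle_id": t, "view_id": v}
        if v != NO_VIEW:
            rec["uv"] = np.round(assignment.uv[t], 4).tolist()
            rec["area_px2"] = round(float(assignment.areas[t]), 4)
        records.append(rec)
    Path(path).write_text(json.dumps(records))


def load_assignment(path: str | Path) -> TextureAssignment:
    records = json.loads(Path(path).read_text())
    n = len(records)
    view_ids = np.full(n, NO_VIEW, dtype=int)
    uv = np.full((n, 3, 2), np.nan)
    areas = np.zeros(n)
    for rec in records:
        t = rec["triangle_id"]
        view_ids[t] = rec["view_id"]
        if rec["view_id"] != NO_VIEW:
            uv[t] = np.asarray(rec["uv"], dtype=float)
            areas[t] = rec["area_px2"]
    return TextureAssignment(view_ids, uv, areas)


def export_textured_obj(
    mesh: trimesh.Trimesh,
    assignment: TextureAssignment,
    views: list[CameraView],
    path: str | Path,
    image_paths: dict[int, str] | None = None,
) -> None:
    """Write OBJ + MTL with one material per source view for inspection.

    Texture coordinates are emitted per corner; OBJ's vt origin is bottom-left
    with normalized coordinates, so pixel uv are flipped and scaled by each
    view's image size.  Unassigned triangles go to a textureless material.
    """
    path = Path(path)
    mtl_path = path.with_suffix(".mtl")
    sizes = {v.view_id: v.image_size for v in views}
    with open(mtl_path, "w") as m:
        m.write("newmtl untextured\nKd 0.6 0.6 0.6\n")
        for v in views:
            m.write(f"\nnewmtl view{v.view_id}\nKd 1 1 1\n")
            if image_paths and v.view_id in image_paths:
                m.write(f"map_Kd {image_paths[v.view_id]}\n")
    with open(path, "w") as f:
        f.write(f"mtllib {mtl_path.name}\n")
        for p in mesh.vertices:
            f.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        vt_index: list[int] = []
        n_vt = 0
        for t in range(len(assignment)):
            v = int(assignment.view_ids[t])
            if v == NO_VIEW:
                vt_index.append(0)
                continue
            w, h = sizes[v]
            for corner in assignment.uv[t]:
                f.write(f"vt {corner[0] / (w - 1):.6f} {1.0 - corner[1] / (h - 1):.6f}\n")
            vt_index.append(n_vt + 1)
            n_vt += 3
        by_view: dict[int, list[int]] = {}
        for t in range(len(assignment)):
            by_view.setdefault(int(assignment.view_ids[t]), []).append(t)
        for v in sorted(by_view):
            f.write(f"usemtl {'untextured' if v == NO_VIEW else f'view{v}'}\n")
            for t in by_view[v]:
                i, j, k = (int(x) + 1 for x in mesh.faces[t])
                if v == NO_VIEW:
                    f.write(f"f {i} {j} {k}\n")
                else:
                    s = vt_index[t]
                    f.write(f"f {i}/{s} {j}/{s + 1} {k}/{s + 2}\n")
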