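"""Visibility testing, per-triangle view selection and picking."""

import numpy as np
import pytest
import trimesh

from orthoskin.geometry import CameraCalib, RigidPose, ocs_to_ccs
from orthoskin.render import CameraView, render_mosaic
from orthoskin.study import raycast_first_hit
from orthoskin.synthdata import ArmSpec, PhantomSpec, build_phantom
from orthoskin.texturing import (
    NO_VIEW,
    PickError,
    assign_textures,
    load_assignment,
    pick,
    save_assignment,
    visibility_test,
    export_textured_obj,
)


def _view(alpha_deg=0.0, h=1.0, r=1.0, size=(160, 160), d=2e-3, view_id=0):
    return CameraView(
        pose=RigidPose.from_degrees(alpha_deg, h, r),
        calib=CameraCalib.ideal(d, size),
        view_id=view_id,
    )


def _project(mesh, view):
    ccs = ocs_to_ccs(mesh.vertices, view.pose, view.calib)
    xy = ccs[:, :2] / (view.calib.d * ccs[:, 2:3]) + view.calib.principal_point
    return xy


class TestVisibility:
    def test_unoccluded_frontal_triangle_visible(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=0.12)
        mesh.apply_translation([0, 1.0, 0])
        view = _view()
        buf = render_mosaic(mesh, view)
        xy = _project(mesh, view)
        # take the triangle covering the image center
        tri = int(buf.index_image[80, 80]) - 1
        assert tri >= 0
        assert visibility_test(tri, xy[mesh.faces[tri]], buf)

    def test_hidden_back_triangle_invisible(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=0.12)
        mesh.apply_translation([0, 1.0, 0])
        view = _view()
        buf = render_mosaic(mesh, view)
        cam = np.array([0.0, 1.0, -1.0])
        back = np.flatnonzero(
            np.einsum("ij,ij->i", mesh.face_normals,
                      mesh.triangles_center - cam) > 0.01
        )
        xy = _project(mesh, view)
        assert not any(visibility_test(t, xy[mesh.faces[t]], buf) for t in back[:20])

    def test_occlusion_matches_raycast_oracle(self):
        # arm cylinder in front of the torso occludes a patch of it
        spec = PhantomSpec(
            segments=72, rings_per_meter=36,
            arms=(ArmSpec(center_x=0.0, center_z=-0.35, radius=0.05, y_range=(0.6, 1.4)),),
        )
        ph = build_phantom(spec)
        view = _view(d=1.6e-3, size=(260, 260))
        buf = render_mosaic(ph.mesh, view)
        xy = _project(ph.mesh, view)
        tri_xy = xy[ph.mesh.faces]
        cam = np.array([0.0, 1.0, -1.0])
        centers = ph.mesh.triangles_center
        dirs = centers - cam
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        hit, dist = raycast_first_hit(ph.mesh, cam, dirs)
        to_center = np.linalg.norm(centers - cam, axis=1)
        front = np.einsum("ij,ij->i", ph.mesh.face_normals, centers - cam) < 0
        oracle_visible = front & (dist > to_center - 1e-6)
        measured = np.array(
            [visibility_test(t, tri_xy[t], buf) for t in range(len(ph.mesh.faces))]
        )
        # only front-facing, on-image triangles are comparable
        h, w = buf.shape
        on_image = np.all(
            (tri_xy[..., 0] >= 0) & (tri_xy[..., 0] <= w - 1)
            & (tri_xy[..., 1] >= 0) & (tri_xy[..., 1] <= h - 1), axis=1
        )
        # exclude silhouette slivers: triangles projecting thinner than a few
        # pixels cannot be sampled reliably by either method
        e01 = np.linalg.norm(tri_xy[:, 1] - tri_xy[:, 0], axis=1)
        e12 = np.linalg.norm(tri_xy[:, 2] - tri_xy[:, 1], axis=1)
        e20 = np.linalg.norm(tri_xy[:, 0] - tri_xy[:, 2], axis=1)
        area2 = np.abs(
            (tri_xy[:, 1, 0] - tri_xy[:, 0, 0]) * (tri_xy[:, 2, 1] - tri_xy[:, 0, 1])
            - (tri_xy[:, 1, 1] - tri_xy[:, 0, 1]) * (tri_xy[:, 2, 0] - tri_xy[:, 0, 0])
        )
        altitude = area2 / np.maximum(np.max([e01, e12, e20], axis=0), 1e-9)
        comparable = front & on_image & (altitude >= 3.0)
        disagree = (measured != oracle_visible) & comparable
        assert disagree.sum() / len(ph.mesh.faces) < 0.02


class TestAssignment:
    def test_single_view_gets_everything_visible(self):
        mesh = trimesh.creation.icosphere(subdivisions=2, radius=0.12)
        mesh.apply_translation([0, 1.0, 0])
        view = _view()
        assignment = assign_textures(mesh, [view])
        assigned = assignment.view_ids != NO_VIEW
        buf = render_mosaic(mesh, view)
        rendered = np.unique(buf.index_image[buf.index_image > 0]) - 1
        # every assigned triangle passed visibility in the only view
        assert set(np.flatnonzero(assigned)) <= set(rendered.tolist())
        assert assigned.sum() > 0.3 * len(mesh.faces)

    def test_frontal_view_beats_oblique_view(self):
        quad = trimesh.Trimesh(
            vertices=[[-0.05, 0.95, 0.0], [0.05, 0.95, 0.0], [0.05, 1.05, 0.0], [-0.05, 1.05, 0.0]],
            faces=[[0, 2, 1], [0, 3, 2]], process=False,
        )
        cam = np.array([0.0, 1.0, -1.0])
        for fid in range(2):
            if quad.face_normals[fid] @ (cam - quad.vertices[quad.faces[fid][0]]) < 0:
                f = quad.faces.copy(); f[fid] = f[fid][::-1]
                quad = trimesh.Trimesh(quad.vertices, f, process=False)
        frontal = _view(alpha_deg=0.0, view_id=0)
        oblique = _view(alpha_deg=60.0, view_id=1)
        assignment = assign_textures(quad, [oblique, frontal])
        assert np.all(assignment.view_ids == 0)

    def test_area_tie_breaks_to_lowest_view_id(self):
        quad = trimesh.Trimesh(
            vertices=[[-0.05, 0.95, 0.0], [0.05, 0.95, 0.0], [0.05, 1.05, 0.0], [-0.05, 1.05, 0.0]],
            faces=[[0, 2, 1], [0, 3, 2]], process=False,
        )
        cam = np.array([0.0, 1.0, -1.0])
        for fid in range(2):
            if quad.face_normals[fid] @ (cam - quad.vertices[quad.faces[fid][0]]) < 0:
                f = quad.faces.copy(); f[fid] = f[fid][::-1]
                quad = trimesh.Trimesh(quad.vertices, f, process=False)
        twin_a = _view(view_id=3)
        twin_b = _view(view_id=1)  # identical pose: identical areas
        assignment = assign_textures(quad, [twin_a, twin_b])
        assert np.all(assignment.view_ids == 1)

    def test_reorder_invariant(self, small_phantom):
        views = [_view(alpha_deg=a, d=4e-3, size=(100, 100), view_id=i)
                 for i, a in enumerate((0.0, 120.0, 240.0))]
        fwd = assign_textures(small_phantom.mesh, views)
        rev = assign_textures(small_phantom.mesh, list(reversed(views)))
        np.testing.assert_array_equal(fwd.view_ids, rev.view_ids)

    def test_roundtrip_json(self, small_phantom, tmp_path):
        views = [_view(d=4e-3, size=(100, 100))]
        assignment = assign_textures(small_phantom.mesh, views)
        save_assignment(assignment, tmp_path / "a.json")
        loaded = load_assignment(tmp_path / "a.json")
        np.testing.assert_array_equal(loaded.view_ids, assignment.view_ids)
        sel = assignment.view_ids != NO_VIEW
        np.testing.assert_allclose(loaded.uv[sel], assignment.uv[sel], atol=1e-4)

    def test_textured_obj_export(self, small_phantom, tmp_path):
        views = [_view(d=4e-3, size=(100, 100))]
        assignment = assign_textures(small_phantom.mesh, views)
        out = tmp_path / "model.obj"
        export_textured_obj(small_phantom.mesh, assignment, views, out)
        text = out.read_text()
        assert "usemtl view0" in text and "vt " in text
        reloaded = trimesh.load(str(out), force="mesh")
        assert len(reloaded.faces) == len(small_phantom.mesh.faces)


class TestPick:
    def test_vertex_pick_recovers_vertex(self):
        mesh = trimesh.Trimesh(
            vertices=[[-0.05, 0.95, 0.0], [0.05, 0.95, 0.0], [0.0, 1.08, 0.0]],
            faces=[[0, 2, 1]], process=False,
        )
        view = _view(size=(200, 200), d=1e-3)
        if mesh.face_normals[0] @ (np.array([0, 1.0, -1.0]) - mesh.vertices[0]) < 0:
            mesh.invert()
        buf = render_mosaic(mesh, view)
        xy = _project(mesh, view)
        centroid = xy.mean(axis=0)
        # sample just inside the corner so the pixel center is in-triangle
        px = np.round(0.93 * xy[0] + 0.07 * centroid).astype(int)
        res = pick((px[0], px[1]), buf, mesh)
        assert res.weights.normalized()[0] > 0.85
        assert np.linalg.norm(res.point - mesh.vertices[0]) < 0.01

    def test_background_pick_raises(self, small_phantom):
        view = _view(size=(64, 64), d=1.2e-2)  # wide view: corners off-body
        buf = render_mosaic(small_phantom.mesh, view)
        assert buf.index_image[0, 0] == 0
        with pytest.raises(PickError):
            pick((0, 0), buf, small_phantom.mesh)
        with pytest.raises(PickError):
            pick((-5, 10), buf, small_phantom.mesh)
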