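"""Synthetic phantom, virtual cameras and depth scanners."""

import numpy as np
import pytest

from orthoskin.geometry import (
    CameraCalib,
    RigidPose,
    dcs_to_ocs,
    ocs_to_ccs,
    project_pinhole,
)
from orthoskin.metrics import fit_ellipse, segment_marker
from orthoskin.synthdata import (
    MarkerSpec,
    PhantomSpec,
    build_phantom,
    generate_session,
    perturb_session,
    virtual_depth_scan,
    virtual_photograph,
)


class TestPhantomGeometry:
    def test_torso_mesh_is_closed(self, small_phantom):
        mesh = small_phantom.mesh
        assert mesh.is_watertight
        assert mesh.euler_number == 2
        assert mesh.volume > 0

    def test_chart_roundtrip(self, small_phantom):
        for u, v in [(0.0, 1.0), (0.3, 0.7), (small_phantom.circumference - 0.01, 1.4)]:
            p = small_phantom.surface_point(u, v)
            uu, vv = small_phantom.chart_coords(p)
            assert abs(float(uu[0]) - u) < 1e-6 or abs(
                abs(float(uu[0]) - u) - small_phantom.circumference
            ) < 1e-6
            assert abs(float(vv[0]) - v) < 1e-12

    def test_marker_painted_at_geodesic_size(self):
        spec = PhantomSpec(markers=(MarkerSpec(u=0.1, v=1.0, diameter_mm=20.0),))
        ph = build_phantom(spec)
        r = 0.010
        m = spec.markers[0]
        inside = ph.surface_point(m.u + 0.7 * r, m.v + 0.7 * r * 0.99)  # |d| ~ 0.99r
        outside = ph.surface_point(m.u + 0.8 * r, m.v + 0.8 * r)  # |d| ~ 1.13r
        assert np.all(ph.texture(inside)[0] < 0.1)
        assert np.all(ph.texture(outside)[0] > 0.5)

    def test_overlapping_markers_rejected(self):
        with pytest.raises(ValueError):
            build_phantom(
                PhantomSpec(markers=(MarkerSpec(u=0.0, v=1.0), MarkerSpec(u=0.01, v=1.0)))
            )

    def test_tag_corners_form_right_angles_in_chart(self, small_phantom):
        spec = PhantomSpec(markers=(MarkerSpec(u=0.2, v=1.1),))
        ph = build_phantom(spec)
        chart = ph.tag_corners_chart(0)
        e1 = chart[1] - chart[0]
        e2 = chart[3] - chart[0]
        assert abs(e1 @ e2) < 1e-12


@pytest.fixture(scope="module")
def frontal_marker_photo():
    spec = PhantomSpec(semi_axes=(0.14, 0.14), markers=(MarkerSpec(u=0.0, v=1.0),))
    ph = build_phantom(spec)
    # camera facing the marker straight on: marker at theta=0 -> x = +a;
    # the camera at alpha=90 deg sits at (+r, h, 0) looking along -X
    pose = RigidPose.from_degrees(90.0, 1.0, 0.8)
    calib = CameraCalib.ideal(2.5e-4, (800, 800))
    view = virtual_photograph(ph, pose, calib)
    return ph, pose, calib, view


class TestVirtualPhotograph:

    def test_marker_disk_diameter_follows_pinhole_magnification(self, frontal_marker_photo):
        ph, pose, calib, view = frontal_marker_photo
        center = ph.marker_center(0)
        z = float(ocs_to_ccs(center, pose, calib)[2])
        px = project_pinhole(ocs_to_ccs(center, pose, calib), calib)
        half = 120
        window = np.asarray(view.image)[
            int(px[1]) - half : int(px[1]) + half, int(px[0]) - half : int(px[0]) + half
        ]
        a, b, _, _ = fit_ellipse(segment_marker(window))
        expected_diameter = 0.020 / (calib.d * z)
        assert abs(2 * a - expected_diameter) / expected_diameter < 0.03
        assert a / b < 1.03  # frontal: circular

    def test_recorded_pose_matches_request(self, frontal_marker_photo):
        ph, pose, calib, view = frontal_marker_photo
        assert view.pose == pose
        assert view.calib is calib

    def test_tilted_marker_foreshortened_to_half(self):
        spec0 = PhantomSpec(semi_axes=(0.14, 0.14))
        plain = build_phantom(spec0)
        pose = RigidPose.from_degrees(0.0, 1.0, 0.8)
        marker = plain.place_marker_at_tilt(pose, 60.0, v=1.0)
        ph = build_phantom(
            PhantomSpec(semi_axes=(0.14, 0.14), markers=(marker,))
        )
        calib = CameraCalib.ideal(2.5e-4, (1600, 1000))
        view = virtual_photograph(ph, pose, calib)
        px = project_pinhole(ocs_to_ccs(ph.marker_center(0), pose, calib), calib)
        half = 120
        window = np.asarray(view.image)[
            int(px[1]) - half : int(px[1]) + half, int(px[0]) - half : int(px[0]) + half
        ]
        a, b, _, _ = fit_ellipse(segment_marker(window))
        assert abs(a / b - 2.0) < 0.06  # 1 / cos(60 deg)


class TestVirtualDepthScan:
    def test_noiseless_points_lie_on_surface(self):
        # planar target: faceting plays no role, points are exactly on-plane
        import trimesh

        quad = trimesh.Trimesh(
            vertices=[[-0.3, 0.5, 0.0], [0.3, 0.5, 0.0], [0.3, 1.5, 0.0], [-0.3, 1.5, 0.0]],
            faces=[[0, 2, 1], [0, 3, 2]], process=False,
        )
        cam = np.array([0.0, 1.0, -0.9])
        for fid in range(2):
            if quad.face_normals[fid] @ (cam - quad.vertices[quad.faces[fid][0]]) < 0:
                f = quad.faces.copy(); f[fid] = f[fid][::-1]
                quad = trimesh.Trimesh(quad.vertices, f, process=False)

        class _PlaneHolder:
            mesh = quad

        pose = RigidPose.from_degrees(0.0, 1.0, 0.9)
        cloud = virtual_depth_scan(_PlaneHolder(), pose, noise_sigma=0.0)
        ocs = dcs_to_ocs(cloud.points, pose)
        assert len(cloud) > 1000
        assert np.abs(ocs[:, 2]).max() < 1e-9

    def test_noise_magnitude_self_consistent(self):
        import trimesh

        quad = trimesh.Trimesh(
            vertices=[[-0.5, 0.2, 0.0], [0.5, 0.2, 0.0], [0.5, 1.8, 0.0], [-0.5, 1.8, 0.0]],
            faces=[[0, 2, 1], [0, 3, 2]], process=False,
        )
        cam = np.array([0.0, 1.0, -0.9])
        for fid in range(2):
            if quad.face_normals[fid] @ (cam - quad.vertices[quad.faces[fid][0]]) < 0:
                f = quad.faces.copy(); f[fid] = f[fid][::-1]
                quad = trimesh.Trimesh(quad.vertices, f, process=False)

        class _PlaneHolder:
            mesh = quad

        pose = RigidPose.from_degrees(0.0, 1.0, 0.9)
        sigma = 0.002
        cloud = virtual_depth_scan(_PlaneHolder(), pose, noise_sigma=sigma, rng=7)
        ocs = dcs_to_ocs(cloud.points, pose)
        rms = np.sqrt(np.mean(ocs[:, 2] ** 2))
        # z-deviation is the along-ray noise times cos(incidence) ~ 1 here
        assert abs(rms - sigma) / sigma < 0.1

    def test_seed_reproducibility_and_dropout(self, small_phantom):
        pose = RigidPose.from_degrees(45.0, 1.0, 0.9)
        a = virtual_depth_scan(small_phantom, pose, noise_sigma=0.002, dropout=0.3, rng=11)
        b = virtual_depth_scan(small_phantom, pose, noise_sigma=0.002, dropout=0.3, rng=11)
        np.testing.assert_array_equal(a.points, b.points)
        full = virtual_depth_scan(small_phantom, pose, noise_sigma=0.0)
        assert len(a) < 0.8 * len(full)


@pytest.fixture(scope="module")
def tiny_session():
    ph = build_phantom(PhantomSpec(segments=48, rings_per_meter=24))
    return generate_session(
        ph, n_angles=4, scanner_heights=(1.0,), noise_sigma=0.0,
        seed=5, render_images=False,
    )


class TestPerturbSession:

    def test_zero_bounds_is_identity(self, tiny_session):
        out = perturb_session(tiny_session, 0.0, 0.0, seed=3)
        for T in out.perturbations:
            np.testing.assert_allclose(T, np.eye(4))
        for a, b in zip(out.clouds, tiny_session.clouds):
            np.testing.assert_allclose(a.points, b.points, atol=1e-12)

    def test_bounds_respected_and_reproducible(self, tiny_session):
        out1 = perturb_session(tiny_session, 3.0, 0.02, seed=3)
        out2 = perturb_session(tiny_session, 3.0, 0.02, seed=3)
        from orthoskin.registration import transform_error

        for T1, T2 in zip(out1.perturbations, out2.perturbations):
            np.testing.assert_array_equal(T1, T2)
        for T in out1.perturbations[1:]:
            rot, trans = transform_error(T)
            assert rot <= 3.0 + 1e-9
            assert trans <= 0.02 + 1e-12

    def test_first_stop_anchored(self, tiny_session):
        out = perturb_session(tiny_session, 3.0, 0.02, seed=3)
        np.testing.assert_allclose(out.perturbations[0], np.eye(4))


def test_session_structure_and_determinism():
    ph = build_phantom(PhantomSpec(segments=48, rings_per_meter=24))
    s1 = generate_session(ph, n_angles=4, scanner_heights=(0.8, 1.2), noise_sigma=0.002,
                          seed=9, render_images=False)
    s2 = generate_session(ph, n_angles=4, scanner_heights=(0.8, 1.2), noise_sigma=0.002,
                          seed=9, render_images=False)
    assert len(s1.clouds) == 8  # 4 angles x 2 scanner heights
    assert len(s1.views) == 16  # 4 angles x 4 default camera heights
    np.testing.assert_allclose(s1.angles_deg, [0, 90, 180, 270])
    for a, b in zip(s1.clouds, s2.clouds):
        np.testing.assert_array_equal(a.points, b.points)
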