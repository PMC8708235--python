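"""Closed-form coordinate-chain math: device, object, camera, virtual frames."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthoskin.geometry import (
    BarycentricWeights,
    CameraCalib,
    DegenerateTriangleError,
    GeometryError,
    NonPositiveDepthError,
    RigidPose,
    VirtualFrame,
    barycentric_point,
    build_virtual_frame,
    camera_center_ocs,
    dcs_to_ocs,
    ocs_to_ccs,
    ocs_to_dcs,
    ocs_to_vcs,
    ortho_project,
    ortho_unproject,
    project_pinhole,
    rot_y,
    vcs_to_ocs,
)

CAL64 = CameraCalib.ideal(d=1e-4, image_size=(64, 64))


class TestScannerToObject:
    @pytest.mark.parametrize(
        "alpha_deg,h,r,p,expected",
        [
            (0.0, 0.0, 0.0, (1.0, 2.0, 3.0), (1.0, 2.0, 3.0)),  # identity pose
            (90.0, 0.0, 0.0, (1.0, 0.0, 0.0), (0.0, 0.0, 1.0)),  # quarter turn
            (270.0, 0.5, 0.0, (0.0, 0.0, 0.0), (0.0, 0.5, 0.0)),  # height offset only
        ],
    )
    def test_known_transforms(self, alpha_deg, h, r, p, expected):
        pose = RigidPose.from_degrees(alpha_deg, h, r)
        np.testing.assert_allclose(dcs_to_ocs(np.array(p), pose), expected, atol=1e-12)

    @pytest.mark.parametrize("alpha_deg", [0.0, 45.0, 133.0, 301.0])
    def test_rotation_axis_point_is_angle_invariant(self, alpha_deg):
        # a point on the optical axis at the axis distance lands on the Y axis
        pose = RigidPose.from_degrees(alpha_deg, 1.2, 0.7)
        out = dcs_to_ocs(np.array([0.0, 0.0, pose.r]), pose)
        np.testing.assert_allclose(out, [0.0, 1.2, 0.0], atol=1e-12)

    def test_camera_transform_inverts_scanner_transform(self, rng):
        pose = RigidPose.from_degrees(77.0, 0.9, 1.1)
        calib = CameraCalib.ideal(d=1e-4, image_size=(100, 100))
        pts = rng.uniform(-2, 2, size=(1000, 3))
        back = ocs_to_ccs(dcs_to_ocs(pts, pose), pose, calib)
        np.testing.assert_allclose(back, pts, atol=1e-12)

    def test_explicit_inverse_roundtrip(self, rng):
        pose = RigidPose.from_degrees(200.0, 1.4, 0.6)
        pts = rng.normal(size=(50, 3))
        np.testing.assert_allclose(ocs_to_dcs(dcs_to_ocs(pts, pose), pose), pts, atol=1e-12)


class TestObjectToCamera:
    def test_camera_center_position(self):
        # with Q = I, T = 0 the projection center sits at R_y(alpha) [0, h, -r]
        pose = RigidPose.from_degrees(30.0, 1.0, 2.0)
        calib = CameraCalib.ideal(d=1e-4, image_size=(10, 10))
        expected = rot_y(pose.alpha) @ np.array([0.0, 1.0, -2.0])
        np.testing.assert_allclose(camera_center_ocs(pose, calib), expected, atol=1e-12)
        np.testing.assert_allclose(
            ocs_to_ccs(expected, pose, calib), np.zeros(3), atol=1e-12
        )

    def test_subject_in_front_has_positive_depth(self):
        # subject point 2 m in front of a camera at (alpha=0, h=1, r=2)
        pose = RigidPose.from_degrees(0.0, 1.0, 2.0)
        calib = CameraCalib.ideal(d=1e-4, image_size=(10, 10))
        out = ocs_to_ccs(np.array([0.0, 1.0, 0.0]), pose, calib)
        np.testing.assert_allclose(out, [0.0, 0.0, 2.0], atol=1e-12)

    def test_calibration_matrix_and_offset_applied(self, rng):
        pose = RigidPose.from_degrees(10.0, 1.0, 1.0)
        Q = np.eye(3) + rng.normal(scale=0.01, size=(3, 3))
        T = rng.normal(scale=0.005, size=3)
        calib = CameraCalib(Q, T, 1e-4, (5.0, 5.0), (11, 11))
        p = rng.normal(size=3)
        ideal = CameraCalib.ideal(1e-4, (11, 11))
        base = ocs_to_ccs(p, pose, ideal)
        np.testing.assert_allclose(ocs_to_ccs(p, pose, calib), Q @ base + T, atol=1e-12)


class TestPinholeProjection:
    def test_optical_axis_maps_to_principal_point(self):
        for z in (0.1, 1.0, 7.3):
            np.testing.assert_allclose(
                project_pinhole(np.array([0.0, 0.0, z]), CAL64), CAL64.principal_point
            )

    def test_direct_evaluation(self):
        calib = CameraCalib(np.eye(3), np.zeros(3), 1e-4, (0.0, 0.0), (1000, 1000))
        out = project_pinhole(np.array([0.02, -0.01, 0.5]), calib)
        np.testing.assert_allclose(out, [400.0, -200.0], atol=1e-9)

    def test_ray_invariance(self, rng):
        p = np.array([0.3, -0.2, 1.5])
        for k in (0.5, 2.0, 13.0):
            np.testing.assert_allclose(
                project_pinhole(k * p, CAL64), project_pinhole(p, CAL64), atol=1e-9
            )

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(NonPositiveDepthError):
            project_pinhole(np.array([0.1, 0.1, 0.0]), CAL64)
        with pytest.raises(NonPositiveDepthError):
            project_pinhole(np.array([0.1, 0.1, -1.0]), CAL64)


class TestTriangleNormal:
    from orthoskin.geometry import triangle_normal

    def test_unit_right_triangle(self):
        from orthoskin.geometry import triangle_normal

        n = triangle_normal(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))
        np.testing.assert_allclose(n, [0, 0, 1.0], atol=1e-12)

    def test_scaling_invariance_and_antisymmetry(self):
        from orthoskin.geometry import triangle_normal

        A, B, C = np.zeros(3), np.array([2.0, 0, 0]), np.array([0, 3.0, 0])
        np.testing.assert_allclose(triangle_normal(A, B, C), [0, 0, 1.0], atol=1e-12)
        np.testing.assert_allclose(triangle_normal(A, C, B), [0, 0, -1.0], atol=1e-12)

    def test_degenerate_triangle_rejected(self):
        from orthoskin.geometry import triangle_normal

        with pytest.raises(DegenerateTriangleError):
            triangle_normal(np.zeros(3), np.ones(3), 2 * np.ones(3))


class TestVirtualFrame:
    @pytest.mark.parametrize(
        "n,expected_G",
        [
            ((0, 0, 1), [[-1, 0, 0], [0, -1, 0], [0, 0, -1]]),
            ((1, 0, 0), [[0, 0, 1], [0, -1, 0], [-1, 0, 0]]),
        ],
    )
    def test_axis_aligned_normals(self, n, expected_G):
        frame = build_virtual_frame(np.array(n, dtype=float), np.zeros(3), 1.0)
        np.testing.assert_allclose(frame.G, expected_G, atol=1e-12)

    def test_degenerate_vertical_normal_falls_back(self):
        frame = build_virtual_frame(np.array([0.0, 1.0, 0.0]), np.zeros(3), 1.0)
        np.testing.assert_allclose(frame.G[0], [1.0, 0.0, 0.0])
        np.testing.assert_allclose(frame.G @ frame.G.T, np.eye(3), atol=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_orthonormal_right_handed_for_random_normals(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.normal(size=3)
        if n[0] ** 2 + n[2] ** 2 < 1e-6:  # excluded degenerate cone
            n[0] += 0.1
        n /= np.linalg.norm(n)
        G = build_virtual_frame(n, np.zeros(3), 1.0).G
        assert np.abs(G @ G.T - np.eye(3)).max() < 1e-9
        # Y = X x Z makes the frame left-handed (image y runs down): det = -1
        assert abs(abs(np.linalg.det(G)) - 1.0) < 1e-9
        np.testing.assert_allclose(G[2], -n, atol=1e-12)
        assert abs(G[0, 1]) < 1e-12  # X axis horizontal

    def test_vcs_roundtrip_and_normal_direction(self, rng):
        n = np.array([0.6, 0.0, 0.8])
        V = np.array([0.1, 1.0, -0.2])
        frame = build_virtual_frame(n, V, 500.0)
        np.testing.assert_allclose(ocs_to_vcs(V, frame), np.zeros(3), atol=1e-12)
        p = rng.normal(size=(20, 3))
        np.testing.assert_allclose(vcs_to_ocs(ocs_to_vcs(p, frame), frame), p, atol=1e-12)
        # along the outward normal: z_VCS = -t
        for t in (0.01, 0.3):
            np.testing.assert_allclose(
                ocs_to_vcs(V + t * n, frame), [0, 0, -t], atol=1e-12
            )

    def test_unnormalized_normal_rejected(self):
        with pytest.raises(GeometryError):
            build_virtual_frame(np.array([0.0, 0.0, 2.0]), np.zeros(3), 1.0)


class TestOrthographicProjection:
    def test_depth_discarded_and_linear(self):
        for z in (-1.0, 0.0, 5.0):
            np.testing.assert_allclose(ortho_project(np.array([0.0, 0.0, z]), 100.0), [0, 0])
        np.testing.assert_allclose(
            ortho_project(np.array([0.01, -0.005, 0.7]), 1000.0), [10.0, -5.0]
        )
        p = np.array([0.02, 0.03, 0.1])
        np.testing.assert_allclose(ortho_project(p, 2000.0), 2 * ortho_project(p, 1000.0))

    def test_unproject_lands_on_tangent_plane(self, rng):
        n = np.array([0.0, 0.6, 0.8])
        V = np.array([0.5, 1.0, 0.0])
        frame = build_virtual_frame(n, V, 2000.0)
        np.testing.assert_allclose(ortho_unproject(np.zeros(2), frame), V, atol=1e-12)
        q = rng.uniform(-50, 50, size=(100, 2))
        p = ortho_unproject(q, frame)
        np.testing.assert_allclose((p - V) @ n, 0.0, atol=1e-12)
        back = ortho_project(ocs_to_vcs(p, frame), frame.s)
        np.testing.assert_allclose(back, q, atol=1e-9)


class TestBarycentric:
    A, B, C = np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0])

    @pytest.mark.parametrize(
        "w,expected",
        [
            ((1, 0, 0), (0, 0, 0)),
            ((1, 1, 1), (1 / 3, 1 / 3, 0)),
            ((0.5, 0.5, 0), (0.5, 0, 0)),
            ((2, 4, 2), (0.5, 0.25, 0)),  # unnormalized weights
        ],
    )
    def test_weighted_combinations(self, w, expected):
        np.testing.assert_allclose(
            barycentric_point(w, self.A, self.B, self.C), expected, atol=1e-12
        )

    def test_all_zero_weights_rejected(self):
        with pytest.raises(GeometryError):
            BarycentricWeights(0.0, 0.0, 0.0)
        with pytest.raises(GeometryError):
            BarycentricWeights(-0.1, 0.5, 0.6)


def test_full_resampling_chain_self_consistent(rng):
    """Tangent plane -> camera -> pinhole, then the analytic inverse, is the
    identity on ortho coordinates to well below a thousandth of a pixel."""
    n = np.array([0.3, 0.1, 0.94])
    n /= np.linalg.norm(n)
    V = np.array([0.0, 1.0, 0.1])
    frame = build_virtual_frame(n, V, 5000.0)
    pose = RigidPose.from_degrees(0.0, 1.0, 1.0)
    calib = CameraCalib.ideal(2.5e-4, (1000, 1000))
    q = rng.uniform(-100, 100, size=(500, 2))
    p = ortho_unproject(q, frame)
    ccs = ocs_to_ccs(p, pose, calib)
    pix = project_pinhole(ccs, calib)
    # invert: pixel ray intersect tangent plane, then project orthographically
    rays = np.column_stack([(pix - calib.principal_point) * calib.d, np.ones(len(pix))])
    cam = camera_center_ocs(pose, calib)
    dirs = rays @ rot_y(pose.alpha).T
    t = ((V - cam) @ n) / (dirs @ n)
    p_back = cam + t[:, None] * dirs
    q_back = ortho_project(ocs_to_vcs(p_back, frame), frame.s)
    assert np.abs(q_back - q).max() < 1e-6
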