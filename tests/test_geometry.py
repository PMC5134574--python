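"""Camera model, pose interpolation and finite epipolar segments."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mvfruit.geometry import (
    CameraIntrinsics,
    Pose,
    TimeOutOfRange,
    Trajectory,
    backproject_ray,
    epipolar_segment,
    interpolate_pose,
    project_point,
)


def _pose(t, pos, yaw_deg=0.0):
    q = Rotation.from_euler("z", np.radians(yaw_deg)).as_quat()
    return Pose(t, np.asarray(pos, float), q)


def _traj(poses, **kw):
    return Trajectory(
        np.array([p.t for p in poses]),
        np.vstack([p.position for p in poses]),
        np.vstack([p.orientation for p in poses]),
        **kw,
    )


class TestInterpolatePose:
    def test_exact_sample_returns_that_pose(self):
        traj = _traj([_pose(0, [0, 0, 0]), _pose(1, [1, 0, 0])])
        p = interpolate_pose(traj, 1.0)
        assert np.allclose(p.position, [1, 0, 0])

    def test_linear_midpoint_position(self):
        traj = _traj([_pose(0, [0, 0, 0]), _pose(1, [1, 0, 0])])
        assert np.allclose(interpolate_pose(traj, 0.5).position, [0.5, 0, 0])

    def test_slerp_yaw_midpoint(self):
        # midway between yaw 0 and yaw 90 must be exactly yaw 45
        traj = _traj([_pose(0, [0, 0, 0], 0.0), _pose(1, [0, 0, 0], 90.0)])
        p = interpolate_pose(traj, 0.5)
        yaw = Rotation.from_quat(p.orientation).as_euler("zyx")[0]
        assert abs(yaw - np.pi / 4) < 1e-9

    def test_outside_span_raises(self):
        traj = _traj([_pose(0, [0, 0, 0]), _pose(1, [1, 0, 0])])
        with pytest.raises(TimeOutOfRange):
            interpolate_pose(traj, 2.0)

    def test_time_offset_shifts_lookup(self):
        traj = _traj([_pose(0, [0, 0, 0]), _pose(1, [1, 0, 0])], time_offset=0.25)
        assert np.allclose(interpolate_pose(traj, 0.25).position, [0.5, 0, 0])


class TestProjection:
    @pytest.mark.parametrize(
        "point, expected_pixel, expected_depth",
        [
            ((0, 0, 5), (1648, 1236), 5.0),  # optical axis
            ((0.5, 0, 5), (1748, 1236), 5.0),  # u = 1000*0.5/5 + 1648
            ((0, 1.0, 4), (1648, 1486), 4.0),  # v grows downward (+Y cam)
        ],
    )
    def test_pinhole_examples(self, identity_pose, survey_cam, point, expected_pixel, expected_depth):
        pix, depth, ok = project_point(identity_pose, survey_cam, np.array(point, float))
        assert ok
        assert np.allclose(pix, expected_pixel)
        assert depth == pytest.approx(expected_depth)

    def test_behind_camera_flagged(self, identity_pose, survey_cam):
        pix, depth, ok = project_point(identity_pose, survey_cam, np.array([0, 0, -1.0]))
        assert not ok
        assert np.all(np.isnan(pix))  # never a usable pixel

    def test_principal_point_backprojects_along_axis(self, identity_pose, survey_cam):
        ray = backproject_ray(identity_pose, survey_cam, np.array([1648.0, 1236.0]))
        assert np.allclose(ray.direction, [0, 0, 1])

    def test_focal_length_offset_gives_45_degrees(self, identity_pose, survey_cam):
        ray = backproject_ray(identity_pose, survey_cam, np.array([2648.0, 1236.0]))
        angle = np.degrees(np.arccos(ray.direction @ np.array([0, 0, 1.0])))
        assert angle == pytest.approx(45.0, abs=1e-9)

    def test_roundtrip_random_poses(self, survey_cam):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            q = Rotation.random(rng=rng).as_quat()
            pose = Pose(0.0, rng.normal(0, 10, 3), q)
            pixel = np.array(
                [rng.uniform(0, survey_cam.width - 1), rng.uniform(0, survey_cam.height - 1)]
            )
            depth = rng.uniform(0.5, 20)
            point = backproject_ray(pose, survey_cam, pixel).point_at(depth)
            pix2, _, ok = project_point(pose, survey_cam, point)
            assert ok
            assert np.allclose(pix2, pixel, atol=1e-6)

    def test_distorted_roundtrip(self, identity_pose):
        cam = CameraIntrinsics(
            1000, 1000, 1648, 1236, 3296, 2472, distortion=(-0.1, 0.02, 1e-4, -1e-4)
        )
        pixel = np.array([900.0, 1700.0])
        point = backproject_ray(identity_pose, cam, pixel).point_at(4.0)
        pix2, _, ok = project_point(identity_pose, cam, point)
        assert ok
        assert np.allclose(pix2, pixel, atol=1e-6)


class TestEpipolarSegment:
    def test_identical_views_degenerate_to_centroid(self, identity_pose, survey_cam):
        c = np.array([1500.0, 900.0])
        seg = epipolar_segment(c, identity_pose, identity_pose, survey_cam)
        assert np.allclose(seg.p0, c, atol=1e-9)
        assert np.allclose(seg.p1, c, atol=1e-9)

    def test_forward_translation_example(self, identity_pose, survey_cam):
        # camera advances 0.28 m along +X (1.4 m/s at 5 Hz)
        pose2 = _pose(0.2, [0.28, 0, 0])
        seg = epipolar_segment(
            np.array([1648.0, 1236.0]), identity_pose, pose2, survey_cam, 2.5, 8.0
        )
        assert np.allclose(seg.p0, [1536.0, 1236.0])
        assert np.allclose(seg.p1, [1613.0, 1236.0])

    def test_near_equals_far_gives_point(self, identity_pose, survey_cam):
        pose2 = _pose(0.2, [0.28, 0, 0])
        seg = epipolar_segment(
            np.array([1648.0, 1236.0]), identity_pose, pose2, survey_cam, 4.0, 4.0
        )
        assert seg.length == pytest.approx(0.0, abs=1e-9)

    def test_behind_second_camera_returns_none(self, identity_pose, survey_cam):
        pose2 = _pose(0.2, [0, 0, 20.0])  # second camera far ahead of the clip range
        seg = epipolar_segment(
            np.array([1648.0, 1236.0]), identity_pose, pose2, survey_cam, 2.5, 8.0
        )
        assert seg is None

    def test_length_monotone_in_range_interval(self, identity_pose, survey_cam):
        pose2 = _pose(0.2, [0.28, 0.05, 0])
        c = np.array([1800.0, 1400.0])
        lengths = [
            epipolar_segment(c, identity_pose, pose2, survey_cam, near, far).length
            for near, far in [(2.5, 8.0), (3.0, 7.0), (3.5, 6.0), (4.0, 5.0)]
        ]
        assert all(a >= b for a, b in zip(lengths, lengths[1:]))

    def test_pure_forward_motion_segments_meet_at_epipole(self, survey_cam):
        # for translation along the optical axis every epipolar segment's
        # supporting line passes through the focus of expansion (principal pt)
        p1 = _pose(0.0, [0, 0, 0])
        p2 = _pose(0.2, [0, 0, 0.3])
        epipole = np.array([survey_cam.cx, survey_cam.cy])
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = np.array(
                [rng.uniform(200, 3000), rng.uniform(200, 2200)]
            )
            seg = epipolar_segment(c, p1, p2, survey_cam, 2.5, 8.0)
            d = seg.p1 - seg.p0
            rel = epipole - seg.p0
            cross = abs(d[0] * rel[1] - d[1] * rel[0]) / (np.linalg.norm(d) + 1e-12)
            assert cross < 1e-6
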