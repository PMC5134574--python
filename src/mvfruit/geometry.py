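"""Camera model, pose interpolation, projection and finite epipolar segments.

Conventions
-----------
* World frame: local metric ENU (x east, y north, z up), anchored wherever
  the trajectory file puts its origin.  All distances in metres.
* Camera frame: z forward along the optical axis, x right (image u),
  y down (image v).
* Pixels: 0-based, origin at the top-left corner, continuous coordinates at
  pixel centres; u grows right, v grows down.
* Orientations are unit quaternions stored scalar-last (x, y, z, w) to match
  :class:`scipy.spatial.transform.Rotation`; file I/O accepts scalar-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "CameraIntrinsics",
    "Pose",
    "Trajectory",
    "Ray",
    "Segment2D",
    "interpolate_pose",
    "project_point",
    "project_points",
    "backproject_ray",
    "epipolar_segment",
]

_EPS_Z = 1e-9  # depth below which a point counts as behind the camera


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics with optional Brown radial-tangential distortion.

    ``distortion`` is ``(k1, k2, p1, p2[, k3])``; an empty tuple means an
    ideal pinhole (the default — lens calibration is user-supplied).
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    distortion: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def diagonal(self) -> float:
        return float(np.hypot(self.width, self.height))

    @property
    def centre(self) -> np.ndarray:
        return np.array([(self.width - 1) / 2.0, (self.height - 1) / 2.0])

    def contains(self, pixel: np.ndarray):
        """Vectorised in-bounds test for pixel coordinates."""
        p = np.asarray(pixel, float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        ok = (
            (p[:, 0] >= 0)
            & (p[:, 0] <= self.width - 1)
            & (p[:, 1] >= 0)
            & (p[:, 1] <= self.height - 1)
        )
        return bool(ok[0]) if single else ok

    def _distort(self, xn: np.ndarray, yn: np.ndarray):
        if not self.distortion:
            return xn, yn
        d = list(self.distortion) + [0.0] * (5 - len(self.distortion))
        k1, k2, p1, p2, k3 = d[:5]
        r2 = xn * xn + yn * yn
        radial = 1 + k1 * r2 + k2 * r2**2 + k3 * r2**3
        xd = xn * radial + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
        yd = yn * radial + p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
        return xd, yd

    def _undistort(self, xd: np.ndarray, yd: np.ndarray):
        if not self.distortion:
            return xd, yd
        # fixed-point iteration; converges quickly for mild lens distortion
        xn, yn = xd.copy(), yd.copy()
        for _ in range(12):
            xdi, ydi = self._distort(xn, yn)
            xn = xn - (xdi - xd)
            yn = yn - (ydi - yd)
        return xn, yn


@dataclass(frozen=True)
class Pose:
    """A time-stamped rigid transform (frame-to-world)."""

    t: float
    position: np.ndarray
    orientation: np.ndarray  # unit quaternion, scalar-last (x, y, z, w)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))
        q = np.asarray(self.orientation, float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"quaternion norm {n} != 1")
        object.__setattr__(self, "orientation", q)

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation)

    def compose(self, other_position: np.ndarray, other_quat: np.ndarray) -> "Pose":
        """This pose ∘ (a child frame expressed in this frame)."""
        r = self.rotation
        return Pose(
            self.t,
            self.position + r.apply(np.asarray(other_position, float)),
            (r * Rotation.from_quat(other_quat)).as_quat(),
        )


@dataclass
class Trajectory:
    """Time-ordered body poses plus a camera extrinsic and a clock offset.

    ``time_offset`` (seconds) is added to image timestamps before pose
    lookup, compensating the asynchronous camera clock against the
    navigation clock.
    """

    times: np.ndarray
    positions: np.ndarray  # (N, 3)
    quats: np.ndarray  # (N, 4), scalar-last
    cam_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    cam_quat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 0.0, 1.0]))
    time_offset: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.positions = np.asarray(self.positions, float)
        self.quats = np.asarray(self.quats, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory timestamps must be strictly increasing")
        norms = np.linalg.norm(self.quats, axis=1)
        self.quats = self.quats / norms[:, None]

    @property
    def t_min(self) -> float:
        return float(self.times[0])

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def covers(self, t_image: float) -> bool:
        t = t_image + self.time_offset
        return self.t_min <= t <= self.t_max

    def body_pose(self, t_image: float) -> Pose:
        return interpolate_pose(self, t_image)

    def camera_pose(self, t_image: float) -> Pose:
        """Interpolated body pose composed with the camera extrinsic."""
        return self.body_pose(t_image).compose(self.cam_position, self.cam_quat)

    def yaw(self) -> np.ndarray:
        """Heading angle (rad) of the body x axis, per sample."""
        fwd = Rotation.from_quat(self.quats).apply(np.array([1.0, 0.0, 0.0]))
        return np.arctan2(fwd[:, 1], fwd[:, 0])


class TimeOutOfRange(ValueError):
    """Image timestamp outside the trajectory span."""


def interpolate_pose(trajectory: Trajectory, t_image: float) -> Pose:
    """Pose at an (offset-corrected) image time: lerp position, slerp attitude.

    Navigation runs much faster than the camera (e.g. 50 Hz vs 5 Hz), so
    piecewise-linear position with spherical-linear orientation between the
    bracketing samples is adequate.
    """
    t = t_image + trajectory.time_offset
    times = trajectory.times
    if not (times[0] <= t <= times[-1]):
        raise TimeOutOfRange(
            f"t={t:.6f}s outside trajectory span [{times[0]:.6f}, {times[-1]:.6f}]"
        )
    i = int(np.searchsorted(times, t, side="right") - 1)
    i = min(max(i, 0), len(times) - 2)
    t0, t1 = times[i], times[i + 1]
    a = (t - t0) / (t1 - t0)
    pos = (1 - a) * trajectory.positions[i] + a * trajectory.positions[i + 1]
    rots = Rotation.from_quat(trajectory.quats[i : i + 2])
    quat = Slerp([t0, t1], rots)(t).as_quat()
    return Pose(t_image, pos, quat)


@dataclass(frozen=True)
class Ray:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        d = np.asarray(self.direction, float)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("ray direction must be unit length")
        object.__setattr__(self, "direction", d)

    def point_at(self, dist: float) -> np.ndarray:
        return self.origin + dist * self.direction


@dataclass(frozen=True)
class Segment2D:
    """Finite epipolar segment in the second image plane."""

    p0: np.ndarray
    p1: np.ndarray

    def __post_init__(self) -> None:
        p0 = np.asarray(self.p0, float)
        p1 = np.asarray(self.p1, float)
        if not (np.all(np.isfinite(p0)) and np.all(np.isfinite(p1))):
            raise ValueError("segment endpoints must be finite")
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p0))


def project_points(pose: Pose, cam: CameraIntrinsics, points: np.ndarray):
    """Project world points into the image; returns (pixels, depths, in_front).

    ``in_front`` flags positive depth; pixels for behind-camera points are
    NaN and must never be treated as valid image coordinates.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    pc = pose.rotation.inv().apply(pts - pose.position)
    z = pc[:, 2]
    in_front = z > _EPS_Z
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = pc[:, 0] / z
        yn = pc[:, 1] / z
    xd, yd = cam._distort(xn, yn)
    pix = np.column_stack([cam.fx * xd + cam.cx, cam.fy * yd + cam.cy])
    pix[~in_front] = np.nan
    return pix, z, in_front


def project_point(pose: Pose, cam: CameraIntrinsics, point: np.ndarray):
    """Scalar wrapper: returns (pixel, depth, in_front)."""
    pix, z, ok = project_points(pose, cam, np.asarray(point, float)[None, :])
    return pix[0], float(z[0]), bool(ok[0])


def backproject_ray(pose: Pose, cam: CameraIntrinsics, pixel: np.ndarray) -> Ray:
    """World-frame viewing ray through a pixel; origin is the camera centre."""
    pixel = np.asarray(pixel, float)
    xd = np.array([(pixel[0] - cam.cx) / cam.fx])
    yd = np.array([(pixel[1] - cam.cy) / cam.fy])
    xn, yn = cam._undistort(xd, yd)
    d_cam = np.array([xn[0], yn[0], 1.0])
    d_world = pose.rotation.apply(d_cam)
    d_world /= np.linalg.norm(d_world)
    return Ray(pose.position, d_world)


def epipolar_segment(
    centroid: np.ndarray,
    pose_n: Pose,
    pose_n1: Pose,
    cam: CameraIntrinsics,
    near: float = 2.5,
    far: float = 8.0,
) -> Segment2D | None:
    """Finite epipolar segment of ``centroid`` (seen at ``pose_n``) in the
    image at ``pose_n1``.

    The viewing ray is clipped to camera-to-fruit ranges [near, far] — a
    conservative envelope for the whole orchard — and both clip points are
    projected into the second view.  Returns ``None`` when the whole chord
    lies behind the second camera.  Endpoints may fall outside the image;
    the segment is allowed to exit the frame.
    """
    if not 0 < near <= far:
        raise ValueError("require 0 < near <= far")
    ray = backproject_ray(pose_n, cam, centroid)
    a = ray.point_at(near)
    b = ray.point_at(far)
    # clip the chord to the z>0 half-space of the second camera so a single
    # behind-camera endpoint degrades gracefully instead of projecting to NaN
    r1 = pose_n1.rotation.inv()
    za = r1.apply(a - pose_n1.position)[2]
    zb = r1.apply(b - pose_n1.position)[2]
    if za <= _EPS_Z and zb <= _EPS_Z:
        return None
    if za <= _EPS_Z or zb <= _EPS_Z:
        s = (1e-6 - za) / (zb - za)
        crossing = a + s * (b - a)
        if za <= _EPS_Z:
            a = crossing
        else:
            b = crossing
    pix, _, ok = project_points(pose_n1, cam, np.vstack([a, b]))
    if not np.all(ok):
        return None
    return Segment2D(pix[0], pix[1])
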