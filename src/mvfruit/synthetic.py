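"""Synthetic orchard scenes with known ground truth.

Generates everything the pipeline consumes — a tree-labelled LiDAR cloud, a
boustrophedon vehicle trajectory, and noisy per-frame fruit detections —
from a compact orchard description, so every stage can be tested without
field data.

The statistical structure mirrors a vehicle-scanned mango block: trees on a
regular row grid, fruit placed in the outer shell of an ellipsoidal canopy,
a sideways-looking camera imaging at 5 Hz while driving 1.4 m/s down the
row centres, and per-fruit visibility azimuth windows standing in for
foliage occlusion (a fruit may be hidden from the central view yet exposed
somewhere along the pass — the regime multi-view counting exploits).
Detection noise covers centroid jitter, Bernoulli misses, uniform false
positives, an injected camera–navigation clock offset, and optional frame
drops.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import CameraIntrinsics, Trajectory, project_points
from .tracking import Detection, FrameDetections
from .trees import LabelledPointCloud

__all__ = [
    "OrchardSpec",
    "SimScene",
    "default_camera",
    "generate_orchard",
    "generate_trajectory",
    "simulate_detections",
    "simulate_scene",
]


def default_camera() -> CameraIntrinsics:
    """Side-looking simulation camera.

    The raster matches the survey camera's 3296 x 2472 sensor so pixel
    quantities (association thresholds, centroid noise, dilation radii)
    live on the scale they were designed for; the ~77 degree horizontal
    field of view suits a 4-5 m camera-to-canopy distance.
    """
    return CameraIntrinsics(
        fx=2060.0, fy=2060.0, cx=1647.5, cy=1235.5, width=3296, height=2472
    )


@dataclass(frozen=True)
class OrchardSpec:
    """Orchard layout, platform and noise model for one simulated scan.

    Defaults reproduce the scan conditions the pipeline targets: 1.4 m/s
    platform speed, 5 Hz imaging, 50 Hz navigation, 2.5–8 m camera-to-fruit
    range.  Fruit load per tree is negative-binomial with mean 130 (the
    average-yield scale of a mature mango block).  The 110° visibility
    window makes a single central view see roughly 30% of the fruit and two
    opposing passes roughly 60% of single-frame unions — while nearly every
    fruit is exposed at some viewpoint along one of the passes.
    """

    n_rows: int = 1
    trees_per_row: int = 16
    tree_spacing: float = 4.0
    row_spacing: float = 9.0
    canopy_semi_axes: tuple[float, float, float] = (1.5, 1.5, 1.6)
    canopy_centre_height: float = 2.0
    fruit_per_tree_mean: float = 130.0
    fruit_per_tree_dispersion: float = 10.0  # negative-binomial k
    fruit_per_tree_fixed: int | None = None
    fruit_shell_inner: float = 0.5  # fruit occupy the outer canopy shell
    fruit_diameter: float = 0.10
    speed: float = 1.4
    frame_rate: float = 5.0
    nav_rate: float = 50.0
    detect_range: tuple[float, float] = (2.5, 8.0)
    occlusion_window_deg: float = 110.0  # >= 360 disables occlusion
    miss_rate: float = 0.05  # persistent per-(fruit, pass) detector blindness
    transient_miss_rate: float = 0.005  # i.i.d. per-frame misses (fragment tracks)
    fp_rate: float = 0.02  # expected FPs per frame as fraction of true detections
    centroid_noise_px: float = 2.0
    time_offset: float = 0.0  # injected camera-navigation clock offset (s)
    pose_noise_m: float = 0.0
    pose_noise_deg: float = 0.0
    # gentle platform wobble (yaw + pitch sinusoids at chassis frequency).
    # Besides realism this is what makes the clock offset observable: on a
    # constant-velocity, constant-attitude path a time shift moves both
    # cameras of a frame pair identically and cancels out of the epipolar
    # geometry; rotation rate x sync error is the signal the offset scan
    # minimises, and it needs rates that decorrelate between consecutive
    # frames.  Large amplitudes emulate the bump/oscillation failure mode.
    attitude_oscillation_deg: float = 1.0
    attitude_oscillation_hz: float = 2.5
    drop_frame_fraction: float = 0.0  # logging-fault failure mode
    headland_margin: float = 6.0
    turn_rate_deg: float = 45.0
    camera_height: float = 2.0
    lidar_points_per_tree: int = 4000
    ground_point_spacing: float = 0.5
    add_grass: bool = False
    grass_height: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.miss_rate, self.transient_miss_rate, self.fp_rate, self.drop_frame_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.tree_spacing, self.row_spacing) <= 0:
            raise ValueError("spacings must be positive")

    @property
    def row_length(self) -> float:
        return (self.trees_per_row - 1) * self.tree_spacing

    def tree_centre(self, row: int, j: int) -> np.ndarray:
        return np.array(
            [j * self.tree_spacing, row * self.row_spacing, self.canopy_centre_height]
        )

    def tree_id_of(self, row: int, j: int) -> int:
        return row * self.trees_per_row + j + 1


@dataclass
class SimScene:
    """A fully ground-truthed simulated scan."""

    spec: OrchardSpec
    cam: CameraIntrinsics
    fruit_positions: np.ndarray  # (M, 3)
    fruit_tree: np.ndarray  # (M,) tree id per fruit
    fruit_row: np.ndarray  # (M,) row id per fruit
    fruit_window_centre: np.ndarray  # (M,) degrees
    cloud: LabelledPointCloud
    trajectory: Trajectory
    passes: list[tuple[int, int, float, float]] = field(default_factory=list)
    frames: list[FrameDetections] = field(default_factory=list)
    correspondence: dict[int, list[int]] = field(default_factory=dict)

    @property
    def n_fruit(self) -> int:
        return len(self.fruit_positions)

    @property
    def frame_times(self) -> dict[int, float]:
        return {f.frame_id: f.timestamp for f in self.frames}

    def true_counts_per_tree(self) -> dict[int, int]:
        trees = np.unique(self.fruit_tree)
        return {int(t): int(np.sum(self.fruit_tree == t)) for t in trees}

    def frames_in_window(self, t0: float, t1: float) -> list[FrameDetections]:
        """Frames whose true capture time falls in [t0, t1] (pass selection)."""
        off = self.spec.time_offset
        return [f for f in self.frames if t0 <= f.timestamp + off <= t1]


def _sample_shell(rng: np.random.Generator, n: int, inner: float) -> np.ndarray:
    """Uniform samples in the unit-ellipsoid shell [inner, 1] (unit frame)."""
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    u = rng.random(n)
    r = (inner**3 + u * (1 - inner**3)) ** (1 / 3)
    return d * r[:, None]


def generate_orchard(spec: OrchardSpec, seed: int | None = None):
    """Trees, fruit and LiDAR cloud for the block.

    Returns ``(fruit_positions, fruit_tree, fruit_row, window_centres,
    cloud)``.  Fruit counts are negative-binomial per tree (or fixed);
    fruit sit uniformly in the outer canopy shell; each fruit receives a
    visibility azimuth window centre.  The cloud samples each canopy
    surface plus a trunk, a ground plane, and (optionally) grass tufts near
    trunks that exercise mask ground-removal leakage.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    a, b, c = spec.canopy_semi_axes
    fruit_pos, fruit_tree, fruit_row = [], [], []
    cloud_pts, cloud_tree, cloud_row = [], [], []
    for row in range(spec.n_rows):
        for j in range(spec.trees_per_row):
            tid = spec.tree_id_of(row, j)
            centre = spec.tree_centre(row, j)
            if spec.fruit_per_tree_fixed is not None:
                n_fruit = spec.fruit_per_tree_fixed
            else:
                k, mu = spec.fruit_per_tree_dispersion, spec.fruit_per_tree_mean
                n_fruit = int(rng.negative_binomial(k, k / (k + mu)))
            shell = _sample_shell(rng, n_fruit, spec.fruit_shell_inner)
            fruit_pos.append(centre + shell * np.array([a, b, c]))
            fruit_tree.append(np.full(n_fruit, tid))
            fruit_row.append(np.full(n_fruit, row + 1))
            # canopy surface + trunk points
            d = rng.normal(size=(spec.lidar_points_per_tree, 3))
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            surf = centre + d * np.array([a, b, c])
            n_trunk = spec.lidar_points_per_tree // 10
            trunk = np.column_stack(
                [
                    centre[0] + rng.normal(0, 0.05, n_trunk),
                    centre[1] + rng.normal(0, 0.05, n_trunk),
                    rng.uniform(0, max(centre[2] - c, 0.3), n_trunk),
                ]
            )
            tree_pts = np.vstack([surf, trunk])
            cloud_pts.append(tree_pts)
            cloud_tree.append(np.full(len(tree_pts), tid))
            cloud_row.append(np.full(len(tree_pts), row + 1))
            if spec.add_grass:
                n_grass = 60
                grass = np.column_stack(
                    [
                        centre[0] + rng.uniform(-2.5, 2.5, n_grass),
                        centre[1] + rng.uniform(-2.5, 2.5, n_grass),
                        rng.uniform(0.0, spec.grass_height, n_grass),
                    ]
                )
                cloud_pts.append(grass)
                cloud_tree.append(np.zeros(n_grass, int))
                cloud_row.append(np.full(n_grass, row + 1))
    # ground plane
    m = spec.headland_margin
    gx = np.arange(-m, spec.row_length + m, spec.ground_point_spacing)
    gy = np.arange(
        -spec.row_spacing, (spec.n_rows - 0.5) * spec.row_spacing, spec.ground_point_spacing
    )
    gxx, gyy = np.meshgrid(gx, gy)
    ground = np.column_stack([gxx.ravel(), gyy.ravel(), np.zeros(gxx.size)])
    cloud_pts.append(ground)
    cloud_tree.append(np.zeros(len(ground), int))
    cloud_row.append(np.zeros(len(ground), int))
    fruit_pos = np.vstack(fruit_pos) if fruit_pos else np.empty((0, 3))
    cloud = LabelledPointCloud(
        np.vstack(cloud_pts), np.concatenate(cloud_tree), np.concatenate(cloud_row)
    )
    windows = rng.uniform(-180.0, 180.0, len(fruit_pos))
    return (
        fruit_pos,
        np.concatenate(fruit_tree) if fruit_tree else np.empty(0, int),
        np.concatenate(fruit_row) if fruit_row else np.empty(0, int),
        windows,
        cloud,
    )


# camera looks to the vehicle's left: optical axis = body +y, image u = body
# +x (direction of travel on an eastbound pass), image v = body -z
_CAM_QUAT = Rotation.from_matrix(
    np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]])
).as_quat()


def _yaw_quat(yaw: np.ndarray) -> np.ndarray:
    return Rotation.from_euler("z", np.reshape(yaw, (-1, 1))).as_quat()


def generate_trajectory(spec: OrchardSpec, seed: int | None = None) -> Trajectory:
    """Boustrophedon row-scanning trajectory at 50 Hz.

    For each row the vehicle drives the south corridor eastbound then the
    north corridor westbound, with on-the-spot headland turns between
    passes, so the left-looking camera views both sides of every row.
    Returns the trajectory; the true pass windows are recomputed by
    :func:`simulate_scene` and stored on the scene.
    """
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    dt = 1.0 / spec.nav_rate
    m = spec.headland_margin
    xs, xe = -m, spec.row_length + m
    waypoints = []  # (start, end, heading)
    for row in range(spec.n_rows):
        y0 = row * spec.row_spacing - spec.row_spacing / 2
        y1 = row * spec.row_spacing + spec.row_spacing / 2
        waypoints.append((np.array([xs, y0, 0.0]), np.array([xe, y0, 0.0]), 0.0))
        waypoints.append((np.array([xe, y1, 0.0]), np.array([xs, y1, 0.0]), np.pi))
    times, positions, yaws = [], [], []
    t = 0.0
    pass_windows = []
    turn_rate = np.radians(spec.turn_rate_deg)

    def add_turn(pos, yaw_from, yaw_to):
        nonlocal t
        delta = np.arctan2(np.sin(yaw_to - yaw_from), np.cos(yaw_to - yaw_from))
        if abs(delta) < 1e-9:
            return
        duration = abs(delta) / turn_rate
        n = max(2, int(np.ceil(duration / dt)))
        for i in range(1, n + 1):
            t += dt
            times.append(t)
            positions.append(pos.copy())
            yaws.append(yaw_from + delta * i / n)

    def add_straight(p0, p1, yaw):
        nonlocal t
        d = np.linalg.norm(p1 - p0)
        n = max(2, int(np.ceil(d / spec.speed / dt)))
        t0 = t
        for i in range(n + 1):
            if i == 0:
                if times:  # join point already sampled by the previous leg
                    continue
            else:
                t += dt
            times.append(t)
            positions.append(p0 + (p1 - p0) * i / n)
            yaws.append(yaw)
        return t0, t

    prev_end, prev_yaw = None, None
    for p0, p1, yaw in waypoints:
        if prev_end is not None:
            connector_yaw = float(np.arctan2(p0[1] - prev_end[1], p0[0] - prev_end[0]))
            if np.linalg.norm(p0 - prev_end) > 1e-9:
                add_turn(prev_end, prev_yaw, connector_yaw)
                add_straight(prev_end, p0, connector_yaw)
                add_turn(p0, connector_yaw, yaw)
            else:
                add_turn(p0, prev_yaw, yaw)
        t0, t1 = add_straight(p0, p1, yaw)
        pass_windows.append((t0, t1))
        prev_end, prev_yaw = p1, yaw
    times = np.asarray(times)
    positions = np.vstack(positions)
    yaws = np.asarray(yaws)
    if spec.attitude_oscillation_deg > 0:
        amp = np.radians(spec.attitude_oscillation_deg)
        f = spec.attitude_oscillation_hz
        yaw_osc = amp * np.sin(2 * np.pi * f * times)
        pitch_osc = 0.5 * amp * np.sin(2 * np.pi * 1.37 * f * times + 1.0)
        quats = (
            Rotation.from_euler("z", (yaws + yaw_osc)[:, None])
            * Rotation.from_euler("y", pitch_osc[:, None])
        ).as_quat()
    else:
        quats = _yaw_quat(yaws)
    if spec.pose_noise_m > 0 or spec.pose_noise_deg > 0:
        positions = positions + rng.normal(0, spec.pose_noise_m, positions.shape)
        jitter = Rotation.from_euler(
            "zyx", rng.normal(0, np.radians(spec.pose_noise_deg), (len(times), 3))
        )
        quats = (Rotation.from_quat(quats) * jitter).as_quat()
    traj = Trajectory(
        times,
        positions,
        quats,
        cam_position=np.array([0.0, 0.0, spec.camera_height]),
        cam_quat=_CAM_QUAT,
        time_offset=spec.time_offset,
    )
    traj._pass_windows = pass_windows  # consumed by simulate_scene
    return traj


def _azimuth_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    return np.degrees(np.arctan2(dy, dx))


def simulate_detections(
    scene: SimScene,
    cam: CameraIntrinsics | None = None,
    seed: int | None = None,
) -> None:
    """Fill ``scene.frames`` and the detection↔fruit correspondence.

    A fruit is detected in a frame iff it projects inside the image, its
    camera range lies in the detection envelope, the viewing azimuth falls
    inside its visibility window, and no miss occurs.  Misses have two
    components: ``miss_rate`` is persistent per fruit and pass (the
    detector consistently fails on that fruit — the dominant real-world
    mode, since detector failures correlate strongly across near-identical
    consecutive views), while ``transient_miss_rate`` is an i.i.d.
    per-frame Bernoulli miss, the component that fragments tracks and
    drives sequential double-counting.  Centroids get Gaussian pixel
    noise; Poisson-many false positives are placed uniformly; logged image
    timestamps are shifted by the injected clock offset (logged = true −
    offset, so the additive correction that realigns them equals +offset);
    frames may be dropped wholesale.
    """
    spec = scene.spec
    cam = cam or scene.cam
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 2)
    traj = scene.trajectory
    # frames at the imaging rate across the whole scan (true capture times)
    t_frames = np.arange(traj.t_min, traj.t_max, 1.0 / spec.frame_rate)
    if spec.drop_frame_fraction > 0:
        keep = rng.random(len(t_frames)) >= spec.drop_frame_fraction
        t_frames = t_frames[keep]
    near, far = spec.detect_range
    half_window = spec.occlusion_window_deg / 2.0
    frames: list[FrameDetections] = []
    correspondence: dict[int, list[int]] = {}
    pass_windows = [(t0, t1) for (_, _, t0, t1) in scene.passes]
    persistent_miss: dict[int, np.ndarray] = {}

    def pass_index(t: float) -> int:
        for i, (a, b) in enumerate(pass_windows):
            if a <= t <= b:
                return i
        return -1

    saved_offset = traj.time_offset
    traj.time_offset = 0.0  # simulate with true capture times
    try:
        for k, t_true in enumerate(t_frames):
            pose = traj.camera_pose(t_true)
            dets: list[Detection] = []
            ids: list[int] = []
            if scene.n_fruit:
                pix, depth, in_front = project_points(pose, cam, scene.fruit_positions)
                visible = in_front.copy()
                visible &= (depth >= near) & (depth <= far)
                idx = np.flatnonzero(visible)
                if len(idx):
                    visible[idx] &= cam.contains(pix[idx])
                if spec.occlusion_window_deg < 360:
                    daz = _azimuth_deg(
                        pose.position[0] - scene.fruit_positions[:, 0],
                        pose.position[1] - scene.fruit_positions[:, 1],
                    ) - scene.fruit_window_centre
                    daz = (daz + 180.0) % 360.0 - 180.0
                    visible &= np.abs(daz) <= half_window
                if spec.miss_rate > 0:
                    p_idx = pass_index(float(t_true))
                    if p_idx not in persistent_miss:
                        persistent_miss[p_idx] = rng.random(scene.n_fruit) < spec.miss_rate
                    visible &= ~persistent_miss[p_idx]
                if spec.transient_miss_rate > 0:
                    visible &= rng.random(scene.n_fruit) >= spec.transient_miss_rate
                for i in np.flatnonzero(visible):
                    size_u = cam.fx * spec.fruit_diameter / depth[i]
                    size_v = cam.fy * spec.fruit_diameter / depth[i]
                    centre = pix[i] + rng.normal(0, spec.centroid_noise_px, 2)
                    dets.append(
                        Detection(
                            k,
                            (
                                centre[0] - size_u / 2,
                                centre[1] - size_v / 2,
                                centre[0] + size_u / 2,
                                centre[1] + size_v / 2,
                            ),
                            score=float(rng.uniform(0.7, 1.0)),
                        )
                    )
                    ids.append(int(i))
            if spec.fp_rate > 0 and dets:
                n_fp = rng.poisson(spec.fp_rate * len(dets))
                for _ in range(n_fp):
                    cu = rng.uniform(20, cam.width - 20)
                    cv = rng.uniform(20, cam.height - 20)
                    s = cam.fx * spec.fruit_diameter / np.mean(spec.detect_range)
                    dets.append(Detection(k, (cu - s / 2, cv - s / 2, cu + s / 2, cv + s / 2), 0.7))
                    ids.append(-1)
            frames.append(FrameDetections(k, float(t_true) - spec.time_offset, dets))
            correspondence[k] = ids
    finally:
        traj.time_offset = saved_offset
    scene.frames = frames
    scene.correspondence = correspondence


def simulate_scene(spec: OrchardSpec, seed: int | None = None) -> SimScene:
    """Generate a complete scene: orchard, trajectory, frames, truth."""
    base = spec.seed if seed is None else seed
    fruit_pos, fruit_tree, fruit_row, windows, cloud = generate_orchard(spec, base)
    traj = generate_trajectory(spec, base)
    pass_windows = traj._pass_windows
    passes = []
    for i, (t0, t1) in enumerate(pass_windows):
        row = i // 2 + 1
        side = i % 2
        passes.append((row, side, t0, t1))
    scene = SimScene(
        spec=spec,
        cam=default_camera(),
        fruit_positions=fruit_pos,
        fruit_tree=fruit_tree,
        fruit_row=fruit_row,
        fruit_window_centre=windows,
        cloud=cloud,
        trajectory=traj,
        passes=passes,
    )
    simulate_detections(scene, seed=base)
    return scene
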