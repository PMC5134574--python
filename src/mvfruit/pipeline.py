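"""End-to-end orchestration: row passes → tracking → counting →
triangulation → masking → tree assignment → statistics.

The stages are usable individually; :func:`run_pipeline` chains them on
files, and the ``*_scene`` helpers run the same logic on an in-memory
synthetic scene (the test path).  Per-tree totals sum the two independent
side passes of each row without cross-side deduplication — tracking never
crosses a row side, so a fruit visible from both sides is tallied on both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mvio
from .geometry import CameraIntrinsics, Trajectory
from .localise import (
    ElevationMap,
    Fruit3D,
    ground_elevation_map,
    height_above_ground,
    triangulate_tracks,
)
from .orchard_stats import OrchardSummary, calibrated_total, per_tree_yield_map
from .tracking import FrameDetections, FruitTrack, TrackerConfig, count_fruit, track_pass
from .trees import (
    LabelledPointCloud,
    RowPass,
    detect_row_passes,
    image_tree_inventory,
    render_tree_mask,
    thin_cloud,
    vote_tree,
)

__all__ = [
    "MaskParams",
    "PipelineConfig",
    "label_detections",
    "track_all_passes",
    "count_scene_per_tree",
    "single_view_counts",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskParams:
    """LiDAR-mask rendering parameters (defaults per the scan protocol)."""

    voxel_size: float = 0.2
    keep_fraction: float = 0.05
    radius_px: int = 20
    ground_cutoff: float = 0.20
    elevation_cell: float = 0.5
    thin_seed: int = 0
    # masks are label lookups, not imagery: rasterising at a fraction of the
    # sensor resolution (with the dilation radius scaled to match) preserves
    # the assignment while cutting render cost ~16x at the default 1/4 scale
    render_scale: float = 0.25


@dataclass
class PipelineConfig:
    """File-based pipeline configuration."""

    trajectory_path: str
    detections_path: str
    camera_path: str
    cloud_path: str | None = None
    output_dir: str = "mvfruit_out"
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    mask: MaskParams = field(default_factory=MaskParams)
    calibration_slope: float | None = None
    write_masks: bool = False
    seed: int = 0


def match_passes_to_rows(
    passes: list[RowPass], trajectory: Trajectory, cloud: LabelledPointCloud
) -> dict[int, int]:
    """Map each detected pass to the nearest labelled cloud row.

    Uses the mean trajectory position over the pass against the centroid of
    each row's labelled points.
    """
    rows = sorted(r for r in np.unique(cloud.row_id) if r > 0)
    centroids = {r: cloud.points[cloud.row_id == r].mean(axis=0) for r in rows}
    mapping = {}
    for p in passes:
        m = (trajectory.times >= p.t_entry) & (trajectory.times <= p.t_exit)
        centre = trajectory.positions[m].mean(axis=0)
        mapping[p.row_id] = min(
            rows, key=lambda r: float(np.linalg.norm(centroids[r][:2] - centre[:2]))
        )
    return mapping


def label_detections(
    frames: list[FrameDetections],
    row_cloud: LabelledPointCloud,
    full_row_cloud: LabelledPointCloud,
    trajectory: Trajectory,
    cam: CameraIntrinsics,
    elevation_map: ElevationMap,
    mask: MaskParams = MaskParams(),
    mask_writer=None,
):
    """Per-detection tree labels for one row pass, rendered frame by frame.

    The thinned cloud builds the frame inventory; the full (un-thinned) row
    cloud renders each mask, which is read at every detection centroid and
    then discarded (masks are only persisted when ``mask_writer`` is given).
    Returns (labels: frame_id → int array, inventory, mask_centroids:
    frame_id → {tree: (u, v)} for best-single-view selection).
    """
    thinned = thin_cloud(row_cloud, mask.voxel_size, mask.keep_fraction, mask.thin_seed)
    s = mask.render_scale
    if s != 1.0:
        render_cam = CameraIntrinsics(
            cam.fx * s,
            cam.fy * s,
            (cam.cx + 0.5) * s - 0.5,
            (cam.cy + 0.5) * s - 0.5,
            int(round(cam.width * s)),
            int(round(cam.height * s)),
            cam.distortion,
        )
        radius = max(1, int(round(mask.radius_px * s)))
    else:
        render_cam, radius = cam, mask.radius_px

    def to_render(p):  # full-res pixel -> render raster pixel
        return (np.asarray(p, float) + 0.5) * s - 0.5

    def to_full(p):  # render raster pixel -> full-res pixel
        return (np.asarray(p, float) + 0.5) / s - 0.5

    frame_times = {f.frame_id: f.timestamp for f in frames}
    inventory = image_tree_inventory(thinned, trajectory, render_cam, frame_times)
    labels: dict[int, np.ndarray] = {}
    centroids: dict[int, dict[int, np.ndarray]] = {}
    for f in frames:
        trees_here = inventory.get(f.frame_id, set())
        if not trajectory.covers(f.timestamp):
            labels[f.frame_id] = np.zeros(len(f.detections), int)
            centroids[f.frame_id] = {}
            continue
        pose = trajectory.camera_pose(f.timestamp)
        tm = render_tree_mask(
            full_row_cloud,
            pose,
            render_cam,
            f.frame_id,
            trees_here,
            elevation_map,
            radius,
            mask.ground_cutoff,
        )
        labels[f.frame_id] = np.array(
            [tm.label_at(to_render(d.centroid)) for d in f.detections], int
        )
        centroids[f.frame_id] = {
            t: to_full(c) for t in trees_here if (c := tm.centroid_of(t)) is not None
        }
        if mask_writer is not None:
            mask_writer(tm)
    return labels, inventory, centroids


def assign_tree_votes(
    tracks: list[FruitTrack],
    labels: dict[int, np.ndarray],
    det_index: dict[tuple[int, int], int],
) -> None:
    """Set each track's tree id by modal vote over its detections' labels."""
    for tr in tracks:
        votes = []
        for f, det in tr.observations:
            idx = det_index.get((f, id(det)))
            if idx is not None and f in labels and idx < len(labels[f]):
                votes.append(int(labels[f][idx]))
        tr.tree_id = vote_tree(votes)


def _detection_index(frames: list[FrameDetections]) -> dict[tuple[int, int], int]:
    return {
        (f.frame_id, id(d)): i for f in frames for i, d in enumerate(f.detections)
    }


def track_all_passes(
    pass_frames: list[list[FrameDetections]],
    trajectory: Trajectory,
    cam: CameraIntrinsics,
    cfg: TrackerConfig,
) -> list[list[FruitTrack]]:
    """Track each row pass independently with globally unique fruit ids."""
    out = []
    next_id = 0
    for frames in pass_frames:
        tracks = track_pass(frames, trajectory, cam, cfg, start_id=next_id)
        next_id += len(tracks)
        out.append(tracks)
    return out


def count_scene_per_tree(
    pass_frames: list[list[FrameDetections]],
    pass_labels: list[dict[int, np.ndarray]],
    trajectory: Trajectory,
    cam: CameraIntrinsics,
    cfg: TrackerConfig,
):
    """Multi-view per-tree counts summed over passes (no cross-side dedup).

    Returns (per-tree dict, all qualifying tracks, unassigned count).
    """
    per_tree: dict[int, int] = {}
    unassigned = 0
    kept_tracks: list[FruitTrack] = []
    for frames, labels in zip(pass_frames, pass_labels):
        tracks = track_pass(frames, trajectory, cam, cfg)
        det_index = _detection_index(frames)
        _, ids = count_fruit(tracks, cfg)
        keep = {i for i in ids}
        counted = [tr for tr in tracks if tr.fruit_id in keep]
        assign_tree_votes(counted, labels, det_index)
        for tr in counted:
            if tr.tree_id is None:
                unassigned += 1
            else:
                per_tree[tr.tree_id] = per_tree.get(tr.tree_id, 0) + 1
        kept_tracks.extend(counted)
    return per_tree, kept_tracks, unassigned


def single_view_counts(
    pass_frames: list[list[FrameDetections]],
    pass_labels: list[dict[int, np.ndarray]],
    pass_centroids: list[dict[int, dict[int, np.ndarray]]],
    cam: CameraIntrinsics,
) -> list[dict[int, int]]:
    """Best-single-image count per tree for each pass.

    For every tree the frame whose mask centroid is nearest the image
    centre is selected, and the detections labelled with that tree in that
    single frame are counted — the single-view baseline that sees only
    unoccluded fruit from the most central vantage point.
    """
    img_centre = cam.centre
    out = []
    for frames, labels, centroids in zip(pass_frames, pass_labels, pass_centroids):
        counts: dict[int, int] = {}
        trees = {t for per in centroids.values() for t in per}
        for tree in trees:
            best, best_d = None, np.inf
            for f in frames:
                c = centroids.get(f.frame_id, {}).get(tree)
                if c is None:
                    continue
                d = float(np.linalg.norm(c - img_centre))
                if d < best_d:
                    best, best_d = f.frame_id, d
            if best is not None:
                counts[tree] = int(np.sum(labels[best] == tree))
        out.append(counts)
    return out


def run_pipeline(config: PipelineConfig) -> OrchardSummary:
    """Run the full file-based pipeline and write all artifacts.

    Stages: read inputs → detect row passes → per-pass tracking and
    counting → triangulation → (if a cloud is given) masking and per-tree
    assignment → statistics.  Without a cloud the output is per-pass/block
    tallies and fruit positions only — per-tree association is the one
    stage that needs LiDAR.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cam, ext = mvio.read_camera_config(config.camera_path)
    trajectory = mvio.read_trajectory_csv(
        config.trajectory_path,
        time_offset=ext["time_offset"],
        cam_position=ext["cam_position"],
        cam_quat=ext["cam_quat"],
    )
    frames = mvio.read_detections_csv(config.detections_path)
    config.tracker.validate_for(cam)

    passes = detect_row_passes(trajectory)
    if not passes:
        raise RuntimeError("row-pass detection: no straight row traversals found")
    off = trajectory.time_offset
    pass_frames = [
        [f for f in frames if p.t_entry <= f.timestamp + off <= p.t_exit] for p in passes
    ]
    log.info("detected %d passes; frames per pass: %s", len(passes), [len(p) for p in pass_frames])

    cloud = mvio.read_ply(config.cloud_path) if config.cloud_path else None
    elevation = (
        ground_elevation_map(cloud.points, config.mask.elevation_cell) if cloud is not None else None
    )

    pass_labels, pass_centroids = [], []
    if cloud is not None:
        row_of_pass = match_passes_to_rows(passes, trajectory, cloud)
        mask_dir = out / "masks"
        if config.write_masks:
            mask_dir.mkdir(exist_ok=True)
        for p, pf in zip(passes, pass_frames):
            row_cloud = cloud.restrict_to_row(row_of_pass[p.row_id])
            writer = (
                (lambda tm, _p=p: mvio.write_mask_png(
                    mask_dir / f"pass{_p.row_id}_frame{tm.frame_id}.png", tm
                ))
                if config.write_masks
                else None
            )
            labels, inventory, centroids = label_detections(
                pf, row_cloud, row_cloud, trajectory, cam, elevation, config.mask, writer
            )
            pass_labels.append(labels)
            pass_centroids.append(centroids)
    else:
        pass_labels = [{f.frame_id: np.zeros(len(f.detections), int) for f in pf} for pf in pass_frames]

    per_tree, tracks, unassigned = count_scene_per_tree(
        pass_frames, pass_labels, trajectory, cam, config.tracker
    )
    if cloud is None:
        # without masks nothing can be attributed: everything is "unassigned"
        per_tree, unassigned = {}, unassigned + sum(per_tree.values())
        for tr in tracks:
            tr.tree_id = None
    log.info(
        "counted %d fruit (%d unassigned to trees) across %d passes",
        len(tracks),
        unassigned,
        len(passes),
    )

    frame_times = {f.frame_id: f.timestamp for f in frames}
    fruit = triangulate_tracks(tracks, frame_times, trajectory, cam, config.tracker.min_observations)
    if cloud is not None:
        tree_rows = {
            int(t): int(np.bincount(cloud.row_id[cloud.tree_id == t]).argmax())
            for t in cloud.trees
        }
        for f in fruit:
            if f.tree_id is not None:
                f.row_id = tree_rows.get(f.tree_id)
    if elevation is not None:
        for f in fruit:
            if f.position is not None:
                f.height_above_ground = height_above_ground(f.position, elevation)

    summary = per_tree_yield_map(fruit)
    if config.calibration_slope:
        summary.calibrated_block_total = calibrated_total(
            summary.block_total, config.calibration_slope
        )
    mvio.write_tracks_csv(out / "tracks.csv", tracks)
    mvio.write_fruit_csv(out / "fruit.csv", fruit)
    summary.per_tree.to_csv(out / "per_tree.csv", index=False)
    summary.per_row.to_csv(out / "per_row.csv", index=False)
    if len(summary.per_tree):
        mvio.write_geojson_points(out / "yield_map.geojson", summary.per_tree)
    return summary
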