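"""Tree inventory, LiDAR-derived image masks and fruit-to-tree assignment.

The tree-labelled LiDAR cloud (segmented upstream; consumed here, not
produced) serves four purposes: splitting the trajectory into row passes,
deciding which trees appear in which images, rasterising occlusion-aware
per-tree pixel masks used to attribute tracked fruit to trees, and canopy
volume.  Masking is only needed for per-tree attribution — row and block
tallies work without any LiDAR input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections import Counter

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import disk

from .geometry import CameraIntrinsics, Pose, Trajectory, project_points
from .localise import ElevationMap
from .tracking import FruitTrack

__all__ = [
    "LabelledPointCloud",
    "TreeMask",
    "RowPass",
    "detect_row_passes",
    "thin_cloud",
    "image_tree_inventory",
    "render_tree_mask",
    "assign_tracks_to_trees",
    "best_single_view",
    "canopy_volume",
]

log = logging.getLogger(__name__)


@dataclass
class LabelledPointCloud:
    """3D points with per-point tree and row labels (0 = ground/unassigned)."""

    points: np.ndarray  # (N, 3)
    tree_id: np.ndarray  # (N,) int
    row_id: np.ndarray  # (N,) int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        self.tree_id = np.asarray(self.tree_id, int)
        self.row_id = np.asarray(self.row_id, int)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def trees(self) -> list[int]:
        return sorted(t for t in np.unique(self.tree_id) if t > 0)

    def tree_points(self, tree: int) -> np.ndarray:
        return self.points[self.tree_id == tree]

    def restrict_to_row(self, row: int) -> "LabelledPointCloud":
        m = self.row_id == row
        return LabelledPointCloud(self.points[m], self.tree_id[m], self.row_id[m])


@dataclass
class TreeMask:
    """Per-image label raster; pixel value = tree id, 0 = background."""

    frame_id: int
    labels: np.ndarray  # (height, width) uint16

    def label_at(self, pixel: np.ndarray) -> int:
        h, w = self.labels.shape
        u = int(np.clip(round(float(pixel[0])), 0, w - 1))
        v = int(np.clip(round(float(pixel[1])), 0, h - 1))
        return int(self.labels[v, u])

    def centroid_of(self, tree: int) -> np.ndarray | None:
        vs, us = np.nonzero(self.labels == tree)
        if len(us) == 0:
            return None
        return np.array([us.mean(), vs.mean()])


@dataclass(frozen=True)
class RowPass:
    """One straight traversal of a row side."""

    row_id: int
    side: int  # 0/1 by direction of travel
    t_entry: float
    t_exit: float

    def contains(self, t: float) -> bool:
        return self.t_entry <= t <= self.t_exit


def detect_row_passes(
    trajectory: Trajectory,
    yaw_rate_threshold_deg: float = 10.0,
    min_length_m: float = 20.0,
    smooth_window_s: float = 0.5,
) -> list[RowPass]:
    """Segment the trajectory into straight row traversals.

    The vehicle drives straight down each row with an on-the-spot turn at
    the headlands; the turn's sustained high yaw rate is the salient marker
    separating passes.  The yaw rate is differenced over a smoothing window
    so chassis vibration does not masquerade as a turn.  Side labels come
    from the direction of travel relative to the first pass (boustrophedon
    scanning views opposite row sides on alternating passes).  Passes
    shorter than ``min_length_m`` of actual path are discarded; a
    stationary trajectory yields none.
    """
    t = trajectory.times
    if len(t) < 2:
        return []
    yaw = np.unwrap(trajectory.yaw())
    k = max(1, int(round(smooth_window_s / max(float(np.median(np.diff(t))), 1e-6))))
    k = min(k, len(t) - 1)
    yaw_rate = np.abs(np.degrees((yaw[k:] - yaw[:-k]) / (t[k:] - t[:-k])))
    # centre the windowed rate estimate on each inter-sample gap
    pad_lo = k // 2
    yaw_rate = np.concatenate(
        [np.full(pad_lo, yaw_rate[0]), yaw_rate, np.full(len(t) - 1 - len(yaw_rate) - pad_lo, yaw_rate[-1])]
    )
    straight = yaw_rate < yaw_rate_threshold_deg
    passes: list[RowPass] = []
    ref_heading = None
    i = 0
    n = len(straight)
    while i < n:
        if not straight[i]:
            i += 1
            continue
        j = i
        while j < n and straight[j]:
            j += 1
        seg = slice(i, j + 1)
        path_len = float(
            np.sum(np.linalg.norm(np.diff(trajectory.positions[seg], axis=0), axis=1))
        )
        if path_len >= min_length_m:
            heading = np.array([np.cos(yaw[i:j + 1]).mean(), np.sin(yaw[i:j + 1]).mean()])
            if ref_heading is None:
                ref_heading = heading
                side = 0
            else:
                side = 0 if heading @ ref_heading > 0 else 1
            passes.append(RowPass(len(passes), side, float(t[i]), float(t[j])))
        i = j
    if not passes:
        log.warning("no straight segment of at least %.1f m found", min_length_m)
    return passes


def thin_cloud(
    cloud: LabelledPointCloud,
    voxel_size: float = 0.2,
    keep_fraction: float = 0.05,
    seed: int = 0,
) -> LabelledPointCloud:
    """Voxel-downsample then randomly thin the cloud (for the inventory step).

    One representative point per occupied voxel, then a seeded uniform
    subsample of ``keep_fraction`` of the representatives.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    vox = np.floor(cloud.points / voxel_size).astype(np.int64)
    # unique voxel per (voxel cell, tree) so tree labels survive downsampling
    key = np.column_stack([vox, cloud.tree_id])
    _, rep_idx = np.unique(key, axis=0, return_index=True)
    if keep_fraction < 1.0:
        rng = np.random.default_rng(seed)
        n_keep = max(1, int(round(keep_fraction * len(rep_idx))))
        rep_idx = rng.choice(rep_idx, size=n_keep, replace=False)
    rep_idx = np.sort(rep_idx)
    return LabelledPointCloud(
        cloud.points[rep_idx], cloud.tree_id[rep_idx], cloud.row_id[rep_idx]
    )


def image_tree_inventory(
    thinned: LabelledPointCloud,
    trajectory: Trajectory,
    cam: CameraIntrinsics,
    frame_times: dict[int, float],
) -> dict[int, set[int]]:
    """Which foreground trees each frame contains.

    A tree is "contained" in a frame as soon as a single thinned point of
    that tree projects inside the image with positive depth.  The caller
    restricts the cloud to the current row (processing is strictly per row,
    which suppresses background-row trees).
    """
    fg = thinned.tree_id > 0
    pts, tids = thinned.points[fg], thinned.tree_id[fg]
    inventory: dict[int, set[int]] = {}
    for frame_id, t in frame_times.items():
        inventory[frame_id] = set()
        if not trajectory.covers(t):
            continue
        pose = trajectory.camera_pose(t)
        pix, _, in_front = project_points(pose, cam, pts)
        ok = in_front.copy()
        ok[in_front] = cam.contains(pix[in_front])
        inventory[frame_id] = set(int(x) for x in np.unique(tids[ok]))
    return inventory


def render_tree_mask(
    cloud: LabelledPointCloud,
    pose: Pose,
    cam: CameraIntrinsics,
    frame_id: int,
    trees_in_frame: set[int],
    elevation_map: ElevationMap | None = None,
    radius_px: int = 20,
    ground_cutoff: float = 0.20,
) -> TreeMask:
    """Rasterise the per-tree pixel mask for one image.

    Points within ``ground_cutoff`` of the local ground surface are deleted
    first (so fallen fruit are not attributed to trees), then the full,
    un-thinned points of all contained trees are projected.  LiDAR and
    camera perspectives differ, so occlusion is resolved point-wise: a
    projected point is suppressed when a point of another tree lies within
    a ``radius_px`` lateral pixel radius at smaller depth.  Each surviving
    tree's pixels are dilated by a disk of the same radius and layered
    farthest-to-nearest tree (by mean point depth) so nearer trees
    overwrite.
    """
    labels = np.zeros((cam.height, cam.width), np.uint16)
    trees = [t for t in sorted(trees_in_frame) if t > 0]
    if not trees:
        return TreeMask(frame_id, labels)
    sel = np.isin(cloud.tree_id, trees)
    pts, tids = cloud.points[sel], cloud.tree_id[sel]
    if elevation_map is not None and ground_cutoff > 0:
        ix = np.clip(
            np.floor((pts[:, 0] - elevation_map.origin[0]) / elevation_map.cell_size),
            0,
            elevation_map.elevation.shape[1] - 1,
        ).astype(int)
        iy = np.clip(
            np.floor((pts[:, 1] - elevation_map.origin[1]) / elevation_map.cell_size),
            0,
            elevation_map.elevation.shape[0] - 1,
        ).astype(int)
        above = pts[:, 2] >= elevation_map.elevation[iy, ix] + ground_cutoff
        pts, tids = pts[above], tids[above]
    pix, depth, in_front = project_points(pose, cam, pts)
    keep = in_front.copy()
    keep[in_front] = cam.contains(pix[in_front])
    pix, depth, tids = pix[keep], depth[keep], tids[keep]
    if len(pix) == 0:
        return TreeMask(frame_id, labels)
    # cross-tree occlusion: nearest point wins within the lateral radius
    if len(set(tids.tolist())) > 1:
        tree_px = cKDTree(pix)
        suppressed = np.zeros(len(pix), bool)
        neighbours = tree_px.query_ball_point(pix, r=radius_px)
        for i, nb in enumerate(neighbours):
            for j in nb:
                if tids[j] != tids[i] and depth[j] < depth[i]:
                    suppressed[i] = True
                    break
        pix, depth, tids = pix[~suppressed], depth[~suppressed], tids[~suppressed]
    order = sorted(trees, key=lambda tr: -float(depth[tids == tr].mean()) if np.any(tids == tr) else 0.0)
    # dilating a sparse point raster by a disk == stamping the disk at each
    # point; stamping is much faster than dense morphology here
    offsets = np.argwhere(disk(radius_px) > 0) - radius_px  # (K, 2) as (dv, du)
    for tree in order:
        m = tids == tree
        if not np.any(m):
            continue
        us = np.clip(np.round(pix[m, 0]).astype(int), 0, cam.width - 1)
        vs = np.clip(np.round(pix[m, 1]).astype(int), 0, cam.height - 1)
        stamped = (np.column_stack([vs, us])[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
        ok = (
            (stamped[:, 0] >= 0)
            & (stamped[:, 0] < cam.height)
            & (stamped[:, 1] >= 0)
            & (stamped[:, 1] < cam.width)
        )
        stamped = stamped[ok]
        labels[stamped[:, 0], stamped[:, 1]] = tree
    return TreeMask(frame_id, labels)


def vote_tree(labels: list[int]) -> int | None:
    """Modal non-zero label; ties break to the lowest tree id; all-zero → None."""
    nz = [x for x in labels if x > 0]
    if not nz:
        return None
    counts = Counter(nz)
    top = max(counts.values())
    return min(t for t, c in counts.items() if c == top)


def assign_tracks_to_trees(
    tracks: list[FruitTrack],
    masks: dict[int, TreeMask],
) -> list[FruitTrack]:
    """Attribute each track to a tree by the maximally-occurring mask vote.

    Each observation reads the mask label under its centroid; the track's
    tree is the modal non-zero label (fruit near a tree boundary may be
    labelled inconsistently frame to frame — the vote settles it).
    """
    for tr in tracks:
        votes = [
            masks[f].label_at(det.centroid)
            for f, det in tr.observations
            if f in masks
        ]
        tr.tree_id = vote_tree(votes)
    return tracks


def best_single_view(masks: dict[int, TreeMask], tree: int) -> int:
    """Frame whose mask centroid for ``tree`` is closest to the image centre.

    Used to emulate single/dual-view counting, where only the most central
    image of each tree side is tallied.
    """
    best, best_d = None, np.inf
    for frame_id, mask in masks.items():
        c = mask.centroid_of(tree)
        if c is None:
            continue
        h, w = mask.labels.shape
        d = float(np.linalg.norm(c - np.array([(w - 1) / 2, (h - 1) / 2])))
        if d < best_d:
            best, best_d = frame_id, d
    if best is None:
        raise ValueError(f"tree {tree} absent from all masks")
    return best


def canopy_volume(
    points: np.ndarray,
    voxel_size: float = 0.2,
    ground_cutoff: float = 0.20,
    elevation_map: ElevationMap | None = None,
) -> float:
    """Canopy volume: occupied-voxel count × voxel volume after ground removal.

    Without an elevation map the lowest point of the tree's own cloud
    stands in for the local ground level.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) == 0:
        return 0.0
    if elevation_map is not None:
        ground = np.array([elevation_map.elevation_at(p) for p in pts])
    else:
        ground = float(pts[:, 2].min())
    pts = pts[pts[:, 2] >= ground + ground_cutoff]
    if len(pts) == 0:
        return 0.0
    vox = np.unique(np.floor(pts / voxel_size).astype(np.int64), axis=0)
    return float(len(vox)) * voxel_size**3
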