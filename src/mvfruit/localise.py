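"""Triangulation of tracks to 3D positions and height above local ground.

A track's observations back-project to (effectively unconstrained) world
rays.  In theory all rays of one fruit meet at a point; calibration, time
synchronisation and centroid errors prevent that in practice, so the
position estimate is the mean of the midpoints of the mutual-closest-point
segments over all unordered ray pairs.  Near-parallel pairs are excluded
because their midpoint is numerically unstable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import CameraIntrinsics, Ray, TimeOutOfRange, Trajectory, backproject_ray
from .tracking import FruitTrack

__all__ = [
    "Fruit3D",
    "ElevationMap",
    "ray_pair_midpoint",
    "triangulate_rays",
    "triangulate_track",
    "triangulate_tracks",
    "ground_elevation_map",
    "height_above_ground",
]

log = logging.getLogger(__name__)

#: ray pairs closer to parallel than this (degrees) are excluded
PARALLEL_TOL_DEG = 0.1


@dataclass
class Fruit3D:
    """A counted fruit with geolocation and canopy attributes."""

    fruit_id: int
    position: np.ndarray | None
    height_above_ground: float | None = None
    n_observations: int = 0
    tree_id: int | None = None
    row_id: int | None = None
    triangulation_failed: bool = False


def ray_pair_midpoint(r1: Ray, r2: Ray) -> np.ndarray | None:
    """Midpoint of the shortest segment between two rays (None if parallel)."""
    d1, d2 = r1.direction, r2.direction
    cos = float(np.clip(abs(d1 @ d2), 0.0, 1.0))
    if np.degrees(np.arccos(cos)) < PARALLEL_TOL_DEG:
        return None
    w0 = r1.origin - r2.origin
    a, b, c = 1.0, float(d1 @ d2), 1.0
    d, e = float(d1 @ w0), float(d2 @ w0)
    denom = a * c - b * b
    s = (b * e - c * d) / denom
    t = (a * e - b * d) / denom
    p1 = r1.origin + s * d1
    p2 = r2.origin + t * d2
    return (p1 + p2) / 2.0


def triangulate_track(
    track: FruitTrack,
    trajectory: Trajectory,
    cam: CameraIntrinsics,
    frame_times: dict[int, float],
) -> Fruit3D:
    """Midpoint-method triangulation of one track.

    All observation rays are used unweighted; the estimate is the average of
    the pairwise closest-point midpoints.  ``frame_times`` maps frame_id to
    the image timestamp (camera clock).  If every pair is near-parallel (or
    pose coverage leaves fewer than two rays) the fruit keeps its count but
    is flagged ``triangulation_failed``.
    """
    rays: list[Ray] = []
    for frame_id, det in track.observations:
        try:
            pose = trajectory.camera_pose(frame_times[frame_id])
        except TimeOutOfRange:
            continue
        rays.append(backproject_ray(pose, cam, det.centroid))
    n = len(rays)
    if n < 2:
        return Fruit3D(track.fruit_id, None, n_observations=len(track), triangulation_failed=True)
    pos = triangulate_rays(rays)
    if pos is None:
        log.warning("track %d: all ray pairs near-parallel", track.fruit_id)
        return Fruit3D(track.fruit_id, None, n_observations=n, triangulation_failed=True)
    return Fruit3D(track.fruit_id, pos, n_observations=n)


def triangulate_rays(rays: list[Ray]) -> np.ndarray | None:
    """Mean of pairwise closest-point midpoints over all unordered ray pairs.

    Returns ``None`` when every pair is within the parallelism tolerance.
    """
    midpoints = [
        m
        for r1, r2 in combinations(rays, 2)
        if (m := ray_pair_midpoint(r1, r2)) is not None
    ]
    if not midpoints:
        return None
    return np.mean(np.vstack(midpoints), axis=0)


def triangulate_tracks(
    tracks: list[FruitTrack],
    frame_times: dict[int, float],
    trajectory: Trajectory,
    cam: CameraIntrinsics,
    min_observations: int = 2,
) -> list[Fruit3D]:
    """Triangulate every track with enough observations.

    ``frame_times`` maps frame_id → image timestamp (camera clock).
    """
    out = []
    for tr in tracks:
        if len(tr) < min_observations:
            continue
        f = triangulate_track(tr, trajectory, cam, frame_times)
        f.tree_id = tr.tree_id
        out.append(f)
    return out


@dataclass
class ElevationMap:
    """Gridded ground elevation derived from the LiDAR cloud.

    Per-cell elevation is a low percentile of point heights, which is robust
    to grass and canopy returns; empty cells inherit the nearest filled
    cell.
    """

    origin: np.ndarray  # (x0, y0) of cell (0, 0)
    cell_size: float
    elevation: np.ndarray  # (ny, nx) metres

    def elevation_at(self, position: np.ndarray) -> float:
        p = np.asarray(position, float)
        ny, nx = self.elevation.shape
        ix = int(np.clip(np.floor((p[0] - self.origin[0]) / self.cell_size), 0, nx - 1))
        iy = int(np.clip(np.floor((p[1] - self.origin[1]) / self.cell_size), 0, ny - 1))
        return float(self.elevation[iy, ix])


def ground_elevation_map(
    points: np.ndarray,
    cell_size: float = 0.5,
    percentile: float = 5.0,
) -> ElevationMap:
    """Build a ground elevation raster from (N, 3) cloud points.

    The per-cell ground estimate is the ``percentile``-th height so canopy
    points above the true ground do not bias the surface; empty cells are
    filled from their nearest non-empty cell.
    """
    pts = np.asarray(points, float)
    if pts.size == 0:
        raise ValueError("empty point cloud")
    pts = pts.reshape(-1, 3)
    x0, y0 = pts[:, 0].min(), pts[:, 1].min()
    ix = np.floor((pts[:, 0] - x0) / cell_size).astype(int)
    iy = np.floor((pts[:, 1] - y0) / cell_size).astype(int)
    nx, ny = ix.max() + 1, iy.max() + 1
    elev = np.full((ny, nx), np.nan)
    flat = iy * nx + ix
    order = np.argsort(flat, kind="stable")
    flat_s, z_s = flat[order], pts[order, 2]
    bounds = np.flatnonzero(np.diff(flat_s)) + 1
    for cell, zs in zip(
        np.split(flat_s, bounds), np.split(z_s, bounds)
    ):
        elev[cell[0] // nx, cell[0] % nx] = np.percentile(zs, percentile)
    # nearest-neighbour fill of empty cells
    if np.any(np.isnan(elev)):
        yy, xx = np.mgrid[0:ny, 0:nx]
        filled = ~np.isnan(elev)
        tree = cKDTree(np.column_stack([xx[filled], yy[filled]]))
        empty = np.isnan(elev)
        _, idx = tree.query(np.column_stack([xx[empty], yy[empty]]))
        elev[empty] = elev[filled][idx]
    return ElevationMap(np.array([x0, y0]), cell_size, elev)


def height_above_ground(position: np.ndarray, elevation_map: ElevationMap) -> float:
    """Vertical distance from a fruit position to the local ground surface.

    Positions outside the map extent use the nearest cell (clamped lookup).
    """
    p = np.asarray(position, float)
    return float(p[2] - elevation_map.elevation_at(p))
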