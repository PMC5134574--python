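"""Readers and writers for the pipeline's on-disk formats.

Trajectory and detections travel as CSV, the camera as YAML/JSON, the
labelled point cloud as ASCII PLY with per-vertex ``tree_id``/``row_id``
scalars, tree masks as 16-bit single-channel PNG, inventories and yield
maps as JSON/GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.spatial.transform import Rotation

from .geometry import CameraIntrinsics, Trajectory
from .localise import Fruit3D
from .tracking import Detection, FrameDetections, FruitTrack
from .trees import LabelledPointCloud, TreeMask

__all__ = [
    "read_trajectory_csv",
    "write_trajectory_csv",
    "read_detections_csv",
    "write_detections_csv",
    "read_camera_config",
    "write_camera_config",
    "read_ply",
    "write_ply",
    "write_tracks_csv",
    "write_fruit_csv",
    "read_fruit_csv",
    "write_mask_png",
    "read_mask_png",
    "write_geojson_points",
]


# -- trajectory -------------------------------------------------------------

def read_trajectory_csv(path, time_offset: float = 0.0, cam_position=None, cam_quat=None) -> Trajectory:
    """Load a pose trajectory from CSV.

    Accepts either quaternion columns ``t,x,y,z,qw,qx,qy,qz`` or Euler
    columns ``t,x,y,z,roll,pitch,yaw`` (degrees), auto-detected from the
    header.
    """
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    t = df[cols["t"]].to_numpy(float)
    pos = df[[cols["x"], cols["y"], cols["z"]]].to_numpy(float)
    if "qw" in cols:
        q_wxyz = df[[cols["qw"], cols["qx"], cols["qy"], cols["qz"]]].to_numpy(float)
        quats = np.column_stack([q_wxyz[:, 1], q_wxyz[:, 2], q_wxyz[:, 3], q_wxyz[:, 0]])
    elif "yaw" in cols:
        rpy = df[[cols["roll"], cols["pitch"], cols["yaw"]]].to_numpy(float)
        quats = Rotation.from_euler("xyz", rpy, degrees=True).as_quat()
    else:
        raise ValueError("trajectory CSV needs qw..qz or roll/pitch/yaw columns")
    kwargs = {}
    if cam_position is not None:
        kwargs["cam_position"] = np.asarray(cam_position, float)
    if cam_quat is not None:
        kwargs["cam_quat"] = np.asarray(cam_quat, float)
    return Trajectory(t, pos, quats, time_offset=time_offset, **kwargs)


def write_trajectory_csv(path, trajectory: Trajectory) -> None:
    q = trajectory.quats
    pd.DataFrame(
        {
            "t": trajectory.times,
            "x": trajectory.positions[:, 0],
            "y": trajectory.positions[:, 1],
            "z": trajectory.positions[:, 2],
            "qw": q[:, 3],
            "qx": q[:, 0],
            "qy": q[:, 1],
            "qz": q[:, 2],
        }
    ).to_csv(path, index=False)


# -- detections -------------------------------------------------------------

def read_detections_csv(path) -> list[FrameDetections]:
    """Columns: frame_id, t, u_min, v_min, u_max, v_max, score."""
    df = pd.read_csv(path)
    frames = []
    for (fid, t), grp in df.groupby(["frame_id", "t"], sort=True):
        dets = [
            Detection(int(fid), (r.u_min, r.v_min, r.u_max, r.v_max), float(r.score))
            for r in grp.itertuples()
        ]
        frames.append(FrameDetections(int(fid), float(t), dets))
    frames.sort(key=lambda f: f.timestamp)
    return frames


def write_detections_csv(path, frames: list[FrameDetections]) -> None:
    rows = [
        (f.frame_id, f.timestamp, *d.bbox, d.score)
        for f in frames
        for d in f.detections
    ]
    pd.DataFrame(
        rows, columns=["frame_id", "t", "u_min", "v_min", "u_max", "v_max", "score"]
    ).to_csv(path, index=False)


# -- camera -----------------------------------------------------------------

def read_camera_config(path):
    """Camera YAML/JSON: intrinsics plus optional extrinsics and time offset.

    Returns (CameraIntrinsics, extrinsic dict) where the extrinsic dict has
    ``cam_position``, ``cam_quat`` (scalar-last) and ``time_offset`` keys
    suitable for :class:`Trajectory`.
    """
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    cam = CameraIntrinsics(
        fx=float(cfg["fx"]),
        fy=float(cfg["fy"]),
        cx=float(cfg["cx"]),
        cy=float(cfg["cy"]),
        width=int(cfg["width"]),
        height=int(cfg["height"]),
        distortion=tuple(cfg.get("distortion", []) or []),
    )
    ext = cfg.get("extrinsic", {}) or {}
    extras = {
        "cam_position": np.asarray(ext.get("position", [0.0, 0.0, 0.0]), float),
        "cam_quat": np.asarray(ext.get("quat_xyzw", [0.0, 0.0, 0.0, 1.0]), float),
        "time_offset": float(cfg.get("time_offset", 0.0)),
    }
    return cam, extras


def write_camera_config(path, cam: CameraIntrinsics, cam_position=None, cam_quat=None, time_offset: float = 0.0) -> None:
    cfg = {
        "fx": cam.fx,
        "fy": cam.fy,
        "cx": cam.cx,
        "cy": cam.cy,
        "width": cam.width,
        "height": cam.height,
        "distortion": list(cam.distortion),
        "time_offset": float(time_offset),
        "extrinsic": {
            "position": [float(v) for v in (cam_position if cam_position is not None else np.zeros(3))],
            "quat_xyzw": [
                float(v)
                for v in (cam_quat if cam_quat is not None else np.array([0, 0, 0, 1.0]))
            ],
        },
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# -- point cloud (ASCII PLY) ------------------------------------------------

def write_ply(path, cloud: LabelledPointCloud) -> None:
    """ASCII PLY with per-vertex scalar properties tree_id and row_id."""
    n = len(cloud)
    header = "\n".join(
        [
            "ply",
            "format ascii 1.0",
            f"element vertex {n}",
            "property float x",
            "property float y",
            "property float z",
            "property int tree_id",
            "property int row_id",
            "end_header",
        ]
    )
    body = np.column_stack([cloud.points, cloud.tree_id, cloud.row_id])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, body, fmt="%.4f %.4f %.4f %d %d")


def read_ply(path) -> LabelledPointCloud:
    """Read an ASCII PLY with x/y/z and optional tree_id/row_id properties."""
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertex = 0
        props: list[str] = []
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: truncated header")
            line = line.strip()
            if line.startswith("format"):
                if "ascii" not in line:
                    raise ValueError(f"{path}: only ASCII PLY supported")
            elif line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        data = np.loadtxt(fh, max_rows=n_vertex).reshape(n_vertex, len(props))
    col = {p: i for i, p in enumerate(props)}
    pts = data[:, [col["x"], col["y"], col["z"]]]
    tree = data[:, col["tree_id"]].astype(int) if "tree_id" in col else np.zeros(n_vertex, int)
    row = data[:, col["row_id"]].astype(int) if "row_id" in col else np.zeros(n_vertex, int)
    return LabelledPointCloud(pts, tree, row)


# -- tracks / fruit tables --------------------------------------------------

def write_tracks_csv(path, tracks: list[FruitTrack]) -> None:
    rows = [
        (tr.fruit_id, f, *d.centroid, tr.tree_id if tr.tree_id is not None else 0)
        for tr in tracks
        for f, d in tr.observations
    ]
    pd.DataFrame(rows, columns=["fruit_id", "frame_id", "u", "v", "tree_id"]).to_csv(
        path, index=False
    )


def write_fruit_csv(path, fruit: list[Fruit3D]) -> None:
    rows = []
    for f in fruit:
        p = f.position if f.position is not None else (np.nan, np.nan, np.nan)
        rows.append(
            (
                f.fruit_id,
                p[0],
                p[1],
                p[2],
                f.height_above_ground if f.height_above_ground is not None else np.nan,
                f.n_observations,
                f.tree_id if f.tree_id is not None else 0,
                f.row_id if f.row_id is not None else 0,
            )
        )
    pd.DataFrame(
        rows, columns=["fruit_id", "x", "y", "z", "height", "n_obs", "tree_id", "row_id"]
    ).to_csv(path, index=False)


def read_fruit_csv(path) -> list[Fruit3D]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        pos = np.array([r.x, r.y, r.z])
        out.append(
            Fruit3D(
                fruit_id=int(r.fruit_id),
                position=None if np.any(np.isnan(pos)) else pos,
                height_above_ground=None if np.isnan(r.height) else float(r.height),
                n_observations=int(r.n_obs),
                tree_id=int(r.tree_id) or None,
                row_id=int(r.row_id) or None,
            )
        )
    return out


# -- masks / geojson --------------------------------------------------------

def write_mask_png(path, mask: TreeMask) -> None:
    iio.imwrite(path, mask.labels.astype(np.uint16))


def read_mask_png(path, frame_id: int = -1) -> TreeMask:
    return TreeMask(frame_id, np.asarray(iio.imread(path), np.uint16))


def write_geojson_points(path, per_tree: pd.DataFrame) -> None:
    """Yield map as GeoJSON points (local metric coordinates)."""
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [float(r.x), float(r.y), float(r.z)],
            },
            "properties": {"tree_id": int(r.tree_id), "row_id": int(r.row_id), "count": int(r.count)},
        }
        for r in per_tree.itertuples()
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
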