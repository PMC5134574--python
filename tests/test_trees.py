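"""Row-pass detection, cloud thinning, inventory, masks and canopy volume."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mvfruit.geometry import Pose, Trajectory
from mvfruit.localise import ground_elevation_map
from mvfruit.synthetic import OrchardSpec, default_camera, simulate_scene
from mvfruit.trees import (
    LabelledPointCloud,
    assign_tracks_to_trees,
    best_single_view,
    canopy_volume,
    detect_row_passes,
    image_tree_inventory,
    render_tree_mask,
    thin_cloud,
    vote_tree,
)
from mvfruit.tracking import Detection, FruitTrack


def _straight_trajectory(length=60.0, speed=1.4, yaw=0.0):
    n = int(length / speed * 50)
    t = np.arange(n) / 50.0
    pos = np.column_stack([speed * t, np.zeros(n), np.zeros(n)])
    q = np.tile(Rotation.from_euler("z", yaw).as_quat(), (n, 1))
    return Trajectory(t, pos, q)


class TestDetectRowPasses:
    def test_single_straight_line_is_one_pass(self):
        traj = _straight_trajectory()
        passes = detect_row_passes(traj)
        assert len(passes) == 1
        assert passes[0].t_entry == pytest.approx(traj.t_min)
        assert passes[0].t_exit == pytest.approx(traj.t_max)

    def test_stationary_trajectory_has_no_passes(self):
        n = 500
        t = np.arange(n) / 50.0
        traj = Trajectory(t, np.zeros((n, 3)), np.tile([0, 0, 0, 1.0], (n, 1)))
        assert detect_row_passes(traj) == []

    def test_boustrophedon_roundtrip_matches_simulator(self):
        scene = simulate_scene(OrchardSpec(trees_per_row=6, fruit_per_tree_fixed=1, seed=2))
        detected = detect_row_passes(scene.trajectory)
        assert len(detected) == len(scene.passes)
        for det, (row, side, t0, t1) in zip(detected, scene.passes):
            assert det.side == side
            assert abs(det.t_entry - t0) < 0.5
            assert abs(det.t_exit - t1) < 0.5


class TestThinCloud:
    def _cloud(self, pts, tree=1, row=1):
        pts = np.asarray(pts, float)
        return LabelledPointCloud(pts, np.full(len(pts), tree), np.full(len(pts), row))

    def test_identical_points_collapse_to_one(self):
        cloud = self._cloud(np.tile([1.0, 2.0, 3.0], (1000, 1)))
        thinned = thin_cloud(cloud, 0.2, keep_fraction=1.0)
        assert len(thinned) == 1

    def test_unit_cube_voxel_occupancy(self):
        rng = np.random.default_rng(0)
        cloud = self._cloud(rng.uniform(0, 0.999, (60000, 3)))
        thinned = thin_cloud(cloud, 0.2, keep_fraction=1.0)
        assert len(thinned) == 125  # 5^3 voxels of 0.2 m

    def test_keep_fraction_subsamples(self):
        rng = np.random.default_rng(1)
        cloud = self._cloud(rng.uniform(0, 10, (5000, 3)))
        full = thin_cloud(cloud, 0.2, keep_fraction=1.0)
        thinned = thin_cloud(cloud, 0.2, keep_fraction=0.05, seed=0)
        assert len(thinned) == max(1, round(0.05 * len(full)))
        # deterministic under the same seed
        again = thin_cloud(cloud, 0.2, keep_fraction=0.05, seed=0)
        assert np.array_equal(thinned.points, again.points)


def _look_at_plus_x():
    # camera z (optical axis) along world +x, u along -y... use body yaw 0 +
    # the simulator's left-looking extrinsic for realistic orientation
    from mvfruit.synthetic import _CAM_QUAT

    return _CAM_QUAT


@pytest.fixture(scope="module")
def two_tree_setup():
    cam = default_camera()
    rng = np.random.default_rng(5)
    # two trees straight ahead of a left-looking camera at y=4.5 and y=8,
    # same bearing: the nearer tree occludes the farther in the overlap

    def ball(centre, n=3000, r=1.2):
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return centre + d * r

    near_pts = ball(np.array([0.0, 4.5, 2.0]))
    far_pts = ball(np.array([0.0, 8.0, 2.0]))
    pts = np.vstack([near_pts, far_pts])
    cloud = LabelledPointCloud(
        pts,
        np.concatenate([np.ones(3000, int), np.full(3000, 2)]),
        np.ones(6000, int),
    )
    pose = Pose(0.0, np.array([0.0, 0.0, 2.0]), _look_at_plus_x())
    return cam, cloud, pose


class TestInventoryAndMasks:
    def test_tree_in_front_is_contained(self, two_tree_setup):
        cam, cloud, pose = two_tree_setup
        traj = Trajectory(
            np.array([-1.0, 1.0]),
            np.zeros((2, 3)),
            np.tile([0, 0, 0, 1.0], (2, 1)),
            cam_position=np.array([0.0, 0.0, 2.0]),
            cam_quat=_look_at_plus_x(),
        )
        inv = image_tree_inventory(cloud, traj, cam, {0: 0.0})
        assert inv[0] == {1, 2}

    def test_tree_behind_camera_not_contained(self, two_tree_setup):
        cam, cloud, pose = two_tree_setup
        behind = LabelledPointCloud(
            cloud.points * np.array([1.0, -1.0, 1.0]),  # mirror to -y: behind
            cloud.tree_id,
            cloud.row_id,
        )
        traj = Trajectory(
            np.array([-1.0, 1.0]),
            np.zeros((2, 3)),
            np.tile([0, 0, 0, 1.0], (2, 1)),
            cam_position=np.array([0.0, 0.0, 2.0]),
            cam_quat=_look_at_plus_x(),
        )
        inv = image_tree_inventory(behind, traj, cam, {0: 0.0})
        assert inv[0] == set()

    def test_occlusion_overlap_labelled_with_nearer_tree(self, two_tree_setup):
        cam, cloud, pose = two_tree_setup
        mask = render_tree_mask(cloud, pose, cam, 0, {1, 2}, radius_px=20)
        # the far tree subtends a subset of the near tree's pixels: every
        # pixel where both could project must carry the near tree's id
        assert np.sum(mask.labels == 1) > 0
        # centre of the image looks straight at both tree centres
        assert mask.label_at(np.array([cam.cx, cam.cy])) == 1

    def test_mask_labels_subset_of_inventory(self, two_tree_setup):
        cam, cloud, pose = two_tree_setup
        mask = render_tree_mask(cloud, pose, cam, 0, {1}, radius_px=10)
        present = set(np.unique(mask.labels)) - {0}
        assert present <= {1}

    def test_no_trees_gives_empty_mask(self, two_tree_setup):
        cam, cloud, pose = two_tree_setup
        mask = render_tree_mask(cloud, pose, cam, 0, set(), radius_px=10)
        assert not mask.labels.any()

    def test_ground_cutoff_removes_low_points(self, two_tree_setup):
        cam, cloud, pose = two_tree_setup
        low = LabelledPointCloud(
            np.column_stack(
                [np.zeros(200), np.linspace(3, 6, 200), np.full(200, 0.05)]
            ),
            np.ones(200, int),
            np.ones(200, int),
        )
        em = ground_elevation_map(
            np.column_stack([np.zeros(100), np.linspace(0, 10, 100), np.zeros(100)]),
            cell_size=1.0,
        )
        mask = render_tree_mask(low, pose, cam, 0, {1}, elevation_map=em, radius_px=10)
        assert not mask.labels.any()


class TestVotesAndBestView:
    def test_majority_vote(self):
        assert vote_tree([3, 3, 4]) == 3

    def test_all_background_is_unassigned(self):
        assert vote_tree([0, 0, 0]) is None

    def test_tie_breaks_to_lowest_id(self):
        assert vote_tree([3, 3, 4, 4]) == 3

    def test_assign_tracks_reads_masks(self):
        from mvfruit.trees import TreeMask

        labels = np.zeros((100, 100), np.uint16)
        labels[40:60, 40:60] = 7
        masks = {0: TreeMask(0, labels), 1: TreeMask(1, labels)}
        d0 = Detection(0, (45, 45, 55, 55))
        d1 = Detection(1, (5, 5, 15, 15))
        tr = FruitTrack(0, [(0, d0), (1, d1)])
        assign_tracks_to_trees([tr], masks)
        assert tr.tree_id == 7

    def test_best_single_view_prefers_centred_mask(self):
        from mvfruit.trees import TreeMask

        def mask_at(u0):
            lab = np.zeros((100, 200), np.uint16)
            lab[40:60, u0 : u0 + 20] = 5
            return lab

        masks = {
            0: TreeMask(0, mask_at(10)),
            7: TreeMask(7, mask_at(90)),  # centred horizontally
            9: TreeMask(9, mask_at(160)),
        }
        assert best_single_view(masks, 5) == 7

    def test_best_single_view_absent_tree_raises(self):
        from mvfruit.trees import TreeMask

        masks = {0: TreeMask(0, np.zeros((10, 10), np.uint16))}
        with pytest.raises(ValueError):
            best_single_view(masks, 3)


class TestCanopyVolume:
    def test_ten_voxels(self):
        # ten clearly separated occupied 0.2 m voxels, all above the cutoff
        pts = np.column_stack(
            [np.arange(10) * 1.0, np.zeros(10), np.full(10, 2.0)]
        )
        pts = np.vstack([pts, [0.0, 0.0, 0.0]])  # ground reference point
        assert canopy_volume(pts, voxel_size=0.2) == pytest.approx(0.08)

    def test_all_points_below_cutoff(self):
        pts = np.column_stack([np.arange(5) * 0.01, np.zeros(5), np.full(5, 0.1)])
        assert canopy_volume(pts, voxel_size=0.2) == 0.0

    def test_solid_cube_within_a_voxel_shell(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, (200000, 3)) + np.array([0, 0, 1.0])
        pts = np.vstack([pts, [0.5, 0.5, 0.0]])
        vol = canopy_volume(pts, voxel_size=0.2)
        assert abs(vol - 1.0) < 6 * 0.2**3 * 25  # within one voxel shell


class TestBackgroundRowSuppression:
    def test_other_row_trees_never_in_masks(self):
        scene = simulate_scene(
            OrchardSpec(n_rows=2, trees_per_row=4, fruit_per_tree_fixed=5, seed=9)
        )
        row1 = scene.cloud.restrict_to_row(1)
        assert set(np.unique(row1.tree_id)) - {0} <= set(range(1, 5))
        thinned = thin_cloud(row1, 0.2, 0.05)
        times = dict(list(scene.frame_times.items())[:20])
        inv = image_tree_inventory(thinned, scene.trajectory, scene.cam, times)
        for trees in inv.values():
            assert all(1 <= t <= 4 for t in trees)
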