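"""Association costs, optimal assignment, track chaining and counting."""

from itertools import permutations

import numpy as np
import pytest

from mvfruit.geometry import Segment2D
from mvfruit.tracking import (
    Detection,
    FrameDetections,
    FruitTrack,
    TrackerConfig,
    association_costs,
    count_fruit,
    solve_assignment,
    track_pass,
)

CFG = TrackerConfig()


def _det(u, v, frame=0, size=10.0):
    return Detection(frame, (u - size / 2, v - size / 2, u + size / 2, v + size / 2))


def brute_force_min_cost(cost: np.ndarray) -> float:
    """Exhaustive minimum over all one-to-one matchings of min(m,n) pairs."""
    m, n = cost.shape
    if m > n:
        return brute_force_min_cost(cost.T)
    best = np.inf
    for perm in permutations(range(n), m):
        best = min(best, sum(cost[i, j] for i, j in enumerate(perm)))
    return best


class TestAssociationCosts:
    seg = Segment2D(np.array([100.0, 200.0]), np.array([200.0, 200.0]))

    def test_perpendicular_offset(self):
        cost = association_costs([self.seg], np.array([[150.0, 190.0]]), CFG)
        assert cost[0, 0] == pytest.approx(10.0)

    def test_centroid_beyond_segment_end_is_invalid(self):
        cost = association_costs([self.seg], np.array([[250.0, 200.0]]), CFG)
        assert cost[0, 0] == CFG.big_cost

    def test_on_segment_costs_zero(self):
        cost = association_costs([self.seg], np.array([[137.0, 200.0]]), CFG)
        assert cost[0, 0] == pytest.approx(0.0)

    def test_above_threshold_invalid(self):
        cost = association_costs([self.seg], np.array([[150.0, 260.0]]), CFG)
        assert cost[0, 0] == CFG.big_cost

    def test_missing_segment_invalid(self):
        cost = association_costs([None], np.array([[150.0, 200.0]]), CFG)
        assert cost[0, 0] == CFG.big_cost

    def test_degenerate_segment_uses_point_distance(self):
        pt = Segment2D(np.array([100.0, 100.0]), np.array([100.0, 100.0]))
        cost = association_costs([pt], np.array([[103.0, 104.0]]), CFG)
        assert cost[0, 0] == pytest.approx(5.0)


class TestSolveAssignment:
    def test_two_by_two_example(self):
        matches = solve_assignment(np.array([[1.0, 2.0], [2.0, 4.0]]))
        assert matches == {(0, 1), (1, 0)}  # total 4 beats 5

    def test_one_by_three_takes_argmin(self):
        assert solve_assignment(np.array([[5.0, 2.0, 9.0]])) == {(0, 1)}

    def test_all_big_cost_yields_no_matches(self):
        big = CFG.big_cost
        cost = np.full((2, 2), big)
        assert solve_assignment(cost, big) == set()

    def test_matches_brute_force_on_random_rectangular(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = rng.integers(1, 7)
            n = rng.integers(1, 8)
            cost = rng.uniform(0, 100, (m, n))
            matches = solve_assignment(cost)
            total = sum(cost[r, c] for r, c in matches)
            assert total == pytest.approx(brute_force_min_cost(cost))


def _stationary_frames(detections_per_frame):
    """Frames for a camera that never moves (degenerate segments)."""
    return [
        FrameDetections(i, float(i) * 0.2, [_det(u, v, i) for u, v in dets])
        for i, dets in enumerate(detections_per_frame)
    ]


@pytest.fixture()
def static_trajectory():
    from mvfruit.geometry import Trajectory

    return Trajectory(
        np.array([0.0, 100.0]),
        np.zeros((2, 3)),
        np.tile([0.0, 0.0, 0.0, 1.0], (2, 1)),
    )


class TestTrackPass:
    def test_static_repeat_detections_chain_with_zero_cost(self, static_trajectory, survey_cam):
        frames = _stationary_frames([[(500, 600)], [(500, 600)]])
        tracks = track_pass(frames, static_trajectory, survey_cam)
        assert len(tracks) == 1
        assert len(tracks[0]) == 2

    def test_gap_breaks_track(self, static_trajectory, survey_cam):
        # visible frames 0-2, absent 3, visible 4-5 -> two separate tracks
        frames = _stationary_frames(
            [[(500, 600)], [(500, 600)], [(500, 600)], [], [(500, 600)], [(500, 600)]]
        )
        tracks = track_pass(frames, static_trajectory, survey_cam)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [2, 3]

    def test_missing_pose_coverage_skips_frame_and_breaks_tracks(self, static_trajectory, survey_cam):
        frames = _stationary_frames([[(500, 600)], [(500, 600)], [(500, 600)]])
        frames[1].timestamp = 500.0  # outside trajectory span
        tracks = track_pass(frames, static_trajectory, survey_cam)
        assert len(tracks) == 2  # no segment synthesised across the gap

    def test_consecutive_visibility_yields_single_track(self, clean_scene, clean_pass):
        tracks = track_pass(clean_pass, clean_scene.trajectory, clean_scene.cam)
        # every (frame, detection) appears in exactly one track
        seen = set()
        for tr in tracks:
            for f, d in tr.observations:
                key = (f, id(d))
                assert key not in seen
                seen.add(key)
        assert len(seen) == sum(len(f.detections) for f in clean_pass)

    def test_noiseless_pass_recovers_exact_count(self, clean_scene, clean_pass):
        tracks = track_pass(clean_pass, clean_scene.trajectory, clean_scene.cam)
        n, _ = count_fruit(tracks)
        assert n == clean_scene.n_fruit

    def test_frame_drop_degrades_count(self):
        # dropping half the frames doubles the travel between views; the
        # longer, more ambiguous epipolar segments must worsen the count
        # (this needs realistic noise: noiseless matches stay exact at any
        # baseline because the true correspondence still has zero cost)
        from mvfruit.synthetic import OrchardSpec, simulate_scene

        base = dict(trees_per_row=6, fruit_per_tree_fixed=40, seed=21)
        errs = {}
        for frac in (0.0, 0.5):
            scene = simulate_scene(OrchardSpec(drop_frame_fraction=frac, **base))
            total = 0
            for row, side, t0, t1 in scene.passes:
                tracks = track_pass(
                    scene.frames_in_window(t0, t1), scene.trajectory, scene.cam
                )
                total += count_fruit(tracks)[0]
            errs[frac] = abs(total - scene.n_fruit) / scene.n_fruit
        assert errs[0.5] > errs[0.0]

    def test_threshold_only_affects_gating(self, clean_scene, clean_pass):
        # noiseless data: any threshold comfortably above zero gives the
        # same exact count (the plateau, in its degenerate noise-free form)
        counts = []
        for th in (15.0, 30.0, 100.0):
            tracks = track_pass(
                clean_pass, clean_scene.trajectory, clean_scene.cam,
                TrackerConfig(distance_threshold=th),
            )
            counts.append(count_fruit(tracks)[0])
        assert counts[0] == counts[1] == counts[2] == clean_scene.n_fruit


class TestCountFruit:
    def _tracks(self, lengths):
        out = []
        for i, ln in enumerate(lengths):
            obs = [(j, _det(100, 100, j)) for j in range(ln)]
            out.append(FruitTrack(i, obs))
        return out

    def test_singletons_rejected(self):
        n, ids = count_fruit(self._tracks([1, 2, 5, 1]))
        assert n == 2
        assert ids == [1, 2]

    def test_empty(self):
        assert count_fruit([]) == (0, [])

    def test_all_long_tracks_counted(self):
        n, _ = count_fruit(self._tracks([2, 3, 4]))
        assert n == 3
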