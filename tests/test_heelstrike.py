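import numpy as np
import pytest

from vidgait.heelstrike import (
    HeelStrikeEvent,
    NoStanceDataError,
    STDBSCANParams,
    detect_stances,
    heel_strikes_auto,
    heel_strikes_manual,
    merge_feet,
    st_dbscan,
)
from vidgait.pose_io import AnnotationSet, BoutMeta, PoseSequence

SCHEME = {"left_hip": 0, "right_hip": 1, "left_ankle": 2, "right_ankle": 3}


def brute_force_st_dbscan(times, coords, eps_s, eps_t, min_pts):
    """Independent oracle: explicit neighborhood graph + core-component
    expansion.  Cluster ids ordered by each component's earliest core; border
    points go to the smallest cluster id among their core neighbors (the
    cluster expanded first claims them)."""
    n = len(times)
    coords = np.asarray(coords, dtype=float).reshape(n, -1)
    neigh = [
        {
            j
            for j in range(n)
            if abs(times[i] - times[j]) <= eps_t
            and np.sqrt(((coords[i] - coords[j]) ** 2).sum()) <= eps_s
        }
        for i in range(n)
    ]
    core = [len(neigh[i]) >= min_pts for i in range(n)]
    # connected components over cores (edges between mutually-neighboring cores)
    comp = [-1] * n
    comp_id = 0
    order = []
    for i in range(n):
        if core[i] and comp[i] == -1:
            stack = [i]
            comp[i] = comp_id
            while stack:
                u = stack.pop()
                for v in neigh[u]:
                    if core[v] and comp[v] == -1:
                        comp[v] = comp_id
                        stack.append(v)
            order.append(comp_id)
            comp_id += 1
    labels = np.full(n, -1, dtype=int)
    for i in range(n):
        if core[i]:
            labels[i] = comp[i]
    for i in range(n):
        if not core[i]:
            owner = [comp[j] for j in neigh[i] if core[j]]
            if owner:
                labels[i] = min(owner)
    return labels


class TestSTDBSCAN:
    def test_degenerate_density_one_cluster(self):
        times = np.linspace(0, 0.3, 10)
        coords = np.zeros((10, 2))
        labels = st_dbscan(times, coords, 1.0, 1.0, 4)
        assert (labels == 0).all()

    def test_isolated_point_is_noise(self):
        labels = st_dbscan(np.array([0.0]), np.zeros((1, 2)), 1.0, 1.0, 2)
        assert labels.tolist() == [-1]

    def test_empty_input(self):
        labels = st_dbscan(np.array([]), np.zeros((0, 2)), 1.0, 1.0, 3)
        assert labels.size == 0

    def test_spatially_separated_groups_two_clusters(self):
        times = np.concatenate([np.linspace(0, 0.5, 8), np.linspace(0.05, 0.55, 8)])
        coords = np.vstack([np.zeros((8, 2)), np.full((8, 2), 100.0)])
        order = np.argsort(times, kind="stable")
        labels = st_dbscan(times[order], coords[order], 5.0, 1.0, 4)
        assert set(labels) == {0, 1}

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            st_dbscan(np.array([1.0, 0.0]), np.zeros((2, 2)), 1.0, 1.0, 2)

    @pytest.mark.parametrize("dims", [1, 2, 3])
    def test_matches_bruteforce_oracle_random(self, dims, rng):
        for _ in range(30):
            n = int(rng.integers(5, 150))
            times = np.sort(rng.uniform(0, 5, n))
            coords = rng.uniform(0, 20, (n, dims))
            eps_s = float(rng.uniform(0.5, 6.0))
            eps_t = float(rng.uniform(0.05, 1.0))
            min_pts = int(rng.integers(2, 10))
            ours = st_dbscan(times, coords, eps_s, eps_t, min_pts)
            oracle = brute_force_st_dbscan(times, coords, eps_s, eps_t, min_pts)
            np.testing.assert_array_equal(ours, oracle)


def _plateau_sequence(plateaus, fps=30.0, swing_frames=10, step_px=60.0):
    """Ankle track with the given number of flat plateaus; returns the
    sequence and the true plateau start frames."""
    frames = []
    starts = []
    pos = 100.0
    f = 0
    for _ in range(plateaus):
        starts.append(f)
        frames.extend([pos] * 12)  # 0.4 s plateau
        f += 12
        last = pos
        pos += step_px
        for k in range(1, swing_frames + 1):
            frames.append(last + (pos - last) * k / (swing_frames + 1))
            f += 1
    frames.extend([pos] * 12)
    x = np.array(frames)
    n = x.size
    coords = np.zeros((n, 4, 2))
    coords[:, 2, 0] = x
    coords[:, 2, 1] = 400.0
    coords[:, 3, :] = 50.0
    coords[:, 0, :] = [300.0, 240.0]
    coords[:, 1, :] = [330.0, 240.0]
    seq = PoseSequence(coords=coords, fps=fps, joint_scheme=dict(SCHEME))
    return seq, starts


class TestDetectStances:
    PARAMS = STDBSCANParams(eps_spatial=8.0, eps_temporal=0.25, min_pts=6,
                            censor_start=False)

    def test_plateaus_recovered_at_their_boundaries(self):
        seq, starts = _plateau_sequence(4)
        stances = detect_stances(seq, "left", self.PARAMS)
        assert [s.frame_first for s in stances] == starts + [len(seq.times) - 12]

    def test_continuously_moving_ankle_gives_no_stances(self):
        n = 200
        coords = np.zeros((n, 4, 2))
        coords[:, 2, 0] = np.arange(n) * 6.0  # fast, never stationary
        coords[:, 2, 1] = 400.0
        coords[:, 0, :] = [300.0, 240.0]
        coords[:, 1, :] = [330.0, 240.0]
        seq = PoseSequence(coords=coords, fps=30.0, joint_scheme=dict(SCHEME))
        assert detect_stances(seq, "left", self.PARAMS) == []

    def test_close_plateaus_merge_into_one_stance(self):
        # two plateaus closer than eps in both space and time are combined —
        # the far-field failure mode for short steps
        seq, _ = _plateau_sequence(2, swing_frames=2, step_px=3.0)
        params = STDBSCANParams(eps_spatial=8.0, eps_temporal=0.25, min_pts=6,
                                censor_start=False)
        stances = detect_stances(seq, "left", params)
        assert len(stances) == 1

    def test_untracked_ankle_raises(self):
        coords = np.full((50, 4, 2), np.nan)
        coords[:, 0, :] = [300.0, 240.0]
        coords[:, 1, :] = [330.0, 240.0]
        seq = PoseSequence(coords=coords, fps=30.0, joint_scheme=dict(SCHEME))
        with pytest.raises(NoStanceDataError):
            detect_stances(seq, "left", self.PARAMS)

    def test_censoring_drops_contact_in_progress_at_window_start(self):
        seq, starts = _plateau_sequence(3)
        params = STDBSCANParams(eps_spatial=8.0, eps_temporal=0.25, min_pts=6,
                                censor_start=True)
        stances = detect_stances(seq, "left", params)
        assert [s.frame_first for s in stances] == starts[1:] + [len(seq.times) - 12]


class TestEvents:
    def test_auto_events_at_stance_first_frames(self):
        seq, starts = _plateau_sequence(3)
        stances = detect_stances(seq, "left", TestDetectStances.PARAMS)
        events = heel_strikes_auto(stances, seq.fps)
        assert [e.frame for e in events] == [s.frame_first for s in stances]
        assert all(e.source == "auto" for e in events)
        assert heel_strikes_auto([], 30.0) == []

    def test_manual_event_position_from_trajectory(self, simple_sequence):
        ann = AnnotationSet(bout_id="b", events=[(30, "left")])
        events = heel_strikes_manual(ann, simple_sequence)
        assert len(events) == 1
        np.testing.assert_allclose(
            events[0].position, simple_sequence.joint_coords("left_ankle")[30]
        )
        assert events[0].source == "manual"

    def test_manual_event_in_gap_dropped_with_warning(self, simple_sequence):
        seq = simple_sequence.copy()
        seq.missing_mask[30, seq.joint_index("left_ankle")] = True
        ann = AnnotationSet(bout_id="b", events=[(30, "left")])
        with pytest.warns(UserWarning, match="dropped"):
            assert heel_strikes_manual(ann, seq) == []


def _ev(frame, foot, fps=30.0):
    return HeelStrikeEvent(
        frame=frame, time_s=frame / fps, foot=foot, position=np.array([0.0, 0.0])
    )


class TestMergeFeet:
    def test_alternating_feet_all_steps_valid(self):
        merged, valid = merge_feet([_ev(10, "left"), _ev(40, "left")], [_ev(25, "right")])
        assert [e.frame for e in merged] == [10, 25, 40]
        assert valid.tolist() == [True, True]

    def test_same_foot_consecutive_invalidates_step(self):
        merged, valid = merge_feet([_ev(10, "left"), _ev(40, "left")], [])
        assert valid.tolist() == [False]
        assert merged[1].flagged

    def test_simultaneous_strikes_left_first_and_flagged(self):
        merged, valid = merge_feet([_ev(10, "left")], [_ev(10, "right")])
        assert [e.foot for e in merged] == ["left", "right"]
        assert merged[1].flagged and valid.tolist() == [False]

    def test_random_interleavings_sorted_permutation(self, rng):
        for _ in range(20):
            lf = sorted(rng.choice(300, size=rng.integers(1, 8), replace=False))
            rf = sorted(rng.choice(300, size=rng.integers(1, 8), replace=False))
            left = [_ev(int(f), "left") for f in lf]
            right = [_ev(int(f), "right") for f in rf]
            merged, _ = merge_feet(left, right)
            frames = [e.frame for e in merged]
            assert frames == sorted(frames)
            assert sorted(frames) == sorted(list(lf) + list(rf))
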