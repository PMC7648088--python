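"""Track linking, kinematics, movement similarity and landmark displacement."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay

import fibroswarm as fs
from conftest import isotropic_motion_tracks, make_tracks, uniform_motion_tracks
from fibroswarm.errors import InputError
from fibroswarm.tracks import pairwise_angles_deg

# ---------------------------------------------------------------------------
# linking


def test_single_detection_per_frame_links_to_one_track():
    det = pd.DataFrame({"frame": np.arange(10), "x": np.arange(10) * 0.5, "y": 0.0, "z": 0.0})
    linked = fs.link_detections(det, max_disp=2.0)
    assert linked["track_id"].nunique() == 1
    assert len(linked) == 10


def test_wellseparated_simulated_tracks_recovered_exactly():
    # cells on a coarse lattice jittered by < max_disp/4: mutual NN is exact
    rng = np.random.default_rng(0)
    gx, gy = np.meshgrid(np.arange(5) * 40.0, np.arange(4) * 40.0)
    p0 = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(20)])
    pos = np.array([p0 + rng.uniform(-1, 1, p0.shape) for _ in range(8)])
    for f in range(1, 8):
        pos[f] = pos[f - 1] + rng.uniform(-1.5, 1.5, p0.shape)
    truth = make_tracks(pos)
    det = truth[["frame", "x", "y", "z"]]
    linked = fs.link_detections(det, max_disp=6.0)
    assert linked["track_id"].nunique() == 20
    # every recovered track follows exactly one ground-truth cell
    merged = linked.merge(truth, on=["frame", "x", "y", "z"])
    groups = merged.groupby("track_id_x")["track_id_y"].nunique()
    assert (groups == 1).all()


def test_jump_longer_than_max_disp_splits_track():
    x = np.concatenate([np.arange(5) * 1.0, 100 + np.arange(5) * 1.0])
    det = pd.DataFrame({"frame": np.arange(10), "x": x, "y": 0.0, "z": 0.0})
    linked = fs.link_detections(det, max_disp=5.0)
    assert linked["track_id"].nunique() == 2
    split = linked[linked["frame"] == 5]["track_id"].iloc[0]
    assert split != linked[linked["frame"] == 4]["track_id"].iloc[0]


def test_empty_detections_give_empty_table():
    out = fs.link_detections(pd.DataFrame(columns=["frame", "x", "y"]), max_disp=1.0)
    assert len(out) == 0


# ---------------------------------------------------------------------------
# kinematics


def test_step_345_gives_displacement_5():
    tracks = make_tracks(np.array([[[0.0, 0, 0]], [[3.0, 4, 0]]]))
    kin, _ = fs.step_kinematics(tracks, dt=15.0)
    assert len(kin) == 1
    assert kin["step_displacement"].iloc[0] == pytest.approx(5.0)
    assert kin["velocity"].iloc[0] == pytest.approx(1 / 3)


def test_stationary_track_zero_velocity_and_singletons_dropped():
    pos = np.zeros((6, 1, 3))
    kin, curve = fs.step_kinematics(make_tracks(pos), dt=15.0)
    assert (kin["velocity"] == 0).all()
    single = make_tracks(np.zeros((1, 1, 3)))
    kin1, _ = fs.step_kinematics(single, dt=15.0)
    assert len(kin1) == 0


def test_step_totals_equal_path_length():
    rng = np.random.default_rng(2)
    pos = np.cumsum(rng.normal(size=(12, 7, 3)), axis=0)
    tracks = make_tracks(pos)
    kin, _ = fs.step_kinematics(tracks, dt=15.0)
    totals = kin.groupby("track_id")["step_displacement"].sum()
    expect = np.linalg.norm(np.diff(pos, axis=0), axis=2).sum(axis=0)
    assert np.allclose(totals.to_numpy(), expect)


def test_velocity_ratio_tracks_simulated_speed_ratio():
    kw = dict(mode="random", n_cells=400, n_frames=15, arena_radius=2000.0, seed=3)
    fast = fs.simulate_tracks(fs.SwarmConfig(speed=4.0, **kw))
    slow = fs.simulate_tracks(fs.SwarmConfig(speed=2.0, **kw))
    vf = fs.step_kinematics(fast, dt=15.0)[0]["velocity"].mean()
    vs = fs.step_kinematics(slow, dt=15.0)[0]["velocity"].mean()
    assert vf / vs == pytest.approx(2.0, rel=0.02)


# ---------------------------------------------------------------------------
# movement similarity


def test_uniform_motion_scores_exactly_zero():
    res = fs.movement_similarity(uniform_motion_tracks())
    assert (res.per_cell["score"] == 0).all()
    assert res.global_score == 0.0


def test_antiparallel_pair_scores_exactly_180():
    # cells 0 and 1 move in exactly opposite directions; the other three are
    # static, so their zero-length vectors are excluded pairwise and the only
    # usable neighbour pair is (0, 1)
    p0 = np.array([[0, 0, 0], [5, 0, 0], [0, 5, 0], [5, 5, 3], [2, 2, 4]], float)
    p1 = p0.copy()
    p1[0] += [1, 0, 0]
    p1[1] -= [1, 0, 0]
    res = fs.movement_similarity(make_tracks(np.array([p0, p1])), min_cells=5)
    scores = res.per_cell.set_index("track_id")["score"]
    assert set(scores.index) == {0, 1}
    assert scores.loc[0] == 180.0 and scores.loc[1] == 180.0
    assert res.global_score == 180.0


def test_isotropic_motion_scores_90_degrees():
    scores = [
        fs.movement_similarity(isotropic_motion_tracks(seed=s)).global_score for s in (0, 1, 2)
    ]
    assert np.mean(scores) == pytest.approx(90.0, abs=1.0)


def test_similarity_invariant_to_rigid_motion_and_vector_scale():
    tracks = isotropic_motion_tracks(n_cells=60, n_frames=5, seed=4)
    base = fs.movement_similarity(tracks).global_score
    # global rotation about z + translation
    th = np.radians(35.0)
    R = np.array([[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    rot = tracks.copy()
    rot[["x", "y", "z"]] = tracks[["x", "y", "z"]].to_numpy() @ R.T + np.array([50, -20, 7])
    assert fs.movement_similarity(rot).global_score == pytest.approx(base, abs=1e-6)
    # uniform rescaling of all coordinates rescales all displacement vectors
    sc = tracks.copy()
    sc[["x", "y", "z"]] *= 3.7
    assert fs.movement_similarity(sc).global_score == pytest.approx(base, abs=1e-6)


def test_small_instance_matches_brute_force():
    # <= 8 cells: recompute per-cell scores from an independent triangulation
    tracks = isotropic_motion_tracks(n_cells=8, n_frames=4, seed=9, spread=60.0)
    res = fs.movement_similarity(tracks, min_cells=5)
    by_frame = {f: df.set_index("track_id") for f, df in tracks.groupby("frame")}
    for f in range(3):
        a, b = by_frame[f], by_frame[f + 1]
        p0 = a[["x", "y", "z"]].to_numpy()
        vec = b[["x", "y", "z"]].to_numpy() - p0
        tri = Delaunay(p0)
        neigh = {i: set() for i in range(8)}
        for simplex in tri.simplices:
            for i in simplex:
                for j in simplex:
                    if i != j:
                        neigh[int(i)].add(int(j))
        for i in range(8):
            angles = [
                pairwise_angles_deg(vec[i], vec[j]) for j in sorted(neigh[i])
            ]
            got = res.per_cell[(res.per_cell.frame == f) & (res.per_cell.track_id == i)][
                "score"
            ].iloc[0]
            assert got == pytest.approx(np.mean(angles), abs=1e-9)


def test_swarm_similarity_below_random_over_seeds():
    for seed in range(5):
        kw = dict(n_cells=150, n_frames=20, speed=2.0, noise_weight=0.3, seed=seed)
        swarm = fs.simulate_tracks(
            fs.SwarmConfig(mode="swarm", alignment_weight=1.0, attraction_weight=1.0, **kw)
        )
        rand = fs.simulate_tracks(fs.SwarmConfig(mode="random", **kw))
        assert (
            fs.movement_similarity(swarm).global_score
            < fs.movement_similarity(rand).global_score
        )


def test_degenerate_coplanar_positions_fall_back_to_2d():
    tracks = uniform_motion_tracks(n_cells=30, step=(2.0, 0.0, 0.0))
    tracks["z"] = 0.0
    res = fs.movement_similarity(tracks)
    assert res.global_score == 0.0


# ---------------------------------------------------------------------------
# landmarks


def test_static_landmarks_flat_zero_series():
    pos = np.tile(np.arange(5)[None, :, None] * 10.0, (8, 1, 3))
    out = fs.landmark_displacement(make_tracks(pos), stride=2)
    assert (out["mean_displacement"] == 0).all()
    assert (out["cumulative"] == 0).all()


def test_translating_landmarks_cumulate_linearly():
    base = np.arange(5)[None, :, None] * 10.0
    pos = np.concatenate([base + 2.0 * f for f in range(9)])[:, :, :1]
    pos = np.concatenate([pos, np.zeros((9, 5, 2))], axis=2)
    out = fs.landmark_displacement(make_tracks(pos), stride=2)
    assert np.allclose(out["mean_displacement"], 4.0)  # 2 px/frame, alternate frames
    assert np.allclose(out["cumulative"], 4.0 * np.arange(1, len(out) + 1))


def test_landmark_count_must_be_five():
    pos = np.zeros((4, 3, 3))
    with pytest.raises(InputError):
        fs.landmark_displacement(make_tracks(pos))


def test_landmarks_match_bruteforce_on_simulated_swarm():
    cfg = fs.SwarmConfig(mode="swarm", n_cells=5, n_frames=12, seed=6)
    tracks = fs.simulate_tracks(cfg)
    out = fs.landmark_displacement(tracks, stride=2)
    pos = tracks.sort_values(["track_id", "frame"])[["x", "y", "z"]].to_numpy().reshape(5, 12, 3)
    sampled = pos[:, ::2]
    expect = np.linalg.norm(np.diff(sampled, axis=1), axis=2).mean(axis=0)
    assert np.allclose(out["mean_displacement"], expect)
    assert np.allclose(out["cumulative"], np.cumsum(expect))


# ---------------------------------------------------------------------------
# time-coded overlay


def test_overlay_emits_tail_segments_with_ramp_endpoint():
    pos = np.cumsum(np.ones((30, 2, 3)), axis=0)
    tracks = make_tracks(pos)
    (ov,) = fs.time_coded_track_export(tracks, tail=12, frames=[29])
    assert (ov.track_ids == 0).sum() == 12
    assert (ov.track_ids == 1).sum() == 12
    from matplotlib import colormaps

    endpoint = colormaps["rainbow"](1.0)
    last = ov.colors[-1]
    assert np.allclose(last, endpoint)
    (ov1,) = fs.time_coded_track_export(tracks, tail=1, frames=[29])
    assert len(ov1.segments) == 2  # one segment per track
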