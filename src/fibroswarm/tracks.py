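"""Track building and kinematic statistics of migrating cells.

The central statistic is the movement-similarity score: for every cell
and frame interval, the movement vector is the displacement to the next
frame; neighbours are the cells sharing a Delaunay edge in the
triangulation of positions at the interval's start frame; the cell's
score is the mean 3D angle (degrees) between its movement vector and
each neighbour's.  Averaging all per-cell scores yields one global
score: 0 deg for perfectly uniform migration, 90 deg expected for
isotropic random migration (the cosine of the angle between independent
isotropic vectors is uniform on [-1, 1]).  Scores live in [0, 180];
display colour maps conventionally clamp at 90.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree

from .errors import InputError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# detection linking


def link_detections(detections: pd.DataFrame, max_disp: float) -> pd.DataFrame:
    """Link per-frame detections into tracks by greedy mutual nearest neighbours.

    ``detections`` needs columns ``frame, x, y, z`` (``z`` optional, taken
    as 0).  Detections in consecutive frames are linked when each is the
    other's nearest neighbour and their distance is <= ``max_disp``;
    unlinked detections start new tracks.  Deterministic.
    """
    if max_disp <= 0:
        raise InputError("max_disp must be > 0")
    det = detections.copy()
    if "z" not in det.columns:
        det["z"] = 0.0
    if len(det) == 0:
        return pd.DataFrame(columns=["track_id", "frame", "t_min", "x", "y", "z"])
    det = det.sort_values(["frame"], kind="stable").reset_index(drop=True)
    frames = np.sort(det["frame"].unique())
    det["track_id"] = -1
    next_id = 0
    prev_idx = det.index[det["frame"] == frames[0]].to_numpy()
    det.loc[prev_idx, "track_id"] = np.arange(len(prev_idx))
    next_id = len(prev_idx)
    cols = ["x", "y", "z"]
    for fa, fb in zip(frames[:-1], frames[1:]):
        cur_idx = det.index[det["frame"] == fb].to_numpy()
        if fb != fa + 1 or len(prev_idx) == 0:
            # gap in the frame sequence: everything starts fresh
            det.loc[cur_idx, "track_id"] = np.arange(next_id, next_id + len(cur_idx))
            next_id += len(cur_idx)
            prev_idx = cur_idx
            continue
        pa = det.loc[prev_idx, cols].to_numpy(float)
        pb = det.loc[cur_idx, cols].to_numpy(float)
        ta = cKDTree(pa)
        tb = cKDTree(pb)
        d_ab, nn_ab = tb.query(pa, k=1)  # for each prev, nearest current
        d_ba, nn_ba = ta.query(pb, k=1)  # for each current, nearest prev
        assigned = np.full(len(cur_idx), -1, int)
        for i, (j, d) in enumerate(zip(nn_ab, d_ab)):
            if d <= max_disp and nn_ba[j] == i:
                assigned[j] = i
        ids = np.empty(len(cur_idx), int)
        for j, i in enumerate(assigned):
            if i >= 0:
                ids[j] = det.at[prev_idx[i], "track_id"]
            else:
                ids[j] = next_id
                next_id += 1
        det.loc[cur_idx, "track_id"] = ids
        prev_idx = cur_idx
    if "t_min" not in det.columns:
        det["t_min"] = det["frame"] * 15.0
    out_cols = ["track_id", "frame", "t_min", "x", "y", "z"]
    extra = [c for c in det.columns if c not in out_cols + ["intensity"]]
    return (
        det[out_cols + [c for c in ["intensity"] if c in det.columns]]
        .sort_values(["track_id", "frame"], kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# step kinematics


def step_kinematics(tracks: pd.DataFrame, dt: float | None = None, smooth_window: int = 5):
    """Per-step 3D displacement and velocity, plus a smoothed velocity curve.

    For each track, the step displacement at frame ``f`` is the Euclidean
    3D distance from the position at ``f`` to the position at the next
    recorded frame; velocity divides by the elapsed time.  The smoothed
    curve is a centred moving average (default window 5) of the mean
    velocity at each time point, the analogue of a smoothing line through
    all per-cell velocity values.

    Returns ``(kinematics, curve)``: a per-step table with columns
    ``track_id, frame, t_min, step_displacement, velocity`` and a
    ``(t_min, mean_velocity, smoothed)`` curve.
    """
    tracks = tracks.sort_values(["track_id", "frame"], kind="stable")
    g = tracks.groupby("track_id", sort=False)
    diffs = g[["x", "y", "z"]].diff()
    dt_col = g["t_min"].diff() if dt is None else g["frame"].diff() * dt
    disp = np.sqrt((diffs**2).sum(axis=1))
    keep = diffs["x"].notna()
    if dt is not None:
        t = tracks["frame"] * dt
    else:
        t = tracks["t_min"]
    kin = pd.DataFrame(
        {
            "track_id": tracks["track_id"],
            "frame": tracks["frame"],
            "t_min": t,
            "step_displacement": disp,
            "velocity": disp / dt_col,
        }
    )[keep].reset_index(drop=True)
    if len(kin):
        curve = kin.groupby("t_min", as_index=False)["velocity"].mean()
        curve = curve.rename(columns={"velocity": "mean_velocity"})
        curve["smoothed"] = (
            curve["mean_velocity"].rolling(smooth_window, center=True, min_periods=1).mean()
        )
    else:
        curve = pd.DataFrame(columns=["t_min", "mean_velocity", "smoothed"])
    return kin, curve


# ---------------------------------------------------------------------------
# movement similarity


@dataclass
class SimilarityResult:
    """Per-cell and global movement-similarity scores (degrees)."""

    per_cell: pd.DataFrame  # track_id, frame, score
    global_score: float
    neighbor_graph: dict  # frame -> (E, 2) array of track_id pairs


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected edges of the Delaunay triangulation of ``points``.

    3D point sets that are degenerate (coplanar within tolerance, or
    rejected by Qhull) fall back to a 2D triangulation on the two
    highest-variance axes.
    """
    pts = points
    if pts.shape[1] == 3:
        var = pts.var(axis=0)
        if var.min() < 1e-12 * max(var.max(), 1.0):
            keep = np.argsort(var)[-2:]
            logger.info("degenerate 3D point set; triangulating axes %s", keep)
            pts = pts[:, np.sort(keep)]
    try:
        tri = Delaunay(pts)
    except QhullError:
        if pts.shape[1] == 3:
            var = pts.var(axis=0)
            keep = np.sort(np.argsort(var)[-2:])
            logger.info("Qhull degenerate in 3D; falling back to axes %s", keep)
            tri = Delaunay(pts[:, keep])
        else:
            raise
    edges = set()
    for simplex in tri.simplices:
        for i in range(len(simplex)):
            for j in range(i + 1, len(simplex)):
                a, b = int(simplex[i]), int(simplex[j])
                edges.add((min(a, b), max(a, b)))
    return np.array(sorted(edges), int).reshape(-1, 2)


def pairwise_angles_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle in degrees between corresponding 3D vectors, in [0, 180].

    Computed as ``atan2(|v1 x v2|, v1 . v2)``, which is numerically exact
    for parallel (0) and antiparallel (180) vectors, unlike the arccos
    form.
    """
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.einsum("...i,...i", v1, v2)
    return np.degrees(np.arctan2(cross, dot))


def movement_similarity(
    tracks: pd.DataFrame,
    frames: np.ndarray | list | None = None,
    min_cells: int = 5,
) -> SimilarityResult:
    """Movement-similarity score from Delaunay-neighbour angle statistics.

    For each interval (frame ``t`` to ``t+1``), cells present at both
    ends are triangulated at their ``t`` positions; each cell's score is
    the mean angle between its movement vector and those of its Delaunay
    neighbours (zero-length vectors are skipped pairwise).  The global
    score is the unweighted mean of all per-cell scores.  Intervals with
    fewer than ``min_cells`` co-occurring cells are skipped.
    """
    tracks = tracks.sort_values(["track_id", "frame"], kind="stable")
    all_frames = np.sort(tracks["frame"].unique())
    if frames is None:
        frames = all_frames[:-1]
    rows = []
    graph: dict = {}
    by_frame = {f: df.set_index("track_id") for f, df in tracks.groupby("frame")}
    for t in frames:
        if t not in by_frame or (t + 1) not in by_frame:
            continue
        a = by_frame[t]
        b = by_frame[t + 1]
        ids = a.index.intersection(b.index)
        if len(ids) < min_cells:
            logger.info("frame %s skipped: only %d co-occurring cells", t, len(ids))
            continue
        p0 = a.loc[ids, ["x", "y", "z"]].to_numpy(float)
        p1 = b.loc[ids, ["x", "y", "z"]].to_numpy(float)
        vec = p1 - p0
        edges = _delaunay_edges(p0)
        graph[int(t)] = np.array([[ids[i], ids[j]] for i, j in edges])
        moving = np.linalg.norm(vec, axis=1) > 0
        angle_sum = np.zeros(len(ids))
        angle_cnt = np.zeros(len(ids), int)
        use = moving[edges[:, 0]] & moving[edges[:, 1]]
        e = edges[use]
        if len(e):
            ang = pairwise_angles_deg(vec[e[:, 0]], vec[e[:, 1]])
            np.add.at(angle_sum, e[:, 0], ang)
            np.add.at(angle_sum, e[:, 1], ang)
            np.add.at(angle_cnt, e[:, 0], 1)
            np.add.at(angle_cnt, e[:, 1], 1)
        has = angle_cnt > 0
        for idx in np.flatnonzero(has):
            rows.append((ids[idx], int(t), angle_sum[idx] / angle_cnt[idx]))
    per_cell = pd.DataFrame(rows, columns=["track_id", "frame", "score"])
    if len(per_cell) == 0:
        raise InputError("no frame interval had enough co-occurring cells to triangulate")
    return SimilarityResult(
        per_cell=per_cell,
        global_score=float(per_cell["score"].mean()),
        neighbor_graph=graph,
    )


# ---------------------------------------------------------------------------
# landmark displacement


def landmark_displacement(landmarks: pd.DataFrame, stride: int = 2) -> pd.DataFrame:
    """Cumulative mean displacement of five landmarks sampled every ``stride`` frames.

    The track table must contain exactly five landmark tracks.  For each
    sampled interval the five landmarks' Euclidean displacements are
    averaged; the running sum of these means is reported versus time.
    Returns columns ``frame, t_min, mean_displacement, cumulative``.
    """
    ids = landmarks["track_id"].unique()
    if len(ids) != 5:
        raise InputError(f"landmark displacement is defined for exactly 5 landmarks, got {len(ids)}")
    if stride < 1:
        raise InputError("stride must be >= 1")
    lm = landmarks.sort_values(["track_id", "frame"], kind="stable")
    frames = np.sort(lm["frame"].unique())
    sampled = frames[::stride]
    by_frame = {f: df.set_index("track_id")[["x", "y", "z"]] for f, df in lm.groupby("frame")}
    rows = []
    cum = 0.0
    for fa, fb in zip(sampled[:-1], sampled[1:]):
        pa = by_frame[fa].loc[ids].to_numpy(float)
        pb = by_frame[fb].loc[ids].to_numpy(float)
        mean_disp = float(np.linalg.norm(pb - pa, axis=1).mean())
        cum += mean_disp
        t = float(lm.loc[lm["frame"] == fb, "t_min"].iloc[0])
        rows.append((int(fb), t, mean_disp, cum))
    return pd.DataFrame(rows, columns=["frame", "t_min", "mean_displacement", "cumulative"])


# ---------------------------------------------------------------------------
# time-coded track rendering


@dataclass
class TrackOverlay:
    """Per-frame coloured trailing segments of each track (a visual artefact)."""

    frame: int
    segments: np.ndarray  # (S, 2, 2) of ((x0, y0), (x1, y1))
    colors: np.ndarray  # (S, 4) RGBA
    track_ids: np.ndarray  # (S,)


def time_coded_track_export(
    tracks: pd.DataFrame,
    tail: int = 12,
    frames: list | None = None,
    cmap: str = "rainbow",
) -> list[TrackOverlay]:
    """Trailing track segments coloured by time along a purple-to-red ramp.

    For each requested frame, emits each track's last ``tail`` segments
    (fewer near a track's start), coloured by segment end frame along the
    colour ramp; the most recent segment always maps to the ramp's red
    endpoint of the movie's time range.
    """
    from matplotlib import colormaps

    if tail < 1:
        raise InputError("tail must be >= 1")
    ramp = colormaps[cmap]
    tracks = tracks.sort_values(["track_id", "frame"], kind="stable")
    fmin, fmax = tracks["frame"].min(), tracks["frame"].max()
    span = max(fmax - fmin, 1)
    if frames is None:
        frames = [int(fmax)]
    overlays = []
    for f in frames:
        segs, cols, tids = [], [], []
        window = tracks[(tracks["frame"] <= f) & (tracks["frame"] > f - tail - 1)]
        for tid, df in window.groupby("track_id"):
            xy = df[["x", "y"]].to_numpy(float)
            fr = df["frame"].to_numpy()
            for k in range(len(xy) - 1):
                segs.append([xy[k], xy[k + 1]])
                cols.append(ramp((fr[k + 1] - fmin) / span))
                tids.append(tid)
        overlays.append(
            TrackOverlay(
                frame=int(f),
                segments=np.array(segs).reshape(-1, 2, 2),
                colors=np.array(cols).reshape(-1, 4),
                track_ids=np.array(tids),
            )
        )
    return overlays


def save_track_overlay(overlays: list[TrackOverlay], path, image_shape=None) -> None:
    """Render overlays to an image file (PNG/SVG), one panel per frame."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import LineCollection

    fig, axes = plt.subplots(1, len(overlays), figsize=(4 * len(overlays), 4), squeeze=False)
    for ax, ov in zip(axes[0], overlays):
        ax.add_collection(LineCollection(ov.segments, colors=ov.colors, linewidths=1.5))
        ax.autoscale()
        if image_shape is not None:
            ax.set_xlim(0, image_shape[1])
            ax.set_ylim(image_shape[0], 0)
        else:
            ax.invert_yaxis()
        ax.set_aspect("equal")
        ax.set_title(f"frame {ov.frame}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
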