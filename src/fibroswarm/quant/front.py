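"""Leading-front contour extraction and trajectory prediction.

The advancing edge of a fluorescent cell swarm is extracted per time
point as an iso-contour of the smoothed (max-projected) intensity.  The
time-indexed fronts define an arrival-order surface: for each pixel, the
number of frames that pass before the swarm covers it.  Predicted
trajectories are integral curves of the gradient of that surface, which
are by construction locally perpendicular to every front contour; they
are seeded on the earliest front and terminate at the latest one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import RegularGridInterpolator
from skimage import measure

from ..errors import InputError
from ..types import ImageStack

logger = logging.getLogger(__name__)


@dataclass
class FrontModel:
    """Per-time leading-front contours and predicted swarm trajectories.

    ``contours`` maps each used time index to a list of (N, 2) polylines
    in (x, y); ``arrival_surface`` is the scalar surface whose gradient
    defines the trajectories; ``trajectories`` is a list of (M, 2)
    polylines seeded on the earliest front.
    """

    times: list[int]
    contours: dict
    arrival_surface: np.ndarray
    trajectories: list[np.ndarray]
    level: float


def _frame_2d(stack, t: int, channel: int) -> np.ndarray:
    if isinstance(stack, ImageStack):
        return stack.frame(t, channel)
    return np.asarray(stack[t], float)


def front_trajectories(
    frames: ImageStack | list[np.ndarray],
    times: list[int] | None = None,
    channel: int = 0,
    smoothing: float = 8.0,
    level_fraction: float = 0.5,
    n_seeds: int = 24,
    step: float = 0.5,
) -> FrontModel:
    """Extract leading-front contours and predict swarm trajectories.

    Per selected time the (max-projected) frame is Gaussian-smoothed at
    ``smoothing`` px and the front is the iso-contour at
    ``level_fraction`` of the global intensity maximum.  Trajectories
    follow the gradient of the smoothed arrival-order surface from
    ``n_seeds`` points on the earliest front until they reach the region
    the swarm never covered, leave the image or the gradient vanishes.
    A static front (identical masks at all times) yields zero-length
    trajectories.
    """
    n_t = frames.n_frames if isinstance(frames, ImageStack) else len(frames)
    if times is None:
        times = list(range(n_t))
    if len(times) < 2:
        raise InputError("front trajectories need at least two time points")
    smoothed, masks, used = [], [], []
    level = None
    for t in times:
        img = ndi.gaussian_filter(_frame_2d(frames, t, channel), smoothing)
        if level is None:
            level = level_fraction * img.max()
        if not (img > level).any() or (img > level).all():
            logger.warning("time %s dropped: front iso-level %.3g not detectable", t, level)
            continue
        smoothed.append(img)
        masks.append(img >= level)
        used.append(int(t))
    if len(used) < 2:
        raise InputError("fewer than two usable time points with a detectable front")

    contours = {}
    for t, img in zip(used, smoothed):
        polys = measure.find_contours(img, level)
        # find_contours returns (row, col); convert to (x, y)
        contours[t] = [p[:, ::-1] for p in sorted(polys, key=len, reverse=True)]

    H, W = masks[0].shape
    arrival = np.zeros((H, W), float)
    for m in masks:
        arrival += ~m  # frames elapsed before coverage
    static = all((m == masks[0]).all() for m in masks[1:])
    surface = ndi.gaussian_filter(arrival, smoothing)

    seeds = _sample_contour(contours[used[0]][0], n_seeds)
    trajectories = []
    if static:
        trajectories = [s[None, :] for s in seeds]
        return FrontModel(used, contours, surface, trajectories, float(level))

    gy, gx = np.gradient(surface)
    itp_gx = RegularGridInterpolator((np.arange(H), np.arange(W)), gx, bounds_error=False, fill_value=0.0)
    itp_gy = RegularGridInterpolator((np.arange(H), np.arange(W)), gy, bounds_error=False, fill_value=0.0)
    itp_a = RegularGridInterpolator((np.arange(H), np.arange(W)), arrival, bounds_error=False, fill_value=len(masks))
    stop_level = len(masks) - 0.5
    max_steps = int(4 * max(H, W) / step)
    for seed in seeds:
        p = seed.astype(float).copy()
        path = [p.copy()]
        for _ in range(max_steps):
            u = float(itp_gx([[p[1], p[0]]])[0])
            v = float(itp_gy([[p[1], p[0]]])[0])
            norm = float(np.hypot(u, v))
            if norm < 1e-6:
                break
            p = p + step * np.array([u, v]) / norm
            if not (0 <= p[0] < W and 0 <= p[1] < H):
                break
            path.append(p.copy())
            if float(itp_a([[p[1], p[0]]])[0]) >= stop_level:
                break
        trajectories.append(np.array(path))
    return FrontModel(used, contours, surface, trajectories, float(level))


def _sample_contour(poly: np.ndarray, n: int) -> np.ndarray:
    """n points spaced evenly by arc length along a polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0], np.cumsum(seg)])
    if s[-1] == 0:
        return np.repeat(poly[:1], n, axis=0)
    targets = np.linspace(0, s[-1], n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(targets, s, poly[:, 0])
    out[:, 1] = np.interp(targets, s, poly[:, 1])
    return out


def trajectory_contour_angles(model: FrontModel) -> np.ndarray:
    """Angles (degrees) between each trajectory and the front contour it crosses.

    For every trajectory with at least two points, takes its initial
    direction and the local tangent of the nearest point of the earliest
    front contour; returns the crossing angles (90 deg = perpendicular).
    """
    poly = model.contours[model.times[0]][0]
    tangents = np.gradient(poly, axis=0)
    angles = []
    for traj in model.trajectories:
        if len(traj) < 2:
            continue
        d = traj[min(4, len(traj) - 1)] - traj[0]
        i = int(np.argmin(np.linalg.norm(poly - traj[0], axis=1)))
        tan = tangents[i]
        cos = abs(np.dot(d, tan)) / (np.linalg.norm(d) * np.linalg.norm(tan) + 1e-12)
        angles.append(90.0 - np.degrees(np.arcsin(np.clip(cos, 0, 1))) + 0.0)
    return np.asarray(angles)
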