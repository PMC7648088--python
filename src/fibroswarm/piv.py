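"""Iterative cross-correlation particle image velocimetry.

A multi-pass window-offsetting scheme: each pass locates every
interrogation window of frame A (decreasing sizes, default
64 -> 32 -> 16 px) inside a search region of frame B by FFT-accelerated
normalized cross-correlation, refines the peak to sub-pixel precision
with a 3-point Gaussian fit per axis, and offsets the next pass's search
windows by the interpolated field of the previous pass.  After every pass
the field is validated with the normalized median test of Westerweel &
Scarano (noise floor 0.2, threshold 5 by default) and flagged vectors are
replaced by the local median before being used as predictors.

Displacements are reported as (u, v) in px per frame pair, u along +x
(columns), v along +y (rows): a feature at ``p`` in frame A is found at
``p + (u, v)`` in frame B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from skimage.feature import match_template

from .errors import InputError, InvalidConfigError


@dataclass
class PIVConfig:
    """Parameters of the iterative PIV cascade.

    ``window_sizes`` must be strictly decreasing, each >= 8 px.  The
    overlap fraction (not stated by the original plugin chain; 0.5 is the
    standard choice for this lineage of iterative PIV) sets the grid
    pitch to ``window * (1 - overlap_fraction)``.
    """

    window_sizes: tuple[int, ...] = (64, 32, 16)
    overlap_fraction: float = 0.5
    subpixel: str = "gaussian3pt"
    mediantest_noise: float = 0.2
    mediantest_threshold: float = 5.0
    replace_invalid: bool = True

    def __post_init__(self) -> None:
        ws = tuple(int(w) for w in self.window_sizes)
        if not ws or any(w < 8 for w in ws) or any(nxt >= prev for nxt, prev in zip(ws[1:], ws)):
            raise InvalidConfigError("window_sizes must be strictly decreasing, each >= 8")
        self.window_sizes = ws
        if not 0 <= self.overlap_fraction < 1:
            raise InvalidConfigError("overlap_fraction must be in [0, 1)")
        if self.subpixel != "gaussian3pt":
            raise InvalidConfigError("subpixel estimator must be 'gaussian3pt'")


@dataclass
class VectorField:
    """A gridded displacement field with per-vector validity flags.

    ``grid_x``/``grid_y`` hold the window-centre coordinates (1D, px);
    ``u``, ``v``, ``valid`` and ``peak_quality`` are (len(grid_y),
    len(grid_x)) arrays.  ``peak_quality`` is the first-to-second
    correlation peak ratio, a diagnostic only.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    peak_quality: np.ndarray = None  # type: ignore[assignment]
    residual: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.peak_quality is None:
            self.peak_quality = np.ones_like(self.u)

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def points(self) -> np.ndarray:
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return np.column_stack([gx.ravel(), gy.ravel()])


def _grid_1d(extent: int, window: int, step: int) -> np.ndarray:
    starts = np.arange(0, extent - window + 1, step)
    return starts


def _subpixel_offset(c_m: float, c_0: float, c_p: float) -> float:
    """3-point Gaussian peak fit; parabolic fallback for non-positive lobes."""
    if c_m > 0 and c_0 > 0 and c_p > 0:
        lm, l0, lp = np.log(c_m), np.log(c_0), np.log(c_p)
        denom = 2 * (lm + lp - 2 * l0)
        if denom != 0:
            return float((lm - lp) / denom)
    denom = 2 * (c_m + c_p - 2 * c_0)
    if denom != 0:
        return float((c_m - c_p) / denom)
    return 0.0


def _correlate_window(wa: np.ndarray, region: np.ndarray):
    """Normalized cross-correlation peak of window ``wa`` inside ``region``.

    Uses fast NCC (local mean/variance normalization, as in
    ``skimage.feature.match_template``) so that partially-overlapped or
    edge-clipped search regions carry no bias envelope.  Returns
    (iy, ix, dy_sub, dx_sub, quality): the integer peak position within
    the valid-mode NCC map, the sub-pixel refinements, and the
    first-to-second peak ratio diagnostic.
    """
    ncc = match_template(region, wa, pad_input=False)
    iy, ix = np.unravel_index(np.argmax(ncc), ncc.shape)
    peak = ncc[iy, ix]
    # quality: ratio of first to second peak, excluding the 3x3 around the first
    masked = ncc.copy()
    masked[max(iy - 1, 0) : iy + 2, max(ix - 1, 0) : ix + 2] = -np.inf
    second = masked.max()
    quality = float(peak / second) if second > 0 else np.inf
    dy_sub = dx_sub = 0.0
    if peak < 1.0 - 1e-9:  # a perfect match is exactly integer
        if 0 < iy < ncc.shape[0] - 1:
            dy_sub = _subpixel_offset(ncc[iy - 1, ix], peak, ncc[iy + 1, ix])
        if 0 < ix < ncc.shape[1] - 1:
            dx_sub = _subpixel_offset(ncc[iy, ix - 1], peak, ncc[iy, ix + 1])
    return int(iy), int(ix), dy_sub, dx_sub, quality


def run_piv(frame_a: np.ndarray, frame_b: np.ndarray, config: PIVConfig | None = None) -> VectorField:
    """Estimate the displacement field from frame A to frame B.

    Runs the full multi-pass cascade of ``config.window_sizes`` and
    returns the field on the grid of the smallest window size.  The
    normalized median test is applied after each pass; on the final pass
    flagged vectors stay flagged (and are replaced by the neighbourhood
    median when ``config.replace_invalid``).
    """
    config = config or PIVConfig()
    a = np.asarray(frame_a, float)
    b = np.asarray(frame_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise InputError(f"frames must be two equal-shape 2D images, got {a.shape} vs {b.shape}")
    H, W = a.shape
    if max(config.window_sizes) > min(H, W):
        raise InvalidConfigError("largest window exceeds the frame size")

    field: VectorField | None = None
    for p, w in enumerate(config.window_sizes):
        step = max(1, int(round(w * (1 - config.overlap_fraction))))
        ys = _grid_1d(H, w, step)
        xs = _grid_1d(W, w, step)
        cy = ys + (w - 1) / 2.0
        cx = xs + (w - 1) / 2.0
        # predictor from the previous pass, interpolated onto the new grid
        if field is None:
            pred_u = np.zeros((len(ys), len(xs)))
            pred_v = np.zeros_like(pred_u)
        else:
            pred_u = _interp_field(field.grid_y, field.grid_x, field.u, cy, cx)
            pred_v = _interp_field(field.grid_y, field.grid_x, field.v, cy, cx)
        u = np.zeros((len(ys), len(xs)))
        v = np.zeros_like(u)
        q = np.zeros_like(u)
        measured = np.ones((len(ys), len(xs)), bool)
        search = w // 2
        for i, y0 in enumerate(ys):
            for j, x0 in enumerate(xs):
                du = int(round(pred_u[i, j]))
                dv = int(round(pred_v[i, j]))
                wa = a[y0 : y0 + w, x0 : x0 + w]
                # search region in b around the offset window, clipped to frame
                ry0 = max(y0 + dv - search, 0)
                rx0 = max(x0 + du - search, 0)
                ry1 = min(y0 + dv + w + search, H)
                rx1 = min(x0 + du + w + search, W)
                region = b[ry0:ry1, rx0:rx1]
                # a window whose predicted displacement cannot fit inside the
                # frame (pattern advected out of view) is unmeasurable: keep
                # the predictor but never report it as a valid measurement
                reachable = (
                    min(region.shape) >= w
                    and ry0 - y0 <= dv <= ry1 - w - y0
                    and rx0 - x0 <= du <= rx1 - w - x0
                )
                if not reachable or wa.std() < 1e-12 or region.std() < 1e-12:
                    u[i, j], v[i, j], q[i, j] = du, dv, 0.0
                    measured[i, j] = False
                    continue
                iy, ix, dys, dxs, qq = _correlate_window(wa, region)
                u[i, j] = rx0 + ix - x0 + dxs
                v[i, j] = ry0 + iy - y0 + dys
                q[i, j] = qq
        field = VectorField(grid_x=cx, grid_y=cy, u=u, v=v, valid=measured, peak_quality=q)
        last = p == len(config.window_sizes) - 1
        field = normalized_median_test(
            field,
            noise=config.mediantest_noise,
            threshold=config.mediantest_threshold,
            replace=config.replace_invalid or not last,
            keep_flags=last,
        )
    return field


def _interp_field(gy, gx, values, new_y, new_x):
    if len(gy) < 2 or len(gx) < 2:
        return np.full((len(new_y), len(new_x)), float(values.mean()))
    itp = RegularGridInterpolator((gy, gx), values, bounds_error=False, fill_value=None)
    yy, xx = np.meshgrid(np.clip(new_y, gy[0], gy[-1]), np.clip(new_x, gx[0], gx[-1]), indexing="ij")
    return itp(np.stack([yy, xx], axis=-1))


def _neighbour_stack(arr: np.ndarray) -> np.ndarray:
    """(8, H, W) stack of shifted copies; NaN where a neighbour falls outside."""
    H, W = arr.shape
    out = np.full((8, H, W), np.nan)
    k = 0
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ys0, ys1 = max(dy, 0), H + min(dy, 0)
            xs0, xs1 = max(dx, 0), W + min(dx, 0)
            out[k, ys0:ys1, xs0:xs1] = arr[ys0 - dy : ys1 - dy, xs0 - dx : xs1 - dx]
            k += 1
    return out


def normalized_median_test(
    field: VectorField,
    noise: float = 0.2,
    threshold: float = 5.0,
    replace: bool = True,
    keep_flags: bool = True,
) -> VectorField:
    """Flag spurious vectors with the normalized median test.

    For each vector component, with ``m`` the median of the 8 neighbouring
    values and ``r_m`` the median of ``|neighbour - m|``, the normalized
    residual is ``|value - m| / (r_m + noise)``.  A vector whose larger
    component residual exceeds ``threshold`` is flagged invalid and,
    when ``replace``, substituted by the component-wise neighbourhood
    median.  Border vectors use their available neighbours.
    """
    H, W = field.shape
    if H * W < 4 or (H == 1 or W == 1) and max(H, W) < 4:
        raise InvalidConfigError("grid too small for the normalized median test")
    n_neigh = np.sum(~np.isnan(_neighbour_stack(np.zeros((H, W)))), axis=0)
    if (n_neigh < 3).any():
        raise InvalidConfigError("every vector needs >= 3 neighbours for the median test")
    res = np.zeros((H, W))
    medians = {}
    for name, comp in (("u", field.u), ("v", field.v)):
        neigh = _neighbour_stack(comp)
        m = np.nanmedian(neigh, axis=0)
        r_m = np.nanmedian(np.abs(neigh - m[None]), axis=0)
        res = np.maximum(res, np.abs(comp - m) / (r_m + noise))
        medians[name] = m
    bad = res > threshold
    u = field.u.copy()
    v = field.v.copy()
    if replace:
        u[bad] = medians["u"][bad]
        v[bad] = medians["v"][bad]
    valid = field.valid & ~bad if keep_flags else field.valid.copy()
    return VectorField(
        grid_x=field.grid_x,
        grid_y=field.grid_y,
        u=u,
        v=v,
        valid=valid,
        peak_quality=field.peak_quality,
        residual=res,
    )


@dataclass
class FieldSummary:
    """Per-vector magnitude/direction maps and their valid-vector means."""

    magnitude: np.ndarray  # px/min
    direction_deg: np.ndarray  # [0, 360)
    mean_speed: float
    mean_direction_deg: float | None  # circular mean; None when undefined
    n_valid: int


def field_summary(field: VectorField, dt: float = 30.0) -> FieldSummary:
    """Magnitude (px/min), direction (degrees) and valid-vector means.

    Direction follows the image convention: degrees counter-clockwise
    from +x towards +y (downwards), in [0, 360).  The mean direction is
    the circular mean of valid vectors; when the resultant length is
    negligible (e.g. two opposing populations) it is undefined and
    reported as None.
    """
    if dt <= 0:
        raise InputError("dt must be > 0")
    mag = np.hypot(field.u, field.v) / dt
    direc = np.degrees(np.arctan2(field.v, field.u)) % 360.0
    ok = field.valid
    if not ok.any():
        return FieldSummary(mag, direc, float("nan"), None, 0)
    mean_speed = float(mag[ok].mean())
    ux = np.cos(np.radians(direc[ok]))
    uy = np.sin(np.radians(direc[ok]))
    rx, ry = ux.mean(), uy.mean()
    if np.hypot(rx, ry) < 1e-3:
        mean_dir = None
    else:
        mean_dir = float(np.degrees(np.arctan2(ry, rx)) % 360.0)
    return FieldSummary(mag, direc, mean_speed, mean_dir, int(ok.sum()))
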