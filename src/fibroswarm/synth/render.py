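"""Rendering of synthetic fluorescence movies and PIV test image pairs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from ..errors import InputError, InvalidConfigError, InvalidFlowError
from ..types import ImageStack


@dataclass
class RenderConfig:
    """How a track table is turned into a fluorescence movie.

    Each cell is drawn as an isotropic Gaussian spot of standard deviation
    ``spot_sigma`` in the channel its lineage maps to; Poisson shot noise
    (scaled by ``photon_scale``) and Gaussian read noise are applied after
    the signal, the standard additive model of fluorescence detection.
    """

    image_shape: tuple[int, int] = (256, 256)
    spot_sigma: float = 2.0
    amplitude: float = 100.0
    background: float = 0.0
    photon_scale: float = 0.0
    read_noise_sd: float = 0.0
    channel_map: dict = field(default_factory=lambda: {0: 0})
    #: (x, y) added to track coordinates before drawing; "center" maps the
    #: track origin (e.g. the arena centre) to the image centre
    origin: tuple[float, float] | str = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_sigma <= 0:
            raise InvalidConfigError("spot_sigma must be > 0")
        if min(self.image_shape) < 1:
            raise InvalidConfigError("image_shape must be positive")


@dataclass
class FlowSpec:
    """A known 2D flow used to displace a texture for PIV validation.

    kinds
    -----
    ``translation``: uniform shift by ``(dx, dy)`` px.
    ``rotation``: rigid rotation by ``angle_deg`` about ``centre`` (x, y).
    ``radial``: uniform expansion about ``centre`` with fractional ``rate``
    (displacement = rate * distance from centre).
    """

    kind: str
    dx: float = 0.0
    dy: float = 0.0
    centre: tuple[float, float] = (0.0, 0.0)
    angle_deg: float = 0.0
    rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("translation", "rotation", "radial"):
            raise InvalidFlowError(f"unknown flow kind {self.kind!r}")

    def displacement(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth displacement (u, v) of the texture at points (x, y)."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if self.kind == "translation":
            return np.full_like(x, self.dx), np.full_like(y, self.dy)
        cx, cy = self.centre
        if self.kind == "rotation":
            th = np.radians(self.angle_deg)
            dxc, dyc = x - cx, y - cy
            u = (np.cos(th) * dxc - np.sin(th) * dyc) - dxc
            v = (np.sin(th) * dxc + np.cos(th) * dyc) - dyc
            return u, v
        return self.rate * (x - cx), self.rate * (y - cy)

    def _inverse_map(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Source coordinates in frame A for each pixel of frame B."""
        if self.kind == "translation":
            return x - self.dx, y - self.dy
        cx, cy = self.centre
        if self.kind == "rotation":
            th = np.radians(self.angle_deg)
            dxc, dyc = x - cx, y - cy
            return (
                cx + np.cos(th) * dxc + np.sin(th) * dyc,
                cy - np.sin(th) * dxc + np.cos(th) * dyc,
            )
        return cx + (x - cx) / (1.0 + self.rate), cy + (y - cy) / (1.0 + self.rate)


def speckle_texture(shape: tuple[int, int], seed: int = 0, grain: float = 1.5) -> np.ndarray:
    """Random speckle pattern with correlation length ~``grain`` px, on [0, 1]."""
    rng = np.random.default_rng(seed)
    img = ndi.gaussian_filter(rng.random(shape), grain)
    lo, hi = img.min(), img.max()
    return (img - lo) / (hi - lo)


def advected_pair(
    flow: FlowSpec,
    render: RenderConfig | None = None,
    *,
    shape: tuple[int, int] | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A speckle texture and the same texture displaced by a known flow.

    Frame B is frame A advected by ``flow``: the texture element at
    ``p`` in A appears at ``p + flow.displacement(p)`` in B.  Sub-pixel
    displacements use cubic-spline interpolation.
    """
    render = render or RenderConfig()
    shape = shape or render.image_shape
    seed = render.seed if seed is None else seed
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    u, v = flow.displacement(xx, yy)
    max_disp = float(np.hypot(u, v).max())
    if max_disp >= min(H, W):
        raise InvalidFlowError("flow displacement exceeds the image extent")
    # Synthesize on a padded canvas and crop to the interior so that frame B
    # is an exact advection of frame A everywhere in the returned pair (no
    # boundary content is invented by the interpolator).
    m = int(np.ceil(max_disp)) + 4
    big = speckle_texture((H + 2 * m, W + 2 * m), seed=seed)
    if flow.kind == "translation":
        shifted = flow
    else:
        shifted = FlowSpec(
            kind=flow.kind,
            centre=(flow.centre[0] + m, flow.centre[1] + m),
            angle_deg=flow.angle_deg,
            rate=flow.rate,
        )
    yb, xb = np.mgrid[0 : H + 2 * m, 0 : W + 2 * m].astype(float)
    sx, sy = shifted._inverse_map(xb, yb)
    b_big = ndi.map_coordinates(big, [sy, sx], order=3, mode="reflect")
    a = big[m : m + H, m : m + W].copy()
    b = b_big[m : m + H, m : m + W].copy()
    return a, b


def render_movie(tracks: pd.DataFrame, render: RenderConfig) -> ImageStack:
    """Render a track table as a multi-channel fluorescence movie.

    One movie frame per track frame; each cell is an isotropic Gaussian
    spot (sd ``spot_sigma``) at its (x, y) position in the channel of its
    lineage.  Noise: ``Poisson(signal * photon_scale) / photon_scale``
    shot noise when ``photon_scale > 0``, then additive Gaussian read
    noise.  Deterministic for a fixed seed.
    """
    if len(tracks) == 0:
        raise InputError("cannot render an empty track table")
    H, W = render.image_shape
    if render.origin == "center":
        ox, oy = W / 2.0, H / 2.0
    else:
        ox, oy = render.origin
    lineages = tracks["lineage"] if "lineage" in tracks.columns else pd.Series(0, index=tracks.index)
    channels = sorted(set(render.channel_map.values()))
    n_chan = max(channels) + 1
    frames = np.sort(tracks["frame"].unique())
    rng = np.random.default_rng(render.seed)
    out = np.zeros((len(frames), n_chan, H, W))
    # render each spot on a small local patch; cheaper than full-frame gaussians
    r = int(np.ceil(4 * render.spot_sigma))
    dyx = np.mgrid[-r : r + 1, -r : r + 1]
    for fi, f in enumerate(frames):
        sel = tracks["frame"] == f
        for xc, yc, lin in zip(tracks.loc[sel, "x"] + ox, tracks.loc[sel, "y"] + oy, lineages[sel]):
            c = render.channel_map.get(int(lin))
            if c is None:
                continue
            xi, yi = int(round(xc)), int(round(yc))
            gy = dyx[0] + yi - yc
            gx = dyx[1] + xi - xc
            spot = render.amplitude * np.exp(-(gx**2 + gy**2) / (2 * render.spot_sigma**2))
            ys, xs = dyx[0] + yi, dyx[1] + xi
            ok = (ys >= 0) & (ys < H) & (xs >= 0) & (xs < W)
            np.add.at(out[fi, c], (ys[ok], xs[ok]), spot[ok])
    out += render.background
    if render.photon_scale > 0:
        out = rng.poisson(out * render.photon_scale) / render.photon_scale
    if render.read_noise_sd > 0:
        out = out + rng.normal(0.0, render.read_noise_sd, out.shape)
    out = np.clip(out, 0.0, None)
    dt = 15.0
    if "t_min" in tracks.columns and len(frames) > 1:
        t = tracks.drop_duplicates("frame").sort_values("frame")["t_min"].to_numpy()
        if len(t) > 1:
            dt = float(t[1] - t[0])
    return ImageStack(out, axes="TCYX", frame_interval=dt)
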