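"""Core in-memory containers shared by all stages.

Coordinate convention used throughout the package: pixel-centre coordinates,
origin at the top-left pixel, ``x`` increasing to the right (columns), ``y``
increasing downwards (rows), 0-based.  Arrays are indexed ``[..., y, x]``.
Times are minutes, with ``t = frame * dt`` and ``t = 0`` at the first frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

#: canonical column order of a track table (lineage optional)
TRACK_COLUMNS = ["track_id", "frame", "t_min", "x", "y", "z"]


def validate_tracks(tracks: pd.DataFrame) -> pd.DataFrame:
    """Validate a track table against its invariants.

    Required columns: ``track_id, frame, t_min, x, y, z`` (``lineage``
    optional).  ``(track_id, frame)`` pairs must be unique, frames strictly
    increasing within a track, and coordinates finite.  Returns the table
    sorted by ``(track_id, frame)``.
    """
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise ValidationError(f"track table missing columns: {missing}")
    dup = tracks.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(f"duplicate (track_id, frame) pair at row {row}")
    coords = tracks[["x", "y", "z"]].to_numpy(float)
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinates in track table")
    out = tracks.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    return out


@dataclass
class ImageStack:
    """A multi-channel time-lapse raster.

    ``pixels`` has axes ``(T, C, Y, X)`` or ``(T, C, Z, Y, X)`` as declared
    by ``axes``.  Intensities are finite and non-negative.

    Parameters
    ----------
    pixels:
        The raster data.
    axes:
        ``"TCYX"`` or ``"TCZYX"``.
    pixel_size:
        Physical size of a pixel in micrometres (optional).
    frame_interval:
        Minutes between consecutive frames.
    """

    pixels: np.ndarray
    axes: str = "TCYX"
    pixel_size: float | None = None
    frame_interval: float = 15.0

    def __post_init__(self) -> None:
        if self.axes not in ("TCYX", "TCZYX"):
            raise InputError(f"unsupported axes string {self.axes!r}")
        if self.pixels.ndim != len(self.axes):
            raise InputError(
                f"pixels has {self.pixels.ndim} axes but axes={self.axes!r}"
            )
        if min(self.pixels.shape) < 1:
            raise InputError("all axis lengths must be >= 1")
        if not np.isfinite(self.pixels).all() or (np.asarray(self.pixels) < 0).any():
            raise InputError("intensities must be finite and non-negative")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def has_z(self) -> bool:
        return "Z" in self.axes

    def frame(self, t: int, c: int = 0, projection: str | None = None) -> np.ndarray:
        """Return a single 2D plane (after max-projection over z if present)."""
        img = self.pixels[t, c]
        if self.has_z:
            if projection not in (None, "max"):
                raise InputError(f"unknown projection {projection!r}")
            img = img.max(axis=0)
        return img


@dataclass
class ROI:
    """A region of interest as a polygon and/or binary mask.

    A polygon is an ``(N, 2)`` array of ``(x, y)`` vertices; the mask is
    rasterised lazily for a given image shape.  Either may be supplied.
    """

    polygon: np.ndarray | None = None
    mask: np.ndarray | None = None
    frame: int | None = None
    channel: int | None = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.polygon is None and self.mask is None:
            raise InputError("ROI needs a polygon or a mask")
        if self.polygon is not None:
            self.polygon = np.asarray(self.polygon, float)
            if self.polygon.ndim != 2 or self.polygon.shape[1] != 2 or len(self.polygon) < 3:
                raise InputError("ROI polygon must be (N>=3, 2) of (x, y)")
        if self.mask is not None and not self.mask.any():
            raise InputError("ROI mask is empty")

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "ROI":
        return cls(mask=np.ones(shape, bool))

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterise the ROI onto an image of the given (H, W) shape."""
        if self.mask is not None:
            if self.mask.shape != tuple(shape):
                raise InputError(
                    f"ROI mask shape {self.mask.shape} != image shape {tuple(shape)}"
                )
            return self.mask
        key = tuple(shape)
        if key not in self._cache:
            from skimage.draw import polygon2mask

            # polygon2mask expects (row, col) = (y, x)
            m = polygon2mask(shape, self.polygon[:, ::-1])
            if not m.any():
                raise InputError("ROI polygon rasterises to an empty mask")
            self._cache[key] = m
        return self._cache[key]
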