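"""Readers and writers for image stacks and track tables.

Track tables travel as CSV with the exact header
``track_id,frame,t_min,x,y,z`` (optional trailing ``lineage``); movies as
multi-page TIFF with an axes tag; fixtures as single-page TIFF or PNG.
Floating-point values are written at 6 significant digits; write-then-
read round trips are identity at that precision (and bit-exact for TIFF
rasters).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ValidationError
from .types import TRACK_COLUMNS, ImageStack, validate_tracks

FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# track tables


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    """Write a track table as canonical CSV (6 significant digits)."""
    cols = TRACK_COLUMNS + (["lineage"] if "lineage" in tracks.columns else [])
    validate_tracks(tracks)
    tracks[cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_tracks(path: str | Path) -> pd.DataFrame:
    """Read and validate a track-table CSV.

    The header must start with ``track_id,frame,t_min,x,y,z`` (an
    optional ``lineage`` column may follow); duplicate ``(track_id,
    frame)`` rows raise a validation error naming the offending row.
    """
    df = pd.read_csv(path)
    header = list(df.columns)
    if header[: len(TRACK_COLUMNS)] != TRACK_COLUMNS or header not in (
        TRACK_COLUMNS,
        TRACK_COLUMNS + ["lineage"],
    ):
        raise ValidationError(
            f"unexpected track CSV header {header}; need {TRACK_COLUMNS} (+ optional lineage)"
        )
    return validate_tracks(df)


# ---------------------------------------------------------------------------
# ROIs


def read_roi(path: str | Path) -> "ROI":
    """Read an ROI from a polygon CSV (columns x, y) or a binary-mask TIFF."""
    from .types import ROI

    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if not {"x", "y"} <= set(df.columns):
            raise ValidationError(f"ROI polygon CSV needs x,y columns, got {list(df.columns)}")
        return ROI(polygon=df[["x", "y"]].to_numpy(float))
    mask = tifffile.imread(path)
    return ROI(mask=np.asarray(mask) > 0)


def write_roi_polygon(roi: "ROI", path: str | Path) -> None:
    if roi.polygon is None:
        raise ValidationError("ROI has no polygon representation")
    pd.DataFrame(roi.polygon, columns=["x", "y"]).to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# image stacks


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an ImageStack as multi-page TIFF with axes and timing metadata."""
    meta = {
        "axes": stack.axes,
        "shape": list(stack.pixels.shape),
        "pixel_size_um": stack.pixel_size,
        "frame_interval_min": stack.frame_interval,
    }
    tifffile.imwrite(
        path,
        stack.pixels,
        photometric="minisblack",
        metadata=None,
        description=json.dumps(meta),
    )


def read_image_stack(
    path: str | Path,
    axes_hint: str | None = None,
    frame_interval: float = 15.0,
    pixel_size: float | None = None,
) -> ImageStack:
    """Read a TIFF/PNG into a normalised (T, C, [Z,] Y, X) ImageStack.

    Axis order is taken from the file's metadata when present, else from
    ``axes_hint``; single-plane greyscale images become a 1x1xHxW stack
    and RGB PNGs a T=1, C=3 stack with channel order preserved.
    """
    path = Path(path)
    if path.suffix.lower() in (".png", ".jpg", ".jpeg"):
        arr = np.asarray(iio.imread(path), float)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:  # (H, W, C) -> (1, C, H, W)
            arr = arr.transpose(2, 0, 1)[None]
        else:
            raise ValidationError(f"cannot interpret image of shape {arr.shape}")
        return ImageStack(arr, axes="TCYX", frame_interval=frame_interval, pixel_size=pixel_size)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        axes = None
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                axes = meta.get("axes")
                frame_interval = meta.get("frame_interval_min") or frame_interval
                pixel_size = meta.get("pixel_size_um") or pixel_size
                shape = meta.get("shape")
                # tifffile squeezes singleton axes on read; restore them
                if shape and tuple(shape) != arr.shape and int(np.prod(shape)) == arr.size:
                    arr = arr.reshape(shape)
            except (json.JSONDecodeError, AttributeError):
                pass
        if axes is None and tif.series:
            axes = tif.series[0].axes.replace("S", "C").replace("Q", "")
    axes = axes_hint or axes
    if axes is None:
        axes = _guess_axes(arr.shape)
    axes = axes.upper()
    if sorted(axes) != sorted(set(axes)) or len(axes) != arr.ndim:
        raise ValidationError(f"ambiguous axes {axes!r} for array of shape {arr.shape}")
    arr, axes = _normalise_axes(np.asarray(arr, float), axes)
    return ImageStack(arr, axes=axes, frame_interval=frame_interval, pixel_size=pixel_size)


def _guess_axes(shape: tuple[int, ...]) -> str:
    guesses = {2: "YX", 3: "TYX", 4: "TCYX", 5: "TCZYX"}
    if len(shape) not in guesses:
        raise ValidationError(f"cannot guess axes for array of shape {shape}")
    return guesses[len(shape)]


def _normalise_axes(arr: np.ndarray, axes: str) -> tuple[np.ndarray, str]:
    """Reorder/expand axes into canonical TCYX or TCZYX."""
    target = "TCZYX" if "Z" in axes else "TCYX"
    unknown = set(axes) - set(target)
    if unknown:
        raise ValidationError(f"unsupported axes {sorted(unknown)} in axis string {axes!r}")
    if "Y" not in axes or "X" not in axes:
        raise ValidationError(f"axis string {axes!r} lacks Y/X")
    for ax in target:
        if ax not in axes:
            arr = arr[None]
            axes = ax + axes
    order = [axes.index(ax) for ax in target]
    return arr.transpose(order), target
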