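"""Binary fractal and trichrome-like histology fixtures with known ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidConfigError, PlacementError

#: approximate stain colours on [0, 1] RGB
_BACKGROUND_RGB = (0.93, 0.91, 0.90)  # unstained tissue, off-white
_NUCLEUS_RGB = (0.24, 0.13, 0.21)  # iron haematoxylin, near-black; no cyan component
_COLLAGEN_RGB = (0.22, 0.34, 0.78)  # aniline blue


def fractal_fixture(kind: str, size: int = 729, depth: int = 5) -> np.ndarray:
    """Binary test pattern of known fractal dimension.

    kinds
    -----
    ``line``: a single-pixel horizontal line (dimension 1).
    ``filled_square``: all-foreground image (dimension 2).
    ``sierpinski``: Sierpinski carpet by recursive centre removal to
    ``depth`` levels (similarity dimension log 8 / log 3 = 1.8928).
    ``size`` must be a multiple of ``3**depth`` for the carpet.
    """
    if size < 1:
        raise InvalidConfigError("size must be positive")
    if kind == "line":
        img = np.zeros((size, size), bool)
        img[size // 2] = True
        return img
    if kind == "filled_square":
        return np.ones((size, size), bool)
    if kind == "sierpinski":
        if depth < 0 or size < 3**depth or size % 3**depth:
            raise InvalidConfigError(
                f"sierpinski needs size a multiple of 3**depth (= {3**depth}), got {size}"
            )
        img = np.ones((1, 1), bool)
        for _ in range(depth):
            hole = np.zeros_like(img)
            img = np.block([[img, img, img], [img, hole, img], [img, img, img]])
        scale = size // 3**depth
        if scale > 1:
            img = np.kron(img, np.ones((scale, scale), bool))
        return img
    raise InvalidConfigError(f"unknown fixture kind {kind!r}")


@dataclass
class HistologyGroundTruth:
    """Planted content of a histology fixture."""

    nucleus_centres: np.ndarray  # (N, 2) of (x, y)
    nucleus_mask: np.ndarray
    collagen_mask: np.ndarray

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_centres)

    @property
    def collagen_area(self) -> int:
        return int(self.collagen_mask.sum())


def _disk_mask(shape, xc, yc, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - xc) ** 2 + (yy - yc) ** 2 <= radius**2


def histology_fixture(
    n_nuclei: int,
    nucleus_area: float = 80.0,
    collagen_area: float = 0.0,
    shape: tuple[int, int] = (512, 512),
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, HistologyGroundTruth]:
    """RGB trichrome-like fixture: dark nuclei disks and a blue collagen patch.

    Nuclei are non-overlapping disks of ~``nucleus_area`` px² on a light
    background; collagen is a blue rectangle of exactly ``collagen_area``
    px² (when feasible as an integer-sided rectangle, else trimmed to the
    requested area).  Returns the image on [0, 1] together with the
    planted ground truth.
    """
    if n_nuclei < 0 or nucleus_area <= 0 and n_nuclei > 0:
        raise InvalidConfigError("need n_nuclei >= 0 and positive nucleus_area")
    H, W = shape
    rng = np.random.default_rng(seed)
    img = np.empty((H, W, 3))
    img[:] = _BACKGROUND_RGB

    collagen_mask = np.zeros((H, W), bool)
    if collagen_area > 0:
        side = int(np.floor(np.sqrt(collagen_area)))
        h = side
        w = int(np.ceil(collagen_area / side))
        if h > H - 20 or w > W - 20:
            raise PlacementError("collagen region does not fit the canvas")
        y0 = 10
        x0 = W - w - 10
        collagen_mask[y0 : y0 + h, x0 : x0 + w] = True
        # trim trailing pixels so the planted area is exact
        excess = int(collagen_mask.sum() - round(collagen_area))
        if excess > 0:
            ys, xs = np.nonzero(collagen_mask)
            collagen_mask[ys[-excess:], xs[-excess:]] = False
        img[collagen_mask] = _COLLAGEN_RGB

    radius = np.sqrt(nucleus_area / np.pi)
    centres = []
    nucleus_mask = np.zeros((H, W), bool)
    margin = radius + 3
    for _ in range(n_nuclei):
        for _attempt in range(2000):
            xc = rng.uniform(margin, W - margin)
            yc = rng.uniform(margin, H - margin)
            if any((xc - x) ** 2 + (yc - y) ** 2 < (4 * radius) ** 2 for x, y in centres):
                continue
            disk = _disk_mask(shape, xc, yc, radius)
            if (disk & collagen_mask).any():
                continue
            centres.append((xc, yc))
            nucleus_mask |= disk
            img[disk] = _NUCLEUS_RGB
            break
        else:
            raise PlacementError(f"could not place nucleus {len(centres) + 1}/{n_nuclei}")
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = HistologyGroundTruth(
        nucleus_centres=np.array(centres).reshape(-1, 2),
        nucleus_mask=nucleus_mask,
        collagen_mask=collagen_mask,
    )
    return img, truth
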