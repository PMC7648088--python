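"""Grid-sampled local orientation from the image structure tensor."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import structure_tensor

from ..errors import InputError


@dataclass
class OrientationField:
    """Local fibre/texture orientation sampled on a coarse grid.

    ``angle_deg`` is the orientation of image structures (not of the
    gradient) in degrees within [0, 180), measured from the +x axis
    towards +y (image rows); ``coherence`` in [0, 1] is the normalised
    eigenvalue anisotropy of the structure tensor, and ``reliable`` flags
    grid cells whose coherence exceeds the reliability floor.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    angle_deg: np.ndarray
    coherence: np.ndarray
    reliable: np.ndarray
    grid_size: int

    def vectors(self, length_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Quiver components (x, y, u, v) with unit ("100%") vector length
        scaled by ``length_scale`` times the grid size."""
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        L = length_scale * self.grid_size
        th = np.radians(self.angle_deg)
        return gx, gy, L * np.cos(th), L * np.sin(th)


def orientation_field(
    image: np.ndarray,
    grid_size: int = 150,
    tensor_sigma: float = 4.0,
    reliability_floor: float = 0.1,
) -> OrientationField:
    """Structure-tensor orientation field on a grid of pitch ``grid_size``.

    Gaussian-derivative gradients build the structure tensor (smoothed at
    ``tensor_sigma``); the tensor is averaged over each grid cell, then
    the structure orientation is ``0.5 * atan2(2 J_xy, J_xx - J_yy)``
    rotated to the structure (gradient-orthogonal) direction and mapped
    to [0, 180).  Coherence is ``(l1 - l2) / (l1 + l2)``; a flat cell has
    coherence 0 and is flagged unreliable.
    """
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise InputError("orientation field is defined on a single greyscale image")
    if min(img.shape) < grid_size:
        raise InputError(f"image {img.shape} smaller than grid_size={grid_size}")
    Jrr, Jrc, Jcc = structure_tensor(img, sigma=tensor_sigma, mode="reflect", order="rc")
    H, W = img.shape
    ny, nx = H // grid_size, W // grid_size
    angle = np.zeros((ny, nx))
    coherence = np.zeros((ny, nx))
    for i in range(ny):
        for j in range(nx):
            sl = (slice(i * grid_size, (i + 1) * grid_size), slice(j * grid_size, (j + 1) * grid_size))
            jrr, jrc, jcc = Jrr[sl].mean(), Jrc[sl].mean(), Jcc[sl].mean()
            trace = jrr + jcc
            # gradient orientation doubled-angle; structures run orthogonal
            grad = 0.5 * np.degrees(np.arctan2(2 * jrc, jcc - jrr))
            angle[i, j] = (grad - 90.0) % 180.0
            coherence[i, j] = np.sqrt((jrr - jcc) ** 2 + 4 * jrc**2) / trace if trace > 1e-12 else 0.0
    grid_y = (np.arange(ny) + 0.5) * grid_size - 0.5
    grid_x = (np.arange(nx) + 0.5) * grid_size - 0.5
    return OrientationField(
        grid_x=grid_x,
        grid_y=grid_y,
        angle_deg=angle,
        coherence=coherence,
        reliable=coherence > reliability_floor,
        grid_size=grid_size,
    )
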