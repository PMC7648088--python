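"""Lineage enrichment index from two-channel fluorescence."""

from __future__ import annotations

import numpy as np

from ..errors import InputError, UndefinedMetricError
from ..types import ROI


def enrichment_index(img_g: np.ndarray, img_r: np.ndarray, roi: ROI | None = None) -> float:
    """Fraction of mean fluorescence attributable to the first channel.

    ``MFI_G / (MFI_G + MFI_R)`` over the ROI, where MFI is the mean pixel
    intensity of a channel.  1.0 means all signal is in the first
    (lineage-positive, e.g. GFP) channel; 0.5 means equal channels.  The
    index assumes the two channels share a common intensity calibration:
    it is invariant to a common gain but not to per-channel gain.
    """
    g = np.asarray(img_g, float)
    r = np.asarray(img_r, float)
    if g.shape != r.shape:
        raise InputError(f"channel shapes differ: {g.shape} vs {r.shape}")
    mask = ROI.full(g.shape).to_mask(g.shape) if roi is None else roi.to_mask(g.shape)
    mfi_g = float(g[mask].mean())
    mfi_r = float(r[mask].mean())
    if mfi_g + mfi_r <= 0:
        raise UndefinedMetricError("enrichment index undefined: both channels are zero in the ROI")
    return mfi_g / (mfi_g + mfi_r)
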