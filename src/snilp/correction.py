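"""Applying a vignetting estimate to images.

Flat-field correction divides each pixel by the normalized estimate,
``I_corr = I / V~`` — in practice a per-pixel multiplication by a
precomputed gain lookup table ``V~^{-1}``, which is how real-time pipelines
apply it.  Corrected values are truncated to the sensor range (``[0, 255]``
for the 8-bit default).  A small ``eps`` guards the division: real flats can
contain dead pixels where the estimate would vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .models import VignettingEstimate, _as_array
from .raster import FlatImage

__all__ = [
    "CorrectionLUT",
    "build_lut",
    "correct",
    "normalize_for_display",
    "clip_range_for_depth",
]


def clip_range_for_depth(bit_depth) -> tuple[float, float]:
    """Truncation range for a bit depth: [0, 255] for 8-bit, [0, 65535] for 16."""
    if bit_depth == "float":
        return (0.0, 1.0)
    return (0.0, float(2**int(bit_depth) - 1))


@dataclass
class CorrectionLUT:
    """Per-pixel gain table ``V~^{-1}`` with provenance and truncation range.

    When the source estimate is normalized (max 1) every gain is >= 1.
    ``flagged`` marks pixels where the estimate fell below ``eps`` and the
    gain was capped at ``1/eps``.
    """

    gain: np.ndarray
    source: dict = field(default_factory=dict)
    clip_range: tuple[float, float] | None = (0.0, 255.0)
    flagged: np.ndarray | None = None

    @property
    def n_flagged(self) -> int:
        return 0 if self.flagged is None else int(np.sum(self.flagged))


def build_lut(v, clip_range=(0.0, 255.0), eps: float = 1e-3) -> CorrectionLUT:
    """Build the reciprocal gain table from a normalized estimate.

    ``gain = 1 / max(V~, eps)`` per pixel; pixels with ``V~ < eps`` are
    flagged (their gain is capped at ``1/eps``).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    source: dict = {}
    if isinstance(v, VignettingEstimate):
        if not v.normalized:
            raise ValueError("estimate must be normalized (max = 1) to build a LUT")
        values = v.values
        source = {"model": v.model.value, "degree": v.degree,
                  "iterations": v.iterations}
    else:
        values = _as_array(v)
        if not np.isclose(values.max(), 1.0, atol=1e-9):
            raise ValueError("estimate must be normalized (max = 1) to build a LUT")
    flagged = values < eps
    gain = 1.0 / np.maximum(values, eps)
    return CorrectionLUT(gain=gain, source=source, clip_range=clip_range,
                         flagged=flagged)


def correct(img, lut: CorrectionLUT) -> FlatImage:
    """Apply a correction LUT: pixelwise product, then truncation.

    Output is float (no re-quantization); truncation clamps to
    ``lut.clip_range`` unless that is ``None``.
    """
    data = _as_array(img)
    if data.shape != lut.gain.shape:
        raise ValueError(
            f"shape mismatch: image {data.shape} vs LUT {lut.gain.shape}"
        )
    out = data * lut.gain
    if lut.clip_range is not None:
        lo, hi = lut.clip_range
        out = np.clip(out, lo, hi)
    vr = lut.clip_range if lut.clip_range is not None else None
    return FlatImage(out, "float", vr)


def _gaussian_kernel_10x10(sigma: float = 0.5) -> np.ndarray:
    """Even-sized 10x10 Gaussian kernel centered between pixels."""
    offsets = np.arange(10) - 4.5
    g = np.exp(-(offsets**2) / (2.0 * sigma**2))
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


def _gaussian_smooth_10x10(data: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    # constant (zero) padding at borders; the kernel is so narrow that only
    # the outermost rows/columns are affected
    return ndimage.correlate(data, _gaussian_kernel_10x10(sigma),
                             mode="constant", cval=0.0)


def normalize_for_display(img) -> FlatImage:
    """Divide by the maximum of a Gaussian-smoothed copy (sigma 0.5, 10x10).

    Visualization-only: the smoothing keeps single hot pixels from driving
    the normalizer.  Never used inside estimation.
    """
    data = _as_array(img)
    smoothed = _gaussian_smooth_10x10(data)
    peak = float(smoothed.max())
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero image for display")
    return FlatImage(data / peak, "float")
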