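"""Accuracy, smoothness and flatness metrics for vignetting estimates.

Accuracy against a known ground-truth surface is the usual MAE / RMSE pair.
Surface smoothness is measured with a moving window:

MLSD
    Mean Local Standard Deviation — the mean, over all interior window
    positions, of the in-window population standard deviation.  Sensitive
    to surface slope, not only to roughness.
MLSCD
    Mean Local Slope-Corrected Deviation — the same statistic computed on
    the residuals from an in-window bivariate OLS polynomial of low degree
    (default 2), which removes the slope/curvature contribution and leaves
    the actual roughness.  With ``detrend_degree=0`` the in-window "fit" is
    just the window mean, so MLSCD reduces to MLSD exactly.

Flatness of a corrected flat-field is summarized by the population standard
deviation and the interquartile range of all pixel values (lower = flatter).

Window centers run over ``[r_x .. M-1-r_x] x [r_y .. N-1-r_y]`` (0-based),
i.e. only windows fully inside the image count, which keeps border effects
out of the smoothness score.  Standard deviations use the population
divisor ``w_x * w_y`` throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .models import _as_array, _p2d_exponents, _scaled_coords

__all__ = [
    "SmoothnessWindowSpec",
    "FlatQuality",
    "mae",
    "rmse",
    "mlsd",
    "mlscd",
    "flat_quality",
]


@dataclass(frozen=True)
class SmoothnessWindowSpec:
    """Moving-window geometry for MLSD/MLSCD.

    ``w_y`` is the vertical window extent (rows), ``w_x`` the horizontal
    one (columns); both must be odd and >= 3.  ``detrend_degree`` is the
    total degree of the in-window bivariate polynomial subtracted before
    the deviation is computed (0 = plain window mean, i.e. MLSD).
    """

    w_x: int = 7
    w_y: int = 7
    detrend_degree: int = 2

    def __post_init__(self) -> None:
        for name, w in (("w_x", self.w_x), ("w_y", self.w_y)):
            if w < 3 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 3, got {w}")
        if self.detrend_degree < 0:
            raise ValueError("detrend_degree must be >= 0")
        nterms = (self.detrend_degree + 1) * (self.detrend_degree + 2) // 2
        if self.w_x * self.w_y <= nterms:
            raise ValueError(
                f"window with {self.w_x * self.w_y} pixels cannot determine "
                f"the {nterms}-term detrending polynomial"
            )

    @property
    def r_x(self) -> int:
        return self.w_x // 2

    @property
    def r_y(self) -> int:
        return self.w_y // 2


class FlatQuality(NamedTuple):
    """Dispersion summary of a corrected flat-field (lower = flatter)."""

    std: float
    iqr: float


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------


def _pair(est, truth):
    a = _as_array(est)
    b = _as_array(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mae(est, truth) -> float:
    """Mean absolute per-pixel difference."""
    a, b = _pair(est, truth)
    return float(np.mean(np.abs(a - b)))


def rmse(est, truth) -> float:
    """Root-mean-square per-pixel difference (always >= MAE)."""
    a, b = _pair(est, truth)
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------------
# smoothness
# ---------------------------------------------------------------------------


def _window_basis(spec: SmoothnessWindowSpec) -> np.ndarray:
    """Orthonormal basis (w_y*w_x, T) of the in-window detrending space.

    One shared design serves every window position (identical geometry), so
    the projector is precomputed once.  Coordinates inside the window are
    scaled to [-1, 1] per axis; the constant term is always present, which
    guarantees the residuals have exactly zero mean in exact arithmetic.
    """
    ys = _scaled_coords(spec.w_y)
    xs = _scaled_coords(spec.w_x)
    xx, yy = np.meshgrid(xs, ys)
    exps = _p2d_exponents(spec.detrend_degree)
    design = np.column_stack(
        [(xx.ravel() ** p) * (yy.ravel() ** q) for p, q in exps]
    )
    q, _ = np.linalg.qr(design)
    return q


def mlscd(img, spec: SmoothnessWindowSpec = SmoothnessWindowSpec()) -> float:
    """Mean local slope-corrected deviation over interior window positions."""
    data = _as_array(img)
    m, n = data.shape
    if spec.w_y >= m or spec.w_x >= n:
        raise ValueError(
            f"window ({spec.w_y}x{spec.w_x}) must be smaller than image ({m}x{n})"
        )
    qbasis = _window_basis(spec)  # (w, T)
    windows = sliding_window_view(data, (spec.w_y, spec.w_x))
    a, b = windows.shape[:2]
    npix = spec.w_y * spec.w_x
    total = 0.0
    # chunk over window-center rows to bound the materialized residual array
    chunk = max(1, int(4e6 // (b * npix)))
    for start in range(0, a, chunk):
        w = windows[start:start + chunk].reshape(-1, npix)
        coef = w @ qbasis
        resid = w - coef @ qbasis.T
        resid -= resid.mean(axis=1, keepdims=True)
        total += float(np.sum(np.sqrt(np.mean(resid**2, axis=1))))
    return total / (a * b)


def mlsd(img, spec: SmoothnessWindowSpec | None = None) -> float:
    """Mean local standard deviation over interior window positions.

    Shares the MLSCD code path with a degree-0 (constant) detrend, so the
    two agree exactly when ``detrend_degree == 0``.
    """
    if spec is None:
        spec = SmoothnessWindowSpec(detrend_degree=0)
    spec0 = SmoothnessWindowSpec(w_x=spec.w_x, w_y=spec.w_y, detrend_degree=0)
    return mlscd(img, spec0)


# ---------------------------------------------------------------------------
# flatness of corrected images
# ---------------------------------------------------------------------------


def flat_quality(corrected) -> FlatQuality:
    """Population STD and IQR of all pixels of a corrected (truncated) flat.

    IQR uses linearly interpolated percentiles (``np.percentile`` default),
    q75 - q25.
    """
    data = _as_array(corrected)
    if data.size == 0:
        raise ValueError("empty image")
    q25, q75 = np.percentile(data, [25.0, 75.0])
    return FlatQuality(std=float(np.std(data)), iqr=float(q75 - q25))
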