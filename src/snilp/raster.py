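"""Raster image I/O and pixel-level utilities for flat-field work.

Axis convention used across the package: arrays are stored row-major with
``axis 0 = rows = vertical`` and ``axis 1 = columns = horizontal``.  All
coordinates are given in ``(row, col)`` order.

Reading and writing goes through :mod:`imageio` / :mod:`tifffile` /
:mod:`numpy`; this module only adds the thin flat-field semantics on top
(bit depth bookkeeping, stack averaging, luma conversion, lossless export
of float estimate matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "FlatImage",
    "load_image",
    "load_stack",
    "save_matrix",
    "average_stack",
    "rgb_to_luma",
    "LUMA_WEIGHTS",
]

#: Grayscale conversion weights for (R, G, B), at the printed 4-decimal
#: precision used as the contract (their sum is 0.9999, not 1).
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


def _infer_bit_depth(dtype: np.dtype) -> int | str:
    dtype = np.dtype(dtype)
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    if dtype.kind == "f":
        return "float"
    raise ValueError(f"unsupported sample type: {dtype}")


def _default_range(bit_depth: int | str, pixels: np.ndarray) -> tuple[float, float]:
    if bit_depth == "float":
        lo = float(np.min(pixels)) if pixels.size else 0.0
        hi = float(np.max(pixels)) if pixels.size else 1.0
        return (min(lo, 0.0), max(hi, 1.0))
    return (0.0, float(2**int(bit_depth) - 1))


@dataclass
class FlatImage:
    """A 2D scalar raster (or an RGB raster as a (M, N, 3) array).

    Parameters
    ----------
    pixels : ndarray
        ``(M, N)`` grayscale or ``(M, N, 3)`` RGB array, ``M, N >= 2``,
        all values finite.
    bit_depth : int or "float"
        8, 16 or ``"float"``; inferred from the dtype when omitted.
    value_range : (lo, hi)
        Range the pixel values are interpreted against; defaults to
        ``[0, 2**bit_depth - 1]`` for integer depths.
    """

    pixels: np.ndarray
    bit_depth: int | str = None  # type: ignore[assignment]
    value_range: tuple[float, float] = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3) or (
            self.pixels.ndim == 3 and self.pixels.shape[2] != 3
        ):
            raise ValueError(
                f"expected (M, N) or (M, N, 3) pixels, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError(f"image too small: {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must all be finite")
        if self.bit_depth is None:
            self.bit_depth = _infer_bit_depth(self.pixels.dtype)
        if self.bit_depth not in (8, 16, "float"):
            raise ValueError(f"bit_depth must be 8, 16 or 'float', got {self.bit_depth}")
        if self.bit_depth != "float":
            lo, hi = 0, 2**int(self.bit_depth) - 1
            if self.pixels.min() < lo or self.pixels.max() > hi:
                raise ValueError(
                    f"pixel values outside [{lo}, {hi}] for bit_depth={self.bit_depth}"
                )
        if self.value_range is None:
            self.value_range = _default_range(self.bit_depth, self.pixels)

    @property
    def shape(self) -> tuple[int, int]:
        """(M, N) = (rows, cols)."""
        return self.pixels.shape[:2]

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    def plane(self, k: int) -> "FlatImage":
        """Return color plane ``k`` (0=R, 1=G, 2=B) as a grayscale image."""
        if not self.is_rgb:
            raise ValueError("not an RGB image")
        return FlatImage(self.pixels[:, :, k], self.bit_depth, self.value_range)

    def astype_float(self) -> np.ndarray:
        return np.asarray(self.pixels, dtype=np.float64)


def _as_pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, FlatImage) else np.asarray(img)


def load_image(path) -> FlatImage:
    """Load a raster file (TIFF/PNG/BMP/NPY) as a :class:`FlatImage`.

    RGB files come back with ``(M, N, 3)`` pixels; use :meth:`FlatImage.plane`
    and :func:`rgb_to_luma` to collapse them.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        if path.suffix.lower() == ".npy":
            arr = np.load(path)
        else:
            import imageio.v3 as iio

            arr = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - reraise with the path attached
        raise IOError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    try:
        return FlatImage(arr)
    except ValueError as exc:  # truncated/partial reads decode to junk shapes
        raise IOError(f"could not read image {path}: {exc}") from exc


def load_stack(path) -> list[FlatImage]:
    """Load a multi-page TIFF (or any multi-frame raster) as a list of frames.

    Pages are returned in file order (acquisition order for stacks written
    by :mod:`snilp`).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    if path.suffix.lower() == ".npy":
        arr = np.load(path)
        if arr.ndim == 2:
            arr = arr[None]
        return [FlatImage(frame) for frame in arr]
    import tifffile

    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not read stack {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = arr[None]
    return [FlatImage(frame) for frame in arr]


def save_matrix(values, path, dtype: str = "float64") -> None:
    """Write a float estimate matrix losslessly.

    ``.npy`` paths get a raw numpy array; anything else is written as a
    single-plane little-endian float TIFF.  64-bit round-trips bit-exactly;
    32-bit is accurate to one float32 ulp.
    """
    arr = np.asarray(getattr(values, "values", getattr(values, "pixels", values)))
    if dtype not in ("float32", "float64"):
        raise ValueError("dtype must be 'float32' or 'float64'")
    arr = arr.astype(dtype)
    path = Path(path)
    try:
        if path.suffix.lower() == ".npy":
            np.save(path, arr)
        else:
            import tifffile

            tifffile.imwrite(path, arr)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"could not write matrix to {path}: {exc}") from exc


def average_stack(images: Sequence) -> FlatImage:
    """Per-pixel arithmetic mean of repeated acquisitions.

    Accumulation is in float64 regardless of input depth, so 8-bit stacks of
    any length average without overflow.  Order of the inputs is irrelevant.
    """
    if len(images) == 0:
        raise ValueError("average_stack needs at least one image")
    first = _as_pixels(images[0])
    acc = np.zeros(first.shape, dtype=np.float64)
    for idx, img in enumerate(images):
        arr = _as_pixels(img)
        if arr.shape != first.shape:
            raise ValueError(
                f"image {idx} has shape {arr.shape}, expected {first.shape}"
            )
        acc += arr
    mean = acc / len(images)
    ref = images[0]
    vr = ref.value_range if isinstance(ref, FlatImage) else None
    return FlatImage(mean, "float", vr)


def rgb_to_luma(r, g, b) -> FlatImage:
    """Collapse color planes to luma: ``0.2989 R + 0.5870 G + 0.1140 B``."""
    rp, gp, bp = (_as_pixels(x).astype(np.float64) for x in (r, g, b))
    if not (rp.shape == gp.shape == bp.shape):
        raise ValueError(
            f"plane shapes differ: {rp.shape}, {gp.shape}, {bp.shape}"
        )
    wr, wg, wb = LUMA_WEIGHTS
    return FlatImage(wr * rp + wg * gp + wb * bp, "float")
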