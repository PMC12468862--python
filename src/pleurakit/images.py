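"""Canonical image representation and file I/O.

The whole pipeline works on plain numpy arrays with a fixed convention:

* grayscale image — 2-D float array, values in [0, 1], row-major,
  0-based indices (``img[row, col]``);
* RGB image — (H, W, 3) float array, per-channel values in [0, 1];
* binary mask — 2-D bool array with the geometry of the image it was
  derived from.

8-bit integer rasters exist only at the file boundary: readers scale to
[0, 1] floats, writers quantize with round-half-away-from-zero.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

from .errors import ImageError

MIN_SIDE = 8  # smaller rasters carry no usable anatomy


def as_gray(img: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Validate and return a float64 grayscale image in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageError(f"{name}: expected a 2-D grayscale array, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ImageError(f"{name}: minimum size is {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}")
    if not np.isfinite(arr).all():
        raise ImageError(f"{name}: non-finite pixel values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ImageError(f"{name}: values must lie in [0, 1], got range "
                         f"[{arr.min():.4g}, {arr.max():.4g}]")
    return arr


def as_rgb(img: np.ndarray, *, name: str = "image") -> np.ndarray:
    """Validate and return a float64 (H, W, 3) RGB image in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageError(f"{name}: expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise ImageError(f"{name}: minimum size is {MIN_SIDE}x{MIN_SIDE}, got {arr.shape[:2]}")
    if not np.isfinite(arr).all():
        raise ImageError(f"{name}: non-finite pixel values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ImageError(f"{name}: values must lie in [0, 1]")
    return arr


def as_mask(mask: np.ndarray, *, name: str = "mask") -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != np.bool_:
        raise ImageError(f"{name}: expected a boolean mask, got dtype {arr.dtype}")
    if arr.ndim != 2:
        raise ImageError(f"{name}: expected a 2-D mask, got shape {arr.shape}")
    return arr


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] float image to 8 bits, round-half-away-from-zero."""
    arr = np.clip(np.asarray(img, dtype=np.float64), 0.0, 1.0) * 255.0
    # np.round is half-to-even; medical viewers expect the classical rule
    return np.floor(arr + 0.5).astype(np.uint8)


def from_uint8(raw: np.ndarray) -> np.ndarray:
    return np.asarray(raw, dtype=np.float64) / 255.0


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read PNG/JPEG/TIFF into the canonical float representation.

    Returns a 2-D grayscale array or an (H, W, 3) RGB array depending on
    the file contents; an alpha channel, if present, is dropped.
    """
    raw = iio.imread(path)
    if raw.ndim == 3 and raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if raw.ndim == 3 and raw.shape[2] == 1:
        raw = raw[:, :, 0]
    if np.issubdtype(raw.dtype, np.integer):
        info = np.iinfo(raw.dtype)
        arr = raw.astype(np.float64) / info.max
    else:
        arr = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return as_rgb(arr) if arr.ndim == 3 else as_gray(arr)


def save_image(path: str | os.PathLike, img: np.ndarray) -> None:
    """Write a [0, 1] float image (or bool mask as 0/255) as 8-bit."""
    arr = np.asarray(img)
    if arr.dtype == np.bool_:
        out = np.where(arr, np.uint8(255), np.uint8(0))
    else:
        out = to_uint8(arr)
    iio.imwrite(path, out)
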