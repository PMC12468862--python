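"""Radiograph preprocessing: grayscale, negative, AHE, binarization, morphology.

The goal of this stage is a clean binary lung-field mask.  On a frontal
chest radiograph the aerated lungs are the darkest structures; inverting
the grayscale image (``1 - I``) turns them into the brightest, adaptive
histogram equalization evens out acquisition-dependent illumination, a
fixed 0.5 threshold then isolates the lung fields, and binary morphology
removes speckle and fills small notches before projection profiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

from .errors import ParameterError
from .images import as_gray, as_mask, as_rgb

#: ITU-R BT.601 luma weights — the conventional "weighted average" of RGB.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class AHEParams:
    """Tile layout for (contrast-limited) adaptive histogram equalization.

    ``clip_limit`` is a fraction in (0, 1]; ``None`` means unclipped AHE,
    which is equivalent to ``clip_limit=1.0``.
    """

    tile_rows: int = 8
    tile_cols: int = 8
    clip_limit: float | None = None

    def __post_init__(self):
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ParameterError("AHE tile grid must have at least one tile per axis")
        if self.clip_limit is not None and not (0.0 < self.clip_limit <= 1.0):
            raise ParameterError(f"clip_limit must lie in (0, 1], got {self.clip_limit}")


@dataclass(frozen=True)
class MorphParams:
    """Structuring element and operation order for mask cleanup.

    Default sequence closes first (fills pinhole gaps in the lung fields,
    including noise in the costophrenic notch) then opens (removes
    isolated speckle), with a disk of radius 3.
    """

    element_shape: str = "disk"
    element_radius: int = 3
    sequence: tuple[str, ...] = ("close", "open")

    _SHAPES = ("disk", "square", "cross")
    _OPS = ("open", "close", "dilate", "erode")

    def __post_init__(self):
        if self.element_shape not in self._SHAPES:
            raise ParameterError(f"element_shape must be one of {self._SHAPES}")
        if self.element_radius < 1:
            raise ParameterError("element_radius must be >= 1")
        if not self.sequence:
            raise ParameterError("morphology sequence must be non-empty")
        bad = [op for op in self.sequence if op not in self._OPS]
        if bad:
            raise ParameterError(f"unknown morphology ops {bad}; valid: {self._OPS}")

    def element(self) -> np.ndarray:
        r = self.element_radius
        if self.element_shape == "disk":
            return morphology.disk(r).astype(bool)
        if self.element_shape == "square":
            return np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
        elem = np.zeros((2 * r + 1, 2 * r + 1), dtype=bool)
        elem[r, :] = True
        elem[:, r] = True
        return elem


def to_grayscale(img: np.ndarray, weights: Sequence[float] = BT601_WEIGHTS) -> np.ndarray:
    """Collapse an RGB radiograph to luma by a weighted channel average.

    ``weights`` must sum to 1 so that the output stays in [0, 1].
    """
    arr = as_rgb(img)
    w = np.asarray(weights, dtype=np.float64)
    if w.shape != (3,):
        raise ParameterError(f"expected 3 grayscale weights, got {w.shape}")
    if not np.isclose(w.sum(), 1.0):
        raise ParameterError(f"grayscale weights must sum to 1, got {w.sum():.6g}")
    return arr @ w


def invert(img: np.ndarray) -> np.ndarray:
    """Negative transform ``1 - I``: air-filled lungs become bright."""
    return 1.0 - as_gray(img)


def adaptive_equalize(img: np.ndarray, params: AHEParams | None = None) -> np.ndarray:
    """Adaptive histogram equalization over a tile grid.

    Unclipped by default; pass a ``clip_limit`` for CLAHE behaviour.
    A constant image is returned unchanged (its histogram is degenerate).
    """
    arr = as_gray(img)
    params = params or AHEParams()
    h, w = arr.shape
    if params.tile_rows > h // 4 or params.tile_cols > w // 4:
        raise ParameterError(
            f"tile grid {params.tile_rows}x{params.tile_cols} too fine for "
            f"a {h}x{w} image (max {h // 4}x{w // 4})")
    if arr.max() == arr.min():
        return arr.copy()
    clip = 1.0 if params.clip_limit is None else params.clip_limit
    kernel = (max(h // params.tile_rows, 1), max(w // params.tile_cols, 1))
    out = exposure.equalize_adapthist(arr, kernel_size=kernel, clip_limit=clip)
    return np.clip(out, 0.0, 1.0)


def binarize(img: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Fixed-threshold binarization; ties (== threshold) go to foreground."""
    arr = as_gray(img)
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must lie in (0, 1), got {threshold}")
    return arr >= threshold


def _apply_morph_op(mask: np.ndarray, op: str, elem: np.ndarray) -> np.ndarray:
    # border_value=0: pixels outside the raster are background for
    # dilation and erosion alike.
    if op == "dilate":
        return ndimage.binary_dilation(mask, structure=elem, border_value=0)
    if op == "erode":
        return ndimage.binary_erosion(mask, structure=elem, border_value=0)
    if op == "open":
        return ndimage.binary_opening(mask, structure=elem, border_value=0)
    if op == "close":
        # scipy's closing pads internally so the border stays background
        return ndimage.binary_closing(mask, structure=elem, border_value=0)
    raise ParameterError(f"unknown morphology op {op!r}")


def morph_clean(mask: np.ndarray, params: MorphParams | None = None) -> np.ndarray:
    """Run the configured opening/closing sequence on a binary mask."""
    arr = as_mask(mask)
    params = params or MorphParams()
    elem = params.element()
    if elem.shape[0] > arr.shape[0] or elem.shape[1] > arr.shape[1]:
        raise ParameterError(
            f"structuring element {elem.shape} larger than mask {arr.shape}")
    out = arr
    for op in params.sequence:
        out = _apply_morph_op(out, op, elem)
    return out


def lung_mask(img: np.ndarray,
              *,
              grayscale_weights: Sequence[float] = BT601_WEIGHTS,
              ahe: AHEParams | None = None,
              binarize_threshold: float = 0.5,
              morph: MorphParams | None = None,
              equalize_before_binarize: bool = False) -> np.ndarray:
    """Full preprocessing chain from radiograph to binary lung-field mask.

    grayscale → negative → [AHE] → threshold 0.5 → morphological cleanup.
    By default the fixed threshold is applied to the negative image
    directly: adaptive equalization maps locally homogeneous regions to
    the top of the range (every tile is stretched to full range by rank),
    which makes a fixed global threshold meaningless after it.  Set
    ``equalize_before_binarize=True`` to binarize the AHE output instead.
    """
    arr = to_grayscale(img, grayscale_weights) if np.ndim(img) == 3 else as_gray(img)
    neg = invert(arr)
    if equalize_before_binarize:
        neg = adaptive_equalize(neg, ahe)
    mask = binarize(neg, binarize_threshold)
    return morph_clean(mask, morph)


def warn_constant(img: np.ndarray, context: str) -> bool:
    """Emit a warning if ``img`` is constant; returns True when it is."""
    if np.ptp(img) == 0.0:
        warnings.warn(f"{context}: constant image, operation is degenerate",
                      RuntimeWarning, stacklevel=3)
        return True
    return False
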