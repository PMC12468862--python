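"""Lung-field localization by projection profiles and ROI extraction.

Foreground counts of the binary lung mask are summed per column and per
row.  The lateral boundaries are the minima of the column profile in the
outer fifths of the image (the soft-tissue chest wall between lung and
background); the upper boundary is the first row whose foreground count
inside the central third of columns (the mediastinal band) exceeds a
fraction of the profile maximum; the lower boundary is the row of the
minimum count in the lower half, which sits just below the costophrenic
angles.  The resulting box is mapped back onto the original grayscale
radiograph, the lower half (heart to costophrenic angle) is kept, and
the ROI is resized to 227x227 for the classifier.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace

import numpy as np
from skimage.transform import resize

from .errors import ParameterError, SegmentationError
from .images import MIN_SIDE, as_gray, as_mask
from .preprocess import AHEParams, MorphParams, lung_mask


@dataclass(frozen=True)
class Profile:
    """Per-column or per-row foreground counts of a binary mask."""

    values: np.ndarray
    axis: str  # "columns" or "rows"

    def __post_init__(self):
        if self.axis not in ("columns", "rows"):
            raise ParameterError(f"profile axis must be 'columns' or 'rows', got {self.axis!r}")
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel rectangle [left, right) x [top, bottom), 0-based,
    in source-image coordinates."""

    left: int
    right: int
    top: int
    bottom: int

    def __post_init__(self):
        if not (0 <= self.left < self.right and 0 <= self.top < self.bottom):
            raise ParameterError(f"degenerate crop box {self}")

    @property
    def width(self) -> int:
        return self.right - self.left

    @property
    def height(self) -> int:
        return self.bottom - self.top

    def mirrored(self, image_width: int) -> "CropBox":
        """The box of the horizontally flipped image."""
        return CropBox(image_width - self.right, image_width - self.left,
                       self.top, self.bottom)

    def intersection_over_union(self, other: "CropBox") -> float:
        iw = min(self.right, other.right) - max(self.left, other.left)
        ih = min(self.bottom, other.bottom) - max(self.top, other.top)
        inter = max(iw, 0) * max(ih, 0)
        union = self.width * self.height + other.width * other.height - inter
        return inter / union if union else 0.0

    def to_json(self, source_shape: tuple[int, int] | None = None) -> str:
        d = {"left": self.left, "right": self.right,
             "top": self.top, "bottom": self.bottom}
        if source_shape is not None:
            d["source_height"], d["source_width"] = map(int, source_shape)
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "CropBox":
        d = json.loads(text)
        return cls(d["left"], d["right"], d["top"], d["bottom"])


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the projection-profile boundary search.

    ``side_fraction`` — width of the lateral search windows as a fraction
    of image width (outer fifths by default).
    ``band_fraction`` — width of the central column band used for the
    upper boundary (central third by default); ``top_band='rows'``
    restricts to the central third of rows of the full-width profile
    instead.
    ``top_threshold`` — fraction of the maximum row count that a row must
    exceed to be accepted as the lung apex.
    ``single_lung`` — optionally keep only the left or right half of the
    cropped lung image before the lower-half step.
    """

    side_fraction: float = 0.2
    top_band: str = "columns"
    band_fraction: float = 1.0 / 3.0
    top_threshold: float = 0.10
    output_size: tuple[int, int] = (227, 227)
    single_lung: str | None = None

    def __post_init__(self):
        for name in ("side_fraction", "band_fraction", "top_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must lie in (0, 1), got {v}")
        if self.top_band not in ("columns", "rows"):
            raise ParameterError("top_band must be 'columns' or 'rows'")
        if self.single_lung not in (None, "left", "right"):
            raise ParameterError("single_lung must be None, 'left' or 'right'")


def column_profile(mask: np.ndarray) -> Profile:
    """Foreground count of every column."""
    return Profile(as_mask(mask).sum(axis=0), "columns")


def row_profile(mask: np.ndarray, column_band: tuple[int, int] | None = None) -> Profile:
    """Foreground count of every row, optionally restricted to a column band."""
    arr = as_mask(mask)
    if column_band is not None:
        lo, hi = column_band
        if not (0 <= lo < hi <= arr.shape[1]):
            raise ParameterError(f"column band {column_band} outside [0, {arr.shape[1]})")
        arr = arr[:, lo:hi]
    return Profile(arr.sum(axis=1), "rows")


def find_lateral_bounds(profile: Profile, side_fraction: float = 0.2) -> tuple[int, int]:
    """Left/right lung boundaries as the minima of the outer column-profile windows.

    Returns a half-open pair ``(left, right)``.  Ties break toward the
    image edge: smallest index in the left window, largest in the right.
    """
    if profile.axis != "columns":
        raise ParameterError("lateral bounds need a column profile")
    if not (0.0 < side_fraction < 1.0):
        raise ParameterError(f"side_fraction must lie in (0, 1), got {side_fraction}")
    v = profile.values
    w = len(v)
    left_hi = math.floor(w * side_fraction)
    right_lo = math.ceil(w * (1.0 - side_fraction))
    if left_hi < 1 or right_lo >= w:
        raise SegmentationError(
            f"profile of length {w} shorter than the lateral search windows",
            stage="lateral-bounds")
    left = int(np.argmin(v[:left_hi]))  # argmin returns the first minimum
    right_window = v[right_lo:]
    # last minimum in the right window = toward the right edge
    right = right_lo + len(right_window) - 1 - int(np.argmin(right_window[::-1]))
    return left, right + 1


def find_vertical_bounds(row_prof: Profile,
                         top_threshold: float = 0.10,
                         bottom_profile: Profile | None = None) -> tuple[int, int]:
    """Upper and lower lung boundaries from row profiles.

    ``top`` is the first row (scanning downward) whose count exceeds
    ``top_threshold`` times the profile maximum.  ``bottom`` is the row of
    the minimum count within the lower half of ``bottom_profile`` (defaults
    to ``row_prof``), ties broken toward the image bottom so the
    costophrenic angle stays in frame.  Returned as ``(top, bottom)`` with
    ``bottom`` an inclusive row index.
    """
    if row_prof.axis != "rows":
        raise ParameterError("vertical bounds need a row profile")
    v = row_prof.values
    cut = top_threshold * v.max()
    above = np.nonzero(v > cut)[0]
    if len(above) == 0:
        raise SegmentationError("no row exceeds the apex threshold", stage="top-bound")
    top = int(above[0])

    bv = (bottom_profile or row_prof).values
    h = len(bv)
    lower = bv[h // 2:]
    bottom = h // 2 + len(lower) - 1 - int(np.argmin(lower[::-1]))
    if top >= bottom:
        raise SegmentationError(
            f"upper bound {top} not above lower bound {bottom}", stage="vertical-bounds")
    return top, bottom


def crop_to_box(img: np.ndarray, box: CropBox) -> np.ndarray:
    arr = as_gray(img)
    h, w = arr.shape
    if box.right > w or box.bottom > h:
        raise ParameterError(f"box {box} exceeds image {h}x{w}")
    return arr[box.top:box.bottom, box.left:box.right].copy()


def extract_lower_half_roi(img: np.ndarray,
                           output_size: tuple[int, int] = (227, 227)) -> np.ndarray:
    """Keep rows [H//2, H) — the heart-to-costophrenic-angle band — and
    resize to the classifier input size (bilinear, anti-aliased)."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ParameterError("need a 2-D image at least 2 rows tall")
    lower = arr[arr.shape[0] // 2:, :]
    out = resize(lower, output_size, order=1, mode="edge",
                 anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def segment(img: np.ndarray,
            params: SegmentationParams | None = None,
            *,
            ahe: AHEParams | None = None,
            morph: MorphParams | None = None,
            binarize_threshold: float = 0.5,
            mask: np.ndarray | None = None,
            search_margin: int | None = None) -> tuple[np.ndarray, CropBox]:
    """Full segmentation: mask → boundaries → crop → lower half → resize.

    The preprocessing chain runs on a working copy; the crop and the ROI
    come from the ORIGINAL grayscale pixels.  Returns ``(roi, box)`` with
    the box in source coordinates for auditability.  A precomputed mask
    may be supplied to skip preprocessing.

    ``search_margin`` excludes an outer pixel frame from the boundary
    search: the morphology border policy (outside = background) leaves
    the outer ``element_radius`` pixels of the cleaned mask empty, and
    treating that artifact as a profile minimum would snap the bounds to
    the raster edge.  Defaults to the structuring-element radius when
    this function computed the mask itself, 0 for a user-supplied mask.
    """
    arr = as_gray(img) if np.ndim(img) == 2 else img
    params = params or SegmentationParams()
    if mask is None:
        if search_margin is None:
            search_margin = (morph or MorphParams()).element_radius
        mask = lung_mask(arr, ahe=ahe, morph=morph,
                         binarize_threshold=binarize_threshold)
    else:
        mask = as_mask(mask)
        if search_margin is None:
            search_margin = 0
    gray = arr if np.ndim(arr) == 2 else None
    if gray is None:
        from .preprocess import to_grayscale
        gray = to_grayscale(arr)
    if np.ptp(gray) == 0.0:
        raise SegmentationError("constant image: no intensity boundary to cross",
                                stage="preprocess")

    m = search_margin
    if m < 0 or 2 * m + MIN_SIDE > min(mask.shape):
        raise ParameterError(f"search_margin {m} leaves no searchable mask area")
    core = mask[m:mask.shape[0] - m, m:mask.shape[1] - m] if m else mask
    if core.all() or not core.any():
        raise SegmentationError("degenerate lung mask (uniform foreground/background)",
                                stage="preprocess")

    left, right = find_lateral_bounds(column_profile(core), params.side_fraction)

    h, w = core.shape
    if params.top_band == "columns":
        lo = int(round(w * (0.5 - params.band_fraction / 2)))
        hi = int(round(w * (0.5 + params.band_fraction / 2)))
        top_prof = row_profile(core, (max(lo, 0), min(hi, w)))
    else:
        top_prof = row_profile(core)
    # the lower boundary is searched on the laterally cropped mask
    bottom_prof = row_profile(core, (left, right))
    if params.top_band == "rows":
        lo = int(round(h * (0.5 - params.band_fraction / 2)))
        v = top_prof.values.copy()
        v[:lo] = 0
        top_prof = Profile(v, "rows")
    top, bottom = find_vertical_bounds(top_prof, params.top_threshold, bottom_prof)

    box = CropBox(left + m, right + m, top + m, bottom + 1 + m)
    lung = crop_to_box(gray, box)
    if params.single_lung is not None:
        mid = lung.shape[1] // 2
        if params.single_lung == "left":
            lung, box = lung[:, :mid], replace(box, right=box.left + mid)
        else:
            lung, box = lung[:, mid:], replace(box, left=box.left + mid)
    roi = extract_lower_half_roi(lung, params.output_size)
    return roi, box


def save_box(path: str | os.PathLike, box: CropBox, source_shape: tuple[int, int]) -> None:
    with open(path, "w") as fh:
        fh.write(box.to_json(source_shape))
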