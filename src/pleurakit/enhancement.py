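"""Two-stage ROI enhancement: contrast stretch, then gradient emphasis.

Fluid in the costal recess renders as a gray, low-contrast opacity that
blunts the normally sharp costophrenic angle.  The selected pipeline
first stretches the ROI histogram onto the full dynamic range (making
the effusion/lung brightness difference explicit) and then blends the
image with its Sobel gradient magnitude (making the presence or absence
of a steep diaphragm-wall edge explicit).  The alternates compared
against it — log transform, CLAHE, plain thresholded Sobel, unsharp
sharpening, Canny — are all available behind the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import feature

from .errors import ParameterError
from .images import as_gray
from .preprocess import AHEParams, adaptive_equalize, warn_constant

#: The two 3x3 Sobel kernels (horizontal and vertical change detectors).
SOBEL_X = np.array([[-1, 0, 1],
                    [-2, 0, 2],
                    [-1, 0, 1]], dtype=np.float64)
SOBEL_Y = np.array([[-1, -2, -1],
                    [0, 0, 0],
                    [1, 2, 1]], dtype=np.float64)

CONTRAST_METHODS = ("none", "log", "clahe", "stretch")
EDGE_METHODS = ("none", "sobel", "sobel_gradient", "sharpen", "canny")


@dataclass(frozen=True)
class SobelConfig:
    """Options of the Sobel gradient chain.

    ``gaussian_sigma=0`` skips pre-smoothing; ``edge_threshold=None``
    skips binarization; the blend step computes
    ``alpha * original + beta * normalized gradient magnitude``.
    """

    gaussian_sigma: float = 1.0
    compute_direction: bool = False
    edge_threshold: float | None = None
    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self):
        if self.gaussian_sigma < 0:
            raise ParameterError("gaussian_sigma must be >= 0")
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta == 0:
            raise ParameterError("blend weights must be >= 0 with alpha + beta > 0")


@dataclass(frozen=True)
class EnhanceConfig:
    """Contrast stage + edge stage selection; defaults are the selected
    pipeline (histogram stretching + Sobel gradient blend)."""

    contrast_method: str = "stretch"
    edge_method: str = "sobel_gradient"
    sobel: SobelConfig = field(default_factory=SobelConfig)
    log_scale: float = 1.0
    clahe_params: AHEParams = field(default_factory=lambda: AHEParams(clip_limit=0.01))
    sharpen_amount: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.2

    def __post_init__(self):
        if self.contrast_method not in CONTRAST_METHODS:
            raise ParameterError(f"contrast_method must be one of {CONTRAST_METHODS}")
        if self.edge_method not in EDGE_METHODS:
            raise ParameterError(f"edge_method must be one of {EDGE_METHODS}")


def histogram_stretch(img: np.ndarray) -> np.ndarray:
    """Linear map of the observed [min, max] onto the full range.

    ``out = (in - min) / (max - min)``; at 8-bit export the x255 scaling
    happens in the writer.  A constant image is returned unchanged with a
    warning (the stretch denominator would vanish).
    """
    arr = as_gray(img)
    if warn_constant(arr, "histogram_stretch"):
        return arr.copy()
    lo, hi = arr.min(), arr.max()
    return (arr - lo) / (hi - lo)


def log_transform(img: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Monotone log remap ``log(1 + c*I)`` normalized to [0, 1]."""
    arr = as_gray(img)
    if scale <= 0:
        raise ParameterError(f"log scale must be > 0, got {scale}")
    out = np.log1p(scale * arr) / np.log1p(scale)
    return np.clip(out, 0.0, 1.0)


def clahe(img: np.ndarray, params: AHEParams | None = None) -> np.ndarray:
    """Contrast-limited AHE (clipped-histogram variant of adaptive_equalize)."""
    params = params or AHEParams(clip_limit=0.01)
    if params.clip_limit is None:
        raise ParameterError("clahe requires a clip_limit; use adaptive_equalize for AHE")
    return adaptive_equalize(img, params)


def sobel_fields(img: np.ndarray, gaussian_sigma: float = 0.0
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw Sobel responses ``(gx, gy, magnitude, direction)``.

    Convolves the literal 3x3 kernels with edge-replicated borders;
    ``magnitude = sqrt(gx**2 + gy**2)`` is NOT normalized here.
    """
    arr = as_gray(img)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ParameterError("image smaller than the 3x3 Sobel kernel")
    if gaussian_sigma > 0:
        arr = ndimage.gaussian_filter(arr, gaussian_sigma, mode="nearest")
    # correlation convention: the printed kernels slide unflipped, so a
    # left-to-right intensity increase gives positive gx
    gx = ndimage.correlate(arr, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(arr, SOBEL_Y, mode="nearest")
    mag = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)
    return gx, gy, mag, theta


def sobel_gradient(img: np.ndarray, cfg: SobelConfig | None = None) -> np.ndarray:
    """The full gradient chain: smooth, convolve, magnitude, optional
    threshold, blend with the original; output renormalized to [0, 1]."""
    cfg = cfg or SobelConfig()
    arr = as_gray(img)
    _, _, mag, _ = sobel_fields(arr, cfg.gaussian_sigma)
    peak = mag.max()
    norm = mag / peak if peak > 0 else mag  # scale-stable blend
    if cfg.edge_threshold is not None:
        norm = (norm > cfg.edge_threshold).astype(np.float64)
    # blend of two [0, 1] maps spans [0, alpha + beta]; rescale to [0, 1]
    return (cfg.alpha * arr + cfg.beta * norm) / (cfg.alpha + cfg.beta)


def sobel_edges(img: np.ndarray, threshold: float = 0.25,
                gaussian_sigma: float = 1.0) -> np.ndarray:
    """Plain Sobel: thresholded binary edge map (no blend), as {0, 1} floats."""
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"edge threshold must lie in (0, 1), got {threshold}")
    _, _, mag, _ = sobel_fields(img, gaussian_sigma)
    peak = mag.max()
    norm = mag / peak if peak > 0 else mag
    return (norm > threshold).astype(np.float64)


def sharpen(img: np.ndarray, amount: float = 1.0) -> np.ndarray:
    """Unsharp masking ``clip(I + amount * (I - blur(I)))``."""
    arr = as_gray(img)
    if amount < 0:
        raise ParameterError(f"sharpen amount must be >= 0, got {amount}")
    blurred = ndimage.gaussian_filter(arr, 1.0, mode="nearest")
    return np.clip(arr + amount * (arr - blurred), 0.0, 1.0)


def canny(img: np.ndarray, low: float = 0.1, high: float = 0.2) -> np.ndarray:
    """Canny edge mask rendered back to a {0, 1} grayscale image."""
    arr = as_gray(img)
    if not (0.0 < low < high < 1.0):
        raise ParameterError(f"need 0 < low < high < 1, got low={low}, high={high}")
    edges = feature.canny(arr, sigma=1.0, low_threshold=low, high_threshold=high)
    return edges.astype(np.float64)


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Apply the contrast stage then the edge stage.

    ``EnhanceConfig('none', 'none')`` is bit-identical to the input.
    """
    cfg = cfg or EnhanceConfig()
    arr = as_gray(img)
    if cfg.contrast_method == "none" and cfg.edge_method == "none":
        return arr.copy()
    try:
        if cfg.contrast_method == "stretch":
            arr = histogram_stretch(arr)
        elif cfg.contrast_method == "log":
            arr = log_transform(arr, cfg.log_scale)
        elif cfg.contrast_method == "clahe":
            arr = clahe(arr, cfg.clahe_params)
    except ParameterError as exc:
        raise ParameterError(f"contrast stage ({cfg.contrast_method}): {exc}") from exc
    try:
        if cfg.edge_method == "sobel_gradient":
            arr = sobel_gradient(arr, cfg.sobel)
        elif cfg.edge_method == "sobel":
            thr = cfg.sobel.edge_threshold if cfg.sobel.edge_threshold is not None else 0.25
            arr = sobel_edges(arr, thr, cfg.sobel.gaussian_sigma)
        elif cfg.edge_method == "sharpen":
            arr = sharpen(arr, cfg.sharpen_amount)
        elif cfg.edge_method == "canny":
            arr = canny(arr, cfg.canny_low, cfg.canny_high)
    except ParameterError as exc:
        raise ParameterError(f"edge stage ({cfg.edge_method}): {exc}") from exc
    return arr
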