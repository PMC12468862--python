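"""Synthetic frontal chest radiograph phantoms with known geometry.

Each phantom renders the structures the pipeline depends on, in real
radiograph polarity (air dark, fluid/bone/mediastinum bright): a dark
background strip either side of the body, a soft-tissue thorax, two dark
lung fields below a neck/shoulder band, a bright mediastinal column with
a heart silhouette biased toward the image-left lung, rib arcs,
diaphragm domes descending to sharp costophrenic angles, optional
pleural fluid filling the costal recess with a blurred meniscus, plus
Gaussian noise and a linear illumination gradient.

The generator records ground truth (lung-field bounding box, the
diaphragm-wall junction per side, the fluid boundary row and a small
costophrenic recess region) so segmentation and classification can be
scored without clinical data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ParameterError
from .images import save_image
from .segmentation import CropBox

# rendered intensities (original polarity, [0, 1])
_I_BACKGROUND = 0.05
_I_TISSUE = 0.58
_I_LUNG = 0.15
_I_MEDIASTINUM = 0.80
_I_ABDOMEN = 0.70
_I_FLUID = 0.65
_RIB_DELTA = 0.18
_MENISCUS_SIGMA = 2.0  # px; renders the blurred fluid margin


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one phantom radiograph.

    ``fill_level`` is the filled fraction of the hemithorax height (0 for
    a normal study); ``heart_shift`` moves the heart silhouette toward
    the image-left lung as a fraction of image width;
    ``illumination_tilt`` is the total top-to-bottom intensity delta;
    ``jitter`` randomly perturbs the anatomical fractions (±jitter).
    """

    image_size: tuple[int, int] = (256, 256)
    effusion: bool = False
    fill_level: float = 0.0
    side: str = "right"
    heart_shift: float = 0.08
    rib_count: int = 5
    noise_sd: float = 0.02
    illumination_tilt: float = 0.04
    exposure_offset: float = 0.0
    gain: float = 1.0
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 64 or w < 64:
            raise ParameterError("phantoms need at least 64x64 pixels of anatomy")
        if self.effusion:
            if not (0.0 < self.fill_level <= 1.0):
                raise ParameterError("effusion phantoms need fill_level in (0, 1]")
        elif self.fill_level != 0.0:
            raise ParameterError("fill_level must be 0 when effusion is off")
        if self.side not in ("left", "right", "both"):
            raise ParameterError("side must be 'left', 'right' or 'both'")
        if self.noise_sd < 0 or self.rib_count < 0:
            raise ParameterError("noise_sd and rib_count must be >= 0")
        if not (0.0 <= self.heart_shift <= 0.30):
            raise ParameterError(
                f"heart_shift {self.heart_shift} would move the mediastinum off-image")
        if not (0.0 <= self.jitter <= 0.05):
            raise ParameterError("jitter must lie in [0, 0.05]")
        if abs(self.exposure_offset) > 0.2 or not (0.5 <= self.gain <= 2.0):
            raise ParameterError("exposure_offset must lie in [-0.2, 0.2] and "
                                 "gain in [0.5, 2.0]")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth geometry, all in source pixel coordinates."""

    lung_box: CropBox
    junctions: dict  # side -> (row, col) of the costophrenic angle
    recess_boxes: dict  # side -> CropBox of the costal recess region
    fill_rows: dict  # side -> fluid boundary row, or None


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray
    label: str  # "normal" | "effusion"
    truth: PhantomTruth
    config: PhantomConfig


def _jit(rng: np.random.Generator, base: float, jitter: float) -> float:
    return base + (rng.uniform(-jitter, jitter) if jitter > 0 else 0.0)


def generate_phantom(cfg: PhantomConfig | None = None) -> PhantomSample:
    """Render one phantom; bit-reproducible for a given config."""
    cfg = cfg or PhantomConfig()
    h, w = cfg.image_size
    rng = np.random.default_rng(cfg.seed)
    j = cfg.jitter

    # anatomical landmarks as row/col fractions
    # the chest wall must stay thicker than the mask-cleanup closing
    # diameter, or the bright background bridges into the lung field
    bg_w = 0.02
    wall_l = _jit(rng, 0.08, j)          # outer lung-field columns
    wall_r = _jit(rng, 0.92, j)
    med_half = _jit(rng, 0.04, j / 2)    # mediastinal half-width
    apex = _jit(rng, 0.13, j)            # lung apex row
    dome_top = _jit(rng, 0.72, j)        # highest diaphragm point
    junction = _jit(rng, 0.90, j / 2)    # costophrenic angle row

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    r_apex = int(apex * h)
    r_junction = min(int(junction * h), h - 2)
    c_med_lo, c_med_hi = (0.5 - med_half) * w, (0.5 + med_half) * w

    img = np.full((h, w), _I_TISSUE)
    img[:, : int(bg_w * w)] = _I_BACKGROUND
    img[:, w - int(bg_w * w):] = _I_BACKGROUND

    lung_fields = np.zeros((h, w), dtype=bool)
    dome_row_map = np.full(w, h, dtype=int)
    spans = {"left": (wall_l * w, c_med_lo), "right": (c_med_hi, wall_r * w)}
    for side, (c_lo, c_hi) in spans.items():
        mid = 0.5 * (c_lo + c_hi)
        half = 0.5 * (c_hi - c_lo)
        rel = np.clip((cols - mid) / half, -1.0, 1.0)
        # quartic apex line: flat centrally, dipping at both lung margins
        top_line = r_apex + (0.06 * h) * rel ** 4
        # dome: highest mid-lung, descending to the angle at the chest wall
        dome_line = dome_top * h + (r_junction - dome_top * h) * rel ** 2
        in_span = (cols >= c_lo) & (cols < c_hi)
        lung = in_span & (rows >= top_line) & (rows <= dome_line)
        lung_fields |= lung
        sel = in_span[0]
        dome_row_map[sel] = np.minimum(dome_row_map[sel],
                                       dome_line[0, sel].astype(int))

    img[lung_fields] = _I_LUNG

    # abdomen below the diaphragm, inside the body
    body = (img != _I_BACKGROUND)
    below_dome = rows > dome_row_map[None, :]
    abdomen = body & below_dome & (dome_row_map[None, :] < h)
    img[abdomen & ~lung_fields] = _I_ABDOMEN

    # mediastinal column and heart silhouette (biased to the image-left lung)
    med = (cols >= c_med_lo) & (cols < c_med_hi) & (rows >= r_apex) & ~abdomen
    img[med] = _I_MEDIASTINUM
    hc_row, hc_col = 0.62 * h, (0.5 - cfg.heart_shift) * w
    sa_r, sa_c = 0.16 * h, 0.13 * w
    if hc_col - sa_c < 0 or hc_col + sa_c > w:
        raise ParameterError("heart_shift moves the heart silhouette off-image")
    heart = ((rows - hc_row) / sa_r) ** 2 + ((cols - hc_col) / sa_c) ** 2 <= 1.0
    img[heart & ~abdomen & (rows > r_apex)] = _I_MEDIASTINUM

    lung_visible = lung_fields & (img == _I_LUNG)

    # rib arcs: thin bright streaks curving downward across each lung
    if cfg.rib_count > 0:
        for side, (c_lo, c_hi) in spans.items():
            mid, half = 0.5 * (c_lo + c_hi), 0.5 * (c_hi - c_lo)
            rel = np.clip((cols - mid) / half, -1.0, 1.0)
            for k in range(cfg.rib_count):
                base = r_apex + (k + 1) * (dome_top * h - r_apex) / (cfg.rib_count + 1)
                arc = base + 0.03 * h * rel ** 2
                rib = lung_visible & (np.abs(rows - arc) <= 1.0)
                img[rib] = _I_LUNG + _RIB_DELTA

    # ground-truth geometry from the rendered lung fields
    lung_rows = np.nonzero(lung_fields.any(axis=1))[0]
    lung_cols = np.nonzero(lung_fields.any(axis=0))[0]
    lung_box = CropBox(int(lung_cols[0]), int(lung_cols[-1]) + 1,
                       int(lung_rows[0]), int(lung_rows[-1]) + 1)
    junctions, recess_boxes, fill_rows = {}, {}, {}
    recess_h = max(int(0.10 * h), 4)
    recess_w = max(int(0.08 * w), 4)
    for side, (c_lo, c_hi) in spans.items():
        jc = int(c_lo) if side == "left" else int(c_hi) - 1
        junctions[side] = (r_junction, jc)
        if side == "left":
            rb = CropBox(int(c_lo), int(c_lo) + recess_w,
                         r_junction - recess_h, r_junction)
        else:
            rb = CropBox(int(c_hi) - recess_w, int(c_hi),
                         r_junction - recess_h, r_junction)
        recess_boxes[side] = rb
        fill_rows[side] = None

    # pleural fluid: bright homogeneous opacity filling the costal recess
    if cfg.effusion:
        hemi = r_junction - r_apex
        fill_row = int(r_junction - cfg.fill_level * hemi)
        sides = ("left", "right") if cfg.side == "both" else (cfg.side,)
        fluid = np.zeros((h, w), dtype=bool)
        for side in sides:
            c_lo, c_hi = spans[side]
            in_span = (cols >= c_lo) & (cols < c_hi)
            fluid |= lung_fields & in_span & (rows >= fill_row)
            fill_rows[side] = fill_row
        alpha = ndimage.gaussian_filter(fluid.astype(np.float64),
                                        _MENISCUS_SIGMA, mode="nearest")
        alpha *= lung_visible  # fluid stays inside the aerated field
        img = img * (1.0 - alpha) + _I_FLUID * alpha

    # radiographic exposure: global gain around mid-gray plus an offset,
    # emulating inter-patient acquisition variability
    if cfg.gain != 1.0 or cfg.exposure_offset != 0.0:
        img = cfg.gain * (img - 0.5) + 0.5 + cfg.exposure_offset
    if cfg.illumination_tilt != 0.0:
        img = img + cfg.illumination_tilt * (rows / h - 0.5)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    truth = PhantomTruth(lung_box, junctions, recess_boxes, fill_rows)
    label = "effusion" if cfg.effusion else "normal"
    return PhantomSample(img, label, truth, cfg)


def recess_mean(sample: PhantomSample, side: str) -> float:
    """Mean intensity inside the recorded costal-recess region."""
    b = sample.truth.recess_boxes[side]
    return float(sample.image[b.top:b.bottom, b.left:b.right].mean())


def generate_samples(n_per_class: int,
                     base_cfg: PhantomConfig | None = None,
                     seed: int = 0,
                     *,
                     fill_range: tuple[float, float] = (0.2, 0.7),
                     jitter: float = 0.02,
                     exposure_range: tuple[float, float] = (-0.03, 0.03),
                     gain_range: tuple[float, float] = (0.9, 1.1)) -> list[PhantomSample]:
    """Balanced in-memory phantom cohort: n normal + n effusion.

    Per-sample seeds and parameters all derive from ``seed`` through one
    generator (no global state); the fluid level of each effusion case is
    drawn uniformly from ``fill_range``, the affected side is random, and
    every sample gets its own radiographic exposure (offset and gain) to
    emulate inter-patient acquisition variability.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    base_cfg = base_cfg or PhantomConfig()
    master = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    for effusion in (False, True):
        for _ in range(n_per_class):
            sub = int(master.integers(0, 2 ** 31 - 1))
            cfg = replace(
                base_cfg,
                effusion=effusion,
                fill_level=float(master.uniform(*fill_range)) if effusion else 0.0,
                side=str(master.choice(["left", "right"])) if effusion else base_cfg.side,
                exposure_offset=float(master.uniform(*exposure_range)),
                gain=float(master.uniform(*gain_range)),
                jitter=jitter,
                seed=sub,
            )
            samples.append(generate_phantom(cfg))
    return samples


def generate_dataset(n_per_class: int,
                     base_cfg: PhantomConfig | None = None,
                     seed: int = 0,
                     out_dir: str | os.PathLike | None = None,
                     *,
                     fill_range: tuple[float, float] = (0.2, 0.7),
                     jitter: float = 0.02) -> pd.DataFrame:
    """Write a labelled phantom dataset (class-balanced PNGs + CSV manifest).

    The manifest has one row per image: filename, label, per-sample seed,
    fill level, affected side, the truth lung box and the junction rows.
    With ``out_dir=None`` nothing is written and only the manifest (with
    empty filenames) is returned.
    """
    samples = generate_samples(n_per_class, base_cfg, seed,
                               fill_range=fill_range, jitter=jitter)
    records = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    counters = {"normal": 0, "effusion": 0}
    for s in samples:
        idx = counters[s.label]
        counters[s.label] += 1
        fname = f"{s.label}_{idx:04d}.png"
        if out is not None:
            save_image(out / fname, s.image)
        b = s.truth.lung_box
        records.append({
            "filename": fname if out is not None else "",
            "label": s.label,
            "seed": s.config.seed,
            "fill_level": s.config.fill_level,
            "side": s.config.side if s.label == "effusion" else "",
            "box_left": b.left, "box_right": b.right,
            "box_top": b.top, "box_bottom": b.bottom,
            "junction_row_left": s.truth.junctions["left"][0],
            "junction_row_right": s.truth.junctions["right"][0],
        })
    manifest = pd.DataFrame.from_records(records)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
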