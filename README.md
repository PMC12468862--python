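# pleurakit

Pleural effusion — fluid accumulating in the pleural cavity — shows on a
frontal chest radiograph (CXR) as a bright opacity that fills the lower
lung field and *blunts the costophrenic angle*, the normally sharp notch
where the diaphragm dome meets the chest wall. `pleurakit` implements a
classical computer-aided screening pipeline for this sign, aimed at
researchers who want a fully inspectable, deterministic baseline: every
stage is a small, testable function, and a built-in phantom generator
supplies labelled synthetic radiographs with known geometry, so the whole
pipeline can be developed and validated without access to clinical data.

## Pipeline

1. **Preprocess** — grayscale (BT.601 weights), negative transform
   `I_neg = 1 − I_gray` (air-dark lungs become the brightest structures),
   fixed-threshold binarization at 0.5, and binary morphology
   (closing then opening, disk radius 3) to produce a clean lung-field mask.
   Adaptive histogram equalization (AHE/CLAHE) is available as a
   configurable contrast aid.
2. **Segment** — projection profiles of the mask locate the lung fields:
   lateral bounds at the column-profile minima within the outer fifths of
   the image, the upper bound at the first row whose count inside the
   central third of columns exceeds 10 % of the profile maximum, the lower
   bound at the row-profile minimum in the lower half (ties toward the
   bottom, keeping the costophrenic angle in frame). The box is cut from
   the *original* image, the lower half (heart to costophrenic angle) is
   kept and resized to 227×227.
3. **Enhance** — histogram stretching
   `I_out = (I_in − min) / (max − min)` onto the full dynamic range,
   followed by a Sobel gradient blend: Gaussian pre-smoothing (σ = 1),
   the 3×3 Sobel pair G_x/G_y, magnitude `|G| = √(G_x² + G_y²)`
   normalized by its maximum, and `0.5·I + 0.5·|G|`. Alternates (log
   transform, CLAHE, plain thresholded Sobel, unsharp sharpening, Canny)
   share the same interface for method comparisons.
4. **Classify / evaluate** — confusion-matrix metrics
   (accuracy, precision = TP/(TP+FP), recall = TP/(TP+FN), F1) with macro
   averaging, a stratified 80/20 split, stratified k-fold
   cross-validation, and comparison grids over input modes and
   enhancement methods. The reference backend (`tinycnn`) is a fixed
   random-filter conv feature extractor with a logistic readout —
   deterministic and CPU-fast; heavier CNN backbones plug in through the
   same registry.

## Worked example

```python
from pleurakit import (EnhanceConfig, PhantomConfig, enhance,
                       generate_phantom, segment)

sample = generate_phantom(PhantomConfig(seed=11, effusion=True, fill_level=0.5))
roi, box = segment(sample.image)
enhanced = enhance(roi, EnhanceConfig("stretch", "sobel_gradient"))
print(box, box.intersection_over_union(sample.truth.lung_box))
```

prints

```
CropBox(left=3, right=253, top=34, bottom=253) 0.770
```

— the detected lung-field box in source coordinates and its overlap
(intersection over union) with the generator's ground-truth box; 0.77
means the crop contains the lung fields with a modest outward margin.
The scripts in `examples/` each demonstrate one capability and print a
line explaining their numbers; `examples/04_method_comparison.py` for
instance emits a cross-validated table whose whole-lung column (96.00 %
accuracy) clearly beats the single-lung average (73.00 %), because the
whole-lung ROI sees both costophrenic angles.

A thin CLI wraps the same functions:

```sh
pleurakit phantom --n 50 --out data/ --seed 42
pleurakit segment --in data/effusion_0000.png --out roi.png --box-json box.json
pleurakit evaluate --manifest data/manifest.csv --k 5 --save-model model.joblib
pleurakit detect data/ --model model.joblib --out-dir out/
pleurakit reproduce-experiments --out repro/ --seed 42
```

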