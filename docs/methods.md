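# Methods

## The screening problem and the model of it

On a frontal chest radiograph, aerated lung is radiolucent (dark) and
fluid is radiopaque (bright). Pleural fluid pools by gravity in the
costal recess, so the earliest radiographic sign of effusion is blunting
of the costophrenic angle — the sharp wedge where the diaphragm dome
meets the chest wall. The pipeline encodes this prior explicitly: it
crops the radiograph to the band from the heart down to the
costophrenic angles, enhances the brightness and edge structure of that
band, and hands a fixed-size ROI to a classifier. Its core assumptions
are (i) a roughly frontal, adult thorax occupying most of the frame;
(ii) lungs darker than surrounding soft tissue so that a global
threshold on the negative image isolates them; and (iii) class
information concentrated in the lower lung field.

## Stage parameters

| parameter | default | units | rationale |
|---|---|---|---|
| grayscale weights | 0.299/0.587/0.114 | — | BT.601 luma; configurable |
| binarize threshold | 0.5 | intensity fraction | fixed global cut on the negative image |
| morphology | close then open, disk r=3 | px | fills mask pinholes, removes speckle; r=3 tolerates ~1 % salt noise |
| AHE tiles | 8×8, unclipped | tiles | local contrast aid; CLAHE via `clip_limit` |
| lateral search window | outer 1/5 of columns | fraction | chest wall lies in the outer fifths |
| apex band | central 1/3 of columns | fraction | read as a *column* band: the upper lung margin is near the image top, so the restriction must be lateral |
| apex threshold | 10 % of max row count | fraction | first crossing from the top |
| ROI size | 227×227 | px | fixed classifier input |
| Sobel chain | σ=1 smoothing, blend α=β=0.5 | — | optional steps of the gradient algorithm; direction/threshold off |
| train fraction / folds | 0.8 / 5 | — | stratified per class, round-to-nearest |

Intensities are floats in [0, 1] throughout; 8-bit conversion happens
only at file I/O (round half away from zero).

## Numerical choices

* **Binarization ties** go to foreground (`>=`), fixing the duality
  `binarize(invert(I), t) == NOT binarize(I, 1−t)` off tie pixels.
* **Morphology border policy**: pixels outside the raster are background
  for dilation and erosion alike. A consequence is that the cleaned mask
  is always empty in the outer `element_radius` frame; the boundary
  search therefore excludes that frame (`search_margin`), otherwise the
  edge-ward tie-break would snap the lateral bounds to the raster edge.
* **Mask chain ordering**: the fixed 0.5 threshold is applied to the
  negative image directly. Adaptive equalization stretches every locally
  homogeneous tile to the full range by rank, which makes a fixed global
  threshold meaningless after it (verified directly: constant regions
  map to 1.0). `equalize_before_binarize=True` restores the
  equalize-first ordering for data where it helps.
* **Profile tie-breaks**: lateral minima break toward the image edge
  (conservative: lungs stay inside the crop); the lower-bound minimum
  breaks toward the image bottom (the costophrenic angle stays in
  frame). The lower bound is searched on the row profile restricted to
  the detected lateral span, since the vertical crop happens after the
  lateral crop.
* **Sobel convention**: the printed 3×3 kernels slide unflipped
  (correlation), so a left-to-right intensity increase gives positive
  G_x; borders are edge-replicated to avoid spurious gradients at ROI
  margins. The magnitude map is normalized by its own maximum before
  blending so the blend is scale-stable; a constant image has exactly
  zero gradient before that normalization.
* **"Sobel" vs "Sobel gradient"** are implemented as two named variants:
  plain Sobel = thresholded binary edge map (no blend); Sobel gradient =
  magnitude blended with the original (α = β = 0.5).
* **Zero-denominator metrics** are reported as 0 with a warning. Macro
  averaging is the default because on exactly class-balanced data macro
  recall equals accuracy — the pattern visible in balanced benchmark
  tables. A per-positive-class mode is also available.
* **Split rounding** is per class, round-to-nearest with the residual in
  training: 461 per class at 0.8 gives 369/92.
* Degenerate inputs fail loudly: constant images raise a segmentation
  error (no boundary to cross), constant ROIs pass through histogram
  stretching unchanged with a warning.

## The phantom generator

Each phantom renders, in real radiograph polarity: dark background
strips, a soft-tissue thorax with a neck/shoulder band, two dark lung
fields under quartic apex lines, a bright mediastinal column with a
heart ellipse biased toward the image-left lung (which is why left-lung
input underperforms right-lung input in the comparison experiment), rib
arcs, diaphragm domes descending to sharp costophrenic angles at 90 % of
the image height, and — for effusion cases — homogeneous bright fluid
filling the costal recess up to `fill_level` of the hemithorax height
with a Gaussian-blurred meniscus (σ = 2 px) that blunts the angle.
Additive Gaussian noise, a linear illumination tilt, and per-sample
exposure variation (gain about mid-gray plus an offset) emulate
acquisition variability; geometric jitter perturbs the anatomical
fractions. All stochastic draws flow from one seeded generator with
per-sample derived seeds, so cohorts are bit-reproducible.

Exposure variation deserves a note: without it, every phantom shares one
global brightness scale and the absolute ROI mean becomes a perfect
class cue that no real radiograph offers — and that contrast
normalization can only remove. Cohort generation therefore draws
offset ∼ U(−0.03, 0.03) and gain ∼ U(0.9, 1.1) per sample.

What the phantom does *not* model: projection physics, overlapping soft
tissue texture, scoliosis or rotation, pediatric or lateral views,
non-effusion opacities (consolidation, masses), and devices (lines,
pacemakers). Passing phantom tests therefore demonstrates that the
implementation is correct and that the pipeline recovers the geometry
and class signal it was designed around — not that clinical performance
transfers.

## Classifier stage

The reference backend (`tinycnn`) resizes the ROI to 64×64, applies
three fixed random-filter conv/ReLU/max-pool blocks (8/16/32 channels,
He-scaled Gaussian filters from the run seed), concatenates global
average and max pooling with the raw ROI mean and standard deviation,
and fits a logistic-regression readout by L-BFGS to convergence. Fixing
the filters keeps training convex, deterministic, and a few seconds on
CPU for hundreds of phantoms; since the feature stages are label-free,
cross-validation computes features once and refits only the readout per
fold. `learning_rate`, `batch_size` and `epochs` in `TrainConfig`
(defaults 1e-5/32/20) parameterize the SGD loop of optional deep
backbones; named CNN backbones without an installed framework raise a
capability error listing what is available.

## Experiment designs and problem sizes

`reproduce_experiments` runs three cross-validated comparisons at
phantom scale: input modes (left / right / whole lung) on an easy cohort
(noise sd 0.02, fill 0.2–0.7), and the contrast-method and edge-method
grids on a hard cohort (noise sd 0.15, fill 0.05–0.15) — enhancement can
only matter where the task is neither saturated nor at chance. Default
sizes are 60 phantoms per class and k = 5, which keeps a full bundle
around half a minute on one CPU; the acceptance script uses 100 per
class for the headline cross-validation figure.

## Known limitations

* The lower-boundary rule (minimum of the row profile, ties toward the
  bottom) runs to the bottom margin whenever everything below the
  diaphragm is mask-background, so detected boxes systematically extend
  below the true lung field; box IoU on noiseless phantoms sits around
  0.73–0.82 rather than near 1.
* With the fixed-filter reference backend, the full two-stage
  enhancement (stretch + Sobel gradient blend) does not reliably beat
  unenhanced input on hard phantoms: at high noise the gradient map is
  noise-dominated and its max-normalization scales anatomy edges down by
  the largest noise spike. The contrast stage alone (histogram
  stretching vs original) and the whole-lung-versus-single-lung
  orderings do replicate directionally; see the summary emitted by
  `reproduce_experiments` and the `enhancement_win_fraction` value from
  `scripts/acceptance.py` for what a given seed actually produced. A
  backbone that learns its filters could plausibly exploit the enhanced
  edges better; that comparison needs a deep-learning framework and is
  out of scope here.
* The fixed 0.5 threshold presumes sensible exposure; heavily over- or
  under-exposed inputs degrade the mask and hence the crop.
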