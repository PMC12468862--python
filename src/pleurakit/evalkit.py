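"""Classification metrics, data splitting and the experiment harness.

Metrics follow the usual confusion-matrix definitions

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with macro averaging (unweighted mean over the two classes) as the
default reporting convention: on exactly class-balanced data the macro
recall equals the accuracy, which is why accuracy and recall columns
coincide in balanced-benchmark tables.  The harness provides the
stratified 80/20 split, stratified k-fold cross-validation, a pluggable
classifier stage and grid comparisons (input mode, contrast method,
edge method) that emit one table per experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .enhancement import EnhanceConfig, enhance
from .errors import ParameterError
from .segmentation import SegmentationParams, segment
from .tinycnn import TinyCNN, make_backbone


# ---------------------------------------------------------------------------
# confusion counts and metrics

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "ConfusionCounts":
        """Counts with the positive/negative roles exchanged."""
        return ConfusionCounts(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str = "macro"  # or "per_positive_class"

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def confusion_matrix(predicted: Sequence, truth: Sequence, positive) -> ConfusionCounts:
    """Tally binary predictions against ground truth."""
    pred = list(predicted)
    true = list(truth)
    if len(pred) != len(true):
        raise ParameterError(f"length mismatch: {len(pred)} predictions, {len(true)} truths")
    labels = set(pred) | set(true)
    if len(labels) > 2:
        raise ParameterError(f"expected binary labels, got {sorted(map(str, labels))}")
    if positive not in labels:
        labels.add(positive)
    tp = sum(1 for p, t in zip(pred, true) if p == positive and t == positive)
    fp = sum(1 for p, t in zip(pred, true) if p == positive and t != positive)
    fn = sum(1 for p, t in zip(pred, true) if p != positive and t == positive)
    tn = len(pred) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def _single_metrics(cm: ConfusionCounts) -> tuple[float, float, float, float]:
    acc = _safe_div(cm.tp + cm.tn, cm.total, "accuracy")
    prec = _safe_div(cm.tp, cm.tp + cm.fp, "precision")
    rec = _safe_div(cm.tp, cm.tp + cm.fn, "recall")
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return acc, prec, rec, f1


def classification_metrics(cm_by_class, averaging: str = "macro") -> MetricSet:
    """Metrics from confusion counts.

    ``cm_by_class`` is either one ``ConfusionCounts`` (its positive class
    is scored; with macro averaging the swapped matrix supplies the
    second class) or a mapping label -> ``ConfusionCounts``.  Accuracy is
    global under both conventions.
    """
    if isinstance(cm_by_class, ConfusionCounts):
        cms = {"positive": cm_by_class}
        if averaging == "macro":
            cms["negative"] = cm_by_class.swapped()
    else:
        cms = dict(cm_by_class)
    if not cms:
        raise ParameterError("no confusion counts supplied")
    if averaging not in ("macro", "per_positive_class"):
        raise ParameterError("averaging must be 'macro' or 'per_positive_class'")
    per_class = {k: _single_metrics(cm) for k, cm in cms.items()}
    any_cm = next(iter(cms.values()))
    accuracy = _safe_div(any_cm.tp + any_cm.tn, any_cm.total, "accuracy")
    if averaging == "per_positive_class":
        acc, prec, rec, f1 = next(iter(per_class.values()))
        return MetricSet(accuracy, prec, rec, f1, "per_positive_class")
    prec = float(np.mean([m[1] for m in per_class.values()]))
    rec = float(np.mean([m[2] for m in per_class.values()]))
    f1 = float(np.mean([m[3] for m in per_class.values()]))
    return MetricSet(accuracy, prec, rec, f1, "macro")


def metrics_from_labels(predicted: Sequence, truth: Sequence,
                        averaging: str = "macro") -> MetricSet:
    """Convenience wrapper: tally labels per class, then score."""
    labels = sorted(set(truth) | set(predicted))
    cms = {lab: confusion_matrix(predicted, truth, positive=lab) for lab in labels}
    if averaging == "per_positive_class":
        # convention: the lexicographically last label is the positive one
        return classification_metrics(cms[labels[-1]], "per_positive_class")
    return classification_metrics(cms, "macro")


def column_mean_percent(values: Iterable[float], decimals: int = 2) -> float:
    """Mean of printed percent values with half-up rounding to ``decimals``.

    Operates on exact decimal representations of the printed numbers so
    e.g. mean(79.87, 82.62) -> 81.25 (not the float-artifact 81.24).
    """
    vals = [Decimal(str(v)) for v in values]
    if not vals:
        raise ParameterError("no values to average")
    mean = sum(vals) / Decimal(len(vals))
    quantum = Decimal(1).scaleb(-decimals)
    return float(mean.quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# splitting

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.train_fraction < 1.0):
            raise ParameterError("train_fraction must lie in (0, 1)")


def _labels_of(items) -> list:
    if isinstance(items, pd.DataFrame):
        return list(items["label"])
    out = []
    for it in items:
        if hasattr(it, "label"):
            out.append(it.label)
        elif isinstance(it, (tuple, list)) and len(it) == 2:
            out.append(it[1])
        else:
            raise ParameterError("items need a .label attribute or (item, label) form")
    return out


def _take(items, idx: list[int]):
    if isinstance(items, pd.DataFrame):
        return items.iloc[idx].reset_index(drop=True)
    return [items[i] for i in idx]


def stratified_split(manifest, spec: SplitSpec | None = None):
    """Per-class round-to-nearest split into (train, validation).

    With 461 samples per class at train_fraction 0.8 each class yields
    369 training and 92 validation items.  Outputs are disjoint,
    exhaustive and reproducible from ``spec.seed``.
    """
    spec = spec or SplitSpec()
    labels = _labels_of(manifest)
    n = len(labels)
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    if spec.stratified:
        groups: dict = {}
        for i, lab in enumerate(labels):
            groups.setdefault(lab, []).append(i)
        for lab in sorted(groups, key=str):
            idx = groups[lab]
            if len(idx) < 2:
                raise ParameterError(f"class {lab!r} has fewer than 2 samples")
            perm = rng.permutation(len(idx))
            n_train = int(np.floor(len(idx) * spec.train_fraction + 0.5))
            n_train = min(max(n_train, 1), len(idx) - 1)
            chosen = [idx[p] for p in perm]
            train_idx += chosen[:n_train]
            val_idx += chosen[n_train:]
    else:
        perm = rng.permutation(n)
        n_train = int(np.floor(n * spec.train_fraction + 0.5))
        train_idx = list(perm[:n_train])
        val_idx = list(perm[n_train:])
    train_idx.sort()
    val_idx.sort()
    return _take(manifest, train_idx), _take(manifest, val_idx)


# ---------------------------------------------------------------------------
# training and cross-validation

@dataclass(frozen=True)
class TrainConfig:
    """Classifier-stage hyperparameters.

    ``learning_rate``, ``batch_size`` and ``epochs`` parameterize the
    SGD loop of the deep backbones (defaults 1e-5 / 32 / 20); the
    tinycnn reference backend fits its convex logistic readout to
    convergence and ignores them.
    """

    learning_rate: float = 1e-5
    batch_size: int = 32
    epochs: int = 20
    backbone: str = "tinycnn"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ParameterError("training hyperparameters must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end preprocessing configuration fed to the classifier stage."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    enhance: EnhanceConfig = field(default_factory=EnhanceConfig)


def pipeline_transform(image: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """segment -> enhance: radiograph to classifier-ready ROI."""
    roi, _ = segment(image, cfg.segmentation)
    return enhance(roi, cfg.enhance)


@dataclass
class FittedClassifier:
    """A trained model handle: pipeline config + fitted backbone."""

    pipeline: PipelineConfig
    backbone: TinyCNN

    def predict_images(self, images: Sequence[np.ndarray]) -> list[str]:
        rois = [pipeline_transform(im, self.pipeline) for im in images]
        return self.backbone.predict(rois)

    def predict(self, samples) -> list[str]:
        return self.predict_images([s.image for s in samples])


@dataclass(frozen=True)
class FoldReport:
    folds: tuple[MetricSet, ...]
    mean: dict
    sd: dict

    @property
    def k(self) -> int:
        return len(self.folds)

    def summary(self) -> str:
        parts = [f"{name} {100 * self.mean[name]:.2f}% ± {100 * self.sd[name]:.2f}"
                 for name in ("accuracy", "precision", "recall", "f1")]
        return "; ".join(parts)


def train_classifier(train_samples,
                     pipeline_cfg: PipelineConfig | None = None,
                     train_cfg: TrainConfig | None = None,
                     seed: int = 0) -> FittedClassifier:
    """Fit the configured backbone on segmented+enhanced training ROIs."""
    if len(train_samples) == 0:
        raise ParameterError("empty training set")
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    train_cfg = train_cfg or TrainConfig()
    backbone = make_backbone(train_cfg.backbone, seed=seed)
    rois = [pipeline_transform(s.image, pipeline_cfg) for s in train_samples]
    backbone.fit(rois, [s.label for s in train_samples])
    return FittedClassifier(pipeline_cfg, backbone)


def _fold_report(fold_metrics: list[MetricSet]) -> FoldReport:
    names = ("accuracy", "precision", "recall", "f1")
    mean = {n: float(np.mean([m.as_dict()[n] for m in fold_metrics])) for n in names}
    sd = {n: float(np.std([m.as_dict()[n] for m in fold_metrics])) for n in names}
    return FoldReport(tuple(fold_metrics), mean, sd)


def kfold_cross_validate(samples,
                         k: int = 5,
                         pipeline_cfg: PipelineConfig | None = None,
                         train_cfg: TrainConfig | None = None,
                         seed: int = 0,
                         *,
                         features: np.ndarray | None = None) -> FoldReport:
    """Stratified k-fold cross-validation of the full pipeline.

    The segmentation/enhancement/feature stages are label-free, so
    features are computed once per sample and only the readout is
    refitted per fold.  Precomputed ``features`` rows (from the same
    backbone seed) may be passed to share work across grid cells.
    """
    labels = np.asarray(_labels_of(samples))
    if k < 2:
        raise ParameterError("k must be >= 2")
    counts = pd.Series(labels).value_counts()
    if counts.min() < k:
        raise ParameterError(f"need at least k={k} samples per class, got {counts.min()}")
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    train_cfg = train_cfg or TrainConfig()
    backbone = make_backbone(train_cfg.backbone, seed=seed)
    if features is None:
        rois = [pipeline_transform(s.image, pipeline_cfg) for s in samples]
        features = backbone.feature_matrix(rois)
    folds = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_ix, val_ix in skf.split(features, labels):
        fold_model = make_backbone(train_cfg.backbone, seed=seed)
        fold_model.fit_features(features[train_ix], labels[train_ix])
        pred = fold_model.predict_features(features[val_ix])
        folds.append(metrics_from_labels(pred, list(labels[val_ix]), "macro"))
    return _fold_report(folds)


# ---------------------------------------------------------------------------
# comparison experiments

METRIC_ROWS = ("accuracy", "precision", "recall", "f1")


def _percent(x: float) -> float:
    return float(Decimal(str(100 * x)).quantize(Decimal("0.01"),
                                                rounding=ROUND_HALF_UP))


def input_mode_grid(base: PipelineConfig | None = None) -> dict[str, PipelineConfig]:
    """Left-lung / right-lung / whole-lung input comparison cells."""
    base = base or PipelineConfig()
    return {
        "left_lung": replace(base, segmentation=replace(base.segmentation,
                                                        single_lung="left")),
        "right_lung": replace(base, segmentation=replace(base.segmentation,
                                                         single_lung="right")),
        "whole_lungs": replace(base, segmentation=replace(base.segmentation,
                                                          single_lung=None)),
    }


def contrast_grid(base: PipelineConfig | None = None) -> dict[str, PipelineConfig]:
    """Contrast-stage comparison: none / log / CLAHE / stretch (no edge stage)."""
    base = base or PipelineConfig()
    return {name: replace(base, enhance=replace(base.enhance,
                                                contrast_method=method,
                                                edge_method="none"))
            for name, method in (("original", "none"), ("log_transform", "log"),
                                 ("clahe", "clahe"), ("histogram_stretch", "stretch"))}


def edge_grid(base: PipelineConfig | None = None) -> dict[str, PipelineConfig]:
    """Edge-stage comparison on top of histogram stretching."""
    base = base or PipelineConfig()
    out = {}
    for name, method in (("stretch_only", "none"), ("stretch_canny", "canny"),
                         ("stretch_sharpen", "sharpen"),
                         ("stretch_sobel", "sobel"),
                         ("stretch_sobel_gradient", "sobel_gradient")):
        out[name] = replace(base, enhance=replace(base.enhance,
                                                  contrast_method="stretch",
                                                  edge_method=method))
    return out


def run_comparison(samples,
                   grid: dict[str, PipelineConfig],
                   train_cfg: TrainConfig | None = None,
                   k: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """One stratified k-fold run per grid cell.

    Returns a table with metric rows and one column per cell, values as
    printed percentages (half-up, two decimals).  When both single-lung
    columns are present an ``average_lungs`` column (their arithmetic
    column mean) is inserted.  A failing cell becomes a NaN column; the
    remaining cells still run.
    """
    if not grid:
        raise ParameterError("empty comparison grid")
    columns: dict[str, list] = {}
    for name, cfg in grid.items():
        try:
            report = kfold_cross_validate(samples, k, cfg, train_cfg, seed)
            columns[name] = [_percent(report.mean[m]) for m in METRIC_ROWS]
        except Exception as exc:  # pragma: no cover - depends on cell content
            warnings.warn(f"comparison cell {name!r} failed: {exc}", RuntimeWarning)
            columns[name] = [np.nan] * len(METRIC_ROWS)
    table = pd.DataFrame(columns, index=list(METRIC_ROWS))
    if {"left_lung", "right_lung"} <= set(table.columns):
        avg = [column_mean_percent([table.loc[m, "left_lung"],
                                    table.loc[m, "right_lung"]])
               for m in METRIC_ROWS]
        pos = list(table.columns).index("right_lung") + 1
        table.insert(pos, "average_lungs", avg)
    return table
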