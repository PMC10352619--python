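"""Confusion-matrix metrics, overlap scores, k-fold CV and the pipeline.

Classification metrics are computed per class one-vs-rest from the counts
TP, FP, FN, TN and reported in percent:

    sensitivity = TP / (TP + FN)            specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / n             jaccard     = TP / (TP + FP + FN)
    F1 = dice   = 2 TP / (FP + 2 TP + FN)
    MCC = (TP TN - FP FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The same Dice/Jaccard formulas applied to pixel counts score segmentation
overlap. Scalar summaries are unweighted (macro) means over classes;
per-class values are always emitted alongside. Ratios with zero
denominators are reported as 0 with a logged warning.

``run_pipeline`` drives the full five-stage chain on a phantom scan
dataset under stratified k-fold cross-validation: segmentation and feature
extraction run per slice; feature selection and classifier training are
fitted on training folds only (never on test data); predictions are pooled
across folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from . import classifier as clf
from . import phantom as ph
from . import segmentation as seg
from . import texture as tex
from .errors import ParameterError, ValidationError
from .imaging_io import Mask
from .selection import FeatureMatrix, GAConfig, evolve

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    table: np.ndarray  # (C, C); rows = true class, cols = predicted
    tp: np.ndarray  # per-class one-vs-rest counts
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    n_samples: int


@dataclass(frozen=True)
class MetricReport:
    """Per-class and macro metrics, percent scale."""

    per_class: dict  # metric -> array of per-class values
    macro: dict  # metric -> float

    def to_dict(self) -> dict:
        return {
            "per_class": {k: list(map(float, v)) for k, v in self.per_class.items()},
            "macro": {k: float(v) for k, v in self.macro.items()},
        }


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignment: np.ndarray  # fold index per sample
    stratified: bool
    seed: int

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def confusion(
    y_true: Sequence[int], y_pred: Sequence[int], n_classes: int = 5
) -> ConfusionMatrix:
    """C x C table plus one-vs-rest TP/FP/FN/TN per class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred differ in length")
    if y_true.size and (
        min(y_true.min(), y_pred.min()) < 0
        or max(y_true.max(), y_pred.max()) >= n_classes
    ):
        raise ValidationError(f"labels out of range [0, {n_classes})")
    table = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(table, (y_true, y_pred), 1)
    n = int(table.sum())
    tp = np.diag(table).astype(np.int64)
    fp = table.sum(axis=0) - tp
    fn = table.sum(axis=1) - tp
    tn = n - tp - fp - fn
    return ConfusionMatrix(table=table, tp=tp, fp=fp, fn=fn, tn=tn, n_samples=n)


def _ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    num = num.astype(np.float64)
    den = den.astype(np.float64)
    out = np.zeros_like(num)
    ok = den > 0
    if not ok.all():
        log.warning("%s: zero denominator for %d class(es); reporting 0",
                    name, int((~ok).sum()))
    out[ok] = num[ok] / den[ok]
    return out


def classification_metrics(cm: ConfusionMatrix) -> MetricReport:
    """All seven metrics per class one-vs-rest, plus macro averages."""
    tp, fp, fn, tn = (x.astype(np.float64) for x in (cm.tp, cm.fp, cm.fn, cm.tn))
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    acc = _ratio(tp + tn, tp + tn + fp + fn, "accuracy")
    f1 = _ratio(2 * tp, fp + 2 * tp + fn, "f1")
    jac = _ratio(tp, tp + fp + fn, "jaccard")
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _ratio(tp * tn - fp * fn, mcc_den, "mcc")
    per_class = {
        "sensitivity": sens * 100,
        "specificity": spec * 100,
        "accuracy": acc * 100,
        "f1": f1 * 100,
        "dice": f1 * 100,  # identical formulas on identical counts
        "jaccard": jac * 100,
        "mcc": mcc * 100,
    }
    macro = {k: float(v.mean()) for k, v in per_class.items()}
    return MetricReport(per_class=per_class, macro=macro)


def overlap_metrics(pred: Mask, truth: Mask) -> tuple[float, float]:
    """Pixel-level (Dice %, Jaccard %); two empty masks score (100, 100)."""
    if pred.shape != truth.shape:
        raise ValidationError("mask shapes differ")
    p, t = pred.pixels, truth.pixels
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    if tp + fp + fn == 0:
        log.warning("overlap_metrics: both masks empty; scoring 100 by convention")
        return 100.0, 100.0
    dice = 2 * tp / (2 * tp + fp + fn) * 100.0
    jac = tp / (tp + fp + fn) * 100.0
    return dice, jac


def kfold_split(
    labels: Sequence, k: int, stratified: bool = True, seed: int = 0
) -> FoldPlan:
    """Deterministic (shuffled, seeded) fold assignment over the samples."""
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2 or k > n:
        raise ValidationError(f"k={k} invalid for n={n}")
    if stratified:
        counts = np.unique(labels, return_counts=True)[1]
        if k > counts.min():
            raise ValidationError(
                f"stratified k={k} exceeds smallest class count {counts.min()}"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    assignment = np.empty(n, dtype=int)
    for fold, (_tr, te) in enumerate(splits):
        assignment[te] = fold
    return FoldPlan(k=k, assignment=assignment, stratified=stratified, seed=seed)


# --- end-to-end pipeline ---------------------------------------------------

@dataclass
class PipelineConfig:
    """Resolved configuration of one cross-validated phantom run.

    GA and training sizes default to desk scale: the phantom study is 300
    scans of 8 slices, so a 50-chromosome, 30-generation GA and 40 Adam
    epochs are ample (see docs/methods.md).
    """

    n_per_class: int = 60
    n_slices: int = 8
    noise_sigma: float = 0.02
    spec_overrides: dict = field(default_factory=dict)
    k: int = 5
    seg_mode: str = "otsu"
    n_bins: int = 256
    min_object_px: int = 10
    block_grid: int = 4
    t_gltp: float = 0.05
    normalize_hist: bool = True
    select: bool = True
    ga_population: int = 50
    ga_generations: int = 30
    ga_alpha: float = 0.9
    epochs: int = 40
    hidden: int = 64
    batch_size: int = 27
    learning_rate: float = 0.001
    grad_clip: float = 1.0
    seed: int = 0


def _extract_scan_features(
    scans: Sequence[ph.PhantomScan], cfg: PipelineConfig
) -> tuple[np.ndarray, list, list[float], list[float], tuple[str, ...]]:
    """Segment + featurize every slice of every scan.

    Returns (features (n, K, D), labels, per-slice dice, jaccard, names).
    """
    feats = []
    labels = []
    dices: list[float] = []
    jaccs: list[float] = []
    names: tuple[str, ...] = ()
    for scan in scans:
        per_slice = []
        for sample in scan.slices:
            roi = sample.brain_mask
            pred = seg.segment_roi(
                sample.image, mode=cfg.seg_mode, roi=roi,
                min_object_px=cfg.min_object_px, n_bins=cfg.n_bins,
            )
            d, j = overlap_metrics(pred, sample.lesion_mask)
            dices.append(d)
            jaccs.append(j)
            mask = pred if pred.n_set > 0 else roi  # fall back to whole brain
            fv = tex.extract_features(
                sample.image, mask, block_grid=cfg.block_grid,
                t_gltp=cfg.t_gltp, normalize_hist=cfg.normalize_hist,
            )
            per_slice.append(fv.values)
            names = fv.names
        feats.append(np.stack(per_slice))
        labels.append(scan.label.value)
    return np.stack(feats), labels, dices, jaccs, names


def run_pipeline(cfg: PipelineConfig,
                 scans: Optional[Sequence[ph.PhantomScan]] = None) -> dict:
    """Segment -> extract -> select -> train -> predict under k-fold CV.

    Feature selection, feature standardization and classifier training see
    training folds only; the report carries per-fold and pooled metrics,
    segmentation overlap scores, GA traces and the resolved config.
    """
    if scans is None:
        overrides = dict(cfg.spec_overrides)
        overrides.setdefault("noise_sigma", cfg.noise_sigma)
        scans = ph.generate_scan_dataset(
            cfg.n_per_class, base_seed=cfg.seed, n_slices=cfg.n_slices,
            spec_overrides=overrides,
        )
    X_seq, labels, dices, jaccs, feat_names = _extract_scan_features(scans, cfg)
    class_names = tuple(sorted(set(labels)))
    y = np.array([class_names.index(lb) for lb in labels])
    n = len(y)

    plan = kfold_split(y, cfg.k, stratified=True, seed=cfg.seed)
    scan_feats = X_seq.mean(axis=1)  # per-scan summary for selection

    y_pred = np.empty(n, dtype=int)
    fold_reports = []
    traces = []
    n_selected = []
    for fold in range(cfg.k):
        tr, te = plan.fold_indices(fold)
        assert np.intersect1d(tr, te).size == 0  # leakage guard
        mu = scan_feats[tr].mean(axis=0)
        sd = scan_feats[tr].std(axis=0)
        sd[sd == 0] = 1.0

        if cfg.select:
            fm = FeatureMatrix(
                (scan_feats[tr] - mu) / sd, y[tr], feature_names=feat_names)
            ga_cfg = GAConfig(
                population_size=cfg.ga_population,
                generations=cfg.ga_generations,
                alpha=cfg.ga_alpha,
                seed=cfg.seed * 1000 + fold,
            )
            result = evolve(fm, ga_cfg)
            sel = result.selected_indices
            traces.append(result.best_fitness_trace.tolist())
        else:
            sel = np.arange(X_seq.shape[2])
        n_selected.append(int(len(sel)))

        Z = (X_seq - mu) / sd  # per-slice, train-fold statistics
        train_set = [
            clf.SequenceSample(Z[i][:, sel], label=int(y[i]), source_id=str(i))
            for i in tr
        ]
        test_set = [
            clf.SequenceSample(Z[i][:, sel], label=int(y[i]), source_id=str(i))
            for i in te
        ]
        tcfg = clf.TrainConfig(
            epochs=cfg.epochs, hidden=cfg.hidden, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, grad_clip=cfg.grad_clip,
            seed=cfg.seed * 1000 + fold,
        )
        model, _losses = clf.train(train_set, tcfg)
        pred_labels, _probs = clf.predict(model, test_set)
        y_pred[te] = np.array(pred_labels, dtype=int)
        fold_cm = confusion(y[te], y_pred[te], n_classes=len(class_names))
        fold_reports.append(classification_metrics(fold_cm).to_dict())

    pooled_cm = confusion(y, y_pred, n_classes=len(class_names))
    pooled = classification_metrics(pooled_cm)
    return {
        "config": asdict(cfg),
        "class_names": list(class_names),
        "n_scans": n,
        "folds": fold_reports,
        "pooled": pooled.to_dict(),
        "pooled_confusion": pooled_cm.table.tolist(),
        "overall_accuracy": float((y_pred == y).mean() * 100.0),
        "segmentation": {
            "mean_dice": float(np.mean(dices)),
            "mean_jaccard": float(np.mean(jaccs)),
            "n_slices": len(dices),
        },
        "selection": {
            "n_selected_per_fold": n_selected,
            "fitness_traces": traces,
        },
    }
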