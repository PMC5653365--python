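"""Evaluation of fluid masks and volumes against reference masks.

2D masks are scored with the dice coefficient 2TP/(2TP+FP+FN), sensitivity
TP/(TP+FN) and precision TP/(TP+FP); 3D volumes with pooled voxelwise TPR and
FPR (the FPR denominator is reported both over all non-fluid voxels and, when
band masks are supplied, over the non-fluid voxels between the layer curves);
cohorts of volumes with the ordinary least-squares regression of estimated on
true fluid volume (Pearson r).

Empty-denominator conventions: when both masks are empty the dice is 1; when
the prediction is empty but truth is not, precision is reported as 1 with the
``pred_empty`` flag so aggregates stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._exceptions import InvalidInputError

__all__ = ["EvalReport", "VolumeReport", "evaluate_mask", "evaluate_volume",
           "volume_regression", "boundary_mae"]


@dataclass
class EvalReport:
    dice: float
    sensitivity: float
    precision: float
    n_true: int
    n_pred: int
    tp: int
    fp: int
    fn: int
    tn: int
    flags: list = field(default_factory=list)


@dataclass
class VolumeReport:
    tpr: float
    fpr: float                 # denominator: all non-fluid voxels
    fpr_band: float | None     # denominator: non-fluid voxels inside the band
    n_true: int
    n_pred: int
    flags: list = field(default_factory=list)


def _confusion(pred: np.ndarray, truth: np.ndarray):
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise InvalidInputError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return pred, truth, tp, fp, fn, tn


def evaluate_mask(pred: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Confusion counts and dice / sensitivity / precision of a 2D mask."""
    pred, truth, tp, fp, fn, tn = _confusion(pred, truth)
    flags = []
    if tp + fp + fn == 0:
        dice = 1.0
        flags.append("both_empty")
    else:
        dice = 2.0 * tp / (2.0 * tp + fp + fn)
    if tp + fn == 0:
        sensitivity = 1.0
        if "both_empty" not in flags:
            flags.append("truth_empty")
    else:
        sensitivity = tp / (tp + fn)
    if tp + fp == 0:
        precision = 1.0
        if "both_empty" not in flags:
            flags.append("pred_empty")
    else:
        precision = tp / (tp + fp)
    return EvalReport(dice=dice, sensitivity=sensitivity, precision=precision,
                      n_true=tp + fn, n_pred=tp + fp,
                      tp=tp, fp=fp, fn=fn, tn=tn, flags=flags)


def evaluate_volume(preds, truths, band_masks=None) -> VolumeReport:
    """Pooled voxelwise TPR / FPR over an aligned stack of masks."""
    preds = list(preds)
    truths = list(truths)
    if len(preds) != len(truths) or not preds:
        raise InvalidInputError("need equally many (>= 1) predicted and true masks")
    pred = np.stack([np.asarray(p).astype(bool) for p in preds])
    truth = np.stack([np.asarray(t).astype(bool) for t in truths])
    _, _, tp, fp, fn, tn = _confusion(pred, truth)
    flags = []
    tpr = tp / (tp + fn) if tp + fn else 1.0
    if tp + fn == 0:
        flags.append("truth_empty")
    fpr = fp / (fp + tn) if fp + tn else 0.0
    fpr_band = None
    if band_masks is not None:
        band = np.stack([np.asarray(b).astype(bool) for b in band_masks])
        if band.shape != pred.shape:
            raise InvalidInputError("band masks must match the volume shape")
        fp_b = int(np.count_nonzero(pred & ~truth & band))
        tn_b = int(np.count_nonzero(~pred & ~truth & band))
        fpr_band = fp_b / (fp_b + tn_b) if fp_b + tn_b else 0.0
    return VolumeReport(tpr=tpr, fpr=fpr, fpr_band=fpr_band,
                        n_true=tp + fn, n_pred=tp + fp, flags=flags)


def volume_regression(estimated, true):
    """OLS of estimated on true per-volume fluid volume across a cohort.

    Returns ``(r, slope, intercept)``; with fewer than two volumes the
    regression is undefined and ``(None, None, None)`` is returned.
    """
    est = np.asarray(estimated, dtype=np.float64)
    tru = np.asarray(true, dtype=np.float64)
    if est.shape != tru.shape:
        raise InvalidInputError("estimated and true volume lists must align")
    if est.size < 2:
        return None, None, None
    fit = stats.linregress(tru, est)
    return float(fit.rvalue), float(fit.slope), float(fit.intercept)


def boundary_mae(pred_curve, true_curve) -> float:
    """Mean absolute per-column row error between two boundary curves."""
    p = np.asarray(getattr(pred_curve, "rows", pred_curve), dtype=np.float64)
    t = np.asarray(getattr(true_curve, "rows", true_curve), dtype=np.float64)
    if p.shape != t.shape:
        raise InvalidInputError("curves must cover the same columns")
    return float(np.abs(p - t).mean())
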