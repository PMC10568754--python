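"""Pixel-level evaluation: binary masks and the full confusion-matrix suite.

Label images are binarized (any nonzero label -> foreground) and compared
pixel by pixel, yielding a complete TP/FP/TN/FN confusion matrix — unlike
the ROI level, true negatives exist here, so a larger metric suite is
available.  All counts are exact integers; metric ratios with zero
denominators are NaN (undefined), never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .regions import as_label_image

#: Pixel-level metric names, in emission order.
PIXEL_METRIC_NAMES = (
    "accuracy",
    "precision",
    "recall",
    "specificity",
    "fdr",
    "fnr",
    "fpr",
    "npv",
    "false_omission_rate",
    "f1",
    "iou",
    "mcc",
    "cohen_kappa",
    "fowlkes_mallows",
    "balanced_accuracy",
    "informedness",
    "markedness",
    "positive_likelihood_ratio",
    "negative_likelihood_ratio",
    "prevalence",
    "g_mean",
    "prevalence_threshold",
)


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def binarize(img) -> np.ndarray:
    """Foreground mask: 1 wherever the label is nonzero, else 0 (uint8)."""
    return (as_label_image(img) > 0).astype(np.uint8)


def pixel_confusion(gt, pred) -> PixelConfusion:
    """Tabulate per-pixel TP/FP/TN/FN between two binary masks.

    TP: both 1.  FP: prediction 1, ground truth 0.  TN: both 0.
    FN: prediction 0, ground truth 1.
    """
    g = np.asarray(gt).astype(bool)
    p = np.asarray(pred).astype(bool)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: gt {g.shape} vs pred {p.shape}")
    tp = int(np.count_nonzero(g & p))
    fp = int(np.count_nonzero(~g & p))
    fn = int(np.count_nonzero(g & ~p))
    tn = g.size - tp - fp - fn
    return PixelConfusion(tp=tp, fp=fp, tn=tn, fn=fn)


def _div(num, den) -> float:
    return num / den if den != 0 else float("nan")


def _mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    # exact-integer path: |MCC| = 1 iff num^2 equals the denominator product,
    # so perfect (anti-)correlation is returned as exactly +/-1.0
    num = tp * tn - fp * fn
    den2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if den2 == 0:
        return float("nan")
    if num * num == den2:
        return math.copysign(1.0, num) if num != 0 else 0.0
    return num / math.sqrt(den2)


def pixel_metrics(c: PixelConfusion) -> dict[str, float]:
    """Full pixel-metric suite (see :data:`PIXEL_METRIC_NAMES`).

    Includes Matthews correlation coefficient and Cohen's kappa computed
    from the marginals; every zero-denominator case yields NaN.
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    n = c.total
    if n < 1:
        raise ValueError("empty confusion matrix")

    precision = _div(tp, tp + fp)
    recall = _div(tp, tp + fn)
    specificity = _div(tn, tn + fp)
    npv = _div(tn, tn + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)

    p_o = (tp + tn) / n
    p_e = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = _div(p_o - p_e, 1.0 - p_e)

    fmi = float("nan")
    if not (math.isnan(precision) or math.isnan(recall)):
        fmi = math.sqrt(precision * recall)
    bal_acc = float("nan")
    if not (math.isnan(recall) or math.isnan(specificity)):
        bal_acc = 0.5 * (recall + specificity)
    informedness = float("nan")
    if not (math.isnan(recall) or math.isnan(specificity)):
        informedness = recall + specificity - 1.0
    markedness = float("nan")
    if not (math.isnan(precision) or math.isnan(npv)):
        markedness = precision + npv - 1.0
    fpr = _div(fp, fp + tn)
    fnr = _div(fn, fn + tp)
    plr = float("nan")
    if not (math.isnan(recall) or math.isnan(fpr)) and fpr != 0:
        plr = recall / fpr
    nlr = float("nan")
    if not (math.isnan(fnr) or math.isnan(specificity)) and specificity != 0:
        nlr = fnr / specificity
    g_mean = float("nan")
    if not (math.isnan(recall) or math.isnan(specificity)):
        g_mean = math.sqrt(recall * specificity)
    pt = float("nan")
    if not (math.isnan(recall) or math.isnan(fpr)) and recall != fpr:
        pt = (math.sqrt(recall * fpr) - fpr) / (recall - fpr)

    return {
        "accuracy": p_o,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "fdr": _div(fp, fp + tp),
        "fnr": fnr,
        "fpr": fpr,
        "npv": npv,
        "false_omission_rate": _div(fn, fn + tn),
        "f1": f1,
        "iou": _div(tp, tp + fp + fn),
        "mcc": _mcc(tp, fp, tn, fn),
        "cohen_kappa": kappa,
        "fowlkes_mallows": fmi,
        "balanced_accuracy": bal_acc,
        "informedness": informedness,
        "markedness": markedness,
        "positive_likelihood_ratio": plr,
        "negative_likelihood_ratio": nlr,
        "prevalence": (tp + fn) / n,
        "g_mean": g_mean,
        "prevalence_threshold": pt,
    }
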