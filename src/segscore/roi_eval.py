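"""ROI-level evaluation: centroid matching and the pseudo confusion matrix.

Each ground-truth ROI is compared with the predicted ROIs by centroid
distance: a predicted region is a candidate match when its centroid lies
strictly within half the minor feret diameter of the ground-truth region.
Because all background pixels form a single "negative object", there is no
true-negative cell — hence a *pseudo* confusion matrix of TP/FP/FN only.

Matching sweeps ground-truth regions in ascending label order.  For each GT
region, every not-yet-claimed candidate is considered: exactly one candidate
is a plain true positive; two or more candidates mean the GT region is
over-segmented (still counted as TP, with the multiplicity recorded); no
candidate is a false negative.  All candidates are then deleted from the
predicted pool, and whatever predictions remain after the sweep are false
positives.  Under-segmentation is assessed against the original (pre-
deletion) sets so it does not depend on sweep order: a predicted region
whose centroid satisfies the match criterion for k >= 2 ground-truth regions
contributes k to the under-segmented tally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .regions import Region

#: ROI-level metric names (all TN-free), in emission order.
ROI_METRIC_NAMES = (
    "precision",
    "recall",
    "f1",
    "fdr",
    "fnr",
    "iou",
    "fowlkes_mallows",
    "over_segmentation_rate",
    "under_segmentation_rate",
)


@dataclass(frozen=True)
class RoiConfusion:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    over_segmented: int = 0
    under_segmented: int = 0


@dataclass
class MatchTable:
    """Match bookkeeping: GT label -> list of matched predicted labels, plus
    the predicted labels left unmatched after the sweep."""

    matches: dict[int, list[int]] = field(default_factory=dict)
    unmatched_pred: list[int] = field(default_factory=list)


def _dist(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def match_rois(
    gt: list[Region], pred: list[Region]
) -> tuple[MatchTable, RoiConfusion]:
    """Match predicted to ground-truth regions and tabulate the pseudo
    confusion matrix.

    Inputs are assumed already size-filtered (see
    :func:`segscore.regions.extract_regions`).  Empty lists are allowed.
    """
    gt_sorted = sorted(gt, key=lambda r: r.label)
    pool = {p.label: p for p in sorted(pred, key=lambda r: r.label)}

    table = MatchTable()
    tp = fn = over = 0
    for g in gt_sorted:
        radius = 0.5 * g.minor_feret
        cands = [
            p.label for p in pool.values() if _dist(p.centroid, g.centroid) < radius
        ]
        table.matches[g.label] = cands
        if not cands:
            fn += 1
        else:
            tp += 1
            if len(cands) > 1:
                over += 1
            for lab in cands:
                del pool[lab]
    table.unmatched_pred = sorted(pool)
    fp = len(pool)

    # under-segmentation against the original, pre-deletion GT set
    under = 0
    for p in pred:
        hits = sum(
            1 for g in gt_sorted if _dist(p.centroid, g.centroid) < 0.5 * g.minor_feret
        )
        if hits >= 2:
            under += hits
    return table, RoiConfusion(tp=tp, fp=fp, fn=fn, over_segmented=over, under_segmented=under)


def _div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def roi_metrics(c: RoiConfusion) -> dict[str, float]:
    """All TN-free metrics from the pseudo confusion matrix.

    0/0 quotients are reported as NaN (undefined), never coerced to zero;
    downstream selection handles missing values explicitly.
    """
    precision = _div(c.tp, c.tp + c.fp)
    recall = _div(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    fmi = float("nan")
    if not (math.isnan(precision) or math.isnan(recall)):
        fmi = math.sqrt(precision * recall)
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "fdr": _div(c.fp, c.fp + c.tp),
        "fnr": _div(c.fn, c.fn + c.tp),
        "iou": _div(c.tp, c.tp + c.fp + c.fn),
        "fowlkes_mallows": fmi,
        "over_segmentation_rate": _div(c.over_segmented, c.tp + c.fn),
        "under_segmentation_rate": _div(c.under_segmented, c.tp + c.fn),
    }
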