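"""Image reading/writing, pair discovery, and the umbrella pipeline.

Label and intensity images are single-channel TIFF (preferred) or PNG.
Ground-truth and predicted files are paired by filename stem; unmatched
files are reported as orphans, never silently dropped.  ``run_all`` chains
region extraction, ROI-, pixel-, and feature-level evaluation per pair into
one wide metric table suitable for PCA metric selection; metric columns are
prefixed ``roi_`` / ``pixel_`` / ``feat_<feature>_`` so names never collide
across levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from . import feature_eval, pixel_eval, roi_eval
from .regions import DEFAULT_MIN_AREA, FEATURE_NAMES, as_label_image, extract_regions

logger = logging.getLogger("segscore")

_TIFF_SUFFIXES = {".tif", ".tiff"}
IMAGE_SUFFIXES = _TIFF_SUFFIXES | {".png"}

#: Features evaluated by default at the feature level: the morphology /
#: intensity subset reported for model comparison.
DEFAULT_FEATURES = ("area", "perimeter", "mean_intensity", "solidity")

#: Fixed significant digits for CSV output, so re-runs are byte-identical.
CSV_FLOAT_FORMAT = "%.6g"


def read_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2D image, got shape {arr.shape}")
    return arr


def read_label_image(path) -> np.ndarray:
    return as_label_image(read_image(path))


def read_intensity_image(path) -> np.ndarray:
    return read_image(path).astype(float)


def write_label_image(path, arr) -> None:
    path = Path(path)
    arr = as_label_image(arr)
    dtype = np.uint16 if arr.max() < 2**16 else np.uint32
    out = arr.astype(dtype)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def write_intensity_image(path, arr) -> None:
    path = Path(path)
    arr = np.asarray(arr, dtype=np.float32)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, np.clip(arr, 0, 65535).astype(np.uint16))


@dataclass(frozen=True)
class Pair:
    pair_id: str
    gt: Path
    pred: Path
    intensity: Path | None = None


@dataclass
class PairManifest:
    pairs: list[Pair] = field(default_factory=list)
    gt_orphans: list[Path] = field(default_factory=list)
    pred_orphans: list[Path] = field(default_factory=list)


def _stem_map(directory: Path, pattern: str) -> dict[str, Path]:
    files = sorted(
        p for p in Path(directory).glob(pattern) if p.suffix.lower() in IMAGE_SUFFIXES
    )
    return {p.stem: p for p in files}


def discover_pairs(
    gt_dir, pred_dir, intensity_dir=None, pattern: str = "*"
) -> PairManifest:
    """Pair ground-truth and predicted images by filename stem.

    Raises ``ValueError`` when no pair is found; orphans on either side are
    recorded in the manifest and logged.
    """
    gt_map = _stem_map(Path(gt_dir), pattern)
    pred_map = _stem_map(Path(pred_dir), pattern)
    int_map = _stem_map(Path(intensity_dir), pattern) if intensity_dir else {}

    manifest = PairManifest()
    for stem in sorted(gt_map):
        if stem in pred_map:
            manifest.pairs.append(
                Pair(
                    pair_id=stem,
                    gt=gt_map[stem],
                    pred=pred_map[stem],
                    intensity=int_map.get(stem),
                )
            )
        else:
            manifest.gt_orphans.append(gt_map[stem])
    manifest.pred_orphans = [pred_map[s] for s in sorted(set(pred_map) - set(gt_map))]
    for orphan in manifest.gt_orphans + manifest.pred_orphans:
        logger.warning("unpaired image: %s", orphan)
    if not manifest.pairs:
        raise ValueError(f"no ground-truth/prediction pairs found in {gt_dir} vs {pred_dir}")
    return manifest


def suite_metric_names() -> dict[str, tuple[str, ...]]:
    """The frozen metric registry, per level (prefixes applied)."""
    return {
        "roi": tuple(f"roi_{m}" for m in roi_eval.ROI_METRIC_NAMES),
        "pixel": tuple(f"pixel_{m}" for m in pixel_eval.PIXEL_METRIC_NAMES),
        "feature": tuple(feature_eval.DISTRIBUTION_METRIC_NAMES),
    }


def suite_size() -> int:
    """Total number of distinct metrics across the three levels."""
    names = suite_metric_names()
    return sum(len(v) for v in names.values())


def evaluate_pair(
    gt_img,
    pred_img,
    intensity=None,
    min_area: int = DEFAULT_MIN_AREA,
    features: Sequence[str] = DEFAULT_FEATURES,
    metrics: Sequence[str] | None = None,
) -> dict[str, float]:
    """All three evaluation levels on one image pair, as one wide row."""
    row: dict[str, float] = {}

    gt_regions = extract_regions(gt_img, min_area=min_area)
    pred_regions = extract_regions(pred_img, min_area=min_area)
    _, conf = roi_eval.match_rois(gt_regions, pred_regions)
    row.update(
        roi_tp=conf.tp,
        roi_fp=conf.fp,
        roi_fn=conf.fn,
        roi_over_segmented=conf.over_segmented,
        roi_under_segmented=conf.under_segmented,
    )
    if conf.tp + conf.fp + conf.fn >= 1:
        for name, value in roi_eval.roi_metrics(conf).items():
            row[f"roi_{name}"] = value
    else:
        for name in roi_eval.ROI_METRIC_NAMES:
            row[f"roi_{name}"] = float("nan")

    pconf = pixel_eval.pixel_confusion(
        pixel_eval.binarize(gt_img), pixel_eval.binarize(pred_img)
    )
    row.update(pixel_tp=pconf.tp, pixel_fp=pconf.fp, pixel_tn=pconf.tn, pixel_fn=pconf.fn)
    for name, value in pixel_eval.pixel_metrics(pconf).items():
        row[f"pixel_{name}"] = value

    for rec in feature_eval.evaluate_feature_level(
        gt_img,
        pred_img,
        intensity=intensity,
        feature_names=features,
        metric_names=metrics,
        min_area=min_area,
    ):
        row[f"feat_{rec['feature']}_{rec['metric']}"] = rec["value"]
    return row


def run_all(
    manifest: PairManifest,
    min_area: int = DEFAULT_MIN_AREA,
    features: Sequence[str] = DEFAULT_FEATURES,
    metrics: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Evaluate every pair in the manifest into one wide metric table.

    Unreadable pairs are skipped with the reason recorded in the returned
    failure list (pair id, message) and logged; the table indexes rows by
    pair id.
    """
    rows: dict[str, dict[str, float]] = {}
    failures: list[tuple[str, str]] = []
    for pair in manifest.pairs:
        try:
            gt = read_label_image(pair.gt)
            pred = read_label_image(pair.pred)
            intensity = read_intensity_image(pair.intensity) if pair.intensity else None
            rows[pair.pair_id] = evaluate_pair(
                gt, pred, intensity, min_area=min_area, features=features, metrics=metrics
            )
        except Exception as exc:  # noqa: BLE001 - pipeline must report, not die
            logger.error("pair %s failed: %s", pair.pair_id, exc)
            failures.append((pair.pair_id, str(exc)))
    if not rows:
        raise ValueError("every pair in the manifest failed to evaluate")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "pair_id"
    return table, failures


def write_table(table: pd.DataFrame, path) -> None:
    """Write a metric table with fixed float formatting (reproducible bytes)."""
    pd.DataFrame(table).to_csv(path, float_format=CSV_FLOAT_FORMAT)
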