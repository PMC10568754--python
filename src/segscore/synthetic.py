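"""Synthetic label/intensity scenes and controlled segmentation corruptions.

The generator places non-overlapping elliptical regions (nucleus-like
shapes; aspect ratio capped at 2 so that bisecting a region leaves both
half-centroids inside the centroid-matching radius) on a blank frame, plus
a matching intensity channel of Gaussian foreground/background levels.
Controlled corruptions — drop, add, split, merge, erode, dilate, shift —
emulate the error modes of real segmenters (missed objects, spurious
detections, over- and under-segmentation, boundary shrink/growth,
misregistration) with analytically known metric consequences, e.g. dropping
``k`` of ``n`` regions gives ROI recall exactly ``(n - k) / n``.

All randomness flows through a single ``numpy.random.default_rng`` seeded
from the spec, so every scene and perturbation is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .regions import as_label_image


class PackingError(RuntimeError):
    """Raised when a feasible non-overlapping placement cannot be found."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``min_separation`` bounds pairwise *centroid* distances from below (in
    addition to masks being strictly disjoint); ``intensity_model`` is
    ``(foreground mean, background mean, noise sd)`` in arbitrary gray
    levels.  Defaults emulate a sparse field of nucleus-sized objects.
    """

    image_size: tuple[int, int] = (192, 192)
    n_regions: int = 15
    radius_range: tuple[float, float] = (4.0, 8.0)
    min_separation: float = 18.0
    intensity_model: tuple[float, float, float] = (200.0, 40.0, 8.0)
    seed: int = 0
    #: rejection-sampling budget: attempts per requested region
    attempts_per_region: int = 500


@dataclass(frozen=True)
class PerturbationSpec:
    """One corruption: ``kind`` in {drop, add, split, merge, erode, dilate,
    shift}; ``magnitude`` is a count (drop/add), a pixel radius
    (erode/dilate), or a ``(drow, dcol)`` displacement (shift); ``target_labels``
    optionally pins the affected regions."""

    kind: str
    magnitude: object = 1
    target_labels: tuple[int, ...] | None = None
    seed: int = 0


def _ellipse_coords(center, a, b, theta, shape):
    """Pixel (row, col) coordinates inside a rotated ellipse."""
    cr, cc = center
    rmax = max(a, b)
    r0, r1 = int(np.floor(cr - rmax)) - 1, int(np.ceil(cr + rmax)) + 2
    c0, c1 = int(np.floor(cc - rmax)) - 1, int(np.ceil(cc + rmax)) + 2
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, shape[0]), min(c1, shape[1])
    rr, cc_ = np.mgrid[r0:r1, c0:c1]
    dr, dc = rr - cr, cc_ - cc
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.stack([rr[inside], cc_[inside]], axis=1)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate a (label image, intensity image) pair per ``spec``.

    Regions get labels ``1..n`` in placement order.  Raises
    :class:`PackingError` when the rejection-sampling budget is exhausted,
    naming the violated constraint.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    labels = np.zeros((h, w), dtype=np.int32)
    rmin, rmax = spec.radius_range
    if rmin > rmax or rmin <= 0:
        raise ValueError("radius_range must be a positive increasing interval")

    centers: list[tuple[float, float]] = []
    budget = spec.attempts_per_region * max(1, spec.n_regions)
    attempts = 0
    placed = 0
    while placed < spec.n_regions:
        if attempts >= budget:
            raise PackingError(
                f"could not place region {placed + 1}/{spec.n_regions} within "
                f"{budget} attempts (min_separation={spec.min_separation}, "
                f"radius_range={spec.radius_range}, image_size={spec.image_size})"
            )
        attempts += 1
        a = rng.uniform(rmin, rmax)
        b = rng.uniform(rmin, rmax)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b) + 1.0
        if 2 * margin >= min(h, w):
            raise PackingError("radius_range too large for image_size")
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        if any(np.hypot(cr - pr, cc - pc) <= spec.min_separation for pr, pc in centers):
            continue
        coords = _ellipse_coords((cr, cc), a, b, theta, (h, w))
        if coords.shape[0] < 3:
            continue
        if np.any(labels[coords[:, 0], coords[:, 1]] != 0):
            continue
        placed += 1
        labels[coords[:, 0], coords[:, 1]] = placed
        centers.append((cr, cc))

    fg_mean, bg_mean, sd = spec.intensity_model
    intensity = rng.normal(bg_mean, sd, size=(h, w))
    fg = labels > 0
    intensity[fg] = rng.normal(fg_mean, sd, size=int(fg.sum()))
    return labels, np.clip(intensity, 0.0, None).astype(np.float32)


def _pick_labels(rng, present, k, target_labels):
    if target_labels is not None:
        chosen = list(target_labels)[:k] if k is not None else list(target_labels)
        missing = set(chosen) - set(present)
        if missing:
            raise ValueError(f"target labels not present in image: {sorted(missing)}")
        return chosen
    if k is None or k >= len(present):
        return list(present)
    return sorted(rng.choice(present, size=k, replace=False).tolist())


def perturb(img, p: PerturbationSpec) -> np.ndarray:
    """Apply one controlled corruption; the input image is never modified."""
    arr = as_label_image(img).copy()
    rng = np.random.default_rng(p.seed)
    present = [int(v) for v in np.unique(arr) if v != 0]
    kind = p.kind

    if kind == "drop":
        k = int(p.magnitude)
        if k > len(present):
            raise ValueError(f"cannot drop {k} of {len(present)} regions")
        for lab in _pick_labels(rng, present, k, p.target_labels):
            arr[arr == lab] = 0
        return arr

    if kind == "add":
        return _add_blobs(arr, int(p.magnitude), rng)

    if kind == "split":
        (lab,) = _pick_labels(rng, present, 1, p.target_labels)
        return _split_region(arr, lab)

    if kind == "merge":
        if len(present) < 2:
            raise ValueError("merge requires at least two regions")
        if p.target_labels is not None:
            la, lb = _pick_labels(rng, present, 2, p.target_labels)
        else:
            la, lb = _closest_pair(arr, present)
        arr[arr == max(la, lb)] = min(la, lb)
        return arr

    if kind in ("erode", "dilate"):
        return _morph(arr, present, kind, int(p.magnitude), p.target_labels, rng)

    if kind == "shift":
        dr, dc = (int(v) for v in p.magnitude)
        targets = set(_pick_labels(rng, present, None, p.target_labels))
        out = np.zeros_like(arr)
        for lab in present:
            if lab not in targets:
                out[arr == lab] = lab
        for lab in present:
            if lab in targets:
                coords = np.argwhere(arr == lab) + (dr, dc)
                keep = (
                    (coords[:, 0] >= 0)
                    & (coords[:, 0] < arr.shape[0])
                    & (coords[:, 1] >= 0)
                    & (coords[:, 1] < arr.shape[1])
                )
                coords = coords[keep]
                free = out[coords[:, 0], coords[:, 1]] == 0
                coords = coords[free]  # collision pixels are lost to the stationary region
                out[coords[:, 0], coords[:, 1]] = lab
        return out

    raise ValueError(
        f"unknown perturbation kind {kind!r}; expected one of "
        "drop/add/split/merge/erode/dilate/shift"
    )


def _add_blobs(arr, m, rng, clearance: float = 2.0, max_attempts: int = 20000):
    """Inject ``m`` spurious elliptical blobs disjoint from all existing
    foreground, with centers kept outside every existing region's match
    radius so added blobs never steal a centroid match."""
    from .regions import extract_regions

    regions = extract_regions(arr, min_area=1)
    keepout = [(r.centroid, r.minor_feret) for r in regions]
    next_label = int(arr.max()) + 1
    h, w = arr.shape
    added = 0
    attempts = 0
    while added < m:
        if attempts >= max_attempts:
            raise PackingError(f"could not place spurious blob {added + 1}/{m}")
        attempts += 1
        a = rng.uniform(2.0, 4.0)
        b = rng.uniform(2.0, 4.0)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b) + 1.0
        cr = rng.uniform(margin, h - 1 - margin)
        cc = rng.uniform(margin, w - 1 - margin)
        if any(
            np.hypot(cr - ctr[0], cc - ctr[1]) <= feret + clearance
            for ctr, feret in keepout
        ):
            continue
        coords = _ellipse_coords((cr, cc), a + clearance, b + clearance, theta, (h, w))
        if np.any(arr[coords[:, 0], coords[:, 1]] != 0):
            continue
        coords = _ellipse_coords((cr, cc), a, b, theta, (h, w))
        if coords.shape[0] < 3:
            continue
        arr[coords[:, 0], coords[:, 1]] = next_label
        keepout.append(((cr, cc), 2 * max(a, b)))
        next_label += 1
        added += 1
    return arr


def _split_region(arr, lab):
    """Bisect region ``lab`` across its centroid, perpendicular to its major
    axis, assigning one half a fresh label."""
    coords = np.argwhere(arr == lab)
    if coords.shape[0] < 2:
        raise ValueError(f"region {lab} too small to split")
    mu = coords - coords.mean(axis=0)
    cov = mu.T.astype(float) @ mu / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    proj = mu @ major
    half = proj > 0
    if not half.any() or half.all():
        half = proj >= np.median(proj)  # degenerate: split at the median
    if not half.any() or half.all():
        raise ValueError(f"region {lab} could not be bisected")
    new_label = int(arr.max()) + 1
    sel = coords[half]
    arr[sel[:, 0], sel[:, 1]] = new_label
    return arr


def _closest_pair(arr, present):
    centroids = {
        lab: np.argwhere(arr == lab).mean(axis=0) for lab in present
    }
    best, best_d = None, np.inf
    for i, la in enumerate(present):
        for lb in present[i + 1 :]:
            d = float(np.hypot(*(centroids[la] - centroids[lb])))
            if d < best_d:
                best, best_d = (la, lb), d
    return best


def _morph(arr, present, kind, magnitude, target_labels, rng):
    if magnitude < 0:
        raise ValueError("morphology magnitude must be >= 0")
    if magnitude == 0:
        return arr
    targets = set(_pick_labels(rng, present, None, target_labels))
    out = arr.copy()
    for lab in present:
        if lab not in targets:
            continue
        mask = arr == lab
        if kind == "erode":
            new = ndimage.binary_erosion(mask, iterations=magnitude)
            out[mask & ~new] = 0
        else:
            new = ndimage.binary_dilation(mask, iterations=magnitude)
            grown = new & ~mask
            collision = grown & (out > 0) & (out != lab)
            if collision.any():
                warnings.warn(
                    f"dilate: skipping region {lab} (would collide with a neighbor)",
                    stacklevel=2,
                )
                continue
            out[grown] = lab
    return out
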