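"""Region extraction and per-region geometry for labeled segmentation images.

A label image is a 2D integer array where 0 is background and each positive
value identifies one region of interest (ROI), e.g. one nucleus.  Regions are
defined by shared label value, not by pixel connectivity: a fragmented label
is still a single region, because in an instance map the label identity is
authoritative.

Geometry conventions (fixed so results are bit-reproducible):

* Coordinates are 0-based ``(row, col)``; pixel centers sit at integer
  coordinates, so a pixel occupies the unit square ``[r-0.5, r+0.5] x
  [c-0.5, c+0.5]``.
* The centroid is the unweighted mean of pixel-center coordinates.
* Feret diameters are measured on the convex hull of the pixel *corner*
  points (pixels treated as unit squares).  The minor feret is the minimum
  caliper width over all rotation angles; this is strictly positive even for
  1-pixel-thick regions, which matters because half the minor feret is used
  as a matching radius downstream and must never be zero.
* The perimeter is the count of exposed unit pixel edges (4-connectivity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np
from scipy.spatial import ConvexHull

#: Regions smaller than this many pixels are ignored everywhere ("size is
#: greater than two pixels" -> area >= 3).
DEFAULT_MIN_AREA = 3

#: Names of the per-region features, in emission order.  Intensity features
#: are NaN when no intensity image is supplied.
FEATURE_NAMES = (
    "area",
    "perimeter",
    "convex_area",
    "solidity",
    "eccentricity",
    "min_feret",
    "max_feret",
    "mean_intensity",
    "median_intensity",
)

_CORNERS = np.array(
    [[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]], dtype=float
)


def as_label_image(img) -> np.ndarray:
    """Validate and coerce ``img`` into a 2D int64 label array.

    Raises ``ValueError`` for non-2D input, negative labels, or non-integral
    values (floats are accepted only if they are exact integers).
    """
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"label image must be 2D and non-empty, got shape {arr.shape}")
    if arr.dtype == bool:
        arr = arr.astype(np.int64)
    elif np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)):
            raise ValueError("label image contains non-finite values")
        if np.any(arr != np.floor(arr)):
            raise ValueError("label image contains non-integer values")
        arr = arr.astype(np.int64)
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int64)
    else:
        raise ValueError(f"label image has unsupported dtype {arr.dtype}")
    if arr.min(initial=0) < 0:
        raise ValueError("label image contains negative labels")
    return arr


@dataclass(frozen=True)
class Region:
    """One labeled region: a label id plus its pixel coordinates.

    ``coords`` is an ``(n, 2)`` integer array of ``(row, col)`` pixel
    centers.  Geometry is computed lazily and cached.
    """

    label: int
    coords: np.ndarray = field(repr=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if coords.shape[0] < 1:
            raise ValueError("a region must contain at least one pixel")
        object.__setattr__(self, "coords", coords)
        if self.label < 1:
            raise ValueError("region labels must be positive integers")

    @property
    def area(self) -> int:
        return int(self.coords.shape[0])

    @cached_property
    def centroid(self) -> tuple[float, float]:
        r, c = self.coords.mean(axis=0)
        return (float(r), float(c))

    @cached_property
    def _corner_hull(self) -> ConvexHull:
        corners = (self.coords[:, None, :] + _CORNERS[None, :, :]).reshape(-1, 2)
        corners = np.unique(corners, axis=0)
        return ConvexHull(corners)

    @cached_property
    def convex_area(self) -> float:
        # hull of unit-square corners: area includes the full pixel extent
        return float(self._corner_hull.volume)

    @cached_property
    def minor_feret(self) -> float:
        return _min_caliper_width(self._corner_hull)

    @cached_property
    def max_feret(self) -> float:
        pts = self._corner_hull.points[self._corner_hull.vertices]
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        return float(np.sqrt(d2.max()))

    @cached_property
    def perimeter(self) -> int:
        """Number of exposed unit pixel edges (4-connectivity boundary)."""
        pix = {(int(r), int(c)) for r, c in self.coords}
        shared = 0
        for r, c in pix:
            if (r + 1, c) in pix:
                shared += 1
            if (r, c + 1) in pix:
                shared += 1
        return 4 * self.area - 2 * shared

    @cached_property
    def eccentricity(self) -> float:
        """Eccentricity of the pixel-coordinate scatter ellipse, in [0, 1)."""
        if self.area < 2:
            return 0.0
        mu = self.coords - self.coords.mean(axis=0)
        cov = (mu.T @ mu) / self.area
        l1, l2 = sorted(np.linalg.eigvalsh(cov), reverse=True)
        if l1 <= 0.0:
            return 0.0
        return float(math.sqrt(max(0.0, 1.0 - l2 / l1)))


def _min_caliper_width(hull: ConvexHull) -> float:
    """Rotating-calipers minimum width of a 2D convex hull."""
    pts = hull.points[hull.vertices]  # counterclockwise
    n = pts.shape[0]
    best = math.inf
    for i in range(n):
        edge = pts[(i + 1) % n] - pts[i]
        norm = math.hypot(edge[0], edge[1])
        if norm == 0.0:
            continue
        rel = pts - pts[i]
        # CCW order: all points lie on the non-negative side of each edge
        width = float(np.max(edge[0] * rel[:, 1] - edge[1] * rel[:, 0]) / norm)
        best = min(best, width)
    return best


def extract_regions(img, min_area: int = DEFAULT_MIN_AREA) -> list[Region]:
    """Extract one :class:`Region` per distinct nonzero label with area >= ``min_area``.

    Output is sorted by ascending label.  Disconnected components sharing a
    label form a single region.
    """
    arr = as_label_image(img)
    regions: list[Region] = []
    for lab in np.unique(arr):
        if lab == 0:
            continue
        coords = np.argwhere(arr == lab)
        if coords.shape[0] >= min_area:
            regions.append(Region(label=int(lab), coords=coords))
    return regions


def region_centroid(r: Region) -> tuple[float, float]:
    """Unweighted arithmetic mean of the region's pixel coordinates."""
    return r.centroid


def minor_feret_diameter(r: Region) -> float:
    """Minimum caliper width of the region's pixel-corner convex hull."""
    return r.minor_feret


def compute_features(
    r: Region, intensity: np.ndarray | None = None
) -> Mapping[str, float]:
    """Per-region feature vector (see :data:`FEATURE_NAMES`).

    ``intensity`` is an optional co-registered grayscale image indexed by the
    region's pixel coordinates; when absent, ``mean_intensity`` and
    ``median_intensity`` are NaN (absent-flagged, never silently zero).

    Guarantees ``0 < solidity <= 1`` and ``min_feret <= max_feret``.
    """
    if intensity is not None:
        intensity = np.asarray(intensity, dtype=float)
        if intensity.ndim != 2:
            raise ValueError("intensity image must be 2D")
        vals = intensity[r.coords[:, 0], r.coords[:, 1]]
        mean_i, median_i = float(vals.mean()), float(np.median(vals))
    else:
        mean_i = median_i = float("nan")
    return {
        "area": float(r.area),
        "perimeter": float(r.perimeter),
        "convex_area": r.convex_area,
        "solidity": min(1.0, r.area / r.convex_area),
        "eccentricity": r.eccentricity,
        "min_feret": r.minor_feret,
        "max_feret": r.max_feret,
        "mean_intensity": mean_i,
        "median_intensity": median_i,
    }
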