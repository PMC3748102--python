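"""Proportional flower cover from quadrat photographs and manual counts.

A quadrat (a 1 m^2 sampling frame in the field protocol) is photographed
from overhead; the photo is rectified by a projective homography mapping
the photographed frame corners onto a square so every pixel represents
equal ground area, the flower colour is thresholded, and image cover is
the flower-pixel fraction.  The traditional manual estimate treats each
flower as an ellipse (area = pi x major radius x minor radius), multiplies
mean flower area by flower count per species and sums over species.  The
two estimators are compared by ordinary least squares; because the camera
sees only the visible (often tilted) flower face, image cover is expected
to be systematically lower than the count x ellipse-area estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
import warnings

import numpy as np
from scipy import stats
from skimage.transform import ProjectiveTransform, warp

from .imaging import ImageRGB
from .segmentation import ThresholdSpec, apply_threshold

__all__ = [
    "QuadratGeometry",
    "CoverEstimate",
    "MethodComparison",
    "deskew",
    "cover_fraction",
    "ellipse_area",
    "manual_cover",
    "compare_methods",
    "DEFAULT_QUADRAT_AREA_CM2",
]

#: 1 m^2 quadrat in cm^2.
DEFAULT_QUADRAT_AREA_CM2 = 10_000.0


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


@dataclass
class QuadratGeometry:
    """Photographed quadrat corners (x, y), ordered TL, TR, BR, BL."""

    corners: np.ndarray  # (4, 2) in source-pixel (x, y) coordinates
    output_side: int = 512

    def __post_init__(self) -> None:
        self.corners = np.asarray(self.corners, dtype=float)
        if self.corners.shape != (4, 2):
            raise ValueError("corners must be a 4x2 array of (x, y) points")
        if self.output_side < 16:
            raise ValueError("output side must be >= 16 pixels")
        c = self.corners
        # opposite edges of a simple quadrilateral never cross; a bow-tie's do
        if _segments_intersect(c[0], c[1], c[2], c[3]) or _segments_intersect(c[1], c[2], c[3], c[0]):
            raise ValueError("self-intersecting quadrilateral")
        area = 0.0
        for i in range(4):
            x1, y1 = c[i]
            x2, y2 = c[(i + 1) % 4]
            area += x1 * y2 - x2 * y1
        if abs(area) < 1e-9:
            raise ValueError("degenerate quadrilateral: corners are collinear")


@dataclass
class CoverEstimate:
    """Cover for one quadrat from pixels and from counts x ellipse areas."""

    image_cover: float
    manual_cover: float
    per_species: list = field(default_factory=list)  # (species, count, mean_area_cm2)
    quadrat_area_cm2: float = DEFAULT_QUADRAT_AREA_CM2

    def __post_init__(self) -> None:
        if not 0.0 <= self.image_cover <= 1.0:
            raise ValueError("image_cover must lie in [0, 1]")
        if self.manual_cover < 0.0:
            raise ValueError("manual_cover must be >= 0")


def deskew(img: ImageRGB, geom: QuadratGeometry) -> ImageRGB:
    """Projective rectification of the quadrat quadrilateral onto a square.

    Bilinear interpolation; the output square has ``geom.output_side``
    pixels per side.  With corners at the image corners and matching side
    length this is the identity.
    """
    side = geom.output_side
    if (
        geom.corners[:, 0].min() < -0.5
        or geom.corners[:, 1].min() < -0.5
        or geom.corners[:, 0].max() > img.pixels.shape[1] - 0.5
        or geom.corners[:, 1].max() > img.pixels.shape[0] - 0.5
    ):
        raise ValueError("quadrat corners fall outside the image")
    dst_square = np.array(
        [[0.0, 0.0], [side - 1.0, 0.0], [side - 1.0, side - 1.0], [0.0, side - 1.0]]
    )
    tform = ProjectiveTransform.from_estimate(dst_square, geom.corners)
    if not tform:
        raise ValueError("could not estimate homography from corners")
    out = warp(img.pixels, inverse_map=tform, output_shape=(side, side), order=1, mode="edge")
    return ImageRGB(pixels=np.clip(out, 0.0, 1.0), source_bit_depth=img.source_bit_depth, path=img.path)


def cover_fraction(img: ImageRGB, spec: ThresholdSpec) -> float:
    """Flower-pixel fraction of a (deskewed) quadrat image."""
    mask = apply_threshold(img, spec)
    return float(mask.mean())


def ellipse_area(major_diameter_cm: float, minor_diameter_cm: float) -> float:
    """Visible flower area treated as an ellipse: pi x major radius x minor radius."""
    if major_diameter_cm <= 0 or minor_diameter_cm <= 0:
        raise ValueError("diameters must be positive")
    if minor_diameter_cm > major_diameter_cm:
        warnings.warn("minor diameter exceeds major; swapping", stacklevel=2)
        major_diameter_cm, minor_diameter_cm = minor_diameter_cm, major_diameter_cm
    return math.pi * (major_diameter_cm / 2.0) * (minor_diameter_cm / 2.0)


def manual_cover(per_species, quadrat_area_cm2: float = DEFAULT_QUADRAT_AREA_CM2) -> float:
    """Count x mean-flower-area cover, summed over species.

    *per_species* is a list of ``(count, mean_flower_area_cm2)`` pairs.
    Can exceed 1 when flowers overlap or overhang the quadrat.
    """
    if quadrat_area_cm2 <= 0:
        raise ValueError("quadrat area must be positive")
    total = 0.0
    for count, area in per_species:
        if count < 0 or area < 0:
            raise ValueError("counts and areas must be non-negative")
        total += count * area
    return total / quadrat_area_cm2


@dataclass
class MethodComparison:
    slope: float
    intercept: float
    r_squared: float
    n: int
    # the reverse regression (manual on image) for completeness
    slope_reverse: float = float("nan")
    intercept_reverse: float = float("nan")


def compare_methods(pairs) -> MethodComparison:
    """OLS of image cover on manual cover across quadrats.

    Returns slope, intercept and R^2 (squared Pearson correlation) of
    ``image_cover ~ manual_cover``, plus the reverse regression.  A slope
    below 1 quantifies how much lower the pixel-based estimate runs.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (image_cover, manual_cover) pairs")
    image, manual = arr[:, 0], arr[:, 1]
    if manual.std() == 0:
        raise ValueError("manual cover has zero variance; regression undefined")
    fwd = stats.linregress(manual, image)
    rev = stats.linregress(image, manual) if image.std() > 0 else None
    return MethodComparison(
        slope=float(fwd.slope),
        intercept=float(fwd.intercept),
        r_squared=float(fwd.rvalue**2),
        n=arr.shape[0],
        slope_reverse=float(rev.slope) if rev else float("nan"),
        intercept_reverse=float(rev.intercept) if rev else float("nan"),
    )
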