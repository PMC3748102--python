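"""Chart-based image standardisation (exposure, black point, temperature, tint).

Camera RGB is device- and light-dependent, so colours must be standardised
against an in-scene reference before they can be compared across images.
The reference here is the 24-patch ColorChecker rendition chart, whose six
neutral patches (black, four greys, white) anchor the four corrections:

* **black point** — an additive offset in linear light,
* **exposure** — a scalar gain in linear light,
* **colour temperature / tint** — per-channel gains on the red and blue
  channels (green pinned at 1), moving colours along the blue–yellow and
  magenta–green axes respectively.

The fit is deterministic.  Because the green gain is fixed at 1, the green
channel of the neutral patches isolates exposure and black point: both are
estimated by least squares of measured-vs-reference *linear green* over all
neutral patches.  The red and blue gains are then anchored so that the grey
patch whose reference brightness is nearest the plant part being measured
matches its reference RGB exactly — sensor non-linearities make a single
global balance across the whole brightness range unreliable, so the balance
is tied to the brightness that matters.  Under a pure gain/offset distortion
this recovers the generating parameters exactly.

Corrections operate in linear RGB (after sRGB decoding): gains and offsets
are physically multiplicative/additive in linear light only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as _raster_polygon

from .colorspace import delta_e_ab, linear_to_srgb, rgb_to_lab, srgb_to_linear
from .imaging import DEFAULT_CLIP_THRESHOLD, ImageRGB

__all__ = [
    "ChartPatch",
    "ChartReference",
    "PatchMeasurement",
    "StandardizationParams",
    "default_chart_reference",
    "load_chart_reference",
    "extract_patches",
    "fit_standardization",
    "apply_standardization",
    "residual_report",
]

# Rec. 709 / sRGB luminance weights for linear RGB.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class ChartPatch:
    name: str
    expected_rgb: tuple  # companded sRGB triple in [0, 1]
    is_neutral: bool


@dataclass
class ChartReference:
    """Expected sRGB values of a 24-patch colour rendition chart."""

    patches: list

    def __post_init__(self) -> None:
        if len(self.patches) != 24:
            raise ValueError(f"chart must have exactly 24 patches, got {len(self.patches)}")
        neutrals = [p for p in self.patches if p.is_neutral]
        if len(neutrals) != 6:
            raise ValueError(f"chart must have exactly 6 neutral patches, got {len(neutrals)}")
        for p in neutrals:
            r, g, b = p.expected_rgb
            if max(r, g, b) - min(r, g, b) > 0.01:
                raise ValueError(f"neutral patch {p.name!r} is not neutral (r=g=b within 0.01)")

    @property
    def neutral_patches(self) -> list:
        return [p for p in self.patches if p.is_neutral]

    def patch(self, name: str) -> ChartPatch:
        for p in self.patches:
            if p.name == name:
                return p
        raise KeyError(name)

    def expected_array(self) -> np.ndarray:
        return np.array([p.expected_rgb for p in self.patches])


@dataclass
class PatchMeasurement:
    """Mean RGB measured over one chart patch in one photograph."""

    name: str
    mean_rgb: tuple
    pixel_count: int

    def __post_init__(self) -> None:
        if self.pixel_count < 1:
            raise ValueError("pixel_count must be >= 1")
        if min(self.mean_rgb) < -1e-12 or max(self.mean_rgb) > 1 + 1e-12:
            raise ValueError("mean_rgb must lie in [0, 1]")


@dataclass
class StandardizationParams:
    """The fitted correction: linear -> (x - black) * exposure * channel gains."""

    black_point: float
    exposure_gain: float
    channel_gains: tuple  # (red, green=1, blue)
    reference_brightness: float = 0.0  # linear luminance of the anchor grey
    anchor_patch: str = ""

    def __post_init__(self) -> None:
        if self.exposure_gain <= 0:
            raise ValueError("exposure_gain must be positive")
        if self.black_point < -1e-9:
            raise ValueError("black_point must be >= 0")
        g = np.asarray(self.channel_gains, dtype=float)
        if g.shape != (3,) or np.any(g <= 0):
            raise ValueError("channel_gains must be 3 positive reals")
        if abs(g[1] - 1.0) > 1e-9:
            raise ValueError("green channel gain is pinned at 1")

    @classmethod
    def identity(cls) -> "StandardizationParams":
        return cls(black_point=0.0, exposure_gain=1.0, channel_gains=(1.0, 1.0, 1.0))


def load_chart_reference(path) -> ChartReference:
    """Load a chart reference CSV (patch_name, r, g, b, is_neutral)."""
    df = pd.read_csv(path)
    patches = [
        ChartPatch(
            name=str(row.patch_name),
            expected_rgb=(float(row.r), float(row.g), float(row.b)),
            is_neutral=bool(int(row.is_neutral)),
        )
        for row in df.itertuples()
    ]
    return ChartReference(patches=patches)


def default_chart_reference() -> ChartReference:
    """The bundled sRGB ColorChecker classic reference table."""
    ref = importlib.resources.files("floracolor") / "data" / "colorchecker_srgb.csv"
    with importlib.resources.as_file(ref) as path:
        return load_chart_reference(path)


def _inner_region_mask(shape, region) -> tuple:
    """Row/col indices of the central 50% of a rectangle or quadrilateral."""
    region = np.asarray(region, dtype=float)
    H, W = shape[:2]
    if region.shape == (4,):
        r0, c0, r1, c1 = region
        if r0 < 0 or c0 < 0 or r1 > H or c1 > W or r1 <= r0 or c1 <= c0:
            raise ValueError(f"region {region} outside image bounds {H}x{W}")
        # central 50% by area: trim a quarter of each side length
        dr, dc = (r1 - r0) / 4.0, (c1 - c0) / 4.0
        rows = np.arange(int(np.ceil(r0 + dr)), int(np.floor(r1 - dr)))
        cols = np.arange(int(np.ceil(c0 + dc)), int(np.floor(c1 - dc)))
        if rows.size == 0 or cols.size == 0:
            raise ValueError("region too small for an inner margin")
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        return rr.ravel(), cc.ravel()
    if region.shape == (4, 2):
        if region[:, 0].min() < 0 or region[:, 1].min() < 0 or region[:, 0].max() > H or region[:, 1].max() > W:
            raise ValueError("quadrilateral outside image bounds")
        centroid = region.mean(axis=0)
        inner = centroid + (region - centroid) / np.sqrt(2.0)  # halve the area
        rr, cc = _raster_polygon(inner[:, 0], inner[:, 1], shape=(H, W))
        if rr.size == 0:
            raise ValueError("quadrilateral too small for an inner margin")
        return rr, cc
    raise ValueError("region must be (r0, c0, r1, c1) or a 4x2 corner array")


def extract_patches(img: ImageRGB, patch_regions, names=None) -> list:
    """Measure mean RGB over the central 50% of each chart patch region.

    Regions are (row0, col0, row1, col1) rectangles or 4x2 corner arrays in
    (row, col) pixel coordinates.  Only the inner half of each region is
    averaged, to avoid bleed from patch borders.
    """
    if names is None:
        names = [f"patch_{i:02d}" for i in range(len(patch_regions))]
    out = []
    for name, region in zip(names, patch_regions):
        rr, cc = _inner_region_mask(img.pixels.shape, region)
        sel = img.pixels[rr, cc, :]
        out.append(PatchMeasurement(name=name, mean_rgb=tuple(sel.mean(axis=0)), pixel_count=sel.shape[0]))
    return out


def fit_standardization(
    measured,
    reference: ChartReference,
    object_brightness: float = 0.4,
    clip_threshold: float = DEFAULT_CLIP_THRESHOLD,
) -> StandardizationParams:
    """Fit black point, exposure and temperature/tint gains from chart neutrals.

    Parameters
    ----------
    measured
        PatchMeasurement list covering (at least) the chart's neutral patches,
        matched to the reference by patch name.
    reference
        Expected chart values.
    object_brightness
        Linear luminance (0–1) of the plant part to be measured; the grey
        patch nearest this brightness anchors the colour balance.
    """
    if not 0.0 <= object_brightness <= 1.0:
        raise ValueError("object_brightness must lie in [0, 1]")
    by_name = {m.name: m for m in measured}
    neutrals = [p for p in reference.neutral_patches if p.name in by_name]
    if len(neutrals) < 2:
        raise ValueError("need at least 2 measured neutral patches to fit exposure and black point")
    meas_rgb = np.array([by_name[p.name].mean_rgb for p in neutrals])
    if np.any(np.all(meas_rgb >= clip_threshold, axis=1)):
        clipped = [p.name for p, m in zip(neutrals, meas_rgb) if np.all(m >= clip_threshold)]
        raise ValueError(f"neutral patch(es) fully clipped: {clipped}; standardisation is invalid")
    meas_lin = srgb_to_linear(meas_rgb)
    ref_lin = srgb_to_linear(np.array([p.expected_rgb for p in neutrals]))

    # Green gain is pinned at 1, so measured_green = ref_green / exposure + black.
    A = np.column_stack([ref_lin[:, 1], np.ones(len(neutrals))])
    (inv_gain, black), *_ = np.linalg.lstsq(A, meas_lin[:, 1], rcond=None)
    if inv_gain <= 0:
        raise ValueError("degenerate neutral measurements: non-positive exposure slope")
    exposure_gain = 1.0 / inv_gain
    black_point = max(black, 0.0)

    # Anchor colour balance at the grey patch nearest the object's brightness.
    ref_luma = ref_lin @ _LUMA
    anchor_idx = int(np.argmin(np.abs(ref_luma - object_brightness)))
    anchor = neutrals[anchor_idx]
    corrected = (meas_lin[anchor_idx] - black_point) * exposure_gain
    if np.any(corrected <= 0):
        raise ValueError(f"anchor patch {anchor.name!r} is at or below the black point")
    target = ref_lin[anchor_idx]
    gains = (target[0] / corrected[0], 1.0, target[2] / corrected[2])
    return StandardizationParams(
        black_point=float(black_point),
        exposure_gain=float(exposure_gain),
        channel_gains=tuple(float(g) for g in gains),
        reference_brightness=float(ref_luma[anchor_idx]),
        anchor_patch=anchor.name,
    )


def apply_standardization(img: ImageRGB, params: StandardizationParams) -> ImageRGB:
    """Apply the correction pixelwise.

    linearise -> subtract black point -> exposure gain -> channel gains ->
    clamp to [0, 1] -> re-compand.  With identity parameters the image is
    returned unchanged (up to floating-point round trip).
    """
    lin = srgb_to_linear(img.pixels)
    lin = (lin - params.black_point) * params.exposure_gain
    lin = lin * np.asarray(params.channel_gains)
    lin = np.clip(lin, 0.0, 1.0)
    return ImageRGB(pixels=linear_to_srgb(lin), source_bit_depth=img.source_bit_depth, path=img.path)


def correct_patch_means(measured, params: StandardizationParams) -> list:
    """Apply the correction to patch mean RGB values (QC convenience)."""
    out = []
    for m in measured:
        lin = (srgb_to_linear(np.asarray(m.mean_rgb)) - params.black_point) * params.exposure_gain
        lin = np.clip(lin * np.asarray(params.channel_gains), 0.0, 1.0)
        out.append(PatchMeasurement(name=m.name, mean_rgb=tuple(linear_to_srgb(lin)), pixel_count=m.pixel_count))
    return out


def residual_report(corrected_patches, reference: ChartReference) -> pd.DataFrame:
    """Per-patch Delta E*ab between corrected measurements and the reference."""
    rows = []
    for m in corrected_patches:
        ref = reference.patch(m.name)
        de = float(delta_e_ab(rgb_to_lab(np.asarray(m.mean_rgb)), rgb_to_lab(np.asarray(ref.expected_rgb))))
        rows.append({"patch_name": m.name, "is_neutral": ref.is_neutral, "delta_e": de})
    return pd.DataFrame(rows)
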