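"""Colour-threshold segmentation of plant parts from the image background.

A pixel belongs to the mask iff every channel of its representation in the
chosen space (Lab, HSB or RGB) falls inside a per-channel interval; the hue
channel may wrap around (e.g. reds spanning 350°–10°).  Thresholds are
meant to be evaluated on the *standardised* image — segment after
standardisation, not before.  Threshold values are user inputs (they depend
on the species and background) and are stored alongside outputs for
provenance.

Optional morphological clean-up (erosion / small-hole removal) is available
as explicit post-steps but is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv
from skimage.morphology import erosion, remove_small_holes

from .colorspace import PixelCloudLab, rgb_to_lab
from .imaging import ImageRGB

logger = logging.getLogger(__name__)

__all__ = ["ThresholdSpec", "apply_threshold", "extract_pixel_cloud", "clean_mask"]

_SPACE_CHANNELS = {
    "Lab": ("L", "a", "b"),
    "HSB": ("H", "S", "B"),
    "RGB": ("R", "G", "B"),
}


@dataclass
class ThresholdSpec:
    """Per-channel inclusion intervals in a named colour space.

    ``channels`` maps each channel of the space to a (min, max) pair.
    Ranges: Lab channels in Lab units (L 0–100); HSB and RGB channels in
    [0, 1].  ``wrap`` may name the hue channel for wraparound intervals
    where min > max means [min, 1] v [0, max].
    """

    space: str
    channels: dict
    wrap: tuple = ()

    def __post_init__(self) -> None:
        if self.space not in _SPACE_CHANNELS:
            raise ValueError(f"unknown colour space {self.space!r}; use Lab, HSB or RGB")
        expected = set(_SPACE_CHANNELS[self.space])
        if set(self.channels) - expected:
            raise ValueError(
                f"channels {sorted(set(self.channels) - expected)} do not belong to space {self.space}"
            )
        for ch in self.wrap:
            if ch != "H" or self.space != "HSB":
                raise ValueError("wraparound is only supported for the HSB hue channel")
        for ch, (lo, hi) in self.channels.items():
            if ch not in self.wrap and lo > hi:
                raise ValueError(f"channel {ch}: min {lo} > max {hi} without wraparound")


def _channel_planes(img: ImageRGB, space: str) -> np.ndarray:
    if space == "RGB":
        return img.pixels
    if space == "HSB":
        return rgb2hsv(img.pixels)
    return rgb_to_lab(img.pixels)


def apply_threshold(img: ImageRGB, spec: ThresholdSpec) -> np.ndarray:
    """Boolean mask of pixels inside every channel interval of *spec*."""
    planes = _channel_planes(img, spec.space)
    mask = np.ones(img.pixels.shape[:2], dtype=bool)
    names = _SPACE_CHANNELS[spec.space]
    for ch, (lo, hi) in spec.channels.items():
        plane = planes[:, :, names.index(ch)]
        if ch in spec.wrap and lo > hi:
            mask &= (plane >= lo) | (plane <= hi)
        else:
            mask &= (plane >= lo) & (plane <= hi)
    return mask


def clean_mask(mask: np.ndarray, erode: int = 0, min_hole_area: int = 0) -> np.ndarray:
    """Optional morphological post-processing (logged, off by default)."""
    out = mask
    if min_hole_area > 0:
        logger.info("segmentation: removing holes smaller than %d px", min_hole_area)
        out = remove_small_holes(out, area_threshold=min_hole_area)
    for _ in range(erode):
        out = erosion(out)
    if erode:
        logger.info("segmentation: applied %d erosion step(s)", erode)
    return out


def extract_pixel_cloud(
    img: ImageRGB,
    mask: np.ndarray,
    specimen_id: str = "",
    species: str = "",
    part: str = "",
    white_point: str = "D65",
) -> PixelCloudLab:
    """Lab values of all masked pixels, in deterministic row-major order."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.pixels.shape[:2]:
        raise ValueError("mask shape must match image shape")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask: no pixels selected")
    lab = rgb_to_lab(img.pixels[mask], white_point=white_point)
    return PixelCloudLab(
        points=lab,
        specimen_id=specimen_id,
        species=species,
        part=part,
        meta={"white_point": white_point, "n_image_pixels": img.n_pixels},
    )
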