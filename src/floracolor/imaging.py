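"""Image and table I/O, bit-depth normalisation and clipping detection.

Images are held as floating-point rasters in [0, 1] in companded
(display-referred) sRGB, exactly as decoded; linearisation happens
explicitly inside the colour-space and standardisation steps.  Channel
clipping — a channel saturating at the sensor maximum — destroys colour
information and invalidates the Lab transform for affected pixels, so a
clipping report is part of the quality-control surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ImageRGB",
    "ClippingReport",
    "read_image",
    "write_image",
    "detect_clipping",
    "write_trait_table",
    "read_trait_table",
    "DEFAULT_CLIP_THRESHOLD",
]

#: Default clipping threshold.  254/255 rather than 1.0 so that 8-bit
#: near-saturation counts as clipped: demosaicing and anti-aliasing rarely
#: leave every clipped pixel at exactly 255.
DEFAULT_CLIP_THRESHOLD = 254.0 / 255.0


@dataclass
class ImageRGB:
    """An H x W x 3 raster of companded sRGB values in [0, 1]."""

    pixels: np.ndarray
    source_bit_depth: int = 8
    path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixels.min() < -1e-12 or self.pixels.max() > 1.0 + 1e-12:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.source_bit_depth not in (8, 16):
            raise ValueError("source_bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0] * self.pixels.shape[1]


@dataclass
class ClippingReport:
    """Fraction of pixels at/above the saturation threshold."""

    clipped_fraction: float
    per_channel_fractions: tuple
    threshold: float = DEFAULT_CLIP_THRESHOLD

    @property
    def any_clipped(self) -> bool:
        return self.clipped_fraction > 0.0


def read_image(path) -> ImageRGB:
    """Read a TIFF/PNG/JPEG image and scale to [0, 1] by 2^depth - 1.

    Grayscale inputs are rejected (colour measurements need 3 channels);
    an alpha channel is dropped with a warning.  JPEG inputs are accepted
    but flagged in the log as lossy.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise IOError(f"could not decode image {path}: {exc}") from exc
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ValueError(f"{path}: single-channel (grayscale) images are not supported")
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path}: expected 3 colour channels, got shape {arr.shape}")
    if arr.shape[2] == 4:
        warnings.warn(f"{path}: dropping alpha channel", stacklevel=2)
        arr = arr[:, :, :3]
    elif arr.shape[2] > 4:
        raise ValueError(f"{path}: expected 3 colour channels, got {arr.shape[2]}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path}: unsupported sample type {arr.dtype}")
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        logger.warning("%s: JPEG is lossy; decoded values may not match the capture", path)
    pixels = arr.astype(float) / float(2**depth - 1)
    return ImageRGB(pixels=pixels, source_bit_depth=depth, path=str(path))


def write_image(img: ImageRGB, path, bit_depth: int | None = None) -> None:
    """Write an image as 8- or 16-bit, quantising by 2^depth - 1.

    16-bit output requires TIFF (the PNG/JPEG encoders here are 8-bit).
    """
    path = Path(path)
    depth = bit_depth if bit_depth is not None else img.source_bit_depth
    if depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if depth == 16 and path.suffix.lower() not in {".tif", ".tiff"}:
        raise ValueError("16-bit colour output is only supported for TIFF")
    scale = float(2**depth - 1)
    dtype = np.uint8 if depth == 8 else np.uint16
    quantised = np.rint(np.clip(img.pixels, 0.0, 1.0) * scale).astype(dtype)
    iio.imwrite(path, quantised)


def detect_clipping(img: ImageRGB, threshold: float = DEFAULT_CLIP_THRESHOLD) -> ClippingReport:
    """Report the fraction of pixels with any channel at/above *threshold*."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    at_max = img.pixels >= threshold
    per_channel = tuple(float(f) for f in at_max.mean(axis=(0, 1)))
    clipped = float(at_max.any(axis=2).mean())
    return ClippingReport(clipped_fraction=clipped, per_channel_fractions=per_channel, threshold=threshold)


# Columns of the per-specimen trait table (one row per specimen/species summary).
_TRAIT_COLUMNS = [
    "species", "part", "n",
    "L_mean", "L_sd", "a_mean", "a_sd", "b_mean", "b_sd",
    "L_skewness", "a_skewness", "b_skewness",
    "L_kurtosis", "a_kurtosis", "b_kurtosis",
    "L_ks_D", "a_ks_D", "b_ks_D",
    "L_ks_p", "a_ks_p", "b_ks_p",
]


def write_trait_table(summaries, path) -> pd.DataFrame:
    """Serialise colour-trait summaries to CSV (RFC-4180, UTF-8).

    Values are written with 6 significant digits and round-trip losslessly
    at that precision.  *summaries* may be ColorTraitSummary objects (from
    :mod:`floracolor.trait_stats`) or dicts with the table's columns.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("cannot write an empty trait table")
    rows = []
    for s in summaries:
        row = s if isinstance(s, dict) else s.as_row()
        rows.append({c: row.get(c, np.nan) for c in _TRAIT_COLUMNS})
    df = pd.DataFrame(rows, columns=_TRAIT_COLUMNS)
    try:
        df.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write trait table to {path}: {exc}") from exc
    return df


def read_trait_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8")
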