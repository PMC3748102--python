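"""Synthetic image generators with known ground truth.

Field photographs carry no ground truth, so every pipeline stage is
exercised against rendered inputs whose generating parameters are known
exactly:

* **charts** — the 24-patch reference chart laid out on a grid, distorted
  in linear light by known exposure/temperature/tint gains and a black
  offset (optionally with Gaussian pixel noise), returning the correction
  parameters that undo the distortion;
* **specimens** — a flower/leaf silhouette whose foreground pixels are
  drawn from independent per-channel Gaussians *in Lab* (all downstream
  statistics live in Lab; channel independence is a deliberate
  simplification), converted to sRGB, on a fixed background colour;
* **quadrats** — non-overlapping flower discs planted until an exact pixel
  count is reached, optionally warped by a known homography.

Every generator is bit-deterministic under a fixed seed and returns its
ground truth alongside the image; tests never have to infer truth from
the rendered raster.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _disk
from skimage.transform import ProjectiveTransform, warp

from .colorspace import PixelCloudLab, lab_to_rgb, linear_to_srgb, srgb_to_linear
from .cover import QuadratGeometry
from .imaging import ImageRGB
from .standardization import ChartReference, StandardizationParams, default_chart_reference

logger = logging.getLogger(__name__)

__all__ = [
    "ChartFixture",
    "SpecimenFixture",
    "QuadratFixture",
    "render_chart",
    "render_specimen",
    "render_quadrat",
    "sample_lab_cloud",
]


@dataclass
class ChartFixture:
    image: ImageRGB
    true_params: StandardizationParams  # the correction that undoes the distortion
    patch_regions: list  # (row0, col0, row1, col1) per patch, chart order
    patch_names: list
    reference: ChartReference


@dataclass
class SpecimenFixture:
    image: ImageRGB
    mask: np.ndarray
    lab_mean: np.ndarray
    lab_sd: np.ndarray
    cloud: PixelCloudLab  # the exact Lab values planted in the foreground
    n_resampled: int = 0


@dataclass
class QuadratFixture:
    image: ImageRGB
    true_cover: float
    geometry: QuadratGeometry
    flat_image: ImageRGB  # the un-warped square quadrat
    flat_mask: np.ndarray


def render_chart(
    exposure: float = 1.0,
    channel_gains=(1.0, 1.0, 1.0),
    black_offset: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    patch_size: int = 24,
    reference: ChartReference | None = None,
) -> ChartFixture:
    """Render the 24-patch chart under a known linear-light distortion.

    The distortion applied per linear channel is
    ``distorted = true * exposure * gain + black_offset`` (+ optional
    Gaussian noise, clamped), so the correction that exactly undoes it —
    and therefore the fit's ground truth — is ``black_point =
    black_offset``, ``exposure_gain = 1/exposure`` and channel gains
    ``1/gain``.  The green distortion gain must be 1 (temperature and tint
    act on red and blue only).
    """
    gains = np.asarray(channel_gains, dtype=float)
    if exposure <= 0 or np.any(gains <= 0):
        raise ValueError("exposure and channel gains must be positive")
    if abs(gains[1] - 1.0) > 1e-12:
        raise ValueError("green distortion gain must be 1 (temperature/tint touch red and blue only)")
    if black_offset < 0 or noise_sd < 0:
        raise ValueError("black_offset and noise_sd must be >= 0")
    if reference is None:
        reference = default_chart_reference()
    n_rows, n_cols = 4, 6
    H, W = n_rows * patch_size, n_cols * patch_size
    lin = srgb_to_linear(np.array([p.expected_rgb for p in reference.patches]))
    distorted = lin * exposure * gains + black_offset
    img = np.empty((H, W, 3))
    regions, names = [], []
    for idx, patch in enumerate(reference.patches):
        r, c = divmod(idx, n_cols)
        r0, c0 = r * patch_size, c * patch_size
        img[r0 : r0 + patch_size, c0 : c0 + patch_size, :] = distorted[idx]
        regions.append((r0, c0, r0 + patch_size, c0 + patch_size))
        names.append(patch.name)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = linear_to_srgb(np.clip(img, 0.0, 1.0))
    true_params = StandardizationParams(
        black_point=black_offset,
        exposure_gain=1.0 / exposure,
        channel_gains=tuple(1.0 / gains),
    )
    return ChartFixture(
        image=ImageRGB(pixels=img, source_bit_depth=16, path="<synthetic chart>"),
        true_params=true_params,
        patch_regions=regions,
        patch_names=names,
        reference=reference,
    )


def sample_lab_cloud(lab_mean, lab_sd, n: int, seed=None, max_resample: int = 100) -> tuple:
    """Draw n Lab points from independent per-channel Gaussians, all in-gamut.

    Out-of-gamut draws are resampled; returns ``(points, n_resampled)``.
    """
    lab_mean = np.asarray(lab_mean, dtype=float)
    lab_sd = np.asarray(lab_sd, dtype=float)
    if np.any(lab_sd < 0):
        raise ValueError("lab_sd must be >= 0")
    rng = np.random.default_rng(seed)
    pts = rng.normal(lab_mean, lab_sd, size=(n, 3))
    n_resampled = 0
    for _ in range(max_resample):
        _, oog = lab_to_rgb(pts)
        bad = oog | (pts[:, 0] < 0) | (pts[:, 0] > 100)
        if not bad.any():
            break
        n_resampled += int(bad.sum())
        pts[bad] = rng.normal(lab_mean, lab_sd, size=(int(bad.sum()), 3))
    else:
        raise RuntimeError("could not draw an in-gamut cloud; mean too close to the gamut boundary")
    if n_resampled:
        logger.info("specimen fixture: resampled %d out-of-gamut draw(s)", n_resampled)
    return pts, n_resampled


def render_specimen(
    lab_mean,
    lab_sd,
    size: int = 64,
    shape: str = "disc",
    background_rgb=(0.85, 0.85, 0.85),
    seed: int = 0,
    species: str = "synthetic",
    specimen_id: str = "synthetic-0",
    part: str = "flower",
) -> SpecimenFixture:
    """Render a specimen whose foreground Lab distribution is known exactly.

    The mean must sit inside the sRGB gamut with >= 3 sigma margin per
    channel (checked on the 3-sigma box corners), so resampling stays a
    tail correction rather than a truncation of the target distribution.
    """
    lab_mean = np.asarray(lab_mean, dtype=float)
    lab_sd = np.asarray(lab_sd, dtype=float)
    corners = lab_mean + 3.0 * lab_sd * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    corners[:, 0] = np.clip(corners[:, 0], 0.0, 100.0)
    _, oog = lab_to_rgb(corners)
    if oog.any():
        raise ValueError("Lab mean is within 3 sigma of the sRGB gamut boundary; pick a safer colour")
    if shape == "disc":
        mask = np.zeros((size, size), dtype=bool)
        rr, cc = _disk((size / 2.0 - 0.5, size / 2.0 - 0.5), size * 0.4, shape=(size, size))
        mask[rr, cc] = True
    elif shape == "rect":
        mask = np.zeros((size, size), dtype=bool)
        q = size // 4
        mask[q : size - q, q : size - q] = True
    else:
        raise ValueError("shape must be 'disc' or 'rect'")
    n_fg = int(mask.sum())
    pts, n_resampled = sample_lab_cloud(lab_mean, lab_sd, n_fg, seed=seed)
    fg_rgb, _ = lab_to_rgb(pts)
    pixels = np.empty((size, size, 3))
    pixels[:] = np.asarray(background_rgb, dtype=float)
    pixels[mask] = fg_rgb
    cloud = PixelCloudLab(points=pts, specimen_id=specimen_id, species=species, part=part)
    return SpecimenFixture(
        image=ImageRGB(pixels=pixels, source_bit_depth=16, path="<synthetic specimen>"),
        mask=mask,
        lab_mean=lab_mean,
        lab_sd=lab_sd,
        cloud=cloud,
        n_resampled=n_resampled,
    )


def render_quadrat(
    cover: float,
    side: int = 400,
    flower_rgb=(0.95, 0.80, 0.10),
    background_rgb=(0.25, 0.45, 0.20),
    surround_rgb=(0.55, 0.50, 0.45),
    disc_radius: int = 9,
    corner_displacement: float = 0.0,
    seed: int = 0,
) -> QuadratFixture:
    """Render a quadrat with an exactly known flower-pixel fraction.

    Discs are placed in disjoint cells of a jittered occupancy grid (so
    they can never overlap, at any achievable cover) until the planted
    pixel count reaches ``round(cover * side**2)`` exactly; the final disc
    is painted partially, in row-major pixel order, to hit the target.
    With ``corner_displacement > 0`` the square is then warped by a known
    homography displacing each corner by up to that many pixels; the truth
    (cover and corner geometry) refers to the pre-warp square.
    """
    if not 0.0 <= cover <= 1.0:
        raise ValueError("cover must lie in [0, 1]")
    if disc_radius < 2:
        raise ValueError("disc_radius must be >= 2")
    rng = np.random.default_rng(seed)
    target = int(round(cover * side * side))
    cell = 2 * disc_radius + 2
    n_cells = (side // cell) ** 2
    rr0, cc0 = _disk((0, 0), disc_radius + 0.5)
    disc_px = rr0.size  # pixels per full disc
    max_cover = n_cells * disc_px / (side * side)
    if target > n_cells * disc_px:
        raise ValueError(
            f"cover {cover} unreachable without overlap: max {max_cover:.3f} "
            f"at disc radius {disc_radius} on a {side}px quadrat"
        )
    flat = np.empty((side, side, 3))
    flat[:] = np.asarray(background_rgb, dtype=float)
    mask = np.zeros((side, side), dtype=bool)
    per_side = side // cell
    cells = [(i, j) for i in range(per_side) for j in range(per_side)]
    rng.shuffle(cells)
    planted = 0
    for i, j in cells:
        if planted >= target:
            break
        # jitter the centre but keep the disc strictly inside its cell
        margin = cell / 2.0 - disc_radius - 0.5
        cy = i * cell + cell / 2.0 + rng.uniform(-margin, margin)
        cx = j * cell + cell / 2.0 + rng.uniform(-margin, margin)
        rr, cc = _disk((cy, cx), disc_radius + 0.5, shape=(side, side))
        take = min(target - planted, rr.size)
        order = np.lexsort((cc, rr))  # row-major partial paint for the last disc
        rr, cc = rr[order][:take], cc[order][:take]
        mask[rr, cc] = True
        flat[rr, cc] = np.asarray(flower_rgb, dtype=float)
        planted += take
    assert planted == target
    true_cover = target / (side * side)
    flat_img = ImageRGB(pixels=flat, source_bit_depth=16, path="<synthetic quadrat>")

    base_corners = np.array(
        [[0.0, 0.0], [side - 1.0, 0.0], [side - 1.0, side - 1.0], [0.0, side - 1.0]]
    )
    if corner_displacement <= 0:
        geom = QuadratGeometry(corners=base_corners, output_side=side)
        return QuadratFixture(flat_img, true_cover, geom, flat_img, mask)

    pad = int(math.ceil(corner_displacement)) + 2
    canvas_shape = (side + 2 * pad, side + 2 * pad)
    displaced = base_corners + pad + rng.uniform(-corner_displacement, corner_displacement, size=(4, 2))
    tform = ProjectiveTransform.from_estimate(displaced, base_corners)
    if not tform:
        raise ValueError("could not build the warp homography")
    warped = warp(
        flat, inverse_map=tform, output_shape=canvas_shape, order=1,
        mode="constant", cval=-1.0,
    )
    outside = np.any(warped < 0, axis=2)
    warped[outside] = np.asarray(surround_rgb, dtype=float)
    img = ImageRGB(pixels=np.clip(warped, 0.0, 1.0), source_bit_depth=16, path="<synthetic quadrat>")
    geom = QuadratGeometry(corners=displaced, output_side=side)
    return QuadratFixture(img, true_cover, geom, flat_img, mask)
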