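"""Conversion between sRGB and the CIE 1976 L*a*b* colour space.

All colour statistics in this package are computed in CIE 1976 L*a*b*
("Lab"), a device-independent space modelled on human colour perception:
L* is lightness (0 black to 100 diffuse white), a* runs green (negative)
to magenta (positive) and b* runs blue (negative) to yellow (positive).
Euclidean distance in Lab (Delta E*ab) approximates perceived colour
difference.

The sRGB <-> XYZ matrix is derived in double precision from the IEC
61966-2-1 primary and D65 white chromaticities, and the reference white
is taken as the image of (1, 1, 1) under that matrix.  This makes the
conversion exactly self-consistent: neutral inputs (r = g = b) map to
a* = b* = 0 to machine precision and the round trip is exact, whereas
matrices copied from rounded published tables leave residuals of ~1e-3.
A D50 white point (ICC profile connection space) is available for
cross-checks against printing-oriented converters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabColor",
    "PixelCloudLab",
    "srgb_to_linear",
    "linear_to_srgb",
    "rgb_to_lab",
    "lab_to_rgb",
    "delta_e_ab",
    "rgb_to_xyz_matrix",
    "WHITE_POINTS",
]

# CIE xy chromaticities of the sRGB primaries and standard whites.
_PRIMARIES = {
    "R": (0.64, 0.33),
    "G": (0.30, 0.60),
    "B": (0.15, 0.06),
}
_WHITE_XY = {
    "D65": (0.3127, 0.3290),
    "D50": (0.3457, 0.3585),
}

# CIE f(t) constants
_DELTA = 6.0 / 29.0
_DELTA3 = _DELTA**3
_KAPPA = 1.0 / (3.0 * _DELTA**2)


def rgb_to_xyz_matrix(white_point: str = "D65") -> np.ndarray:
    """3x3 linear-sRGB -> XYZ matrix for the given adopted white."""
    if white_point not in _WHITE_XY:
        raise ValueError(f"unknown white point {white_point!r}; use D65 or D50")
    prim = np.empty((3, 3))
    for j, key in enumerate("RGB"):
        x, y = _PRIMARIES[key]
        prim[:, j] = (x / y, 1.0, (1.0 - x - y) / y)
    xw, yw = _WHITE_XY[white_point]
    white = np.array([xw / yw, 1.0, (1.0 - xw - yw) / yw])
    scale = np.linalg.solve(prim, white)
    return prim * scale


_M_RGB2XYZ = {wp: rgb_to_xyz_matrix(wp) for wp in _WHITE_XY}
_M_XYZ2RGB = {wp: np.linalg.inv(m) for wp, m in _M_RGB2XYZ.items()}

#: Reference white tristimulus for each supported illuminant (image of RGB white).
WHITE_POINTS = {wp: m @ np.ones(3) for wp, m in _M_RGB2XYZ.items()}


@dataclass(frozen=True)
class LabColor:
    """A single CIE 1976 L*a*b* colour."""

    L: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.L <= 100.0 + 1e-9:
            raise ValueError(f"L* must lie in [0, 100], got {self.L}")

    def as_array(self) -> np.ndarray:
        return np.array([self.L, self.a, self.b])


@dataclass
class PixelCloudLab:
    """All Lab pixel values of one segmented specimen (flower or leaf)."""

    points: np.ndarray  # (N, 3) of L*, a*, b*
    specimen_id: str = ""
    species: str = ""
    part: str = ""  # "flower" | "leaf"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array of Lab values")
        if self.points.shape[0] < 1:
            raise ValueError("a pixel cloud needs at least one point")
        L = self.points[:, 0]
        if L.min() < -1e-9 or L.max() > 100.0 + 1e-9:
            raise ValueError("L* values outside [0, 100]")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def channel(self, name: str) -> np.ndarray:
        return self.points[:, "Lab".index(name)]


def _check_unit_range(v: np.ndarray, what: str) -> None:
    if v.size and (v.min() < -1e-12 or v.max() > 1.0 + 1e-12):
        raise ValueError(f"{what} values must lie in [0, 1]")


def srgb_to_linear(v):
    """sRGB electro-optical transfer: companded [0,1] -> linear [0,1]."""
    v = np.asarray(v, dtype=float)
    _check_unit_range(v, "companded sRGB")
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(v):
    """Inverse of :func:`srgb_to_linear` (linear light -> companded sRGB)."""
    v = np.asarray(v, dtype=float)
    _check_unit_range(v, "linear RGB")
    return np.where(v <= 0.04045 / 12.92, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)


def _f_cie(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA3, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_cie_inv(ft: np.ndarray) -> np.ndarray:
    return np.where(ft > _DELTA, ft**3, (ft - 4.0 / 29.0) / _KAPPA)


def rgb_to_lab(rgb, white_point: str = "D65") -> np.ndarray:
    """Convert companded sRGB to CIE 1976 L*a*b*.

    Accepts a triple, an (N, 3) cloud or an (H, W, 3) image; the trailing
    axis is the colour axis and the output has the same shape.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("last axis must hold 3 (R, G, B) channels")
    lin = srgb_to_linear(rgb)
    xyz = lin @ _M_RGB2XYZ[white_point].T
    ft = _f_cie(xyz / WHITE_POINTS[white_point])
    fx, fy, fz = ft[..., 0], ft[..., 1], ft[..., 2]
    lab = np.empty_like(rgb)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab


def lab_to_rgb(lab, white_point: str = "D65"):
    """Convert Lab back to companded sRGB.

    Returns ``(rgb, out_of_gamut)`` where ``out_of_gamut`` flags inputs
    whose linear channels fall outside [0, 1] before clamping.  On the
    in-gamut domain this is the exact inverse of :func:`rgb_to_lab`.
    """
    lab = np.asarray(lab, dtype=float)
    if lab.shape[-1] != 3:
        raise ValueError("last axis must hold 3 (L*, a*, b*) values")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    ft = np.stack([fx, fy, fz], axis=-1)
    xyz = _f_cie_inv(ft) * WHITE_POINTS[white_point]
    lin = xyz @ _M_XYZ2RGB[white_point].T
    out_of_gamut = np.any((lin < -1e-9) | (lin > 1.0 + 1e-9), axis=-1)
    lin = np.clip(lin, 0.0, 1.0)
    return linear_to_srgb(lin), out_of_gamut


def delta_e_ab(lab1, lab2) -> np.ndarray:
    """Delta E*ab: Euclidean distance between Lab colours (broadcasting)."""
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    return np.sqrt(np.sum((lab1 - lab2) ** 2, axis=-1))
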