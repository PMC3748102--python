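import numpy as np
import pytest

from floracolor.imaging import ImageRGB


@pytest.fixture
def rng():
    return np.random.default_rng(20130820)


@pytest.fixture
def uniform_image():
    """A 10x10 mid-grey image."""
    return ImageRGB(pixels=np.full((10, 10, 3), 0.5), source_bit_depth=8)


def reference_lab_oracle(rgb):
    """Independent evaluation of the CIE L*a*b* formulas for tests.

    Derives the sRGB->XYZ matrix from the IEC 61966-2-1 primary/white
    chromaticities by explicit cofactor inversion and evaluates the sRGB
    decoding and CIE f() piecewise functions scalar-by-scalar, sharing no
    code with the package implementation.
    """
    rgb = np.atleast_2d(np.asarray(rgb, dtype=float))

    def decode(u):
        return u / 12.92 if u <= 0.04045 else ((u + 0.055) / 1.055) ** 2.4

    # columns: XYZ of unit primaries scaled so white (1,1,1) hits D65
    chroma = {"R": (0.64, 0.33), "G": (0.30, 0.60), "B": (0.15, 0.06)}
    cols = {}
    for k, (x, y) in chroma.items():
        cols[k] = [x / y, 1.0, (1.0 - x - y) / y]
    P = [[cols[k][i] for k in "RGB"] for i in range(3)]
    xw, yw = 0.3127, 0.3290
    W = [xw / yw, 1.0, (1.0 - xw - yw) / yw]
    # solve P s = W via cofactor (adjugate) inverse
    det = (
        P[0][0] * (P[1][1] * P[2][2] - P[1][2] * P[2][1])
        - P[0][1] * (P[1][0] * P[2][2] - P[1][2] * P[2][0])
        + P[0][2] * (P[1][0] * P[2][1] - P[1][1] * P[2][0])
    )
    adj = [
        [
            P[1][1] * P[2][2] - P[1][2] * P[2][1],
            P[0][2] * P[2][1] - P[0][1] * P[2][2],
            P[0][1] * P[1][2] - P[0][2] * P[1][1],
        ],
        [
            P[1][2] * P[2][0] - P[1][0] * P[2][2],
            P[0][0] * P[2][2] - P[0][2] * P[2][0],
            P[0][2] * P[1][0] - P[0][0] * P[1][2],
        ],
        [
            P[1][0] * P[2][1] - P[1][1] * P[2][0],
            P[0][1] * P[2][0] - P[0][0] * P[2][1],
            P[0][0] * P[1][1] - P[0][1] * P[1][0],
        ],
    ]
    s = [sum(adj[i][j] * W[j] for j in range(3)) / det for i in range(3)]
    M = [[P[i][j] * s[j] for j in range(3)] for i in range(3)]
    Wn = [sum(M[i][j] for j in range(3)) for i in range(3)]

    def f(t):
        d = 6.0 / 29.0
        return t ** (1.0 / 3.0) if t > d**3 else t / (3.0 * d**2) + 4.0 / 29.0

    out = np.empty_like(rgb)
    for row in range(rgb.shape[0]):
        lin = [decode(v) for v in rgb[row]]
        xyz = [sum(M[i][j] * lin[j] for j in range(3)) for i in range(3)]
        fx, fy, fz = (f(xyz[i] / Wn[i]) for i in range(3))
        out[row] = [116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)]
    return out
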