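"""Colorimetric primitives.

CIE xyY <-> L*a*b* conversion under a fixed white point, the two colour
difference formulas used throughout the package (plain Euclidean Delta-E and
CIE94), and the rotation operator about the L* axis that underlies every
randomisation in the toolkit.

Conventions
-----------
* The white point is illuminant C with the CIE 1931 2-degree observer,
  chromaticity (x, y) = (0.31006, 0.31616), luminance factor Y = 100.
* Angles are degrees at the API boundary, radians internally.
* CIE94 uses the graphic-arts constants (kL = kC = kH = 1, K1 = 0.045,
  K2 = 0.015) and is asymmetric: the *first* argument is the reference
  colour whose chroma enters the S_C and S_H weights.  A symmetrised
  variant (geometric-mean chroma) is available behind ``symmetric=True``.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np


class XyYPoint(NamedTuple):
    """A colour in CIE xyY: chromaticity (x, y) and luminance factor Y."""

    x: float
    y: float
    Y: float


class LabPoint(NamedTuple):
    """A colour in CIE L*a*b*."""

    L: float
    a: float
    b: float


#: Illuminant C, 2-degree observer, Y normalised to 100.
ILLUMINANT_C = XyYPoint(0.31006, 0.31616, 100.0)

_DELTA = 6.0 / 29.0  # cusp of the CIE f(t) piecewise function


def _whitepoint_xyz(whitepoint: XyYPoint) -> np.ndarray:
    x, y, Y = whitepoint
    if Y != 100.0:
        raise ValueError("whitepoint must have Y normalised to 100")
    if y <= 0:
        raise ValueError("whitepoint chromaticity y must be positive")
    return np.array([x * Y / y, Y, (1.0 - x - y) * Y / y])


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3.0 * _DELTA**2) + 4.0 / 29.0)


def _finv(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(u > _DELTA, u**3, 3.0 * _DELTA**2 * (u - 4.0 / 29.0))


def _as_triplets(p) -> tuple[np.ndarray, bool]:
    """Coerce a point or an (n, 3) array to (n, 3); flag if input was a point."""
    arr = np.asarray(p, dtype=float)
    if arr.shape == (3,):
        return arr[None, :], True
    if arr.ndim == 2 and arr.shape[1] == 3:
        return arr, False
    raise ValueError(f"expected a 3-vector or an (n, 3) array, got shape {arr.shape}")


def xyy_to_lab(p, whitepoint: XyYPoint = ILLUMINANT_C):
    """Convert xyY to L*a*b* via the standard xyY -> XYZ -> L*a*b* chain.

    ``p`` may be an :class:`XyYPoint` (returns :class:`LabPoint`) or an
    (n, 3) array of xyY rows (returns an (n, 3) array of Lab rows).

    Raises
    ------
    ValueError
        If any chromaticity y is zero (undefined chromaticity) or any
        coordinate violates the xyY invariants.
    """
    arr, single = _as_triplets(p)
    x, y, Y = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(y <= 0):
        raise ValueError("chromaticity y = 0: chromaticity undefined")
    if np.any((x < 0) | (Y < 0) | (x + y > 1.0 + 1e-12)):
        raise ValueError("xyY coordinates out of range (need x,y >= 0, x+y <= 1, Y >= 0)")
    X = x * Y / y
    Z = (1.0 - x - y) * Y / y
    wp = _whitepoint_xyz(whitepoint)
    fx, fy, fz = _f(X / wp[0]), _f(Y / wp[1]), _f(Z / wp[2])
    lab = np.column_stack([116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz)])
    if single:
        return LabPoint(*lab[0])
    return lab


def lab_to_xyy(p, whitepoint: XyYPoint = ILLUMINANT_C):
    """Inverse of :func:`xyy_to_lab`.

    For L* = 0 the luminance is zero and the chromaticity is undefined; the
    white point chromaticity is returned by convention.
    """
    arr, single = _as_triplets(p)
    L, a, b = arr[:, 0], arr[:, 1], arr[:, 2]
    wp = _whitepoint_xyz(whitepoint)
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    X = wp[0] * _finv(fx)
    Y = wp[1] * _finv(fy)
    Z = wp[2] * _finv(fz)
    s = X + Y + Z
    wx, wy = whitepoint.x, whitepoint.y
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(s > 0, X / np.where(s > 0, s, 1.0), wx)
        y = np.where(s > 0, Y / np.where(s > 0, s, 1.0), wy)
    xyy = np.column_stack([x, y, Y])
    if single:
        return XyYPoint(*xyy[0])
    return xyy


def euclidean_delta_e(u, v) -> float | np.ndarray:
    """Plain Euclidean distance in L*a*b* (the dispersion statistic's Delta-E)."""
    ua, us = _as_triplets(u)
    va, vs = _as_triplets(v)
    d = np.sqrt(np.sum((ua - va) ** 2, axis=1))
    if us and vs:
        return float(d[0])
    return d


def cie94_delta_e(u, v, symmetric: bool = False) -> float | np.ndarray:
    """CIE94 colour difference with graphic-arts constants.

    The first argument is the reference colour (its chroma sets the S_C and
    S_H weights) unless ``symmetric=True``, in which case the geometric mean
    of the two chromas is used and the formula becomes symmetric.
    """
    ua, us = _as_triplets(u)
    va, vs = _as_triplets(v)
    dL = ua[:, 0] - va[:, 0]
    da = ua[:, 1] - va[:, 1]
    db = ua[:, 2] - va[:, 2]
    c1 = np.hypot(ua[:, 1], ua[:, 2])
    c2 = np.hypot(va[:, 1], va[:, 2])
    dC = c1 - c2
    dH2 = np.maximum(da**2 + db**2 - dC**2, 0.0)
    c_ref = np.sqrt(c1 * c2) if symmetric else c1
    sC = 1.0 + 0.045 * c_ref
    sH = 1.0 + 0.015 * c_ref
    d = np.sqrt(dL**2 + (dC / sC) ** 2 + dH2 / sH**2)
    if us and vs:
        return float(d[0])
    return d


def cie94_matrix(labs, labs2=None, symmetric: bool = False) -> np.ndarray:
    """Pairwise CIE94 distances, rows referencing ``labs`` (first-argument rule).

    Returns an (n, m) array with entry [i, j] = CIE94(labs[i], labs2[j]).
    With ``labs2=None`` the matrix is labs-vs-labs (asymmetric unless
    ``symmetric=True``).
    """
    A = np.asarray(labs, dtype=float)
    B = A if labs2 is None else np.asarray(labs2, dtype=float)
    dL = A[:, 0:1] - B[None, :, 0]
    da = A[:, 1:2] - B[None, :, 1]
    db = A[:, 2:3] - B[None, :, 2]
    c1 = np.hypot(A[:, 1], A[:, 2])[:, None]
    c2 = np.hypot(B[:, 1], B[:, 2])[None, :]
    dC = c1 - c2
    dH2 = np.maximum(da**2 + db**2 - dC**2, 0.0)
    c_ref = np.sqrt(c1 * c2) if symmetric else np.broadcast_to(c1, dC.shape)
    sC = 1.0 + 0.045 * c_ref
    sH = 1.0 + 0.015 * c_ref
    return np.sqrt(dL**2 + (dC / sC) ** 2 + dH2 / sH**2)


def rotate_about_L(p, angle_degrees):
    """Rotate a Lab point (or rows of points) about the L* axis.

    L* is untouched; (a*, b*) rotate in the chromatic plane, so the chroma
    radius sqrt(a*^2 + b*^2) is preserved.  ``angle_degrees`` may be a scalar
    or, for array input, one angle per row.
    """
    arr, single = _as_triplets(p)
    theta = np.deg2rad(np.asarray(angle_degrees, dtype=float))
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    a, b = arr[:, 1], arr[:, 2]
    out = np.column_stack([arr[:, 0], a * cos_t - b * sin_t, a * sin_t + b * cos_t])
    if single:
        return LabPoint(*out[0])
    return out


def hue_angle(a, b) -> np.ndarray:
    """Hue angle atan2(b*, a*) in radians, wrap-aware (quadrant-correct)."""
    return np.arctan2(np.asarray(b, dtype=float), np.asarray(a, dtype=float))


def chroma_radius(a, b) -> np.ndarray:
    """Chroma radius sqrt(a*^2 + b*^2)."""
    return np.hypot(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


def angular_difference(t1, t2) -> np.ndarray:
    """Absolute angular difference in radians, wrapped to [0, pi]."""
    d = np.abs(np.asarray(t1, dtype=float) - np.asarray(t2, dtype=float)) % (2 * np.pi)
    return np.where(d > np.pi, 2 * np.pi - d, d)
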