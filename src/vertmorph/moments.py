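"""Density-weighted cross-sectional bone parameters.

For one segmented cross-section with per-pixel bone mineral density
BMD(x, y) (mg/cm^3), the flexural-strength index is the minimum over axis
angle theta of the density-weighted second moment about a line through the
density-weighted center of gravity (X_g, Y_g):

    I(theta) = sum_pixels  dist(pixel, line)^2 * BMD * dA      [mg*cm]
    dist     = | -sin(theta) (x - X_g) + cos(theta) (y - Y_g) |

and the torsional-strength index is the polar moment about the centroid:

    J = sum_pixels  r^2 * BMD * dA,   r^2 = (x - X_g)^2 + (y - Y_g)^2.

I(theta) is a quadratic form of the 2x2 density-weighted second-moment
tensor, so I_min is its smaller eigenvalue and J its trace; the module also
computes volumetric BMD (mineral content / (d * sum S(i))), mean cortical
thickness, and vertebral body height/width, each averaged over L2-L4.

Pixels are treated as point masses at pixel centers carrying their pixel
area; coordinates are pixel centers times the pixel spacing.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .segment import BoneMask, local_thickness_px
from .stack_io import CalibratedStack

__all__ = [
    "compute_centroid",
    "moment_about_axis",
    "second_moment_tensor",
    "minimum_cross_sectional_moment",
    "polar_moment",
    "bmd_and_volume",
    "slice_cortical_thickness",
    "mean_cortical_thickness",
    "vertebral_dimensions",
    "vertebra_average",
]

DEFAULT_VERTEBRAE = ("L2", "L3", "L4")

# relative scale below which the second-moment tensor is treated as isotropic
_TIE_RTOL = 1e-12


def _bone_mask(mask) -> np.ndarray:
    if isinstance(mask, BoneMask):
        return mask.bone
    return np.asarray(mask, dtype=bool)


def _bone_coords(slice_map, mask, pixel_spacing):
    """(x, y, bmd) arrays over bone pixels, pixel-center coordinates in cm."""
    bone = _bone_mask(mask)
    if not bone.any():
        raise ValueError("empty bone mask")
    rows, cols = np.nonzero(bone)
    x = (cols + 0.5) * pixel_spacing
    y = (rows + 0.5) * pixel_spacing
    bmd = np.asarray(slice_map, dtype=float)[rows, cols]
    return x, y, bmd


def compute_centroid(slice_map, mask, pixel_spacing: float) -> tuple[float, float]:
    """Density-weighted center of gravity (X_g, Y_g) of one slice, in cm."""
    x, y, bmd = _bone_coords(slice_map, mask, pixel_spacing)
    total = bmd.sum()
    if total <= 0:
        raise ValueError("non-positive total density in bone mask")
    return float((x * bmd).sum() / total), float((y * bmd).sum() / total)


def moment_about_axis(
    slice_map, mask, centroid: tuple[float, float], theta: float, pixel_spacing: float
) -> float:
    """Density-weighted second moment about the centroid line at angle theta.

    Direct per-pixel sum of squared point-to-line distances; finite for all
    theta including pi/2.  Units mg*cm.
    """
    x, y, bmd = _bone_coords(slice_map, mask, pixel_spacing)
    xg, yg = centroid
    dist = -math.sin(theta) * (x - xg) + math.cos(theta) * (y - yg)
    area = pixel_spacing * pixel_spacing
    return float((dist * dist * bmd).sum() * area)


def second_moment_tensor(
    slice_map, mask, centroid: tuple[float, float], pixel_spacing: float
) -> tuple[float, float, float]:
    """(Ixx, Iyy, Ixy) about the centroid, density weighted.

    Ixx = sum BMD dy^2 dA (moment about the horizontal axis), Iyy about the
    vertical axis, Ixy the product term; I(theta) = cos^2 Ixx + sin^2 Iyy -
    2 sin cos Ixy.
    """
    x, y, bmd = _bone_coords(slice_map, mask, pixel_spacing)
    xg, yg = centroid
    dx, dy = x - xg, y - yg
    area = pixel_spacing * pixel_spacing
    ixx = float((bmd * dy * dy).sum() * area)
    iyy = float((bmd * dx * dx).sum() * area)
    ixy = float((bmd * dx * dy).sum() * area)
    return ixx, iyy, ixy


def minimum_cross_sectional_moment(
    slice_map, mask, centroid: tuple[float, float], pixel_spacing: float
) -> tuple[float, float]:
    """Closed-form minimum of I(theta) and its principal angle.

    Returns ``(I_min, theta_star)`` with theta_star in [0, pi); an isotropic
    tensor (circular symmetry) reports theta_star = 0.
    """
    ixx, iyy, ixy = second_moment_tensor(slice_map, mask, centroid, pixel_spacing)
    avg = 0.5 * (ixx + iyy)
    diff = 0.5 * (ixx - iyy)
    radius = math.hypot(diff, ixy)
    imin = max(avg - radius, 0.0)
    if radius <= _TIE_RTOL * max(avg, 1.0):
        return imin, 0.0
    theta = 0.5 * math.atan2(ixy, -diff)
    return imin, theta % math.pi


def polar_moment(
    slice_map, mask, centroid: tuple[float, float], pixel_spacing: float
) -> float:
    """Density-weighted polar moment J about the centroid, mg*cm."""
    x, y, bmd = _bone_coords(slice_map, mask, pixel_spacing)
    xg, yg = centroid
    r2 = (x - xg) ** 2 + (y - yg) ** 2
    area = pixel_spacing * pixel_spacing
    return float((r2 * bmd).sum() * area)


def bmd_and_volume(
    stack: CalibratedStack,
    masks: Sequence[BoneMask | np.ndarray | None],
    vertebrae: Sequence[str] | None = None,
) -> tuple[float, float, float]:
    """Volumetric BMD over the labeled analysis window.

    S(i) is the bone-pixel area of slice i; volume = d * sum S(i); mineral
    content integrates BMD over bone pixels times pixel area times d; BMD is
    their ratio.  Slices with a missing or empty mask are excluded; if every
    slice is excluded this is an error.
    Returns ``(bmd mg/cm^3, mineral_content mg, volume cm^3)``.
    """
    indices = stack.labeled_slices(vertebrae)
    area = stack.pixel_spacing**2
    d = stack.slice_interval_d
    total_area = 0.0
    mineral = 0.0
    used = 0
    for i in indices:
        m = masks[i]
        if m is None:
            continue
        bone = _bone_mask(m)
        if not bone.any():
            continue
        total_area += bone.sum() * area
        mineral += float(stack.slices[i][bone].sum()) * area * d
        used += 1
    if used == 0:
        raise ValueError("all slices excluded; cannot compute BMD")
    volume = d * total_area
    return mineral / volume, mineral, volume


def slice_cortical_thickness(mask: BoneMask, pixel_spacing: float) -> float:
    """Mean cortical thickness of one slice in mm; NaN for a broken ring."""
    if mask.empty or not mask.ring_ok:
        return float("nan")
    t_px = local_thickness_px(mask.cortical)
    return t_px * pixel_spacing * 10.0


def mean_cortical_thickness(
    masks_by_vertebra: Mapping[str, Sequence[BoneMask]],
    pixel_spacing: float,
    vertebrae: Sequence[str] = DEFAULT_VERTEBRAE,
) -> float:
    """L2-L4 mean cortical thickness, mm.

    Per-slice local thickness (medial-axis rule) is averaged within each
    vertebra (broken-ring slices skipped), then the per-vertebra means are
    averaged.  A vertebra whose every ring is broken is an error.
    """
    per_vertebra: dict[str, float] = {}
    for name in vertebrae:
        if name not in masks_by_vertebra:
            raise ValueError(f"missing vertebra {name!r} for thickness")
        vals = [
            slice_cortical_thickness(m, pixel_spacing) for m in masks_by_vertebra[name]
        ]
        vals = [v for v in vals if not math.isnan(v)]
        if not vals:
            raise ValueError(f"vertebra {name!r}: every cortical ring is broken")
        per_vertebra[name] = float(np.mean(vals))
    return vertebra_average(per_vertebra, vertebrae)


def _transverse_extent_mm(bone: np.ndarray, pixel_spacing: float) -> float:
    cols = np.nonzero(bone.any(axis=0))[0]
    if cols.size == 0:
        return float("nan")
    return (cols[-1] - cols[0] + 1) * pixel_spacing * 10.0


def vertebral_dimensions(
    stack: CalibratedStack,
    masks: Sequence[BoneMask | np.ndarray | None],
    vertebra: str,
) -> tuple[float, float]:
    """Body height and width of one vertebra, mm.

    Height is the labeled slice count times the inter-slice interval d.
    Width follows the intermediate-value convention: the mean of the
    transverse bone extents at the superior (first) and inferior (last)
    labeled slices.
    """
    first, last = stack.vertebra_labels[vertebra]
    n = last - first + 1
    if n < 2:
        raise ValueError(f"vertebra {vertebra!r} spans a single slice")
    height = n * stack.slice_interval_d * 10.0
    extents = []
    for i in (first, last):
        m = masks[i]
        if m is None:
            raise ValueError(f"vertebra {vertebra!r}: end slice {i} has no mask")
        extents.append(_transverse_extent_mm(_bone_mask(m), stack.pixel_spacing))
    width = float(np.mean(extents))
    return height, width


def vertebra_average(
    values: Mapping[str, float], vertebrae: Sequence[str] = DEFAULT_VERTEBRAE
) -> float:
    """Arithmetic mean over the L2-L4 values; a missing vertebra is an error."""
    missing = [v for v in vertebrae if v not in values]
    if missing:
        raise ValueError(f"missing vertebra value(s): {missing}")
    return float(np.mean([values[v] for v in vertebrae]))
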