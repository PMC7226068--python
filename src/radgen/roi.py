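"""Whole / inner / outer ROI partitioning of a tumor mask.

The tumor core ("inner" ROI) is obtained by morphological erosion of the
whole mask with an ellipsoidal structuring element whose physical radius is
``(1 - inner_fraction)`` times the equivalent-sphere radius of the tumor.
The peripheral rim ("outer" ROI) is the set difference.  Erosion is defined
in millimetres and discretized per axis through the voxel spacing, so the
split behaves sensibly on anisotropic CT grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ROISet:
    """Disjoint partition of a tumor mask into core and rim.

    Invariants: ``inner | outer == whole``, ``inner & outer == {}``.
    """

    whole: np.ndarray
    inner: np.ndarray
    outer: np.ndarray
    inner_fraction: float

    def __post_init__(self) -> None:
        if self.whole.shape != self.inner.shape or self.whole.shape != self.outer.shape:
            raise ValueError("ROI masks must share one shape")


def equivalent_sphere_radius_mm(mask: np.ndarray, spacing) -> float:
    """Radius (mm) of the sphere whose volume equals the mask volume."""
    volume = int(np.count_nonzero(mask)) * float(np.prod(spacing))
    return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def _ellipsoid_structuring_element(radius_mm: float, spacing) -> np.ndarray:
    """Ball of the given physical radius, discretized on the voxel grid."""
    r_vox = np.maximum(radius_mm / np.asarray(spacing, dtype=float), 0.0)
    half = np.floor(r_vox).astype(int)
    grids = np.ogrid[tuple(slice(-h, h + 1) for h in half)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, np.asarray(spacing, dtype=float)))
    return dist2 <= radius_mm**2 + 1e-9


def partition_roi(mask: np.ndarray, spacing, inner_fraction: float = 0.5) -> ROISet:
    """Split a binary tumor mask into whole, inner (core) and outer (rim) ROIs.

    Parameters
    ----------
    mask:
        Binary 3D array, non-empty.
    spacing:
        Voxel spacing in mm per axis (positive).
    inner_fraction:
        In (0, 1).  The erosion radius is ``(1 - inner_fraction)`` times the
        equivalent-sphere radius of the mask, so larger values keep a larger
        core.  If the erosion empties the mask the inner ROI is empty and the
        outer ROI equals the whole mask.

    Returns
    -------
    ROISet
        With ``inner ∪ outer = whole`` and ``inner ∩ outer = ∅``.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError("spacing must be three positive finite values (mm)")
    if not 0.0 < inner_fraction < 1.0:
        raise ValueError("inner_fraction must lie strictly between 0 and 1")

    radius_mm = (1.0 - inner_fraction) * equivalent_sphere_radius_mm(mask, spacing)
    selem = _ellipsoid_structuring_element(radius_mm, spacing)
    if selem.size == 1:
        # sub-voxel radius: erode with the minimal 6-connected element so a
        # positive radius always peels at least the surface layer
        selem = ndimage.generate_binary_structure(3, 1)
    inner = ndimage.binary_erosion(mask, structure=selem)
    if not inner.any():
        inner = np.zeros_like(mask)
    outer = mask & ~inner
    return ROISet(whole=mask, inner=inner, outer=outer, inner_fraction=inner_fraction)
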