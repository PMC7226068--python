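"""Morphology (shape) features of the whole-tumor mask."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from radgen.features.registry import MORPHOLOGY_FEATURES


def _surface_area(mask: np.ndarray, spacing: np.ndarray) -> float:
    """Triangulated iso-surface area (mm^2) of the mask via marching cubes.

    The binary mask is lightly smoothed (Gaussian, 0.5 voxel) before
    iso-surfacing to suppress the staircase area inflation of a raw voxel
    surface; tiny masks whose smoothed field never reaches the 0.5 level
    fall back to the raw binary surface.
    """
    padded = np.pad(mask.astype(float), 2)
    smoothed = ndimage.gaussian_filter(padded, sigma=0.5)
    field = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5, spacing=tuple(spacing))
    return float(measure.mesh_surface_area(verts, faces))


def _max_diameter(coords_mm: np.ndarray) -> float:
    """Largest pairwise Euclidean distance (mm) between mask voxel centres."""
    if len(coords_mm) <= 2:
        return float(pdist(coords_mm).max()) if len(coords_mm) == 2 else 0.0
    try:
        pts = coords_mm[ConvexHull(coords_mm).vertices]
    except QhullError:  # degenerate (coplanar/collinear) clouds
        pts = coords_mm
    return float(pdist(pts).max())


def morphology_features(mask: np.ndarray, spacing) -> dict[str, float]:
    """The 8 geometry features of a binary tumor mask.

    Volume is voxel count x voxel volume; surface area comes from a
    marching-cubes iso-surface; sphericity is ``(36 pi V^2)^(1/3) / A`` (1 for
    a perfect ball); compactness is ``36 pi V^2 / A^3``; elongation and
    flatness are ``sqrt(l2/l1)`` and ``sqrt(l3/l1)`` for the sorted
    eigenvalues ``l1 >= l2 >= l3`` of the voxel point cloud's covariance (1
    for an isotropic cloud, small for stick- or plate-like shapes).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a non-empty 3D array")
    spacing = np.asarray(spacing, dtype=float)
    voxel_volume = float(np.prod(spacing))

    volume = float(np.count_nonzero(mask)) * voxel_volume
    area = _surface_area(mask, spacing)
    coords = np.argwhere(mask) * spacing

    if len(coords) > 1:
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(coords.T)))[::-1]
        eigvals = np.clip(eigvals, 0.0, None)
        elongation = float(np.sqrt(eigvals[1] / eigvals[0])) if eigvals[0] > 0 else 1.0
        flatness = float(np.sqrt(eigvals[2] / eigvals[0])) if eigvals[0] > 0 else 1.0
    else:
        elongation = flatness = 1.0

    out = {
        "Volume": volume,
        "SurfaceArea": area,
        "SurfaceToVolumeRatio": area / volume,
        "Sphericity": float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area),
        "Compactness": float(36.0 * np.pi * volume**2 / area**3),
        "Max3DDiameter": _max_diameter(coords),
        "Elongation": elongation,
        "Flatness": flatness,
    }
    assert tuple(out) == MORPHOLOGY_FEATURES
    return out
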