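"""Intensity size-zone features.

A zone is a maximal 26-connected set of in-mask voxels sharing one
discretized gray level (32 equal-width bins by default).  Two summary
features are exposed: the zone percentage (zones per voxel — high when the
texture fragments into many small zones) and the normalized size-zone
non-uniformity (concentration of the zone-size distribution — 1 when all
zones have the same size).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from radgen.features.glcm import discretize
from radgen.features.registry import ISZM_FEATURES

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def zone_sizes(intensities: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Sizes (voxel counts) of all constant-gray-level 26-connected zones."""
    mask = np.asarray(mask).astype(bool)
    levels = discretize(intensities, mask, n_bins)
    sizes: list[int] = []
    for lev in np.unique(levels[mask]):
        labeled, n_zones = ndimage.label(levels == lev, structure=_STRUCT_26)
        counts = np.bincount(labeled.ravel())[1:]  # drop background
        sizes.extend(int(c) for c in counts if c > 0)
    return np.asarray(sizes, dtype=int)


def iszm_features(intensities: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> dict[str, float]:
    """Zone percentage and normalized size-zone non-uniformity of an ROI."""
    mask = np.asarray(mask).astype(bool)
    n_voxels = int(np.count_nonzero(mask))
    if n_voxels == 0:
        raise ValueError("empty ROI")
    sizes = zone_sizes(intensities, mask, n_bins)
    n_zones = sizes.size
    size_hist = np.bincount(sizes)
    out = {
        "ZonePercentage": n_zones / n_voxels,
        "SizeZoneNonUniformityNormalized": float(np.sum(size_hist.astype(float) ** 2)) / n_zones**2,
    }
    assert tuple(out) == ISZM_FEATURES
    return out
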