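"""Gray-level co-occurrence matrix (GLCM) texture features in 3D.

Co-occurrences are counted over the 13 unique 3D unit offsets (half of the
26-neighborhood; the other half is covered by symmetrization), restricted to
voxel pairs that both lie inside the mask.  Each per-offset matrix is
normalized to sum 1; the 16 features are computed per offset and averaged
over offsets that contain at least one pair.
"""

from __future__ import annotations

import numpy as np

from radgen.features.registry import GLCM_FEATURES

#: The 13 unique unit displacement vectors of the 26-neighborhood.
GLCM_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)
assert len(GLCM_OFFSETS) == 13


def discretize(intensities: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning of in-mask intensities to levels 0..n_bins-1.

    Out-of-mask voxels get level -1.  A constant region maps to level 0.
    """
    mask = np.asarray(mask).astype(bool)
    vals = np.asarray(intensities, dtype=float)
    inroi = vals[mask]
    if inroi.size == 0:
        raise ValueError("empty ROI")
    lo, hi = float(inroi.min()), float(inroi.max())
    levels = np.full(vals.shape, -1, dtype=np.int64)
    if lo == hi:
        levels[mask] = 0
    else:
        idx = np.floor((vals[mask] - lo) / (hi - lo) * n_bins).astype(np.int64)
        levels[mask] = np.clip(idx, 0, n_bins - 1)
    return levels


def glcm_matrices(
    intensities: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 128,
    offsets=GLCM_OFFSETS,
) -> list[np.ndarray]:
    """Symmetric, normalized co-occurrence matrices, one per offset with pairs."""
    levels = discretize(intensities, mask, n_bins)
    n_levels = int(levels.max()) + 1
    matrices = []
    for off in offsets:
        a = levels
        b = levels
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate(off):
            if d > 0:
                src[ax], dst[ax] = slice(None, -d), slice(d, None)
            elif d < 0:
                src[ax], dst[ax] = slice(-d, None), slice(None, d)
        i = a[tuple(src)].ravel()
        j = b[tuple(dst)].ravel()
        valid = (i >= 0) & (j >= 0)
        if not valid.any():
            continue
        m = np.zeros((n_levels, n_levels), dtype=float)
        np.add.at(m, (i[valid], j[valid]), 1.0)
        m = m + m.T  # symmetric counting
        matrices.append(m / m.sum())
    if not matrices:
        raise ValueError("no in-mask voxel pair for any offset")
    return matrices


def _matrix_features(p: np.ndarray) -> dict[str, float]:
    """The 16 features of one normalized symmetric GLCM (1-based gray levels)."""
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(i * px))
    sigma2 = float(np.sum((i - mu) ** 2 * px))

    # sum and difference distributions
    k_sum = np.arange(2, 2 * n + 1, dtype=float)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())
    k_diff = np.arange(0, n, dtype=float)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-np.sum(q * np.log2(q)))

    hxy = ent(p)
    hx = ent(px)
    pxpy = np.outer(px, px)
    valid = (p > 0) & (pxpy > 0)
    hxy1 = float(-np.sum(p[valid] * np.log2(pxpy[valid])))
    hxy2 = ent(pxpy)
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    autocorr = float(np.sum(ii * jj * p))
    out = {
        "Autocorrelation": autocorr,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": (autocorr - mu**2) / sigma2 if sigma2 > 0 else 1.0,
        "DifferenceEntropy": ent(p_diff),
        "Dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "AngularSecondMoment": float(np.sum(p**2)),
        "Entropy": hxy,
        "InverseDifferenceMoment": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "IMC1": imc1,
        "IMC2": imc2,
        "MaxProbability": float(p.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": ent(p_sum),
    }
    assert tuple(out) == GLCM_FEATURES
    return out


def glcm_features(
    intensities: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 128,
    offsets=GLCM_OFFSETS,
) -> dict[str, float]:
    """Offset-averaged GLCM features of the in-mask intensities."""
    matrices = glcm_matrices(intensities, mask, n_bins=n_bins, offsets=offsets)
    per_offset = [_matrix_features(m) for m in matrices]
    return {
        name: float(np.mean([f[name] for f in per_offset])) for name in GLCM_FEATURES
    }
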