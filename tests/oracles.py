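"""Independent brute-force oracles used to pin the feature implementations.

Everything here is written as plain loops over voxels/bins, deliberately
avoiding the vectorized code paths of the package.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


# --------------------------------------------------------------------------
# first-order
# --------------------------------------------------------------------------

def brute_histogram_features(values, n_bins=128, voxel_volume=1.0):
    vals = sorted(float(v) for v in np.asarray(values).ravel())
    n = len(vals)
    lo, hi = vals[0], vals[-1]
    mean = sum(vals) / n
    m2 = sum((v - mean) ** 2 for v in vals) / n
    m3 = sum((v - mean) ** 3 for v in vals) / n
    m4 = sum((v - mean) ** 4 for v in vals) / n

    if lo == hi:
        counts = [n]
    else:
        counts = [0] * n_bins
        width = (hi - lo) / n_bins
        for v in vals:
            b = min(int((v - lo) / width), n_bins - 1)
            counts[b] += 1
    probs = [c / n for c in counts]

    p10, p25, p75, p90 = (float(np.percentile(vals, q)) for q in (10, 25, 75, 90))
    robust = [v for v in vals if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    energy = sum(c**2 for c in counts)
    return {
        "Min": lo,
        "Max": hi,
        "Mean": mean,
        "Median": float(np.median(vals)),
        "P10": p10,
        "P90": p90,
        "IQR": p75 - p25,
        "Range": hi - lo,
        "MAD": sum(abs(v - mean) for v in vals) / n,
        "RobustMAD": sum(abs(v - rmean) for v in robust) / len(robust),
        "RMS": math.sqrt(sum(v**2 for v in vals) / n),
        "StdDev": math.sqrt(m2),
        "Variance": m2,
        "Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "Entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "Uniformity": sum(p**2 for p in probs),
        "Energy": float(energy),
        "TotalEnergy": float(energy) * voxel_volume,
    }


# --------------------------------------------------------------------------
# GLCM
# --------------------------------------------------------------------------

def brute_discretize(intensities, mask, n_bins):
    vals = [float(intensities[idx]) for idx in zip(*np.nonzero(mask))]
    lo, hi = min(vals), max(vals)
    levels = {}
    for idx in zip(*np.nonzero(mask)):
        if lo == hi:
            levels[idx] = 0
        else:
            b = int((float(intensities[idx]) - lo) / (hi - lo) * n_bins)
            levels[idx] = min(max(b, 0), n_bins - 1)
    return levels


def brute_glcm_matrix(intensities, mask, offset, n_bins=128):
    """Symmetric normalized co-occurrence matrix for one offset, or None."""
    levels = brute_discretize(intensities, mask, n_bins)
    n_levels = max(levels.values()) + 1
    counts: Counter = Counter()
    for (x, y, z), li in levels.items():
        nb = (x + offset[0], y + offset[1], z + offset[2])
        if nb in levels:
            lj = levels[nb]
            counts[(li, lj)] += 1
            counts[(lj, li)] += 1
    if not counts:
        return None
    total = sum(counts.values())
    p = np.zeros((n_levels, n_levels))
    for (i, j), c in counts.items():
        p[i, j] = c / total
    return p


def brute_glcm_matrix_features(p):
    """The 16 features of one normalized matrix, by explicit summation."""
    n = p.shape[0]
    px = [sum(p[i, j] for j in range(n)) for i in range(n)]
    mu = sum((i + 1) * px[i] for i in range(n))
    sigma2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(n))

    p_sum = Counter()
    p_diff = Counter()
    for i in range(n):
        for j in range(n):
            if p[i, j] > 0:
                p_sum[i + j + 2] += p[i, j]
                p_diff[abs(i - j)] += p[i, j]

    def H(probs):
        return -sum(q * math.log2(q) for q in probs if q > 0)

    hxy = H([p[i, j] for i in range(n) for j in range(n)])
    hx = H(px)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(n)
        for j in range(n)
        if p[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = H([px[i] * px[j] for i in range(n) for j in range(n)])

    autocorr = sum((i + 1) * (j + 1) * p[i, j] for i in range(n) for j in range(n))
    out = {
        "Autocorrelation": autocorr,
        "ClusterProminence": sum((i + j + 2 - 2 * mu) ** 4 * p[i, j] for i in range(n) for j in range(n)),
        "ClusterShade": sum((i + j + 2 - 2 * mu) ** 3 * p[i, j] for i in range(n) for j in range(n)),
        "ClusterTendency": sum((i + j + 2 - 2 * mu) ** 2 * p[i, j] for i in range(n) for j in range(n)),
        "Contrast": sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n)),
        "Correlation": (autocorr - mu**2) / sigma2 if sigma2 > 0 else 1.0,
        "DifferenceEntropy": H(p_diff.values()),
        "Dissimilarity": sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n)),
        "AngularSecondMoment": sum(p[i, j] ** 2 for i in range(n) for j in range(n)),
        "Entropy": hxy,
        "InverseDifferenceMoment": sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n)),
        "IMC1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "IMC2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "MaxProbability": float(p.max()),
        "SumAverage": sum(k * v for k, v in p_sum.items()),
        "SumEntropy": H(p_sum.values()),
    }
    return out


def brute_glcm_features(intensities, mask, n_bins=128, offsets=None):
    from radgen.features.glcm import GLCM_OFFSETS

    offsets = offsets or GLCM_OFFSETS
    per_offset = []
    for off in offsets:
        p = brute_glcm_matrix(intensities, mask, off, n_bins)
        if p is not None:
            per_offset.append(brute_glcm_matrix_features(p))
    keys = per_offset[0].keys()
    return {k: sum(f[k] for f in per_offset) / len(per_offset) for k in keys}


# --------------------------------------------------------------------------
# size-zone (flood fill over the 26-neighborhood)
# --------------------------------------------------------------------------

def brute_iszm_features(intensities, mask, n_bins=32):
    levels = brute_discretize(intensities, mask, n_bins)
    seen = set()
    sizes = []
    for start in levels:
        if start in seen:
            continue
        lev = levels[start]
        stack, zone = [start], set()
        seen.add(start)
        while stack:
            x, y, z = stack.pop()
            zone.add((x, y, z))
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if dx == dy == dz == 0:
                            continue
                        nb = (x + dx, y + dy, z + dz)
                        if nb in levels and nb not in seen and levels[nb] == lev:
                            seen.add(nb)
                            stack.append(nb)
        sizes.append(len(zone))
    n_voxels = len(levels)
    n_zones = len(sizes)
    size_counts = Counter(sizes)
    return {
        "ZonePercentage": n_zones / n_voxels,
        "SizeZoneNonUniformityNormalized": sum(c**2 for c in size_counts.values()) / n_zones**2,
    }


# --------------------------------------------------------------------------
# ROI erosion
# --------------------------------------------------------------------------

def brute_erode(mask, spacing, radius_mm):
    """Voxel is kept iff every voxel offset within radius_mm is in the mask."""
    spacing = [float(s) for s in spacing]
    half = [int(math.floor(radius_mm / s)) for s in spacing]
    offsets = [
        (dx, dy, dz)
        for dx in range(-half[0], half[0] + 1)
        for dy in range(-half[1], half[1] + 1)
        for dz in range(-half[2], half[2] + 1)
        if (dx * spacing[0]) ** 2 + (dy * spacing[1]) ** 2 + (dz * spacing[2]) ** 2
        <= radius_mm**2 + 1e-9
    ]
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for idx in zip(*np.nonzero(mask)):
        ok = True
        for off in offsets:
            nb = tuple(idx[a] + off[a] for a in range(3))
            if any(nb[a] < 0 or nb[a] >= shape[a] for a in range(3)) or not mask[nb]:
                ok = False
                break
        out[idx] = ok
    return out
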