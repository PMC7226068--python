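"""First-order (histogram) features of the in-ROI intensity distribution."""

from __future__ import annotations

import numpy as np

from radgen.features.registry import HISTOGRAM_FEATURES


def _bin_probabilities(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width bin counts and probabilities over the ROI's own [min, max]."""
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:  # constant ROI: all mass in a single bin
        counts = np.array([values.size], dtype=float)
    else:
        counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
        counts = counts.astype(float)
    return counts, counts / counts.sum()


def histogram_features(
    values: np.ndarray, n_bins: int = 128, voxel_volume: float = 1.0
) -> dict[str, float]:
    """The 19 first-order features of a set of in-ROI HU values.

    Parameters
    ----------
    values:
        In-ROI intensities (any shape; flattened), at least one voxel.
    n_bins:
        Number of equal-width bins spanning ``[min, max]`` for the
        entropy/uniformity/energy features.
    voxel_volume:
        Physical voxel volume in mm^3 (enters TotalEnergy only).

    Notes
    -----
    Entropy is in bits over normalized bin probabilities; uniformity is
    ``sum(p_i^2)``; energy is ``sum(n_i^2)`` over bin *counts*; skewness and
    kurtosis (Pearson, ``m4/m2^2``) of a constant ROI are defined as 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("empty ROI")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite intensities")

    mean = float(values.mean())
    centered = values - mean
    m2 = float(np.mean(centered**2))
    p10, p25, p75, p90 = np.percentile(values, [10, 25, 75, 90])
    robust = values[(values >= p10) & (values <= p90)]

    counts, probs = _bin_probabilities(values, n_bins)
    nonzero = probs[probs > 0]

    if m2 > 0:
        skewness = float(np.mean(centered**3)) / m2**1.5
        kurtosis = float(np.mean(centered**4)) / m2**2
    else:
        skewness = 0.0
        kurtosis = 0.0

    energy = float(np.sum(counts**2))
    out = {
        "Min": float(values.min()),
        "Max": float(values.max()),
        "Mean": mean,
        "Median": float(np.median(values)),
        "P10": float(p10),
        "P90": float(p90),
        "IQR": float(p75 - p25),
        "Range": float(values.max() - values.min()),
        "MAD": float(np.mean(np.abs(centered))),
        "RobustMAD": float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0,
        "RMS": float(np.sqrt(np.mean(values**2))),
        "StdDev": float(np.sqrt(m2)),
        "Variance": m2,
        "Skewness": skewness,
        "Kurtosis": kurtosis,
        "Entropy": float(-np.sum(nonzero * np.log2(nonzero))),
        "Uniformity": float(np.sum(probs**2)),
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume),
    }
    assert tuple(out) == HISTOGRAM_FEATURES
    return out
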