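"""Per-patient and per-cohort feature extraction."""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from radgen.features.firstorder import histogram_features
from radgen.features.glcm import glcm_features, glcm_matrices
from radgen.features.iszm import iszm_features
from radgen.features.morphology import morphology_features
from radgen.features.registry import FEATURE_COLUMNS, SEMANTIC_FEATURES
from radgen.roi import ROISet, partition_roi

logger = logging.getLogger(__name__)


def semantic_hu_ratios(
    intensities: np.ndarray, mask: np.ndarray, thresholds: Iterable[float] = (100.0, 80.0)
) -> dict[str, float]:
    """Fraction of in-mask voxels strictly under each HU threshold.

    The defaults (100, 80 HU) target the non-enhancing (necrotic) portion of
    a contrast-enhanced nephrographic-phase CT.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    vals = np.asarray(intensities, dtype=float)[mask]
    return {
        f"Under{int(t)}HURatio": float(np.count_nonzero(vals < t)) / vals.size
        for t in thresholds
    }


def _texture_block(roi_name: str, intensities: np.ndarray, mask: np.ndarray,
                   voxel_volume: float) -> dict[str, float]:
    vals = intensities[mask]
    out = {}
    for name, v in histogram_features(vals, n_bins=128, voxel_volume=voxel_volume).items():
        out[f"{roi_name}_{name}_Hist"] = v
    for name, v in glcm_features(intensities, mask, n_bins=128).items():
        out[f"{roi_name}_{name}_GLCM"] = v
    for name, v in iszm_features(intensities, mask, n_bins=32).items():
        out[f"{roi_name}_{name}_ISZM"] = v
    return out


def extract_features(
    intensities: np.ndarray,
    mask: np.ndarray,
    spacing,
    inner_fraction: float = 0.5,
) -> dict[str, float]:
    """All 121 features of one patient volume.

    Texture families (histogram / GLCM / size-zone) are computed on the
    whole, inner and outer ROIs; morphology and the semantic HU ratios on
    the whole ROI only.  If erosion empties the inner ROI, inner-family
    features fall back to the whole ROI (logged per patient by the caller).
    """
    rois: ROISet = partition_roi(mask, spacing, inner_fraction)
    voxel_volume = float(np.prod(np.asarray(spacing, dtype=float)))
    out: dict[str, float] = {}
    for roi_name, roi_mask in (("WHOLE", rois.whole), ("INNER", rois.inner), ("OUTER", rois.outer)):
        if not roi_mask.any():
            logger.warning("empty %s ROI; texture features fall back to the whole ROI", roi_name)
            roi_mask = rois.whole
        out.update(_texture_block(roi_name, intensities, roi_mask, voxel_volume))
    for name, v in morphology_features(rois.whole, spacing).items():
        out[f"WHOLE_{name}_Morph"] = v
    out.update(semantic_hu_ratios(intensities, rois.whole))
    return {c: out[c] for c in FEATURE_COLUMNS}


def signature_features(
    intensities: np.ndarray,
    mask: np.ndarray,
    spacing,
    inner_fraction: float = 0.5,
) -> dict[str, float]:
    """Only the four signature features (fast path for large simulations).

    Computes INNER_Min_Hist, INNER_MaxProbability_GLCM, OUTER_Energy_Hist and
    Under80HURatio without the remaining 117 columns; values are identical to
    the corresponding :func:`extract_features` entries.
    """
    rois = partition_roi(mask, spacing, inner_fraction)
    inner = rois.inner if rois.inner.any() else rois.whole
    outer = rois.outer if rois.outer.any() else rois.whole
    matrices = glcm_matrices(intensities, inner, n_bins=128)
    max_prob = float(np.mean([m.max() for m in matrices]))
    outer_vals = intensities[outer]
    lo, hi = float(outer_vals.min()), float(outer_vals.max())
    if lo == hi:
        energy = float(outer_vals.size) ** 2
    else:
        counts, _ = np.histogram(outer_vals, bins=128, range=(lo, hi))
        energy = float(np.sum(counts.astype(float) ** 2))
    return {
        "INNER_Min_Hist": float(intensities[inner].min()),
        "INNER_MaxProbability_GLCM": max_prob,
        "OUTER_Energy_Hist": energy,
        "Under80HURatio": semantic_hu_ratios(intensities, rois.whole)["Under80HURatio"],
    }


def extract_feature_table(cohort, inner_fraction: float = 0.5) -> pd.DataFrame:
    """Feature table (patients x 121 named features) for a list of volumes.

    Parameters
    ----------
    cohort:
        Iterable of :class:`~radgen.cohort.TumorVolume`.
    inner_fraction:
        Core fraction passed to the ROI partitioner.

    Raises
    ------
    RuntimeError
        Naming the patient on any per-patient failure.
    """
    rows = {}
    for vol in cohort:
        try:
            rows[vol.patient_id] = extract_features(
                vol.intensities, vol.mask, vol.spacing, inner_fraction
            )
        except Exception as exc:  # noqa: BLE001 - re-raise with patient context
            raise RuntimeError(f"feature extraction failed for patient {vol.patient_id}: {exc}") from exc
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_COLUMNS))
    table.index.name = "patient_id"
    return table
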