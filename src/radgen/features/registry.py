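"""Frozen feature registry: names, families and the canonical column order.

The exact membership of the 19-histogram / 16-GLCM / 2-size-zone rosters is a
package design choice pinned here (and by the test suite); the four signature
features the downstream risk model uses -- INNER_Min_Hist, OUTER_Energy_Hist,
INNER_MaxProbability_GLCM, Under80HURatio -- are guaranteed members.

Conventions pinned by this registry
-----------------------------------
* histogram ``Energy`` is the sum of squared *bin counts* (and
  ``TotalEnergy`` multiplies it by the voxel volume in mm^3); ``Uniformity``
  is the sum of squared bin probabilities -- the two are kept distinct,
* all entropies use log base 2 (bits),
* skewness and kurtosis of a constant ROI are defined as 0,
* GLCM gray levels are 1-based bin indices; features are averaged over the
  13 unique symmetric 3D unit offsets,
* "under t HU" uses strict ``<``.
"""

from __future__ import annotations

HISTOGRAM_FEATURES: tuple[str, ...] = (
    "Min",
    "Max",
    "Mean",
    "Median",
    "P10",
    "P90",
    "IQR",
    "Range",
    "MAD",
    "RobustMAD",
    "RMS",
    "StdDev",
    "Variance",
    "Skewness",
    "Kurtosis",
    "Entropy",
    "Uniformity",
    "Energy",
    "TotalEnergy",
)

GLCM_FEATURES: tuple[str, ...] = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceEntropy",
    "Dissimilarity",
    "AngularSecondMoment",
    "Entropy",
    "InverseDifferenceMoment",
    "IMC1",
    "IMC2",
    "MaxProbability",
    "SumAverage",
    "SumEntropy",
)

ISZM_FEATURES: tuple[str, ...] = (
    "ZonePercentage",
    "SizeZoneNonUniformityNormalized",
)

MORPHOLOGY_FEATURES: tuple[str, ...] = (
    "Volume",
    "SurfaceArea",
    "SurfaceToVolumeRatio",
    "Sphericity",
    "Compactness",
    "Max3DDiameter",
    "Elongation",
    "Flatness",
)

SEMANTIC_FEATURES: tuple[str, ...] = ("Under100HURatio", "Under80HURatio")

ROIS: tuple[str, ...] = ("WHOLE", "INNER", "OUTER")

#: The four-feature prognostic signature of the metastasis model.
SIGNATURE: tuple[str, ...] = (
    "INNER_Min_Hist",
    "INNER_MaxProbability_GLCM",
    "OUTER_Energy_Hist",
    "Under80HURatio",
)


def _columns() -> tuple[str, ...]:
    cols: list[str] = []
    for roi in ROIS:
        cols += [f"{roi}_{name}_Hist" for name in HISTOGRAM_FEATURES]
        cols += [f"{roi}_{name}_GLCM" for name in GLCM_FEATURES]
        cols += [f"{roi}_{name}_ISZM" for name in ISZM_FEATURES]
    cols += [f"WHOLE_{name}_Morph" for name in MORPHOLOGY_FEATURES]
    cols += list(SEMANTIC_FEATURES)
    return tuple(cols)


#: Canonical column order of the full feature table (119 + 2 columns).
FEATURE_COLUMNS: tuple[str, ...] = _columns()

NON_SEMANTIC_COLUMNS: tuple[str, ...] = tuple(
    c for c in FEATURE_COLUMNS if c not in SEMANTIC_FEATURES
)

assert len(NON_SEMANTIC_COLUMNS) == 119
assert len(FEATURE_COLUMNS) == 121
assert set(SIGNATURE) <= set(FEATURE_COLUMNS)
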