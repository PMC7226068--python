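"""Synthetic cohort generation: CT-like tumors, outcomes and expression.

The generator emulates the statistical structure the downstream analysis
assumes, not renal CT physics:

* each tumor is an axis-aligned ellipsoid with a hypodense (necrotic) core
  and an enhancing, textured rim; metastatic-class tumors get a larger
  necrotic core and stronger rim texture contrast, so the four signature
  features separate the classes,
* metastasis-free survival is exponential with subject hazard
  ``baseline_hazard_rate * exp(sum(beta_k * z_k))`` over the standardized
  signature features, with independent exponential censoring,
* gene expression is log-normal around a linear function of an assigned
  signature feature for planted "signal" genes (a configurable fraction with
  negative sign) and pure noise for the rest — Spearman screens are
  invariant to the exponential link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from radgen.features.extract import signature_features
from radgen.features.registry import SIGNATURE


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 58 patients with a 12/58 metastasis
    fraction, nephrographic-phase rim enhancement around 140 HU, necrotic
    core around 25 HU (low-attenuation necrosis), and the four printed
    log-hazard coefficients of the risk-score model as the true weights.
    Times are in months; hazard/censoring rates are per month.
    """

    n_patients: int = 58
    metastasis_fraction: float = 12 / 58
    grid_size: int = 32
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rim_hu_mean: float = 140.0
    rim_hu_sd: float = 18.0
    core_hu_mean: float = 25.0
    core_hu_sd: float = 10.0
    necrotic_fraction_by_class: tuple[float, float] = (0.08, 0.35)
    rim_texture_contrast_by_class: tuple[float, float] = (1.0, 1.7)
    texture_correlation_length: float = 1.5
    hazard_coefficients: tuple[float, float, float, float] = (-0.1020, 0.0343, 0.4302, 0.6369)
    baseline_hazard_rate: float = 0.02
    censoring_rate: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if self.grid_size < 16:
            raise ValueError("grid_size must be >= 16")
        for name in ("metastasis_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for v in self.necrotic_fraction_by_class:
            if not 0.0 <= v <= 1.0:
                raise ValueError("necrotic fractions must lie in [0, 1]")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        if self.baseline_hazard_rate <= 0 or self.censoring_rate < 0:
            raise ValueError("rates must be positive (censoring may be 0)")


@dataclass(frozen=True)
class TumorVolume:
    """One patient's HU grid, binary tumor mask and voxel spacing (mm)."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    patient_id: str

    def __post_init__(self) -> None:
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensities and mask shapes differ")
        if not np.any(self.mask):
            raise ValueError("empty tumor mask")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite HU values")


def _correlated_noise(rng: np.random.Generator, shape, correlation_length: float) -> np.ndarray:
    """Unit-variance Gaussian field with the given smoothing scale (voxels)."""
    white = rng.standard_normal(shape)
    if correlation_length <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=correlation_length)
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate_tumor_volume(
    spec: CohortSpec, class_label: int, seed: int, patient_id: str = "P0"
) -> TumorVolume:
    """One ellipsoidal tumor with hypodense core and textured rim.

    ``class_label`` 1 (metastasis) draws the larger necrotic fraction and the
    stronger rim texture contrast from the cohort spec.  The core is a
    concentric ellipsoid scaled so its volume fraction matches the class
    necrotic fraction.  Identical spec/seed pairs give bit-identical output.
    """
    rng = np.random.default_rng(seed)
    n = spec.grid_size
    center = (n - 1) / 2.0
    radii = n * rng.uniform(0.22, 0.30, size=3)
    if np.any(radii < 2):
        raise ValueError("grid too small to contain a tumor")

    grid = np.ogrid[0:n, 0:n, 0:n]
    dist2 = sum(((g - center) / r) ** 2 for g, r in zip(grid, radii))
    mask = dist2 <= 1.0

    necrotic = spec.necrotic_fraction_by_class[int(class_label)]
    contrast = spec.rim_texture_contrast_by_class[int(class_label)]
    core = dist2 <= necrotic ** (2.0 / 3.0) if necrotic > 0 else np.zeros_like(mask)
    rim = mask & ~core

    noise = _correlated_noise(rng, (n, n, n), spec.texture_correlation_length)
    intensities = np.full((n, n, n), 40.0)  # unenhanced soft-tissue background
    intensities[rim] = spec.rim_hu_mean + spec.rim_hu_sd * contrast * noise[rim]
    intensities[core] = spec.core_hu_mean + spec.core_hu_sd * noise[core]
    return TumorVolume(
        intensities=intensities,
        mask=mask,
        spacing=tuple(spec.voxel_spacing),
        patient_id=patient_id,
    )


def generate_cohort(
    spec: CohortSpec, inner_fraction: float = 0.5
) -> tuple[list[TumorVolume], pd.DataFrame]:
    """Volumes plus an outcome table (patient_id, metastasis, time, event).

    Class counts follow ``round(n * metastasis_fraction)``.  Survival times
    are exponential with hazard ``baseline * exp(X_std @ hazard_coefficients)``
    where ``X_std`` holds the cohort-standardized signature features of the
    generated tumors; censoring is independent exponential.
    """
    rng = np.random.default_rng(spec.seed)
    n_met = int(round(spec.n_patients * spec.metastasis_fraction))
    labels = np.zeros(spec.n_patients, dtype=int)
    labels[rng.permutation(spec.n_patients)[:n_met]] = 1
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_patients)

    volumes = [
        generate_tumor_volume(spec, int(lab), int(s), patient_id=f"P{i:04d}")
        for i, (lab, s) in enumerate(zip(labels, seeds))
    ]
    X = np.array(
        [
            [
                signature_features(v.intensities, v.mask, v.spacing, inner_fraction)[k]
                for k in SIGNATURE
            ]
            for v in volumes
        ]
    )
    X_std = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    hazard = spec.baseline_hazard_rate * np.exp(X_std @ np.asarray(spec.hazard_coefficients))
    event_time = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censoring_rate, size=spec.n_patients)
    else:
        censor_time = np.full(spec.n_patients, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    outcomes = pd.DataFrame(
        {
            "patient_id": [v.patient_id for v in volumes],
            "metastasis": labels,
            "time": np.maximum(time, 1e-6),
            "event": event,
        }
    )
    return volumes, outcomes


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample abundance matrix plus the planted-signal annotation."""

    values: pd.DataFrame
    annotation: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene_id", "feature", "effect", "sign"])
    )

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression must be non-negative")


def generate_expression(
    features: pd.DataFrame,
    n_genes: int = 2000,
    n_signal_per_feature: int = 50,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    negative_fraction: float | Mapping[str, float] = 0.5,
) -> ExpressionMatrix:
    """Log-normal expression with planted gene-feature Spearman correlations.

    Each signal gene assigned to feature ``f`` is
    ``exp(sign * effect * z(f) + noise_sd * N(0,1))``; the exponential link
    keeps abundances positive without touching rank correlations.
    ``negative_fraction`` (scalar or per-feature mapping, e.g. the emulated
    91%-negative setting for INNER_Min_Hist) sets the fraction of
    negative-sign signal genes per feature.  Remaining genes are pure noise.
    """
    if features.empty:
        raise ValueError("features must be non-empty")
    if effect == 0 and noise_sd == 0:
        raise ValueError("effect 0 with noise_sd 0 would generate constant genes")
    feat_names = list(features.columns)
    if n_signal_per_feature * len(feat_names) > n_genes:
        raise ValueError("n_signal_per_feature x n_features exceeds n_genes")

    rng = np.random.default_rng(seed)
    samples = list(features.index)
    n_samples = len(samples)
    values = np.empty((n_genes, n_samples))
    ann_rows = []

    g = 0
    for fname in feat_names:
        z = features[fname].to_numpy(dtype=float)
        sd = z.std()
        z = (z - z.mean()) / (sd if sd > 0 else 1.0)
        neg = (
            negative_fraction[fname]
            if isinstance(negative_fraction, Mapping)
            else negative_fraction
        )
        n_neg = int(round(n_signal_per_feature * neg))
        for j in range(n_signal_per_feature):
            sign = -1 if j < n_neg else 1
            values[g] = np.exp(sign * effect * z + noise_sd * rng.standard_normal(n_samples))
            ann_rows.append({"gene_id": f"G{g:05d}", "feature": fname, "effect": effect, "sign": sign})
            g += 1
    values[g:] = np.exp(rng.standard_normal((n_genes - g, n_samples)))

    frame = pd.DataFrame(values, index=[f"G{i:05d}" for i in range(n_genes)], columns=samples)
    frame.index.name = "gene_id"
    return ExpressionMatrix(values=frame, annotation=pd.DataFrame(ann_rows, columns=["gene_id", "feature", "effect", "sign"]))


def synthetic_feature_table(
    n_negative: int = 46,
    n_positive: int = 12,
    effect_size: float = 3.0,
    columns: tuple[str, ...] | None = None,
    planted: tuple[str, ...] = SIGNATURE,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tabular cohort with class-separating signal planted on named columns.

    All columns are independent standard normal except the ``planted`` ones,
    whose positive-class mean is shifted by ``effect_size`` standard
    deviations — a separable cohort for exercising the balancing/selection
    stack without the collinearity of image-derived features.  Returns the
    feature table (default: the canonical 121 columns) and binary labels.
    """
    from radgen.features.registry import FEATURE_COLUMNS

    cols = list(columns if columns is not None else FEATURE_COLUMNS)
    missing = set(planted) - set(cols)
    if missing:
        raise ValueError(f"planted columns not in table: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = n_negative + n_positive
    X = rng.standard_normal((n, len(cols)))
    labels = np.array([0] * n_negative + [1] * n_positive)
    for name in planted:
        X[labels == 1, cols.index(name)] += effect_size
    table = pd.DataFrame(X, columns=cols, index=[f"P{i:04d}" for i in range(n)])
    table.index.name = "patient_id"
    return table, labels
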