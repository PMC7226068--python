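"""End-to-end pipeline: simulate -> ROI/features -> select -> risk -> genes.

One global seed deterministically derives a per-stage seed by stable hashing
of the stage name, so each stage is independently re-runnable and two runs
with the same configuration are identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from radgen import io as rio
from radgen.cohort import CohortSpec, generate_cohort, generate_expression
from radgen.features.extract import extract_feature_table
from radgen.features.registry import SIGNATURE
from radgen.genes import (
    cluster_and_survival,
    enrichment_scores,
    jaccard_matrix,
    trait_gene_correlation,
)
from radgen.risk import compute_rrs, fit_rrs_model, km_logrank, optimal_cutoff, plot_km
from radgen.selection import (
    SelectionConfig,
    adasyn_balance,
    bootstrap_lasso_selection,
    evaluate_classifiers,
    logistic_importance,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    In simulation mode (``simulate=True``) the cohort spec drives data
    generation; otherwise ``volumes_dir``/``outcomes_path`` (and optionally
    ``expression_path``) must point at existing inputs.
    """

    out_dir: Path = Path("radgen_run")
    seed: int = 0
    simulate: bool = True
    cohort: CohortSpec = field(default_factory=CohortSpec)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    inner_fraction: float = 0.5
    search_band: tuple[float, float] = (15.0, 85.0)
    n_genes: int = 2000
    n_signal_per_feature: int = 50
    expression_effect: float = 1.0
    expression_noise_sd: float = 0.5
    alpha: float = 0.05
    top_n: int = 100
    es_clusters: int = 3
    volumes_dir: Path | None = None
    outcomes_path: Path | None = None
    expression_path: Path | None = None

    def validate(self) -> None:
        if not self.simulate:
            for name in ("volumes_dir", "outcomes_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} must exist in non-simulation mode: {p}")

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        if "selection" in kwargs:
            kwargs["selection"] = SelectionConfig(**kwargs["selection"])
        return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write a run manifest plus per-stage outputs.

    Returns the manifest dictionary (also written to ``manifest.json``).
    Stage failures raise with the stage name; outputs of completed stages
    remain on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": _jsonable(config),
        "stages": {},
    }

    def run_stage(name, fn):
        t0 = _time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(_time.perf_counter() - t0, 3),
        }
        return result

    # --- simulate / load -------------------------------------------------
    def _inputs():
        if config.simulate:
            spec = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
            volumes, outcomes = generate_cohort(spec, config.inner_fraction)
            rio.save_outcomes(outcomes, out / "outcomes.csv")
            return volumes, outcomes
        outcomes = rio.load_outcomes(config.outcomes_path)
        vol_dir = Path(config.volumes_dir)
        volumes = [
            rio.load_volume(p, vol_dir / p.name.replace("_image", "_mask"))
            for p in sorted(vol_dir.glob("*_image.nii.gz"))
        ]
        return volumes, outcomes

    volumes, outcomes = run_stage("simulate" if config.simulate else "load", _inputs)
    outcomes = outcomes.set_index("patient_id")

    # --- features --------------------------------------------------------
    def _features():
        table = extract_feature_table(volumes, config.inner_fraction)
        table.to_csv(out / "features.csv")
        return table

    features = run_stage("features", _features)
    outcomes = outcomes.loc[features.index]

    # --- selection -------------------------------------------------------
    def _selection():
        sel_cfg = dataclasses.replace(config.selection, seed=stage_seed(config.seed, "select"))
        labels = outcomes["metastasis"].to_numpy(dtype=int)
        feats = features
        if sel_cfg.adasyn_mode == "global":
            feats, labels = adasyn_balance(
                features, labels, k=sel_cfg.adasyn_k, seed=stage_seed(config.seed, "adasyn")
            )
        result = bootstrap_lasso_selection(feats, labels, sel_cfg)
        signature = result.signature or list(SIGNATURE)
        report = evaluate_classifiers(feats[signature], labels, sel_cfg)
        importance = logistic_importance(feats[signature], labels)
        result.frequencies.to_csv(out / "selection_frequencies.csv")
        report.to_csv(out / "classifier_report.csv")
        importance.to_csv(out / "logistic_importance.csv")
        (out / "selection.json").write_text(
            json.dumps(
                {
                    "signature": signature,
                    "stable_signature": result.signature,
                    "frequencies": result.frequencies.to_dict(),
                },
                indent=2,
            )
        )
        return signature, result, report, importance

    signature, sel_result, clf_report, importance = run_stage("select", _selection)

    # --- risk ------------------------------------------------------------
    def _risk():
        model = fit_rrs_model(features[signature], outcomes)
        scores = compute_rrs(model, features)
        cutoff, pct = optimal_cutoff(scores, outcomes, config.search_band)
        model.cutoff, model.cutoff_percentile = cutoff, pct
        report = km_logrank(scores, cutoff, outcomes)
        pd.concat([report.scores.rename("RRS"), report.groups], axis=1).to_csv(out / "rrs.csv")
        for name, curve in report.km_curves.items():
            curve.to_csv(out / f"km_{name}.csv")
        plot_km(report, out / "km.png")
        return model, report

    model, strat = run_stage("risk", _risk)

    # --- genes -----------------------------------------------------------
    def _genes():
        if config.simulate:
            expr = generate_expression(
                features[signature],
                n_genes=config.n_genes,
                n_signal_per_feature=min(
                    config.n_signal_per_feature, config.n_genes // len(signature)
                ),
                effect=config.expression_effect,
                noise_sd=config.expression_noise_sd,
                seed=stage_seed(config.seed, "expression"),
            )
            expr_values = expr.values
        elif config.expression_path is not None:
            expr_values = rio.load_expression(config.expression_path)
        else:
            return None
        gene_sets = trait_gene_correlation(
            expr_values, features[signature], alpha=config.alpha, top_n=config.top_n
        )
        full_sets = {f: gene_sets.gene_set(f) for f in signature if len(gene_sets.gene_set(f))}
        jac = jaccard_matrix(full_sets) if len(full_sets) >= 2 else None
        top_sets = {f: gene_sets.top_gene_set(f) for f in signature}
        top_sets = {f: s for f, s in top_sets.items() if len(s) >= 5}
        es = enrichment_scores(expr_values, top_sets) if top_sets else None
        labels = p = None
        if es is not None and es.shape[1] >= config.es_clusters:
            labels, p = cluster_and_survival(es, outcomes, k=config.es_clusters)
        rio.save_expression(expr_values, out / "expression.tsv")
        rio.save_gmt(top_sets, out / "trait_gene_sets.gmt")
        if jac is not None:
            jac.to_csv(out / "jaccard.csv")
        if es is not None:
            es.to_csv(out / "enrichment_scores.tsv", sep="\t")
        return gene_sets, jac, labels, p

    genes_out = run_stage("genes", _genes)

    manifest["report"] = _jsonable(
        {
            "signature": signature,
            "stable_signature": sel_result.signature,
            "selection_frequencies_top10": sel_result.frequencies.sort_values(ascending=False)
            .head(10)
            .to_dict(),
            "classifier_test_auc": {
                clf: clf_report.loc[(clf, "test"), "auc"]
                for clf in clf_report.index.get_level_values(0).unique()
            },
            "rrs_coefficients": model.coefficients.to_dict(),
            "cutoff": model.cutoff,
            "cutoff_percentile": model.cutoff_percentile,
            "hazard_ratio": strat.hazard_ratio,
            "logrank_p": strat.logrank_p,
            "es_group_logrank_p": genes_out[3] if genes_out else None,
        }
    )
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    return manifest
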