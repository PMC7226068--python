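"""Radiogenomic linkage: trait-associated gene sets, overlap, enrichment.

Genes whose expression Spearman-correlates (two-sided p < alpha, default
0.05, uncorrected) with a signature radiomics feature form that feature's
trait-associated gene set; pairwise dependence between features is summarized
by the Jaccard similarity of their sets.  A per-sample enrichment score (ES)
of a gene set is the rank-sum z-score of the set's within-sample expression
ranks — positive when the set is coordinately up-regulated in the sample.
Samples are subgrouped by Ward clustering of their ES profiles and the
extreme (high vs low mean ES) subgroups are compared by log-rank.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from lifelines.statistics import logrank_test

logger = logging.getLogger(__name__)


@dataclass
class TraitGeneSets:
    """Per-feature trait-associated genes with rho, p and sign."""

    tables: dict[str, pd.DataFrame]  # feature -> columns gene_id, rho, p, sign
    alpha: float
    top_n: int = 100

    def gene_set(self, feature: str) -> set[str]:
        return set(self.tables[feature]["gene_id"])

    def top_gene_set(self, feature: str) -> set[str]:
        """Top-``top_n`` genes of a feature, ranked by |rho|."""
        t = self.tables[feature]
        return set(t.reindex(t["rho"].abs().sort_values(ascending=False).index)["gene_id"].head(self.top_n))


def _exact_spearman_pvalues(n: int, rhos: np.ndarray) -> np.ndarray:
    """Two-sided permutation p-values by full enumeration of rank orders."""
    base = np.arange(1.0, n + 1.0)
    perms = np.array(list(permutations(base)))
    # Spearman rho between a fixed rank vector and every permuted rank vector
    # reduces to the Pearson correlation of centered rank vectors.
    c = perms - base.mean()
    denom = float(np.sqrt(np.sum((base - base.mean()) ** 2)))
    null = (c @ (base - base.mean())) / denom**2
    null = np.sort(null)
    ps = np.searchsorted(null, -np.abs(rhos) + 1e-12, side="right") + (
        len(null) - np.searchsorted(null, np.abs(rhos) - 1e-12, side="left")
    )
    return ps / len(null)


def _spearman_screen(
    expr: np.ndarray, feat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho and two-sided p of each gene row vs one feature."""
    n = feat.size
    rx = stats.rankdata(expr, axis=1)
    ry = stats.rankdata(feat)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx_c @ ry_c) / denom
    rho = np.clip(rho, -1.0, 1.0)
    if n >= 10:  # t-approximation
        with np.errstate(invalid="ignore", divide="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    else:  # exact permutation null (n! enumerable for n < 10)
        p = _exact_spearman_pvalues(n, rho)
    return rho, p


def trait_gene_correlation(
    expression,
    features: pd.DataFrame,
    alpha: float = 0.05,
    top_n: int = 100,
    fdr: bool = False,
) -> TraitGeneSets:
    """Spearman screen of every gene against every signature feature.

    ``expression`` is a genes x samples DataFrame (or an object with a
    ``.values`` DataFrame attribute); ``features`` is samples x signature
    columns.  Genes with two-sided p < alpha are retained per feature; with
    ``fdr=True`` the threshold is applied to Benjamini-Hochberg-adjusted
    p-values instead.  Constant gene rows are skipped with a warning.
    """
    values = expression.values if hasattr(expression, "annotation") else expression
    if not isinstance(values, pd.DataFrame):
        raise TypeError("expression must be a genes x samples DataFrame")
    shared = [s for s in values.columns if s in features.index]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples between expression and features")
    E = values[shared]
    constant = E.std(axis=1) == 0
    if constant.any():
        logger.warning("skipping %d constant gene row(s)", int(constant.sum()))
        E = E.loc[~constant]
    mat = E.to_numpy(dtype=float)
    genes = np.asarray(E.index)

    tables = {}
    for fname in features.columns:
        rho, p = _spearman_screen(mat, features.loc[shared, fname].to_numpy(dtype=float))
        crit = p
        if fdr:
            crit = stats.false_discovery_control(p)
        keep = crit < alpha
        tables[fname] = pd.DataFrame(
            {
                "gene_id": genes[keep],
                "rho": rho[keep],
                "p": p[keep],
                "sign": np.sign(rho[keep]).astype(int),
            }
        ).reset_index(drop=True)
    return TraitGeneSets(tables=tables, alpha=alpha, top_n=top_n)


def jaccard_matrix(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Pairwise Jaccard similarity |S_i & S_j| / |S_i | S_j| of named sets."""
    names = list(sets)
    for name in names:
        if len(sets[name]) == 0:
            raise ValueError(f"empty gene set: {name}")
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            inter = len(sets[a] & sets[b])
            union = len(sets[a] | sets[b])
            out.iloc[i, j] = out.iloc[j, i] = inter / union
    return out


def enrichment_scores(expression, gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Rank-sum z enrichment score of each gene set in each sample.

    Per sample, genes are ranked by expression (average ties); the ES of a
    set of m genes among N total is::

        ES = (mean in-set rank - (N + 1) / 2) / sqrt((N + 1) (N - m) / (12 m))

    i.e. the z-score of the in-set mean rank under uniform sampling without
    replacement, so a random set scores ~N(0, 1).  The statistic depends on
    expression only through within-sample ranks.
    """
    values = expression.values if hasattr(expression, "annotation") else expression
    if not isinstance(values, pd.DataFrame):
        raise TypeError("expression must be a genes x samples DataFrame")
    N = values.shape[0]
    ranks = values.rank(axis=0, method="average")
    rows = {}
    for name, genes in gene_sets.items():
        present = [g for g in genes if g in values.index]
        if len(present) < 5:
            raise ValueError(f"gene set '{name}' shares fewer than 5 genes with the matrix")
        m = len(present)
        mean_rank = ranks.loc[present].mean(axis=0)
        se = math.sqrt((N + 1) * (N - m) / (12.0 * m))
        rows[name] = (mean_rank - (N + 1) / 2.0) / se
    es = pd.DataFrame(rows).T
    es.index.name = "gene_set"
    return es


def cluster_and_survival(
    es: pd.DataFrame, outcomes: pd.DataFrame, k: int = 3
) -> tuple[pd.Series, float]:
    """Ward-cluster samples on their ES profiles; log-rank high vs low group.

    Clusters are ordered by their mean combined ES (mean over gene sets);
    labels are "low", ("mid_1", ...), "high".  Returns the per-sample labels
    and the log-rank p between the high and low groups.  ``outcomes`` is
    indexed by sample/patient id with time and event columns.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    samples = [s for s in es.columns if s in outcomes.index]
    if k > len(samples):
        raise ValueError("more clusters than samples")
    X = es[samples].T.to_numpy(dtype=float)
    Z = linkage(X, method="ward", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")

    combined = es[samples].mean(axis=0).to_numpy()
    cluster_means = [combined[raw == c].mean() for c in range(1, k + 1)]
    order = np.argsort(cluster_means)  # cluster ids (0-based) by ascending mean ES
    names = ["low"] + [f"mid_{i}" for i in range(1, k - 1)] + ["high"]
    label_of = {int(order[i]) + 1: names[i] for i in range(k)}
    labels = pd.Series([label_of[int(c)] for c in raw], index=samples, name="es_group")

    hi = labels == "high"
    lo = labels == "low"
    t = outcomes.loc[samples, "time"].to_numpy()
    e = outcomes.loc[samples, "event"].to_numpy()
    res = logrank_test(t[hi.to_numpy()], t[lo.to_numpy()], e[hi.to_numpy()], e[lo.to_numpy()])
    return labels, float(res.p_value)
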