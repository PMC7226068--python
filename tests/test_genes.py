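import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from radgen import generate_expression
from radgen.features.registry import SIGNATURE
from radgen.genes import (
    cluster_and_survival,
    enrichment_scores,
    jaccard_matrix,
    trait_gene_correlation,
)


def feature_frame(n=11, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, 4)),
        columns=list(SIGNATURE),
        index=[f"S{i:02d}" for i in range(n)],
    )


def expression_frame(genes, samples, values):
    return pd.DataFrame(values, index=genes, columns=samples)


class TestTraitGeneCorrelation:
    def test_monotone_genes_retained_with_correct_sign(self):
        feats = feature_frame(n=12)
        f = feats["Under80HURatio"]
        expr = expression_frame(
            ["up", "down"],
            feats.index,
            np.vstack([np.exp(f.to_numpy()), np.exp(-f.to_numpy())]),
        )
        sets = trait_gene_correlation(expr, feats, alpha=0.05)
        t = sets.tables["Under80HURatio"].set_index("gene_id")
        assert t.loc["up", "rho"] == pytest.approx(1.0)
        assert t.loc["up", "sign"] == 1
        assert t.loc["down", "rho"] == pytest.approx(-1.0)
        assert t.loc["down", "sign"] == -1

    def test_exact_small_sample_pvalues_match_scipy_permutation(self):
        # n = 8 engages the exact enumeration path
        feats = feature_frame(n=8, seed=3)
        rng = np.random.default_rng(4)
        expr = expression_frame(["g0", "g1"], feats.index, rng.normal(size=(2, 8)))
        sets = trait_gene_correlation(expr, feats, alpha=1.0000001)
        f = feats["INNER_Min_Hist"].to_numpy()
        for gene in ("g0", "g1"):
            row = sets.tables["INNER_Min_Hist"].set_index("gene_id").loc[gene]
            ref = stats.spearmanr(expr.loc[gene], f)
            assert row["rho"] == pytest.approx(ref.statistic, abs=1e-12)
        # exact p lies in [0,1] and is two-sided symmetric
        t = sets.tables["INNER_Min_Hist"]
        assert ((t["p"] > 0) & (t["p"] <= 1)).all()

    def test_null_retention_near_alpha(self):
        # all-null expression: the screen should keep ~alpha of gene-feature pairs
        kept = total = 0
        for seed in range(20):
            feats = feature_frame(n=11, seed=100 + seed)
            rng = np.random.default_rng(200 + seed)
            expr = expression_frame(
                [f"g{i}" for i in range(100)], feats.index, np.exp(rng.normal(size=(100, 11)))
            )
            sets = trait_gene_correlation(expr, feats, alpha=0.05)
            kept += sum(len(t) for t in sets.tables.values())
            total += 100 * 4
        assert kept / total == pytest.approx(0.05, abs=0.02)

    def test_too_few_shared_samples_rejected(self):
        feats = feature_frame(n=4)
        expr = expression_frame(["g"], feats.index, np.ones((1, 4)))
        with pytest.raises(ValueError):
            trait_gene_correlation(expr, feats)

    def test_planted_negative_sign_fraction_recovered(self):
        # emulation setting: 91% of INNER_Min_Hist-associated genes negative
        fracs = []
        for seed in range(3):
            feats = feature_frame(n=40, seed=50 + seed)
            expr = generate_expression(
                feats,
                n_genes=800,
                n_signal_per_feature=150,
                effect=1.2,
                noise_sd=0.6,
                seed=seed,
                negative_fraction={
                    f: (0.91 if f == "INNER_Min_Hist" else 0.08) for f in SIGNATURE
                },
            )
            sets = trait_gene_correlation(expr.values, feats, alpha=0.05)
            t = sets.tables["INNER_Min_Hist"]
            planted = set(
                expr.annotation.loc[expr.annotation.feature == "INNER_Min_Hist", "gene_id"]
            )
            sig = t[t.gene_id.isin(planted)]
            fracs.append((sig["sign"] == -1).mean())
        assert np.mean(fracs) == pytest.approx(0.91, abs=0.05)


class TestJaccard:
    def test_hand_computed_values(self):
        m = jaccard_matrix({"A": {"a", "b", "c"}, "B": {"b", "c", "d"}})
        assert m.loc["A", "B"] == pytest.approx(0.5)  # 2 shared / 4 total

    def test_identity_symmetry_disjoint(self):
        rng = np.random.default_rng(1)
        sets = {
            f"S{i}": set(rng.choice(50, size=rng.integers(3, 15), replace=False).tolist())
            for i in range(5)
        }
        m = jaccard_matrix(sets)
        assert np.allclose(np.diag(m), 1.0)
        assert np.allclose(m, m.T)
        m2 = jaccard_matrix({"A": {"x"}, "B": {"y"}})
        assert m2.loc["A", "B"] == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            jaccard_matrix({"A": set(), "B": {"x"}})


class TestEnrichmentScores:
    def make_expr(self, n_genes=200, n_samples=10, seed=2):
        rng = np.random.default_rng(seed)
        return expression_frame(
            [f"g{i}" for i in range(n_genes)],
            [f"S{j}" for j in range(n_samples)],
            rng.lognormal(size=(n_genes, n_samples)),
        )

    def test_top_expressed_set_is_sample_maximum(self):
        expr = self.make_expr()
        top50 = set(expr["S3"].nlargest(50).index)
        es = enrichment_scores(expr, {"top": top50})
        assert es.loc["top"].idxmax() == "S3"

    def test_random_sets_score_near_null(self):
        expr = self.make_expr()
        rng = np.random.default_rng(3)
        sets = {
            f"r{i}": set(rng.choice(expr.index, size=30, replace=False).tolist())
            for i in range(50)
        }
        es = enrichment_scores(expr, sets)
        vals = es.to_numpy().ravel()
        assert abs(vals.mean()) < 0.3
        assert np.all(np.abs(vals) < 4.0)
        assert 0.5 < vals.std() < 1.5

    def test_invariance_under_monotone_sample_transform(self):
        expr = self.make_expr()
        sets = {"s": set(expr.index[:40])}
        base = enrichment_scores(expr, sets)
        assert np.allclose(enrichment_scores(np.exp(expr / 3), sets), base)
        assert np.allclose(enrichment_scores(expr**3, sets), base)

    def test_consistent_gene_relabelling_invariance(self):
        expr = self.make_expr(n_genes=50)
        mapping = {g: f"x{g}" for g in expr.index}
        sets = {"s": set(expr.index[:10])}
        base = enrichment_scores(expr, sets)
        renamed = enrichment_scores(
            expr.rename(index=mapping), {"s": {mapping[g] for g in sets["s"]}}
        )
        assert np.allclose(renamed, base)

    def test_small_overlap_rejected(self):
        expr = self.make_expr(n_genes=20)
        with pytest.raises(ValueError, match="tiny"):
            enrichment_scores(expr, {"tiny": {"g0", "g1"}})


class TestClusterAndSurvival:
    def planted_es(self, n_per=20, seed=4):
        rng = np.random.default_rng(seed)
        centers = [-3.0, 0.0, 3.0]
        cols, truth = [], []
        for c, mu in enumerate(centers):
            for i in range(n_per):
                cols.append(rng.normal(mu, 0.3, size=4))
                truth.append(c)
        es = pd.DataFrame(
            np.array(cols).T,
            index=[f"set{i}" for i in range(4)],
            columns=[f"S{i:03d}" for i in range(3 * n_per)],
        )
        return es, np.array(truth)

    def test_planted_clusters_recovered_exactly(self):
        es, truth = self.planted_es()
        rng = np.random.default_rng(5)
        outcomes = pd.DataFrame(
            {"time": rng.exponential(20, len(truth)), "event": 1}, index=es.columns
        )
        labels, _ = cluster_and_survival(es, outcomes, k=3)
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0
        # ordering by mean ES: cluster around +3 must be "high"
        assert set(labels[truth == 2]) == {"high"}
        assert set(labels[truth == 0]) == {"low"}

    def test_k1_rejected(self):
        es, truth = self.planted_es(n_per=3)
        outcomes = pd.DataFrame({"time": np.ones(9), "event": 1}, index=es.columns)
        with pytest.raises(ValueError):
            cluster_and_survival(es, outcomes, k=1)

    def test_high_es_hazard_detected(self):
        hits = 0
        for seed in range(5):
            es, truth = self.planted_es(n_per=50, seed=10 + seed)
            rng = np.random.default_rng(20 + seed)
            rate = np.where(truth == 2, 0.25, 0.05)
            outcomes = pd.DataFrame(
                {"time": rng.exponential(1.0 / rate), "event": 1}, index=es.columns
            )
            _, p = cluster_and_survival(es, outcomes, k=3)
            hits += p < 0.05
        assert hits >= 4
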