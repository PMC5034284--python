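import numpy as np
import pandas as pd
import pytest

import proteoscope as ps
from proteoscope.structure import SUBUNIT_GENES
from oracles import fisher_exact_p


class TestPCASubunits:
    @staticmethod
    def _two_block_z(n=400, seed=0):
        """Two perfectly correlated blocks: CP+... one factor, IP+PSME the other."""
        rng = np.random.default_rng(seed)
        f1 = rng.standard_normal(n)
        f2 = rng.standard_normal(n)
        f1 = f1 - f1.mean()
        f2 = f2 - f2.mean()
        f2 = f2 - f1 * (f1 @ f2) / (f1 @ f1)  # empirically orthogonal factors
        rows = {}
        for g in SUBUNIT_GENES:
            base = f1 if g in ps.CP_GENES else f2
            rows[g] = (base - base.mean()) / base.std(ddof=1)
        return pd.DataFrame(rows, index=[f"S{i}" for i in range(n)]).T

    def test_perfect_blocks_separate_in_loading_space(self):
        z = self._two_block_z()
        res = ps.pca_subunits(z)
        cp = list(ps.CP_GENES)
        ip = list(ps.IP_GENES + ps.REGULATORY_GENES)
        # within each block all loadings equal (rank-2 block covariance):
        # PC1 is uniform on the 5-gene IP+PSME block, PC2 on the CP block
        assert res.loadings.loc[ip, "PC1"].std() < 1e-9
        assert res.loadings.loc[cp, "PC2"].std() < 1e-9
        assert np.abs(res.loadings.loc[cp, "PC1"]).max() < 1e-9
        assert np.abs(res.loadings.loc[ip, "PC2"]).max() < 1e-9
        assert res.variance_fractions[0] == pytest.approx(5 / 8)
        assert res.variance_fractions[1] == pytest.approx(3 / 8)

    def test_sample_duplication_leaves_loadings_unchanged(self, breast_cohort):
        expr, _ = breast_cohort
        z = ps.zscore(expr)
        res1 = ps.pca_subunits(z)
        dup = pd.concat([z, z.rename(columns=lambda c: c + "_dup")], axis=1)
        # re-standardise after duplication (moments unchanged up to ddof)
        res2 = ps.pca_subunits(dup)
        assert np.allclose(res1.loadings, res2.loadings, atol=1e-8)

    def test_loadings_orthonormal_and_variance_fractions_valid(self, breast_cohort):
        expr, _ = breast_cohort
        res = ps.pca_subunits(ps.zscore(expr))
        v = res.loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(2), atol=1e-10)
        assert np.all(np.diff(res.variance_fractions) <= 1e-12)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_ip_and_regulatory_subunits_cocluster_apart_from_cp(self, breast_cohort):
        """IP catalytic subunits load with PSME1/2 in a half-plane away from CP."""
        expr, _ = breast_cohort
        res = ps.pca_subunits(ps.zscore(expr))
        ip_block = res.loadings.loc[list(ps.IP_GENES + ps.REGULATORY_GENES)]
        cp_block = res.loadings.loc[list(ps.CP_GENES)]
        centroid = ip_block.mean(axis=0).to_numpy()
        centroid /= np.linalg.norm(centroid)
        assert (ip_block.to_numpy() @ centroid > 0).all()
        assert ((ip_block.to_numpy() @ centroid).min()
                > (cp_block.to_numpy() @ centroid).max())

    def test_rank_deficient_rejected(self):
        n = 50
        base = np.random.default_rng(1).standard_normal(n)
        z = pd.DataFrame({g: (base - base.mean()) / base.std(ddof=1)
                          for g in SUBUNIT_GENES},
                         index=[f"S{i}" for i in range(n)]).T
        with pytest.raises(ps.ValidationError, match="rank"):
            ps.pca_subunits(z)


class TestMarkerCorrelation:
    def test_self_and_negated(self):
        s = pd.Series([1.0, 2.0, 4.0, 3.0], index=list("abcd"))
        assert ps.marker_correlation(s, s) == pytest.approx(1.0)
        assert ps.marker_correlation(s, -s) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ps.ValidationError, match="constant"):
            ps.marker_correlation(s, pd.Series([5.0, 5.0, 5.0], index=list("abc")))

    def test_breast_vs_aml_marker_coupling(self, breast_cohort, aml_cohort):
        for cohort, cond in ((breast_cohort, "breast"), (aml_cohort, "aml")):
            expr, _ = cohort
            st = ps.score_table(expr)
            r = ps.marker_correlation(st.scores["ip_score"], expr.values.loc["IFNG"])
            if cond == "breast":
                assert r > 0.5
            else:
                assert abs(r) < 0.2


class TestHierarchicalClustering:
    def test_identical_samples_merge_first(self):
        vals = np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 6.0], [3.0, 3.0, 7.0]])
        mat = ps.ExpressionMatrix(
            pd.DataFrame(vals, index=list(ps.IP_GENES), columns=["a", "b", "c"]),
            "log10p")
        res = ps.hcluster_samples(mat, k=2)
        assert res.merge_heights[0] == pytest.approx(0.0)
        assert res.labels["a"] == res.labels["b"] != res.labels["c"]

    def test_two_blobs_recovered_exactly(self):
        rng = np.random.default_rng(6)
        blob1 = rng.normal(0, 1, size=(3, 30))
        blob2 = rng.normal(30, 1, size=(3, 30))  # 10+ SDs apart, clipped safe
        vals = np.abs(np.concatenate([blob1 + 10, blob2], axis=1))
        mat = ps.ExpressionMatrix(
            pd.DataFrame(vals, index=list(ps.IP_GENES),
                         columns=[f"S{i}" for i in range(60)]), "log10p")
        res = ps.hcluster_samples(mat, k=2)
        labels = res.labels.to_numpy()
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[-1]
        assert np.all(np.diff(res.merge_heights) >= -1e-9)

    def test_k_equals_n_singletons(self, small_log_expr):
        res = ps.hcluster_samples(small_log_expr, k=small_log_expr.n_samples)
        assert res.labels.nunique() == small_log_expr.n_samples

    def test_k_too_large_rejected(self, small_log_expr):
        with pytest.raises(ps.ValidationError):
            ps.hcluster_samples(small_log_expr, k=100)


class TestClusterEnrichment:
    @staticmethod
    def _clustering(labels, index):
        return ps.SampleClustering(
            labels=pd.Series(labels, index=index),
            merge_heights=np.array([]), linkage_name="complete")

    def test_odds_ratio_arithmetic(self):
        # cluster 1 = first 10 samples: a=8 M5, b=2 other; rest c=2, d=8
        idx = [f"P{i}" for i in range(20)]
        clust = self._clustering([1] * 10 + [2] * 10, idx)
        cats = pd.Series(["M5"] * 8 + ["M0"] * 2 + ["M5"] * 2 + ["M0"] * 8, index=idx)
        res = ps.cluster_enrichment(clust, cats)
        row = res[(res["cluster"] == 1) & (res["category"] == "M5")].iloc[0]
        assert row["odds_ratio"] == pytest.approx(16.0)

    def test_uniform_category_no_association(self):
        idx = [f"P{i}" for i in range(40)]
        clust = self._clustering([1] * 20 + [2] * 20, idx)
        cats = pd.Series((["M5"] * 10 + ["M0"] * 10) * 2, index=idx)
        res = ps.cluster_enrichment(clust, cats)
        assert np.allclose(res["odds_ratio"], 1.0)
        assert np.allclose(res["p"], 1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(8)
        idx = [f"P{i}" for i in range(30)]
        clust = self._clustering(list(rng.integers(1, 4, 30)), idx)
        cats = pd.Series(rng.choice(["M3", "M5", "other"], 30), index=idx)
        res = ps.cluster_enrichment(clust, cats)
        for _, row in res.iterrows():
            oracle = fisher_exact_p(int(row["a"]), int(row["b"]),
                                    int(row["c"]), int(row["d"]), "two-sided")
            assert row["p"] == pytest.approx(oracle, abs=1e-10)

    def test_single_category_rejected(self):
        idx = [f"P{i}" for i in range(10)]
        clust = self._clustering([1] * 5 + [2] * 5, idx)
        with pytest.raises(ps.ValidationError):
            ps.cluster_enrichment(clust, pd.Series(["M5"] * 10, index=idx))


class TestMethylationFilter:
    @staticmethod
    def _fixture(n=300, rho=-0.9, seed=0):
        spec = ps.CohortSpec(mode="aml_like", n_samples=n, seed=seed)
        expr, _ = ps.generate_cohort(spec)
        meth, annots = ps.generate_methylation(
            expr, ["PSMB8"], rho_m=rho, n_cpg_per_gene=8, n_decoy_per_gene=8,
            seed=seed + 1)
        return expr, meth, annots

    def test_strong_planted_sites_kept_decoys_not(self):
        expr, meth, annots = self._fixture()
        res = ps.methylation_filter(meth, annots, expr, "PSMB8")
        by_id = {m.cpg_id: m for m in res}
        for ann in annots:
            m = by_id[ann.cpg_id]
            if "decoy" in ann.cpg_id:
                assert not m.kept  # outside the 10 kb window
                assert abs(m.signed_distance) >= 10_000
            else:
                assert m.kept
                assert m.r < -0.5

    def test_thresholds_strict(self):
        expr, meth, annots = self._fixture()
        res = ps.methylation_filter(meth, annots, expr, "PSMB8",
                                    r_meth=0.999, window_bp=10_000)
        assert not any(m.kept for m in res)  # |r| never exceeds 0.999

    def test_missing_gene_rejected(self):
        expr, meth, annots = self._fixture(n=50)
        with pytest.raises(ps.ValidationError):
            ps.methylation_filter(meth, annots, expr, "NOT_A_GENE")
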