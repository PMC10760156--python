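"""Normalization, HVG, regress/scale, clustering, DE and proportions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from incitekit import expression, synthetic
from incitekit.expression import HVGParams
from conftest import make_gex


class TestNormalize:
    def test_zero_count_maps_to_zero(self):
        out = expression.normalize_log1p(make_gex([[5, 0], [1, 1]]), 100)
        assert out[0, 1] == 0.0

    def test_proportional_nuclei_normalize_identically(self):
        out = expression.normalize_log1p(make_gex([[10, 30], [20, 60]]), 100)
        np.testing.assert_allclose(out[0], out[1])

    def test_hand_arithmetic(self):
        """counts (10,10,0) at target sum 100 -> (ln 51, ln 51, 0)."""
        out = expression.normalize_log1p(make_gex([[10, 10, 0]]), 100)
        np.testing.assert_allclose(out[0], [np.log(51), np.log(51), 0.0])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            expression.normalize_log1p(np.array([[0.0, 0.0]]))


class TestHVG:
    def test_constant_gene_excluded(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(0.1, size=(300, 50)).astype(float)
        X[:, 7] = 3.0  # constant: no dispersion
        ln = np.log1p(X)
        mask = expression.select_hvg(ln, HVGParams(0.001, 10.0, 0.3))
        assert not mask[7]

    def test_mean_above_band_excluded(self):
        rng = np.random.default_rng(1)
        X = np.log1p(rng.poisson(0.1, size=(300, 50)).astype(float))
        X[:, 3] = rng.normal(8.0, 2.0, 300)  # huge mean, huge dispersion
        mask = expression.select_hvg(X, HVGParams(0.001, 0.5, 0.3))
        assert not mask[3]

    def test_engineered_high_dispersion_genes_selected(self):
        """10 bursty genes (same mean as background, far larger dispersion)
        are exactly the selected set; single dispersion bin keeps the
        z-score margin wide (hot z ~ 3, background z < 0)."""
        rng = np.random.default_rng(2)
        n, g = 600, 100
        counts = rng.poisson(1.0, size=(n, g)).astype(float)
        hot = np.arange(10)
        counts[:, hot] = np.where(rng.random((n, 10)) < 1 / 30, 30.0, 0.0)
        ln = np.log1p(counts)
        mask = expression.select_hvg(ln, HVGParams(0.01, 50.0, 1.5, n_bins=1))
        assert set(np.flatnonzero(mask)) == set(hot)


class TestRegressAndScale:
    def test_orthogonal_covariate_leaves_centered_input(self):
        rng = np.random.default_rng(3)
        cov = np.array([1.0, -1.0, 1.0, -1.0])
        gene = np.array([2.0, 2.0, 4.0, 4.0])  # orthogonal to cov
        X = gene[:, None]
        out = expression.regress_and_scale(X, cov, max_value=100)
        centered = gene - gene.mean()
        np.testing.assert_allclose(
            out[:, 0], centered / centered.std(), atol=1e-12
        )

    def test_gene_linear_in_covariate_is_flattened(self):
        cov = np.arange(6, dtype=float)
        X = (3.0 + 2.0 * cov)[:, None]
        out = expression.regress_and_scale(X, cov)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            X = rng.normal(size=(5, 3))
            cov = rng.normal(size=5)
            D = np.column_stack([np.ones(5), cov])
            beta = np.linalg.solve(D.T @ D, D.T @ X)
            resid = X - D @ beta
            sd = resid.std(axis=0)
            expected = np.clip(resid / sd, -10, 10)
            out = expression.regress_and_scale(X, cov)
            np.testing.assert_allclose(out, expected, atol=1e-10)


class TestEmbedAndCluster:
    def test_two_separated_blobs_two_clusters(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(70, 40))
        b = rng.normal(10, 1, size=(70, 40))
        X = np.vstack([a, b])
        res = expression.embed_and_cluster(
            X, [str(i) for i in range(140)], n_pcs=10, seed=0
        )
        assert len(np.unique(res.labels)) == 2
        assert len(np.unique(res.labels[:70])) == 1

    def test_single_batch_correction_is_identity(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(80, 20))
        ids = [str(i) for i in range(80)]
        r1 = expression.embed_and_cluster(X, ids, n_pcs=5, seed=0)
        r2 = expression.embed_and_cluster(
            X, ids, n_pcs=5, seed=0, batch=np.zeros(80)
        )
        np.testing.assert_allclose(r1.pcs, r2.pcs)

    def test_n_pcs_clipped_with_warning(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        with pytest.warns(UserWarning, match="clipped"):
            res = expression.embed_and_cluster(
                X, [str(i) for i in range(30)], n_pcs=40, seed=0
            )
        assert res.pcs.shape[1] == 4

    def test_celltype_recovery_ari(self):
        """Adjusted Rand index >= 0.9 against generator cell types."""
        cfg = synthetic.celltype_cohort_config(
            n_donors_per_group=2, nuclei_per_donor=120, doublet_rate=0.0, seed=13
        )
        cohort = synthetic.generate_cohort(cfg)
        ln = expression.normalize_log1p(cohort.gex)
        tot = np.asarray(cohort.gex.values.sum(axis=1)).ravel()
        scaled = expression.regress_and_scale(ln, tot.astype(float))
        res = expression.embed_and_cluster(
            scaled, cohort.gex.nucleus_ids,
            batch=[cohort.meta["batch_id"].to_numpy(),
                   cohort.meta["donor_id"].to_numpy()],
            seed=0,
        )
        from sklearn.metrics import adjusted_rand_score

        ari = adjusted_rand_score(cohort.meta["true_celltype"], res.labels)
        assert ari >= 0.90

    def test_clustering_stable_across_seeds(self):
        cfg = synthetic.celltype_cohort_config(
            n_donors_per_group=2, nuclei_per_donor=100, doublet_rate=0.0, seed=14
        )
        cohort = synthetic.generate_cohort(cfg)
        ln = expression.normalize_log1p(cohort.gex)
        tot = np.asarray(cohort.gex.values.sum(axis=1)).ravel().astype(float)
        scaled = expression.regress_and_scale(ln, tot)
        res = [
            expression.embed_and_cluster(
                scaled, cohort.gex.nucleus_ids, seed=s
            )
            for s in (0, 1)
        ]
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(res[0].labels, res[1].labels) >= 0.95


class TestSubcluster:
    def test_subcluster_on_all_nuclei_reproduces_first_pass(self):
        """With identical settings and the full population as the 'subset',
        the second pass is the same computation as the first."""
        cfg = synthetic.celltype_cohort_config(
            n_donors_per_group=1, nuclei_per_donor=120, doublet_rate=0.0, seed=16
        )
        cohort = synthetic.generate_cohort(cfg)
        ln = expression.normalize_log1p(cohort.gex)
        tot = np.asarray(cohort.gex.values.sum(axis=1)).ravel().astype(float)
        batch = cohort.meta["batch_id"].to_numpy()
        first = expression.embed_and_cluster(
            expression.regress_and_scale(ln, tot),
            cohort.gex.nucleus_ids, batch=batch, seed=0,
        )
        again = expression.two_pass_subcluster(
            ln, cohort.gex.nucleus_ids, np.ones(len(ln), bool), tot, batch, seed=0
        )
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(first.labels, again.labels) == 1.0

    def test_homogeneous_subset_subclusters_carry_no_disease_structure(self):
        """A cell type without engineered substructure may still be split by
        community detection at the working resolution, but the pieces are
        exchangeable: subcluster membership is independent of disease state."""
        cfg = synthetic.celltype_cohort_config(
            n_donors_per_group=2, nuclei_per_donor=150, doublet_rate=0.0, seed=15
        )
        cohort = synthetic.generate_cohort(cfg)
        ln = expression.normalize_log1p(cohort.gex)
        tot = np.asarray(cohort.gex.values.sum(axis=1)).ravel().astype(float)
        subset = cohort.meta["true_celltype"].eq("EC").to_numpy()
        res = expression.two_pass_subcluster(
            ln, cohort.gex.nucleus_ids, subset, tot,
            cohort.meta["batch_id"].to_numpy(), seed=0,
        )
        meta = cohort.meta.loc[res.nucleus_ids]
        dis = meta["disease_state"].isin(synthetic.DISEASE_ONLY).to_numpy()
        table = pd.crosstab(pd.Series(res.labels), dis)
        table = table[table.sum(axis=1) >= 5]
        assert st.chi2_contingency(table.to_numpy()).pvalue > 0.01

    def test_small_subset_rejected(self):
        rng = np.random.default_rng(8)
        ln = rng.normal(size=(60, 10))
        with pytest.raises(ValueError):
            expression.two_pass_subcluster(
                ln, [str(i) for i in range(60)],
                np.arange(60) < 20, np.ones(60), np.zeros(60),
            )

    def test_disease_program_separates_subclusters(self, default_cohort, analysis):
        """Engineered healthy/disease programs yield subclusters whose
        disease-state composition differs (Fisher p < 0.01)."""
        sub = analysis.subcluster
        meta = analysis.meta.loc[sub.nucleus_ids]
        lab = pd.Series(sub.labels, index=sub.nucleus_ids)
        a = lab == analysis.disease_cluster
        b = lab == analysis.control_cluster
        dis = meta["disease_state"].isin(synthetic.DISEASE_ONLY)
        table = [
            [int((a & dis).sum()), int((a & ~dis).sum())],
            [int((b & dis).sum()), int((b & ~dis).sum())],
        ]
        assert st.fisher_exact(table).pvalue < 0.01


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        X = np.tile([[1.0, 2.0, 3.0]], (4, 1))
        de = expression.differential_expression(X, X, ["a", "b", "c"])
        assert (de["t"] == 0).all() and (de["lfc"] == 0).all()
        assert (de["pval"] == 1).all()

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(9)
        A, B = rng.normal(size=(5, 8)), rng.normal(size=(7, 8))
        d1 = expression.differential_expression(A, B, list("abcdefgh"))
        d2 = expression.differential_expression(B, A, list("abcdefgh"))
        np.testing.assert_allclose(d1["t"], -d2["t"])
        np.testing.assert_allclose(d1["lfc"], -d2["lfc"])

    def test_welch_formula_oracle(self):
        rng = np.random.default_rng(10)
        A, B = rng.normal(size=(5, 4)), rng.normal(1, 2, size=(6, 4))
        de = expression.differential_expression(A, B, list("abcd"))
        va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
        t_oracle = (A.mean(0) - B.mean(0)) / np.sqrt(va / 5 + vb / 6)
        np.testing.assert_allclose(de["t"], t_oracle, atol=1e-10)

    def test_adjusted_p_at_least_p(self):
        rng = np.random.default_rng(11)
        de = expression.differential_expression(
            rng.normal(size=(6, 20)), rng.normal(size=(6, 20)), range(20)
        )
        assert (de["qval"] >= de["pval"] - 1e-12).all()


class TestProportions:
    def _meta(self, donors):
        return pd.DataFrame(
            {"donor_id": donors},
            index=pd.Index([f"n{i}" for i in range(len(donors))]),
        )

    def test_single_cluster_donor(self):
        meta = self._meta(["d1"] * 3 + ["d2"] * 3 + ["d3"] * 2)
        labels = pd.Series(
            ["c0", "c0", "c0", "c0", "c1", "c1", "c1", "c1"], index=meta.index
        )
        prop = expression.cluster_proportions(meta, labels)
        assert prop.loc["d1", "c0"] == 1.0 and prop.loc["d1", "c1"] == 0.0
        np.testing.assert_allclose(prop.sum(axis=1), 1.0)

    def test_perfect_monotone_rho(self):
        meta = self._meta(["d1", "d2", "d3", "d4"])
        labels = pd.Series(["c0"] * 4, index=meta.index)
        prop = pd.DataFrame(
            {"c0": [0.1, 0.2, 0.3, 0.4]}, index=["d1", "d2", "d3", "d4"]
        )
        age = pd.Series([20, 40, 60, 80], index=prop.index)
        out = expression.correlate_proportion(prop, age)
        assert out.loc["c0", "rho"] == 1.0

    def test_spearman_matches_manual_ranks(self):
        prop = pd.DataFrame(
            {"c0": [0.05, 0.30, 0.10, 0.20, 0.25, 0.15]},
            index=[f"d{i}" for i in range(6)],
        )
        age = pd.Series([22, 71, 25, 80, 68, 90], index=prop.index)
        out = expression.correlate_proportion(prop, age)
        rx = st.rankdata(prop["c0"])
        ry = st.rankdata(age)
        rho_manual = np.corrcoef(rx, ry)[0, 1]
        np.testing.assert_allclose(out.loc["c0", "rho"], rho_manual, atol=1e-12)

    def test_needs_three_donors(self):
        meta = self._meta(["d1", "d2"])
        labels = pd.Series(["c0", "c0"], index=meta.index)
        with pytest.raises(ValueError):
            expression.cluster_proportions(meta, labels)
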