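"""Pseudobulk, NB DE, modality merging, deconvolution, projection, scoring."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st

from agelung import integration
from agelung.containers import CountMatrix


class TestPseudobulk:
    def test_hand_sum_and_conservation(self):
        dense = np.array([[1, 0, 5], [2, 4, 0]])
        matrix = CountMatrix(sp.csr_matrix(dense), ["g0", "g1"], ["c0", "c1", "c2"])
        pb = integration.pseudobulk(matrix, ["m1", "m1", "m1"])
        np.testing.assert_array_equal(pb["m1"].to_numpy(), [6, 6])
        assert pb.to_numpy().sum() == dense.sum()

    def test_single_cell_mouse_column_equals_cell(self):
        dense = np.array([[3, 7], [1, 2]])
        matrix = CountMatrix(sp.csr_matrix(dense), ["g0", "g1"], ["c0", "c1"])
        pb = integration.pseudobulk(matrix, ["mA", "mB"])
        np.testing.assert_array_equal(pb["mB"].to_numpy(), dense[:, 1])


class TestSizeFactors:
    def test_doubled_sample_gives_sqrt2_factors(self, rng):
        counts = pd.DataFrame({"s1": rng.poisson(50, 200) + 1})
        counts["s2"] = counts["s1"] * 2
        sf = integration.median_of_ratios_size_factors(counts)
        assert sf["s1"] == pytest.approx(1 / np.sqrt(2), rel=1e-9)
        assert sf["s2"] == pytest.approx(np.sqrt(2), rel=1e-9)


class TestNbDifferential:
    def test_identical_groups_null(self, rng):
        base = rng.poisson(40, size=(50, 3))
        counts = pd.DataFrame(
            np.hstack([base, base]),
            columns=[f"y{i}" for i in range(3)] + [f"o{i}" for i in range(3)],
        )
        age = pd.Series(["young"] * 3 + ["old"] * 3, index=counts.columns)
        de = integration.nb_differential(counts, age)
        np.testing.assert_allclose(de["log2fc"], 0.0, atol=1e-6)
        assert (de["p"] > 0.9).all()

    def test_estimator_recovers_planted_fold_change(self):
        """Sum-scale counts (as in pseudobulk): log2FC=1 recovered within
        +-0.3 for >=95% of genes at mean 2000 and dispersion 0.005."""
        rng = np.random.default_rng(12)
        n_genes, n_effect, mu, alpha = 300, 100, 2000.0, 0.005
        fc = np.ones(n_genes)
        fc[:n_effect] = 2.0  # null majority anchors the size factors
        young = rng.poisson(rng.gamma(1 / alpha, alpha * mu, size=(n_genes, 6)))
        old = rng.poisson(rng.gamma(1 / alpha, alpha * mu * fc[:, None], size=(n_genes, 6)))
        counts = pd.DataFrame(
            np.hstack([young, old]),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"y{i}" for i in range(6)] + [f"o{i}" for i in range(6)],
        )
        age = pd.Series(["young"] * 6 + ["old"] * 6, index=counts.columns)
        de = integration.nb_differential(counts, age)
        err = de["log2fc"].iloc[:n_effect] - 1.0
        assert (err.abs() <= 0.3).mean() >= 0.95
        assert (de["p_adj"].iloc[:n_effect] < 0.1).mean() >= 0.95

    def test_low_count_genes_filtered(self, rng):
        counts = pd.DataFrame(rng.poisson(30, size=(20, 4)) + 5)
        counts.iloc[0] = [1, 0, 2, 1]
        counts.columns = ["y1", "y2", "o1", "o2"]
        age = pd.Series(["young", "young", "old", "old"], index=counts.columns)
        de = integration.nb_differential(counts, age, min_total=10)
        assert 0 not in de.index

    def test_agrees_with_independent_deseq2_fit(self):
        """Cross-check fold changes against pyDESeq2 on a small table."""
        rng = np.random.default_rng(3)
        mu = rng.uniform(50, 500, size=40)
        fc = rng.choice([1.0, 2.0, 0.5], size=40)
        young = rng.poisson(np.tile(mu[:, None], (1, 4)))
        old = rng.poisson(np.tile((mu * fc)[:, None], (1, 4)))
        counts = pd.DataFrame(
            np.hstack([young, old]),
            index=[f"g{i}" for i in range(40)],
            columns=[f"y{i}" for i in range(4)] + [f"o{i}" for i in range(4)],
        )
        age = pd.Series(["young"] * 4 + ["old"] * 4, index=counts.columns)
        mine = integration.nb_differential(counts, age)

        import warnings

        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        meta = pd.DataFrame({"condition": age})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dds = DeseqDataSet(
                counts=counts.T, metadata=meta, design="~condition", quiet=True
            )
            dds.deseq2()
            stats = DeseqStats(
                dds, contrast=["condition", "old", "young"], quiet=True
            )
            stats.summary()
        theirs = stats.results_df["log2FoldChange"]
        diff = (mine["log2fc"] - theirs.reindex(mine.index)).abs()
        assert diff.median() < 0.1
        assert st.pearsonr(mine["log2fc"], theirs.reindex(mine.index)).statistic > 0.99


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        out = integration.quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)

    def test_two_column_row_means(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = integration.quantile_normalize(m)
        np.testing.assert_allclose(out["a"], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out["b"], [2.5, 3.5, 4.5])

    def test_sorted_values_identical_across_columns(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        out = integration.quantile_normalize(m)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcd":
            np.testing.assert_allclose(np.sort(out[c].to_numpy()), ref)

    def test_ties_get_average_reference(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 3.0, 4.0]})
        out = integration.quantile_normalize(m)
        ref = np.sort(m.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)


class TestMergeModalities:
    def test_empty_intersection_errors(self):
        a = pd.DataFrame(np.ones((3, 2)), index=["g1", "g2", "g3"])
        b = pd.DataFrame(np.ones((3, 2)), index=["g4", "g5", "g6"])
        with pytest.raises(ValueError):
            integration.merge_modalities(a, b, a)

    def test_modality_labels_attached(self, rng):
        genes = [f"g{i}" for i in range(20)]
        frames = [
            pd.DataFrame(rng.normal(size=(20, k)), index=genes,
                         columns=[f"x{k}{j}" for j in range(k)])
            for k in (4, 3, 5)
        ]
        _, scores, evr = integration.merge_modalities(*frames)
        assert list(scores["modality"]).count("pseudobulk") == 4
        assert list(scores["modality"]).count("proteome") == 5
        assert np.all(np.isfinite(evr))


class TestKsSignatureEnrichment:
    def test_null_markers_uniform_p(self, rng):
        fc = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        ps = []
        for _ in range(200):
            members = rng.choice(2000, size=50, replace=False)
            out = integration.ks_signature_enrichment(
                fc, {"s": [f"g{i}" for i in members]}
            )
            ps.append(out["p"].iloc[0])
        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_markers_match_ecdf_oracle(self, rng):
        from oracles import ks_statistic

        fc = pd.Series(rng.normal(size=2000), index=[f"g{i}" for i in range(2000)])
        members = [f"g{i}" for i in range(50)]
        fc.loc[members] += 1.0
        out = integration.ks_signature_enrichment(fc, {"sig": members})
        inside = fc.loc[members].to_numpy()
        outside = fc.drop(members).to_numpy()
        assert out["D"].iloc[0] == pytest.approx(ks_statistic(inside, outside), abs=1e-12)
        assert out["p"].iloc[0] < 1e-6
        assert out["direction"].iloc[0] == 1

    def test_p_clamped_at_floor(self, rng):
        """A shift so extreme the raw KS p underflows 1e-50 reports 1e-50."""
        fc = pd.Series(rng.normal(size=3000), index=[f"g{i}" for i in range(3000)])
        members = [f"g{i}" for i in range(400)]
        fc.loc[members] += 50.0
        out = integration.ks_signature_enrichment(fc, {"sig": members})
        raw = st.ks_2samp(fc.loc[members], fc.drop(members)).pvalue
        assert raw < 1e-50
        assert out["p"].iloc[0] == 1e-50

    def test_too_few_markers_skipped(self, rng):
        fc = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        with pytest.warns(UserWarning, match="skipped"):
            out = integration.ks_signature_enrichment(fc, {"tiny": ["g0", "g1"]})
        assert out.empty


class TestPcaProject:
    @pytest.fixture(scope="class")
    def setup(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(30)]
        train = pd.DataFrame(
            rng.normal(size=(30, 10)), index=genes, columns=[f"t{j}" for j in range(10)]
        )
        markers = pd.DataFrame(
            [(g, "A", 1.0, 0.5, 0.1, 1e-4, 1e-3) for g in genes[:20]],
            columns=["gene", "cell_type", "avg_log2fc", "pct_in", "pct_out", "p", "p_adj"],
        )
        return train, markers

    def test_projecting_training_sample_reproduces_score(self, setup):
        train, markers = setup
        scores, projected = integration.pca_project(train, markers, train[["t3"]])
        np.testing.assert_allclose(
            projected.iloc[0].to_numpy(), scores.loc["t3"].to_numpy(), atol=1e-10
        )

    def test_training_mean_projects_to_origin(self, setup):
        train, markers = setup
        mean = train.mean(axis=1).to_frame("mean_sample")
        _, projected = integration.pca_project(train, markers, mean)
        np.testing.assert_allclose(projected.to_numpy(), 0.0, atol=1e-10)

    def test_missing_marker_genes_error(self, setup):
        train, markers = setup
        new = train.iloc[5:][["t0"]]
        with pytest.raises(ValueError, match="lack"):
            integration.pca_project(train, markers, new)


class TestConcordance:
    def test_monotone_transform_rho_one(self, rng):
        a = pd.Series(rng.normal(size=50))
        out = integration.concordance(a, np.exp(a))
        assert out["spearman_rho"] == pytest.approx(1.0)

    def test_sign_table_odds_ratio(self):
        a = pd.Series(np.r_[np.ones(30), np.ones(10), -np.ones(5), -np.ones(25)])
        b = pd.Series(np.r_[np.ones(30), -np.ones(10), np.ones(5), -np.ones(25)])
        out = integration.concordance(a, b)
        np.testing.assert_array_equal(out["sign_table"], [[30, 10], [5, 25]])
        assert out["odds_ratio"] == pytest.approx(15.0)
        expected = st.fisher_exact([[30, 10], [5, 25]])[1]
        assert out["fisher_p"] == pytest.approx(expected)

    def test_independent_signs_null(self, rng):
        ps = []
        for _ in range(200):
            a = pd.Series(rng.choice([-1.0, 1.0], size=60))
            b = pd.Series(rng.choice([-1.0, 1.0], size=60))
            ps.append(integration.concordance(a, b)["fisher_p"])
        assert np.mean(np.array(ps) < 0.05) < 0.10


class TestUpstreamRegulator:
    universe = [f"g{i}" for i in range(1000)]

    def _fc(self, n_regulated=500):
        rng = np.random.default_rng(0)
        fc = pd.Series(0.0, index=self.universe)
        fc.iloc[:n_regulated] = rng.choice([-1.0, 1.0], size=n_regulated)
        return fc

    def test_all_agreeing_targets(self):
        fc = self._fc()
        targets = [(g, int(np.sign(fc[g]))) for g in self.universe[:25]]
        out = integration.upstream_regulator_z(fc, {"R": targets}, self.universe)
        assert out["z"].iloc[0] == pytest.approx(5.0)
        assert out["state"].iloc[0] == "activated"

    def test_half_split_undetermined(self):
        fc = self._fc()
        scored = self.universe[:24]
        targets = [
            (g, int(np.sign(fc[g])) if i < 12 else -int(np.sign(fc[g])))
            for i, g in enumerate(scored)
        ]
        out = integration.upstream_regulator_z(fc, {"R": targets}, self.universe)
        assert out["z"].iloc[0] == pytest.approx(0.0)
        assert out["state"].iloc[0] == "undetermined"

    def test_dual_threshold_requires_overlap_p(self):
        """z passing alone does not call activation if the overlap p fails."""
        fc = self._fc(n_regulated=500)
        # 9 agreeing targets: z = 3, but overlap of 9 in a 1000-gene
        # universe with 500 regulated genes is unremarkable
        targets = [(g, int(np.sign(fc[g]))) for g in self.universe[:9]]
        out = integration.upstream_regulator_z(fc, {"R": targets}, self.universe)
        assert out["z"].iloc[0] == pytest.approx(3.0)
        assert out["neg_log10_overlap_p"].iloc[0] <= 7.0
        assert out["state"].iloc[0] == "undetermined"

    def test_zero_scored_targets(self):
        fc = self._fc(n_regulated=10)
        targets = [(g, 1) for g in self.universe[500:505]]
        out = integration.upstream_regulator_z(fc, {"R": targets}, self.universe)
        assert np.isnan(out["z"].iloc[0])
        assert out["state"].iloc[0] == "undetermined"

    def test_target_outside_universe_errors(self):
        fc = self._fc()
        with pytest.raises(ValueError, match="outside"):
            integration.upstream_regulator_z(fc, {"R": [("nope", 1)]}, self.universe)
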