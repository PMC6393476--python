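"""Cell calling, consensus HVG, embedding, clustering, markers, signatures."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
import scipy.stats as st
from sklearn.metrics import adjusted_rand_score

from agelung import atlas
from agelung.containers import CountMatrix, Embedding


def _calls(totals, genes, **kw):
    return atlas.call_cells(pd.Series(totals), pd.Series(genes), **kw)


class TestCallCells:
    def test_rank_and_gene_thresholds(self):
        n = 1500
        totals = {f"b{i}": 5000 - i for i in range(n)}
        genes = {f"b{i}": 500 for i in range(n)}
        genes["b99"] = 150  # rank 100 but too few genes
        calls = _calls(totals, genes)
        assert "b1299" not in calls.cells  # rank 1300: excluded regardless
        assert "b99" not in calls.cells
        genes["b99"] = 300
        calls = _calls(totals, genes)
        assert "b99" in calls.cells
        assert set(calls.cells) | set(calls.empty_pool) == set(totals)

    def test_gene_threshold_is_strict(self):
        totals = {f"b{i}": 100 - i for i in range(10)}
        genes = {f"b{i}": 200 for i in range(10)}
        genes["b0"] = 201
        calls = _calls(totals, genes, max_barcodes=10, min_genes=200)
        assert calls.cells == ["b0"]

    def test_ties_at_cutoff_all_kept(self):
        # 12 barcodes, top-10 rule, ranks 9..12 share the cutoff total
        totals = {f"b{i}": 1000 - 10 * i for i in range(8)}
        totals.update({f"t{i}": 500 for i in range(4)})
        genes = {b: 400 for b in totals}
        calls = _calls(totals, genes, max_barcodes=10, min_genes=200)
        assert {f"t{i}" for i in range(4)} <= set(calls.cells)
        assert len(calls.cells) == 12

    def test_order_invariance(self, rng):
        totals = pd.Series(rng.integers(1, 5000, size=300), index=[f"b{i}" for i in range(300)])
        genes = pd.Series(rng.integers(50, 600, size=300), index=totals.index)
        a = _calls(totals, genes, max_barcodes=100)
        perm = rng.permutation(300)
        b = _calls(totals.iloc[perm], genes.iloc[perm], max_barcodes=100)
        assert set(a.cells) == set(b.cells)

    def test_fewer_barcodes_than_cutoff_warns_and_keeps_all(self):
        totals = {f"b{i}": 100 + i for i in range(5)}
        genes = {f"b{i}": 300 for i in range(5)}
        with pytest.warns(UserWarning, match="barcodes"):
            calls = _calls(totals, genes, max_barcodes=1200)
        assert len(calls.cells) == 5


def _matrix_from_dense(dense, prefix="c"):
    dense = np.asarray(dense)
    return CountMatrix(
        sp.csr_matrix(dense),
        [f"g{i}" for i in range(dense.shape[0])],
        [f"{prefix}{j}" for j in range(dense.shape[1])],
    )


class TestConsensusHVG:
    @pytest.fixture(scope="class")
    def per_mouse(self):
        """8 mice; gene g0 wildly variable in all, g1 variable in exactly 4,
        gene g2 zero-variance everywhere.  Library sizes are equalized so a
        constant raw count stays constant after normalization."""
        rng = np.random.default_rng(42)
        mice = {}
        for m in range(8):
            base = rng.poisson(5, size=(60, 80))
            base[0] = np.r_[rng.poisson(12.0, size=40), rng.poisson(0.2, size=40)]
            if m < 4:
                base[1] = np.r_[rng.poisson(12.0, size=40), rng.poisson(0.2, size=40)]
            else:
                base[1] = 5
            base[2] = 3
            totals = base.sum(axis=0)
            base[59] += totals.max() - totals
            mice[f"m{m}"] = _matrix_from_dense(base, prefix=f"m{m}c")
        return mice

    # wide mean window: the synthetic libraries are tiny, so normalized
    # means fall outside the droplet-scale defaults
    KW = dict(min_mean=0.0, max_mean=1e9)

    def test_strict_threshold_and_zero_variance(self, per_mouse):
        hvg = atlas.consensus_hvg(per_mouse, min_samples=4, **self.KW)
        assert "g1" not in hvg  # in exactly 4 sets: strict >4 excludes
        assert "g2" not in hvg  # zero variance is never highly variable
        hvg3 = atlas.consensus_hvg(per_mouse, min_samples=3, **self.KW)
        assert "g1" in hvg3
        assert "g0" in hvg3

    def test_cell_cycle_genes_removed(self, per_mouse):
        hvg = atlas.consensus_hvg(per_mouse, min_samples=3, **self.KW)
        assert "g0" in hvg
        filtered = atlas.consensus_hvg(
            per_mouse, min_samples=3, cell_cycle_genes={"g0"}, **self.KW
        )
        assert "g0" not in filtered

    def test_lowering_min_samples_is_monotone(self, per_mouse):
        sets = [
            atlas.consensus_hvg(per_mouse, min_samples=k, **self.KW) for k in (6, 4, 2, 0)
        ]
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger


class TestEmbedding:
    def test_scaled_vectors_are_standardized(self, small_cells):
        matrix, _ = small_cells
        genes = matrix.gene_ids[:40]
        scaled = atlas.scaled_expression(matrix, genes)
        np.testing.assert_allclose(scaled.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(scaled.std(axis=0), 1.0, atol=1e-8)

    def test_gene_proportional_to_total_umi_regresses_away(self):
        """A gene that is an exact share of each cell's library is constant
        after library-size normalization, hence zero residual."""
        rng = np.random.default_rng(0)
        dense = rng.poisson(4, size=(50, 120))
        dense[0] = dense[1:].sum(axis=0)  # proportional to total
        matrix = _matrix_from_dense(dense)
        from agelung._stats import log_normalize

        logged = log_normalize(matrix.values)
        residual = logged[0] - logged[0].mean()
        assert np.abs(residual).max() < 1e-6

    def test_same_seed_identical_embedding(self, small_cells):
        matrix, _ = small_cells
        hvg = matrix.gene_ids[:80]
        a = atlas.normalize_and_embed(matrix, hvg, k=5, seed=3)
        b = atlas.normalize_and_embed(matrix, hvg, k=5, seed=3)
        np.testing.assert_allclose(a.coords, b.coords)

    def test_k_larger_than_hvg_errors(self, small_cells):
        matrix, _ = small_cells
        with pytest.raises(ValueError, match="k="):
            atlas.normalize_and_embed(matrix, matrix.gene_ids[:5], k=10)


class TestClustering:
    @pytest.fixture(scope="class")
    def blobs(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 0.1, size=(100, 3))
        b = rng.normal(10.0, 0.1, size=(100, 3))
        coords = np.vstack([a, b])
        labels = np.array([0] * 100 + [1] * 100)
        return Embedding(coords, "test", 3, 0), labels

    def test_planted_partition_recovered(self, blobs):
        emb, truth = blobs
        labels = atlas.cluster_cells(emb, resolution=0.1, seed=0)
        assert len(set(labels)) == 2
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_partition_refines_blobs_at_default_resolution(self, blobs):
        """Higher resolutions may split blobs but never mix them."""
        emb, truth = blobs
        labels = atlas.cluster_cells(emb, resolution=1.0, seed=0)
        for c in set(labels):
            assert len(set(truth[labels == c])) == 1

    def test_resolution_to_zero_gives_single_cluster(self):
        rng = np.random.default_rng(3)
        emb = Embedding(rng.normal(size=(150, 3)), "t", 3, 0)
        labels = atlas.cluster_cells(emb, resolution=1e-4, seed=0)
        assert len(set(labels)) == 1

    def test_permuting_cells_permutes_partition(self, blobs):
        emb, _ = blobs
        labels = atlas.cluster_cells(emb, resolution=1.0, seed=0)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(labels))
        emb2 = Embedding(emb.coords[perm], "test", 3, 0)
        labels2 = atlas.cluster_cells(emb2, resolution=1.0, seed=0)
        assert adjusted_rand_score(labels[perm], labels2) == 1.0

    def test_single_cell_errors(self):
        with pytest.raises(ValueError):
            atlas.cluster_cells(Embedding(np.zeros((1, 2)), "t", 2, 0))


class TestBatchSilhouette:
    def test_hand_computed_two_mouse_line(self):
        emb = Embedding(np.array([[0.0], [0.1], [10.0], [10.1]]), "t", 1, 0)
        s = atlas.batch_silhouette(emb, ["A", "A", "B", "B"])
        assert s == pytest.approx(0.990, abs=1e-3)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(2)
        emb = Embedding(rng.normal(size=(500, 4)), "t", 4, 0)
        labels = rng.choice(["A", "B"], size=500)
        assert abs(atlas.batch_silhouette(emb, labels)) < 0.1

    def test_identical_points_zero_by_convention(self):
        emb = Embedding(np.zeros((6, 2)), "t", 2, 0)
        assert atlas.batch_silhouette(emb, ["A"] * 3 + ["B"] * 3) == 0.0

    def test_single_mouse_errors(self):
        emb = Embedding(np.zeros((3, 2)), "t", 2, 0)
        with pytest.raises(ValueError):
            atlas.batch_silhouette(emb, ["A", "A", "A"])


class TestFindMarkers:
    def test_exclusive_gene_is_a_strong_marker(self, rng):
        dense = rng.poisson(5, size=(30, 40))
        dense[0, :20] = rng.poisson(20, size=20)
        dense[0, 20:] = 0
        matrix = _matrix_from_dense(dense)
        labels = ["A"] * 20 + ["B"] * 20
        table = atlas.find_markers(matrix, labels)
        row = table[(table["gene"] == "g0") & (table["cell_type"] == "A")].iloc[0]
        assert row["p"] < 1e-6
        assert row["pct_out"] == 0.0
        assert row["avg_log2fc"] > 1.0

    def test_null_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(7)
        dense = rng.poisson(5, size=(1000, 60))
        matrix = _matrix_from_dense(dense)
        labels = ["A"] * 30 + ["B"] * 30
        table = atlas.find_markers(matrix, labels)
        sub = table[table["cell_type"] == "A"]
        fpr = float((sub["p"] < 0.05).mean())
        lo, hi = st.binom.interval(0.999, 1000, 0.05)
        assert lo / 1000 <= fpr <= hi / 1000

    def test_zero_means_give_zero_fold_change(self, rng):
        dense = rng.poisson(5, size=(10, 20))
        dense[3] = 0
        table = atlas.find_markers(_matrix_from_dense(dense), ["A"] * 10 + ["B"] * 10)
        assert (table.loc[table["gene"] == "g3", "avg_log2fc"] == 0.0).all()

    def test_small_label_skipped_with_warning(self, rng):
        dense = rng.poisson(5, size=(10, 23))
        labels = ["A"] * 10 + ["B"] * 11 + ["C"] * 2
        with pytest.warns(UserWarning, match="'C'"):
            table = atlas.find_markers(_matrix_from_dense(dense), labels)
        assert set(table["cell_type"]) == {"A", "B"}

    def test_recovers_planted_markers(self, small_atlas, small_markers):
        """>=90% of planted markers pass p_adj < 0.1 at log2FC >= 2."""
        _, _, _, truth = small_atlas
        planted = {
            (truth.gene_ids[g], ct) for ct, genes in truth.marker_genes.items() for g in genes
        }
        hits = small_markers[(small_markers["p_adj"] < 0.1) & (small_markers["avg_log2fc"] > 1)]
        found = set(zip(hits["gene"], hits["cell_type"]))
        assert len(planted & found) / len(planted) >= 0.9


class TestSignatureFisher:
    def test_perfect_overlap_matches_hypergeometric_minimum(self):
        genes = [f"g{i}" for i in range(20)]
        universe = [f"g{i}" for i in range(100)]
        out = atlas.signature_fisher({"q": genes}, {"r": genes}, universe)
        expected = st.hypergeom.sf(19, 100, 20, 20) + st.hypergeom.pmf(20, 100, 20, 20)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_independence_level_overlap_is_not_significant(self):
        universe = [f"g{i}" for i in range(100)]
        q = [f"g{i}" for i in range(20)]  # |A| = 20
        r = [f"g{i}" for i in range(16, 66)]  # |B| = 50, overlap 4 < 10 = |A||B|/N
        out = atlas.signature_fisher({"q": q}, {"r": r}, universe)
        assert out["p"].iloc[0] >= 0.4

    def test_disjoint_sets_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        out = atlas.signature_fisher(
            {"q": universe[:10]}, {"r": universe[20:30]}, universe
        )
        assert out["p"].iloc[0] == 1.0

    def test_capitalization_maps_mouse_to_human_symbols(self):
        out = atlas.signature_fisher(
            {"q": ["Scgb1a1", "Sftpc"]}, {"r": ["SCGB1A1", "SFTPC"]},
            ["SCGB1A1", "SFTPC"] + [f"G{i}" for i in range(30)],
        )
        assert out["overlap"].iloc[0] == 2

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            atlas.signature_fisher({"q": []}, {"r": []}, [])


class TestSignatureMatch:
    def _table(self, sets):
        rows = []
        for ct, genes in sets.items():
            for g in genes:
                rows.append((g, ct, 2.0, 0.9, 0.1, 1e-6, 1e-4))
        return pd.DataFrame(rows, columns=atlas.MARKER_COLUMNS)

    def test_identity_diagonal_and_disjoint_zero(self):
        table = self._table({"A": {"g1", "g2"}, "B": {"g3", "g4"}})
        jac = atlas.signature_match(table, table)
        assert jac.loc["A", "A"] == 1.0 and jac.loc["B", "B"] == 1.0
        assert jac.loc["A", "B"] == 0.0

    def test_partial_overlap_jaccard(self):
        a = self._table({"A": {f"g{i}" for i in range(10)}})
        b = self._table({"B": {f"g{i}" for i in range(5, 15)}})
        jac = atlas.signature_match(a, b)
        assert jac.loc["A", "B"] == pytest.approx(5 / 15)

    def test_self_match_has_diagonal_maxima(self, small_markers):
        jac = atlas.signature_match(small_markers, small_markers)
        for ct in jac.index:
            assert jac.loc[ct, ct] == jac.loc[ct].max() == 1.0
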