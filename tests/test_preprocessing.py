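"""In-database preprocessing against dense numpy oracles."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scsql import (
    calculate_differential_expression,
    calculate_gene_counts,
    calculate_pca,
    calculate_total_counts,
    calculate_variable_genes,
    delete_query,
    expression_log,
    expression_normalize,
    make_db,
    query,
    reconstruct_bundle,
    run_clustering,
    run_embedding,
    select_top_variable_genes,
)
from scsql.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientCellsError,
    NotConfiguredError,
    OrderingContractError,
    ScsqlError,
)

from conftest import make_bundle


def bundle_from(X, celltypes=None):
    import anndata

    X = np.asarray(X, dtype=np.float32)
    bundle = anndata.AnnData(X=X)
    bundle.obs_names = [f"c{i}" for i in range(X.shape[0])]
    bundle.var_names = [f"g{j}" for j in range(X.shape[1])]
    if celltypes is not None:
        bundle.obs["celltype"] = celltypes
    return bundle


class TestTotalCounts:
    def test_simple_sums(self):
        db = make_db(bundle_from([[1, 2, 3], [0, 0, 0]]))
        ann = calculate_total_counts(db)
        assert ann.total_counts.tolist() == [6.0, 0.0]
        # column lands on X and obs
        assert query(db, "SELECT total_counts FROM obs ORDER BY rowid").iloc[0, 0] == 6
        db.close()

    @pytest.mark.parametrize("chunk_size", [1, 7, 300])
    def test_matches_dense_row_sum_oracle(self, chunk_size):
        bundle = make_bundle(n_cells=300, n_genes=40, seed=12)
        db = make_db(bundle)
        ann = calculate_total_counts(db, chunk_size=chunk_size)
        oracle = bundle.X.astype(np.float64).sum(axis=1)
        assert np.allclose(ann.total_counts.to_numpy(), oracle, rtol=1e-6)
        db.close()

    def test_recompute_overwrites(self):
        db = make_db(bundle_from([[1, 1]]))
        calculate_total_counts(db)
        query(db, "SELECT 1")  # no-op
        from scsql import update_query

        update_query(db, "X", {"g0": "5"})
        ann = calculate_total_counts(db)
        assert ann.total_counts.iloc[0] == 6.0
        db.close()


class TestGeneCounts:
    def test_simple_column_sum(self):
        db = make_db(bundle_from([[0, 1], [1, 2], [4, 0]]))
        ann = calculate_gene_counts(db)
        assert ann.total_gene_counts.tolist() == [5.0, 3.0]
        db.close()

    def test_linearity_after_delete(self):
        db = make_db(bundle_from([[1, 2], [3, 4], [5, 6]]))
        first = calculate_gene_counts(db).total_gene_counts
        delete_query(db, "X", "cell_id = 'c0'")
        second = calculate_gene_counts(db).total_gene_counts
        assert (first - second).tolist() == [1.0, 2.0]
        db.close()

    def test_conservation_with_total_counts(self):
        bundle = make_bundle(n_cells=40, n_genes=9, integer_counts=True, seed=3)
        db = make_db(bundle)
        tc = calculate_total_counts(db).total_counts
        gc = calculate_gene_counts(db).total_gene_counts
        assert tc.sum() == gc.sum()  # exact for integer fixtures
        db.close()


class TestNormalize:
    def test_default_target_arithmetic(self):
        db = make_db(bundle_from([[1, 3], [0, 0]]))
        calculate_total_counts(db)
        expression_normalize(db)
        X = reconstruct_bundle(db).X
        assert np.allclose(X[0], [2500, 7500], rtol=1e-6)
        assert np.array_equal(X[1], [0, 0])  # zero cells untouched
        db.close()

    def test_requires_total_counts_first(self):
        db = make_db(bundle_from([[1, 2]]))
        with pytest.raises(OrderingContractError, match="calculate_total_counts"):
            expression_normalize(db)
        db.close()

    def test_matches_dense_oracle(self):
        bundle = make_bundle(n_cells=150, n_genes=25, seed=14)
        db = make_db(bundle)
        calculate_total_counts(db, chunk_size=41)
        expression_normalize(db, chunk_size=37)
        X = reconstruct_bundle(db).X.astype(np.float64)
        dense = bundle.X.astype(np.float64)
        oracle = dense * 10_000.0 / dense.sum(axis=1, keepdims=True)
        assert np.allclose(X, oracle, rtol=1e-5)
        db.close()

    def test_warns_when_library_sizes_stale(self):
        from scsql import update_query

        db = make_db(bundle_from([[1, 2], [3, 4]]))
        calculate_total_counts(db)
        update_query(db, "X", {"g0": "g0 * 2"})
        with pytest.warns(UserWarning, match="stale"):
            expression_normalize(db)
        db.close()


class TestLogTransform:
    @pytest.mark.parametrize("base", ["ln", "log2", "log10"])
    def test_zero_maps_to_zero(self, base):
        db = make_db(bundle_from([[0.0, 3.0]]))
        expression_log(db, base=base)
        X = reconstruct_bundle(db).X
        assert X[0, 0] == 0.0
        db.close()

    def test_log2_of_three_is_two(self):
        db = make_db(bundle_from([[3.0]]))
        expression_log(db, base="log2")
        assert reconstruct_bundle(db).X[0, 0] == pytest.approx(2.0, abs=1e-7)
        db.close()

    @pytest.mark.parametrize("base,fn", [("ln", np.log1p), ("log2", lambda v: np.log2(1 + v)), ("log10", lambda v: np.log10(1 + v))])
    def test_matches_dense_log1p_oracle(self, base, fn):
        bundle = make_bundle(n_cells=80, n_genes=10, seed=15)
        db = make_db(bundle)
        expression_log(db, base=base, chunk_size=13)
        X = reconstruct_bundle(db).X.astype(np.float64)
        assert np.allclose(X, fn(bundle.X.astype(np.float64)), atol=1e-6)
        db.close()

    def test_negative_value_names_cell_and_gene(self):
        bundle = bundle_from([[1.0, 2.0], [1.0, -0.5]])
        db = make_db(bundle)
        with pytest.raises(DomainError, match=r"g1.*c1"):
            expression_log(db)
        # nothing was modified
        assert np.allclose(reconstruct_bundle(db).X, bundle.X)
        db.close()

    def test_monotone_within_gene(self):
        bundle = make_bundle(n_cells=50, n_genes=3, seed=16)
        order_before = np.argsort(bundle.X[:, 1], kind="stable")
        db = make_db(bundle)
        expression_log(db, base="log10")
        X = reconstruct_bundle(db).X
        assert np.array_equal(np.argsort(X[:, 1], kind="stable"), order_before)
        db.close()


class TestVariance:
    def test_closed_form_small_gene(self):
        db = make_db(bundle_from([[1], [2], [3]]))
        pop = calculate_variable_genes(db, estimator="population").variance.iloc[0]
        samp = calculate_variable_genes(db, estimator="sample").variance.iloc[0]
        assert pop == pytest.approx(2 / 3, rel=1e-9)
        assert samp == pytest.approx(1.0, rel=1e-9)

    def test_constant_gene_is_zero(self):
        db = make_db(bundle_from([[5, 1], [5, 2], [5, 3], [5, 4]]))
        for estimator in ("population", "sample"):
            v = calculate_variable_genes(db, estimator=estimator).variance
            assert v.iloc[0] == 0.0
        db.close()

    def test_bessel_relation_exact(self):
        bundle = make_bundle(n_cells=60, n_genes=12, seed=17)
        db = make_db(bundle)
        pop = calculate_variable_genes(db, estimator="population").variance
        samp = calculate_variable_genes(db, estimator="sample").variance
        n = 60
        assert np.allclose(samp, pop * n / (n - 1), rtol=1e-10)
        db.close()

    def test_chunked_matches_streaming_moments_oracle(self):
        bundle = make_bundle(n_cells=500, n_genes=30, seed=18)
        db = make_db(bundle)
        chunked = calculate_variable_genes(db, chunked=True, chunk_size=37)
        assert chunked.estimator == "sample"  # chunked path defaults to Bessel
        oracle = bundle.X.astype(np.float64).var(axis=0, ddof=1)
        assert np.allclose(chunked.variance.to_numpy(), oracle, rtol=1e-6)
        # one-pass and chunked paths agree
        whole = calculate_variable_genes(db, estimator="sample", chunked=False)
        assert np.allclose(chunked.variance, whole.variance, rtol=1e-6)
        db.close()

    def test_single_cell_sample_variance_undefined(self):
        db = make_db(bundle_from([[1, 2]]))
        with pytest.raises(InsufficientCellsError):
            calculate_variable_genes(db, estimator="sample")
        db.close()


class TestTopVariableGenes:
    def test_sorted_descending_with_ordinal_ties(self):
        db = make_db(bundle_from([[0, 0, 0], [0.1, 5.0, 2.0], [0.2, 10.0, 4.0]]))
        calculate_variable_genes(db)
        assert select_top_variable_genes(db, 2) == ["g1", "g2"]
        assert select_top_variable_genes(db, 99) == ["g1", "g2", "g0"]
        db.close()

    def test_requires_variance_first(self):
        db = make_db(make_bundle())
        with pytest.raises(OrderingContractError, match="calculate_variable_genes"):
            select_top_variable_genes(db, 2)
        db.close()

    def test_matches_dense_sort_oracle(self):
        bundle = make_bundle(n_cells=100, n_genes=20, seed=19)
        db = make_db(bundle)
        calculate_variable_genes(db, estimator="sample")
        got = select_top_variable_genes(db, 20)
        variances = bundle.X.astype(np.float64).var(axis=0, ddof=1)
        oracle = [f"g{j}" for j in np.lexsort((np.arange(20), -variances))]
        assert got == oracle
        db.close()


class TestPCA:
    def _fit(self, bundle, k, n_top=None, chunk_size=5000):
        db = make_db(bundle)
        calculate_variable_genes(db, estimator="sample")
        result = calculate_pca(db, k, n_top_genes=n_top, chunk_size=chunk_size)
        return db, result

    def test_rank_one_data(self):
        rng = np.random.default_rng(20)
        base = rng.random(40)
        X = np.column_stack([base, 2 * base])  # perfectly correlated
        db, result = self._fit(bundle_from(X), 2)
        total = result.explained_variance.sum()
        assert result.explained_variance[0] / total == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(result.scores[:, 1], 0, atol=1e-5)
        db.close()

    def test_scores_orthogonal_and_persisted(self):
        bundle = make_bundle(n_cells=100, n_genes=12, seed=21)
        db, result = self._fit(bundle, 4, chunk_size=17)
        gram = result.scores.T @ result.scores
        off = gram - np.diag(np.diag(gram))
        assert np.all(np.abs(off) < 1e-6 * np.abs(np.diag(gram)).max())
        stored = query(db, "SELECT * FROM PC_scores ORDER BY rowid")
        assert np.allclose(stored.iloc[:, 1:].to_numpy(), result.scores)
        assert stored["cell_id"].tolist() == result.cell_ids
        db.close()

    def test_matches_dense_covariance_eigh_oracle(self):
        bundle = make_bundle(n_cells=200, n_genes=25, seed=22)
        db, result = self._fit(bundle, 6, n_top=20, chunk_size=31)
        # dense oracle restricted to the same genes
        cols = [int(g[1:]) for g in result.genes_used]
        dense = bundle.X.astype(np.float64)[:, cols]
        centered = dense - dense.mean(axis=0)
        eigenvalues, eigenvectors = np.linalg.eigh(np.cov(dense, rowvar=False))
        order = np.argsort(eigenvalues)[::-1][:6]
        oracle = centered @ eigenvectors[:, order]
        for j in range(6):
            a, b = result.scores[:, j], oracle[:, j]
            sign = np.sign(a @ b)
            assert np.linalg.norm(a - sign * b) < 1e-4 * np.linalg.norm(b)
        assert np.all(np.diff(result.explained_variance) <= 1e-12)
        assert np.allclose(np.linalg.norm(result.loadings, axis=0), 1.0, atol=1e-9)
        db.close()

    def test_contract_errors(self):
        bundle = make_bundle(n_cells=10, n_genes=4)
        db = make_db(bundle)
        with pytest.raises(OrderingContractError):
            calculate_pca(db, 2)
        calculate_variable_genes(db)
        with pytest.raises(ScsqlError, match="n_components"):
            calculate_pca(db, 5)
        db.close()
        constant = bundle_from(np.ones((6, 3)))
        db = make_db(constant)
        calculate_variable_genes(db)
        with pytest.raises(DegenerateInputError):
            calculate_pca(db, 1)
        db.close()


class TestDifferentialExpression:
    def test_identical_groups_null_result(self):
        X = np.tile([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]], (2, 1))
        labels = ["a"] * 3 + ["b"] * 3
        db = make_db(bundle_from(X, celltypes=labels))
        table = calculate_differential_expression(db, "celltype", "a", "b")
        assert np.allclose(table["statistic"], 0)
        assert np.allclose(table["p_value"], 1)
        assert np.allclose(table["log2_fold_change"], 0)
        db.close()

    def test_doubled_expression_gives_lfc_one(self):
        base = np.array([[1.0], [2.0], [3.0]])
        X = np.vstack([2 * base, base])
        db = make_db(bundle_from(X, celltypes=["a"] * 3 + ["b"] * 3))
        table = calculate_differential_expression(db, "celltype", "a", "b")
        assert table["log2_fold_change"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        db.close()

    def test_planted_shift_matches_welch_oracle_and_ranks_first(self):
        rng = np.random.default_rng(23)
        n_per, n_genes = 40, 30
        X = rng.normal(10, 1, size=(2 * n_per, n_genes))
        planted = [0, 7, 13, 21, 29]
        X[:n_per, planted] += 3.0
        X = np.round(np.abs(X), 3)
        labels = ["a"] * n_per + ["b"] * n_per
        db = make_db(bundle_from(X, celltypes=labels))
        table = calculate_differential_expression(db, "celltype", "a", "b")
        # X is stored at float32 precision; the oracle uses the same values
        Xf = X.astype(np.float32).astype(np.float64)
        oracle = stats.ttest_ind(Xf[:n_per], Xf[n_per:], equal_var=False)
        assert np.allclose(table["statistic"], oracle.statistic, rtol=1e-6)
        assert np.allclose(table["p_value"], oracle.pvalue, rtol=1e-5, atol=1e-12)
        top5 = table.reindex(table["statistic"].abs().sort_values(ascending=False).index)
        assert set(top5["gene"].head(5)) == {f"g{j}" for j in planted}
        db.close()

    def test_unknown_label_lists_available(self):
        db = make_db(bundle_from([[1.0]] * 4, celltypes=["a", "a", "b", "b"]))
        with pytest.raises(ScsqlError, match="available labels"):
            calculate_differential_expression(db, "celltype", "a", "zz")
        db.close()

    def test_small_group_rejected(self):
        db = make_db(bundle_from([[1.0]] * 4, celltypes=["a", "b", "b", "b"]))
        with pytest.raises(InsufficientCellsError):
            calculate_differential_expression(db, "celltype", "a", "b")
        db.close()


class TestDelegates:
    def _with_pcs(self, n_cells=20, k=3):
        bundle = make_bundle(n_cells=n_cells, n_genes=6, seed=24)
        db = make_db(bundle)
        calculate_variable_genes(db)
        calculate_pca(db, k)
        return db

    def test_identity_embedding_passthrough(self):
        db = self._with_pcs()
        run_embedding(db, lambda m: m[:, :2])
        emb = query(db, "SELECT * FROM umap_embeddings ORDER BY rowid")
        pcs = query(db, "SELECT * FROM PC_scores ORDER BY rowid")
        assert np.allclose(emb[["umap1", "umap2"]], pcs[["pc1", "pc2"]])
        db.close()

    def test_constant_label_clustering(self):
        db = self._with_pcs()
        run_clustering(db, lambda m: np.zeros(len(m), dtype=int))
        labels = query(db, "SELECT leiden_clusters FROM obs")
        assert (labels["leiden_clusters"] == 0).all()
        db.close()

    def test_missing_delegate_fails_loudly(self):
        db = self._with_pcs()
        with pytest.raises(NotConfiguredError):
            run_embedding(db)
        with pytest.raises(NotConfiguredError):
            run_clustering(db)
        db.close()

    def test_output_alignment_to_cell_ids(self):
        """The persisted embedding row for each cell carries that cell's own
        PC value, even though the delegate only sees a bare matrix."""
        db = self._with_pcs(n_cells=15)
        run_embedding(db, lambda m: np.column_stack([m[:, 0], np.arange(len(m))]))
        joined = query(
            db,
            "SELECT u.cell_id, u.umap1, p.pc1 FROM umap_embeddings u "
            "JOIN PC_scores p ON u.cell_id = p.cell_id",
        )
        assert np.allclose(joined["umap1"], joined["pc1"])
        db.close()


def test_pipeline_equivalence_with_dense_oracle():
    """total_counts -> normalize -> ln-log in the database equals the dense
    row-normalize-then-log1p pipeline elementwise."""
    bundle = make_bundle(n_cells=400, n_genes=60, seed=25)
    db = make_db(bundle, chunk_size=101)
    calculate_total_counts(db, chunk_size=89)
    expression_normalize(db, chunk_size=97)
    expression_log(db, base="ln", chunk_size=103)
    got = reconstruct_bundle(db).X.astype(np.float64)
    dense = bundle.X.astype(np.float64)
    oracle = np.log1p(dense * 10_000.0 / dense.sum(axis=1, keepdims=True))
    assert np.allclose(got, oracle, rtol=1e-5, atol=1e-5)
    db.close()
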