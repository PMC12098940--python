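# scsql

SQL-queryable relational databases for single-cell expression data.

Atlas-scale single-cell RNA-seq datasets (millions of cells by tens of
thousands of genes) strain the hierarchical containers most analysis stacks
are built on: loading the full matrix into memory fails, and disk-backed
streaming modes typically cannot run aggregate statistics. `scsql` takes the
other road: it converts a layered single-cell object (an
[AnnData](https://anndata.readthedocs.io), in memory or streamed from an
H5AD file in backed mode) into an **in-process relational database** —
either in memory or a single `.asql` file on disk — and makes the cell-by-gene
matrix a first-class SQL table. Filtering, aggregation and preprocessing then
run *inside* the database, chunk by chunk, so memory use is bounded by one
cell block rather than the dataset.

It is written for computational biologists who want fluid SQL access to
expression matrices, and for pipelines that need larger-than-memory
preprocessing on modest hardware.

## Data model

Each layer of the source object maps to one table:

| table | contents |
|---|---|
| `X` | one row per cell: `cell_id` plus one FLOAT column per gene |
| `obs` | `cell_id` plus one column per per-cell annotation |
| `var` | `gene_id` (0-based gene ordinal), `var_names`, per-gene annotations |
| `obsm_<p>` / `varm_<p>` | one table per multi-dimensional annotation (e.g. `obsm_X_pca`) |
| `obsp_<p>` | pairwise cell graphs as `(row_id, col_id, value)` edge lists |
| `uns_raw` | unstructured metadata as `(key, value, data_type)` rows, exactly reconstructible |

A convenience view `adata` joins `obs` and `X` on `cell_id` so annotations
and expression are queryable together. Gene names are sanitized into
SQL-safe identifiers (`HLA-A` → `HLA_A`) with a persisted original→sanitized
map; queries may use either form.

## Core computations

All statistics stream over cell chunks using in-database aggregates:

- **Library sizes** — `total_counts[c] = Σ_g X[c, g]`, written to `X` and `obs`;
  per-gene totals `total_gene_counts[g] = Σ_c X[c, g]` written to `var`.
- **Normalization** — `X[c, g] ← X[c, g] · T / total_counts[c]` with target
  `T = 10,000` by default, so every non-empty cell sums to `T`.
- **Log transforms** — `X[c, g] ← log_b(1 + X[c, g])` for `b ∈ {e, 2, 10}`.
- **Gene variance** — population estimator `Σ(x − x̄)²/n` from SQL moments, or
  the Bessel-corrected sample estimator (`n − 1` denominator) on the chunked
  path; feeds top-variable-gene selection.
- **Hybrid PCA** — the covariance matrix `C = (XᵀX − n·x̄x̄ᵀ)/(n − 1)` of the
  centered top-variable-gene submatrix is accumulated from streamed chunk
  cross-products; the symmetric eigendecomposition runs in numpy; per-cell
  scores land in the `PC_scores` table.
- **Differential expression** — Welch's two-sample *t* per gene from
  in-database group moments, with Welch–Satterthwaite degrees of freedom and
  Benjamini–Hochberg adjusted q-values.
- **UMAP / Leiden** — pluggable delegation points only: a user-supplied
  callable receives the PC-score matrix and its output is persisted to
  `umap_embeddings` / `obs.leiden_clusters`.

The engine is Python's built-in in-process SQLite — zero configuration, one
file on disk. One engine limit to know: a wide table holds at most 2,000
columns, so the cell-by-gene table supports up to 1,999 genes (subset to
variable genes first for larger panels).

## Worked example

```python
import numpy as np
from scsql import *

# dense synthetic dataset: 1,000 cells x 100 genes, 5 random cell types
bundle = generate_dataset(SyntheticSpec(n_cells=1000, n_genes=100, seed=7))
db = make_db(bundle, db_name="sim", db_path=".")   # writes ./sim.asql

print(query(db, "SELECT cell_type, COUNT(*) AS n, AVG(gene_0) AS mean_g0 "
                "FROM adata GROUP BY cell_type ORDER BY cell_type"))
#   cell_type    n   mean_g0
# 0        T0  200  5.027712
# 1        T1  204  5.229534
# 2        T2  189  5.155513
# 3        T3  219  5.167413
# 4        T4  188  4.984984

calculate_total_counts(db)          # library sizes -> X and obs
expression_normalize(db)            # per-cell sum -> 10,000
expression_log(db, base="ln")       # ln(1 + x)
calculate_variable_genes(db, estimator="sample")

pca = calculate_pca(db, n_components=10, n_top_genes=50)
print(np.round(pca.explained_variance[:3], 4))
# [1.3102 1.2708 1.2478]
print(query(db, "SELECT cell_id, pc1, pc2 FROM PC_scores LIMIT 3"))
#   cell_id       pc1       pc2
# 0  cell_0  0.501335 -2.964180
# 1  cell_1  0.854092 -3.077518
# 2  cell_2 -0.406890 -0.355342

de = calculate_differential_expression(db, "cell_type", "T0", "T1")
print(de.sort_values("p_value")[["gene", "statistic", "p_value"]].head(3))
#        gene  statistic   p_value
# 12  gene_12   2.949892  0.003373
# 93  gene_93   2.626453  0.008969
# 25  gene_25   2.593009  0.009865
db.close()
```

The group-by table shows the random cell-type assignment is balanced and
gene 0's mean sits near 5 (uniform values on [0, 10)); after normalization
and `ln(1+x)`, per-gene variances are ~1 and the leading PCs of unstructured
noise carry near-equal variance. The DE table shows no gene survives
multiple-testing on null data, as it should.

Queries can also return results as an annotated matrix
(`return_mode="annotated_matrix"`) or a Parquet file
(`return_mode="parquet"`), and the same operations are scriptable from the
shell via `scsql build / query / preprocess / bench`.

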