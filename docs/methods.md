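# Methods

## The relational mapping

A layered single-cell object is flattened into one table per layer property.
The expression matrix becomes a *wide* table — `cell_id` plus one FLOAT
column per gene — because column-wise analytics (per-gene aggregates,
single-gene filters) are the dominant access pattern. Per-cell annotations
(`obs`) keep `cell_id` as the join key; per-gene annotations (`var`) are
keyed by `gene_id`, the 0-based ordinal of the gene in the source, with the
gene names themselves in a `var_names` column (kept inside `var` rather than
as a separate table: the names are one-to-one with gene ordinals, and a
second table would add a join for no information). Multi-dimensional
annotations (`obsm`, `varm`) each get their own table named
`<layer>_<property>` with generic component columns `c0..c{k-1}`. Pairwise
cell layers (`obsp`) are stored as `(row_id, col_id, value)` edge lists — a
cells-wide table is infeasible and pairwise graphs are sparse in practice.

Unstructured metadata (`uns`) is serialized into `(key, value, data_type)`
rows. The value is a recursive, self-describing JSON encoding tagged with a
type from `{string, int, float, bool, array, mapping, null}`; arrays record
dtype, shape and kind (ndarray vs list vs tuple) so reconstruction is exact,
not merely approximate. Unserializable values raise immediately, naming the
offending key.

### Identifier sanitization

Gene and column names are mapped to SQL-safe identifiers: every character
outside `[A-Za-z0-9_]` becomes `_`, a leading digit gets a `_` prefix, and
collisions are resolved deterministically with `_1`, `_2`, … suffixes in
source order. The original→sanitized map is persisted inside the database,
so original names are always recoverable, and the query layer rewrites
original names to sanitized ones before execution (both bare and
double-quoted occurrences, longest-first, in a single pass so one gene's
sanitized form can never be corrupted by another's rewrite). Two caveats are
accepted and documented rather than engineered around: the rewrite is
textual, so a gene name that appears inside a *string literal* in a query
is also rewritten; and when sanitization displaces a literal name (gene
`MT.CO1` claims `MT_CO1` before a gene literally named `MT_CO1` is seen),
the original spelling always wins during rewriting — write the suffixed
sanitized name to address the displaced column. Generated SQL always quotes
identifiers, so genes named after SQL keywords need no special casing.

## The engine

The store is Python's built-in SQLite: a true in-process, single-file,
zero-configuration SQL engine, giving the package its `.asql` on-disk format
and in-memory mode with an identical surface. Two consequences are worth
stating plainly:

- **Column cap.** SQLite tables hold at most 2,000 columns, so wide X
  tables support ≤ 1,999 genes. Within this package's scope (desk-scale
  synthetic data, variable-gene workflows) that is sufficient; full-genome
  panels must be subset before building. The cap is checked with a clear
  error at build time.
- **Row-oriented storage.** Every query reads whole rows. Aggregate scans
  are therefore linear in *cells × genes* rather than in the queried columns
  alone, and the near-flat query-time scaling that columnar engines show on
  single-column queries is **not** reproduced here. The benchmark harness
  (below) measures and reports this honestly; on the 25k→50k cell step the
  database path's suite time grows by a factor ≥ the dense numpy scan's.
  Durability pragmas are relaxed (`journal_mode=MEMORY`, `synchronous=OFF`)
  — this is an analytics store rebuilt from source data, not a system of
  record.

Write access follows a single-writer contract; read-only handles are
enforced at the engine level (URI `mode=ro`).

## Chunked out-of-core operation

Ingestion and every preprocessing pass iterate cells in blocks
(`chunk_size`, default 5,000 cells — small enough that a block of a
10k-gene-wide dataset stays well under 1 GiB, large enough to amortize
per-statement overhead). The source matrix accessor is only ever asked for
one `[start:stop]` slice at a time, which is what bounds ingestion memory
for H5AD sources opened in backed mode; the property is testable by
instrumenting the accessor's maximum request size. Sparse sources are
densified one chunk at a time (storage is dense by design — one FLOAT per
cell × gene). Values are cast to single precision on ingestion; integer
counts above 2²⁴ would lose exactness, which is noted rather than guarded.

Chunk iteration after deletions walks rowid *ranges* (min to max in fixed
steps), so gaps left by `DELETE` cannot skip or double-count cells; blocks
may simply run short. All per-cell transforms are algebraically independent
of the chunking, and streamed accumulations (moments, cross-products) differ
only by floating-point summation order — tolerances of 1e-6 relative cover
this comfortably at the fixture sizes used.

## Preprocessing semantics

- **Ordering contracts.** Operations with prerequisites fail loudly
  (`OrderingContractError`) instead of computing on wrong state: normalize
  requires library sizes; variable-gene selection and PCA require stored
  variances.
- **Library sizes are frozen at compute time.** Normalization divides by the
  *stored* `total_counts`; if X changed since they were computed, a warning
  says to recompute. This makes "normalize twice" a deliberate two-step
  rather than a silent re-normalization.
- **Log pseudocount.** The transforms compute `log_b(1 + x)` — the
  single-cell convention — so zeros stay finite and map to zero; negative
  values are a domain error naming the cell and gene, raised before any
  value is modified.
- **Variance estimators.** The whole-table path defaults to the population
  estimator (computed from in-database SUM/SUM-of-squares moments); the
  chunked path defaults to the Bessel-corrected sample estimator from
  streamed per-gene `(n, Σx, Σx²)` accumulators. The asymmetry of the
  defaults is intentional and mirrors how the two code paths are typically
  used; both estimators are available on both paths, and
  `sample = population · n/(n−1)` holds to machine precision because both
  derive from the same moments. Moment-based variance is numerically safe
  here (nonnegative bounded expression values; a `max(·, 0)` clamp absorbs
  the last-ulp cancellation for constant genes).
- **PCA.** Covariance (not correlation) of mean-centered top-variable genes,
  matching the covariance-matrix formulation; variance scaling is available
  but off by default. Eigenvectors come from `numpy.linalg.eigh`; components
  are sorted by descending eigenvalue and each loading vector's
  largest-magnitude element is made positive, a deterministic sign
  convention across eigensolvers. Degenerate input (only zero-variance genes
  selected) is an error, not a NaN.
- **Differential expression.** Welch's *t* was chosen because it is exactly
  computable from the streamed per-group moments the engine already
  produces, needs no equal-variance assumption, and degrades gracefully:
  identical groups give `t = 0, p = 1`; a zero-variance nonzero shift gives
  `p = 0`. Fold changes use `log2((m_a + ε)/(m_b + ε))` with `ε = 1e-9` to
  guard silent genes. Benjamini–Hochberg q-values are appended as a
  convenience column.
- **Embedding/clustering.** UMAP and Leiden are delegation points only: the
  caller supplies the routine, the package guarantees row alignment of its
  output to `cell_id` and persists under the conventional names
  (`umap_embeddings`, `obs.leiden_clusters`). No silent fallback exists.

## Synthetic data

The generator emulates the runtime-profiling datasets: a fully dense matrix
of random expression values — uniform on [0, 10) by default, or
negative-binomial (mean 2, dispersion 0.5; variance = m + αm²) for
count-like data — with 10,000 genes by default and one uniformly random
cell-type label per cell, seeded and bit-reproducible. What it deliberately
does *not* emulate: sparsity, mean–variance coupling across genes, library-
size variation, batch structure, or biological cluster structure. Tests
passing on these fixtures therefore demonstrate *computational* correctness
(SQL ↔ dense-oracle equivalence, chunk invariance, contracts), not
biological recovery on realistic data — except where a test plants explicit
structure (rank-k signal for PCA, mean shifts for DE) and checks its
recovery.

## Benchmark harness

The six-query default suite rises in complexity: single-gene select,
single-gene threshold filter, two-gene conjunctive filter, per-gene average
over all cells, group-by-cell-type aggregate, and an obs-joined filtered
aggregate; the suite is a plain list of (SQL, dense-evaluator) pairs and is
fully replaceable. Benchmarking is **correctness-gated**: each query's
result must equal the dense oracle's value-for-value before a single timing
is recorded; a mismatch is a hard failure, so no timing can ever describe a
wrong answer. Method comparisons pair replicates on
(library size, query, replicate) and apply a paired t-test per library size
with Bonferroni correction across sizes (flagging at corrected p < .001).
The degenerate zero-variance-of-differences case is handled explicitly:
all-equal pairs are a non-result (t = 0, p = 1); a constant nonzero shift is
reported significant with p ≈ 0 and flagged as degenerate. Default problem
sizes are desk-scale (ladder 1k–50k cells; 500-gene benchmark tables;
acceptance fixtures up to 50,000 × 1,000) so the full suite runs in minutes
on one CPU.

## Known limitations

- ≤ 1,999 genes per wide table (engine column cap).
- Row-oriented storage: no columnar scan advantage; see "The engine".
- Identifier rewriting is textual (string literals containing gene names
  are rewritten too).
- No multi-matrix slots (`layers`, `raw`), no schema normalization, no
  concurrent writers, no server mode.
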