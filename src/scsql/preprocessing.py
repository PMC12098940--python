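"""Chunked, in-database preprocessing for cell-by-gene databases.

All statistics are computed by SQL aggregation inside the engine, streaming
over cell blocks so nothing larger than one chunk of X is ever materialized:

* per-cell library sizes (``total_counts`` on X and obs),
* per-gene totals (``total_gene_counts`` on var),
* library-size normalization to a fixed target sum (default 10,000),
* ``log(1+x)`` transforms in natural log, log2 or log10,
* per-gene expression variance (population or Bessel-corrected sample
  estimator) feeding variable-gene selection,
* hybrid PCA: the covariance matrix of the centered top-variable-gene
  submatrix is accumulated from streamed cross-products, the
  eigendecomposition runs outside the database, and per-cell scores are
  persisted to the ``PC_scores`` table,
* Welch's t differential expression from in-database group moments,
* pluggable embedding/clustering delegates persisted as the
  ``umap_embeddings`` table and the ``obs.leiden_clusters`` column.

Operations with prerequisites fail loudly with an ordering-contract error
(e.g. normalization before total counts) rather than computing on wrong
state.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .database_io import DatabaseHandle
from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientCellsError,
    MissingTableError,
    NotConfiguredError,
    OrderingContractError,
    ScsqlError,
)
from .schema_builder import create_convenience_view, quote_identifier

DEFAULT_CHUNK_SIZE = 5_000
DEFAULT_NORMALIZE_TARGET = 10_000.0

LOG_FUNCTIONS = {"ln": "ln", "log2": "log2", "log10": "log10"}


@dataclass
class CountsAnnotation:
    """Per-cell library sizes and/or per-gene totals, as written to the
    database (indexed by cell_id / original gene name)."""

    total_counts: pd.Series | None = None
    total_gene_counts: pd.Series | None = None


@dataclass
class VarianceAnnotation:
    """Per-gene expression variance stored in var's ``variance`` column."""

    variance: pd.Series
    estimator: str  # 'population' or 'sample'


@dataclass
class PCAResult:
    """Principal components of the top-variable-gene submatrix.

    ``scores`` (cells x k) is also persisted to the ``PC_scores`` table;
    ``loadings`` columns are unit-norm with a deterministic sign (largest
    magnitude element positive); ``explained_variance`` is non-increasing.
    """

    cell_ids: list[str]
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    genes_used: list[str]


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _require_table(db: DatabaseHandle, table: str) -> None:
    if not db.has_table(table):
        raise MissingTableError(f"table {table!r} does not exist in this database")


def _gene_entries(db: DatabaseHandle) -> list[tuple[str, str, int]]:
    entries = db.identifier_map.entries("X")
    if not entries:
        raise MissingTableError("no gene columns recorded for table 'X'")
    return entries


def _batched(seq: Sequence, size: int) -> Iterator[Sequence]:
    for start in range(0, len(seq), size):
        yield seq[start : start + size]


def _grouped_sum(columns: Sequence[str], term: str = "{col}") -> str:
    """Left-associative sums nested in groups of 100 to keep the parse tree
    shallow for wide tables."""
    groups = [
        "(" + " + ".join(term.format(col=quote_identifier(c)) for c in group) + ")"
        for group in _batched(list(columns), 100)
    ]
    return " + ".join(groups)


def _rowid_ranges(
    db: DatabaseHandle, table: str, chunk_size: int
) -> Iterator[tuple[int, int]]:
    """Inclusive rowid ranges covering the table in blocks of ``chunk_size``
    rowids (robust to gaps left by deletes)."""
    row = db.execute(
        f"SELECT MIN(rowid), MAX(rowid) FROM {quote_identifier(table)}"
    ).fetchone()
    if row[0] is None:
        return
    lo, hi = int(row[0]), int(row[1])
    for start in range(lo, hi + 1, chunk_size):
        yield start, min(start + chunk_size - 1, hi)


def _ensure_column(db: DatabaseHandle, table: str, column: str, sql_type: str) -> None:
    if column not in db.table_columns(table):
        db.execute(
            f"ALTER TABLE {quote_identifier(table)} ADD COLUMN "
            f"{quote_identifier(column)} {sql_type}"
        )


def _ensure_var_table(db: DatabaseHandle) -> None:
    if not db.has_table("var"):
        db.execute('CREATE TABLE "var" (gene_id BIGINT, var_names TEXT)')
        db.executemany(
            'INSERT INTO "var" VALUES (?, ?)',
            ((ordinal, original) for original, _, ordinal in _gene_entries(db)),
        )


def _refresh_view(db: DatabaseHandle) -> None:
    if db.has_table("adata"):
        create_convenience_view(db, replace=True)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def calculate_total_counts(
    db: DatabaseHandle, chunk_size: int = DEFAULT_CHUNK_SIZE
) -> CountsAnnotation:
    """Per-cell library sizes: iterate cells in chunks summing all gene
    columns, writing ``total_counts`` to X and then obs.

    Recomputing overwrites the column (idempotent). The library sizes are
    frozen as of this call: normalization later warns if X changed in
    between.
    """
    _require_table(db, "X")
    columns = [s for _, s, _ in _gene_entries(db)]
    _ensure_column(db, "X", "total_counts", "DOUBLE")
    sum_expr = _grouped_sum(columns)
    for lo, hi in _rowid_ranges(db, "X", chunk_size):
        db.execute(
            f'UPDATE "X" SET "total_counts" = {sum_expr} '
            f"WHERE rowid BETWEEN {lo} AND {hi}"
        )
    if db.has_table("obs"):
        _ensure_column(db, "obs", "total_counts", "DOUBLE")
        db.execute(
            'UPDATE "obs" SET "total_counts" = '
            '(SELECT "total_counts" FROM "X" WHERE "X"."cell_id" = "obs"."cell_id")'
        )
        _refresh_view(db)
    db.commit()
    db.set_meta("x_version_at_total_counts", db.get_meta("x_version", 0))
    rows = db.execute('SELECT "cell_id", "total_counts" FROM "X" ORDER BY rowid').fetchall()
    series = pd.Series(
        [r[1] for r in rows], index=[r[0] for r in rows], name="total_counts"
    )
    return CountsAnnotation(total_counts=series)


def calculate_gene_counts(db: DatabaseHandle) -> CountsAnnotation:
    """Per-gene totals via the engine's SUM aggregate, written to
    ``var.total_gene_counts`` in gene-ordinal order."""
    _require_table(db, "X")
    entries = _gene_entries(db)
    sums: list[float] = []
    for batch in _batched(entries, 500):
        select = ", ".join(f"SUM({quote_identifier(s)})" for _, s, _ in batch)
        row = db.execute(f'SELECT {select} FROM "X"').fetchone()
        sums.extend(0.0 if v is None else float(v) for v in row)
    _ensure_var_table(db)
    _ensure_column(db, "var", "total_gene_counts", "DOUBLE")
    db.executemany(
        'UPDATE "var" SET "total_gene_counts" = ? WHERE "gene_id" = ?',
        ((sums[i], ordinal) for i, (_, _, ordinal) in enumerate(entries)),
    )
    db.commit()
    series = pd.Series(
        sums, index=[original for original, _, _ in entries], name="total_gene_counts"
    )
    return CountsAnnotation(total_gene_counts=series)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def expression_normalize(
    db: DatabaseHandle,
    target: float = DEFAULT_NORMALIZE_TARGET,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> None:
    """Library-size normalization: each value becomes
    ``x * target / total_counts`` so every cell with positive counts sums to
    ``target``; all-zero cells are left untouched.

    Requires :func:`calculate_total_counts` first (ordering contract). The
    stored library sizes are used as-is; if X changed since they were
    computed a warning is emitted.
    """
    _require_table(db, "X")
    if target <= 0:
        raise ValueError("normalization target must be positive")
    if "total_counts" not in db.table_columns("X"):
        raise OrderingContractError(
            "expression_normalize requires the total_counts column; "
            "run calculate_total_counts first"
        )
    recorded = db.get_meta("x_version_at_total_counts")
    if recorded is None or recorded != db.get_meta("x_version", 0):
        warnings.warn(
            "X changed since total_counts was computed; normalizing against "
            "the stored (stale) library sizes — rerun calculate_total_counts "
            "to refresh them",
            stacklevel=2,
        )
    columns = [s for _, s, _ in _gene_entries(db)]
    target_literal = repr(float(target))
    assignments = ", ".join(
        f"{quote_identifier(c)} = CASE WHEN \"total_counts\" > 0 "
        f"THEN {quote_identifier(c)} * {target_literal} / \"total_counts\" "
        f"ELSE {quote_identifier(c)} END"
        for c in columns
    )
    for lo, hi in _rowid_ranges(db, "X", chunk_size):
        db.execute(f'UPDATE "X" SET {assignments} WHERE rowid BETWEEN {lo} AND {hi}')
    db.commit()
    db.bump_x_version()


def expression_log(
    db: DatabaseHandle, base: str = "ln", chunk_size: int = DEFAULT_CHUNK_SIZE
) -> None:
    """Replace every value x with ``log_base(1 + x)`` (``ln``, ``log2`` or
    ``log10``), chunk by chunk; zeros map to zero.

    Negative values are a domain error reported with the offending cell and
    gene before anything is modified.
    """
    _require_table(db, "X")
    if base not in LOG_FUNCTIONS:
        raise ValueError(f"base must be one of {tuple(LOG_FUNCTIONS)}, got {base!r}")
    entries = _gene_entries(db)
    for batch in _batched(entries, 500):
        select = ", ".join(f"MIN({quote_identifier(s)})" for _, s, _ in batch)
        row = db.execute(f'SELECT {select} FROM "X"').fetchone()
        for (original, sanitized, _), minimum in zip(batch, row):
            if minimum is not None and minimum < 0:
                cell = db.execute(
                    f'SELECT "cell_id" FROM "X" WHERE {quote_identifier(sanitized)} < 0 '
                    "LIMIT 1"
                ).fetchone()[0]
                raise DomainError(
                    f"negative expression value for gene {original!r} in cell "
                    f"{cell!r}; log transforms require nonnegative X"
                )
    fn = LOG_FUNCTIONS[base]
    assignments = ", ".join(
        f"{quote_identifier(s)} = {fn}(1.0 + {quote_identifier(s)})"
        for _, s, _ in entries
    )
    for lo, hi in _rowid_ranges(db, "X", chunk_size):
        db.execute(f'UPDATE "X" SET {assignments} WHERE rowid BETWEEN {lo} AND {hi}')
    db.commit()
    db.bump_x_version()


# ---------------------------------------------------------------------------
# variance and variable genes
# ---------------------------------------------------------------------------


def _gene_moments(
    db: DatabaseHandle,
    entries: Sequence[tuple[str, str, int]],
    where: str | None = None,
) -> tuple[int, np.ndarray, np.ndarray]:
    """In-database (count, per-gene sum, per-gene sum of squares)."""
    where_clause = f" WHERE {where}" if where else ""
    n = int(db.execute(f'SELECT COUNT(*) FROM "X"{where_clause}').fetchone()[0])
    s = np.zeros(len(entries))
    ss = np.zeros(len(entries))
    offset = 0
    for batch in _batched(list(entries), 250):
        select = ", ".join(
            f"SUM({quote_identifier(c)}), SUM({quote_identifier(c)} * {quote_identifier(c)})"
            for _, c, _ in batch
        )
        row = db.execute(f'SELECT {select} FROM "X"{where_clause}').fetchone()
        for i in range(len(batch)):
            s[offset + i] = row[2 * i] or 0.0
            ss[offset + i] = row[2 * i + 1] or 0.0
        offset += len(batch)
    return n, s, ss


def calculate_variable_genes(
    db: DatabaseHandle,
    estimator: str | None = None,
    chunked: bool = False,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> VarianceAnnotation:
    """Per-gene expression variance, stored in var's ``variance`` column.

    The whole-table path defaults to the population estimator
    (sum((x-mean)^2)/n, computed from SQL moments); the chunked path streams
    per-gene (count, sum, sum of squares) accumulators over cell blocks and
    defaults to the Bessel-corrected sample estimator (denominator n-1).
    Either estimator can be requested on either path.
    """
    _require_table(db, "X")
    if estimator is None:
        estimator = "sample" if chunked else "population"
    if estimator not in ("population", "sample"):
        raise ValueError(f"estimator must be 'population' or 'sample', got {estimator!r}")
    entries = _gene_entries(db)

    if chunked:
        n = 0
        s = np.zeros(len(entries))
        ss = np.zeros(len(entries))
        for lo, hi in _rowid_ranges(db, "X", chunk_size):
            offset = 0
            n += int(
                db.execute(
                    f'SELECT COUNT(*) FROM "X" WHERE rowid BETWEEN {lo} AND {hi}'
                ).fetchone()[0]
            )
            for batch in _batched(entries, 250):
                select = ", ".join(
                    f"SUM({quote_identifier(c)}), "
                    f"SUM({quote_identifier(c)} * {quote_identifier(c)})"
                    for _, c, _ in batch
                )
                row = db.execute(
                    f'SELECT {select} FROM "X" WHERE rowid BETWEEN {lo} AND {hi}'
                ).fetchone()
                for i in range(len(batch)):
                    s[offset + i] += row[2 * i] or 0.0
                    ss[offset + i] += row[2 * i + 1] or 0.0
                offset += len(batch)
    else:
        n, s, ss = _gene_moments(db, entries)

    if n == 0 or (estimator == "sample" and n < 2):
        raise InsufficientCellsError(
            f"{estimator} variance is undefined for {n} cell(s)"
        )
    population = np.maximum(ss / n - (s / n) ** 2, 0.0)
    variance = population * n / (n - 1) if estimator == "sample" else population

    _ensure_var_table(db)
    _ensure_column(db, "var", "variance", "DOUBLE")
    db.executemany(
        'UPDATE "var" SET "variance" = ? WHERE "gene_id" = ?',
        (
            (float(variance[i]), ordinal)
            for i, (_, _, ordinal) in enumerate(entries)
        ),
    )
    db.commit()
    db.set_meta("variance_estimator", estimator)
    series = pd.Series(
        variance, index=[original for original, _, _ in entries], name="variance"
    )
    return VarianceAnnotation(variance=series, estimator=estimator)


def select_top_variable_genes(db: DatabaseHandle, n_top: int) -> list[str]:
    """Genes ordered by stored variance (descending, ties broken by gene
    ordinal), clamped to the number of genes; returns original gene names."""
    _require_table(db, "var")
    if "variance" not in db.table_columns("var"):
        raise OrderingContractError(
            "no variance column on var; run calculate_variable_genes first"
        )
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    rows = db.execute(
        'SELECT "var_names" FROM "var" ORDER BY "variance" DESC, "gene_id" ASC '
        f"LIMIT {int(n_top)}"
    ).fetchall()
    return [r[0] for r in rows]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def calculate_pca(
    db: DatabaseHandle,
    n_components: int,
    n_top_genes: int | None = None,
    center: bool = True,
    scale: bool = False,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> PCAResult:
    """Hybrid PCA over the top-variable-gene submatrix.

    The gene-gene covariance matrix is accumulated from streamed chunk
    cross-products (nothing wider than ``chunk_size x n_top_genes`` is ever
    in memory); the symmetric eigendecomposition runs in numpy; per-cell
    scores (centered data projected on the top-``n_components`` eigenvectors)
    are persisted to ``PC_scores`` with columns ``cell_id, pc1..pck``.

    Genes are mean-centered but not variance-scaled by default (covariance,
    not correlation, PCA); pass ``scale=True`` for the correlation variant.
    Loading signs are fixed so each component's largest-magnitude loading is
    positive, making results reproducible across eigensolvers.
    """
    _require_table(db, "X")
    genes_used = select_top_variable_genes(
        db, n_top_genes if n_top_genes is not None else len(_gene_entries(db))
    )
    if n_components < 1 or n_components > len(genes_used):
        raise ScsqlError(
            f"n_components={n_components} must be in [1, {len(genes_used)}] "
            "(number of genes used)"
        )
    id_map = db.identifier_map
    columns = [id_map.sanitized("X", g) for g in genes_used]
    col_sql = ", ".join(quote_identifier(c) for c in columns)

    p = len(columns)
    n = 0
    colsum = np.zeros(p)
    cross = np.zeros((p, p))
    for lo, hi in _rowid_ranges(db, "X", chunk_size):
        block = np.asarray(
            db.execute(
                f'SELECT {col_sql} FROM "X" WHERE rowid BETWEEN {lo} AND {hi} '
                "ORDER BY rowid"
            ).fetchall(),
            dtype=np.float64,
        )
        if block.size == 0:
            continue
        n += block.shape[0]
        colsum += block.sum(axis=0)
        cross += block.T @ block
    if n < 2:
        raise InsufficientCellsError("PCA requires at least 2 cells")

    mean = colsum / n if center else np.zeros(p)
    cov = (cross - n * np.outer(mean, mean)) / (n - 1)
    diag = np.diag(cov).copy()
    if not np.any(diag > 0):
        raise DegenerateInputError(
            "all selected genes have zero variance; PCA input is degenerate"
        )
    std = np.ones(p)
    if scale:
        std = np.sqrt(np.maximum(diag, 0.0))
        std[std == 0] = 1.0
        cov = cov / np.outer(std, std)

    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1][:n_components]
    explained = np.maximum(eigenvalues[order], 0.0)
    loadings = eigenvectors[:, order]
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] = -loadings[:, j]

    db.execute('DROP TABLE IF EXISTS "PC_scores"')
    pc_cols = ", ".join(f'"pc{j + 1}" DOUBLE' for j in range(n_components))
    db.execute(f'CREATE TABLE "PC_scores" ("cell_id" TEXT, {pc_cols})')
    placeholders = ", ".join(["?"] * (n_components + 1))

    cell_ids: list[str] = []
    score_blocks: list[np.ndarray] = []
    for lo, hi in _rowid_ranges(db, "X", chunk_size):
        rows = db.execute(
            f'SELECT "cell_id", {col_sql} FROM "X" WHERE rowid BETWEEN {lo} AND {hi} '
            "ORDER BY rowid"
        ).fetchall()
        if not rows:
            continue
        ids = [r[0] for r in rows]
        block = np.asarray([r[1:] for r in rows], dtype=np.float64)
        block_scores = ((block - mean) / std) @ loadings
        db.executemany(
            f'INSERT INTO "PC_scores" VALUES ({placeholders})',
            (
                (ids[i], *block_scores[i].tolist())
                for i in range(len(ids))
            ),
        )
        cell_ids.extend(ids)
        score_blocks.append(block_scores)
    db.commit()

    return PCAResult(
        cell_ids=cell_ids,
        scores=np.vstack(score_blocks),
        loadings=loadings,
        explained_variance=explained,
        genes_used=genes_used,
    )


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

FOLD_CHANGE_EPSILON = 1e-9


def calculate_differential_expression(
    db: DatabaseHandle,
    group_column: str,
    group_a,
    group_b,
    genes: Sequence[str] | None = None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Welch's two-sample t-test per gene between two obs-defined groups.

    Group (count, mean, sample variance) are computed inside the database
    from streamed SUM/SUM-of-squares aggregates; the t statistic uses the
    Welch-Satterthwaite degrees of freedom and a two-sided p-value.
    ``log2_fold_change = log2((mean_a + eps) / (mean_b + eps))`` with
    ``eps = 1e-9`` guarding silent genes. Benjamini-Hochberg ``q_value`` is
    appended unless ``adjust=False``.
    """
    _require_table(db, "X")
    _require_table(db, "obs")
    id_map = db.identifier_map
    try:
        group_sanitized = id_map.sanitized("obs", group_column)
    except KeyError:
        if group_column in db.table_columns("obs"):
            group_sanitized = group_column
        else:
            raise ScsqlError(
                f"obs has no column {group_column!r}; available: "
                f"{db.table_columns('obs')}"
            ) from None
    gq = quote_identifier(group_sanitized)
    labels = [
        r[0] for r in db.execute(f'SELECT DISTINCT {gq} FROM "obs"').fetchall()
    ]
    for label in (group_a, group_b):
        if label not in labels:
            raise ScsqlError(
                f"unknown group label {label!r} in column {group_column!r}; "
                f"available labels: {sorted(map(str, labels))}"
            )

    entries = _gene_entries(db)
    if genes is not None:
        wanted = set(genes)
        entries = [e for e in entries if e[0] in wanted]
        if not entries:
            raise ScsqlError("none of the requested genes exist in X")

    def group_moments(label) -> tuple[int, np.ndarray, np.ndarray]:
        base = (
            'FROM "X" JOIN "obs" ON "X"."cell_id" = "obs"."cell_id" '
            f'WHERE "obs".{gq} = ?'
        )
        n = int(db.execute(f"SELECT COUNT(*) {base}", (label,)).fetchone()[0])
        s = np.zeros(len(entries))
        ss = np.zeros(len(entries))
        offset = 0
        for batch in _batched(entries, 250):
            select = ", ".join(
                f'SUM("X".{quote_identifier(c)}), '
                f'SUM("X".{quote_identifier(c)} * "X".{quote_identifier(c)})'
                for _, c, _ in batch
            )
            row = db.execute(f"SELECT {select} {base}", (label,)).fetchone()
            for i in range(len(batch)):
                s[offset + i] = row[2 * i] or 0.0
                ss[offset + i] = row[2 * i + 1] or 0.0
            offset += len(batch)
        return n, s, ss

    n_a, s_a, ss_a = group_moments(group_a)
    n_b, s_b, ss_b = group_moments(group_b)
    for label, count in ((group_a, n_a), (group_b, n_b)):
        if count < 2:
            raise InsufficientCellsError(
                f"group {label!r} has {count} cell(s); at least 2 required"
            )

    mean_a, mean_b = s_a / n_a, s_b / n_b
    var_a = np.maximum((ss_a - s_a**2 / n_a) / (n_a - 1), 0.0)
    var_b = np.maximum((ss_b - s_b**2 / n_b) / (n_b - 1), 0.0)

    se2 = var_a / n_a + var_b / n_b
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        statistic = np.where(se2 > 0, diff / np.sqrt(se2), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        df_num = se2**2
        df_den = (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
        dof = np.where(df_den > 0, df_num / df_den, 1.0)
    p_value = np.where(
        np.isinf(statistic),
        0.0,
        2.0 * stats.t.sf(np.abs(statistic), np.maximum(dof, 1e-12)),
    )
    p_value = np.where(se2 == 0, np.where(diff == 0, 1.0, 0.0), p_value)
    eps = FOLD_CHANGE_EPSILON
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2((mean_a + eps) / (mean_b + eps))

    out = pd.DataFrame(
        {
            "gene": [original for original, _, _ in entries],
            "n_a": n_a,
            "n_b": n_b,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fold_change": lfc,
            "statistic": statistic,
            "p_value": p_value,
        }
    )
    if adjust and len(out):
        out["q_value"] = stats.false_discovery_control(
            np.clip(out["p_value"].to_numpy(), 0.0, 1.0), method="bh"
        )
    return out


# ---------------------------------------------------------------------------
# pluggable embedding / clustering delegates
# ---------------------------------------------------------------------------


def _pc_matrix(db: DatabaseHandle) -> tuple[list[str], np.ndarray]:
    if not db.has_table("PC_scores"):
        raise OrderingContractError(
            "PC_scores does not exist; run calculate_pca first"
        )
    rows = db.execute('SELECT * FROM "PC_scores" ORDER BY rowid').fetchall()
    return [r[0] for r in rows], np.asarray([r[1:] for r in rows], dtype=np.float64)


def run_embedding(
    db: DatabaseHandle, delegate: Callable[[np.ndarray], np.ndarray] | None = None
) -> np.ndarray:
    """Feed the PC-score matrix to an external embedding routine (e.g. a
    fitted UMAP's transform) and persist its cells x 2 output to the
    ``umap_embeddings`` table, row-aligned to cell_id.

    No algorithm is implemented here; without a delegate this raises rather
    than silently falling back.
    """
    if delegate is None:
        raise NotConfiguredError(
            "no embedding delegate configured; pass a callable mapping the "
            "PC-score matrix (cells x k) to a cells x 2 embedding"
        )
    cell_ids, matrix = _pc_matrix(db)
    embedding = np.asarray(delegate(matrix), dtype=np.float64)
    if embedding.shape != (len(cell_ids), 2):
        raise ScsqlError(
            f"embedding delegate returned shape {embedding.shape}; expected "
            f"({len(cell_ids)}, 2)"
        )
    db.execute('DROP TABLE IF EXISTS "umap_embeddings"')
    db.execute('CREATE TABLE "umap_embeddings" ("cell_id" TEXT, "umap1" DOUBLE, "umap2" DOUBLE)')
    db.executemany(
        'INSERT INTO "umap_embeddings" VALUES (?, ?, ?)',
        ((cell_ids[i], *embedding[i].tolist()) for i in range(len(cell_ids))),
    )
    db.commit()
    return embedding


def run_clustering(
    db: DatabaseHandle, delegate: Callable[[np.ndarray], Sequence[int]] | None = None
) -> pd.Series:
    """Feed the PC-score matrix to an external clustering routine (e.g. a
    Leiden implementation) and persist per-cell integer labels as the
    ``obs.leiden_clusters`` column."""
    if delegate is None:
        raise NotConfiguredError(
            "no clustering delegate configured; pass a callable mapping the "
            "PC-score matrix (cells x k) to per-cell integer labels"
        )
    _require_table(db, "obs")
    cell_ids, matrix = _pc_matrix(db)
    labels = np.asarray(delegate(matrix))
    if labels.shape != (len(cell_ids),):
        raise ScsqlError(
            f"clustering delegate returned shape {labels.shape}; expected "
            f"({len(cell_ids)},)"
        )
    _ensure_column(db, "obs", "leiden_clusters", "BIGINT")
    db.executemany(
        'UPDATE "obs" SET "leiden_clusters" = ? WHERE "cell_id" = ?',
        ((int(labels[i]), cell_ids[i]) for i in range(len(cell_ids))),
    )
    db.commit()
    _refresh_view(db)
    return pd.Series(labels, index=cell_ids, name="leiden_clusters")
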