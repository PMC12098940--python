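"""User-facing query surface: SELECTs with multiple return contracts,
verbatim raw execution, and guarded update/delete helpers.

Three return contracts for ``query``:

* ``frame`` (default) — a pandas DataFrame;
* ``annotated_matrix`` — an AnnData whose X holds the numeric result columns
  (original gene names restored) and whose obs carries ``cell_id`` plus the
  non-numeric columns;
* ``parquet`` — the result written to a Parquet file, returning its path.

Queries may reference genes by their *original* names; identifiers are
rewritten through the persisted name map before execution, so ``"HLA-A"``
and ``HLA_A`` address the same column.
"""
from __future__ import annotations

import re
import sqlite3
import tempfile
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .database_io import DatabaseHandle
from .errors import (
    MissingColumnError,
    NotSelectError,
    QueryExecutionError,
    ScsqlError,
)
from .schema_builder import quote_identifier

RETURN_MODES = ("frame", "annotated_matrix", "parquet")

_COMMENT_RE = re.compile(r"(--[^\n]*\n)|(/\*.*?\*/)", re.S)


def _first_keyword(sql: str) -> str:
    stripped = _COMMENT_RE.sub(" ", sql + "\n").strip()
    match = re.match(r"[A-Za-z]+", stripped)
    return match.group(0).upper() if match else ""


def is_select_statement(sql: str) -> bool:
    return _first_keyword(sql) in ("SELECT", "WITH", "VALUES")


def rewrite_identifiers(db: DatabaseHandle, sql: str) -> str:
    """Replace original column names with their sanitized counterparts.

    Word-boundary textual substitution over the statement; both bare and
    double-quoted occurrences are rewritten. Only names whose sanitized form
    differs are touched, so already-safe SQL passes through unchanged. All
    names are rewritten in one pass, so a sanitized name that happens to
    equal some other gene's original name cannot be rewritten twice.
    """
    id_map = db.identifier_map
    replacements: dict[str, str] = {}
    for table in id_map.tables():
        for original, sanitized, _ in id_map.entries(table):
            if original != sanitized:
                replacements.setdefault(original, sanitized)
    if not replacements:
        return sql
    # longest first so a name that is a prefix of another cannot shadow it
    alternation = "|".join(
        re.escape(name) for name in sorted(replacements, key=len, reverse=True)
    )
    pattern = re.compile(
        rf'"(?:{alternation})"|(?<![A-Za-z0-9_\"])(?:{alternation})(?![A-Za-z0-9_\"])'
    )

    def _substitute(match: re.Match) -> str:
        name = match.group(0)
        if name.startswith('"') and name.endswith('"'):
            name = name[1:-1]
        return quote_identifier(replacements[name])

    return pattern.sub(_substitute, sql)


def _augment_column_error(db: DatabaseHandle, exc: sqlite3.OperationalError) -> ScsqlError:
    message = str(exc)
    match = re.search(r"no such column:?\s*(\S+)", message)
    if match:
        missing = match.group(1).strip('"')
        id_map = db.identifier_map
        for table in id_map.tables():
            for original, sanitized, _ in id_map.entries(table):
                if missing in (original, sanitized):
                    return MissingColumnError(
                        f"no such column: {sanitized!r} (original name {original!r}, "
                        f"table {table!r})"
                    )
        return MissingColumnError(f"no such column: {missing!r}")
    return QueryExecutionError(message, "")


def _fetch_frame(db: DatabaseHandle, sql: str) -> pd.DataFrame:
    cursor = db.execute(sql)
    columns = [d[0] for d in cursor.description] if cursor.description else []
    return pd.DataFrame(cursor.fetchall(), columns=columns)


def query(
    db: DatabaseHandle,
    sql: str,
    return_mode: str = "frame",
    parquet_path: str | Path | None = None,
):
    """Execute a read-only SELECT and return it under the chosen contract.

    Non-SELECT statements are rejected; route mutations through
    :func:`update_query` / :func:`delete_query` or :func:`query_raw`.
    Row order is unspecified unless the statement carries an ORDER BY.
    """
    if return_mode not in RETURN_MODES:
        raise ValueError(f"return_mode must be one of {RETURN_MODES}, got {return_mode!r}")
    if not is_select_statement(sql):
        raise NotSelectError(
            "query() only accepts SELECT statements; use update_query/delete_query "
            "for mutations or query_raw for arbitrary SQL"
        )
    rewritten = rewrite_identifiers(db, sql)
    try:
        frame = _fetch_frame(db, rewritten)
    except sqlite3.OperationalError as exc:
        raise _augment_column_error(db, exc) from exc
    if return_mode == "frame":
        return frame
    if return_mode == "annotated_matrix":
        return to_annotated_matrix(frame, db)
    return _write_parquet(frame, parquet_path)


def query_raw(db: DatabaseHandle, sql: str, params: tuple = ()) -> list[tuple]:
    """Execute any statement verbatim (DDL and DML included) and return the
    fetched rows; the caller owns interpretation. Engine errors propagate with
    the offending statement attached."""
    try:
        cursor = db.execute(sql, params)
    except ScsqlError:
        raise
    except sqlite3.Error as exc:
        raise QueryExecutionError(str(exc), sql) from exc
    rows = cursor.fetchall() if cursor.description else []
    if _mutates_x(sql):
        db.bump_x_version()
    db.commit()
    return rows


_X_MUTATION_RE = re.compile(r"^\s*(UPDATE|DELETE\s+FROM|INSERT\s+INTO)\s+\"?X\"?\b", re.I)


def _mutates_x(sql: str) -> bool:
    return bool(_X_MUTATION_RE.match(_COMMENT_RE.sub(" ", sql + "\n").strip()))


def update_query(
    db: DatabaseHandle, table: str, assignments: str | dict[str, Any], where: str | None = None
) -> int:
    """UPDATE ``table`` and return the affected row count.

    ``assignments`` is either a raw ``SET`` fragment or a mapping of column ->
    SQL expression. A predicate matching zero rows returns 0; a read-only
    handle raises. The ``adata`` view reflects the change with no rebuild.
    """
    if isinstance(assignments, dict):
        set_clause = ", ".join(
            f"{quote_identifier(col)} = {expr}" for col, expr in assignments.items()
        )
    else:
        set_clause = assignments
    sql = f"UPDATE {quote_identifier(table)} SET {set_clause}"
    if where:
        sql += f" WHERE {where}"
    sql = rewrite_identifiers(db, sql)
    try:
        cursor = db.execute(sql)
    except sqlite3.OperationalError as exc:
        raise _augment_column_error(db, exc) from exc
    db.commit()
    if table == "X":
        db.bump_x_version()
    return cursor.rowcount


def delete_query(db: DatabaseHandle, table: str, where: str | None = None) -> int:
    """DELETE from ``table`` and return the affected row count."""
    sql = f"DELETE FROM {quote_identifier(table)}"
    if where:
        sql += f" WHERE {where}"
    sql = rewrite_identifiers(db, sql)
    try:
        cursor = db.execute(sql)
    except sqlite3.OperationalError as exc:
        raise _augment_column_error(db, exc) from exc
    db.commit()
    if table == "X":
        db.bump_x_version()
    return cursor.rowcount


def to_annotated_matrix(frame: pd.DataFrame, db: DatabaseHandle | None = None):
    """Convert a query result into an annotated matrix (AnnData).

    Numeric columns become X (in result order, with original gene names
    restored through the identifier map when available); ``cell_id`` and the
    non-numeric columns land in obs. Requires a ``cell_id`` column.
    """
    import anndata

    if "cell_id" not in frame.columns:
        raise ScsqlError(
            "annotated_matrix return mode requires a cell_id column in the result"
        )
    numeric = [
        c
        for c in frame.columns
        if c != "cell_id" and pd.api.types.is_numeric_dtype(frame[c])
    ]
    other = [c for c in frame.columns if c != "cell_id" and c not in numeric]
    obs = frame[["cell_id"] + other].copy()
    obs.index = obs["cell_id"].astype(str)
    obs.index.name = None
    X = frame[numeric].to_numpy(dtype=np.float32) if numeric else np.empty(
        (len(frame), 0), dtype=np.float32
    )
    var_names = list(numeric)
    if db is not None:
        originals = {s: o for o, s, _ in db.identifier_map.entries("X")}
        var_names = [originals.get(c, c) for c in numeric]
    bundle = anndata.AnnData(X=X, obs=obs)
    bundle.var_names = var_names
    return bundle


def _write_parquet(frame: pd.DataFrame, path: str | Path | None) -> Path:
    import pyarrow as pa
    import pyarrow.parquet as pq

    if path is None:
        path = Path(tempfile.mkdtemp(prefix="scsql_")) / "query_result.parquet"
    path = Path(path)
    pq.write_table(pa.Table.from_pandas(frame, preserve_index=False), path)
    return path


def show_settings(db: DatabaseHandle) -> dict[str, Any]:
    """Key/value listing of engine configuration for this handle.

    Stable keys; values reflect live PRAGMA state, so configuration changes
    made through ``query_raw`` show up here.
    """
    def pragma(name: str):
        row = db.execute(f"PRAGMA {name}").fetchone()
        return row[0] if row is not None else 0

    cache_pages = pragma("cache_size")
    page_size = pragma("page_size")
    # negative cache_size is -KiB; positive is pages
    memory_limit = -cache_pages * 1024 if cache_pages < 0 else cache_pages * page_size
    return {
        "engine": f"sqlite {sqlite3.sqlite_version}",
        "location": db.location,
        "mode": db.mode,
        "memory_limit_bytes": int(memory_limit),
        "threads": int(pragma("threads")),
        "page_size_bytes": int(page_size),
        "journal_mode": pragma("journal_mode"),
        "mmap_size_bytes": int(pragma("mmap_size")),
    }


def show_tables(db: DatabaseHandle) -> list[str]:
    """Convenience alias mirroring the handle's table listing."""
    from .database_io import list_tables

    return list_tables(db)
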