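"""Build, persist and reopen single-file relational databases.

Databases live either in memory or in a single on-disk file with the
``.asql`` extension, powered by the in-process SQLite engine (no server, no
configuration). Building from an H5AD source works in two modes: fully
in-memory, or *backed* — the expression matrix is streamed from disk in
cell chunks so peak ingestion memory is bounded by
``O(chunk_size x n_genes)`` regardless of dataset size.

Engine limit: a table holds at most 2000 columns, so wide cell-by-gene
tables support up to :data:`MAX_GENE_COLUMNS` genes. The cap is checked
up front with a clear error.
"""
from __future__ import annotations

import json
import math
import os
import sqlite3
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import schema_builder as sb
from .errors import (
    MissingTableError,
    OverwriteError,
    ReadOnlyError,
    ScsqlError,
    StaleHandleError,
)
from .schema_builder import (
    IdentifierMap,
    LayerSpec,
    create_convenience_view,
    normalize_layer_selection,
    plan_schema,
    quote_identifier,
)

DB_EXTENSION = ".asql"
DEFAULT_CHUNK_SIZE = 5_000
#: SQLite caps tables at 2000 columns; one is reserved for cell_id.
MAX_GENE_COLUMNS = 1_999

_META_TABLE = "_scsql_meta"
_IDMAP_TABLE = "_scsql_identifier_map"
_INTERNAL_TABLES = (_META_TABLE, _IDMAP_TABLE)


@dataclass(frozen=True)
class ChunkPlan:
    """Block iteration plan along one axis ('cells' or 'genes').

    Blocks cover the axis exactly once, in order, without overlap; the last
    block may be short.
    """

    axis: str
    block_size: int
    n_total: int

    def __post_init__(self) -> None:
        if self.axis not in ("cells", "genes"):
            raise ValueError(f"axis must be 'cells' or 'genes', got {self.axis!r}")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")

    @property
    def n_blocks(self) -> int:
        return math.ceil(self.n_total / self.block_size) if self.n_total else 0

    def blocks(self) -> Iterator[tuple[int, int]]:
        """Yield half-open ``(start, stop)`` index ranges."""
        for start in range(0, self.n_total, self.block_size):
            yield start, min(start + self.block_size, self.n_total)


class DatabaseHandle:
    """Connection to an in-memory or on-disk database with a known schema.

    Single-writer: read-write handles assume exclusive write access; open
    additional handles read-only. On-disk handles persist across process
    restarts with identical contents.
    """

    def __init__(self, connection: sqlite3.Connection, location: str, mode: str):
        self._con = connection
        self.location = location
        self.mode = mode
        self._closed = False
        self._id_map_cache: IdentifierMap | None = None

    # -- low-level ---------------------------------------------------------

    @property
    def connection(self) -> sqlite3.Connection:
        self._check_open()
        return self._con

    def _check_open(self) -> None:
        if self._closed:
            raise StaleHandleError(f"database handle for {self.location!r} is closed")

    def execute(self, sql: str, params: Sequence = ()) -> sqlite3.Cursor:
        self._check_open()
        try:
            return self._con.execute(sql, params)
        except sqlite3.OperationalError as exc:
            if "readonly" in str(exc):
                raise ReadOnlyError(
                    f"database {self.location!r} was opened read-only"
                ) from exc
            raise

    def executemany(self, sql: str, rows) -> sqlite3.Cursor:
        self._check_open()
        try:
            return self._con.executemany(sql, rows)
        except sqlite3.OperationalError as exc:
            if "readonly" in str(exc):
                raise ReadOnlyError(
                    f"database {self.location!r} was opened read-only"
                ) from exc
            raise

    def commit(self) -> None:
        self._check_open()
        self._con.commit()

    def close(self) -> None:
        if not self._closed:
            self._con.close()
            self._closed = True

    def __enter__(self) -> "DatabaseHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- schema introspection ---------------------------------------------

    def tables_with_types(self) -> list[tuple[str, str]]:
        """``(name, 'table'|'view')`` pairs in creation order, internal
        bookkeeping tables excluded."""
        rows = self.execute(
            "SELECT name, type FROM sqlite_master WHERE type IN ('table','view') "
            "ORDER BY rowid"
        ).fetchall()
        return [
            (name, kind)
            for name, kind in rows
            if name not in _INTERNAL_TABLES and not name.startswith("sqlite_")
        ]

    def table_columns(self, table: str) -> list[str]:
        rows = self.execute(f"PRAGMA table_info({quote_identifier(table)})").fetchall()
        if not rows:
            raise MissingTableError(f"table {table!r} does not exist")
        return [r[1] for r in rows]

    def has_table(self, table: str) -> bool:
        return any(name == table for name, _ in self.tables_with_types())

    # -- persistent bookkeeping -------------------------------------------

    def _ensure_internal_tables(self) -> None:
        self.execute(
            f"CREATE TABLE IF NOT EXISTS {_META_TABLE} (key TEXT PRIMARY KEY, value TEXT)"
        )
        self.execute(
            f"CREATE TABLE IF NOT EXISTS {_IDMAP_TABLE} "
            "(table_name TEXT, original TEXT, sanitized TEXT, ordinal BIGINT)"
        )

    def set_meta(self, key: str, value) -> None:
        self._ensure_internal_tables()
        self.execute(
            f"INSERT INTO {_META_TABLE}(key, value) VALUES (?, ?) "
            "ON CONFLICT(key) DO UPDATE SET value = excluded.value",
            (key, json.dumps(value)),
        )
        self.commit()

    def get_meta(self, key: str, default=None):
        try:
            row = self.execute(
                f"SELECT value FROM {_META_TABLE} WHERE key = ?", (key,)
            ).fetchone()
        except sqlite3.OperationalError:
            return default
        return default if row is None else json.loads(row[0])

    def bump_x_version(self) -> int:
        version = int(self.get_meta("x_version", 0)) + 1
        self.set_meta("x_version", version)
        return version

    @property
    def identifier_map(self) -> IdentifierMap:
        if self._id_map_cache is None:
            try:
                rows = self.execute(
                    f"SELECT table_name, original, sanitized, ordinal FROM {_IDMAP_TABLE}"
                ).fetchall()
            except sqlite3.OperationalError:
                rows = []
            self._id_map_cache = IdentifierMap.from_rows(rows)
        return self._id_map_cache

    def store_identifier_map(self, id_map: IdentifierMap) -> None:
        self._ensure_internal_tables()
        self.execute(f"DELETE FROM {_IDMAP_TABLE}")
        self.executemany(
            f"INSERT INTO {_IDMAP_TABLE} VALUES (?, ?, ?, ?)", id_map.iter_rows()
        )
        self.commit()
        self._id_map_cache = None

    def gene_columns(self) -> list[str]:
        """Sanitized X gene columns in gene-ordinal order."""
        return [s for _, s, _ in self.identifier_map.entries("X")]


def _connect(location: str, mode: str) -> sqlite3.Connection:
    if mode == "read-only":
        con = sqlite3.connect(f"file:{location}?mode=ro", uri=True)
    else:
        con = sqlite3.connect(location)
        # analytics workload: trade durability for ingestion speed
        con.execute("PRAGMA journal_mode=MEMORY")
        con.execute("PRAGMA synchronous=OFF")
    return con


def open_database(path: str | os.PathLike, mode: str = "read-write") -> DatabaseHandle:
    """Reopen a previously built database file.

    A missing file raises ``FileNotFoundError``; an unexpected extension only
    warns. Read-only handles reject every mutation at the engine level.
    """
    if mode not in ("read-write", "read-only"):
        raise ValueError(f"mode must be 'read-write' or 'read-only', got {mode!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"database file not found: {path}")
    if path.suffix != DB_EXTENSION:
        warnings.warn(
            f"expected a {DB_EXTENSION!r} file, got {path.suffix!r}; opening anyway",
            stacklevel=2,
        )
    return DatabaseHandle(_connect(str(path), mode), str(path), mode)


def list_tables(db: DatabaseHandle) -> list[str]:
    """Layer tables and views (including ``adata`` when present), in creation
    order; internal bookkeeping tables are hidden."""
    return [name for name, _ in db.tables_with_types()]


def _as_dense_chunk(block) -> np.ndarray:
    """Densify one chunk of an X accessor (ndarray / sparse / h5py slice)."""
    if hasattr(block, "toarray"):
        block = block.toarray()
    return np.asarray(block, dtype=np.float32)


def insert_x_chunked(
    db: DatabaseHandle,
    source,
    plan: ChunkPlan,
    cell_ids: Sequence[str],
    gene_columns: Sequence[str] | None = None,
) -> int:
    """Stream ``source`` (any object sliceable as ``source[start:stop]``) into
    the already-created X table, one cell block at a time.

    Values are cast to FLOAT (single precision) and cell order is preserved.
    Only one block is materialized at a time, which is what bounds ingestion
    memory for backed sources. A mid-ingestion failure reports the failed
    block and leaves the database detectably incomplete (short row count).
    """
    if gene_columns is None:
        gene_columns = db.gene_columns()
    placeholders = ", ".join(["?"] * (len(gene_columns) + 1))
    insert_sql = f'INSERT INTO "X" VALUES ({placeholders})'
    inserted = 0
    for block_index, (start, stop) in enumerate(plan.blocks()):
        try:
            chunk = _as_dense_chunk(source[start:stop])
            rows = chunk.tolist()
            db.executemany(
                insert_sql,
                ((cell_ids[start + i], *rows[i]) for i in range(stop - start)),
            )
            db.commit()
        except ScsqlError:
            raise
        except Exception as exc:
            raise ScsqlError(
                f"X ingestion failed at block {block_index} "
                f"(cells {start}:{stop}): {exc}"
            ) from exc
        inserted += stop - start
    return inserted


def _column_values(series: pd.Series) -> list:
    """Engine-friendly python scalars for one annotation column."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [None if pd.isna(v) else str(v) for v in series]
    if pd.api.types.is_bool_dtype(series.dtype):
        return [None if pd.isna(v) else int(v) for v in series]
    values = series.tolist()
    return [None if (isinstance(v, float) and math.isnan(v)) else v for v in values]


def _frame_rows(df: pd.DataFrame) -> list[tuple]:
    return list(zip(*[_column_values(df[c]) for c in df.columns])) if len(df.columns) else []


def _dtype_record(df: pd.DataFrame) -> dict[str, str]:
    return {
        str(col): ("category" if isinstance(df[col].dtype, pd.CategoricalDtype) else str(df[col].dtype))
        for col in df.columns
    }


def make_db(
    source,
    db_name: str | None = None,
    db_path: str | os.PathLike | None = None,
    layers: Sequence[LayerSpec | str] | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    convenience_view: bool = True,
    overwrite: bool = False,
) -> DatabaseHandle:
    """Build a database from an H5AD file path or an in-memory AnnData-like
    bundle.

    With ``db_path=None`` the database is built in memory; otherwise the file
    ``<db_path>/<db_name>.asql`` is created (refusing to clobber an existing
    file unless ``overwrite=True``). String sources are opened in backed mode
    so X is streamed chunk by chunk and never fully materialized.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")

    opened_here = None
    if isinstance(source, (str, os.PathLike)):
        import anndata

        src_path = Path(source)
        if not src_path.exists():
            raise FileNotFoundError(f"H5AD source not found: {src_path}")
        bundle = anndata.read_h5ad(src_path, backed="r")
        opened_here = bundle
    else:
        bundle = source

    try:
        if db_path is None:
            location = ":memory:"
        else:
            if not db_name:
                raise ValueError("db_name must be non-empty for on-disk databases")
            db_dir = Path(db_path)
            db_dir.mkdir(parents=True, exist_ok=True)
            location = str(db_dir / f"{db_name}{DB_EXTENSION}")
            if os.path.exists(location):
                if not overwrite:
                    raise OverwriteError(
                        f"{location} exists; pass overwrite=True to replace it"
                    )
                os.remove(location)

        n_cells, n_genes = bundle.shape
        if n_genes > MAX_GENE_COLUMNS:
            raise ScsqlError(
                f"{n_genes} genes exceed the {MAX_GENE_COLUMNS}-column limit of a "
                "wide X table; subset the genes before building"
            )

        schemas, id_map = plan_schema(bundle, layers)
        selected = normalize_layer_selection(layers)

        db = DatabaseHandle(_connect(location, "read-write"), location, "read-write")
        db._ensure_internal_tables()
        for schema in schemas:
            db.execute(schema.create_sql())
        db.store_identifier_map(id_map)

        cell_ids = [str(c) for c in bundle.obs_names]
        if len(set(cell_ids)) != len(cell_ids) or not cell_ids and n_cells:
            cell_ids = [f"cell_{i}" for i in range(n_cells)]

        plan = ChunkPlan("cells", chunk_size, n_cells)
        insert_x_chunked(db, bundle.X, plan, cell_ids)
        db.execute('CREATE UNIQUE INDEX "idx_X_cell_id" ON "X"("cell_id")')

        if "obs" in selected:
            obs = bundle.obs
            cols = ", ".join(["?"] * (1 + len(obs.columns)))
            db.executemany(
                f'INSERT INTO "obs" VALUES ({cols})',
                (
                    (cell_ids[i], *rest)
                    for i, rest in enumerate(
                        _frame_rows(obs) if len(obs.columns) else [()] * n_cells
                    )
                ),
            )
            db.execute('CREATE UNIQUE INDEX "idx_obs_cell_id" ON "obs"("cell_id")')
            db.set_meta("obs_dtypes", _dtype_record(obs))

        if "var" in selected or "var_names" in selected:
            var = bundle.var if "var" in selected else bundle.var[[]]
            gene_names = [str(g) for g in bundle.var_names]
            cols = ", ".join(["?"] * (2 + len(var.columns)))
            db.executemany(
                f'INSERT INTO "var" VALUES ({cols})',
                (
                    (i, gene_names[i], *rest)
                    for i, rest in enumerate(
                        _frame_rows(var) if len(var.columns) else [()] * n_genes
                    )
                ),
            )
            db.set_meta("var_dtypes", _dtype_record(var))

        if "obsm" in selected:
            for prop in sorted(bundle.obsm.keys()):
                mat = np.asarray(bundle.obsm[prop], dtype=float)
                table = f"obsm_{sb.sanitize_identifier(prop)}"
                cols = ", ".join(["?"] * (1 + mat.shape[1]))
                db.executemany(
                    f"INSERT INTO {quote_identifier(table)} VALUES ({cols})",
                    ((cell_ids[i], *mat[i].tolist()) for i in range(n_cells)),
                )
        if "varm" in selected:
            for prop in sorted(bundle.varm.keys()):
                mat = np.asarray(bundle.varm[prop], dtype=float)
                table = f"varm_{sb.sanitize_identifier(prop)}"
                cols = ", ".join(["?"] * (1 + mat.shape[1]))
                db.executemany(
                    f"INSERT INTO {quote_identifier(table)} VALUES ({cols})",
                    ((i, *mat[i].tolist()) for i in range(n_genes)),
                )
        if "obsp" in selected:
            from scipy import sparse

            for prop in sorted(bundle.obsp.keys()):
                mat = sparse.coo_matrix(bundle.obsp[prop])
                table = f"obsp_{sb.sanitize_identifier(prop)}"
                db.executemany(
                    f"INSERT INTO {quote_identifier(table)} VALUES (?, ?, ?)",
                    zip(
                        (int(r) for r in mat.row),
                        (int(c) for c in mat.col),
                        (float(v) for v in mat.data),
                    ),
                )
        if "uns" in selected:
            rows = sb.build_uns_payload(dict(bundle.uns))
            db.executemany('INSERT INTO "uns_raw" VALUES (?, ?, ?)', rows)

        if convenience_view and "obs" in selected:
            create_convenience_view(db)

        db.set_meta("x_version", 0)
        db.set_meta("convenience_view", bool(convenience_view and "obs" in selected))
        db.commit()
        return db
    finally:
        if opened_here is not None:
            opened_here.file.close()


def reconstruct_bundle(db: DatabaseHandle):
    """Rebuild an AnnData object from a database: X (FLOAT precision), obs/var
    with original column names and dtypes, obsm/varm/obsp matrices and the
    deserialized uns mapping."""
    import anndata
    from scipy import sparse

    id_map = db.identifier_map
    gene_entries = id_map.entries("X")
    gene_cols = ", ".join(quote_identifier(s) for _, s, _ in gene_entries)
    rows = db.execute(f'SELECT "cell_id", {gene_cols} FROM "X" ORDER BY rowid').fetchall()
    cell_ids = [r[0] for r in rows]
    X = np.asarray([r[1:] for r in rows], dtype=np.float32).reshape(
        len(rows), len(gene_entries)
    )

    table_names = dict(db.tables_with_types())

    def restore_frame(table: str, key_col: str, entries, dtype_meta_key: str) -> pd.DataFrame:
        cols = [key_col] + [s for _, s, _ in entries]
        sql_cols = ", ".join(quote_identifier(c) for c in cols)
        data = db.execute(
            f"SELECT {sql_cols} FROM {quote_identifier(table)} ORDER BY rowid"
        ).fetchall()
        df = pd.DataFrame(data, columns=cols).set_index(key_col)
        df.columns = [o for o, _, _ in entries]
        dtypes = db.get_meta(dtype_meta_key, {})
        for col, dtype in dtypes.items():
            if col in df.columns:
                df[col] = df[col].astype(dtype)
        return df

    obs = None
    if "obs" in table_names:
        obs = restore_frame("obs", "cell_id", id_map.entries("obs"), "obs_dtypes")
        obs.index.name = None
    var = None
    if "var" in table_names:
        var = restore_frame("var", "var_names", id_map.entries("var"), "var_dtypes")
        var.index.name = None

    bundle = anndata.AnnData(
        X=X,
        obs=obs if obs is not None else pd.DataFrame(index=cell_ids),
        var=var,
    )
    if obs is None:
        bundle.obs_names = cell_ids

    for name in table_names:
        if name.startswith("obsm_"):
            data = db.execute(
                f"SELECT * FROM {quote_identifier(name)} ORDER BY rowid"
            ).fetchall()
            bundle.obsm[name[len("obsm_"):]] = np.asarray(
                [r[1:] for r in data], dtype=float
            )
        elif name.startswith("varm_"):
            data = db.execute(
                f"SELECT * FROM {quote_identifier(name)} ORDER BY rowid"
            ).fetchall()
            bundle.varm[name[len("varm_"):]] = np.asarray(
                [r[1:] for r in data], dtype=float
            )
        elif name.startswith("obsp_"):
            data = db.execute(f"SELECT * FROM {quote_identifier(name)}").fetchall()
            n = bundle.n_obs
            if data:
                r, c, v = zip(*data)
                bundle.obsp[name[len("obsp_"):]] = sparse.coo_matrix(
                    (v, (r, c)), shape=(n, n)
                ).tocsr()
            else:
                bundle.obsp[name[len("obsp_"):]] = sparse.csr_matrix((n, n))
    if "uns_raw" in table_names:
        rows = db.execute('SELECT "key", "value", "data_type" FROM "uns_raw"').fetchall()
        for key, value in sb.reconstruct_uns(rows).items():
            bundle.uns[key] = value
    return bundle
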