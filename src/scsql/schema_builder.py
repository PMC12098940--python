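"""Plan and create the relational schema mirroring a layered single-cell object.

A layered object (an :class:`anndata.AnnData`, or anything structurally
equivalent) is mapped to one table per layer property:

* ``X``       — one row per cell: a ``cell_id`` column plus one FLOAT column
  per gene.
* ``obs``     — ``cell_id`` plus one column per per-cell annotation.
* ``var``     — an auto-incremented ``gene_id`` (0-based, equal to the gene's
  ordinal position) plus one column per per-gene annotation; the gene names
  themselves are stored in a ``var_names`` column.
* ``obsm_<p>`` / ``varm_<p>`` — one table per multi-dimensional annotation,
  e.g. ``obsm_X_pca`` holding the cell-by-component matrix.
* ``obsp_<p>`` — pairwise (cell x cell) layers as edge lists
  ``(row_id, col_id, value)``; a wide n_cells-column table is infeasible.
* ``uns_raw`` — unstructured metadata serialized as ``(key, value, data_type)``
  rows from which the original values can be reconstructed exactly.

Raw column/gene names are sanitized into SQL-safe identifiers; the
original -> sanitized mapping is retained (and persisted by
:mod:`scsql.database_io`) so original names are always recoverable.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InconsistentBundleError,
    InvalidIdentifierError,
    MissingTableError,
    SerializationError,
)

LAYER_NAMES = ("X", "obs", "var", "var_names", "obsm", "varm", "obsp", "uns")

_SAFE_PATTERN = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_UNSAFE_CHARS = re.compile(r"[^A-Za-z0-9_]")


@dataclass(frozen=True)
class LayerSpec:
    """Selection flag for one layer of the source object.

    ``X`` is always included; the other layers are user-selectable.
    """

    layer_name: str
    include: bool = True

    def __post_init__(self) -> None:
        if self.layer_name not in LAYER_NAMES:
            raise ValueError(
                f"unknown layer {self.layer_name!r}; expected one of {LAYER_NAMES}"
            )


def normalize_layer_selection(layers: Sequence[LayerSpec | str] | None) -> set[str]:
    """Resolve a layer selection to the set of included layer names.

    ``None`` selects every layer. ``X`` is always included regardless of the
    selection.
    """
    if layers is None:
        selected = set(LAYER_NAMES)
    else:
        selected = set()
        for spec in layers:
            if isinstance(spec, str):
                spec = LayerSpec(spec)
            if spec.include:
                selected.add(spec.layer_name)
    selected.add("X")
    return selected


def sanitize_identifier(name: str, taken: Iterable[str] = ()) -> str:
    """Return a unique SQL-safe identifier for ``name``.

    Every character outside ``[A-Za-z0-9_]`` is replaced with ``_``; a leading
    digit is prefixed with ``_``. Collisions with ``taken`` are resolved by
    appending the smallest integer suffix ``_1``, ``_2``, ... not yet taken.
    Deterministic given ``(name, taken)`` and idempotent on names that are
    already safe and unique.
    """
    if not isinstance(name, str) or name == "":
        raise InvalidIdentifierError("identifier name must be a non-empty string")
    taken = set(taken)
    candidate = _UNSAFE_CHARS.sub("_", name)
    if candidate[0].isdigit():
        candidate = "_" + candidate
    if candidate not in taken:
        return candidate
    suffix = 1
    while f"{candidate}_{suffix}" in taken:
        suffix += 1
    return f"{candidate}_{suffix}"


def quote_identifier(name: str) -> str:
    """Double-quote an identifier for use in generated SQL.

    Always quoting means gene names that collide with SQL keywords (a gene
    literally named ``SELECT``) need no keyword list.
    """
    return '"' + name.replace('"', '""') + '"'


@dataclass
class IdentifierMap:
    """Original -> sanitized column-name mapping, per table.

    Entries record ``(original, sanitized, ordinal)`` where ``ordinal`` is the
    0-based position of the column in its source layer. Sanitized names are
    unique within a table and the mapping is persisted alongside the database
    so original names are always recoverable.
    """

    _entries: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)

    def assign(self, table: str, original: str) -> str:
        per_table = self._entries.setdefault(table, [])
        taken = {s for _, s, _ in per_table}
        sanitized = sanitize_identifier(original, taken)
        per_table.append((original, sanitized, len(per_table)))
        return sanitized

    def tables(self) -> list[str]:
        return list(self._entries)

    def entries(self, table: str) -> list[tuple[str, str, int]]:
        """``(original, sanitized, ordinal)`` triples in source order."""
        return list(self._entries.get(table, ()))

    def sanitized(self, table: str, original: str) -> str:
        for o, s, _ in self._entries.get(table, ()):
            if o == original:
                return s
        raise KeyError(f"no column {original!r} recorded for table {table!r}")

    def original(self, table: str, sanitized: str) -> str:
        for o, s, _ in self._entries.get(table, ()):
            if s == sanitized:
                return o
        raise KeyError(f"no sanitized column {sanitized!r} in table {table!r}")

    def iter_rows(self) -> Iterator[tuple[str, str, str, int]]:
        for table, entries in self._entries.items():
            for original, sanitized, ordinal in entries:
                yield table, original, sanitized, ordinal

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, int]]) -> "IdentifierMap":
        m = cls()
        staged: dict[str, list[tuple[int, str, str]]] = {}
        for table, original, sanitized, ordinal in rows:
            staged.setdefault(table, []).append((ordinal, original, sanitized))
        for table, entries in staged.items():
            entries.sort()
            m._entries[table] = [(o, s, i) for i, o, s in entries]
        return m


@dataclass
class TableSchema:
    """Planned layout of one table: name, ordered (column, storage type) pairs,
    and the source layer/property it encodes."""

    table_name: str
    columns: list[tuple[str, str]]
    provenance: str

    def create_sql(self) -> str:
        cols = ", ".join(f"{quote_identifier(n)} {t}" for n, t in self.columns)
        return f"CREATE TABLE {quote_identifier(self.table_name)} ({cols})"


def _storage_type(dtype) -> str:
    if pd.api.types.is_bool_dtype(dtype):
        return "BIGINT"
    if pd.api.types.is_integer_dtype(dtype):
        return "BIGINT"
    if pd.api.types.is_float_dtype(dtype):
        return "DOUBLE"
    return "TEXT"


def plan_schema(
    bundle, layers: Sequence[LayerSpec | str] | None = None
) -> tuple[list[TableSchema], IdentifierMap]:
    """Plan the full table layout for ``bundle`` under a layer selection.

    ``bundle`` is an AnnData-like object (``X``, ``obs``, ``var``, ``obsm``,
    ``varm``, ``obsp``, ``uns`` attributes). Planning is deterministic:
    identical bundles and selections yield identical schemas.

    Raises :class:`InconsistentBundleError` when X's shape disagrees with the
    obs/var layers.
    """
    selected = normalize_layer_selection(layers)

    n_cells, n_genes = bundle.X.shape if bundle.X is not None else bundle.shape
    if len(bundle.obs) != n_cells:
        raise InconsistentBundleError(
            f"X has {n_cells} rows but obs has {len(bundle.obs)}"
        )
    if len(bundle.var) != n_genes:
        raise InconsistentBundleError(
            f"X has {n_genes} columns but var has {len(bundle.var)}"
        )

    schemas: list[TableSchema] = []
    id_map = IdentifierMap()

    x_cols: list[tuple[str, str]] = [("cell_id", "TEXT")]
    for gene in map(str, bundle.var_names):
        x_cols.append((id_map.assign("X", gene), "FLOAT"))
    schemas.append(TableSchema("X", x_cols, "X"))

    if "obs" in selected:
        obs_cols: list[tuple[str, str]] = [("cell_id", "TEXT")]
        for col in bundle.obs.columns:
            obs_cols.append(
                (id_map.assign("obs", str(col)), _storage_type(bundle.obs[col].dtype))
            )
        schemas.append(TableSchema("obs", obs_cols, "obs"))

    if "var" in selected or "var_names" in selected:
        var_cols: list[tuple[str, str]] = [("gene_id", "BIGINT"), ("var_names", "TEXT")]
        if "var" in selected:
            for col in bundle.var.columns:
                var_cols.append(
                    (
                        id_map.assign("var", str(col)),
                        _storage_type(bundle.var[col].dtype),
                    )
                )
        schemas.append(TableSchema("var", var_cols, "var"))

    if "obsm" in selected:
        for prop in sorted(bundle.obsm.keys()):
            width = np.asarray(bundle.obsm[prop]).shape[1]
            cols = [("cell_id", "TEXT")] + [(f"c{i}", "DOUBLE") for i in range(width)]
            schemas.append(
                TableSchema(f"obsm_{sanitize_identifier(prop)}", cols, f"obsm.{prop}")
            )
    if "varm" in selected:
        for prop in sorted(bundle.varm.keys()):
            width = np.asarray(bundle.varm[prop]).shape[1]
            cols = [("gene_id", "BIGINT")] + [(f"c{i}", "DOUBLE") for i in range(width)]
            schemas.append(
                TableSchema(f"varm_{sanitize_identifier(prop)}", cols, f"varm.{prop}")
            )
    if "obsp" in selected:
        for prop in sorted(bundle.obsp.keys()):
            cols = [("row_id", "BIGINT"), ("col_id", "BIGINT"), ("value", "DOUBLE")]
            schemas.append(
                TableSchema(f"obsp_{sanitize_identifier(prop)}", cols, f"obsp.{prop}")
            )
    if "uns" in selected:
        schemas.append(
            TableSchema(
                "uns_raw",
                [("key", "TEXT"), ("value", "TEXT"), ("data_type", "TEXT")],
                "uns",
            )
        )
    return schemas, id_map


# ---------------------------------------------------------------------------
# uns serialization
#
# Self-describing recursive encoding with a data_type tag from the fixed enum
# {string, int, float, bool, array, mapping, null}. Python lists/tuples and
# numpy arrays all fall under "array"; the payload records which, so the
# round trip reconstructs the exact original kind, dtype and shape.
# ---------------------------------------------------------------------------

UNS_DATA_TYPES = ("string", "int", "float", "bool", "array", "mapping", "null")


def _tag(value: Any, key: str) -> dict:
    if value is None:
        return {"t": "null", "v": None}
    if isinstance(value, (bool, np.bool_)):
        return {"t": "bool", "v": bool(value)}
    if isinstance(value, (int, np.integer)):
        return {"t": "int", "v": int(value)}
    if isinstance(value, (float, np.floating)):
        return {"t": "float", "v": float(value)}
    if isinstance(value, str):
        return {"t": "string", "v": value}
    if isinstance(value, np.ndarray):
        if value.dtype == object:
            raise SerializationError(
                f"uns key {key!r}: object-dtype arrays are not serializable"
            )
        return {
            "t": "array",
            "v": {
                "kind": "ndarray",
                "dtype": str(value.dtype),
                "shape": list(value.shape),
                "data": value.ravel().tolist(),
            },
        }
    if isinstance(value, (list, tuple)):
        return {
            "t": "array",
            "v": {
                "kind": "tuple" if isinstance(value, tuple) else "list",
                "items": [_tag(item, key) for item in value],
            },
        }
    if isinstance(value, Mapping):
        out = {}
        for k, v in value.items():
            if not isinstance(k, str):
                raise SerializationError(
                    f"uns key {key!r}: mapping keys must be strings, got {type(k).__name__}"
                )
            out[k] = _tag(v, key)
        return {"t": "mapping", "v": out}
    raise SerializationError(
        f"uns key {key!r}: cannot serialize value of type {type(value).__name__}"
    )


def _untag(node: dict) -> Any:
    t, v = node["t"], node["v"]
    if t == "null":
        return None
    if t in ("bool", "int", "float", "string"):
        return v
    if t == "array":
        if v["kind"] == "ndarray":
            return np.array(v["data"], dtype=np.dtype(v["dtype"])).reshape(v["shape"])
        items = [_untag(item) for item in v["items"]]
        return tuple(items) if v["kind"] == "tuple" else items
    if t == "mapping":
        return {k: _untag(item) for k, item in v.items()}
    raise SerializationError(f"unknown data_type tag {t!r}")


def build_uns_payload(uns: Mapping[str, Any]) -> list[tuple[str, str, str]]:
    """Serialize an unstructured-metadata mapping to ``(key, value, data_type)``
    rows; one row per top-level key.

    The rows are self-describing: :func:`reconstruct_uns` recovers the original
    values (including array dtype/shape and list-vs-tuple kind) exactly.
    Unserializable values raise :class:`SerializationError` naming the key.
    """
    rows = []
    for key, value in uns.items():
        tagged = _tag(value, key)
        rows.append((str(key), json.dumps(tagged), tagged["t"]))
    return rows


def reconstruct_uns(rows: Iterable[tuple[str, str, str]]) -> dict[str, Any]:
    """Inverse of :func:`build_uns_payload`."""
    return {key: _untag(json.loads(serialized)) for key, serialized, _ in rows}


def create_convenience_view(db, replace: bool = False) -> None:
    """Create the ``adata`` view joining ``obs`` and ``X`` on ``cell_id``.

    The view exposes every obs column followed by every X column whose name is
    not already taken by obs, so per-cell annotations and expression are
    queryable together. With ``replace=True`` an existing view is rebuilt,
    which is needed after preprocessing adds columns to the base tables.
    """
    existing = {name for name, _ in db.tables_with_types()}
    for required in ("X", "obs"):
        if required not in existing:
            raise MissingTableError(
                f"cannot create the 'adata' view: table {required!r} does not exist"
            )
    obs_cols = db.table_columns("obs")
    x_cols = db.table_columns("X")
    select_cols = [f"{quote_identifier('obs')}.{quote_identifier(c)}" for c in obs_cols]
    obs_set = set(obs_cols)
    select_cols += [
        f"{quote_identifier('X')}.{quote_identifier(c)}"
        for c in x_cols
        if c not in obs_set
    ]
    if replace:
        db.execute('DROP VIEW IF EXISTS "adata"')
    db.execute(
        'CREATE VIEW "adata" AS SELECT {cols} FROM "obs" JOIN "X" '
        'ON "obs"."cell_id" = "X"."cell_id"'.format(cols=", ".join(select_cols))
    )
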