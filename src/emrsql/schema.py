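"""Database schema model, SQLite fixtures, query execution, value lookup.

The schema is the action universe for the grammar-constrained decoder:
``SelectColumn`` actions index into :attr:`DatabaseSchema.columns` and
``SelectTable`` actions into :attr:`DatabaseSchema.tables`. A bundled
schema mirroring the shape of a five-table EMR database (demographics,
diagnoses, procedures, prescriptions, laboratory tests with 23/5/5/7/9
columns) ships with the package and is the default universe everywhere.

Fixture databases are single SQLite files. Text content is lower-cased at
load time and rendered condition values are lower-cased too, so string
conditions match case-insensitively; numeric columns get NUMERIC affinity
so quoted numeric literals in conditions compare numerically.
"""

from __future__ import annotations

import sqlite3
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ExecutionError, LoadError, SchemaError

__all__ = [
    "ColumnDef",
    "TableDef",
    "DatabaseSchema",
    "ResultTable",
    "Database",
    "load_schema",
    "bundled_schema",
    "build_fixture_db",
    "execute_query",
    "lookup_values",
]

VALUE_KINDS = ("text", "numeric")


@dataclass(frozen=True)
class ColumnDef:
    """One column: its name, owning table, and value kind (text/numeric)."""

    name: str
    table: str
    value_kind: str = "text"
    is_join_key: bool = False

    def __post_init__(self):
        if not self.name:
            raise SchemaError("column name must be nonempty")
        if self.value_kind not in VALUE_KINDS:
            raise SchemaError(
                f"column {self.table}.{self.name}: unknown value kind "
                f"{self.value_kind!r} (expected one of {VALUE_KINDS})"
            )

    @property
    def qualified(self) -> str:
        return f"{self.table}.{self.name}"

    @property
    def name_words(self) -> tuple[str, ...]:
        """Lower-cased words of the column name, split on underscores."""
        return tuple(w for w in self.name.lower().split("_") if w)


@dataclass(frozen=True)
class TableDef:
    name: str
    columns: tuple[ColumnDef, ...]

    def __post_init__(self):
        if not self.columns:
            raise SchemaError(f"table {self.name!r} has no columns")
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate column names in table {self.name!r}")
        for c in self.columns:
            if c.table != self.name:
                raise SchemaError(
                    f"column {c.qualified} declared inside table {self.name!r}"
                )

    @property
    def name_words(self) -> tuple[str, ...]:
        return tuple(w for w in self.name.lower().split("_") if w)

    def column(self, name: str) -> ColumnDef:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"no column {name!r} in table {self.name!r}")


@dataclass(frozen=True)
class DatabaseSchema:
    """Ordered tables plus the join-key graph connecting them."""

    tables: tuple[TableDef, ...]
    join_edges: tuple[tuple[str, str, str], ...] = ()

    def __post_init__(self):
        names = [t.name for t in self.tables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate table names in schema")
        by_name = {t.name: t for t in self.tables}
        for t1, t2, key in self.join_edges:
            for t in (t1, t2):
                if t not in by_name:
                    raise SchemaError(f"join edge references unknown table {t!r}")
            for t in (t1, t2):
                if key not in {c.name for c in by_name[t].columns}:
                    raise SchemaError(
                        f"join edge ({t1}, {t2}, {key}): column {key!r} "
                        f"missing from table {t!r}"
                    )
        # join graph must be connected so every multi-table query has a path
        if len(self.tables) > 1:
            adj: dict[str, set[str]] = {t.name: set() for t in self.tables}
            for t1, t2, _ in self.join_edges:
                adj[t1].add(t2)
                adj[t2].add(t1)
            seen = {self.tables[0].name}
            frontier = deque(seen)
            while frontier:
                for nb in adj[frontier.popleft()]:
                    if nb not in seen:
                        seen.add(nb)
                        frontier.append(nb)
            if len(seen) != len(self.tables):
                missing = sorted(set(adj) - seen)
                raise SchemaError(f"join graph is disconnected: {missing}")

    # ---- lookup helpers -------------------------------------------------

    @property
    def columns(self) -> tuple[ColumnDef, ...]:
        """All columns, schema-qualified, in declaration order.

        This flat ordering defines the SelectColumn action universe.
        """
        return tuple(c for t in self.tables for c in t.columns)

    def table(self, name: str) -> TableDef:
        for t in self.tables:
            if t.name == name:
                return t
        raise SchemaError(f"no table named {name!r}")

    def table_index(self, name: str) -> int:
        for i, t in enumerate(self.tables):
            if t.name == name:
                return i
        raise SchemaError(f"no table named {name!r}")

    def column_index(self, table: str, name: str) -> int:
        for i, c in enumerate(self.columns):
            if c.table == table and c.name == name:
                return i
        raise SchemaError(f"no column {table}.{name}")

    def tables_with_column(self, column_name: str) -> tuple[int, ...]:
        """Indices of tables containing a column of this name (pruning)."""
        return tuple(
            i
            for i, t in enumerate(self.tables)
            if any(c.name == column_name for c in t.columns)
        )

    def join_path(self, origin: str, target: str) -> list[tuple[str, str, str]]:
        """Shortest join-edge path between two tables (BFS, declaration order)."""
        if origin == target:
            return []
        adj: dict[str, list[tuple[str, str, str]]] = {t.name: [] for t in self.tables}
        for edge in self.join_edges:
            t1, t2, key = edge
            adj[t1].append((t1, t2, key))
            adj[t2].append((t2, t1, key))
        prev: dict[str, tuple[str, str, str, str]] = {}
        seen = {origin}
        frontier = deque([origin])
        while frontier:
            cur = frontier.popleft()
            for src, dst, key in adj[cur]:
                if dst not in seen:
                    seen.add(dst)
                    prev[dst] = (src, dst, key, cur)
                    if dst == target:
                        frontier.clear()
                        break
                    frontier.append(dst)
        if target not in prev:
            from .errors import JoinPathError

            raise JoinPathError(f"no join path from {origin!r} to {target!r}")
        path = []
        node = target
        while node != origin:
            src, dst, key, parent = prev[node]
            path.append((src, dst, key))
            node = parent
        path.reverse()
        return path


@dataclass
class ResultTable:
    """Execution output: ordered column labels and row tuples."""

    column_labels: list[str]
    rows: list[tuple]

    def __post_init__(self):
        for row in self.rows:
            if len(row) != len(self.column_labels):
                raise ExecutionError("row width does not match column labels")

    def same_result(self, other: "ResultTable") -> bool:
        """Equality with column order respected, row order ignored.

        Labels are not compared: two queries selecting the same values
        under different expressions count as the same answer.
        """
        if len(self.column_labels) != len(other.column_labels):
            return False
        key = lambda r: tuple(repr(v) for v in r)  # noqa: E731 - mixed types
        return sorted(self.rows, key=key) == sorted(other.rows, key=key)


# ---------------------------------------------------------------------------
# schema loading


def _parse_schema_dict(raw: Mapping) -> DatabaseSchema:
    if not isinstance(raw, Mapping) or "tables" not in raw:
        raise SchemaError("schema config must be a mapping with a 'tables' key")
    tables = []
    for traw in raw["tables"]:
        tname = traw.get("name")
        if not tname:
            raise SchemaError(f"table entry without a name: {traw!r}")
        cols = []
        for craw in traw.get("columns", []):
            if isinstance(craw, str):
                craw = {"name": craw}
            if "name" not in craw:
                raise SchemaError(f"column entry without a name in table {tname!r}")
            cols.append(
                ColumnDef(
                    name=craw["name"],
                    table=tname,
                    value_kind=craw.get("kind", "text"),
                    is_join_key=bool(craw.get("join_key", False)),
                )
            )
        tables.append(TableDef(name=tname, columns=tuple(cols)))
    joins = tuple((j[0], j[1], j[2]) for j in raw.get("joins", []))
    return DatabaseSchema(tables=tuple(tables), join_edges=joins)


def schema_to_dict(schema: DatabaseSchema) -> dict:
    """Inverse of the config format accepted by :func:`load_schema`."""
    return {
        "tables": [
            {
                "name": t.name,
                "columns": [
                    {"name": c.name, "kind": c.value_kind,
                     "join_key": c.is_join_key}
                    for c in t.columns
                ],
            }
            for t in schema.tables
        ],
        "joins": [list(e) for e in schema.join_edges],
    }


def schema_from_dict(raw: Mapping) -> DatabaseSchema:
    return _parse_schema_dict(raw)


def load_schema(path) -> DatabaseSchema:
    """Load and validate a schema from a YAML/JSON config file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise SchemaError(f"cannot parse schema config {path}: {exc}") from exc
    return _parse_schema_dict(raw)


def bundled_schema() -> DatabaseSchema:
    """The packaged five-table EMR-style schema (23/5/5/7/9 columns)."""
    ref = resources.files("emrsql").joinpath("data/mimicsql_like.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _parse_schema_dict(raw)


# ---------------------------------------------------------------------------
# SQLite fixtures


class Database:
    """Handle over a SQLite file plus the schema it was built from."""

    def __init__(self, path: str, schema: DatabaseSchema):
        self.path = str(path)
        self.schema = schema
        self._conn = sqlite3.connect(self.path)

    def close(self):
        self._conn.close()

    def execute(self, sql: str) -> ResultTable:
        return execute_query(self, sql)

    def executes_ok(self, sql: str) -> bool:
        try:
            self.execute(sql)
            return True
        except ExecutionError:
            return False


def _normalise_cell(col: ColumnDef, value):
    if value is None:
        return None
    if col.value_kind == "numeric":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise LoadError(
                f"column {col.qualified} is numeric but got {value!r}"
            )
        return value
    if not isinstance(value, str):
        raise LoadError(f"column {col.qualified} is text but got {value!r}")
    return value.lower()


def build_fixture_db(
    schema: DatabaseSchema,
    records: Mapping[str, Sequence[Mapping | Sequence]],
    path,
) -> Database:
    """Create a SQLite fixture holding ``records`` under ``schema``.

    ``records`` maps table name to rows; a row is either a mapping from
    column name to value or a sequence in column order. Text is stored
    lower-cased (case-insensitive condition matching), numeric columns get
    NUMERIC affinity.
    """
    db = Database(str(path), schema)
    conn = db._conn
    try:
        cur = conn.cursor()
        for t in schema.tables:
            cur.execute(f'DROP TABLE IF EXISTS "{t.name}"')
            decls = ", ".join(
                f'"{c.name}" {"NUMERIC" if c.value_kind == "numeric" else "TEXT"}'
                for c in t.columns
            )
            cur.execute(f'CREATE TABLE "{t.name}" ({decls})')
        for tname, rows in records.items():
            t = schema.table(tname)
            placeholders = ", ".join("?" for _ in t.columns)
            for row in rows:
                if isinstance(row, Mapping):
                    cells = [row.get(c.name) for c in t.columns]
                else:
                    if len(row) != len(t.columns):
                        raise LoadError(
                            f"row width {len(row)} != {len(t.columns)} "
                            f"columns in table {tname!r}"
                        )
                    cells = list(row)
                cells = [
                    _normalise_cell(c, v) for c, v in zip(t.columns, cells)
                ]
                cur.execute(
                    f'INSERT INTO "{tname}" VALUES ({placeholders})', cells
                )
        conn.commit()
    except Exception:
        db.close()
        raise
    return db


def execute_query(db: Database, sql: str) -> ResultTable:
    """Run SQL text, wrapping any engine failure as :class:`ExecutionError`."""
    try:
        cur = db._conn.cursor()
        cur.execute(sql)
        labels = [d[0] for d in cur.description] if cur.description else []
        rows = [tuple(r) for r in cur.fetchall()]
    except sqlite3.Error as exc:
        raise ExecutionError(f"query failed: {exc}") from exc
    return ResultTable(column_labels=labels, rows=rows)


def lookup_values(db: Database, column: ColumnDef) -> list:
    """Distinct stored values of a column in stable first-seen order."""
    if column.table not in {t.name for t in db.schema.tables}:
        raise SchemaError(f"unknown table {column.table!r}")
    db.schema.table(column.table).column(column.name)  # raises if missing
    res = execute_query(db, f'select "{column.name}" from "{column.table}"')
    seen = set()
    out = []
    for (v,) in res.rows:
        if v is None or v in seen:
            continue
        seen.add(v)
        out.append(v)
    return out
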