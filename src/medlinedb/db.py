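"""Relational backend: schema creation, bulk appends, and the file ledger.

The embedded backend is stdlib :mod:`sqlite3` (a single file or
``:memory:``), which is the one exercised by the test suite and recommended
for small-scale work.  A PostgreSQL dialect sits behind the same
:class:`Database` interface for server deployments (connection string of the
form ``postgresql://user@host:port/dbname``; the password is read from the
``MEDLINEDB_PASSWORD`` environment variable, never from the URL).

All article data flows through :func:`append_batch`; one source file is one
transaction, so a crashed run can simply be re-run — the ``xml_processed``
ledger records which files already contributed rows.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
import re
import sqlite3
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .registry import REGISTRY, TMP_DELETION, TMP_PREFIX, TableSpec, get_table

logger = logging.getLogger(__name__)

_SQLITE_TYPES = {
    "integer": "INTEGER",
    "text": "TEXT",
    "date": "TEXT",
    "boolean": "INTEGER",
    "timestamp": "TEXT",
}

_PG_TYPES = {
    "integer": "BIGINT",
    "text": "TEXT",
    "date": "DATE",
    "boolean": "BOOLEAN",
    "timestamp": "TIMESTAMPTZ",
}


class SchemaError(RuntimeError):
    """Raised when a requested schema operation would destroy existing data."""


class Database:
    """Thin dialect-aware wrapper over a DB-API connection.

    Statements are written with ``?`` placeholders and rewritten to the
    backend's paramstyle.  Explicit transactions only — autocommit is off
    and every mutation happens inside a :meth:`transaction` block.
    """

    def __init__(self, conn, dialect: str = "sqlite") -> None:
        if dialect not in ("sqlite", "postgres"):
            raise ValueError(f"unknown dialect {dialect!r}")
        self._conn = conn
        self.dialect = dialect
        self._txn_depth = 0

    # -- construction ------------------------------------------------------

    @classmethod
    def connect(cls, target: str = ":memory:") -> "Database":
        """Open a database.

        ``target`` is a SQLite path (or ``:memory:``), or a
        ``postgresql://`` URL for the server backend.
        """
        if target.startswith("postgresql://") or target.startswith("postgres://"):
            import psycopg2  # deferred: server deployments only

            m = re.match(r"postgres(?:ql)?://(?:([^@/]+)@)?([^:/]+)(?::(\d+))?/(.+)", target)
            if not m:
                raise ValueError(f"cannot parse connection URL {target!r}")
            user, host, port, name = m.groups()
            conn = psycopg2.connect(
                host=host,
                port=int(port) if port else 5432,
                user=user,
                dbname=name,
                password=os.environ.get("MEDLINEDB_PASSWORD"),
            )
            conn.autocommit = False
            return cls(conn, "postgres")
        conn = sqlite3.connect(target, isolation_level=None)
        conn.execute("PRAGMA foreign_keys = ON")
        return cls(conn, "sqlite")

    # -- statement plumbing ------------------------------------------------

    def _sql(self, sql: str) -> str:
        if self.dialect == "postgres":
            return sql.replace("?", "%s")
        return sql

    def execute(self, sql: str, params: Sequence = ()) -> "sqlite3.Cursor":
        cur = self._conn.cursor()
        cur.execute(self._sql(sql), tuple(params))
        return cur

    def executemany(self, sql: str, rows: Iterable[Sequence]) -> None:
        cur = self._conn.cursor()
        cur.executemany(self._sql(sql), rows)

    def fetchall(self, sql: str, params: Sequence = ()) -> list[tuple]:
        return list(self.execute(sql, params).fetchall())

    def fetchone(self, sql: str, params: Sequence = ()):
        return self.execute(sql, params).fetchone()

    @contextmanager
    def transaction(self) -> Iterator[None]:
        """``BEGIN``/``COMMIT`` block; any exception rolls the whole unit back.

        Re-entrant: nested blocks join the outermost transaction, so a
        failure anywhere rolls back the entire outer unit.
        """
        if self._txn_depth > 0:
            self._txn_depth += 1
            try:
                yield
            finally:
                self._txn_depth -= 1
            return
        if self.dialect == "sqlite":
            self._conn.execute("BEGIN")
        self._txn_depth = 1
        try:
            yield
        except BaseException:
            self._conn.rollback()
            raise
        else:
            self._conn.commit()
        finally:
            self._txn_depth = 0

    def close(self) -> None:
        self._conn.close()

    # -- catalog -----------------------------------------------------------

    def table_names(self) -> list[str]:
        if self.dialect == "sqlite":
            rows = self.fetchall(
                "SELECT name FROM sqlite_master WHERE type='table' "
                "AND name NOT LIKE 'sqlite_%'"
            )
        else:
            rows = self.fetchall(
                "SELECT tablename FROM pg_tables WHERE schemaname='public'"
            )
        return sorted(r[0] for r in rows)

    def has_table(self, name: str) -> bool:
        return name in self.table_names()

    def row_count(self, table: str) -> int:
        return self.fetchone(f"SELECT COUNT(*) FROM {table}")[0]

    def drop_table(self, name: str) -> None:
        self.execute(f"DROP TABLE IF EXISTS {name}")

    def rename_table(self, old: str, new: str) -> None:
        self.execute(f"ALTER TABLE {old} RENAME TO {new}")

    def column_types(self) -> dict[str, str]:
        return _SQLITE_TYPES if self.dialect == "sqlite" else _PG_TYPES


# -- schema creation -------------------------------------------------------


def _create_sql(db: Database, spec: TableSpec, name: str, extra: tuple = ()) -> str:
    types = db.column_types()
    cols = ", ".join(f"{c} {types[t]}" for c, t in spec.columns + tuple(extra))
    return f"CREATE TABLE {name} ({cols})"


def init_tables(
    db: Database,
    registry: Sequence[TableSpec] = REGISTRY,
    temporary: bool = False,
) -> None:
    """Create the main tables, or the staging twins of the versioned ones.

    With ``temporary=False`` every registry table is created; an existing
    *non-empty* main table is a hard error — never silently overwritten.
    With ``temporary=True`` each versioned table gets a ``tmp_``-prefixed
    twin carrying an extra ``source_file`` column, plus the deletion-notice
    staging table; stale twins from a crashed run are dropped first.
    """
    existing = set(db.table_names())
    with db.transaction():
        if temporary:
            for spec in registry:
                if not spec.keyed_by_version:
                    continue
                twin = TMP_PREFIX + spec.name
                db.drop_table(twin)
                db.execute(_create_sql(db, spec, twin, (("source_file", "text"),)))
            db.drop_table(TMP_DELETION)
            types = db.column_types()
            db.execute(
                f"CREATE TABLE {TMP_DELETION} "
                f"(pmid {types['integer']}, source_file {types['text']})"
            )
            return
        for spec in registry:
            if spec.name in existing:
                if db.row_count(spec.name) > 0:
                    raise SchemaError(
                        f"table {spec.name!r} already exists and is not empty; "
                        "refusing to overwrite an existing database"
                    )
                db.drop_table(spec.name)
            db.execute(_create_sql(db, spec, spec.name))
        for spec in registry:
            if spec.name == "xml_processed":
                db.execute(
                    "CREATE INDEX idx_xml_processed_file ON xml_processed (file_name)"
                )
            elif spec.keyed_by_version:
                db.execute(
                    f"CREATE INDEX idx_{spec.name}_pmid ON {spec.name} (pmid, version)"
                )


# -- appends ---------------------------------------------------------------


def append_batch(
    db: Database,
    batch,
    into_temporary: bool = False,
    _in_transaction: bool = False,
) -> dict[str, int]:
    """Append one parsed file's rows; returns rows inserted per table.

    Atomic per file: a failure on any table rolls back every table's
    contribution.  Staging appends additionally tag each row with the batch's
    source file so the update pipeline can resolve per-PMID winners.
    """
    counts: dict[str, int] = {}

    def _do() -> None:
        for table, rows in batch.rows_by_table.items():
            spec = get_table(table)
            if not rows:
                counts[table] = 0
                continue
            cols = list(spec.column_names)
            target = table
            if into_temporary:
                target = TMP_PREFIX + table
                cols.append("source_file")
            placeholders = ", ".join("?" * len(cols))
            sql = f"INSERT INTO {target} ({', '.join(cols)}) VALUES ({placeholders})"
            tuples = []
            for row in rows:
                extra = set(row) - set(spec.column_names)
                if extra:
                    raise ValueError(
                        f"row for table {table!r} has unknown column(s) {sorted(extra)}"
                    )
                vals = [_to_sql_value(row.get(c)) for c in spec.column_names]
                if into_temporary:
                    vals.append(batch.source_file)
                tuples.append(tuple(vals))
            db.executemany(sql, tuples)
            counts[table] = len(tuples)

    if _in_transaction:
        _do()
    else:
        with db.transaction():
            _do()
    return counts


def _to_sql_value(v):
    if isinstance(v, bool):
        return int(v)
    return v


# -- processed-file ledger -------------------------------------------------


@dataclass(frozen=True)
class FileLogEntry:
    """Provenance record: one processed source file and when it was processed."""

    file_name: str
    processed_at: _dt.datetime
    checksum: str | None = None


class DuplicateFileError(RuntimeError):
    """A file already present in the ledger was logged again."""


def log_file(db: Database, entry: FileLogEntry, _in_transaction: bool = False) -> None:
    """Record a processed file in the ledger; duplicate names are an error."""
    if db.fetchone(
        "SELECT 1 FROM xml_processed WHERE file_name = ?", (entry.file_name,)
    ):
        raise DuplicateFileError(f"file {entry.file_name!r} already logged")
    ts = entry.processed_at
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=_dt.timezone.utc)
    ts = ts.astimezone(_dt.timezone.utc)
    sql = "INSERT INTO xml_processed (file_name, processed_at, checksum) VALUES (?, ?, ?)"
    params = (entry.file_name, ts.isoformat(), entry.checksum)
    if _in_transaction:
        db.execute(sql, params)
    else:
        with db.transaction():
            db.execute(sql, params)


def processed_files(db: Database) -> list[str]:
    return [r[0] for r in db.fetchall("SELECT file_name FROM xml_processed")]


_SEQ_RE = re.compile(r"n(\d+)", re.IGNORECASE)


def file_sort_key(name: str) -> tuple:
    """Total order on source files.

    NLM file names encode their sequence in a zero-padded numeric segment
    (``pubmed26n0042.xml.gz`` → 42); files are ordered by that number, with
    a plain lexicographic fallback for names outside the pattern.
    """
    base = os.path.basename(name)
    m = _SEQ_RE.search(base)
    if m:
        return (0, int(m.group(1)), base)
    return (1, 0, base)


def unprocessed(available_files: Sequence[str], db: Database) -> list[str]:
    """Files in ``available_files`` absent from the ledger, in sequence order."""
    done = {os.path.basename(f) for f in processed_files(db)}
    todo = [f for f in available_files if os.path.basename(f) not in done]
    return sorted(todo, key=file_sort_key)


# -- state snapshot (testing / verification) -------------------------------


def database_state(
    db: Database, tables: Iterable[str] | None = None
) -> dict[str, dict[tuple, int]]:
    """Multiset of rows per versioned table, for whole-state comparison."""
    from .registry import VERSIONED_TABLES

    state: dict[str, dict[tuple, int]] = {}
    for name in tables if tables is not None else VERSIONED_TABLES:
        spec = get_table(name)
        cols = ", ".join(spec.column_names)
        multiset: dict[tuple, int] = {}
        for row in db.fetchall(f"SELECT {cols} FROM {name}"):
            multiset[row] = multiset.get(row, 0) + 1
        state[name] = multiset
    return state
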