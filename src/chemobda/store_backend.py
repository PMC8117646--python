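"""Embedded relational backend (SQLite).

Creates the declared schema with PK/FK/NOT NULL constraints enforced,
loads delimited files, executes rendered SQL and decodes result rows back
into RDF terms, and applies diff-based single-transaction updates so that
readers never observe a partially updated dataset.
"""

from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .mapping_model import RelationalSchema, TableDecl
from .rdf_core import SolutionMultiset

_SQLITE_TYPES = {
    "integer": "INTEGER",
    "text": "TEXT",
    "real": "REAL",
    "boolean": "INTEGER",  # stored as 0/1
}


class BackendError(RuntimeError):
    def __init__(self, message: str, sql: Optional[str] = None) -> None:
        if sql:
            message = f"{message}\n  while executing: {sql}"
        super().__init__(message)
        self.sql = sql


@dataclass
class RowDelta:
    """Changes applied to one table by a diff update."""

    table: str
    inserts: list[dict] = field(default_factory=list)
    deletes: list[tuple] = field(default_factory=list)
    replacements: list[dict] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.inserts or self.deletes or self.replacements)

    def summary(self) -> str:
        return (
            f"{self.table}: {len(self.inserts)} inserted, "
            f"{len(self.deletes)} deleted, {len(self.replacements)} replaced"
        )


def _ddl_for_table(t: TableDecl) -> str:
    parts = []
    for c in t.columns:
        decl = f"{_q(c.name)} {_SQLITE_TYPES[c.type]}"
        if c.notnull:
            decl += " NOT NULL"
        parts.append(decl)
    if t.primary_key:
        parts.append("PRIMARY KEY (" + ", ".join(_q(c) for c in t.primary_key) + ")")
    for fk in t.foreign_keys:
        parts.append(
            "FOREIGN KEY ("
            + ", ".join(_q(c) for c in fk.columns)
            + f") REFERENCES {_q(fk.ref_table)} ("
            + ", ".join(_q(c) for c in fk.ref_columns)
            + ")"
        )
    return f"CREATE TABLE {_q(t.name)} (\n  " + ",\n  ".join(parts) + "\n)"


def _q(ident: str) -> str:
    return '"' + ident.replace('"', '""') + '"'


def _coerce(value: str, sql_type: str):
    """Coerce a CSV field to a SQL value; the empty string is NULL."""
    if value == "" or value is None:
        return None
    if sql_type == "integer":
        return int(value)
    if sql_type == "real":
        return float(value)
    if sql_type == "boolean":
        if value in ("true", "True", "1"):
            return 1
        if value in ("false", "False", "0"):
            return 0
        raise ValueError(f"not a boolean: {value!r}")
    return value


class Database:
    """A schema-aware connection to an embedded SQLite store."""

    def __init__(self, path: str, schema: RelationalSchema) -> None:
        self.path = path
        self.schema = schema
        self.conn = sqlite3.connect(path)
        self.conn.execute("PRAGMA foreign_keys = ON")

    # -- schema -------------------------------------------------------------

    @classmethod
    def create(cls, path: str, schema: RelationalSchema) -> "Database":
        db = cls(path, schema)
        db.create_schema()
        return db

    @classmethod
    def open(cls, path: str, schema: RelationalSchema) -> "Database":
        return cls(path, schema)

    def create_schema(self) -> None:
        try:
            for t in self.schema.tables:
                self.conn.execute(_ddl_for_table(t))
            self.conn.commit()
        except sqlite3.Error as exc:
            self.conn.rollback()
            raise BackendError(f"schema creation failed: {exc}") from exc

    def close(self) -> None:
        self.conn.close()

    # -- loading ------------------------------------------------------------

    def load_rows(self, table: str, rows: Iterable[dict]) -> int:
        """Insert rows atomically; any constraint violation aborts the load."""
        t = self.schema.table(table)
        if t is None:
            raise BackendError(f"unknown table {table}")
        cols = t.column_names
        sql = (
            f"INSERT INTO {_q(table)} ("
            + ", ".join(_q(c) for c in cols)
            + ") VALUES ("
            + ", ".join("?" for _ in cols)
            + ")"
        )
        count = 0
        try:
            for row in rows:
                self.conn.execute(sql, tuple(row.get(c) for c in cols))
                count += 1
            self.conn.commit()
        except sqlite3.Error as exc:
            self.conn.rollback()
            raise BackendError(f"load into {table} aborted: {exc}", sql) from exc
        return count

    def load_csv(self, table: str, source) -> int:
        """Load a delimited file (header row, RFC-4180, empty field = NULL)."""
        t = self.schema.table(table)
        if t is None:
            raise BackendError(f"unknown table {table}")
        close = False
        if isinstance(source, str):
            source = open(source, "r", encoding="utf-8", newline="")
            close = True
        try:
            reader = csv.DictReader(source)
            rows = []
            for rec in reader:
                row = {}
                for c in t.columns:
                    if c.name in rec:
                        row[c.name] = _coerce(rec[c.name], c.type)
                rows.append(row)
        finally:
            if close:
                source.close()
        return self.load_rows(table, rows)

    # -- reading ------------------------------------------------------------

    def fetch_rows(self, table: str) -> list[dict]:
        t = self.schema.table(table)
        if t is None:
            raise BackendError(f"unknown table {table}")
        cols = t.column_names
        cur = self.conn.execute(
            f"SELECT {', '.join(_q(c) for c in cols)} FROM {_q(table)}"
        )
        return [dict(zip(cols, row)) for row in cur.fetchall()]

    def execute_sql(self, sql: str, params: tuple = ()) -> list[tuple]:
        try:
            cur = self.conn.execute(sql, params)
            return cur.fetchall()
        except sqlite3.Error as exc:
            raise BackendError(str(exc), sql) from exc

    # -- solution decoding --------------------------------------------------

    def execute(self, compiled) -> Union[SolutionMultiset, bool]:
        """Run a :class:`~chemobda.sql_render.CompiledQuery` and decode each
        result column back into an RDF term (or UNBOUND for SQL NULL)."""
        raw = self.execute_sql(compiled.sql)
        if compiled.form == "ASK":
            return bool(raw)
        rows = []
        for raw_row in raw:
            row = {}
            offset = 0
            for var, dec in zip(compiled.variables, compiled.decoders):
                width = dec.width
                term = dec.decode(raw_row[offset : offset + width]) if width else None
                offset += max(width, 1)
                if term is not None:
                    row[var] = term
            rows.append(row)
        return SolutionMultiset(list(compiled.variables), rows)

    # -- diff updates --------------------------------------------------------

    def diff_update(self, table: str, incoming: Iterable[dict]) -> RowDelta:
        """Bring a table to the incoming snapshot in one transaction.

        New keys are inserted, absent keys deleted, and rows whose non-key
        columns changed are replaced.  A constraint violation rolls back
        the entire delta.
        """
        t = self.schema.table(table)
        if t is None:
            raise BackendError(f"unknown table {table}")
        pk = t.primary_key
        if not pk:
            raise BackendError(f"diff update needs a primary key on {table}")
        cols = t.column_names
        nonkey = [c for c in cols if c not in pk]

        def key_of(row: dict) -> tuple:
            return tuple(row.get(c) for c in pk)

        current = {key_of(r): r for r in self.fetch_rows(table)}
        new = {}
        for r in incoming:
            r = {c: r.get(c) for c in cols}
            new[key_of(r)] = r

        delta = RowDelta(table)
        for key, row in new.items():
            if key not in current:
                delta.inserts.append(row)
            elif any(current[key].get(c) != row.get(c) for c in nonkey):
                delta.replacements.append(row)
        for key in current:
            if key not in new:
                delta.deletes.append(key)

        ins_sql = (
            f"INSERT INTO {_q(table)} ("
            + ", ".join(_q(c) for c in cols)
            + ") VALUES ("
            + ", ".join("?" for _ in cols)
            + ")"
        )
        del_sql = f"DELETE FROM {_q(table)} WHERE " + " AND ".join(
            f"{_q(c)} = ?" for c in pk
        )
        upd_sql = (
            f"UPDATE {_q(table)} SET "
            + ", ".join(f"{_q(c)} = ?" for c in nonkey)
            + " WHERE "
            + " AND ".join(f"{_q(c)} = ?" for c in pk)
        ) if nonkey else None

        try:
            for key in delta.deletes:
                self.conn.execute(del_sql, key)
            for row in delta.replacements:
                self.conn.execute(
                    upd_sql,
                    tuple(row.get(c) for c in nonkey) + tuple(row.get(c) for c in pk),
                )
            for row in delta.inserts:
                self.conn.execute(ins_sql, tuple(row.get(c) for c in cols))
            self.conn.commit()
        except sqlite3.Error as exc:
            self.conn.rollback()
            raise BackendError(f"diff update of {table} rolled back: {exc}") from exc
        return delta


def create_schema(db: Database, schema: RelationalSchema) -> None:
    """Create ``schema`` in ``db`` (module-level convenience)."""
    db.schema = schema
    db.create_schema()


def load_table(db: Database, table: str, source) -> int:
    return db.load_csv(table, source)


def execute(db: Database, compiled):
    return db.execute(compiled)


def diff_update(db: Database, table: str, incoming: Iterable[dict]) -> RowDelta:
    return db.diff_update(table, incoming)
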