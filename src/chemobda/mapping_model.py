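"""Relational-to-RDF mapping model.

A mapping set has two parts, mirroring the way SQL-backed SPARQL stores
declare their view of a relational database:

* **IRI classes** — a bijection between an IRI template (fixed prefix,
  typed slots, fixed infixes/suffix) and tuples of relational key values.
  All classes of a mapping set are pairwise disjoint, so any IRI decodes
  under at most one class.
* **Quad mappings** — one rule per kind of triple: every table row whose
  required columns are all non-null yields exactly one quad, with each
  term generated from columns (through an IRI class or as a typed
  literal) or fixed as a constant.

The mapping set is the translator's semantic ground truth.  The
:func:`materialize` operation — explicitly generating every quad over a
database — exists only to feed the reference evaluator in tests; the
production path translates queries instead of materialising data.
"""

from __future__ import annotations

import re
import urllib.parse
from dataclasses import dataclass, field
from typing import Optional, Union

import yaml

from .rdf_core import (
    DEFAULT_GRAPH,
    IRI,
    Literal,
    Quad,
    QuadStore,
    XSD_BOOLEAN,
    XSD_DECIMAL,
    XSD_DOUBLE,
    XSD_FLOAT,
    XSD_INTEGER,
    XSD_STRING,
    float_lexical,
)
from .sparql_frontend import PrefixTable

# ---------------------------------------------------------------------------
# Relational schema declarations

SQL_TYPES = ("integer", "text", "real", "boolean")

#: SQL column types a literal datatype can be generated from
_DATATYPE_COLUMN_TYPES = {
    XSD_INTEGER: {"integer"},
    XSD_STRING: {"text"},
    XSD_DOUBLE: {"real", "integer"},
    XSD_FLOAT: {"real", "integer"},
    XSD_DECIMAL: {"real", "integer"},
    XSD_BOOLEAN: {"boolean", "integer"},
}


class MappingError(ValueError):
    """Invalid mapping set; carries the full violation list."""

    def __init__(self, violations: list[str]) -> None:
        super().__init__("; ".join(violations))
        self.violations = violations


@dataclass(frozen=True)
class Column:
    name: str
    type: str
    notnull: bool = False

    def __post_init__(self) -> None:
        if self.type not in SQL_TYPES:
            raise ValueError(f"unknown SQL type {self.type!r} for column {self.name}")


@dataclass(frozen=True)
class ForeignKey:
    columns: tuple[str, ...]
    ref_table: str
    ref_columns: tuple[str, ...]


@dataclass(frozen=True)
class TableDecl:
    name: str
    columns: tuple[Column, ...]
    primary_key: tuple[str, ...]
    foreign_keys: tuple[ForeignKey, ...] = ()

    def column(self, name: str) -> Optional[Column]:
        for c in self.columns:
            if c.name == name:
                return c
        return None

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


@dataclass(frozen=True)
class RelationalSchema:
    tables: tuple[TableDecl, ...]

    def table(self, name: str) -> Optional[TableDecl]:
        for t in self.tables:
            if t.name == name:
                return t
        return None

    def validate(self) -> list[str]:
        out: list[str] = []
        seen = set()
        for t in self.tables:
            if t.name in seen:
                out.append(f"duplicate table {t.name}")
            seen.add(t.name)
            colnames = t.column_names
            if len(set(colnames)) != len(colnames):
                out.append(f"table {t.name}: duplicate column names")
            for pk in t.primary_key:
                col = t.column(pk)
                if col is None:
                    out.append(f"table {t.name}: primary-key column {pk} missing")
                elif not col.notnull:
                    out.append(f"table {t.name}: primary-key column {pk} must be NOT NULL")
            for fk in t.foreign_keys:
                ref = self.table(fk.ref_table)
                if ref is None:
                    out.append(f"table {t.name}: foreign key references unknown table {fk.ref_table}")
                    continue
                if tuple(fk.ref_columns) != tuple(ref.primary_key):
                    out.append(
                        f"table {t.name}: foreign key to {fk.ref_table} must reference its full primary key"
                    )
                for c in fk.columns:
                    if t.column(c) is None:
                        out.append(f"table {t.name}: foreign-key column {c} missing")
        return out


# ---------------------------------------------------------------------------
# IRI classes


@dataclass(frozen=True)
class Slot:
    name: str
    type: str  # integer | text


_TEMPLATE_SLOT_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*):(integer|text)\}")
_INT_SLOT_RE = r"(0|[1-9][0-9]*)"
_TEXT_SLOT_RE = r"((?:[A-Za-z0-9_.~\-]|%[0-9A-Fa-f]{2})+)"


class IRIClass:
    """A bijection between an IRI template and tuples of SQL key values.

    Templates interleave fixed text with typed slots, e.g.
    ``http://.../endpoint/SID{sid:integer}_AID{aid:integer}_{mg:integer}``.
    Integer slots render without sign or leading zeros; text slots are
    percent-encoded, so encode-then-decode is the identity and decode
    rejects non-canonical forms.
    """

    def __init__(self, name: str, template: str) -> None:
        self.name = name
        self.template = template
        parts: list[Union[str, Slot]] = []
        pos = 0
        for m in _TEMPLATE_SLOT_RE.finditer(template):
            if m.start() > pos:
                parts.append(template[pos : m.start()])
            parts.append(Slot(m.group(1), m.group(2)))
            pos = m.end()
        if pos < len(template):
            parts.append(template[pos:])
        self.parts = tuple(parts)
        self.slots = tuple(p for p in self.parts if isinstance(p, Slot))
        if not self.slots:
            raise ValueError(f"IRI class {name}: template has no slots")
        regex = []
        prev_slot = False
        for p in self.parts:
            if isinstance(p, Slot):
                if prev_slot:
                    raise ValueError(
                        f"IRI class {name}: adjacent slots without a fixed separator are ambiguous"
                    )
                regex.append(_INT_SLOT_RE if p.type == "integer" else _TEXT_SLOT_RE)
                prev_slot = True
            else:
                regex.append(re.escape(p))
                prev_slot = False
        self._regex = re.compile("".join(regex) + r"\Z")

    @property
    def slot_types(self) -> tuple[str, ...]:
        return tuple(s.type for s in self.slots)

    def encode(self, values: tuple) -> IRI:
        if len(values) != len(self.slots):
            raise ValueError(
                f"IRI class {self.name}: expected {len(self.slots)} values, got {len(values)}"
            )
        out = []
        vi = 0
        for p in self.parts:
            if isinstance(p, Slot):
                v = values[vi]
                vi += 1
                if v is None:
                    raise ValueError(f"IRI class {self.name}: null value for slot {p.name}")
                if p.type == "integer":
                    if isinstance(v, bool) or not isinstance(v, int):
                        raise ValueError(
                            f"IRI class {self.name}: slot {p.name} needs an integer, got {v!r}"
                        )
                    if v < 0:
                        raise ValueError(f"IRI class {self.name}: negative key {v}")
                    out.append(str(v))
                else:
                    if not isinstance(v, str):
                        raise ValueError(
                            f"IRI class {self.name}: slot {p.name} needs text, got {v!r}"
                        )
                    out.append(urllib.parse.quote(v, safe=""))
            else:
                out.append(p)
        return IRI("".join(out))

    def decode(self, iri: Union[IRI, str]) -> Optional[tuple]:
        """Slot values if the IRI is a member of this class, else ``None``."""
        text = iri.value if isinstance(iri, IRI) else iri
        m = self._regex.fullmatch(text)
        if m is None:
            return None
        values = []
        for slot, group in zip(self.slots, m.groups()):
            if slot.type == "integer":
                values.append(int(group))
            else:
                decoded = urllib.parse.unquote(group)
                # reject non-canonical percent-encodings
                if urllib.parse.quote(decoded, safe="") != group:
                    return None
                values.append(decoded)
        return tuple(values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IRIClass({self.name}: {self.template})"


def iri_encode(cls: IRIClass, values: tuple) -> IRI:
    return cls.encode(values)


def iri_decode(cls: IRIClass, iri: Union[IRI, str]) -> Optional[tuple]:
    return cls.decode(iri)


# ---------------------------------------------------------------------------
# Term and quad mappings


@dataclass(frozen=True)
class ConstantIRI:
    iri: IRI

    @property
    def columns(self) -> tuple[str, ...]:
        return ()


@dataclass(frozen=True)
class ConstantLiteral:
    literal: Literal

    @property
    def columns(self) -> tuple[str, ...]:
        return ()


@dataclass(frozen=True)
class ColumnLiteral:
    column: str
    datatype: str = XSD_STRING
    language: Optional[str] = None

    @property
    def columns(self) -> tuple[str, ...]:
        return (self.column,)


@dataclass(frozen=True)
class ColumnIRI:
    iri_class: IRIClass
    column_names: tuple[str, ...]

    @property
    def columns(self) -> tuple[str, ...]:
        return self.column_names


TermMapping = Union[ConstantIRI, ConstantLiteral, ColumnLiteral, ColumnIRI]


@dataclass(frozen=True)
class QuadMapping:
    table: str
    subject: TermMapping
    predicate: TermMapping
    object: TermMapping
    graph: Union[ConstantIRI, None] = None  # None == default graph
    condition: tuple[tuple[str, object], ...] = ()  # (column, required value)
    label: str = ""

    @property
    def required_columns(self) -> tuple[str, ...]:
        cols: list[str] = []
        for tm in (self.subject, self.predicate, self.object):
            for c in tm.columns:
                if c not in cols:
                    cols.append(c)
        for c, _ in self.condition:
            if c not in cols:
                cols.append(c)
        return tuple(cols)

    def describe(self) -> str:
        return self.label or f"{self.table}:{_term_mapping_text(self.subject)} {_term_mapping_text(self.predicate)} {_term_mapping_text(self.object)}"


def _term_mapping_text(tm: TermMapping) -> str:
    if isinstance(tm, ConstantIRI):
        return f"<{tm.iri.value}>"
    if isinstance(tm, ConstantLiteral):
        return repr(tm.literal)
    if isinstance(tm, ColumnLiteral):
        return f"({tm.column})^^<{tm.datatype}>"
    if isinstance(tm, ColumnIRI):
        return f"{tm.iri_class.name}({', '.join(tm.column_names)})"
    return repr(tm)


# ---------------------------------------------------------------------------
# Mapping set


@dataclass
class MappingSet:
    schema: RelationalSchema
    iri_classes: dict[str, IRIClass]
    quad_mappings: list[QuadMapping]

    def classify_iri(self, iri: Union[IRI, str]):
        """The unique (class, decoded values) an IRI belongs to, or ``None``."""
        for cls in self.iri_classes.values():
            values = cls.decode(iri)
            if values is not None:
                return cls, values
        return None

    # -- validation ---------------------------------------------------------

    _DISJOINTNESS_SAMPLES = {
        "integer": (0, 1, 7, 42, 1234567),
        "text": ("a", "z9", "x_y", "CHEMBL", "25"),
    }

    def validate(self) -> list[str]:
        out = list(self.schema.validate())
        out.extend(self._validate_disjointness())
        for qm in self.quad_mappings:
            out.extend(self._validate_quad_mapping(qm))
        return out

    def _validate_disjointness(self) -> list[str]:
        out = []
        classes = list(self.iri_classes.values())
        for i, a in enumerate(classes):
            for b in classes[i + 1 :]:
                if a.template == b.template:
                    out.append(f"IRI classes {a.name} and {b.name} have identical templates")
                    continue
                for cls, other in ((a, b), (b, a)):
                    for sample in self._sample_iris(cls):
                        if other.decode(sample) is not None:
                            out.append(
                                f"IRI classes {cls.name} and {other.name} overlap on {sample.value}"
                            )
                            break
        return out

    def _sample_iris(self, cls: IRIClass):
        for i in range(len(self._DISJOINTNESS_SAMPLES["integer"])):
            values = tuple(
                self._DISJOINTNESS_SAMPLES[s.type][i % len(self._DISJOINTNESS_SAMPLES[s.type])]
                for s in cls.slots
            )
            yield cls.encode(values)

    def _validate_quad_mapping(self, qm: QuadMapping) -> list[str]:
        out = []
        table = self.schema.table(qm.table)
        where = f"quad mapping on {qm.table}"
        if table is None:
            return [f"{where}: unknown table"]
        if not isinstance(qm.predicate, ConstantIRI):
            out.append(f"{where}: predicate must be a constant IRI")
        if not isinstance(qm.subject, (ColumnIRI, ConstantIRI)):
            out.append(f"{where}: subject must map to an IRI")
        if qm.graph is not None and not isinstance(qm.graph, ConstantIRI):
            out.append(f"{where}: graph must be a constant IRI or default")
        for tm in (qm.subject, qm.predicate, qm.object):
            if isinstance(tm, ColumnIRI):
                if tm.iri_class.name not in self.iri_classes:
                    out.append(f"{where}: undeclared IRI class {tm.iri_class.name}")
                if len(tm.column_names) != len(tm.iri_class.slots):
                    out.append(
                        f"{where}: class {tm.iri_class.name} has {len(tm.iri_class.slots)} slots, "
                        f"{len(tm.column_names)} columns given"
                    )
                for col, slot in zip(tm.column_names, tm.iri_class.slots):
                    c = table.column(col)
                    if c is None:
                        out.append(f"{where}: missing column {col}")
                    elif c.type != slot.type:
                        out.append(
                            f"{where}: column {col} has type {c.type}, slot {slot.name} wants {slot.type}"
                        )
            elif isinstance(tm, ColumnLiteral):
                c = table.column(tm.column)
                if c is None:
                    out.append(f"{where}: missing column {tm.column}")
                else:
                    allowed = _DATATYPE_COLUMN_TYPES.get(tm.datatype)
                    if allowed is not None and c.type not in allowed:
                        out.append(
                            f"{where}: column {tm.column} ({c.type}) cannot carry datatype {tm.datatype}"
                        )
        for col, _ in qm.condition:
            if table.column(col) is None:
                out.append(f"{where}: condition on missing column {col}")
        return out

    def validated(self) -> "MappingSet":
        violations = self.validate()
        if violations:
            raise MappingError(violations)
        return self


def validate(ms: MappingSet) -> list[str]:
    return ms.validate()


def classify_iri(iri: Union[IRI, str], ms: MappingSet):
    return ms.classify_iri(iri)


# ---------------------------------------------------------------------------
# Materialisation (testing oracle input only)


def term_from_row(tm: TermMapping, row: dict):
    """RDF term a term mapping generates from a row (requires non-nulls)."""
    if isinstance(tm, ConstantIRI):
        return tm.iri
    if isinstance(tm, ConstantLiteral):
        return tm.literal
    if isinstance(tm, ColumnIRI):
        return tm.iri_class.encode(tuple(row[c] for c in tm.column_names))
    if isinstance(tm, ColumnLiteral):
        v = row[tm.column]
        if tm.language is not None:
            return Literal(str(v), language=tm.language)
        if tm.datatype == XSD_BOOLEAN:
            return Literal("true" if v else "false", XSD_BOOLEAN)
        if isinstance(v, float):
            return Literal(float_lexical(v), tm.datatype)
        return Literal(str(v), tm.datatype)
    raise TypeError(f"not a term mapping: {tm!r}")


def materialize(ms: MappingSet, db) -> QuadStore:
    """Generate every quad the mapping set defines over a database.

    ``db`` must provide ``fetch_rows(table) -> list[dict]``.  A row yields a
    quad only if all required columns are non-null and the mapping's
    discriminator condition (if any) holds.
    """
    store = QuadStore()
    for qm in ms.quad_mappings:
        required = qm.required_columns
        for row in db.fetch_rows(qm.table):
            if any(row.get(c) is None for c in required):
                continue
            if any(row.get(c) != v for c, v in qm.condition):
                continue
            graph = qm.graph.iri if qm.graph is not None else DEFAULT_GRAPH
            store.add(
                Quad(
                    term_from_row(qm.subject, row),
                    term_from_row(qm.predicate, row),
                    term_from_row(qm.object, row),
                    graph,
                )
            )
    return store


# ---------------------------------------------------------------------------
# Declarative config (YAML)
#
# The config file mirrors the compact notation used for quad mappings,
# e.g.  subject "document(id)", predicate "dcterms:title",
# object "(title)^^xsd:string".

_COLUMN_IRI_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_]*)\(\s*([A-Za-z0-9_,\s]+)\)\Z")
_COLUMN_LIT_RE = re.compile(
    r"\(\s*([A-Za-z_][A-Za-z0-9_]*)\s*\)(?:\^\^([A-Za-z_][A-Za-z0-9_]*:[A-Za-z0-9_]+)|@([A-Za-z-]+))?\Z"
)
_CONST_LIT_RE = re.compile(
    r'"((?:[^"\\]|\\.)*)"(?:\^\^([A-Za-z_][A-Za-z0-9_]*:[A-Za-z0-9_]+)|@([A-Za-z-]+))?\Z'
)


def _parse_term_mapping(
    text: str, classes: dict[str, IRIClass], prefixes: PrefixTable
) -> TermMapping:
    text = str(text).strip()
    if text.startswith("<") and text.endswith(">"):
        return ConstantIRI(IRI(text[1:-1]))
    m = _COLUMN_IRI_RE.fullmatch(text)
    if m and m.group(1) in classes:
        cols = tuple(c.strip() for c in m.group(2).split(","))
        return ColumnIRI(classes[m.group(1)], cols)
    m = _COLUMN_LIT_RE.fullmatch(text)
    if m:
        col = m.group(1)
        if m.group(3):
            return ColumnLiteral(col, language=m.group(3))
        dt = prefixes.expand(m.group(2)) if m.group(2) else XSD_STRING
        return ColumnLiteral(col, dt)
    m = _CONST_LIT_RE.fullmatch(text)
    if m:
        lex = m.group(1).replace('\\"', '"').replace("\\\\", "\\")
        if m.group(3):
            return ConstantLiteral(Literal(lex, language=m.group(3)))
        dt = prefixes.expand(m.group(2)) if m.group(2) else XSD_STRING
        return ConstantLiteral(Literal(lex, dt))
    if re.fullmatch(r"-?\d+", text):
        return ConstantLiteral(Literal(text, XSD_INTEGER))
    if text in ("true", "false"):
        return ConstantLiteral(Literal(text, XSD_BOOLEAN))
    if ":" in text:
        return ConstantIRI(IRI(prefixes.expand(text)))
    raise ValueError(f"cannot parse term mapping {text!r}")


def _parse_schema(data: dict) -> RelationalSchema:
    tables = []
    for t in data.get("tables", []):
        columns = tuple(
            Column(c["name"], c.get("type", "text"), bool(c.get("notnull", False)))
            for c in t.get("columns", [])
        )
        fks = tuple(
            ForeignKey(
                tuple(fk["columns"]),
                fk["references"],
                tuple(fk.get("ref_columns", [])),
            )
            for fk in t.get("foreign_keys", [])
        )
        tables.append(
            TableDecl(
                t["name"],
                columns,
                tuple(t.get("primary_key", [])),
                fks,
            )
        )
    return RelationalSchema(tuple(tables))


def parse_mapping_config(source: Union[str, dict]) -> MappingSet:
    """Parse (and validate) a mapping config from YAML text or a dict."""
    data = yaml.safe_load(source) if isinstance(source, str) else source
    prefixes = PrefixTable(data.get("prefixes"))
    schema = _parse_schema(data.get("schema", {}))
    classes: dict[str, IRIClass] = {}
    for c in data.get("iri_classes", []):
        cls = IRIClass(c["name"], c["template"])
        if cls.name in classes:
            raise MappingError([f"duplicate IRI class {cls.name}"])
        classes[cls.name] = cls
    mappings: list[QuadMapping] = []
    for i, qm in enumerate(data.get("quad_mappings", [])):
        condition = tuple(sorted((qm.get("condition") or {}).items()))
        graph = None
        if qm.get("graph"):
            g = _parse_term_mapping(qm["graph"], classes, prefixes)
            if not isinstance(g, ConstantIRI):
                raise MappingError([f"quad mapping #{i}: graph must be a constant IRI"])
            graph = g
        mappings.append(
            QuadMapping(
                table=qm["table"],
                subject=_parse_term_mapping(qm["subject"], classes, prefixes),
                predicate=_parse_term_mapping(qm["predicate"], classes, prefixes),
                object=_parse_term_mapping(qm["object"], classes, prefixes),
                graph=graph,
                condition=condition,
                label=qm.get("label", f"m{i}"),
            )
        )
    ms = MappingSet(schema, classes, mappings)
    return ms.validated()


def load_mapping_config(path) -> MappingSet:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_mapping_config(fh.read())
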