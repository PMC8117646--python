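"""RDF terms, quads, an indexed in-memory quad store, and N-Triples I/O.

The logical data model of the engine: every piece of information is a
subject-predicate-object triple, optionally qualified by a named graph
(a *quad*).  :class:`QuadStore` is a set-semantics container used as the
input of the reference SPARQL evaluator; it is deliberately naive — the
production path never materialises quads, it translates queries to SQL.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

# ---------------------------------------------------------------------------
# Well-known namespaces / datatypes

XSD = "http://www.w3.org/2001/XMLSchema#"
XSD_STRING = XSD + "string"
XSD_INTEGER = XSD + "integer"
XSD_DECIMAL = XSD + "decimal"
XSD_DOUBLE = XSD + "double"
XSD_FLOAT = XSD + "float"
XSD_BOOLEAN = XSD + "boolean"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDF_TYPE = RDF_NS + "type"
RDF_LANGSTRING = RDF_NS + "langString"

#: datatypes compared by numeric value in filters and joins
NUMERIC_DATATYPES = frozenset(
    {
        XSD_INTEGER,
        XSD_DECIMAL,
        XSD_DOUBLE,
        XSD_FLOAT,
        XSD + "int",
        XSD + "long",
        XSD + "short",
        XSD + "byte",
        XSD + "nonNegativeInteger",
        XSD + "positiveInteger",
        XSD + "unsignedInt",
        XSD + "unsignedLong",
    }
)


class RDFError(ValueError):
    """Malformed RDF term or quad."""


@dataclass(frozen=True, slots=True)
class IRI:
    """An absolute IRI."""

    value: str

    def __post_init__(self) -> None:
        if not self.value or ":" not in self.value:
            raise RDFError(f"not an absolute IRI: {self.value!r}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{self.value}>"


@dataclass(frozen=True, slots=True)
class Literal:
    """A typed (or language-tagged) literal.

    Plain literals carry ``xsd:string``; a language tag forces the
    ``rdf:langString`` datatype, mirroring RDF 1.1.
    """

    lexical: str
    datatype: str = XSD_STRING
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if self.language is not None:
            object.__setattr__(self, "datatype", RDF_LANGSTRING)
        elif self.datatype == RDF_LANGSTRING:
            raise RDFError("rdf:langString literal requires a language tag")
        if not self.datatype or ":" not in self.datatype:
            raise RDFError(f"literal datatype must be an absolute IRI: {self.datatype!r}")

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.language:
            return f'"{self.lexical}"@{self.language}'
        return f'"{self.lexical}"^^<{self.datatype}>'


@dataclass(frozen=True, slots=True)
class BlankNode:
    label: str


class _DefaultGraph:
    """Singleton marker for the default graph."""

    _instance: Optional["_DefaultGraph"] = None

    def __new__(cls) -> "_DefaultGraph":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "DEFAULT_GRAPH"


DEFAULT_GRAPH = _DefaultGraph()

Term = Union[IRI, Literal, BlankNode]
GraphName = Union[IRI, _DefaultGraph]


@dataclass(frozen=True, slots=True)
class Quad:
    subject: Union[IRI, BlankNode]
    predicate: IRI
    object: Term
    graph: GraphName = DEFAULT_GRAPH

    def __post_init__(self) -> None:
        if not isinstance(self.subject, (IRI, BlankNode)):
            raise RDFError(f"quad subject must be IRI or blank node, got {self.subject!r}")
        if not isinstance(self.predicate, IRI):
            raise RDFError(f"quad predicate must be an IRI, got {self.predicate!r}")
        if not isinstance(self.object, (IRI, Literal, BlankNode)):
            raise RDFError(f"quad object must be an RDF term, got {self.object!r}")

    @property
    def triple(self) -> tuple:
        return (self.subject, self.predicate, self.object)


def numeric_value(lit: Literal):
    """Numeric value of a literal, or ``None`` if it is not numeric."""
    if lit.datatype not in NUMERIC_DATATYPES:
        return None
    try:
        if lit.datatype in (XSD_DOUBLE, XSD_FLOAT, XSD_DECIMAL):
            return float(lit.lexical)
        return int(lit.lexical)
    except ValueError:
        try:
            return float(lit.lexical)
        except ValueError:
            return None


def float_lexical(x: float) -> str:
    """Canonical lexical form for values decoded from REAL columns.

    Doubles print at 12 significant digits so that sums computed in a
    different association order (SQL aggregate vs Python) decode to the
    same term.
    """
    return repr(float(f"{float(x):.12g}"))


def literal_from_sql(value, datatype: str) -> Literal:
    """Build a literal with a canonical lexical form from a SQL value."""
    if datatype == XSD_BOOLEAN:
        return Literal("true" if value else "false", XSD_BOOLEAN)
    if isinstance(value, bool):
        return Literal("true" if value else "false", XSD_BOOLEAN)
    if isinstance(value, float):
        return Literal(float_lexical(value), datatype)
    if isinstance(value, int):
        return Literal(str(value), datatype)
    return Literal(str(value), datatype)


# ---------------------------------------------------------------------------
# Quad store


class QuadStore:
    """In-memory quad set with a predicate index.

    Set semantics: adding a duplicate quad is a no-op.  ``match`` treats
    ``None`` as a wildcard in any position.
    """

    def __init__(self, quads: Iterable[Quad] = ()) -> None:
        self._quads: set[Quad] = set()
        self._by_predicate: dict[IRI, set[Quad]] = {}
        self._by_subject: dict[Union[IRI, BlankNode], set[Quad]] = {}
        for q in quads:
            self.add(q)

    def add(self, quad: Quad) -> None:
        if quad in self._quads:
            return
        self._quads.add(quad)
        self._by_predicate.setdefault(quad.predicate, set()).add(quad)
        self._by_subject.setdefault(quad.subject, set()).add(quad)

    def update(self, quads: Iterable[Quad]) -> None:
        for q in quads:
            self.add(q)

    def __len__(self) -> int:
        return len(self._quads)

    def __iter__(self) -> Iterator[Quad]:
        return iter(self._quads)

    def __contains__(self, quad: Quad) -> bool:
        return quad in self._quads

    def __eq__(self, other) -> bool:
        if not isinstance(other, QuadStore):
            return NotImplemented
        return self._quads == other._quads

    def match(
        self,
        subject=None,
        predicate=None,
        object=None,
        graph=None,
    ) -> set[Quad]:
        """Quads agreeing with every concrete (non-``None``) position."""
        if subject is not None:
            candidates = self._by_subject.get(subject, set())
        elif predicate is not None:
            candidates = self._by_predicate.get(predicate, set())
        else:
            candidates = self._quads
        out = set()
        for q in candidates:
            if predicate is not None and q.predicate != predicate:
                continue
            if object is not None and q.object != object:
                continue
            if graph is not None and q.graph != graph:
                continue
            out.add(q)
        return out


# ---------------------------------------------------------------------------
# N-Triples I/O


class NTriplesParseError(ValueError):
    def __init__(self, message: str, line: int) -> None:
        super().__init__(f"line {line}: {message}")
        self.line = line


_NT_ESCAPES = {
    "\\": "\\\\",
    '"': '\\"',
    "\n": "\\n",
    "\r": "\\r",
    "\t": "\\t",
}


def _nt_escape(s: str) -> str:
    out = []
    for ch in s:
        if ch in _NT_ESCAPES:
            out.append(_NT_ESCAPES[ch])
        elif ord(ch) < 0x20:
            out.append(f"\\u{ord(ch):04X}")
        else:
            out.append(ch)
    return "".join(out)


def format_term(term: Term) -> str:
    if isinstance(term, IRI):
        return f"<{term.value}>"
    if isinstance(term, BlankNode):
        return f"_:{term.label}"
    if isinstance(term, Literal):
        lex = _nt_escape(term.lexical)
        if term.language:
            return f'"{lex}"@{term.language}'
        if term.datatype == XSD_STRING:
            return f'"{lex}"'
        return f'"{lex}"^^<{term.datatype}>'
    raise RDFError(f"not an RDF term: {term!r}")


def write_ntriples(store: QuadStore, sink) -> None:
    """Serialize the default-graph content of ``store`` as N-Triples.

    Named graphs are outside the N-Triples model and raise an error.
    """
    lines = []
    for q in store:
        if q.graph is not DEFAULT_GRAPH:
            raise RDFError("N-Triples cannot express named graphs; use a quad format")
        lines.append(
            f"{format_term(q.subject)} {format_term(q.predicate)} {format_term(q.object)} ."
        )
    for line in sorted(lines):
        sink.write(line + "\n")


def _from_rdflib(node) -> Term:
    import rdflib

    if isinstance(node, rdflib.URIRef):
        return IRI(str(node))
    if isinstance(node, rdflib.BNode):
        return BlankNode(str(node))
    if isinstance(node, rdflib.Literal):
        if node.language:
            return Literal(str(node), language=str(node.language))
        dt = str(node.datatype) if node.datatype else XSD_STRING
        return Literal(str(node), dt)
    raise RDFError(f"unsupported rdflib node: {node!r}")


def read_ntriples(source) -> QuadStore:
    """Parse N-Triples from a text stream into a default-graph store.

    Parse errors carry the 1-based line number of the offending line.
    """
    from rdflib.plugins.parsers.ntriples import W3CNTriplesParser

    class _Sink:
        def __init__(self) -> None:
            self.triples: list[tuple] = []

        def triple(self, s, p, o) -> None:
            self.triples.append((s, p, o))

    store = QuadStore()
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        sink = _Sink()
        parser = W3CNTriplesParser(sink)
        try:
            parser.parsestring(raw if raw.endswith("\n") else raw + "\n")
        except Exception as exc:
            raise NTriplesParseError(str(exc), lineno) from exc
        for s, p, o in sink.triples:
            store.add(Quad(_from_rdflib(s), _from_rdflib(p), _from_rdflib(o)))
    return store


# ---------------------------------------------------------------------------
# Solution multisets (shared result contract of oracle and SQL engine)


UNBOUND = None


@dataclass
class SolutionMultiset:
    """A SPARQL solution multiset.

    ``rows`` is a list of dicts binding a subset of ``variables`` to terms;
    a missing/``None`` entry is an unbound variable.  Equality is
    order-insensitive multiset equality over (variable, term) rows; ordered
    results should be compared with :func:`solutions_equal` which also
    verifies sortedness when a comparator is given.
    """

    variables: list[str]
    rows: list[dict] = field(default_factory=list)

    def key_counter(self):
        from collections import Counter

        return Counter(
            tuple(r.get(v) for v in self.variables) for r in self.rows
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SolutionMultiset):
            return NotImplemented
        return (
            self.variables == other.variables
            and self.key_counter() == other.key_counter()
        )

    def __len__(self) -> int:
        return len(self.rows)


def solutions_equal(a: SolutionMultiset, b: SolutionMultiset, order_cmp=None) -> bool:
    """Multiset equality; with ``order_cmp`` additionally require both row
    sequences to be non-decreasing under the comparator (ties free)."""
    if a != b:
        return False
    if order_cmp is not None:
        for seq in (a.rows, b.rows):
            for i in range(len(seq) - 1):
                if order_cmp(seq[i], seq[i + 1]) > 0:
                    return False
    return True


def first_difference(a: SolutionMultiset, b: SolutionMultiset):
    """First (row, count-in-a, count-in-b) differing between the multisets."""
    ca, cb = a.key_counter(), b.key_counter()
    for key in sorted(set(ca) | set(cb), key=repr):
        if ca.get(key, 0) != cb.get(key, 0):
            return dict(zip(a.variables, key)), ca.get(key, 0), cb.get(key, 0)
    return None
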