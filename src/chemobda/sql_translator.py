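"""SPARQL-to-SQL translation with semantic optimization.

For every triple pattern the translator determines which quad mappings can
generate matching triples (*candidate selection*), turns each candidate
into a base-table fragment, and combines fragments according to the SPARQL
algebra: shared variables become join equalities on the underlying key
columns (annotated with their IRI classes), OPTIONAL becomes a left join,
UNION a union-all, MINUS/NOT EXISTS anti-joins, FILTER a selection and
aggregates a grouped query.  Schema constraints then drive three
optimizations, applied to a fixpoint:

1. *self-join merge* — two fragments of the same table joined on its full
   primary key are the same row and collapse into one fragment;
2. *foreign-key join elimination* — a fragment reachable only through a
   foreign-key→primary-key equality that exports nothing beyond the joined
   key is dropped (an IS NOT NULL filter survives when the FK columns are
   nullable);
3. *empty-relation propagation* — branches made unsatisfiable by IRI-class
   disjointness or contradictory constants are removed.

Rendering is deterministic: the same plan always produces the same SQL
text, so translation reports can be re-derived from the rendering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .rdf_core import (
    IRI,
    Literal,
    NUMERIC_DATATYPES,
    XSD_BOOLEAN,
    XSD_DOUBLE,
    XSD_INTEGER,
    XSD_STRING,
    float_lexical,
    literal_from_sql,
)
from .mapping_model import (
    ColumnIRI,
    ColumnLiteral,
    ConstantIRI,
    ConstantLiteral,
    IRIClass,
    MappingSet,
    QuadMapping,
    TableDecl,
)
from .sparql_frontend import (
    Aggregate,
    Arith,
    BGP,
    BoundExpr,
    Comparison,
    ConstExpr,
    Expr,
    Filter,
    GroupPattern,
    InExpr,
    IsIRIExpr,
    JoinPattern,
    LogicalAnd,
    LogicalNot,
    LogicalOr,
    MinusPattern,
    NotExistsExpr,
    OptionalPattern,
    QueryAST,
    TriplePattern,
    UnionPattern,
    UnsupportedFeatureError,
    ValuesPattern,
    Var,
)

# ---------------------------------------------------------------------------
# Variable annotations


@dataclass(frozen=True)
class ClassAnn:
    """Variable ranges over IRIs of one class; value is the key tuple."""

    cls: IRIClass

    @property
    def width(self) -> int:
        return len(self.cls.slots)


@dataclass(frozen=True)
class LitAnn:
    """Variable ranges over literals of one datatype (single column)."""

    datatype: str
    language: Optional[str] = None

    @property
    def width(self) -> int:
        return 1


@dataclass(frozen=True)
class TextAnn:
    """Fallback: the variable is carried as one encoded-term text column.

    Encoding: ``I<iri>``, ``L<datatype> <lexical>``, ``G<lang> <lexical>``.
    Used when union arms disagree on a variable's annotation or for
    constant IRIs outside every declared class.
    """

    @property
    def width(self) -> int:
        return 1


Annotation = Union[ClassAnn, LitAnn, TextAnn]


def encode_term_text(term) -> str:
    if isinstance(term, IRI):
        return "I" + term.value
    if isinstance(term, Literal):
        if term.language:
            return f"G{term.language} {term.lexical}"
        return f"L{term.datatype} {term.lexical}"
    raise TypeError(f"cannot text-encode {term!r}")


def decode_term_text(text: str):
    if text.startswith("I"):
        return IRI(text[1:])
    if text.startswith("L"):
        dt, _, lex = text[1:].partition(" ")
        return Literal(lex, dt)
    if text.startswith("G"):
        lang, _, lex = text[1:].partition(" ")
        return Literal(lex, language=lang)
    raise ValueError(f"bad term encoding {text!r}")


# ---------------------------------------------------------------------------
# Branches: conjunctions of base-table fragments


@dataclass(frozen=True)
class ColRef:
    frag: int
    column: str


@dataclass(frozen=True)
class ConstPart:
    value: object  # SQL value (int/float/str/bool)


Part = Union[ColRef, ConstPart]


@dataclass(frozen=True)
class ValueSpec:
    ann: Annotation
    parts: tuple[Part, ...]


@dataclass
class Fragment:
    table: TableDecl
    constraints: dict[str, object] = field(default_factory=dict)
    notnull: set[str] = field(default_factory=set)


@dataclass
class Branch:
    """One conjunctive plan: an inner join of base-table fragments."""

    fragments: dict[int, Fragment] = field(default_factory=dict)
    bindings: dict[str, ValueSpec] = field(default_factory=dict)
    equalities: set[frozenset] = field(default_factory=set)  # of ColRef pairs
    filters: list[Expr] = field(default_factory=list)
    anti: list[tuple[str, GroupPattern]] = field(default_factory=list)  # minus|notexists
    empty: bool = False
    _next_id: int = 0

    def new_fragment(self, table: TableDecl) -> int:
        fid = self._next_id
        self._next_id += 1
        self.fragments[fid] = Fragment(table)
        return fid

    def constrain(self, ref: ColRef, value) -> None:
        frag = self.fragments[ref.frag]
        existing = frag.constraints.get(ref.column)
        if existing is not None and existing != value:
            self.empty = True
        frag.constraints[ref.column] = value
        frag.notnull.add(ref.column)

    def equate(self, a: ColRef, b: ColRef) -> None:
        if a != b:
            self.equalities.add(frozenset((a, b)))

    def bind(self, var: str, spec: ValueSpec) -> None:
        old = self.bindings.get(var)
        if old is None:
            self.bindings[var] = spec
            return
        self._unify(old, spec)

    def _unify(self, a: ValueSpec, b: ValueSpec) -> None:
        ok = True
        if isinstance(a.ann, ClassAnn) and isinstance(b.ann, ClassAnn):
            ok = a.ann.cls is b.ann.cls or a.ann.cls.template == b.ann.cls.template
        elif isinstance(a.ann, LitAnn) and isinstance(b.ann, LitAnn):
            ok = a.ann == b.ann
        elif isinstance(a.ann, TextAnn) or isinstance(b.ann, TextAnn):
            ok = self._unify_text(a, b)
            return
        else:
            ok = False  # IRI class vs literal: disjoint
        if not ok:
            self.empty = True
            return
        for pa, pb in zip(a.parts, b.parts):
            if isinstance(pa, ColRef) and isinstance(pb, ColRef):
                self.equate(pa, pb)
            elif isinstance(pa, ColRef) and isinstance(pb, ConstPart):
                self.constrain(pa, pb.value)
            elif isinstance(pa, ConstPart) and isinstance(pb, ColRef):
                self.constrain(pb, pa.value)
            elif pa != pb:
                self.empty = True

    def _unify_text(self, a: ValueSpec, b: ValueSpec) -> bool:
        # only constant TextAnn specs occur (unclassifiable constant IRIs)
        ta, tb = a, b
        if isinstance(tb.ann, TextAnn):
            ta, tb = tb, ta
        if not all(isinstance(p, ConstPart) for p in ta.parts):
            self.empty = True  # non-constant text join inside a branch: give up
            return True
        const_text = ta.parts[0].value
        if isinstance(tb.ann, TextAnn):
            if tb.parts[0] != ta.parts[0]:
                self.empty = True
        elif isinstance(tb.ann, ClassAnn):
            if not str(const_text).startswith("I"):
                self.empty = True
                return True
            values = tb.ann.cls.decode(str(const_text)[1:])
            if values is None:
                self.empty = True
                return True
            for part, v in zip(tb.parts, values):
                if isinstance(part, ColRef):
                    self.constrain(part, v)
                elif part.value != v:
                    self.empty = True
        else:
            self.empty = True
        return True

    def rename_refs(self, mapping: dict[ColRef, ColRef]) -> None:
        def rn(ref: ColRef) -> ColRef:
            return mapping.get(ref, ref)

        self.bindings = {
            v: ValueSpec(s.ann, tuple(rn(p) if isinstance(p, ColRef) else p for p in s.parts))
            for v, s in self.bindings.items()
        }
        new_eqs = set()
        for eq in self.equalities:
            pair = tuple(eq)
            a, b = rn(pair[0]), (rn(pair[1]) if len(pair) > 1 else rn(pair[0]))
            if a != b:
                new_eqs.add(frozenset((a, b)))
        self.equalities = new_eqs

    def clone(self) -> "Branch":
        br = Branch(
            fragments={
                fid: Fragment(f.table, dict(f.constraints), set(f.notnull))
                for fid, f in self.fragments.items()
            },
            bindings=dict(self.bindings),
            equalities=set(self.equalities),
            filters=list(self.filters),
            anti=list(self.anti),
            empty=self.empty,
        )
        br._next_id = self._next_id
        return br


# ---------------------------------------------------------------------------
# Plan tree


@dataclass
class BranchSet:
    branches: list[Branch]


@dataclass
class LeftJoinNode:
    left: "Plan"
    right: "Plan"
    condition: Optional[Expr] = None


@dataclass
class JoinNode:
    left: "Plan"
    right: "Plan"


@dataclass
class FilterNode:
    inner: "Plan"
    filters: list[Expr]
    anti: list[tuple[str, GroupPattern]] = field(default_factory=list)


Plan = Union[BranchSet, LeftJoinNode, JoinNode, FilterNode]


@dataclass
class SQLQuery:
    """Abstract SQL tree for a whole query, plus the AST-level modifiers."""

    ast: QueryAST
    plan: Plan
    mapping_set: MappingSet


@dataclass
class TranslationReport:
    candidates: list[tuple[str, list[str]]] = field(default_factory=list)
    base_tables_before: int = 0
    base_tables_after: int = 0
    joins_after: int = 0
    rewrites: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"base table references: {self.base_tables_before} -> {self.base_tables_after}",
            f"joins after optimization: {self.joins_after}",
        ]
        for pat, cands in self.candidates:
            lines.append(f"pattern {pat}: candidates [{', '.join(cands)}]")
        lines.extend(f"rewrite: {r}" for r in self.rewrites)
        return "\n".join(lines)


def count_fragments(plan: Plan) -> int:
    if isinstance(plan, BranchSet):
        return sum(len(b.fragments) for b in plan.branches)
    if isinstance(plan, (LeftJoinNode, JoinNode)):
        return count_fragments(plan.left) + count_fragments(plan.right)
    if isinstance(plan, FilterNode):
        return count_fragments(plan.inner)
    raise TypeError(plan)


def count_joins(plan: Plan) -> int:
    if isinstance(plan, BranchSet):
        return sum(max(len(b.fragments) - 1, 0) for b in plan.branches)
    if isinstance(plan, (LeftJoinNode, JoinNode)):
        return count_joins(plan.left) + count_joins(plan.right) + 1
    if isinstance(plan, FilterNode):
        return count_joins(plan.inner)
    raise TypeError(plan)


# ---------------------------------------------------------------------------
# Candidate selection


def _sql_value_for_literal(lit: Literal, column_type: str):
    """SQL value a constant literal corresponds to in a column, or None."""
    try:
        if column_type == "integer":
            if lit.datatype == XSD_BOOLEAN:
                return 1 if lit.lexical == "true" else 0
            return int(lit.lexical)
        if column_type == "real":
            return float(lit.lexical)
        if column_type == "boolean":
            return 1 if lit.lexical == "true" else 0
        return lit.lexical
    except ValueError:
        return None


def _literal_matches_mapping(lit: Literal, tm: ColumnLiteral) -> bool:
    if tm.language is not None:
        return lit.language == tm.language
    return lit.language is None and lit.datatype == tm.datatype


def candidate_mappings(pattern: TriplePattern, ms: MappingSet) -> list[QuadMapping]:
    """Quad mappings that can generate triples matched by the pattern."""
    out = []
    for qm in ms.quad_mappings:
        if qm.graph is not None:
            continue  # queries address the default graph
        if _pattern_compatible(pattern, qm):
            out.append(qm)
    return out


def _pattern_compatible(pattern: TriplePattern, qm: QuadMapping) -> bool:
    for pterm, tm in (
        (pattern.subject, qm.subject),
        (pattern.predicate, qm.predicate),
        (pattern.object, qm.object),
    ):
        if isinstance(pterm, Var):
            continue
        if isinstance(pterm, IRI):
            if isinstance(tm, ConstantIRI):
                if tm.iri != pterm:
                    return False
            elif isinstance(tm, ColumnIRI):
                if tm.iri_class.decode(pterm) is None:
                    return False
            else:
                return False
        elif isinstance(pterm, Literal):
            if isinstance(tm, ConstantLiteral):
                if tm.literal != pterm:
                    return False
            elif isinstance(tm, ColumnLiteral):
                if not _literal_matches_mapping(pterm, tm):
                    return False
            else:
                return False
        else:  # blank node in a pattern: mappings never generate them
            return False
    return True


# ---------------------------------------------------------------------------
# Translation


class TranslationError(ValueError):
    pass


def _spec_for_term(ms: MappingSet, tm, fid: int) -> ValueSpec:
    if isinstance(tm, ColumnIRI):
        return ValueSpec(
            ClassAnn(tm.iri_class), tuple(ColRef(fid, c) for c in tm.column_names)
        )
    if isinstance(tm, ColumnLiteral):
        return ValueSpec(LitAnn(tm.datatype, tm.language), (ColRef(fid, tm.column),))
    if isinstance(tm, ConstantIRI):
        hit = ms.classify_iri(tm.iri)
        if hit is not None:
            cls, values = hit
            return ValueSpec(ClassAnn(cls), tuple(ConstPart(v) for v in values))
        return ValueSpec(TextAnn(), (ConstPart(encode_term_text(tm.iri)),))
    if isinstance(tm, ConstantLiteral):
        lit = tm.literal
        if lit.language is None and lit.datatype in NUMERIC_DATATYPES | {
            XSD_STRING,
            XSD_BOOLEAN,
        }:
            if lit.datatype == XSD_BOOLEAN:
                value: object = 1 if lit.lexical == "true" else 0
            elif lit.datatype in (XSD_DOUBLE,):
                value = float(lit.lexical)
            elif lit.datatype in NUMERIC_DATATYPES:
                try:
                    value = int(lit.lexical)
                except ValueError:
                    value = float(lit.lexical)
            else:
                value = lit.lexical
            return ValueSpec(LitAnn(lit.datatype, None), (ConstPart(value),))
        return ValueSpec(TextAnn(), (ConstPart(encode_term_text(lit)),))
    raise TypeError(tm)


def _add_pattern_to_branch(
    branch: Branch, pattern: TriplePattern, qm: QuadMapping, ms: MappingSet
) -> None:
    table = ms.schema.table(qm.table)
    fid = branch.new_fragment(table)
    frag = branch.fragments[fid]
    for col, value in qm.condition:
        frag.constraints[col] = value
        frag.notnull.add(col)
    frag.notnull.update(qm.required_columns)
    for pterm, tm in (
        (pattern.subject, qm.subject),
        (pattern.predicate, qm.predicate),
        (pattern.object, qm.object),
    ):
        if isinstance(pterm, Var):
            branch.bind(pterm.name, _spec_for_term(ms, tm, fid))
            continue
        # constant pattern position: constrain the fragment
        if isinstance(tm, ColumnIRI):
            values = tm.iri_class.decode(pterm)  # pre-checked by candidates
            if values is None:
                branch.empty = True
                return
            for col, v in zip(tm.column_names, values):
                branch.constrain(ColRef(fid, col), v)
        elif isinstance(tm, ColumnLiteral):
            col = table.column(tm.column)
            v = _sql_value_for_literal(pterm, col.type)
            if v is None:
                branch.empty = True
                return
            branch.constrain(ColRef(fid, tm.column), v)
        # constant-vs-constant agreement was established by candidate selection


def _translate_bgp(patterns: tuple[TriplePattern, ...], ms: MappingSet, report) -> BranchSet:
    per_pattern: list[list[QuadMapping]] = []
    for tp in patterns:
        cands = candidate_mappings(tp, ms)
        if report is not None:
            report.candidates.append((_pattern_key(tp), [qm.describe() for qm in cands]))
        per_pattern.append(cands)
    branches: list[Branch] = []
    for choice in itertools.product(*per_pattern) if patterns else [()]:
        branch = Branch()
        for tp, qm in zip(patterns, choice):
            _add_pattern_to_branch(branch, tp, qm, ms)
            if branch.empty:
                break
        if not branch.empty:
            branches.append(branch)
    if not patterns:
        branches = [Branch()]
    return BranchSet(branches)


def _pattern_key(tp: TriplePattern) -> str:
    from .sparql_frontend import _term_text

    return f"{_term_text(tp.subject)} {_term_text(tp.predicate)} {_term_text(tp.object)}"


def _join_branchsets(a: BranchSet, b: BranchSet) -> BranchSet:
    out = []
    for ba, bb in itertools.product(a.branches, b.branches):
        merged = ba.clone()
        offset = merged._next_id
        # renumber bb's fragments into merged
        for fid, frag in bb.fragments.items():
            merged.fragments[fid + offset] = Fragment(
                frag.table, dict(frag.constraints), set(frag.notnull)
            )
        merged._next_id = offset + bb._next_id

        def shift(p: Part) -> Part:
            if isinstance(p, ColRef):
                return ColRef(p.frag + offset, p.column)
            return p

        for eq in bb.equalities:
            pair = tuple(eq)
            merged.equalities.add(frozenset(shift(r) for r in pair))
        for var, spec in bb.bindings.items():
            merged.bind(var, ValueSpec(spec.ann, tuple(shift(p) for p in spec.parts)))
        merged.filters.extend(bb.filters)
        merged.anti.extend(bb.anti)
        merged.empty = merged.empty or bb.empty
        if not merged.empty:
            out.append(merged)
    return BranchSet(out)


def _values_branchset(vp: ValuesPattern, ms: MappingSet) -> BranchSet:
    branches = []
    for row in vp.rows:
        br = Branch()
        for var, term in zip(vp.variables, row):
            if term is None:
                continue
            if isinstance(term, IRI):
                hit = ms.classify_iri(term)
                if hit is not None:
                    cls, values = hit
                    br.bind(var.name, ValueSpec(ClassAnn(cls), tuple(ConstPart(v) for v in values)))
                else:
                    br.bind(var.name, ValueSpec(TextAnn(), (ConstPart(encode_term_text(term)),)))
            elif isinstance(term, Literal):
                br.bind(var.name, _spec_for_term(ms, ConstantLiteral(term), -1))
            else:
                raise UnsupportedFeatureError("blank nodes in VALUES")
        branches.append(br)
    return BranchSet(branches)


def _translate_group(gp: GroupPattern, ms: MappingSet, report) -> Plan:
    if isinstance(gp, BGP):
        return _translate_bgp(gp.patterns, ms, report)
    if isinstance(gp, JoinPattern):
        left = _translate_group(gp.left, ms, report)
        right = _translate_group(gp.right, ms, report)
        if isinstance(left, BranchSet) and isinstance(right, BranchSet):
            return _join_branchsets(left, right)
        return JoinNode(left, right)
    if isinstance(gp, Filter):
        inner = _translate_group(gp.inner, ms, report)
        if isinstance(gp.expr, NotExistsExpr):
            if report is not None:
                _collect_candidates(gp.expr.pattern, ms, report)
            if isinstance(inner, BranchSet):
                for br in inner.branches:
                    br.anti.append(("notexists", gp.expr.pattern))
                return inner
            return FilterNode(inner, [], [("notexists", gp.expr.pattern)])
        if isinstance(inner, BranchSet):
            for br in inner.branches:
                br.filters.append(gp.expr)
            return inner
        return FilterNode(inner, [gp.expr])
    if isinstance(gp, OptionalPattern):
        return LeftJoinNode(
            _translate_group(gp.left, ms, report),
            _translate_group(gp.right, ms, report),
            gp.condition,
        )
    if isinstance(gp, UnionPattern):
        left = _translate_group(gp.left, ms, report)
        right = _translate_group(gp.right, ms, report)
        if isinstance(left, BranchSet) and isinstance(right, BranchSet):
            return BranchSet(left.branches + right.branches)
        raise UnsupportedFeatureError("UNION over non-conjunctive operands")
    if isinstance(gp, MinusPattern):
        inner = _translate_group(gp.left, ms, report)
        if report is not None:
            _collect_candidates(gp.right, ms, report)
        if isinstance(inner, BranchSet):
            for br in inner.branches:
                br.anti.append(("minus", gp.right))
            return inner
        return FilterNode(inner, [], [("minus", gp.right)])
    if isinstance(gp, ValuesPattern):
        return _values_branchset(gp, ms)
    raise UnsupportedFeatureError(f"pattern {type(gp).__name__}")


def _collect_candidates(gp: GroupPattern, ms: MappingSet, report) -> None:
    """Record candidate mappings for patterns nested in MINUS/NOT EXISTS."""
    if isinstance(gp, BGP):
        for tp in gp.patterns:
            report.candidates.append(
                (_pattern_key(tp), [qm.describe() for qm in candidate_mappings(tp, ms)])
            )
    elif isinstance(gp, Filter):
        _collect_candidates(gp.inner, ms, report)
    elif isinstance(gp, (JoinPattern, OptionalPattern, UnionPattern, MinusPattern)):
        _collect_candidates(gp.left, ms, report)
        _collect_candidates(gp.right, ms, report)


def translate(ast: QueryAST, ms: MappingSet) -> tuple[SQLQuery, TranslationReport]:
    """Translate a query into an (unoptimized) abstract SQL tree."""
    report = TranslationReport()
    plan = _translate_group(ast.pattern, ms, report)
    report.base_tables_before = count_fragments(plan)
    report.base_tables_after = report.base_tables_before
    report.joins_after = count_joins(plan)
    return SQLQuery(ast, plan, ms), report


# ---------------------------------------------------------------------------
# Optimization


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _equality_classes(branch: Branch) -> _UnionFind:
    uf = _UnionFind()
    for eq in branch.equalities:
        pair = tuple(eq)
        if len(pair) == 2:
            uf.union(pair[0], pair[1])
    return uf


def _try_self_join_merge(branch: Branch, report: Optional[TranslationReport]) -> bool:
    uf = _equality_classes(branch)
    fids = sorted(branch.fragments)
    for i, fa in enumerate(fids):
        for fb in fids[i + 1 :]:
            a, b = branch.fragments[fa], branch.fragments[fb]
            if a.table.name != b.table.name or not a.table.primary_key:
                continue
            if all(
                uf.find(ColRef(fa, c)) == uf.find(ColRef(fb, c))
                for c in a.table.primary_key
            ):
                _merge_fragments(branch, fa, fb)
                if report is not None:
                    report.rewrites.append(
                        f"self-join merge on {a.table.name} (full primary key)"
                    )
                return True
    return False


def _merge_fragments(branch: Branch, keep: int, drop: int) -> None:
    a, b = branch.fragments[keep], branch.fragments[drop]
    for col, v in b.constraints.items():
        if col in a.constraints and a.constraints[col] != v:
            branch.empty = True
        a.constraints[col] = v
    a.notnull.update(b.notnull)
    mapping = {ColRef(drop, c.name): ColRef(keep, c.name) for c in b.table.columns}
    branch.rename_refs(mapping)
    del branch.fragments[drop]


def _filter_vars(expr: Expr) -> set[str]:
    out: set[str] = set()

    def walk(e) -> None:
        if isinstance(e, Var):
            out.add(e.name)
            return
        if isinstance(e, BoundExpr):
            out.add(e.var.name)
            return
        if isinstance(e, NotExistsExpr):
            from .sparql_frontend import pattern_variables

            out.update(v.name for v in pattern_variables(e.pattern))
            return
        for attr in ("left", "right", "arg"):
            sub = getattr(e, attr, None)
            if sub is not None and not isinstance(sub, str):
                walk(sub)
        if isinstance(e, InExpr):
            for o in e.options:
                walk(o)

    walk(expr)
    return out


def _try_fk_elimination(branch: Branch, report: Optional[TranslationReport]) -> bool:
    from .sparql_frontend import pattern_variables

    # variables an outer construct may still need: every bound variable is
    # considered exported (projection pruning is not attempted), so a
    # fragment is removable only if its bindings can be re-expressed on the
    # referencing fragment's FK columns.
    for fid in sorted(branch.fragments):
        frag = branch.fragments[fid]
        pk = tuple(frag.table.primary_key)
        if not pk:
            continue
        if any(c not in pk for c in frag.constraints):
            continue
        if any(c not in pk for c in frag.notnull):
            continue
        # collect equalities touching this fragment
        touching = [eq for eq in branch.equalities if any(r.frag == fid for r in eq)]
        partners: dict[int, dict[str, str]] = {}  # other fid -> {pk col: other col}
        ok = True
        for eq in touching:
            pair = tuple(eq)
            mine = [r for r in pair if r.frag == fid]
            other = [r for r in pair if r.frag != fid]
            if len(mine) != 1 or len(other) != 1:
                ok = False
                break
            partners.setdefault(other[0].frag, {})[mine[0].column] = other[0].column
        if not ok or len(partners) != 1:
            continue
        (gid, colmap), = partners.items()
        gfrag = branch.fragments[gid]
        # the equality set must be exactly an FK of g referencing this table's PK
        fk = next(
            (
                fk
                for fk in gfrag.table.foreign_keys
                if fk.ref_table == frag.table.name
                and set(fk.ref_columns) == set(colmap)
                and all(colmap[rc] == c for c, rc in zip(fk.columns, fk.ref_columns))
            ),
            None,
        )
        if fk is None or set(colmap) != set(pk):
            continue
        # rebind anything referencing this fragment onto g's FK columns
        mapping = {
            ColRef(fid, rc): ColRef(gid, c) for c, rc in zip(fk.columns, fk.ref_columns)
        }
        if any(
            isinstance(p, ColRef) and p.frag == fid and p not in mapping
            for spec in branch.bindings.values()
            for p in spec.parts
        ):
            continue  # exports a non-key column: not removable
        for c, v in frag.constraints.items():
            branch.constrain(mapping[ColRef(fid, c)], v)
        branch.rename_refs(mapping)
        for c, rc in zip(fk.columns, fk.ref_columns):
            col = gfrag.table.column(c)
            if col is not None and not col.notnull:
                gfrag.notnull.add(c)
        del branch.fragments[fid]
        if report is not None:
            report.rewrites.append(
                f"foreign-key join elimination of {frag.table.name} via {gfrag.table.name}"
            )
        return True
    return False


def optimize(q: SQLQuery, ms: Optional[MappingSet] = None, report: Optional[TranslationReport] = None) -> SQLQuery:
    """Apply self-join merge, FK join elimination and empty-relation
    propagation to a fixpoint; the result multiset is unchanged."""
    ms = ms or q.mapping_set

    def opt_plan(plan: Plan) -> Plan:
        if isinstance(plan, BranchSet):
            kept = []
            for br in plan.branches:
                br = br.clone()
                for _ in range(len(br.fragments) + 1):
                    changed = _try_self_join_merge(br, report)
                    if not changed:
                        changed = _try_fk_elimination(br, report)
                    if br.empty or not changed:
                        break
                if not br.empty:
                    kept.append(br)
                elif report is not None:
                    report.rewrites.append("empty-relation propagation: branch removed")
            return BranchSet(kept)
        if isinstance(plan, LeftJoinNode):
            return LeftJoinNode(opt_plan(plan.left), opt_plan(plan.right), plan.condition)
        if isinstance(plan, JoinNode):
            return JoinNode(opt_plan(plan.left), opt_plan(plan.right))
        if isinstance(plan, FilterNode):
            return FilterNode(opt_plan(plan.inner), plan.filters, plan.anti)
        raise TypeError(plan)

    new_plan = opt_plan(q.plan)
    if report is not None:
        report.base_tables_after = count_fragments(new_plan)
        report.joins_after = count_joins(new_plan)
    return SQLQuery(q.ast, new_plan, ms)


# rendering lives in sql_render; re-exported here as part of the module API
from .sql_render import CompiledQuery, compile_query, render_sql  # noqa: E402,F401
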