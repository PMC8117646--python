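"""Deterministic SQL rendering of translated query plans.

Every plan node renders to a SELECT whose output columns are determined by
a *target signature*: for each exported variable either the raw key/value
columns (when all union arms agree on the variable's annotation) or a
single encoded-term text column (the general fallback).  SPARQL expression
errors map onto SQL NULL, so SQL's three-valued logic reproduces SPARQL's
error-elimination semantics in WHERE clauses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .rdf_core import (
    IRI,
    Literal,
    NUMERIC_DATATYPES,
    XSD_BOOLEAN,
    XSD_DOUBLE,
    XSD_INTEGER,
    XSD_STRING,
    literal_from_sql,
)
from .mapping_model import IRIClass, MappingSet, Slot
from .sparql_frontend import (
    Aggregate,
    Arith,
    BoundExpr,
    Comparison,
    ConstExpr,
    Expr,
    InExpr,
    IsIRIExpr,
    LogicalAnd,
    LogicalNot,
    LogicalOr,
    NotExistsExpr,
    QueryAST,
    UnsupportedFeatureError,
    Var,
    pattern_variables,
)
from .sql_translator import (
    Annotation,
    Branch,
    BranchSet,
    ClassAnn,
    ColRef,
    ConstPart,
    FilterNode,
    JoinNode,
    LeftJoinNode,
    LitAnn,
    Plan,
    SQLQuery,
    TextAnn,
    TranslationReport,
    ValueSpec,
    _translate_group,
    decode_term_text,
    encode_term_text,
    optimize,
    translate,
)


def _q(ident: str) -> str:
    return '"' + ident.replace('"', '""') + '"'


def _sql_literal(value) -> str:
    if value is None:
        return "NULL"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (int, float)):
        return repr(value)
    return "'" + str(value).replace("'", "''") + "'"


def _ann_eq(a: Annotation, b: Annotation) -> bool:
    if isinstance(a, ClassAnn) and isinstance(b, ClassAnn):
        return a.cls.template == b.cls.template
    return a == b


def _col(var: str, i: int) -> str:
    return f"{var}__{i}"


# ---------------------------------------------------------------------------
# Signatures


def plan_signature(plan: Plan) -> dict[str, Annotation]:
    if isinstance(plan, BranchSet):
        sig: dict[str, Annotation] = {}
        for br in plan.branches:
            for var, spec in br.bindings.items():
                if var not in sig:
                    sig[var] = spec.ann
                elif not _ann_eq(sig[var], spec.ann):
                    sig[var] = TextAnn()
        return sig
    if isinstance(plan, (LeftJoinNode, JoinNode)):
        sig = plan_signature(plan.left)
        for var, ann in plan_signature(plan.right).items():
            if var not in sig:
                sig[var] = ann
            elif not _ann_eq(sig[var], ann):
                sig[var] = TextAnn()
        return sig
    if isinstance(plan, FilterNode):
        return plan_signature(plan.inner)
    raise TypeError(plan)


# ---------------------------------------------------------------------------
# Compiled expression values


@dataclass
class CVal:
    kind: str  # num | str | bool | lang | iri | text | err
    parts: list[str]
    ann: Optional[Annotation] = None

    @property
    def sql(self) -> str:
        return self.parts[0]


_ERR = CVal("err", ["NULL"])


class Renderer:
    def __init__(self, ms: MappingSet) -> None:
        self.ms = ms
        self._alias = 0

    def alias(self) -> str:
        self._alias += 1
        return f"t{self._alias}"

    # -- plan rendering -----------------------------------------------------

    def render_plan(self, plan: Plan, target: dict[str, Annotation]) -> str:
        if isinstance(plan, BranchSet):
            if not plan.branches:
                return self._render_empty(target)
            arms = [self._render_branch(br, target) for br in plan.branches]
            return " UNION ALL ".join(arms)
        if isinstance(plan, LeftJoinNode):
            return self._render_join(plan, target, left_join=True)
        if isinstance(plan, JoinNode):
            return self._render_join(plan, target, left_join=False)
        if isinstance(plan, FilterNode):
            return self._render_filter_node(plan, target)
        raise TypeError(plan)

    def _select_list(self, exprs: dict[str, list[str]], target) -> str:
        items = []
        for var in sorted(target):
            for i, e in enumerate(exprs[var]):
                items.append(f"{e} AS {_q(_col(var, i))}")
        return ", ".join(items) if items else "1 AS one"

    def _render_empty(self, target: dict[str, Annotation]) -> str:
        exprs = {var: ["NULL"] * target[var].width for var in target}
        return f"SELECT {self._select_list(exprs, target)} WHERE 0"

    def _branch_env(self, br: Branch, aliases: dict[int, str]) -> dict[str, CVal]:
        env = {}
        for var, spec in br.bindings.items():
            env[var] = self._spec_cval(spec, aliases)
        return env

    def _part_sql(self, p, aliases) -> str:
        if isinstance(p, ColRef):
            return f"{aliases[p.frag]}.{_q(p.column)}"
        return _sql_literal(p.value)

    def _spec_cval(self, spec: ValueSpec, aliases) -> CVal:
        parts = [self._part_sql(p, aliases) for p in spec.parts]
        ann = spec.ann
        if isinstance(ann, ClassAnn):
            return CVal("iri", parts, ann)
        if isinstance(ann, TextAnn):
            return CVal("text", parts, ann)
        if ann.language is not None:
            return CVal("lang", parts, ann)
        if ann.datatype == XSD_BOOLEAN:
            return CVal("bool", parts, ann)
        if ann.datatype in NUMERIC_DATATYPES:
            return CVal("num", parts, ann)
        return CVal("str", parts, ann)

    def _encode_sql(self, cval: CVal) -> str:
        """Render a value as its encoded-term text expression."""
        ann = cval.ann
        if isinstance(ann, TextAnn) or ann is None:
            return cval.sql
        if isinstance(ann, ClassAnn):
            pieces = ["'I'"]
            pi = 0
            for part in ann.cls.parts:
                if isinstance(part, Slot):
                    expr = cval.parts[pi]
                    pi += 1
                    if part.type == "integer":
                        pieces.append(f"CAST({expr} AS TEXT)")
                    else:
                        pieces.append(expr)
                else:
                    pieces.append(_sql_literal(part))
            concat = " || ".join(pieces)
            return f"CASE WHEN {cval.parts[0]} IS NOT NULL THEN {concat} END"
        if ann.language is not None:
            return f"CASE WHEN {cval.sql} IS NOT NULL THEN 'G{ann.language} ' || {cval.sql} END"
        if ann.datatype == XSD_BOOLEAN:
            t = _sql_literal(f"L{XSD_BOOLEAN} true")
            f = _sql_literal(f"L{XSD_BOOLEAN} false")
            return f"CASE WHEN {cval.sql} IS NULL THEN NULL WHEN {cval.sql} THEN {t} ELSE {f} END"
        prefix = _sql_literal(f"L{ann.datatype} ")
        return f"CASE WHEN {cval.sql} IS NOT NULL THEN {prefix} || CAST({cval.sql} AS TEXT) END"

    def _render_branch(self, br: Branch, target: dict[str, Annotation]) -> str:
        aliases = {fid: self.alias() for fid in sorted(br.fragments)}
        env = self._branch_env(br, aliases)
        exprs: dict[str, list[str]] = {}
        for var in sorted(target):
            ann_t = target[var]
            cval = env.get(var)
            if cval is None:
                exprs[var] = ["NULL"] * ann_t.width
            elif _ann_eq(cval.ann, ann_t):
                exprs[var] = list(cval.parts)
            else:
                exprs[var] = [self._encode_sql(cval)]
        where: list[str] = []
        for fid in sorted(br.fragments):
            frag = br.fragments[fid]
            a = aliases[fid]
            for col in sorted(frag.constraints):
                where.append(f"{a}.{_q(col)} = {_sql_literal(frag.constraints[col])}")
            for col in sorted(frag.notnull):
                decl = frag.table.column(col)
                if col in frag.constraints:
                    continue
                if decl is not None and decl.notnull:
                    continue
                where.append(f"{a}.{_q(col)} IS NOT NULL")
        for eq in sorted(
            (sorted(pair, key=lambda r: (r.frag, r.column)) for pair in br.equalities),
            key=lambda p: (p[0].frag, p[0].column, p[-1].frag, p[-1].column),
        ):
            if len(eq) == 2:
                where.append(
                    f"{self._part_sql(eq[0], aliases)} = {self._part_sql(eq[1], aliases)}"
                )
        for f in br.filters:
            where.append(self.compile_bool(f, env))
        for kind, pattern in br.anti:
            clause = self._anti_sql(kind, pattern, env)
            if clause:
                where.append(clause)
        from_clause = ", ".join(
            f"{_q(br.fragments[fid].table.name)} AS {aliases[fid]}" for fid in sorted(br.fragments)
        )
        sql = f"SELECT {self._select_list(exprs, target)}"
        if from_clause:
            sql += f" FROM {from_clause}"
        if where:
            sql += " WHERE " + " AND ".join(where)
        return sql

    def _render_join(self, node, target, left_join: bool) -> str:
        lsig = plan_signature(node.left)
        rsig = plan_signature(node.right)
        shared = sorted(set(lsig) & set(rsig))
        # unify shared annotations between the two sides
        for v in shared:
            if not _ann_eq(lsig[v], rsig[v]):
                lsig[v] = rsig[v] = TextAnn()
        for v, ann in target.items():
            if v in lsig and not _ann_eq(lsig[v], ann) and v not in shared:
                lsig[v] = ann
            if v in rsig and not _ann_eq(rsig[v], ann) and v not in shared:
                rsig[v] = ann
        ltarget = {v: lsig[v] for v in lsig if v in target or v in shared}
        rtarget = {v: rsig[v] for v in rsig if v in target or v in shared}
        lsql = self.render_plan(node.left, ltarget)
        rsql = self.render_plan(node.right, rtarget)
        la, ra = self.alias(), self.alias()
        conds = []
        for v in shared:
            for i in range(ltarget[v].width):
                conds.append(f"{la}.{_q(_col(v, i))} = {ra}.{_q(_col(v, i))}")
        if left_join and getattr(node, "condition", None) is not None:
            env = {}
            for v, ann in ltarget.items():
                env[v] = self._alias_cval(la, v, ann)
            for v, ann in rtarget.items():
                if v not in env:
                    env[v] = self._alias_cval(ra, v, ann)
            conds.append(self.compile_bool(node.condition, env))
        on = " AND ".join(conds) if conds else "1"
        exprs: dict[str, list[str]] = {}
        for var in sorted(target):
            src = None
            if var in ltarget:
                src = (la, ltarget[var])
            elif var in rtarget:
                src = (ra, rtarget[var])
            if src is None:
                exprs[var] = ["NULL"] * target[var].width
            else:
                alias, ann = src
                cval = self._alias_cval(alias, var, ann)
                if _ann_eq(ann, target[var]):
                    exprs[var] = list(cval.parts)
                else:
                    exprs[var] = [self._encode_sql(cval)]
        join_kw = "LEFT JOIN" if left_join else "JOIN"
        return (
            f"SELECT {self._select_list(exprs, target)} "
            f"FROM ({lsql}) AS {la} {join_kw} ({rsql}) AS {ra} ON {on}"
        )

    def _alias_cval(self, alias: str, var: str, ann: Annotation) -> CVal:
        parts = [f"{alias}.{_q(_col(var, i))}" for i in range(ann.width)]
        return self._spec_cval_from_parts(parts, ann)

    def _spec_cval_from_parts(self, parts: list[str], ann) -> CVal:
        if isinstance(ann, ClassAnn):
            return CVal("iri", parts, ann)
        if isinstance(ann, TextAnn):
            return CVal("text", parts, ann)
        if isinstance(ann, NumAnn):
            return CVal("num", parts, ann)
        if ann.language is not None:
            return CVal("lang", parts, ann)
        if ann.datatype == XSD_BOOLEAN:
            return CVal("bool", parts, ann)
        if ann.datatype in NUMERIC_DATATYPES:
            return CVal("num", parts, ann)
        return CVal("str", parts, ann)

    def _render_filter_node(self, node: FilterNode, target) -> str:
        inner_sig = plan_signature(node.inner)
        itarget = dict(target)
        for v in _expr_vars_of(node):
            if v in inner_sig and v not in itarget:
                itarget[v] = inner_sig[v]
        isql = self.render_plan(node.inner, itarget)
        a = self.alias()
        env = {v: self._alias_cval(a, v, ann) for v, ann in itarget.items()}
        where = [self.compile_bool(f, env) for f in node.filters]
        for kind, pattern in node.anti:
            clause = self._anti_sql(kind, pattern, env)
            if clause:
                where.append(clause)
        exprs = {}
        for var in sorted(target):
            if var in itarget:
                exprs[var] = list(self._alias_cval(a, var, itarget[var]).parts)
            else:
                exprs[var] = ["NULL"] * target[var].width
        sql = f"SELECT {self._select_list(exprs, target)} FROM ({isql}) AS {a}"
        if where:
            sql += " WHERE " + " AND ".join(where)
        return sql

    # -- anti joins (MINUS / NOT EXISTS) ------------------------------------

    def _anti_sql(self, kind: str, pattern, env: dict[str, CVal]) -> Optional[str]:
        sub = _translate_group(pattern, self.ms, None)
        sub = _optimize_plan_for_render(sub)
        sub_sig = plan_signature(sub)
        shared = sorted(v for v in sub_sig if v in env)
        if kind == "minus" and not shared:
            return None  # MINUS with disjoint domains keeps every row
        target: dict[str, Annotation] = {}
        outer: dict[str, CVal] = {}
        for v in shared:
            ocv = env[v]
            if _ann_eq(ocv.ann, sub_sig[v]):
                target[v] = sub_sig[v]
                outer[v] = ocv
            else:
                target[v] = TextAnn()
                outer[v] = CVal("text", [self._encode_sql(ocv)], TextAnn())
        sub_sql = self.render_plan(sub, target)
        s = self.alias()
        conds = []
        overlap = []
        for v in shared:
            width = target[v].width
            for i in range(width):
                oexpr = outer[v].parts[i]
                sexpr = f"{s}.{_q(_col(v, i))}"
                if kind == "minus":
                    conds.append(f"({oexpr} IS NULL OR {sexpr} IS NULL OR {sexpr} = {oexpr})")
                else:
                    conds.append(f"({oexpr} IS NULL OR {sexpr} = {oexpr})")
            overlap.append(
                f"({outer[v].parts[0]} IS NOT NULL AND {s}.{_q(_col(v, 0))} IS NOT NULL)"
            )
        if kind == "minus":
            conds.append("(" + " OR ".join(overlap) + ")")
        where = " WHERE " + " AND ".join(conds) if conds else ""
        return f"NOT EXISTS (SELECT 1 FROM ({sub_sql}) AS {s}{where})"

    # -- expression compilation ---------------------------------------------

    def compile_bool(self, expr: Expr, env: dict[str, CVal]) -> str:
        v = self.compile_value(expr, env)
        return self._ebv(v)

    def _ebv(self, v: CVal) -> str:
        if v.kind == "bool":
            return f"({v.sql})"
        if v.kind == "num":
            return f"(({v.sql}) <> 0)"
        if v.kind in ("str", "lang"):
            return f"(LENGTH({v.sql}) > 0)"
        return "NULL"

    def compile_value(self, expr: Expr, env: dict[str, CVal]) -> CVal:
        if isinstance(expr, Var):
            return env.get(expr.name, _ERR)
        if isinstance(expr, ConstExpr):
            return self._const_cval(expr.term)
        if isinstance(expr, Comparison):
            return self._compile_comparison(expr, env)
        if isinstance(expr, LogicalAnd):
            l, r = self.compile_bool(expr.left, env), self.compile_bool(expr.right, env)
            return CVal("bool", [f"({l} AND {r})"])
        if isinstance(expr, LogicalOr):
            l, r = self.compile_bool(expr.left, env), self.compile_bool(expr.right, env)
            return CVal("bool", [f"({l} OR {r})"])
        if isinstance(expr, LogicalNot):
            return CVal("bool", [f"(NOT {self.compile_bool(expr.arg, env)})"])
        if isinstance(expr, Arith):
            l = self.compile_value(expr.left, env)
            r = self.compile_value(expr.right, env)
            if l.kind != "num" or r.kind != "num":
                return _ERR
            if expr.op == "/":
                return CVal("num", [f"(CAST({l.sql} AS REAL) / ({r.sql}))"])
            return CVal("num", [f"(({l.sql}) {expr.op} ({r.sql}))"])
        if isinstance(expr, InExpr):
            arg = self.compile_value(expr.arg, env)
            comps = []
            for opt in expr.options:
                c = self._compile_eq(arg, self.compile_value(opt, env), "=")
                if c.kind != "err":
                    comps.append(self._ebv(c))
            if not comps:
                body = "0"
            else:
                body = f"COALESCE(({' OR '.join(comps)}), 0)"
            if expr.negated:
                body = f"(NOT {body})"
            return CVal("bool", [body])
        if isinstance(expr, BoundExpr):
            cv = env.get(expr.var.name)
            if cv is None:
                return CVal("bool", ["0"])
            return CVal("bool", [f"({cv.parts[0]} IS NOT NULL)"])
        if isinstance(expr, IsIRIExpr):
            arg = self.compile_value(expr.arg, env)
            if arg.kind == "iri":
                return CVal("bool", [f"CASE WHEN {arg.parts[0]} IS NOT NULL THEN 1 END"])
            if arg.kind == "text":
                return CVal(
                    "bool",
                    [
                        f"CASE WHEN {arg.sql} IS NULL THEN NULL "
                        f"WHEN SUBSTR({arg.sql}, 1, 1) = 'I' THEN 1 ELSE 0 END"
                    ],
                )
            if arg.kind == "err":
                return _ERR
            return CVal("bool", [f"CASE WHEN {arg.sql} IS NOT NULL THEN 0 END"])
        if isinstance(expr, NotExistsExpr):
            clause = self._anti_sql("notexists", expr.pattern, env)
            return CVal("bool", [clause if clause else "1"])
        if isinstance(expr, Aggregate):
            return _ERR  # aggregates are compiled by the aggregation node
        raise UnsupportedFeatureError(f"expression {type(expr).__name__}")

    def _const_cval(self, term) -> CVal:
        if isinstance(term, IRI):
            hit = self.ms.classify_iri(term)
            if hit is not None:
                cls, values = hit
                return CVal("iri", [_sql_literal(v) for v in values], ClassAnn(cls))
            return CVal("text", [_sql_literal(encode_term_text(term))], TextAnn())
        if isinstance(term, Literal):
            if term.language is not None:
                return CVal("lang", [_sql_literal(term.lexical)], LitAnn(term.datatype, term.language))
            if term.datatype == XSD_BOOLEAN:
                return CVal("bool", [_sql_literal(term.lexical == "true")], LitAnn(XSD_BOOLEAN))
            if term.datatype in NUMERIC_DATATYPES:
                try:
                    value = int(term.lexical)
                except ValueError:
                    value = float(term.lexical)
                return CVal("num", [_sql_literal(value)], LitAnn(term.datatype))
            if term.datatype == XSD_STRING:
                return CVal("str", [_sql_literal(term.lexical)], LitAnn(XSD_STRING))
            return CVal("text", [_sql_literal(encode_term_text(term))], TextAnn())
        return _ERR

    def _compile_comparison(self, expr: Comparison, env) -> CVal:
        l = self.compile_value(expr.left, env)
        r = self.compile_value(expr.right, env)
        if expr.op in ("=", "!="):
            return self._compile_eq(l, r, expr.op)
        if l.kind == "num" and r.kind == "num":
            return CVal("bool", [f"(({l.sql}) {expr.op} ({r.sql}))"])
        if l.kind == r.kind and l.kind in ("str", "bool"):
            if l.kind == "str" and not _same_lit_ann(l, r):
                return _ERR
            return CVal("bool", [f"(({l.sql}) {expr.op} ({r.sql}))"])
        if l.kind == r.kind == "lang" and l.ann == r.ann:
            return CVal("bool", [f"(({l.sql}) {expr.op} ({r.sql}))"])
        return _ERR

    def _compile_eq(self, l: CVal, r: CVal, op: str) -> CVal:
        if l.kind == "err" or r.kind == "err":
            return _ERR
        if l.kind == "iri" and r.kind == "iri":
            if _ann_eq(l.ann, r.ann):
                eqs = " AND ".join(
                    f"({a} = {b})" for a, b in zip(l.parts, r.parts)
                )
                body = f"({eqs})"
                if op == "!=":
                    body = f"(NOT {body})"
                return CVal("bool", [body])
            # disjoint classes: never equal, but unbound operands still error
            res = "0" if op == "=" else "1"
            return CVal(
                "bool",
                [
                    f"CASE WHEN {l.parts[0]} IS NOT NULL AND {r.parts[0]} IS NOT NULL "
                    f"THEN {res} END"
                ],
            )
        if "text" in (l.kind, r.kind):
            a = self._encode_sql(l) if l.kind != "text" else l.sql
            b = self._encode_sql(r) if r.kind != "text" else r.sql
            body = f"({a} = {b})"
            if op == "!=":
                body = f"(NOT {body})"
            return CVal("bool", [body])
        if l.kind == "num" and r.kind == "num":
            body = f"(({l.sql}) = ({r.sql}))"
            if op == "!=":
                body = f"(NOT {body})"
            return CVal("bool", [body])
        if l.kind == r.kind and l.kind in ("str", "bool", "lang"):
            if l.kind == "str" and not _same_lit_ann(l, r):
                return _ERR
            if l.kind == "lang" and l.ann != r.ann:
                return _ERR
            body = f"(({l.sql}) = ({r.sql}))"
            if op == "!=":
                body = f"(NOT {body})"
            return CVal("bool", [body])
        return _ERR


def _same_lit_ann(l: CVal, r: CVal) -> bool:
    if isinstance(l.ann, LitAnn) and isinstance(r.ann, LitAnn):
        return l.ann.datatype == r.ann.datatype
    return True


def _expr_vars_of(node: FilterNode) -> set[str]:
    from .sql_translator import _filter_vars

    out: set[str] = set()
    for f in node.filters:
        out |= _filter_vars(f)
    for _, pattern in node.anti:
        out |= {v.name for v in pattern_variables(pattern)}
    return out


def _optimize_plan_for_render(plan: Plan) -> Plan:
    from .sql_translator import BranchSet as BS, _try_fk_elimination, _try_self_join_merge

    if isinstance(plan, BS):
        kept = []
        for br in plan.branches:
            br = br.clone()
            for _ in range(len(br.fragments) + 1):
                changed = _try_self_join_merge(br, None) or _try_fk_elimination(br, None)
                if br.empty or not changed:
                    break
            if not br.empty:
                kept.append(br)
        return BS(kept)
    return plan


# ---------------------------------------------------------------------------
# Result decoding


@dataclass
class ClassDecoder:
    cls: IRIClass

    @property
    def width(self) -> int:
        return len(self.cls.slots)

    def decode(self, values):
        if any(v is None for v in values):
            return None
        return self.cls.encode(tuple(values))


@dataclass
class LiteralDecoder:
    datatype: str
    language: Optional[str] = None

    width = 1

    def decode(self, values):
        (v,) = values
        if v is None:
            return None
        if self.language is not None:
            return Literal(str(v), language=self.language)
        return literal_from_sql(v, self.datatype)


@dataclass
class TextDecoder:
    width = 1

    def decode(self, values):
        (v,) = values
        if v is None:
            return None
        return decode_term_text(str(v))


@dataclass(frozen=True)
class NumAnn:
    """Numeric result whose exact datatype depends on the SQL value (SUM:
    integer over integer inputs, double otherwise, integer 0 when empty)."""

    @property
    def width(self) -> int:
        return 1


@dataclass
class NumericDecoder:
    width = 1

    def decode(self, values):
        (v,) = values
        if v is None:
            return None
        if isinstance(v, float):
            return literal_from_sql(v, XSD_DOUBLE)
        return literal_from_sql(v, XSD_INTEGER)


@dataclass
class NullDecoder:
    width = 0

    def decode(self, values):
        return None


def _decoder_for(ann):
    if ann is None:
        return NullDecoder()
    if isinstance(ann, ClassAnn):
        return ClassDecoder(ann.cls)
    if isinstance(ann, TextAnn):
        return TextDecoder()
    if isinstance(ann, NumAnn):
        return NumericDecoder()
    return LiteralDecoder(ann.datatype, ann.language)


# ---------------------------------------------------------------------------
# Whole-query rendering


@dataclass
class CompiledQuery:
    sql: str
    variables: list[str]
    decoders: list
    form: str
    ast: QueryAST
    report: Optional[TranslationReport] = None


def render_sql(q: SQLQuery, dialect: str = "sqlite") -> str:
    """Deterministic SQL text for the embedded backend's dialect."""
    if dialect != "sqlite":
        raise ValueError(f"unknown dialect {dialect!r}")
    return _render_query(q)[0]


def _agg_sql(agg: Aggregate, env: dict[str, CVal], renderer: Renderer):
    """SQL text and output annotation of an aggregate expression."""
    if agg.func == "COUNT":
        if agg.arg is None:
            return "COUNT(*)", LitAnn(XSD_INTEGER)
        cv = env.get(agg.arg.name)
        if cv is None:
            return "0", LitAnn(XSD_INTEGER)
        if agg.distinct:
            inner = renderer._encode_sql(cv) if len(cv.parts) > 1 or cv.kind == "iri" else cv.sql
            return f"COUNT(DISTINCT {inner})", LitAnn(XSD_INTEGER)
        return f"COUNT({cv.parts[0]})", LitAnn(XSD_INTEGER)
    cv = env.get(agg.arg.name) if agg.arg is not None else None
    if cv is None:
        return "NULL", TextAnn()
    d = "DISTINCT " if agg.distinct else ""
    if agg.func in ("SUM", "AVG"):
        if cv.kind != "num":
            return "NULL", TextAnn()
        if agg.func == "SUM":
            return f"SUM({d}{cv.sql})", NumAnn()
        return f"AVG({d}{cv.sql})", LitAnn(XSD_DOUBLE)
    if agg.func in ("MIN", "MAX"):
        if cv.kind in ("num", "str", "bool", "lang"):
            return f"{agg.func}({d}{cv.sql})", cv.ann
        return f"{agg.func}({d}{renderer._encode_sql(cv)})", TextAnn()
    raise UnsupportedFeatureError(f"aggregate {agg.func}")


def _compile_group_expr(expr: Expr, env, renderer: Renderer) -> str:
    """Compile a HAVING expression, inlining aggregate sub-expressions."""

    def rewrite(e: Expr) -> CVal:
        if isinstance(e, Aggregate):
            sql, ann = _agg_sql(e, env, renderer)
            return renderer._spec_cval_from_parts([sql], ann)
        if isinstance(e, Comparison):
            return renderer._compile_comparison_from(rewrite(e.left), rewrite(e.right), e.op)
        return renderer.compile_value(e, env)

    return renderer._ebv(rewrite(expr))


def _compile_comparison_from(self, l: CVal, r: CVal, op: str) -> CVal:
    if op in ("=", "!="):
        return self._compile_eq(l, r, op)
    if l.kind == "num" and r.kind == "num":
        return CVal("bool", [f"(({l.sql}) {op} ({r.sql}))"])
    return _ERR


Renderer._compile_comparison_from = _compile_comparison_from


def _render_query(q: SQLQuery) -> tuple[str, list[str], list]:
    ast = q.ast
    renderer = Renderer(q.mapping_set)
    sig = plan_signature(q.plan)

    if ast.form == "ASK":
        inner = renderer.render_plan(q.plan, {})
        return f"SELECT 1 AS one FROM ({inner}) AS a LIMIT 1", [], []

    needed: set[str] = set()
    for p in ast.projection:
        if isinstance(p.expr, Var):
            needed.add(p.expr.name)
        elif isinstance(p.expr, Aggregate) and p.expr.arg is not None:
            needed.add(p.expr.arg.name)
    needed.update(v.name for v in ast.group_by)
    if ast.having is not None:
        from .sql_translator import _filter_vars

        needed |= _filter_vars(ast.having)
    for oc in ast.order_by:
        if isinstance(oc.expr, Var):
            needed.add(oc.expr.name)
        elif isinstance(oc.expr, Aggregate) and oc.expr.arg is not None:
            needed.add(oc.expr.arg.name)
    target = {v: sig[v] for v in sorted(needed) if v in sig}
    inner_sql = renderer.render_plan(q.plan, target)

    out_ann: dict[str, Optional[Annotation]] = {}
    if ast.has_aggregates:
        a = renderer.alias()
        env = {v: renderer._alias_cval(a, v, ann) for v, ann in target.items()}
        select_items = []
        key_cols = []
        for v in ast.group_by:
            ann = target.get(v.name)
            out_ann[v.name] = ann
            if ann is None:
                select_items.append(f"NULL AS {_q(_col(v.name, 0))}")
                continue
            for i in range(ann.width):
                col = f"{a}.{_q(_col(v.name, i))}"
                key_cols.append(col)
                select_items.append(f"{col} AS {_q(_col(v.name, i))}")
        for p in ast.projection:
            if isinstance(p.expr, Aggregate):
                sql, ann = _agg_sql(p.expr, env, renderer)
                if (
                    p.expr.func == "SUM"
                    and not ast.group_by
                ):
                    sql = f"COALESCE({sql}, 0)"
                out_ann[p.var.name] = ann
                select_items.append(f"{sql} AS {_q(_col(p.var.name, 0))}")
            elif isinstance(p.expr, Var) and p.expr.name != p.var.name:
                ann = target.get(p.expr.name)
                out_ann[p.var.name] = ann
                src = f"{a}.{_q(_col(p.expr.name, 0))}" if ann else "NULL"
                select_items.append(f"{src} AS {_q(_col(p.var.name, 0))}")
        sql = f"SELECT {', '.join(select_items)} FROM ({inner_sql}) AS {a}"
        if key_cols:
            sql += " GROUP BY " + ", ".join(key_cols)
        if ast.having is not None:
            sql += " HAVING " + _compile_group_expr(ast.having, env, renderer)
        body_cols = {
            p.var.name: out_ann.get(p.var.name) for p in ast.projection
        }
    else:
        sql = inner_sql
        for p in ast.projection:
            src = p.expr.name if isinstance(p.expr, Var) else p.var.name
            out_ann[p.var.name] = target.get(src)
        body_cols = {p.var.name: out_ann.get(p.var.name) for p in ast.projection}

    # outermost projection + modifiers
    b = renderer.alias()
    proj_items = []
    decoders = []
    variables = []
    for p in ast.projection:
        ann = body_cols.get(p.var.name)
        variables.append(p.var.name)
        decoders.append(_decoder_for(ann))
        if ann is None:
            proj_items.append(f"NULL AS {_q(_col(p.var.name, 0))}")
            continue
        src = p.var.name if (ast.has_aggregates or not isinstance(p.expr, Var)) else p.expr.name
        for i in range(ann.width):
            proj_items.append(f"{b}.{_q(_col(src, i))} AS {_q(_col(p.var.name, i))}")
    distinct = "DISTINCT " if ast.distinct else ""
    final = f"SELECT {distinct}{', '.join(proj_items) or '1 AS one'} FROM ({sql}) AS {b}"

    if ast.order_by:
        order_items = []
        for oc in ast.order_by:
            expr = oc.expr
            if isinstance(expr, Aggregate):
                # ORDER BY an aggregate must match a projected alias
                alias = next(
                    (p.var.name for p in ast.projection if p.expr == expr), None
                )
                if alias is None:
                    raise UnsupportedFeatureError("ORDER BY unprojected aggregate")
                expr = Var(alias)
            if not isinstance(expr, Var):
                raise UnsupportedFeatureError("ORDER BY arbitrary expression")
            ann = body_cols.get(expr.name)
            if ann is None and not ast.has_aggregates:
                ann = target.get(expr.name)
            if ann is None:
                continue
            if isinstance(ann, ClassAnn):
                cv = renderer._alias_cval(b, expr.name, ann)
                item = renderer._encode_sql(cv)
            else:
                item = f"{b}.{_q(_col(expr.name, 0))}"
            order_items.append(item + (" DESC" if oc.descending else ""))
        if order_items:
            final += " ORDER BY " + ", ".join(order_items)
    if ast.limit is not None or ast.offset:
        final += f" LIMIT {ast.limit if ast.limit is not None else -1}"
        if ast.offset:
            final += f" OFFSET {ast.offset}"
    return final, variables, decoders


def compile_query(
    ast: QueryAST, ms: MappingSet, do_optimize: bool = True
) -> CompiledQuery:
    """Translate, optionally optimize, and render a query for execution."""
    q, report = translate(ast, ms)
    if do_optimize:
        q = optimize(q, report=report)
    sql, variables, decoders = _render_query(q)
    return CompiledQuery(sql, variables, decoders, ast.form, ast, report)
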