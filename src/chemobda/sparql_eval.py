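"""Reference SPARQL evaluator over an in-memory quad store.

This is the correctness oracle for the SQL translation path: it evaluates a
:class:`~chemobda.sparql_frontend.QueryAST` by exhaustive pattern matching
and the standard SPARQL algebra (join, left join, union, minus, filter,
aggregation, solution modifiers), with no reliance on mappings or SQL.
It favours clarity over speed; quad-store inputs are expected to stay in
the toy-scale range (up to roughly a million quads).
"""

from __future__ import annotations

import functools
from typing import Optional, Union

from .rdf_core import (
    BlankNode,
    IRI,
    Literal,
    NUMERIC_DATATYPES,
    QuadStore,
    SolutionMultiset,
    XSD_BOOLEAN,
    XSD_DOUBLE,
    XSD_INTEGER,
    XSD_STRING,
    float_lexical,
    numeric_value,
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


class ExprError(Exception):
    """SPARQL expression evaluation error (eliminates the row in FILTER)."""


Binding = dict  # var name -> Term


# ---------------------------------------------------------------------------
# Pattern evaluation


def _unify(tp: TriplePattern, quad, binding: Binding) -> Optional[Binding]:
    ext: Binding = {}
    for pterm, qterm in zip(tp.terms(), quad.triple):
        if isinstance(pterm, Var):
            bound = binding.get(pterm.name, ext.get(pterm.name))
            if bound is None:
                ext[pterm.name] = qterm
            elif bound != qterm:
                return None
        elif pterm != qterm:
            return None
    return ext


def _match_pattern(tp: TriplePattern, store: QuadStore, binding: Binding):
    def concrete(t):
        if isinstance(t, Var):
            return binding.get(t.name)
        return t

    s, p, o = (concrete(t) for t in tp.terms())
    # literals can never be subjects/predicates; such patterns match nothing
    if isinstance(s, Literal) or isinstance(p, (Literal, BlankNode)):
        return
    for quad in store.match(s, p, o):
        ext = _unify(tp, quad, binding)
        if ext is not None:
            merged = dict(binding)
            merged.update(ext)
            yield merged


def _bound_score(tp: TriplePattern, bound_vars: set[str]) -> int:
    score = 0
    for t in tp.terms():
        if not isinstance(t, Var) or t.name in bound_vars:
            score += 1
    return score


def _eval_bgp(patterns: tuple[TriplePattern, ...], store: QuadStore) -> list[Binding]:
    rows: list[Binding] = [{}]
    remaining = list(patterns)
    bound: set[str] = set()
    while remaining:
        remaining.sort(key=lambda tp: -_bound_score(tp, bound))
        tp = remaining.pop(0)
        rows = [m for r in rows for m in _match_pattern(tp, store, r)]
        bound.update(v.name for v in tp.variables())
        if not rows:
            return []
    return rows


def _compatible(a: Binding, b: Binding) -> Optional[Binding]:
    for k, v in b.items():
        if k in a and a[k] != v:
            return None
    merged = dict(a)
    merged.update(b)
    return merged


def _merge_join(left: list[Binding], right: list[Binding]) -> list[Binding]:
    out = []
    for l in left:
        for r in right:
            m = _compatible(l, r)
            if m is not None:
                out.append(m)
    return out


def _substitute_pattern(gp: GroupPattern, binding: Binding) -> GroupPattern:
    def sub_term(t):
        if isinstance(t, Var) and t.name in binding:
            return binding[t.name]
        return t

    if isinstance(gp, BGP):
        return BGP(
            tuple(
                TriplePattern(sub_term(tp.subject), sub_term(tp.predicate), sub_term(tp.object))
                for tp in gp.patterns
            )
        )
    if isinstance(gp, Filter):
        return Filter(_substitute_expr(gp.expr, binding), _substitute_pattern(gp.inner, binding))
    if isinstance(gp, JoinPattern):
        return JoinPattern(
            _substitute_pattern(gp.left, binding), _substitute_pattern(gp.right, binding)
        )
    if isinstance(gp, OptionalPattern):
        cond = _substitute_expr(gp.condition, binding) if gp.condition is not None else None
        return OptionalPattern(
            _substitute_pattern(gp.left, binding), _substitute_pattern(gp.right, binding), cond
        )
    if isinstance(gp, UnionPattern):
        return UnionPattern(
            _substitute_pattern(gp.left, binding), _substitute_pattern(gp.right, binding)
        )
    if isinstance(gp, MinusPattern):
        # per SPARQL, substitution does not descend into MINUS
        return MinusPattern(_substitute_pattern(gp.left, binding), gp.right)
    if isinstance(gp, ValuesPattern):
        return gp
    raise TypeError(f"not a group pattern: {gp!r}")


def _substitute_expr(e: Expr, binding: Binding) -> Expr:
    if isinstance(e, Var):
        if e.name in binding:
            return ConstExpr(binding[e.name])
        return e
    if isinstance(e, ConstExpr):
        return e
    if isinstance(e, Comparison):
        return Comparison(e.op, _substitute_expr(e.left, binding), _substitute_expr(e.right, binding))
    if isinstance(e, LogicalAnd):
        return LogicalAnd(_substitute_expr(e.left, binding), _substitute_expr(e.right, binding))
    if isinstance(e, LogicalOr):
        return LogicalOr(_substitute_expr(e.left, binding), _substitute_expr(e.right, binding))
    if isinstance(e, LogicalNot):
        return LogicalNot(_substitute_expr(e.arg, binding))
    if isinstance(e, Arith):
        return Arith(e.op, _substitute_expr(e.left, binding), _substitute_expr(e.right, binding))
    if isinstance(e, InExpr):
        return InExpr(
            _substitute_expr(e.arg, binding),
            tuple(_substitute_expr(o, binding) for o in e.options),
            e.negated,
        )
    if isinstance(e, BoundExpr):
        if e.var.name in binding:
            return ConstExpr(Literal("true", XSD_BOOLEAN))
        return e
    if isinstance(e, IsIRIExpr):
        return IsIRIExpr(_substitute_expr(e.arg, binding))
    if isinstance(e, NotExistsExpr):
        return NotExistsExpr(_substitute_pattern(e.pattern, binding))
    return e


def eval_group(gp: GroupPattern, store: QuadStore) -> list[Binding]:
    if isinstance(gp, BGP):
        return _eval_bgp(gp.patterns, store)
    if isinstance(gp, JoinPattern):
        return _merge_join(eval_group(gp.left, store), eval_group(gp.right, store))
    if isinstance(gp, Filter):
        rows = eval_group(gp.inner, store)
        return [r for r in rows if _filter_passes(gp.expr, r, store)]
    if isinstance(gp, OptionalPattern):
        left = eval_group(gp.left, store)
        right = eval_group(gp.right, store)
        out = []
        for l in left:
            extended = []
            for r in right:
                m = _compatible(l, r)
                if m is not None and (
                    gp.condition is None or _filter_passes(gp.condition, m, store)
                ):
                    extended.append(m)
            out.extend(extended if extended else [l])
        return out
    if isinstance(gp, UnionPattern):
        return eval_group(gp.left, store) + eval_group(gp.right, store)
    if isinstance(gp, MinusPattern):
        left = eval_group(gp.left, store)
        right = eval_group(gp.right, store)
        out = []
        for l in left:
            removed = False
            for r in right:
                shared = set(l) & set(r)
                if shared and _compatible(l, r) is not None:
                    removed = True
                    break
            if not removed:
                out.append(l)
        return out
    if isinstance(gp, ValuesPattern):
        rows = []
        for row in gp.rows:
            b = {
                v.name: t
                for v, t in zip(gp.variables, row)
                if t is not None
            }
            rows.append(b)
        return rows
    raise UnsupportedFeatureError(f"pattern {type(gp).__name__}")


def _filter_passes(expr: Expr, row: Binding, store: QuadStore) -> bool:
    try:
        return _ebv(eval_expr(expr, row, store))
    except ExprError:
        return False


# ---------------------------------------------------------------------------
# Expression evaluation


TRUE = Literal("true", XSD_BOOLEAN)
FALSE = Literal("false", XSD_BOOLEAN)


def _ebv(term) -> bool:
    """Effective boolean value."""
    if isinstance(term, Literal):
        if term.datatype == XSD_BOOLEAN:
            return term.lexical == "true"
        nv = numeric_value(term)
        if nv is not None:
            return nv != 0
        if term.datatype == XSD_STRING or term.language:
            return len(term.lexical) > 0
    raise ExprError(f"no effective boolean value for {term!r}")


def _compare(op: str, left, right) -> bool:
    if left is None or right is None:
        raise ExprError("unbound operand in comparison")
    if isinstance(left, IRI) and isinstance(right, IRI):
        if op == "=":
            return left == right
        if op == "!=":
            return left != right
        raise ExprError("IRIs admit only equality comparison")
    if isinstance(left, Literal) and isinstance(right, Literal):
        lv, rv = numeric_value(left), numeric_value(right)
        if lv is not None and rv is not None:
            return _apply_cmp(op, lv, rv)
        if left.datatype == right.datatype and left.language == right.language:
            if left.datatype == XSD_BOOLEAN:
                return _apply_cmp(op, left.lexical == "true", right.lexical == "true")
            return _apply_cmp(op, left.lexical, right.lexical)
        raise ExprError(
            f"cannot compare {left.datatype} with {right.datatype}"
        )
    if op == "=":
        return left == right if type(left) is type(right) else _raise_cross(left, right)
    if op == "!=":
        return left != right if type(left) is type(right) else _raise_cross(left, right)
    raise ExprError(f"cannot order {left!r} and {right!r}")


def _raise_cross(left, right):
    raise ExprError(f"cross-type comparison of {left!r} and {right!r}")


def _apply_cmp(op: str, l, r) -> bool:
    if op == "=":
        return l == r
    if op == "!=":
        return l != r
    if op == "<":
        return l < r
    if op == "<=":
        return l <= r
    if op == ">":
        return l > r
    if op == ">=":
        return l >= r
    raise ExprError(f"unknown comparison operator {op!r}")


def eval_expr(expr: Expr, row: Binding, store: QuadStore):
    if isinstance(expr, Var):
        term = row.get(expr.name)
        if term is None:
            raise ExprError(f"unbound variable ?{expr.name}")
        return term
    if isinstance(expr, ConstExpr):
        return expr.term
    if isinstance(expr, Comparison):
        l = eval_expr(expr.left, row, store)
        r = eval_expr(expr.right, row, store)
        return TRUE if _compare(expr.op, l, r) else FALSE
    if isinstance(expr, LogicalAnd):
        # three-valued: error && false == false
        lres: Optional[bool]
        try:
            lres = _ebv(eval_expr(expr.left, row, store))
        except ExprError:
            lres = None
        try:
            rres = _ebv(eval_expr(expr.right, row, store))
        except ExprError:
            rres = None
        if lres is False or rres is False:
            return FALSE
        if lres is None or rres is None:
            raise ExprError("error in && operand")
        return TRUE
    if isinstance(expr, LogicalOr):
        try:
            lres = _ebv(eval_expr(expr.left, row, store))
        except ExprError:
            lres = None
        try:
            rres = _ebv(eval_expr(expr.right, row, store))
        except ExprError:
            rres = None
        if lres is True or rres is True:
            return TRUE
        if lres is None or rres is None:
            raise ExprError("error in || operand")
        return FALSE
    if isinstance(expr, LogicalNot):
        return FALSE if _ebv(eval_expr(expr.arg, row, store)) else TRUE
    if isinstance(expr, Arith):
        l = eval_expr(expr.left, row, store)
        r = eval_expr(expr.right, row, store)
        if not isinstance(l, Literal) or not isinstance(r, Literal):
            raise ExprError("arithmetic on non-literals")
        lv, rv = numeric_value(l), numeric_value(r)
        if lv is None or rv is None:
            raise ExprError("arithmetic on non-numeric literals")
        if expr.op == "+":
            res = lv + rv
        elif expr.op == "-":
            res = lv - rv
        elif expr.op == "*":
            res = lv * rv
        elif expr.op == "/":
            if rv == 0:
                raise ExprError("division by zero")
            res = lv / rv  # SPARQL numeric division never truncates
        else:
            raise ExprError(f"unknown arithmetic operator {expr.op!r}")
        if isinstance(res, int):
            return Literal(str(res), XSD_INTEGER)
        return Literal(float_lexical(res), XSD_DOUBLE)
    if isinstance(expr, InExpr):
        arg = eval_expr(expr.arg, row, store)
        found = False
        for opt in expr.options:
            try:
                if _compare("=", arg, eval_expr(opt, row, store)):
                    found = True
                    break
            except ExprError:
                continue
        return TRUE if found != expr.negated else FALSE
    if isinstance(expr, BoundExpr):
        return TRUE if row.get(expr.var.name) is not None else FALSE
    if isinstance(expr, IsIRIExpr):
        return TRUE if isinstance(eval_expr(expr.arg, row, store), IRI) else FALSE
    if isinstance(expr, NotExistsExpr):
        sub = _substitute_pattern(expr.pattern, row)
        return TRUE if not eval_group(sub, store) else FALSE
    if isinstance(expr, Aggregate):
        raise ExprError("aggregate outside of aggregation context")
    raise UnsupportedFeatureError(f"expression {type(expr).__name__}")


# ---------------------------------------------------------------------------
# Aggregation


def _eval_aggregate(agg: Aggregate, rows: list[Binding]):
    if agg.func == "COUNT":
        if agg.arg is None:
            return Literal(str(len(rows)), XSD_INTEGER)
        values = [r[agg.arg.name] for r in rows if r.get(agg.arg.name) is not None]
        if agg.distinct:
            values = list(set(values))
        return Literal(str(len(values)), XSD_INTEGER)
    if agg.arg is None:
        raise ExprError(f"{agg.func} requires a variable argument")
    terms = [r[agg.arg.name] for r in rows if r.get(agg.arg.name) is not None]
    if agg.distinct:
        terms = list(set(terms))
    if agg.func == "SUM":
        values = [numeric_value(t) if isinstance(t, Literal) else None for t in terms]
        if any(v is None for v in values):
            raise ExprError("SUM over non-numeric values")
        total = sum(values) if values else 0
        if isinstance(total, int):
            return Literal(str(total), XSD_INTEGER)
        return Literal(float_lexical(total), XSD_DOUBLE)
    if agg.func == "AVG":
        values = [numeric_value(t) if isinstance(t, Literal) else None for t in terms]
        if not values or any(v is None for v in values):
            raise ExprError("AVG over empty or non-numeric values")
        return Literal(float_lexical(sum(values) / len(values)), XSD_DOUBLE)
    if agg.func in ("MIN", "MAX"):
        if not terms:
            raise ExprError(f"{agg.func} of empty group")
        key = functools.cmp_to_key(compare_terms)
        return min(terms, key=key) if agg.func == "MIN" else max(terms, key=key)
    raise UnsupportedFeatureError(f"aggregate {agg.func}")


def _eval_group_expr(expr: Expr, group_row: Binding, member_rows: list[Binding], store):
    """Evaluate a HAVING/ORDER expression that may contain aggregates."""
    if isinstance(expr, Aggregate):
        return _eval_aggregate(expr, member_rows)
    if isinstance(expr, Comparison):
        l = _eval_group_expr(expr.left, group_row, member_rows, store)
        r = _eval_group_expr(expr.right, group_row, member_rows, store)
        return TRUE if _compare(expr.op, l, r) else FALSE
    if isinstance(expr, (LogicalAnd, LogicalOr)):
        op = LogicalAnd if isinstance(expr, LogicalAnd) else LogicalOr
        l = _eval_group_expr(expr.left, group_row, member_rows, store)
        r = _eval_group_expr(expr.right, group_row, member_rows, store)
        lb, rb = _ebv(l), _ebv(r)
        res = (lb and rb) if op is LogicalAnd else (lb or rb)
        return TRUE if res else FALSE
    return eval_expr(expr, group_row, store)


# ---------------------------------------------------------------------------
# Term ordering (ORDER BY and MIN/MAX)


def _term_rank(term) -> int:
    if term is None:
        return 0
    if isinstance(term, BlankNode):
        return 1
    if isinstance(term, IRI):
        return 2
    return 3


def compare_terms(a, b) -> int:
    """Total order used for ORDER BY: unbound < blank < IRI < literal;
    numeric literals by value, other literals by (datatype, lexical)."""
    ra, rb = _term_rank(a), _term_rank(b)
    if ra != rb:
        return -1 if ra < rb else 1
    if a is None:
        return 0
    if isinstance(a, BlankNode):
        return (a.label > b.label) - (a.label < b.label)
    if isinstance(a, IRI):
        return (a.value > b.value) - (a.value < b.value)
    na, nb = numeric_value(a), numeric_value(b)
    if na is not None and nb is not None:
        return (na > nb) - (na < nb)
    if na is not None:
        return -1
    if nb is not None:
        return 1
    ka = (a.datatype, a.lexical)
    kb = (b.datatype, b.lexical)
    return (ka > kb) - (ka < kb)


def order_comparator(order_by, store=None):
    """Row comparator implementing a query's ORDER BY conditions over
    projected rows (order expressions must use projected variables)."""

    def cmp(row_a: Binding, row_b: Binding) -> int:
        for oc in order_by:
            if isinstance(oc.expr, Var):
                ta, tb = row_a.get(oc.expr.name), row_b.get(oc.expr.name)
            else:
                try:
                    ta = eval_expr(oc.expr, row_a, store)
                except ExprError:
                    ta = None
                try:
                    tb = eval_expr(oc.expr, row_b, store)
                except ExprError:
                    tb = None
            c = compare_terms(ta, tb)
            if oc.descending:
                c = -c
            if c:
                return c
        return 0

    return cmp


# ---------------------------------------------------------------------------
# Query evaluation


def evaluate_oracle(query: QueryAST, store: QuadStore) -> Union[SolutionMultiset, bool]:
    """Evaluate a query by exhaustive matching; returns a solution multiset
    for SELECT and a boolean for ASK."""
    rows = eval_group(query.pattern, store)
    if query.form == "ASK":
        return bool(rows)

    if query.has_aggregates:
        groups: dict[tuple, list[Binding]] = {}
        if query.group_by:
            for r in rows:
                key = tuple(r.get(v.name) for v in query.group_by)
                groups.setdefault(key, []).append(r)
        else:
            groups[()] = rows  # single implicit group, present even if empty
        out_rows: list[Binding] = []
        for key, members in groups.items():
            row: Binding = {}
            for v, t in zip(query.group_by, key):
                if t is not None:
                    row[v.name] = t
            ok = True
            for p in query.projection:
                if isinstance(p.expr, Aggregate):
                    try:
                        row[p.var.name] = _eval_aggregate(p.expr, members)
                    except ExprError:
                        pass  # aggregate error leaves the variable unbound
                elif isinstance(p.expr, Var) and p.expr.name != p.var.name:
                    row[p.var.name] = row.get(p.expr.name)
            if query.having is not None:
                try:
                    ok = _ebv(_eval_group_expr(query.having, row, members, store))
                except ExprError:
                    ok = False
            if ok:
                out_rows.append(row)
        rows = out_rows

    if query.order_by:
        rows = sorted(rows, key=functools.cmp_to_key(order_comparator(query.order_by, store)))

    variables = [p.var.name for p in query.projection]
    projected = [{v: r.get(v) for v in variables if r.get(v) is not None} for r in rows]

    if query.distinct:
        seen = set()
        deduped = []
        for r in projected:
            key = tuple(r.get(v) for v in variables)
            if key not in seen:
                seen.add(key)
                deduped.append(r)
        projected = deduped

    if query.offset:
        projected = projected[query.offset :]
    if query.limit is not None:
        projected = projected[: query.limit]

    return SolutionMultiset(variables, projected)
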