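"""Candidate selection, translation, optimization, and SQL rendering."""

import re

import pytest

from chemobda import (
    IRI,
    candidate_mappings,
    compile_query,
    evaluate_oracle,
    optimize,
    parse_query,
    render_sql,
    translate,
)
from chemobda.sparql_frontend import TriplePattern, Var
from chemobda.sql_translator import TranslationReport, count_fragments, count_joins


def _base_table_refs(sql: str, ms) -> list[str]:
    """Base-table names referenced in rendered SQL (via FROM/JOIN clauses)."""
    names = [t.name for t in ms.schema.tables]
    return [n for n in names for _ in re.findall(rf'"{n}" AS ', sql)]


DCTERMS_TITLE = IRI("http://purl.org/dc/terms/title")


class TestCandidates:
    def test_title_pattern_selects_the_title_mapping(self, fig_bundle):
        ms = fig_bundle.mapping_set()
        tp = TriplePattern(Var("d"), DCTERMS_TITLE, Var("t"))
        cands = candidate_mappings(tp, ms)
        assert [qm.label for qm in cands] == ["document-title"]

    def test_unknown_predicate_gives_no_candidates(self, fig_bundle):
        ms = fig_bundle.mapping_set()
        tp = TriplePattern(Var("d"), IRI("http://nowhere.example/p"), Var("t"))
        assert candidate_mappings(tp, ms) == []

    def test_constant_subject_of_wrong_class_excluded(self, fig_bundle):
        ms = fig_bundle.mapping_set()
        journal = IRI("http://rdf.ebi.ac.uk/resource/chembl/journal/CHEMBL_JRN_4")
        tp = TriplePattern(journal, DCTERMS_TITLE, Var("t"))
        assert candidate_mappings(tp, ms) == []
        document = IRI("http://rdf.ebi.ac.uk/resource/chembl/document/CHEMBL1139452")
        assert len(candidate_mappings(TriplePattern(document, DCTERMS_TITLE, Var("t")), ms)) == 1

    def test_variable_predicate_matches_every_mapping(self, fig_bundle):
        ms = fig_bundle.mapping_set()
        tp = TriplePattern(Var("s"), Var("p"), Var("o"))
        assert len(candidate_mappings(tp, ms)) == len(ms.quad_mappings)


class TestWorkedExample:
    def test_unoptimized_translation_has_three_fragments(self, fig_world):
        bundle, ms, _, _ = fig_world
        ast = parse_query(bundle.queries["documents_with_journals"])
        q, report = translate(ast, ms)
        assert report.base_tables_before == 3

    def test_optimization_merges_and_eliminates(self, fig_world):
        bundle, ms, _, _ = fig_world
        ast = parse_query(bundle.queries["documents_with_journals"])
        q, report = translate(ast, ms)
        q = optimize(q, report=report)
        assert report.base_tables_after == 1 and report.joins_after == 0
        assert any("self-join merge" in r for r in report.rewrites)
        assert any("foreign-key join elimination" in r for r in report.rewrites)

    def test_rendered_sql_references_one_base_table(self, fig_world):
        bundle, ms, _, _ = fig_world
        ast = parse_query(bundle.queries["documents_with_journals"])
        compiled = compile_query(ast, ms)
        refs = _base_table_refs(compiled.sql, ms)
        assert refs == ["documents"]

    def test_nullable_fk_elimination_keeps_notnull_filter(self, fig_world):
        bundle, ms, _, _ = fig_world
        ast = parse_query(bundle.queries["documents_with_journals"])
        compiled = compile_query(ast, ms)
        assert '"journal_id" IS NOT NULL' in compiled.sql

    def test_short_title_variant_keeps_the_journals_table(self, fig_world):
        """The journals fragment exports a non-key column and must survive."""
        bundle, ms, _, _ = fig_world
        ast = parse_query(bundle.queries["documents_with_journal_titles"])
        compiled = compile_query(ast, ms)
        assert sorted(_base_table_refs(compiled.sql, ms)) == ["documents", "journals"]


class TestCaseThree:
    def test_seven_patterns_three_tables_two_joins(self, toy_world):
        bundle, ms, _, _ = toy_world
        ast = parse_query(bundle.queries["case3_substances_per_protein"])
        q, report = translate(ast, ms)
        assert report.base_tables_before == 7
        q = optimize(q, report=report)
        assert report.base_tables_after == 3
        assert report.joins_after == 2

    def test_redundant_pattern_contributes_no_table(self, toy_world):
        """Dropping the substance-to-measure-group pattern leaves the
        optimized plan shape unchanged: the pattern is redundant."""
        bundle, ms, _, _ = toy_world
        full = parse_query(bundle.queries["case3_substances_per_protein"])
        reduced = parse_query(
            """
            SELECT ?protein (COUNT(?substance) AS ?count) WHERE {
              ?mg obo:OBI_0000299 ?endpoint .
              ?endpoint obo:IAO_0000136 ?substance .
              ?endpoint rdf:type bao:BAO_0000190 .
              ?endpoint sio:SIO_000300 ?value .
              ?mg obo:RO_0000057 ?protein .
              ?protein rdf:type bp:Protein .
            } GROUP BY ?protein
            """
        )
        full_sql = compile_query(full, ms).sql
        reduced_sql = compile_query(reduced, ms).sql
        assert sorted(_base_table_refs(full_sql, ms)) == sorted(
            _base_table_refs(reduced_sql, ms)
        )

    def test_report_counts_agree_with_rendered_sql(self, toy_world):
        bundle, ms, _, _ = toy_world
        ast = parse_query(bundle.queries["case3_substances_per_protein"])
        compiled = compile_query(ast, ms)
        assert len(_base_table_refs(compiled.sql, ms)) == compiled.report.base_tables_after


class TestDegenerateCases:
    def test_single_pattern_single_fragment(self, fig_world):
        bundle, ms, _, _ = fig_world
        ast = parse_query("SELECT ?d ?t WHERE { ?d dcterms:title ?t }")
        q, report = translate(ast, ms)
        assert report.base_tables_before == 1 and count_joins(q.plan) == 0
        compiled = compile_query(ast, ms)
        assert _base_table_refs(compiled.sql, ms) == ["documents"]

    def test_disjoint_class_join_yields_empty_plan(self, fig_world):
        """A variable used as both document and journal has no solutions."""
        bundle, ms, db, store = fig_world
        ast = parse_query(
            "SELECT ?x WHERE { ?x dcterms:title ?t . ?x bibo:shortTitle ?s }"
        )
        q, report = translate(ast, ms)
        q = optimize(q, report=report)
        assert count_fragments(q.plan) == 0
        result = db.execute(compile_query(ast, ms))
        assert len(result) == 0
        assert len(evaluate_oracle(ast, store)) == 0

    def test_unsatisfiable_constant_renders_zero_rows(self, fig_world):
        bundle, ms, db, _ = fig_world
        ast = parse_query(
            "SELECT ?d WHERE { ?d rdf:type cco:Assay }"  # no such mapping here
        )
        result = db.execute(compile_query(ast, ms))
        assert len(result) == 0

    def test_rendering_is_deterministic(self, toy_world):
        bundle, ms, _, _ = toy_world
        ast = parse_query(bundle.queries["case2_role_inhibited_proteins"])
        assert compile_query(ast, ms).sql == compile_query(ast, ms).sql
        assert render_sql(optimize(translate(ast, ms)[0])) == render_sql(
            optimize(translate(ast, ms)[0])
        )

    def test_unknown_dialect_rejected(self, fig_world):
        bundle, ms, _, _ = fig_world
        ast = parse_query("SELECT ?d ?t WHERE { ?d dcterms:title ?t }")
        q, _ = translate(ast, ms)
        with pytest.raises(ValueError):
            render_sql(q, dialect="postgres")


class TestOptimizationInvariants:
    def test_optimize_never_increases_counts_and_terminates(self, toy_world):
        bundle, ms, _, _ = toy_world
        for text in bundle.queries.values():
            ast = parse_query(text)
            q, _ = translate(ast, ms)
            before = (count_fragments(q.plan), count_joins(q.plan))
            q1 = optimize(q)
            mid = (count_fragments(q1.plan), count_joins(q1.plan))
            q2 = optimize(q1)
            after = (count_fragments(q2.plan), count_joins(q2.plan))
            assert mid[0] <= before[0]
            assert after == mid  # fixpoint: re-optimizing changes nothing

    def test_soundness_on_fixture_queries(self, toy_world):
        """Optimized and unoptimized SQL return equal multisets."""
        bundle, ms, db, _ = toy_world
        for text in bundle.queries.values():
            ast = parse_query(text)
            assert db.execute(compile_query(ast, ms)) == db.execute(
                compile_query(ast, ms, do_optimize=False)
            )
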