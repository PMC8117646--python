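"""SPARQL subset parser: expansion, subset boundary, round trips."""

import pytest

from chemobda import (
    SparqlSyntaxError,
    UnsupportedFeatureError,
    parse_query,
    pattern_count,
    to_sparql,
)
from chemobda.chem_fixtures import build_case_queries
from chemobda.sparql_frontend import (
    Aggregate,
    BGP,
    PrefixTable,
    TriplePattern,
    UnionPattern,
    Var,
)
from chemobda.rdf_core import IRI, Literal, XSD_BOOLEAN, XSD_INTEGER


class TestParsing:
    def test_predefined_prefix_expansion(self):
        ast = parse_query("SELECT ?d WHERE { ?d rdf:type cco:Document }")
        tp = ast.pattern.patterns[0]
        assert tp.predicate == IRI("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
        assert tp.object == IRI("http://rdf.ebi.ac.uk/terms/chembl#Document")

    def test_user_prefix_overrides_default(self):
        ast = parse_query(
            'PREFIX cco: <http://other.example/> SELECT ?d WHERE { ?d a cco:Document }'
        )
        assert ast.pattern.patterns[0].object == IRI("http://other.example/Document")

    def test_ask_empty_pattern(self):
        ast = parse_query("ASK { }")
        assert ast.form == "ASK" and ast.pattern == BGP(())

    def test_a_keyword_is_rdf_type(self):
        ast = parse_query("SELECT ?s WHERE { ?s a cco:Assay }")
        assert ast.pattern.patterns[0].predicate.value.endswith("#type")

    def test_numeric_and_boolean_literals(self):
        ast = parse_query("SELECT ?s WHERE { ?s ex:hasStructure true . ?s ex:n 42 }")
        objs = [tp.object for tp in ast.pattern.patterns]
        assert objs[0] == Literal("true", XSD_BOOLEAN)
        assert objs[1] == Literal("42", XSD_INTEGER)

    def test_semicolon_and_comma_abbreviations(self):
        ast = parse_query(
            "SELECT * WHERE { ?s rdf:type cco:Document ; dcterms:title ?t , ?u . }"
        )
        assert len(ast.pattern.patterns) == 3
        assert all(tp.subject == Var("s") for tp in ast.pattern.patterns)

    def test_syntax_error_reports_position(self):
        with pytest.raises(SparqlSyntaxError) as exc:
            parse_query("SELECT ?s WHERE { ?s rdf:type }")
        assert exc.value.position > 0

    def test_projection_must_use_pattern_variables(self):
        with pytest.raises(SparqlSyntaxError):
            parse_query("SELECT ?nope WHERE { ?s ?p ?o }")


class TestSubsetBoundary:
    @pytest.mark.parametrize(
        "text,feature",
        [
            ("SELECT ?s WHERE { SERVICE <http://x/> { ?s ?p ?o } }", "SERVICE"),
            ("SELECT ?s WHERE { BIND(1 AS ?s) }", "BIND"),
            ("CONSTRUCT { ?s ?p ?o } WHERE { ?s ?p ?o }", "CONSTRUCT"),
            ("SELECT ?s WHERE { GRAPH <http://g> { ?s ?p ?o } }", "GRAPH"),
            ("SELECT ?s FROM <http://g> WHERE { ?s ?p ?o }", "FROM"),
            ("SELECT ?s WHERE { ?s rdf:type/rdfs:subClassOf ?o }", "property path"),
        ],
    )
    def test_unsupported_constructs_fail_loudly(self, text, feature):
        with pytest.raises(UnsupportedFeatureError) as exc:
            parse_query(text)
        assert feature in str(exc.value)

    def test_subquery_rejected(self):
        with pytest.raises((UnsupportedFeatureError, SparqlSyntaxError)):
            parse_query("SELECT ?s WHERE { { SELECT ?s WHERE { ?s ?p ?o } } }")


class TestPatternCount:
    def test_empty_bgp(self):
        assert pattern_count(parse_query("ASK { }")) == 0

    def test_case3_has_seven_patterns(self):
        queries = build_case_queries()
        ast = parse_query(queries["case3_substances_per_protein"])
        assert pattern_count(ast) == 7

    def test_union_counts_are_additive(self):
        ast = parse_query(
            """SELECT ?s WHERE {
              { ?s ?p ?a . ?s ?q ?b } UNION { ?s ?r ?c . ?s ?t ?d }
            }"""
        )
        assert isinstance(ast.pattern, UnionPattern)
        assert pattern_count(ast) == 4

    def test_not_exists_patterns_are_counted(self):
        ast = parse_query(
            "SELECT ?s WHERE { ?s ?p ?o . FILTER NOT EXISTS { ?s ?q ?r } }"
        )
        assert pattern_count(ast) == 2


class TestRoundTrip:
    @pytest.mark.parametrize("name", sorted(build_case_queries()))
    def test_fixture_queries_roundtrip(self, name):
        """Parsing the serialized AST reproduces the AST (fixed point)."""
        text = build_case_queries()[name]
        ast = parse_query(text)
        again = parse_query(to_sparql(ast))
        assert again == ast

    def test_modifier_roundtrip(self):
        text = """
        SELECT DISTINCT ?p (COUNT(?s) AS ?n) WHERE {
          ?s ?x ?p . FILTER (?n1 < 5 || ?s = ?p)
          OPTIONAL { ?p ?y ?z . }
        } GROUP BY ?p HAVING (COUNT(?s) > 1) ORDER BY DESC(?n) LIMIT 10 OFFSET 2
        """
        ast = parse_query(text)
        assert parse_query(to_sparql(ast)) == ast

    def test_values_roundtrip(self):
        text = 'SELECT ?s WHERE { ?s ?p ?o . VALUES (?o) { (1) (UNDEF) ("x") } }'
        ast = parse_query(text)
        assert parse_query(to_sparql(ast)) == ast


class TestGroupingValidation:
    def test_plain_variable_outside_group_by_rejected(self):
        with pytest.raises(SparqlSyntaxError):
            parse_query(
                "SELECT ?o (COUNT(?s) AS ?n) WHERE { ?s ?p ?o } GROUP BY ?p"
            )

    def test_aggregate_without_group_by_is_single_group(self):
        ast = parse_query("SELECT (COUNT(*) AS ?n) WHERE { ?s ?p ?o }")
        assert ast.has_aggregates and not ast.group_by
        assert isinstance(ast.projection[0].expr, Aggregate)
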