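"""Terms, quad store, N-Triples round trips, and the reference evaluator."""

import io

import pytest
from hypothesis import given, strategies as st

from chemobda import (
    IRI,
    Literal,
    Quad,
    QuadStore,
    SolutionMultiset,
    evaluate_oracle,
    parse_query,
    read_ntriples,
    write_ntriples,
)
from chemobda.rdf_core import (
    DEFAULT_GRAPH,
    NTriplesParseError,
    RDF_LANGSTRING,
    RDF_TYPE,
    RDFError,
    XSD_INTEGER,
    XSD_STRING,
)

CCO = "http://rdf.ebi.ac.uk/terms/chembl#"


class TestTerms:
    def test_iri_requires_scheme(self):
        with pytest.raises(RDFError):
            IRI("no-scheme-here")
        with pytest.raises(RDFError):
            IRI("")

    def test_plain_literal_is_xsd_string(self):
        assert Literal("hello").datatype == XSD_STRING

    def test_language_tag_forces_langstring(self):
        lit = Literal("hola", language="es")
        assert lit.datatype == RDF_LANGSTRING

    def test_term_equality_is_componentwise(self):
        assert Literal("5", XSD_INTEGER) == Literal("5", XSD_INTEGER)
        assert Literal("5", XSD_INTEGER) != Literal("5", XSD_STRING)

    def test_quad_predicate_must_be_iri(self):
        with pytest.raises(RDFError):
            Quad(IRI("http://a/s"), Literal("p"), IRI("http://a/o"))


class TestStore:
    def test_empty_store_wildcard_match(self):
        assert QuadStore().match() == set()

    def test_duplicate_insert_is_noop(self):
        q = Quad(IRI("http://a/s"), IRI("http://a/p"), Literal("x"))
        store = QuadStore([q, q])
        store.add(q)
        assert len(store) == 1

    def test_match_by_fixed_predicate(self):
        q1 = Quad(IRI("http://a/s"), IRI("http://a/p"), Literal("x"))
        q2 = Quad(IRI("http://a/s"), IRI("http://a/q"), Literal("y"))
        store = QuadStore([q1, q2])
        assert store.match(predicate=IRI("http://a/p")) == {q1}

    def test_fig_fixture_document_type_count(self, fig_world):
        _, _, _, store = fig_world
        hits = store.match(None, IRI(RDF_TYPE), IRI(CCO + "Document"), DEFAULT_GRAPH)
        assert len(hits) == 4
        assert len(store.match(None, IRI(RDF_TYPE), IRI(CCO + "Journal"))) == 2


class TestNTriples:
    def roundtrip(self, store):
        buf = io.StringIO()
        write_ntriples(store, buf)
        buf.seek(0)
        return read_ntriples(buf)

    def test_empty_roundtrip(self):
        assert len(self.roundtrip(QuadStore())) == 0

    def test_typed_literal_roundtrip(self):
        q = Quad(IRI("http://a/s"), IRI("http://a/p"), Literal("42", XSD_INTEGER))
        store = QuadStore([q])
        buf = io.StringIO()
        write_ntriples(store, buf)
        line = buf.getvalue().strip()
        assert line.endswith(f'"42"^^<{XSD_INTEGER}> .')
        assert self.roundtrip(store) == store

    def test_escapes_roundtrip(self):
        q = Quad(IRI("http://a/s"), IRI("http://a/p"), Literal('say "hi"\n\ttab'))
        store = QuadStore([q])
        assert self.roundtrip(store) == store

    def test_fig_store_roundtrip(self, fig_world):
        _, _, _, store = fig_world
        assert self.roundtrip(store) == store

    def test_named_graph_rejected_by_writer(self):
        q = Quad(IRI("http://a/s"), IRI("http://a/p"), Literal("x"), IRI("http://g"))
        with pytest.raises(RDFError):
            write_ntriples(QuadStore([q]), io.StringIO())

    def test_parse_error_carries_line_number(self):
        doc = '<http://a/s> <http://a/p> "ok" .\n<broken line\n'
        with pytest.raises(NTriplesParseError) as exc:
            read_ntriples(io.StringIO(doc))
        assert exc.value.line == 2


class TestOracle:
    def test_any_query_on_empty_store(self):
        ast = parse_query("SELECT ?s WHERE { ?s ?p ?o }")
        assert len(evaluate_oracle(ast, QuadStore())) == 0

    def test_fig_query_row_count(self, fig_world):
        bundle, _, _, store = fig_world
        ast = parse_query(bundle.queries["documents_with_journals"])
        result = evaluate_oracle(ast, store)
        assert len(result) == 3  # one per document with a journal link

    def test_grouped_count_matches_brute_force(self, fig_world):
        _, _, _, store = fig_world
        ast = parse_query(
            """
            SELECT ?journal (COUNT(?document) AS ?n) WHERE {
              ?document <http://rdf.ebi.ac.uk/terms/chembl#hasJournal> ?journal .
            } GROUP BY ?journal
            """
        )
        result = evaluate_oracle(ast, store)
        tally = {}
        for q in store.match(predicate=IRI(CCO + "hasJournal")):
            tally[q.object] = tally.get(q.object, 0) + 1
        got = {r["journal"]: int(r["n"].lexical) for r in result.rows}
        assert got == tally

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["s1", "s2", "s3"]),
                st.sampled_from(["p1", "p2"]),
                st.sampled_from(["o1", "o2", "o3"]),
            ),
            max_size=12,
        ),
        st.tuples(
            st.sampled_from(["s1", "s2", "s3"]),
            st.sampled_from(["p1", "p2"]),
            st.sampled_from(["o1", "o2"]),
        ),
    )
    def test_bgp_monotonicity(self, triples, extra):
        """Adding quads never removes BGP solutions."""

        def mk(t):
            return Quad(IRI("http://x/" + t[0]), IRI("http://x/" + t[1]), IRI("http://x/" + t[2]))

        ast = parse_query(
            "SELECT ?a ?b WHERE { ?a <http://x/p1> ?b . ?b <http://x/p2> ?c }"
        )
        small = QuadStore(mk(t) for t in triples)
        big = QuadStore(mk(t) for t in triples)
        big.add(mk(extra))
        before = evaluate_oracle(ast, small).key_counter()
        after = evaluate_oracle(ast, big).key_counter()
        assert all(after[k] >= n for k, n in before.items())


class TestSolutionMultiset:
    def test_equality_is_order_insensitive(self):
        a = SolutionMultiset(["x"], [{"x": Literal("1", XSD_INTEGER)}, {"x": Literal("2", XSD_INTEGER)}])
        b = SolutionMultiset(["x"], [{"x": Literal("2", XSD_INTEGER)}, {"x": Literal("1", XSD_INTEGER)}])
        assert a == b

    def test_multiplicity_matters(self):
        row = {"x": Literal("1", XSD_INTEGER)}
        assert SolutionMultiset(["x"], [row, row]) != SolutionMultiset(["x"], [row])


def test_oracle_agrees_with_rdflib_on_fixture_query(fig_world):
    """Cross-check the reference evaluator against an independent
    third-party SPARQL implementation on the worked example."""
    import rdflib

    bundle, _, _, store = fig_world
    g = rdflib.Graph()
    buf = io.StringIO()
    write_ntriples(store, buf)
    g.parse(data=buf.getvalue(), format="nt")
    from chemobda.sparql_frontend import DEFAULT_PREFIXES

    text = bundle.queries["documents_with_journal_titles"]
    ours = evaluate_oracle(parse_query(text), store)
    init_ns = {k: rdflib.Namespace(v) for k, v in DEFAULT_PREFIXES.items()}
    theirs = {
        (str(r["document"]), str(r["title"]), str(r["short"]))
        for r in g.query(text, initNs=init_ns)
    }
    got = {
        (row["document"].value, row["title"].lexical, row["short"].lexical)
        for row in ours.rows
    }
    assert got == theirs and len(ours) == len(theirs)
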