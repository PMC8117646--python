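"""The central property: the SQL engine is equivalent to the reference
SPARQL evaluator on every packaged query and on random (query, data)
instances, optimized or not."""

import io
import random

import pytest

from chemobda import (
    SynthConfig,
    build_toy_bundle,
    compile_query,
    evaluate_oracle,
    materialize,
    parse_query,
    random_query,
    solutions_equal,
    write_ntriples,
)
from chemobda.sparql_eval import order_comparator


def _check(ast, ms, db, store):
    oracle = evaluate_oracle(ast, store)
    engine = db.execute(compile_query(ast, ms))
    plain = db.execute(compile_query(ast, ms, do_optimize=False))
    if isinstance(oracle, bool):
        assert engine == oracle == plain
        return
    cmp = order_comparator(ast.order_by, store) if ast.order_by and ast.limit is None else None
    assert solutions_equal(engine, oracle, cmp)
    assert solutions_equal(plain, oracle, cmp)


@pytest.mark.parametrize("bundle_name", ["fig", "toy"])
def test_fixture_queries_match_oracle(bundle_name, fig_world, toy_world):
    bundle, ms, db, store = fig_world if bundle_name == "fig" else toy_world
    for name in sorted(bundle.queries):
        _check(parse_query(bundle.queries[name]), ms, db, store)


def test_random_instances_match_oracle():
    """Seeded random (query, data) instances: engine == oracle, and the
    optimizer never changes the result multiset."""
    for dseed in (11, 12):
        bundle = build_toy_bundle(SynthConfig(seed=dseed))
        ms = bundle.mapping_set()
        db = bundle.make_database()
        store = materialize(ms, db)
        for qseed in range(20):
            rng = random.Random(dseed * 100 + qseed)
            text = random_query(rng)
            _check(parse_query(text), ms, db, store)


def test_modifier_queries_match_oracle(toy_world):
    """Targeted constructs the random generator exercises rarely."""
    bundle, ms, db, store = toy_world
    texts = [
        # VALUES joined against a pattern
        """SELECT ?s ?o WHERE { ?s vocab:PubChemAssayOutcome ?o .
           VALUES ?o { vocab:active } }""",
        # ORDER BY with LIMIT/OFFSET over unique sort keys
        """SELECT ?d ?pmid WHERE { ?d bibo:pmid ?pmid } ORDER BY DESC(?pmid) LIMIT 5 OFFSET 2""",
        # HAVING over a grouped count
        """SELECT ?p (COUNT(?s) AS ?n) WHERE { ?s obo:BFO_0000056 ?m . ?m obo:RO_0000057 ?p }
           GROUP BY ?p HAVING (COUNT(?s) > 3)""",
        # arithmetic and logical connectives in FILTER
        """SELECT ?e WHERE { ?e sio:SIO_000300 ?v . FILTER (?v * 2 < 5 || ?v >= 900) }""",
        # IN over IRIs
        """SELECT ?e WHERE { ?e vocab:PubChemAssayOutcome ?o .
           FILTER (?o IN (vocab:active, vocab:inconclusive)) }""",
        # MINUS with shared variable
        """SELECT ?s WHERE { ?s obo:BFO_0000056 ?m MINUS { ?s cheminf:CHEMINF_000477 ?c } }""",
        # isIRI and bound over an optional variable
        """SELECT ?m ?c WHERE { ?m rdf:type cco:Substance .
           OPTIONAL { ?s skos:exactMatch ?m . ?s cheminf:CHEMINF_000477 ?c }
           FILTER (!bound(?c) || isIRI(?c)) }""",
        # union with aggregation on top
        """SELECT (COUNT(?x) AS ?n) WHERE {
           { ?x ex:hasStructure true } UNION { ?x ex:importedFromPubChem false } }""",
        # SUM / AVG / MIN / MAX over measured values
        """SELECT (SUM(?v) AS ?total) (AVG(?v) AS ?mean) (MIN(?v) AS ?lo) (MAX(?v) AS ?hi)
           WHERE { ?e sio:SIO_000300 ?v }""",
        # COUNT DISTINCT over a composite-key IRI variable
        """SELECT (COUNT(DISTINCT ?m) AS ?n) WHERE { ?m obo:OBI_0000299 ?e }""",
        # ASK with a filter
        """ASK { ?e sio:SIO_000300 ?v . FILTER (?v < 0.01) }""",
        # aggregate over the empty solution set: COUNT 0, SUM 0, AVG unbound
        """SELECT (COUNT(?v) AS ?n) (SUM(?v) AS ?t) (AVG(?v) AS ?m) WHERE {
           ?e sio:SIO_000300 ?v . FILTER (?v < -1) }""",
        # variable predicate
        """SELECT ?p (COUNT(*) AS ?n) WHERE { ?s ?p ?o . ?s rdf:type cco:Mechanism }
           GROUP BY ?p""",
    ]
    for text in texts:
        _check(parse_query(text), ms, db, store)


def test_engine_agrees_with_rdflib_on_audit_query(toy_world):
    """Independent third-party cross-check on a negation-heavy query."""
    import rdflib

    from chemobda.sparql_frontend import DEFAULT_PREFIXES

    bundle, ms, db, store = toy_world
    g = rdflib.Graph()
    buf = io.StringIO()
    write_ntriples(store, buf)
    g.parse(data=buf.getvalue(), format="nt")
    text = bundle.queries["audit_lost_documents"]
    engine = db.execute(compile_query(parse_query(text), ms))
    init_ns = {k: rdflib.Namespace(v) for k, v in DEFAULT_PREFIXES.items()}
    theirs = {str(r["document"]) for r in g.query(text, initNs=init_ns)}
    assert {row["document"].value for row in engine.rows} == theirs
    assert len(engine) == len(theirs) == bundle.manifest["audit_lost_documents"]
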