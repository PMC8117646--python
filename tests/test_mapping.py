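"""IRI class bijections, mapping validation, and materialisation."""

import pytest
from hypothesis import given, strategies as st

from chemobda import (
    IRI,
    IRIClass,
    MappingError,
    iri_decode,
    iri_encode,
    materialize,
    parse_mapping_config,
)
from chemobda.rdf_core import RDF_TYPE

DOC_CLS = IRIClass("document", "http://example.org/doc/CHEMBL{id:integer}")
EP_CLS = IRIClass(
    "endpoint", "http://example.org/ep/SID{sid:integer}_AID{aid:integer}_{mg:integer}"
)
TXT_CLS = IRIClass("named", "http://example.org/n/{name:text}/x")


class TestIRICodec:
    def test_encode_concatenates_template(self):
        assert iri_encode(DOC_CLS, (42,)) == IRI("http://example.org/doc/CHEMBL42")

    def test_decode_inverse_of_encode(self):
        assert iri_decode(DOC_CLS, "http://example.org/doc/CHEMBL42") == (42,)

    @pytest.mark.parametrize(
        "bad",
        [
            "http://example.org/doc/CHEMBLxyz",  # non-integer slot
            "http://other.org/doc/42",  # wrong prefix
            "http://example.org/doc/CHEMBL042",  # leading zero: non-canonical
            "http://example.org/doc/CHEMBL-42",  # sign
            "http://example.org/doc/CHEMBL42x",  # trailing garbage (anchored)
        ],
    )
    def test_decode_rejects_non_members(self, bad):
        assert iri_decode(DOC_CLS, bad) is None

    def test_encode_null_slot_is_error(self):
        with pytest.raises(ValueError):
            iri_encode(DOC_CLS, (None,))

    def test_arity_mismatch_is_error(self):
        with pytest.raises(ValueError):
            iri_encode(EP_CLS, (1, 2))

    @given(st.integers(0, 10**9), st.integers(0, 10**6), st.integers(0, 99))
    def test_composite_bijection(self, sid, aid, mg):
        iri = iri_encode(EP_CLS, (sid, aid, mg))
        assert iri_decode(EP_CLS, iri) == (sid, aid, mg)

    @given(st.text(alphabet=st.characters(codec="utf-8", exclude_characters="\x00"), min_size=1, max_size=20))
    def test_text_slot_bijection_survives_reserved_characters(self, value):
        iri = iri_encode(TXT_CLS, (value,))
        assert iri_decode(TXT_CLS, iri) == (value,)


class TestClassification:
    def test_every_declared_class_classifies_its_own_iris(self, toy_world):
        _, ms, _, _ = toy_world
        samples = {"integer": 7, "text": "active"}
        for cls in ms.iri_classes.values():
            values = tuple(samples[s.type] for s in cls.slots)
            hit = ms.classify_iri(cls.encode(values))
            assert hit is not None and hit[0].name == cls.name and hit[1] == values

    def test_unknown_iri_classifies_to_none(self, toy_world):
        _, ms, _, _ = toy_world
        assert ms.classify_iri(IRI("http://nowhere.example/thing/1")) is None

    def test_overlapping_templates_rejected_at_load(self):
        cfg = """
        schema: {tables: []}
        iri_classes:
          - {name: a, template: "http://x/{id:integer}"}
          - {name: b, template: "http://x/{id:integer}"}
        quad_mappings: []
        """
        with pytest.raises(MappingError) as exc:
            parse_mapping_config(cfg)
        assert any("identical templates" in v or "overlap" in v for v in exc.value.violations)


class TestValidation:
    def test_fig_mapping_set_is_valid(self, fig_bundle):
        assert fig_bundle.mapping_set().validate() == []

    def test_toy_mapping_set_is_valid(self, toy_bundle):
        assert toy_bundle.mapping_set().validate() == []

    def test_missing_column_reported(self):
        cfg = """
        schema:
          tables:
            - name: t
              columns: [{name: id, type: integer, notnull: true}]
              primary_key: [id]
        iri_classes:
          - {name: thing, template: "http://x/T{id:integer}"}
        quad_mappings:
          - {table: t, subject: "thing(id)", predicate: "rdf:type", object: "(missing)^^xsd:string"}
        """
        with pytest.raises(MappingError) as exc:
            parse_mapping_config(cfg)
        assert any("missing column" in v for v in exc.value.violations)

    def test_foreign_key_must_reference_full_primary_key(self):
        cfg = """
        schema:
          tables:
            - name: a
              columns:
                - {name: x, type: integer, notnull: true}
                - {name: y, type: integer, notnull: true}
              primary_key: [x, y]
            - name: b
              columns:
                - {name: id, type: integer, notnull: true}
                - {name: ax, type: integer}
              primary_key: [id]
              foreign_keys:
                - {columns: [ax], references: a, ref_columns: [x]}
        iri_classes:
          - {name: thing, template: "http://x/T{id:integer}"}
        quad_mappings: []
        """
        with pytest.raises(MappingError) as exc:
            parse_mapping_config(cfg)
        assert any("full primary key" in v for v in exc.value.violations)


class TestMaterialize:
    def test_empty_database_gives_empty_store(self, fig_bundle):
        ms = fig_bundle.mapping_set()
        db = __import__("chemobda").Database.create(":memory:", ms.schema)
        assert len(materialize(ms, db)) == 0

    def test_fig_type_counts(self, fig_world):
        _, _, _, store = fig_world
        cco = "http://rdf.ebi.ac.uk/terms/chembl#"
        docs = {q.subject for q in store.match(None, IRI(RDF_TYPE), IRI(cco + "Document"))}
        journals = {q.subject for q in store.match(None, IRI(RDF_TYPE), IRI(cco + "Journal"))}
        assert len(docs) == 4 and len(journals) == 2

    def test_null_required_column_emits_no_quad(self, fig_world):
        bundle, _, _, store = fig_world
        links = store.match(None, IRI("http://rdf.ebi.ac.uk/terms/chembl#hasJournal"))
        assert len(links) == 3  # the document with a null journal_id is skipped
        # but that document still has its type and title quads
        unlinked = IRI("http://rdf.ebi.ac.uk/resource/chembl/document/CHEMBL1160237")
        assert len(store.match(unlinked)) == 2

    def test_quad_count_matches_hand_count(self, fig_world):
        # 4 doc types + 4 titles + 3 links + 2 journal types + 2 short titles
        _, _, _, store = fig_world
        assert len(store) == 15

    def test_materialisation_is_monotone_in_the_data(self, fig_bundle):
        ms = fig_bundle.mapping_set()
        db = fig_bundle.make_database()
        before = materialize(ms, db)
        db.load_rows("documents", [{"id": 9999999, "title": "new", "journal_id": 4}])
        after = materialize(ms, db)
        assert all(q in after for q in before)
        assert len(after) == len(before) + 3  # type + title + link
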