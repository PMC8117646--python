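"""Embedded backend: schema DDL, loads, decoding, diff updates."""

import io

import pytest

from chemobda import (
    Database,
    IRI,
    Literal,
    compile_query,
    parse_query,
)
from chemobda.rdf_core import XSD_INTEGER
from chemobda.store_backend import BackendError


@pytest.fixture
def fig_ms(fig_bundle):
    return fig_bundle.mapping_set()


class TestSchema:
    def test_create_schema_declares_all_tables(self, fig_ms):
        db = Database.create(":memory:", fig_ms.schema)
        names = {
            r[0]
            for r in db.execute_sql(
                "SELECT name FROM sqlite_master WHERE type = 'table'"
            )
        }
        assert {"journals", "documents"} <= names

    def test_duplicate_create_fails(self, fig_ms):
        db = Database.create(":memory:", fig_ms.schema)
        with pytest.raises(BackendError):
            db.create_schema()

    def test_toy_schema_includes_case3_tables(self, toy_bundle):
        """The three tables the aggregate use case joins must exist."""
        db = Database.create(":memory:", toy_bundle.mapping_set().schema)
        names = {
            r[0]
            for r in db.execute_sql(
                "SELECT name FROM sqlite_master WHERE type = 'table'"
            )
        }
        assert {"pc_endpoint", "pc_mg_target", "pc_measurement"} <= names


class TestLoading:
    def test_fig_csv_loads_expected_counts(self, fig_bundle, fig_ms):
        db = Database.create(":memory:", fig_ms.schema)
        n_j = db.load_csv("journals", io.StringIO(fig_bundle.table_csv("journals")))
        n_d = db.load_csv("documents", io.StringIO(fig_bundle.table_csv("documents")))
        assert (n_j, n_d) == (2, 4)

    def test_fk_violation_aborts_whole_load(self, fig_bundle, fig_ms):
        db = Database.create(":memory:", fig_ms.schema)
        db.load_csv("journals", io.StringIO(fig_bundle.table_csv("journals")))
        rows = [
            {"id": 1, "title": "ok", "journal_id": 4},
            {"id": 2, "title": "bad fk", "journal_id": 999},
        ]
        with pytest.raises(BackendError):
            db.load_rows("documents", rows)
        assert db.fetch_rows("documents") == []  # atomic: nothing visible

    def test_empty_file_loads_zero_rows(self, fig_ms):
        db = Database.create(":memory:", fig_ms.schema)
        assert db.load_csv("journals", io.StringIO("id,short_title\n")) == 0

    def test_empty_csv_field_is_null(self, fig_bundle, fig_ms):
        db = Database.create(":memory:", fig_ms.schema)
        db.load_csv("journals", io.StringIO(fig_bundle.table_csv("journals")))
        db.load_csv("documents", io.StringIO('id,title,journal_id\n7,"t",\n'))
        assert db.fetch_rows("documents")[0]["journal_id"] is None


class TestDecoding:
    def test_result_terms_are_class_iris(self, fig_world):
        bundle, ms, db, _ = fig_world
        ast = parse_query(bundle.queries["documents_with_journals"])
        result = db.execute(compile_query(ast, ms))
        for row in result.rows:
            hit = ms.classify_iri(row["document"])
            assert hit is not None and hit[0].name == "document"
            assert isinstance(row["title"], Literal)

    def test_unmatched_optional_decodes_to_unbound(self, fig_world):
        bundle, ms, db, _ = fig_world
        ast = parse_query(
            """
            SELECT ?d ?j WHERE {
              ?d dcterms:title ?t .
              OPTIONAL { ?d cco:hasJournal ?j . }
            }
            """
        )
        result = db.execute(compile_query(ast, ms))
        unbound = [r for r in result.rows if r.get("j") is None]
        assert len(result) == 4 and len(unbound) == 1

    def test_count_decodes_to_integer_literal(self, fig_world):
        bundle, ms, db, _ = fig_world
        ast = parse_query("SELECT (COUNT(*) AS ?n) WHERE { ?d dcterms:title ?t }")
        result = db.execute(compile_query(ast, ms))
        (row,) = result.rows
        assert row["n"] == Literal("4", XSD_INTEGER)

    def test_ask_returns_boolean(self, fig_world):
        bundle, ms, db, _ = fig_world
        yes = parse_query("ASK { ?d rdf:type cco:Document }")
        no = parse_query("ASK { ?d rdf:type cco:Assay }")
        assert db.execute(compile_query(yes, ms)) is True
        assert db.execute(compile_query(no, ms)) is False


class TestDiffUpdate:
    def _db(self, fig_bundle):
        return fig_bundle.make_database()

    def test_insert_only_delta(self, fig_bundle):
        db = self._db(fig_bundle)
        rows = db.fetch_rows("journals") + [{"id": 99, "short_title": "New J."}]
        delta = db.diff_update("journals", rows)
        assert len(delta.inserts) == 1 and not delta.deletes and not delta.replacements

    def test_delete_and_replace_delta(self, fig_bundle):
        db = self._db(fig_bundle)
        incoming = [{"id": 4, "short_title": "J. Med. Chem. (2nd series)"}]
        # journal 12 is referenced by a document; retarget that document first
        db.execute_sql("UPDATE documents SET journal_id = 4 WHERE journal_id = 12")
        db.conn.commit()
        delta = db.diff_update("journals", incoming)
        assert len(delta.deletes) == 1 and len(delta.replacements) == 1
        assert db.fetch_rows("journals") == [
            {"id": 4, "short_title": "J. Med. Chem. (2nd series)"}
        ]

    def test_idempotence(self, fig_bundle):
        db = self._db(fig_bundle)
        snapshot = db.fetch_rows("documents")
        first = db.diff_update("documents", snapshot)
        second = db.diff_update("documents", snapshot)
        assert first.empty and second.empty

    def test_atomicity_under_injected_failure(self, fig_bundle):
        """A delta whose tail row violates a constraint leaves no trace."""
        db = self._db(fig_bundle)
        before = db.fetch_rows("documents")
        incoming = before + [
            {"id": 50, "title": "fine", "journal_id": 4},
            {"id": 51, "title": "broken", "journal_id": 12345},  # FK violation
        ]
        with pytest.raises(BackendError):
            db.diff_update("documents", incoming)
        assert db.fetch_rows("documents") == before

    def test_summary_counts(self, fig_bundle):
        db = self._db(fig_bundle)
        delta = db.diff_update("documents", db.fetch_rows("documents"))
        assert delta.summary() == "documents: 0 inserted, 0 deleted, 0 replaced"
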