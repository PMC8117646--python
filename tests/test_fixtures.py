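"""Synthetic world generator: determinism, planted truths, link derivation."""

import pytest

from chemobda import (
    SynthConfig,
    build_toy_bundle,
    compile_query,
    derive_pmid_links,
    parse_query,
)
from chemobda.chem_fixtures import AUDIT_MANIFEST_KEYS, ROLE_CLASS_ID, SynthConfigError


class TestDeterminism:
    def test_same_seed_gives_byte_identical_output(self):
        a = build_toy_bundle(SynthConfig(seed=42))
        b = build_toy_bundle(SynthConfig(seed=42))
        assert a.manifest == b.manifest
        for table in a.tables:
            assert a.table_csv(table) == b.table_csv(table)

    def test_different_seed_gives_different_data(self):
        a = build_toy_bundle(SynthConfig(seed=1))
        b = build_toy_bundle(SynthConfig(seed=2))
        assert any(a.table_csv(t) != b.table_csv(t) for t in a.tables)


class TestPlantedTruths:
    @pytest.mark.parametrize("seed", [0, 7])
    def test_audit_counts_equal_manifest(self, seed):
        bundle = build_toy_bundle(SynthConfig(seed=seed))
        ms = bundle.mapping_set()
        db = bundle.make_database()
        for name, key in AUDIT_MANIFEST_KEYS.items():
            ast = parse_query(bundle.queries[name])
            got = len(db.execute(compile_query(ast, ms)))
            assert got == bundle.manifest[key], name

    def test_clean_world_audits_return_zero(self):
        bundle = build_toy_bundle(SynthConfig(seed=3).clean())
        ms = bundle.mapping_set()
        db = bundle.make_database()
        for name in AUDIT_MANIFEST_KEYS:
            ast = parse_query(bundle.queries[name])
            assert len(db.execute(compile_query(ast, ms))) == 0, name

    def test_case2_returns_exactly_the_planted_proteins(self, toy_world):
        bundle, ms, db, _ = toy_world
        ast = parse_query(bundle.queries["case2_role_inhibited_proteins"])
        result = db.execute(compile_query(ast, ms))
        got = {ms.classify_iri(r["protein"])[1][0] for r in result.rows}
        assert got == set(bundle.manifest["case2_proteins"])

    def test_case1_row_count_matches_manifest(self, toy_world):
        bundle, ms, db, _ = toy_world
        ast = parse_query(bundle.queries["case1_scaffold_active_targets"])
        assert len(db.execute(compile_query(ast, ms))) == bundle.manifest["case1_result_rows"]


class TestGeneratedValues:
    def test_ic50_values_positive_and_within_bounds(self):
        cfg = SynthConfig(seed=5)
        bundle = build_toy_bundle(cfg)
        for row in bundle.tables["pc_measurement"]:
            assert 10 ** cfg.ic50_log10_lo * 0.999 <= row["value"] <= 10 ** cfg.ic50_log10_hi * 1.001
            assert row["value"] > 0

    def test_role_annotations_use_declared_role_class(self):
        bundle = build_toy_bundle(SynthConfig(seed=5))
        assert all(r["role_id"] == ROLE_CLASS_ID for r in bundle.tables["chebi_role"])

    def test_impossible_config_raises(self):
        with pytest.raises(SynthConfigError):
            build_toy_bundle(SynthConfig(seed=0, compounds=1, substances_per_compound=1,
                                         unlinked_molecules=5))
        with pytest.raises(SynthConfigError):
            build_toy_bundle(SynthConfig(seed=0, endpoints=10**6))


class TestPmidLinks:
    def test_shared_pmid_gives_one_link(self):
        links, dups = derive_pmid_links(
            [{"id": 1, "pmid": 12345}], [{"pmid": 12345}]
        )
        assert links == [{"document_id": 1, "pmid": 12345}] and not dups

    def test_null_pmid_never_matches(self):
        links, _ = derive_pmid_links([{"id": 1, "pmid": None}], [{"pmid": 12345}])
        assert links == []

    def test_unknown_pmid_gives_no_link(self):
        links, _ = derive_pmid_links([{"id": 1, "pmid": 777}], [{"pmid": 12345}])
        assert links == []

    def test_duplicate_pmids_recorded_for_review(self):
        links, dups = derive_pmid_links(
            [{"id": 1, "pmid": 5}, {"id": 2, "pmid": 5}], [{"pmid": 5}]
        )
        assert len(links) == 2 and dups == {5: [1, 2]}


class TestBundleIO:
    def test_write_and_reload_round_trip(self, tmp_path, toy_bundle):
        outdir = tmp_path / "bundle"
        toy_bundle.write(str(outdir))
        assert (outdir / "mapping.yaml").exists()
        assert (outdir / "manifest.json").exists()
        # a written CSV reloads into the same relational content
        from chemobda import Database

        ms = toy_bundle.mapping_set()
        db = Database.create(":memory:", ms.schema)
        for t in ms.schema.tables:
            db.load_csv(t.name, str(outdir / "data" / f"{t.name}.csv"))
        assert db.fetch_rows("pc_endpoint") == toy_bundle.tables["pc_endpoint"]
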