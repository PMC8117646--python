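"""Packaged fixtures: schemas, mappings, data and queries.

Two worlds ship with the package:

* the **journal/document bundle** — the two-table worked example used to
  demonstrate translation and both optimizations (self-join merge and
  foreign-key elimination);
* the **toy small-molecule world** — a seeded synthetic emulation of a
  PubChem/ChEMBL/ChEBI-style integrated database: substances standardised
  to compounds, bioassays divided into measure groups containing endpoints
  with outcomes/types/values, measure groups pointing at proteins,
  documents with PubMed identifiers on both sides, ChEBI classes with role
  annotations, and cross-dataset identity links.  The generator plants a
  configurable number of cross-dataset inconsistencies and records them in
  a manifest, so audit queries have an exact ground truth.

Chemical realism is a non-goal: structure search is replaced by a
generated boolean scaffold flag, and IC50 values are stored in a single
standard unit (micromolar) so thresholds are plain numeric comparisons.
"""

from __future__ import annotations

import csv
import io
import json
import os
import random
from dataclasses import dataclass, field, asdict
from typing import Optional

from .mapping_model import MappingSet, parse_mapping_config
from .store_backend import Database

# ---------------------------------------------------------------------------
# Journal/document worked-example bundle

FIG_MAPPING_YAML = """
schema:
  tables:
    - name: journals
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: short_title, type: text, notnull: true}
      primary_key: [id]
    - name: documents
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: title, type: text, notnull: true}
        - {name: journal_id, type: integer}
      primary_key: [id]
      foreign_keys:
        - {columns: [journal_id], references: journals, ref_columns: [id]}

iri_classes:
  - name: document
    template: "http://rdf.ebi.ac.uk/resource/chembl/document/CHEMBL{id:integer}"
  - name: journal
    template: "http://rdf.ebi.ac.uk/resource/chembl/journal/CHEMBL_JRN_{id:integer}"

quad_mappings:
  - {table: documents, subject: "document(id)", predicate: "rdf:type", object: "cco:Document",
     label: document-type}
  - {table: documents, subject: "document(id)", predicate: "dcterms:title",
     object: "(title)^^xsd:string", label: document-title}
  - {table: documents, subject: "document(id)", predicate: "cco:hasJournal",
     object: "journal(journal_id)", label: document-journal}
  - {table: journals, subject: "journal(id)", predicate: "rdf:type", object: "cco:Journal",
     label: journal-type}
  - {table: journals, subject: "journal(id)", predicate: "bibo:shortTitle",
     object: "(short_title)^^xsd:string", label: journal-shorttitle}
"""

#: the document/journal query whose translation shrinks from three derived
#: tables to one (documents joined to themselves on the primary key merge;
#: the journals reference is removed through the journal_id foreign key)
FIG_QUERY = """
SELECT ?document ?title ?journal WHERE {
  ?document dcterms:title ?title .
  ?document cco:hasJournal ?journal .
  ?journal rdf:type cco:Journal .
}
"""

#: variant that also fetches the journal's short title (the journals table
#: then exports a non-key column and must survive optimization)
FIG_QUERY_TITLES = """
SELECT ?document ?title ?short WHERE {
  ?document dcterms:title ?title .
  ?document cco:hasJournal ?journal .
  ?journal bibo:shortTitle ?short .
}
"""


@dataclass
class FixtureBundle:
    """A self-contained world: schema+mapping config, data, queries, truth."""

    name: str
    mapping_yaml: str
    tables: dict[str, list[dict]]
    queries: dict[str, str] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    _ms: Optional[MappingSet] = None

    def mapping_set(self) -> MappingSet:
        if self._ms is None:
            self._ms = parse_mapping_config(self.mapping_yaml)
        return self._ms

    def make_database(self, path: str = ":memory:") -> Database:
        ms = self.mapping_set()
        db = Database.create(path, ms.schema)
        for t in ms.schema.tables:  # declaration order respects FKs
            rows = self.tables.get(t.name, [])
            if rows:
                db.load_rows(t.name, rows)
        return db

    def table_csv(self, table: str) -> str:
        ms = self.mapping_set()
        decl = ms.schema.table(table)
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(decl.column_names)
        for row in self.tables.get(table, []):
            writer.writerow(
                ["" if row.get(c) is None else row.get(c) for c in decl.column_names]
            )
        return buf.getvalue()

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "mapping.yaml"), "w", encoding="utf-8") as fh:
            fh.write(self.mapping_yaml)
        datadir = os.path.join(outdir, "data")
        os.makedirs(datadir, exist_ok=True)
        for table in self.mapping_set().schema.tables:
            with open(os.path.join(datadir, f"{table.name}.csv"), "w", encoding="utf-8") as fh:
                fh.write(self.table_csv(table.name))
        qdir = os.path.join(outdir, "queries")
        os.makedirs(qdir, exist_ok=True)
        for name, text in sorted(self.queries.items()):
            with open(os.path.join(qdir, f"{name}.rq"), "w", encoding="utf-8") as fh:
                fh.write(text.strip() + "\n")
        with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


def build_fig_fixture() -> FixtureBundle:
    """The packaged two-table journal/document bundle (4 documents, 2
    journals; 3 documents carry a journal link, 1 does not)."""
    tables = {
        "journals": [
            {"id": 4, "short_title": "J. Med. Chem."},
            {"id": 12, "short_title": "Bioorg. Med. Chem. Lett."},
        ],
        "documents": [
            {"id": 1139452, "title": "Synthesis of potent kinase inhibitors", "journal_id": 4},
            {"id": 1148466, "title": "Acetylcholinesterase ligands revisited", "journal_id": 4},
            {"id": 1155381, "title": "Fragment screening of protease targets", "journal_id": 12},
            {"id": 1160237, "title": "Deposited screening summary", "journal_id": None},
        ],
    }
    return FixtureBundle(
        name="journals",
        mapping_yaml=FIG_MAPPING_YAML,
        tables=tables,
        queries={
            "documents_with_journals": FIG_QUERY,
            "documents_with_journal_titles": FIG_QUERY_TITLES,
        },
        manifest={"documents": 4, "journals": 2, "linked_documents": 3},
    )


# ---------------------------------------------------------------------------
# Toy small-molecule world

TOY_MAPPING_YAML = """
schema:
  tables:
    - name: chebi_class
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: parent_id, type: integer}
      primary_key: [id]
      foreign_keys:
        - {columns: [parent_id], references: chebi_class, ref_columns: [id]}
    - name: chebi_role
      columns:
        - {name: class_id, type: integer, notnull: true}
        - {name: role_id, type: integer, notnull: true}
      primary_key: [class_id, role_id]
      foreign_keys:
        - {columns: [class_id], references: chebi_class, ref_columns: [id]}
        - {columns: [role_id], references: chebi_class, ref_columns: [id]}
    - name: pc_compound
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: scaffold_hit, type: boolean, notnull: true}
      primary_key: [id]
    - name: pc_substance
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: compound_id, type: integer}
      primary_key: [id]
      foreign_keys:
        - {columns: [compound_id], references: pc_compound, ref_columns: [id]}
    - name: pc_substance_type
      columns:
        - {name: substance_id, type: integer, notnull: true}
        - {name: chebi_id, type: integer, notnull: true}
      primary_key: [substance_id, chebi_id]
      foreign_keys:
        - {columns: [substance_id], references: pc_substance, ref_columns: [id]}
        - {columns: [chebi_id], references: chebi_class, ref_columns: [id]}
    - name: pc_protein
      columns:
        - {name: id, type: integer, notnull: true}
      primary_key: [id]
    - name: pc_assay
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: title, type: text, notnull: true}
      primary_key: [id]
    - name: pc_mg
      columns:
        - {name: assay_id, type: integer, notnull: true}
        - {name: mg_no, type: integer, notnull: true}
      primary_key: [assay_id, mg_no]
      foreign_keys:
        - {columns: [assay_id], references: pc_assay, ref_columns: [id]}
    - name: pc_mg_target
      columns:
        - {name: assay_id, type: integer, notnull: true}
        - {name: mg_no, type: integer, notnull: true}
        - {name: protein_id, type: integer, notnull: true}
      primary_key: [assay_id, mg_no]
      foreign_keys:
        - {columns: [assay_id, mg_no], references: pc_mg, ref_columns: [assay_id, mg_no]}
        - {columns: [protein_id], references: pc_protein, ref_columns: [id]}
    - name: pc_endpoint
      columns:
        - {name: substance_id, type: integer, notnull: true}
        - {name: assay_id, type: integer, notnull: true}
        - {name: mg_no, type: integer, notnull: true}
        - {name: outcome, type: text, notnull: true}
      primary_key: [substance_id, assay_id, mg_no]
      foreign_keys:
        - {columns: [substance_id], references: pc_substance, ref_columns: [id]}
        - {columns: [assay_id, mg_no], references: pc_mg, ref_columns: [assay_id, mg_no]}
    - name: pc_measurement
      columns:
        - {name: substance_id, type: integer, notnull: true}
        - {name: assay_id, type: integer, notnull: true}
        - {name: mg_no, type: integer, notnull: true}
        - {name: mtype, type: text, notnull: true}
        - {name: value, type: real, notnull: true}
      primary_key: [substance_id, assay_id, mg_no]
      foreign_keys:
        - {columns: [substance_id, assay_id, mg_no], references: pc_endpoint,
           ref_columns: [substance_id, assay_id, mg_no]}
    - name: pc_reference
      columns:
        - {name: pmid, type: integer, notnull: true}
      primary_key: [pmid]
    - name: ch_molecule
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: has_structure, type: boolean, notnull: true}
      primary_key: [id]
    - name: ch_assay
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: from_pubchem, type: boolean, notnull: true}
      primary_key: [id]
    - name: ch_document
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: pmid, type: integer}
      primary_key: [id]
    - name: ch_activity
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: assay_id, type: integer, notnull: true}
        - {name: molecule_id, type: integer, notnull: true}
        - {name: document_id, type: integer}
      primary_key: [id]
      foreign_keys:
        - {columns: [assay_id], references: ch_assay, ref_columns: [id]}
        - {columns: [molecule_id], references: ch_molecule, ref_columns: [id]}
        - {columns: [document_id], references: ch_document, ref_columns: [id]}
    - name: ch_mechanism
      columns:
        - {name: id, type: integer, notnull: true}
        - {name: molecule_id, type: integer, notnull: true}
        - {name: description, type: text, notnull: true}
        - {name: action_type, type: text, notnull: true}
      primary_key: [id]
      foreign_keys:
        - {columns: [molecule_id], references: ch_molecule, ref_columns: [id]}
    - name: link_substance
      columns:
        - {name: substance_id, type: integer, notnull: true}
        - {name: molecule_id, type: integer, notnull: true}
      primary_key: [substance_id]
      foreign_keys:
        - {columns: [substance_id], references: pc_substance, ref_columns: [id]}
        - {columns: [molecule_id], references: ch_molecule, ref_columns: [id]}
    - name: link_assay
      columns:
        - {name: pc_assay_id, type: integer, notnull: true}
        - {name: ch_assay_id, type: integer, notnull: true}
      primary_key: [pc_assay_id]
      foreign_keys:
        - {columns: [pc_assay_id], references: pc_assay, ref_columns: [id]}
        - {columns: [ch_assay_id], references: ch_assay, ref_columns: [id]}
    - name: link_document
      columns:
        - {name: document_id, type: integer, notnull: true}
        - {name: pmid, type: integer, notnull: true}
      primary_key: [document_id]
      foreign_keys:
        - {columns: [document_id], references: ch_document, ref_columns: [id]}
        - {columns: [pmid], references: pc_reference, ref_columns: [pmid]}

iri_classes:
  - {name: compound, template: "http://rdf.ncbi.nlm.nih.gov/pubchem/compound/CID{id:integer}"}
  - {name: substance, template: "http://rdf.ncbi.nlm.nih.gov/pubchem/substance/SID{id:integer}"}
  - {name: bioassay, template: "http://rdf.ncbi.nlm.nih.gov/pubchem/bioassay/AID{id:integer}"}
  - {name: measuregroup,
     template: "http://rdf.ncbi.nlm.nih.gov/pubchem/measuregroup/AID{aid:integer}_{mg:integer}"}
  - {name: endpoint,
     template: "http://rdf.ncbi.nlm.nih.gov/pubchem/endpoint/SID{sid:integer}_AID{aid:integer}_{mg:integer}"}
  - {name: pcprotein, template: "http://rdf.ncbi.nlm.nih.gov/pubchem/protein/ACC{id:integer}"}
  - {name: reference, template: "http://rdf.ncbi.nlm.nih.gov/pubchem/reference/PMID{pmid:integer}"}
  - {name: outcome,
     template: "http://rdf.ncbi.nlm.nih.gov/pubchem/vocabulary#{outcome:text}"}
  - {name: chebi, template: "http://purl.obolibrary.org/obo/CHEBI_{id:integer}"}
  - {name: restriction,
     template: "http://example.org/chemtoy/restriction/CHEBI{cls:integer}_{role:integer}"}
  - {name: molecule,
     template: "http://rdf.ebi.ac.uk/resource/chembl/molecule/CHEMBL{id:integer}"}
  - {name: chassay, template: "http://rdf.ebi.ac.uk/resource/chembl/assay/CHEMBL_ASY_{id:integer}"}
  - {name: chdocument,
     template: "http://rdf.ebi.ac.uk/resource/chembl/document/CHEMBL_DOC_{id:integer}"}
  - {name: chactivity,
     template: "http://rdf.ebi.ac.uk/resource/chembl/activity/CHEMBL_ACT_{id:integer}"}
  - {name: chmechanism,
     template: "http://rdf.ebi.ac.uk/resource/chembl/drug_mechanism/CHEMBL_MEC_{id:integer}"}

quad_mappings:
  # --- ChEBI: hierarchy and role annotations (OWL restriction shape) ---
  - {table: chebi_class, subject: "chebi(id)", predicate: "rdfs:subClassOf",
     object: "chebi(parent_id)", label: chebi-parent}
  - {table: chebi_role, subject: "chebi(class_id)", predicate: "rdfs:subClassOf",
     object: "restriction(class_id, role_id)", label: chebi-role-subclass}
  - {table: chebi_role, subject: "restriction(class_id, role_id)", predicate: "rdf:type",
     object: "owl:Restriction", label: chebi-role-restriction-type}
  - {table: chebi_role, subject: "restriction(class_id, role_id)", predicate: "owl:onProperty",
     object: "obo:RO_0000087", label: chebi-role-onproperty}
  - {table: chebi_role, subject: "restriction(class_id, role_id)", predicate: "owl:someValuesFrom",
     object: "chebi(role_id)", label: chebi-role-somevalues}
  # --- PubChem ---
  - {table: pc_compound, subject: "compound(id)", predicate: "rdf:type",
     object: "sio:SIO_010004", label: compound-type}
  - {table: pc_compound, subject: "compound(id)", predicate: "rdf:type",
     object: "ex:ScaffoldHit", condition: {scaffold_hit: 1}, label: compound-scaffold}
  - {table: pc_substance, subject: "substance(id)", predicate: "cheminf:CHEMINF_000477",
     object: "compound(compound_id)", label: substance-standardized}
  - {table: pc_substance_type, subject: "substance(substance_id)", predicate: "rdf:type",
     object: "chebi(chebi_id)", label: substance-chebi-type}
  - {table: pc_protein, subject: "pcprotein(id)", predicate: "rdf:type",
     object: "bp:Protein", label: protein-type}
  - {table: pc_assay, subject: "bioassay(id)", predicate: "rdf:type",
     object: "bao:BAO_0000015", label: bioassay-type}
  - {table: pc_assay, subject: "bioassay(id)", predicate: "dcterms:title",
     object: "(title)^^xsd:string", label: bioassay-title}
  - {table: pc_mg, subject: "measuregroup(assay_id, mg_no)", predicate: "rdf:type",
     object: "bao:BAO_0000040", label: mg-type}
  - {table: pc_mg, subject: "bioassay(assay_id)", predicate: "bao:BAO_0000209",
     object: "measuregroup(assay_id, mg_no)", label: assay-mg}
  - {table: pc_mg_target, subject: "measuregroup(assay_id, mg_no)", predicate: "obo:RO_0000057",
     object: "pcprotein(protein_id)", label: mg-protein}
  - {table: pc_endpoint, subject: "endpoint(substance_id, assay_id, mg_no)",
     predicate: "rdf:type", object: "bao:BAO_0003115", label: endpoint-type}
  - {table: pc_endpoint, subject: "endpoint(substance_id, assay_id, mg_no)",
     predicate: "obo:IAO_0000136", object: "substance(substance_id)", label: endpoint-substance}
  - {table: pc_endpoint, subject: "measuregroup(assay_id, mg_no)",
     predicate: "obo:OBI_0000299", object: "endpoint(substance_id, assay_id, mg_no)",
     label: mg-endpoint}
  - {table: pc_endpoint, subject: "substance(substance_id)", predicate: "obo:BFO_0000056",
     object: "measuregroup(assay_id, mg_no)", label: substance-mg}
  - {table: pc_endpoint, subject: "endpoint(substance_id, assay_id, mg_no)",
     predicate: "vocab:PubChemAssayOutcome", object: "outcome(outcome)", label: endpoint-outcome}
  - {table: pc_measurement, subject: "endpoint(substance_id, assay_id, mg_no)",
     predicate: "rdf:type", object: "bao:BAO_0000190", condition: {mtype: IC50},
     label: endpoint-ic50-type}
  - {table: pc_measurement, subject: "endpoint(substance_id, assay_id, mg_no)",
     predicate: "rdf:type", object: "bao:BAO_0000188", condition: {mtype: EC50},
     label: endpoint-ec50-type}
  - {table: pc_measurement, subject: "endpoint(substance_id, assay_id, mg_no)",
     predicate: "rdf:type", object: "bao:BAO_0000192", condition: {mtype: Ki},
     label: endpoint-ki-type}
  - {table: pc_measurement, subject: "endpoint(substance_id, assay_id, mg_no)",
     predicate: "sio:SIO_000300", object: "(value)^^xsd:double", label: endpoint-value}
  - {table: pc_reference, subject: "reference(pmid)", predicate: "rdf:type",
     object: "fabio:Article", label: reference-type}
  - {table: pc_reference, subject: "reference(pmid)", predicate: "bibo:pmid",
     object: "(pmid)^^xsd:integer", label: reference-pmid}
  # --- ChEMBL ---
  - {table: ch_molecule, subject: "molecule(id)", predicate: "rdf:type",
     object: "cco:Substance", label: molecule-type}
  - {table: ch_molecule, subject: "molecule(id)", predicate: "ex:hasStructure",
     object: "(has_structure)^^xsd:boolean", label: molecule-structure}
  - {table: ch_assay, subject: "chassay(id)", predicate: "rdf:type",
     object: "cco:Assay", label: chassay-type}
  - {table: ch_assay, subject: "chassay(id)", predicate: "ex:importedFromPubChem",
     object: "(from_pubchem)^^xsd:boolean", label: chassay-origin-flag}
  - {table: ch_document, subject: "chdocument(id)", predicate: "rdf:type",
     object: "cco:Document", label: chdocument-type}
  - {table: ch_document, subject: "chdocument(id)", predicate: "bibo:pmid",
     object: "(pmid)^^xsd:integer", label: chdocument-pmid}
  - {table: ch_activity, subject: "chactivity(id)", predicate: "rdf:type",
     object: "cco:Activity", label: activity-type}
  - {table: ch_activity, subject: "chassay(assay_id)", predicate: "cco:hasActivity",
     object: "chactivity(id)", label: assay-activity}
  - {table: ch_activity, subject: "molecule(molecule_id)", predicate: "cco:hasActivity",
     object: "chactivity(id)", label: molecule-activity}
  - {table: ch_activity, subject: "chactivity(id)", predicate: "cco:hasDocument",
     object: "chdocument(document_id)", label: activity-document}
  - {table: ch_mechanism, subject: "chmechanism(id)", predicate: "rdf:type",
     object: "cco:Mechanism", label: mechanism-type}
  - {table: ch_mechanism, subject: "molecule(molecule_id)", predicate: "cco:hasMechanism",
     object: "chmechanism(id)", label: molecule-mechanism}
  - {table: ch_mechanism, subject: "chmechanism(id)", predicate: "cco:mechanismDescription",
     object: "(description)^^xsd:string", label: mechanism-description}
  - {table: ch_mechanism, subject: "chmechanism(id)", predicate: "cco:mechanismActionType",
     object: "(action_type)^^xsd:string", label: mechanism-actiontype}
  # --- cross-dataset identity links ---
  - {table: link_substance, subject: "substance(substance_id)", predicate: "skos:exactMatch",
     object: "molecule(molecule_id)", label: link-substance}
  - {table: link_assay, subject: "bioassay(pc_assay_id)", predicate: "skos:exactMatch",
     object: "chassay(ch_assay_id)", label: link-assay}
  - {table: link_document, subject: "chdocument(document_id)", predicate: "skos:exactMatch",
     object: "reference(pmid)", label: link-document}
"""

#: ChEBI identifier of the cholinesterase-inhibitor role used by the
#: role-annotation use case
ROLE_CLASS_ID = 37733


@dataclass
class SynthConfig:
    """Study conditions for the toy world generator.

    IC50 values are log-uniform in micromolar between ``10**ic50_log10_lo``
    and ``10**ic50_log10_hi``, spanning potent (nanomolar) to inactive
    (millimolar) compounds around the conventional 10 uM activity cutoff.
    """

    seed: int = 0
    compounds: int = 60
    substances_per_compound: int = 2
    assays: int = 20
    mgs_per_assay: int = 2
    endpoints: int = 300
    proteins: int = 15
    documents: int = 30
    chebi_classes: int = 12
    role_annotated_classes: int = 3
    typed_substance_fraction: float = 0.3
    activity_fraction: float = 0.4
    scaffold_fraction: float = 0.25
    ic50_log10_lo: float = -3.0
    ic50_log10_hi: float = 3.0
    # planted cross-dataset inconsistencies (the audit ground truth)
    unlinked_molecules: int = 3
    unstandardized_molecules: int = 4
    unlinked_assays: int = 2
    lost_activities: int = 3
    docs_without_pmid: int = 5
    lost_documents: int = 2

    def clean(self) -> "SynthConfig":
        """Same world with zero planted inconsistencies."""
        cfg = SynthConfig(**asdict(self))
        cfg.unlinked_molecules = 0
        cfg.unstandardized_molecules = 0
        cfg.unlinked_assays = 0
        cfg.lost_activities = 0
        cfg.docs_without_pmid = 0
        cfg.lost_documents = 0
        return cfg


class SynthConfigError(ValueError):
    pass


def derive_pmid_links(docs: list[dict], refs: list[dict]):
    """Identity links between two document tables sharing PubMed IDs.

    One link per (doc, ref) pair with equal non-null PMIDs; null PMIDs
    never match.  Returns ``(links, duplicate_pairs)`` where duplicates
    arise from repeated PMIDs on the document side (recorded for review).
    """
    by_pmid: dict[int, int] = {}
    for r in refs:
        if r.get("pmid") is not None:
            by_pmid[r["pmid"]] = r["pmid"]
    links = []
    seen_pmids: dict[int, list[int]] = {}
    for d in docs:
        pmid = d.get("pmid")
        if pmid is None or pmid not in by_pmid:
            continue
        links.append({"document_id": d["id"], "pmid": pmid})
        seen_pmids.setdefault(pmid, []).append(d["id"])
    duplicates = {p: ids for p, ids in seen_pmids.items() if len(ids) > 1}
    return links, duplicates


def build_toy_bundle(config: Optional[SynthConfig] = None) -> FixtureBundle:
    """Deterministically generate the toy small-molecule world.

    Referential integrity holds everywhere except for the planted
    inconsistencies, whose exact counts are recorded in the manifest.
    """
    cfg = config or SynthConfig()
    rng = random.Random(cfg.seed)

    n_sub = cfg.compounds * cfg.substances_per_compound
    if cfg.unlinked_molecules + cfg.unstandardized_molecules > n_sub:
        raise SynthConfigError("more planted molecules than substances exist")
    if cfg.docs_without_pmid + cfg.lost_documents > cfg.documents:
        raise SynthConfigError("more planted documents than documents exist")
    n_mg = cfg.assays * cfg.mgs_per_assay
    if cfg.endpoints > n_sub * n_mg:
        raise SynthConfigError("more endpoints than substance/measure-group pairs")

    tables: dict[str, list[dict]] = {}

    # --- ChEBI ------------------------------------------------------------
    chebi_ids = [ROLE_CLASS_ID] + [10000 + i for i in range(cfg.chebi_classes)]
    chebi_rows = []
    for i, cid in enumerate(chebi_ids):
        parent = None
        if i >= 2:
            parent = rng.choice(chebi_ids[1:i])
        elif i == 1:
            parent = None
        chebi_rows.append({"id": cid, "parent_id": parent})
    tables["chebi_class"] = chebi_rows
    role_classes = sorted(rng.sample(chebi_ids[1:], min(cfg.role_annotated_classes, cfg.chebi_classes)))
    tables["chebi_role"] = [{"class_id": c, "role_id": ROLE_CLASS_ID} for c in role_classes]

    # --- PubChem compounds / substances, ChEMBL molecules -----------------
    compound_ids = [1000 + i for i in range(cfg.compounds)]
    tables["pc_compound"] = [
        {"id": cid, "scaffold_hit": 1 if rng.random() < cfg.scaffold_fraction else 0}
        for cid in compound_ids
    ]
    substance_ids = [2000 + i for i in range(n_sub)]
    molecule_ids = [i + 1 for i in range(n_sub)]
    k_a, k_b = cfg.unlinked_molecules, cfg.unstandardized_molecules
    unlinked = set(range(n_sub - k_a, n_sub))
    unstandardized = set(range(n_sub - k_a - k_b, n_sub - k_a))
    sub_rows, mol_rows, link_sub_rows = [], [], []
    for i in range(n_sub):
        comp = None if i in unstandardized or i in unlinked else compound_ids[i // cfg.substances_per_compound]
        sub_rows.append({"id": substance_ids[i], "compound_id": comp})
        mol_rows.append({"id": molecule_ids[i], "has_structure": 0 if i in unlinked else 1})
        if i not in unlinked:
            link_sub_rows.append({"substance_id": substance_ids[i], "molecule_id": molecule_ids[i]})
    tables["pc_substance"] = sub_rows
    tables["ch_molecule"] = mol_rows
    tables["link_substance"] = link_sub_rows

    # substance -> ChEBI class typing
    st_rows = []
    for i in range(n_sub):
        if rng.random() < cfg.typed_substance_fraction:
            st_rows.append(
                {"substance_id": substance_ids[i], "chebi_id": rng.choice(chebi_ids[1:])}
            )
    tables["pc_substance_type"] = st_rows

    # --- proteins, assays, measure groups ---------------------------------
    protein_ids = [7000 + i for i in range(cfg.proteins)]
    tables["pc_protein"] = [{"id": p} for p in protein_ids]
    assay_ids = [500 + i for i in range(cfg.assays)]
    tables["pc_assay"] = [
        {"id": a, "title": f"Confirmatory screen {a}"} for a in assay_ids
    ]
    mg_rows, mgt_rows = [], []
    mg_list = []
    for a in assay_ids:
        for m in range(1, cfg.mgs_per_assay + 1):
            mg_rows.append({"assay_id": a, "mg_no": m})
            mgt_rows.append(
                {"assay_id": a, "mg_no": m, "protein_id": rng.choice(protein_ids)}
            )
            mg_list.append((a, m))
    tables["pc_mg"] = mg_rows
    tables["pc_mg_target"] = mgt_rows
    mg_protein = {(r["assay_id"], r["mg_no"]): r["protein_id"] for r in mgt_rows}

    # --- ChEMBL assays and cross links ------------------------------------
    ch_assay_ids = [i + 1 for i in range(cfg.assays)]
    ch_assay_rows = [{"id": i, "from_pubchem": 0} for i in ch_assay_ids]
    next_ch_assay = cfg.assays + 1
    for _ in range(cfg.unlinked_assays):
        ch_assay_rows.append({"id": next_ch_assay, "from_pubchem": 0})
        next_ch_assay += 1
    n_from_pubchem = 2 if cfg.assays > 0 else 0
    for _ in range(n_from_pubchem):
        ch_assay_rows.append({"id": next_ch_assay, "from_pubchem": 1})
        next_ch_assay += 1
    tables["ch_assay"] = ch_assay_rows
    tables["link_assay"] = [
        {"pc_assay_id": a, "ch_assay_id": c} for a, c in zip(assay_ids, ch_assay_ids)
    ]
    pc_assay_of_ch = dict(zip(ch_assay_ids, assay_ids))

    # --- documents and references -----------------------------------------
    k_e, k_f = cfg.docs_without_pmid, cfg.lost_documents
    doc_rows = []
    lost_pmids = set()
    for i in range(cfg.documents):
        doc_id = i + 1
        if i >= cfg.documents - k_e:
            pmid = None
        else:
            pmid = 900000 + i
            if cfg.documents - k_e - k_f <= i < cfg.documents - k_e:
                lost_pmids.add(pmid)
        doc_rows.append({"id": doc_id, "pmid": pmid})
    tables["ch_document"] = doc_rows
    ref_rows = [
        {"pmid": d["pmid"]}
        for d in doc_rows
        if d["pmid"] is not None and d["pmid"] not in lost_pmids
    ]
    ref_rows += [{"pmid": 990001 + i} for i in range(3)]  # PubChem-only articles
    tables["pc_reference"] = ref_rows
    links, dup_pmids = derive_pmid_links(doc_rows, ref_rows)
    tables["link_document"] = links

    # --- endpoints, measurements, activities -------------------------------
    cells = rng.sample(range(n_sub * n_mg), cfg.endpoints)
    ep_rows, meas_rows = [], []
    endpoint_cells = set()
    ep_by_sub_assay: set[tuple[int, int]] = set()
    for cell in sorted(cells):
        si, mi = divmod(cell, n_mg)
        sid = substance_ids[si]
        aid, mg = mg_list[mi]
        outcome = "active" if rng.random() < cfg.activity_fraction else "inactive"
        ep_rows.append(
            {"substance_id": sid, "assay_id": aid, "mg_no": mg, "outcome": outcome}
        )
        mtype = rng.choice(["IC50", "IC50", "EC50", "Ki"])
        value = round(10 ** rng.uniform(cfg.ic50_log10_lo, cfg.ic50_log10_hi), 4)
        meas_rows.append(
            {
                "substance_id": sid,
                "assay_id": aid,
                "mg_no": mg,
                "mtype": mtype,
                "value": value,
            }
        )
        endpoint_cells.add((si, mi))
        ep_by_sub_assay.add((sid, aid))
    tables["pc_endpoint"] = ep_rows
    tables["pc_measurement"] = meas_rows

    act_rows = []
    next_act = 1
    doc_ids = [d["id"] for d in doc_rows]
    for row in ep_rows:
        si = row["substance_id"] - 2000
        if si in unlinked:
            continue
        ch_assay = next(
            (c for c, a in pc_assay_of_ch.items() if a == row["assay_id"]), None
        )
        if ch_assay is None:
            continue
        doc = rng.choice(doc_ids) if rng.random() < 0.9 else None
        act_rows.append(
            {
                "id": next_act,
                "assay_id": ch_assay,
                "molecule_id": molecule_ids[si],
                "document_id": doc,
            }
        )
        next_act += 1
    # planted: activities whose endpoint was never deposited on the PubChem side
    planted_lost = 0
    attempts = 0
    while planted_lost < cfg.lost_activities:
        attempts += 1
        if attempts > 10000:
            raise SynthConfigError("cannot place the requested lost activities")
        si = rng.randrange(n_sub)
        ci = rng.randrange(cfg.assays) if cfg.assays else None
        if ci is None:
            raise SynthConfigError("lost activities need at least one assay")
        if si in unlinked:
            continue
        ch_assay = ch_assay_ids[ci]
        aid = pc_assay_of_ch[ch_assay]
        if (substance_ids[si], aid) in ep_by_sub_assay:
            continue
        ep_by_sub_assay.add((substance_ids[si], aid))  # avoid duplicates
        act_rows.append(
            {
                "id": next_act,
                "assay_id": ch_assay,
                "molecule_id": molecule_ids[si],
                "document_id": None,
            }
        )
        next_act += 1
        planted_lost += 1
    tables["ch_activity"] = act_rows

    mech_rows = []
    for j, i in enumerate(range(0, min(10, n_sub))):
        mech_rows.append(
            {
                "id": j + 1,
                "molecule_id": molecule_ids[i],
                "description": f"inhibitor of target {protein_ids[j % len(protein_ids)]}",
                "action_type": "INHIBITOR",
            }
        )
    tables["ch_mechanism"] = mech_rows

    # --- manifest: planted ground truth ------------------------------------
    typed_role_subs = {
        r["substance_id"]
        for r in st_rows
        if r["chebi_id"] in role_classes
    }
    # a typed substance participates in a measure group; any IC50 endpoint
    # of that group below threshold qualifies the group's protein target
    mgs_of_typed = {
        (r["assay_id"], r["mg_no"])
        for r in ep_rows
        if r["substance_id"] in typed_role_subs
    }
    case2_proteins = set()
    for m in meas_rows:
        if m["mtype"] == "IC50" and m["value"] < 10 and (m["assay_id"], m["mg_no"]) in mgs_of_typed:
            prot = mg_protein.get((m["assay_id"], m["mg_no"]))
            if prot is not None:
                case2_proteins.add(prot)
    case1_triples = 0
    scaffold_compounds = {
        r["id"] for r in tables["pc_compound"] if r["scaffold_hit"]
    }
    sub_compound = {r["id"]: r["compound_id"] for r in sub_rows}
    for row in ep_rows:
        comp = sub_compound.get(row["substance_id"])
        if comp in scaffold_compounds and row["outcome"] == "active":
            if (row["assay_id"], row["mg_no"]) in mg_protein:
                case1_triples += 1

    manifest = {
        "seed": cfg.seed,
        "audit_unlinked_molecules": k_a,
        "audit_unstandardized_structures": k_b,
        "audit_lost_assays": cfg.unlinked_assays,
        "audit_lost_activities": cfg.lost_activities,
        "audit_docs_without_pmid": k_e,
        "audit_lost_documents": k_f,
        "case2_proteins": sorted(case2_proteins),
        "case1_result_rows": case1_triples,
        "duplicate_pmids": {str(k): v for k, v in dup_pmids.items()},
        "endpoints": len(ep_rows),
    }

    return FixtureBundle(
        name="toyworld",
        mapping_yaml=TOY_MAPPING_YAML,
        tables=tables,
        queries=build_case_queries(),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Use-case and audit queries


CASE1_QUERY = """
SELECT ?compound ?bioassay ?protein WHERE {
  ?compound rdf:type ex:ScaffoldHit .
  ?substance cheminf:CHEMINF_000477 ?compound .
  ?endpoint obo:IAO_0000136 ?substance .
  ?mg obo:OBI_0000299 ?endpoint .
  ?bioassay bao:BAO_0000209 ?mg .
  ?endpoint vocab:PubChemAssayOutcome vocab:active .
  ?mg obo:RO_0000057 ?protein .
  ?protein rdf:type bp:Protein .
}
"""

CASE2_QUERY = """
SELECT DISTINCT ?protein WHERE {
  ?class rdfs:subClassOf ?restriction .
  ?restriction owl:onProperty obo:RO_0000087 .
  ?restriction owl:someValuesFrom obo:CHEBI_37733 .
  ?substance rdf:type ?class .
  ?substance obo:BFO_0000056 ?mg .
  ?mg obo:OBI_0000299 ?endpoint .
  ?endpoint rdf:type bao:BAO_0000190 .
  ?endpoint sio:SIO_000300 ?value .
  ?mg obo:RO_0000057 ?protein .
  FILTER (?value < 10)
}
"""

CASE3_QUERY = """
SELECT ?protein (COUNT(?substance) AS ?count) WHERE {
  ?substance obo:BFO_0000056 ?mg .
  ?mg obo:OBI_0000299 ?endpoint .
  ?endpoint obo:IAO_0000136 ?substance .
  ?endpoint rdf:type bao:BAO_0000190 .
  ?endpoint sio:SIO_000300 ?value .
  ?mg obo:RO_0000057 ?protein .
  ?protein rdf:type bp:Protein .
}
GROUP BY ?protein
ORDER BY DESC(?count)
"""

AUDIT_QUERIES = {
    # molecules never deposited as PubChem substances
    "audit_unlinked_molecules": """
SELECT ?molecule WHERE {
  ?molecule rdf:type cco:Substance .
  FILTER NOT EXISTS { ?substance skos:exactMatch ?molecule . }
}
""",
    # structured molecules whose deposited substances were never standardised
    "audit_unstandardized_structures": """
SELECT ?molecule WHERE {
  ?molecule rdf:type cco:Substance .
  ?molecule ex:hasStructure true .
  FILTER NOT EXISTS {
    ?substance skos:exactMatch ?molecule .
    ?substance cheminf:CHEMINF_000477 ?compound .
  }
}
""",
    # native assays with no PubChem counterpart
    "audit_lost_assays": """
SELECT ?assay WHERE {
  ?assay rdf:type cco:Assay .
  ?assay ex:importedFromPubChem false .
  FILTER NOT EXISTS { ?bioassay skos:exactMatch ?assay . }
}
""",
    # activities of linked assays/molecules with no deposited endpoint
    "audit_lost_activities": """
SELECT ?activity WHERE {
  ?activity rdf:type cco:Activity .
  ?assay rdf:type cco:Assay .
  ?molecule rdf:type cco:Substance .
  ?assay cco:hasActivity ?activity .
  ?molecule cco:hasActivity ?activity .
  ?bioassay skos:exactMatch ?assay .
  ?substance skos:exactMatch ?molecule .
  FILTER NOT EXISTS {
    ?bioassay bao:BAO_0000209 ?mg .
    ?mg obo:OBI_0000299 ?endpoint .
    ?endpoint obo:IAO_0000136 ?substance .
  }
}
""",
    # documents that can never be matched because they lack a PubMed ID
    "audit_docs_without_pmid": """
SELECT ?document WHERE {
  ?document rdf:type cco:Document .
  FILTER NOT EXISTS { ?document bibo:pmid ?pmid . }
}
""",
    # documents with a PubMed ID that the other dataset does not know
    "audit_lost_documents": """
SELECT ?document WHERE {
  ?document rdf:type cco:Document .
  ?document bibo:pmid ?pmid .
  FILTER NOT EXISTS {
    ?reference bibo:pmid ?pmid .
    ?reference rdf:type fabio:Article .
  }
}
""",
    # same audit through the derived identity links instead of raw PMIDs
    "audit_lost_documents_via_links": """
SELECT ?document WHERE {
  ?document rdf:type cco:Document .
  ?document bibo:pmid ?pmid .
  FILTER NOT EXISTS {
    ?document skos:exactMatch ?reference .
    ?reference rdf:type fabio:Article .
  }
}
""",
}


def build_case_queries() -> dict[str, str]:
    """All packaged use-case and audit query reconstructions."""
    out = {
        "case1_scaffold_active_targets": CASE1_QUERY,
        "case2_role_inhibited_proteins": CASE2_QUERY,
        "case3_substances_per_protein": CASE3_QUERY,
    }
    out.update(AUDIT_QUERIES)
    return out


#: manifest key each audit query's row count must equal, exactly
AUDIT_MANIFEST_KEYS = {
    "audit_unlinked_molecules": "audit_unlinked_molecules",
    "audit_unstandardized_structures": "audit_unstandardized_structures",
    "audit_lost_assays": "audit_lost_assays",
    "audit_lost_activities": "audit_lost_activities",
    "audit_docs_without_pmid": "audit_docs_without_pmid",
    "audit_lost_documents": "audit_lost_documents",
    "audit_lost_documents_via_links": "audit_lost_documents",
}


# ---------------------------------------------------------------------------
# Random query generation (for oracle-equivalence testing)

_PATTERN_POOL = [
    "?endpoint obo:IAO_0000136 ?substance",
    "?mg obo:OBI_0000299 ?endpoint",
    "?substance obo:BFO_0000056 ?mg",
    "?mg obo:RO_0000057 ?protein",
    "?endpoint rdf:type bao:BAO_0000190",
    "?endpoint sio:SIO_000300 ?value",
    "?endpoint vocab:PubChemAssayOutcome vocab:active",
    "?substance cheminf:CHEMINF_000477 ?compound",
    "?substance skos:exactMatch ?molecule",
    "?molecule rdf:type cco:Substance",
    "?molecule ex:hasStructure true",
    "?bioassay bao:BAO_0000209 ?mg",
    "?bioassay dcterms:title ?title",
    "?assay cco:hasActivity ?activity",
    "?molecule cco:hasActivity ?activity",
    "?activity cco:hasDocument ?document",
    "?document bibo:pmid ?pmid",
    "?bioassay skos:exactMatch ?assay",
    "?class rdfs:subClassOf ?superclass",
    "?substance rdf:type ?class",
    "?compound rdf:type ex:ScaffoldHit",
    "?protein rdf:type bp:Protein",
    "?assay ex:importedFromPubChem false",
]


def _pattern_vars(p: str) -> set[str]:
    return {tok[1:] for tok in p.split() if tok.startswith("?")}


def random_query(rng: random.Random) -> str:
    """A random query over the toy world, inside the supported subset.

    Queries are connected conjunctions of two to five patterns drawn from
    the predicate pool, optionally decorated with a numeric FILTER, an
    OPTIONAL part, negation (NOT EXISTS or MINUS), a UNION, DISTINCT, or a
    grouped COUNT.  ORDER BY is omitted so results compare as multisets.
    """
    n = rng.randint(2, 5)
    first = rng.choice(_PATTERN_POOL)
    chosen = [first]
    vars_seen = _pattern_vars(first)
    tries = 0
    while len(chosen) < n and tries < 50:
        tries += 1
        cand = rng.choice(_PATTERN_POOL)
        if cand in chosen:
            continue
        if vars_seen & _pattern_vars(cand):
            chosen.append(cand)
            vars_seen |= _pattern_vars(cand)
    body = [p + " ." for p in chosen]

    core_vars = set(vars_seen)
    optional_vars: set[str] = set()

    if "value" in vars_seen and rng.random() < 0.6:
        op = rng.choice(["<", ">", "<=", ">="])
        threshold = round(10 ** rng.uniform(-1.0, 2.0), 3)
        body.append(f"FILTER (?value {op} {threshold})")

    if rng.random() < 0.3:
        linked = [
            p
            for p in _PATTERN_POOL
            if p not in chosen and vars_seen & _pattern_vars(p)
        ]
        if linked:
            opt = rng.choice(linked)
            body.append("OPTIONAL { " + opt + " . }")
            optional_vars = _pattern_vars(opt) - core_vars

    if rng.random() < 0.3:
        linked = [
            p
            for p in _PATTERN_POOL
            if p not in chosen and core_vars & _pattern_vars(p)
        ]
        if linked:
            neg = rng.choice(linked)
            kw = "MINUS" if rng.random() < 0.3 else "FILTER NOT EXISTS"
            body.append(kw + " { " + neg + " . }")

    if rng.random() < 0.2 and "molecule" in core_vars:
        body.append(
            "{ ?molecule ex:hasStructure true . } UNION { ?molecule ex:hasStructure false . }"
        )

    visible = sorted(core_vars | optional_vars)
    if rng.random() < 0.25 and len(core_vars) >= 2:
        key, arg = rng.sample(sorted(core_vars), 2)
        distinct = "DISTINCT " if rng.random() < 0.5 else ""
        head = f"SELECT ?{key} (COUNT({distinct}?{arg}) AS ?n)"
        tail = f"GROUP BY ?{key}"
        return head + " WHERE {\n  " + "\n  ".join(body) + "\n} " + tail
    k = rng.randint(1, min(3, len(visible)))
    proj = " ".join(f"?{v}" for v in sorted(rng.sample(visible, k)))
    distinct = "DISTINCT " if rng.random() < 0.3 else ""
    return f"SELECT {distinct}{proj} WHERE {{\n  " + "\n  ".join(body) + "\n}"
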