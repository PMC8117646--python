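# chemobda

SPARQL over relational small-molecule data — without a native triple store.

Public bioactivity datasets in the PubChem/ChEMBL/ChEBI mould publish their
data as RDF, but answering SPARQL queries over hundreds of millions of
triples is far more efficient when the data stay in a well-indexed
relational database and the *queries* are translated instead of the data.
`chemobda` implements that ontology-based data access (OBDA) approach for
desk-scale experimentation: a declarative relational-to-RDF mapping
formalism, a SPARQL-subset-to-SQL translation engine with semantic
optimizations, a naive reference SPARQL evaluator that serves as a
correctness oracle, and a seeded synthetic generator for a toy bioassay
world so that every translation and optimization claim is testable without
downloading anything.

## The model

A **mapping set** over a relational schema has two parts:

* **IRI classes.** All resource IRIs are divided into pairwise disjoint
  classes; each class is a bijection between an IRI template and tuples of
  SQL key values,

  ```
  endpoint:  http://…/endpoint/SID{sid:integer}_AID{aid:integer}_{mg:integer}  ↔  (sid, aid, mg)
  ```

  so resources are identified in SQL by compact keys, and any constant IRI
  in a query can be decoded back to key values (or proven unsatisfiable).

* **Quad mappings.** Each rule turns every table row into one RDF quad —
  subject/predicate/object/graph each generated from columns (through an
  IRI class, or as a typed literal) or fixed as constants. A row yields a
  quad only if all required columns are non-null.

Translation proceeds per triple pattern: the engine selects the *candidate*
quad mappings whose generated triples could match the pattern, emits one
base-table fragment per candidate (a union if several), and joins
fragments according to the SPARQL algebra — shared variables become
equalities on key columns, `OPTIONAL` a left join, `MINUS`/`NOT EXISTS`
anti-joins, aggregates a grouped query. Schema constraints then optimize
the SQL:

1. **self-join merge** — two fragments of one table joined on its full
   primary key are the same row and collapse into one fragment;
2. **foreign-key join elimination** — a fragment reachable only through an
   FK→PK equality that exports nothing beyond the joined key is removed
   (an `IS NOT NULL` filter survives when the FK columns are nullable);
3. **empty-relation propagation** — joins between variables annotated with
   disjoint IRI classes are pruned as provably empty.

The reference evaluator (`evaluate_oracle`) answers the same queries by
exhaustive pattern matching over the materialised quad set, so
`SQL(query) == oracle(query)` is a checkable property, not a promise.

## Worked example

The packaged two-table bundle maps `documents(id, title, journal_id)` and
`journals(id, short_title)` to typed, titled, and linked RDF resources
(4 documents, 2 journals; one document has no journal link):

```python
from chemobda import build_fig_fixture, compile_query, parse_query

bundle = build_fig_fixture()
ms = bundle.mapping_set()
db = bundle.make_database()

ast = parse_query("""
SELECT ?document ?title ?journal WHERE {
  ?document dcterms:title ?title .
  ?document cco:hasJournal ?journal .
  ?journal rdf:type cco:Journal .
}
""")
compiled = compile_query(ast, ms)
print(compiled.report.summary())
for row in db.execute(compiled).rows:
    print(row["document"].value, "|", row["title"].lexical)
```

prints

```
base table references: 3 -> 1
joins after optimization: 0
pattern ?document <http://purl.org/dc/terms/title> ?title: candidates [document-title]
pattern ?document <http://rdf.ebi.ac.uk/terms/chembl#hasJournal> ?journal: candidates [document-journal]
pattern ?journal <…rdf-syntax-ns#type> <…chembl#Journal>: candidates [journal-type]
rewrite: self-join merge on documents (full primary key)
rewrite: foreign-key join elimination of journals via documents
http://rdf.ebi.ac.uk/resource/chembl/document/CHEMBL1139452 | Synthesis of potent kinase inhibitors
http://rdf.ebi.ac.uk/resource/chembl/document/CHEMBL1148466 | Acetylcholinesterase ligands revisited
http://rdf.ebi.ac.uk/resource/chembl/document/CHEMBL1155381 | Fragment screening of protease targets
```

Three triple patterns become three derived tables; the two `documents`
fragments merge on the primary key, and the `journals` fragment is
eliminated through the `journal_id` foreign key because no journal column
beyond the key is needed — one base table remains, and the three result
rows are exactly the documents that carry a journal link. The toy bioassay
world works the same way at larger scale: its seven-pattern
substances-per-protein aggregation compiles to two joins of three tables,
with the redundant substance–measure-group pattern contributing no table
at all.

## Command line

```bash
chemobda generate --seed 5 --out bundle          # synthetic toy world + manifest
chemobda init --mapping bundle/mapping.yaml --db toy.db --data bundle/data
chemobda query --mapping bundle/mapping.yaml --db toy.db \
        --query bundle/queries/case3_substances_per_protein.rq --mode check
chemobda explain --mapping bundle/mapping.yaml --db toy.db --query …
chemobda materialize --mapping bundle/mapping.yaml --db toy.db --out dump.nt
chemobda update --mapping bundle/mapping.yaml --db toy.db --table pc_protein --csv new.csv
chemobda check-suite                             # every packaged query, engine vs oracle
```

`--mode check` runs both evaluation paths and exits non-zero on the first
differing row. Exit codes distinguish syntax errors (3), unsupported
SPARQL features (4), mapping violations (5), and mismatches (6).

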