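# Methods

This note documents the model the engine implements, the choices made
where the design was genuinely open, what the synthetic data do and do not
emulate, and the numerical conventions both evaluators share.

## Mapping formalism

A mapping set couples a relational schema (tables, SQL types, NOT NULL,
primary keys, foreign keys that always reference the full primary key of
their target) with IRI classes and quad mappings.

**IRI classes** are anchored templates with typed slots. Integer slots
render canonically (no sign, no leading zeros) and decoding rejects
non-canonical forms, so encode∘decode and decode∘encode are identities.
Text slots are percent-encoded on encode and re-encoded on decode to
reject non-canonical escapes. Adjacent slots without a fixed separator are
rejected at load time as ambiguous. Pairwise disjointness of classes is
checked at load time by template identity plus sample cross-decoding; the
test suite additionally verifies disjointness over randomized slot tuples
and over every IRI the fixtures actually generate. Classes may be
composite ("SQL types", plural): the toy world's endpoint class maps
`(substance, assay, measure-group)` triples, which is what lets a
three-way self-join collapse (see below).

**Quad mappings** have constant-IRI predicates (every mapping in scope has
a fixed predicate; variable predicates in *queries* are still supported —
each mapping is then a candidate and the predicate variable binds to the
mapping's constant). Beyond the non-null rule, a mapping may declare an
equality condition on a discriminator column; this is how one measurement
table maps to several endpoint-type classes (IC50/EC50/Ki), and the
condition participates in candidate pruning.

**Soundness condition (duplicate-free mappings).** SQL preserves row
multiplicity while RDF graphs are sets, so the translation is
multiset-correct only if no two (mapping, row) pairs generate the same
quad. Every packaged mapping references a column set containing the
table's full primary key, which guarantees this by construction. The
validator cannot check the condition in general (it depends on data); the
oracle-equivalence suite confirms it for the fixtures.

## Translation

Each basic graph pattern expands to the cross product of its patterns'
candidate mappings; every combination becomes one *branch* — a conjunction
of base-table fragments with constant constraints, non-null requirements,
and join equalities induced by shared variables. Unions (from multiple
candidates or syntactic `UNION`) are distributed before optimization, so
each branch is optimized independently; cross-branch merging is not
attempted. Variables carry static annotations per branch — an IRI class, a
literal datatype, or a fallback "encoded term text" — and a join between
variables of disjoint classes marks the branch empty.

`OPTIONAL` becomes a left join between subplans (a trailing `FILTER` in
the optional part moves into the join condition, per the algebra);
`MINUS` and `FILTER NOT EXISTS` become correlated anti-joins, with the
domain-overlap requirement that distinguishes `MINUS` (no shared variables
⇒ nothing is removed) rendered explicitly. `VALUES` rows join into
branches as constant bindings.

### Optimization passes and their order

Per branch, to a fixpoint (each pass strictly decreases the fragment
count, so at most `fragments` iterations run):

1. *Self-join merge.* Fragments of the same table whose join-equality
   classes cover the full primary key denote the same row; constraints,
   non-nulls and bindings unite. This pass also covers redundant patterns:
   in the seven-pattern aggregation use case the substance→measure-group
   pattern merges into the fragment already derived from the
   substance–measure-group–endpoint relation table, so it contributes no
   table. A separate "duplicate collapse" pass would be unsound without
   the PK condition (duplicates not keyed to the same row multiply
   multiplicities) and is therefore deliberately absent.
2. *FK join elimination.* A fragment is dropped when (a) it is joined to
   exactly one other fragment, (b) those equalities are exactly a declared
   FK→PK link, (c) it binds variables and constants only on PK columns.
   Bindings and constants transfer to the FK columns; if those columns are
   nullable an `IS NOT NULL` filter is added (the inner join required a
   row), otherwise nothing remains. The single-partner restriction is a
   design choice: transferring joins through rebinding would be sound but
   would collapse plans further than the documented target shapes; it also
   keeps the pass obviously correct.
3. *Empty-relation propagation.* Branches emptied by class disjointness or
   contradictory constants are removed; a query whose branches all vanish
   renders as a `SELECT … WHERE 0` returning no rows rather than an error.

Join order and physical planning are left entirely to SQLite; the
translator guarantees only the algebraic shape, which the
`TranslationReport` records (candidates per pattern, base-table references
before/after, joins after, rewrite log). Rendering is deterministic —
stable alias numbering, sorted clause order — so report counts can be
re-derived by scanning the SQL text, and the tests do exactly that.

## Expression semantics

SPARQL expression *errors* map to SQL `NULL`; SQLite's three-valued logic
then reproduces SPARQL's error propagation in `WHERE` (error ⇒ row
eliminated, `error && false ⇒ false`, etc.). Static type conflicts
(IRI vs literal, string vs number) compile to constant `NULL`, except
`=`/`!=` between disjoint IRI classes, which are decidable (false/true for
bound operands). Numeric comparisons are value-based across numeric
datatypes, string/boolean comparisons require matching datatypes, and
division always widens to double (SPARQL numeric division does not
truncate). Effective boolean value wraps string operands in a length test
because SQLite would otherwise coerce text to numbers.

Two places where both evaluators deliberately implement the same
simplification rather than the letter of the SPARQL spec, so that they
remain comparable: `IN` treats type-mismatched list members as non-matches
instead of propagating errors, and join compatibility is term equality
(same datatype, same canonical lexical) — literal values of *different*
numeric datatypes never join, matching the materialised terms the oracle
sees. Fixture schemas give each semantic field a single SQL type, so the
restriction has no observable effect there.

Aggregates follow the SQL implementations the backend provides, which
coincide with the SPARQL definitions on the cases in scope: `COUNT` is an
integer; `SUM` over an empty implicit group is integer 0 (`COALESCE`d in
SQL) and otherwise follows the input type; `AVG` of an empty group is
unbound (SQL `NULL`, SPARQL error); `MIN`/`MAX` over IRI-valued variables
compare by full IRI string (the engine orders by an encoded-text
rendering whose string order equals IRI order). Doubles decode through a
shared canonical lexical printed at 12 significant digits so that sums
computed in different association orders decode to the same term;
generator values carry at most 4 decimals, far below that precision.

Ordered results are compared as multisets plus a sortedness check under
the query's comparator (ties may legitimately differ between evaluators);
`LIMIT` with ties at the cut is inherently implementation-defined and the
packaged queries avoid it.

## The reference oracle

`evaluate_oracle` implements the algebra directly over an indexed
in-memory quad store: naive BGP join with greedy most-bound-first pattern
ordering, left joins by compatibility merging, substitution semantics for
`NOT EXISTS`, and Python-side aggregation. It is independent of mappings
and SQL by construction; its only shared code with the engine is the term
model and the canonical lexical forms. On the worked example and an
audit query it is additionally cross-checked against rdflib's SPARQL
engine in the test suite (a dev-time check, not a runtime dependency).
It is comfortable up to ~10^6 quads; beyond that, it is the wrong tool —
which is the engine's raison d'être.

## Synthetic toy world

The generator emulates the structure of an integrated small-molecule
database at desk scale: compounds standardised from deposited substances
(nullable standardisation link); bioassays divided into measure groups
that contain endpoints (outcome per endpoint, typed measured values in a
separate table keyed by the same composite key) and point at protein
targets; a parallel bioactivity dataset with molecules, assays,
activities, documents with nullable PubMed IDs and drug mechanisms; a
compound-classification hierarchy with role annotations expressed in the
OWL-restriction shape (`subClassOf → onProperty/someValuesFrom`) but
stored and matched as plain triples; and cross-dataset `skos:exactMatch`
links, including document links *derived* by equating non-null PMIDs.

Defaults (60 compounds × 2 substances, 20 assays × 2 measure groups, 300
endpoints, 15 proteins, 30 documents, ~900 relational rows ≈ 4 000 quads)
keep a full equivalence run over 200 random query/data instances under
half a minute on one CPU. IC50 values are log-uniform over
10⁻³–10³ µM — nanomolar to millimolar around the conventional 10 µM
cutoff — stored in a single unit so thresholds are plain comparisons.
Structure search is replaced by a generated boolean scaffold flag; a
fraction of substances carry classification types; 40 % of endpoints are
"active".

Planted inconsistencies are the audit ground truth: molecules never
deposited on the other side, structured molecules whose substances were
never standardised, native assays without a counterpart, activities whose
endpoint is missing, documents without PMIDs, and documents whose PMID
the other side lacks. Planted sets are disjoint by construction and
recorded in a manifest; each audit query must return *exactly* the
manifest count for any seed. Same config ⇒ byte-identical output.

What passing these tests does **not** show about real data: the toy world
has no blank nodes, no language-tagged text, no OWL reasoning (restriction
triples are matched syntactically), clean referential integrity outside
the planted faults, uniform key distributions, and mapping sets designed
to be duplicate-free. Scale behaviour of the generated SQL (indexes,
statistics, join order) is delegated to the backend and not measured here.

## Known limitations

- SPARQL subset only; everything outside it fails loudly with the
  construct's name (property paths, SERVICE, BIND, subqueries,
  CONSTRUCT/DESCRIBE, EXISTS in projections).
- Variables that are unbound on one side of a later join (non-well-designed
  optionals) follow SQL NULL-join semantics rather than SPARQL
  compatibility; the fixtures and the generator stay within well-designed
  patterns.
- IRI classes with text slots cannot be percent-encoded inside SQL, so the
  encoded-text fallback assumes text keys drawn from unreserved
  characters; generator text slots comply.
- The backend is single-writer/multi-reader SQLite; diff updates are
  single transactions per table, not cross-table snapshots.
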