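# Methods

## Model

The validator treats a metadata checklist as a draft-07 JSON Schema
augmented with four semantic keywords. Validation of a document is the
conjunction of two layers:

1. **Structural layer.** The full standard draft-07 vocabulary, delegated
   to the `jsonschema` library. The dialect is pinned: a `$schema` marker
   naming any other dialect is a compile error. This bounds the
   conformance surface to one well-defined revision rather than
   approximating several.
2. **Semantic layer.** Wherever one of the four custom keywords annotates
   a subschema, the instance value at that location is checked against
   ontology/taxonomy content held by a backend.

An ontology is modelled as a multi-relation directed acyclic graph:
terms (id, label, synonyms, obsolescence, optional replacement) and
labelled edges (child, relation, parent). The only reasoning performed is
reachability over stored edges restricted to a relation set — no
equivalence axioms, no property chains, no OWL semantics. A term's
ancestors under relations R are the transitive closure of the
R-restricted edge relation; `direct` mode truncates the closure to
single-edge parents; the queried term is never its own ancestor, so
reflexivity is controlled entirely by the `include_self` toggle.

`graph_restriction` combines two predicates with explicit OR-semantics:
membership in at least one listed ontology, and descent from at least one
listed class. OR was chosen because checklist constraints of the form
"PATO or MONDO disease terms" are disjunctive by nature, and conjunction
is already expressible by schema composition (`allOf` of two
`graph_restriction` blocks). A consequence used as a test invariant:
adding a class to `classes` can never turn a passing value into a failing
one.

`isChildTermOf` is the fixed-configuration special case: subclass
relation only, transitive, non-reflexive. It is extensionally identical
to `graph_restriction` with a single class and default toggles, and a
test asserts that equivalence over every loaded term. Keeping the simple
keyword simple (two parameters) and the rich keyword configurable (five)
mirrors how checklist authors actually use them.

## Semantic decisions where the design was open

* **Obsolete terms fail validation** in all keywords, with the
  replacement id included in the message when the ontology records one.
  A validator whose purpose is quality control should not wave through
  deprecated identifiers; an archive wanting to accept them can drop the
  keyword.
* **Default relation set is subclass only** (`rdfs:subClassOf`, spelled
  `is_a` internally, both accepted in schemas). Part-whole traversal
  (`part_of`) and any relation declared by a loaded OBO file can be opted
  into per keyword block; unknown relation names are rejected at
  compile time, against the vocabulary of the loaded graphs.
* **Ontology membership is graph presence, not prefix matching.**
  Ontologies import foreign terms routinely (a MONDO release carries PATO
  terms), so the testable criterion is "present in the loaded graph of
  ontology O". CURIE prefixes are compared case-insensitively, local ids
  case-sensitively; CURIE→IRI expansion exists for export but validation
  never round-trips through IRIs, keeping comparisons string-exact.
* **Malformed instance values are validation errors, never exceptions**
  — including non-string instances under a term keyword. Silently
  ignoring a keyword on a mistyped instance would hide schema bugs;
  crashing would make the service unusable on bad submissions.
* **Cycles are load-time errors.** Ancestor semantics are undefined on
  cyclic input; the loader reports one offending cycle's term ids.
  Acyclicity is checked on the union of all relations, which implies
  acyclicity of every relation subset.
* **Backends are pluggable and pure.** Keyword checks call four
  operations (`term_exists`, `find_term`, `is_descendant`,
  `taxon_exists`) behind a protocol. The default backend is local and
  file-backed (OBO + taxonomy dumps) so that operation is fully hermetic;
  an OLS-style HTTP client implements the same signatures for
  deployments that prefer a hosted ontology source. Answers are pure
  functions of (query, loaded content), which licenses transparent
  memoisation of ancestor sets — a property the suite checks by
  comparing cached and uncached backends query-for-query.
* **`is_descendant` searches every loaded graph containing the queried
  term.** The backend operation takes no ontology list; scoping to
  specific ontologies is the keyword layer's membership check. This
  keeps the two failure reasons (not a member / not a descendant)
  separately reportable.
* **Taxonomy name matching** is case-insensitive with internal
  whitespace collapsed, across all name classes (scientific names,
  synonyms, common names). A name resolving to more than one taxon is an
  explicit "ambiguous" verdict listing the candidates, not a pass.
  Dump files mix cases and spacing; strict matching would reject
  legitimate submissions on formatting noise.

## Engine mechanics

Compilation validates the schema against the draft-07 metaschema, checks
every custom keyword block against that keyword's parameter metaschema
(errors carry the JSON-Pointer schema path), and resolves every `$ref`
against a local schema registry keyed by `$id` — remote `$ref` fetching
is disabled, so validation cannot silently depend on network state.
Registration is idempotent for identical content and an error for
conflicting content under one `$id`.

Validation collects all failures (no first-error short-circuit), because
a submission broker needs the complete defect list in one round. Reports
are ordered deterministically — document order of instance paths, then
schema path, then message — and serialized by a single canonical JSON
writer (sorted keys, two-space indent) used by the library, the CLI and
the HTTP service alike; the byte-identity of the three interfaces is an
asserted property, not an aspiration. Validity is carried in the payload
(`"valid": false` with HTTP 200), reserving 4xx for malformed requests
and unknown schema ids.

Error messages are structured (keyword, instance path, message, parameter
echo) but make no attempt to be string-compatible with any other
validator's phrasing.

## Synthetic content and what it does (not) show

All test content is generated: random DAG ontologies, a miniature
disease/phenotype ontology pair, a five-taxon plant taxonomy, and a
MIAPPE-style checklist. Generator defaults define the test conditions:

* **Random DAGs** — 30 terms, at most 3 parents per term, 20 %
  `part_of` edges, seeded `random.Random`; edges always point from
  higher-index to lower-index terms, so acyclicity holds by construction
  and the generator cannot mask a cycle-detection defect. 30 terms keeps
  exhaustive all-pairs oracle comparison cheap while exceeding the depth
  and fan-in at which BFS bookkeeping errors appear.
* **Mini disease ontologies** — the two anchor classes reuse the real
  CURIE spellings `MONDO:0000001` and `PATO:0000461` so schema blocks
  read exactly like production checklists; every descendant uses the
  fixture prefix `MINI:` so no fact about the real ontologies is
  asserted. The pair includes a child, a grandchild, an
  ontology-member-but-not-descendant term and an obsolete child with a
  recorded replacement — one term per distinct verdict the keywords can
  produce.
* **Mini taxonomy** — real NCBI tax_ids for familiar plants (3702
  *Arabidopsis thaliana*, 4530 *Oryza sativa*) plus a deliberately
  colliding synonym ("rockcress") to force the ambiguous verdict.

What passing on this content shows: the keyword semantics, closure
queries, error shapes and interface contracts are correct on graphs of
realistic shape. What it does not show: performance or correctness at
the scale of full MONDO/NCBI releases (hundreds of thousands of terms),
tolerance of the real dumps' irregularities, or behaviour of the remote
backend against a live ontology service — none of which the local test
conditions can exercise.

## Verification strategy

Graph queries are checked against an independent oracle: transitive
closure by repeated boolean adjacency-matrix multiplication, a different
algorithm on a different data structure from the production BFS. The
acceptance run compares every ordered node pair in both direct modes on
200 seeded DAGs (360 000 comparisons). Conservativity is checked on a
107-case structural corpus in the official draft-07 test-suite format,
covering type/properties/required/enum/items/combinators/`$ref`; every
recorded expectation is itself re-verified in-test against the
unextended `jsonschema.Draft7Validator`, so the corpus cannot drift from
the reference semantics. Property-based tests (seeded, derandomised
Hypothesis) cover closure monotonicity under edge addition,
direct-⊆-transitive, reflexivity control, OBO round-trips and cache
transparency.

## Problem sizes

Defaults were sized for exhaustive verification rather than scale:
30-term DAGs for all-pairs oracle comparison (200 seeds in the
acceptance run), 25-term ontologies for 50 round-trip seeds, a 5-taxon
taxonomy, and a 6-pair fixture suite for interface coherence. The entire
suite and the acceptance script each complete in a few seconds on one
CPU.

## Known limitations

* No OWL/RDF input and no reasoning beyond stored-edge closure.
* One schema per request; heterogeneous per-document schemas in a batch
  are not supported.
* The HTTP service is a JSON API only (no HTML interface, auth or rate
  limiting) and loads ontology content once at startup.
* Identifier cross-reference checking (e.g. resolving database
  accessions) is out of scope.
* A top-level JSON array submitted as `data` is interpreted as a batch;
  to validate a document that *is* an array, wrap it in a single-element
  batch.
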