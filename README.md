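# ontoschema

JSON Schema validation with ontology- and taxonomy-aware keywords, for
life-science metadata.

## The problem

JSON Schema is excellent at checking the *structure* of a metadata
document — which fields exist, their types, their shapes — but says
nothing about the *semantics* of the values. A sample record can be
structurally perfect while its `disease` field holds a term that does not
exist in any disease ontology, or an `organism` that names no known
taxon. Archives and submission brokers that enforce community checklists
(MIAPPE for plant phenotyping, MIxS for genomic samples, BioSamples
checklists generally) need both layers enforced at once.

`ontoschema` extends the draft-07 JSON Schema vocabulary with four custom
keywords that validate instance values against ontology graphs and a
taxonomy table:

| keyword | constraint on the instance value |
| --- | --- |
| `isValidTerm` | names an existing, non-obsolete ontology term |
| `isChildTermOf` | is a strict subclass descendant (`is_a`⁺) of a given parent term, within given ontologies |
| `isValidTaxonomy` | resolves to exactly one taxon by id or name |
| `graph_restriction` | is a member of at least one listed ontology **and** descends from at least one listed class along listed relations (OR across both lists), with `direct` and `include_self` toggles |

Formally, for an ontology graph G = (T, E) with labelled edges
(c, r, p) ∈ E, the ancestor set of a term t under relation set R is

    anc_R(t) = { p : t →_R⁺ p },

the transitive closure of the edge relation restricted to R.
`graph_restriction` with ontologies O, classes C, relations R accepts
value v iff v ∈ terms(o) for some o ∈ O and (c ∈ anc_R(v) for some
c ∈ C, or `include_self` and v ∈ C). With `direct: true` the closure is
replaced by single-edge parenthood.

The standard draft-07 vocabulary is delegated unchanged to the
`jsonschema` library, so a schema that uses no custom keywords validates
exactly as plain draft-07 — the extension is conservative.

Ontology content loads from OBO 1.2 flat files into a local graph backend
(no network needed); taxonomy content loads from NCBI-style pipe-delimited
nodes/names dumps. An OLS-style remote backend with the same operation
signatures is available as an optional alternative.

## Worked example

A checklist constrains `disease_ontology_id` to subclasses of the disease
classes `PATO:0000461` or `MONDO:0000001`:

```json
{
  "type": "object",
  "properties": {
    "disease_ontology_id": {
      "type": "string",
      "graph_restriction": {
        "ontologies": ["minimondo", "minipato"],
        "classes": ["MONDO:0000001", "PATO:0000461"],
        "relations": ["rdfs:subClassOf"],
        "direct": false,
        "include_self": false
      }
    }
  },
  "required": ["disease_ontology_id"]
}
```

Validating a document whose term is a loaded subclass of
`MONDO:0000001`:

```python
from ontoschema import compile_schema
from ontoschema.fixtures import fixture_backend, disease_example_fixture

example = disease_example_fixture()
validator = compile_schema(example["schema"], backend=fixture_backend())
print(validator.validate({"disease_ontology_id": "MINI:0000010"}).to_json())
```

prints

```json
{
  "errors": [],
  "valid": true
}
```

while an out-of-hierarchy term fails with a single structured error:

```json
{
  "errors": [
    {
      "instancePath": "/disease_ontology_id",
      "keyword": "graph_restriction",
      "message": "term MINI:0000099 does not descend from any of ['MONDO:0000001', 'PATO:0000461'] via relations ['is_a']",
      "params": {
        "classes": [
          "MONDO:0000001",
          "PATO:0000461"
        ],
        "direct": false,
        "include_self": false,
        "ontologies": [
          "minimondo",
          "minipato"
        ],
        "relations": [
          "rdfs:subClassOf"
        ]
      }
    }
  ],
  "valid": false
}
```

`valid: true` means every structural and every semantic check passed;
each error names the failing keyword, the JSON-Pointer location of the
offending value, a human-readable reason and the keyword's parameters.

## Run modes

One-shot CLI (exit 0 valid, 1 invalid, 2 usage/parse error):

```bash
ontoschema validate --schema checklist.json --data sample.json --config content.yaml
```

HTTP service (`POST /validate` with `{"schema": ... | "schema_id": ...,
"data": <doc> | [<docs>]}`; batch responses align index-for-index;
`GET /health`):

```bash
ontoschema serve --port 8080 --config content.yaml
```

The config file lists OBO ontology files and the taxonomy dump pair;
content is loaded once at startup. CLI, single HTTP and batch HTTP
produce byte-identical report JSON for the same inputs.

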