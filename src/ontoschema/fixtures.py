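"""Deterministic test content: synthetic ontologies, taxonomy, checklists.

Everything the test suite validates against is generated here, offline:

* random ontology DAGs with known, seed-reproducible structure (the
  substrate for closure-oracle comparisons);
* a miniature disease ontology pair (``minimondo``/``minipato``) whose two
  anchor classes reuse the real CURIE spellings ``MONDO:0000001`` and
  ``PATO:0000461`` so schema blocks read like production checklists, with
  all descendants under a fixture ``MINI:`` prefix;
* a miniature taxonomy dump (plant-flavoured, with a constructed synonym
  collision);
* a MIAPPE-style plant-sample checklist schema with documents of known
  verdicts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .backend import LocalBackend
from .curie import TermId
from .engine import SchemaRegistry, canonical_json
from .ontology import SUBCLASS, OntologyGraph, OntologyTerm, write_obo
from .taxonomy import TaxonomyTable, load_taxonomy

FIXTURE_PREFIX = "FIX"


@dataclass(frozen=True)
class DagSpec:
    """Recipe for a random ontology DAG.

    Edges always point from a higher-index term to a lower-index one, so
    acyclicity holds by construction.  ``part_of_fraction`` is the
    probability an edge is ``part_of`` rather than ``is_a``;
    ``obsolete_fraction`` marks that share of non-root terms obsolete.
    """

    n_terms: int
    max_parents: int = 3
    part_of_fraction: float = 0.2
    obsolete_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ValueError("n_terms must be positive")
        if self.max_parents < 1:
            raise ValueError("max_parents must be positive")
        if self.n_terms > 1 and self.max_parents >= self.n_terms:
            raise ValueError("max_parents must be smaller than n_terms")
        if not 0.0 <= self.obsolete_fraction <= 1.0:
            raise ValueError("obsolete_fraction must be in [0, 1]")


def _fixture_id(i: int) -> TermId:
    return TermId(FIXTURE_PREFIX, f"{i:07d}")


def generate_dag_ontology(spec: DagSpec) -> OntologyGraph:
    """Generate a random DAG ontology; same spec -> identical graph."""
    rng = random.Random(spec.seed)
    graph = OntologyGraph(ontology_id=f"fixdag{spec.seed}")

    n_obsolete = int(spec.obsolete_fraction * max(spec.n_terms - 1, 0))
    obsolete_ids = set(
        rng.sample(range(2, spec.n_terms + 1), n_obsolete)
        if n_obsolete
        else []
    )
    for i in range(1, spec.n_terms + 1):
        tid = _fixture_id(i)
        graph.terms[tid] = OntologyTerm(
            id=tid,
            label=f"fixture term {i}",
            obsolete=i in obsolete_ids,
            replaced_by=_fixture_id(1) if i in obsolete_ids else None,
        )
    for i in range(2, spec.n_terms + 1):
        n_parents = rng.randint(1, min(spec.max_parents, i - 1))
        for parent_index in rng.sample(range(1, i), n_parents):
            relation = (
                "part_of"
                if rng.random() < spec.part_of_fraction
                else SUBCLASS
            )
            graph.edges.add((_fixture_id(i), relation, _fixture_id(parent_index)))
    return graph.validate()


# ---------------------------------------------------------------------
# The worked disease-checklist example


def disease_example_ontologies() -> dict[str, OntologyGraph]:
    """Mini disease/phenotype ontology pair.

    ``minimondo`` holds the disease anchor ``MONDO:0000001`` with a child
    ``MINI:0000010``, a grandchild ``MINI:0000011``, an out-of-hierarchy
    member ``MINI:0000099``, and an obsolete child ``MINI:0000666``
    (replaced by ``MINI:0000010``).  ``minipato`` holds the phenotype
    anchor ``PATO:0000461`` with child ``MINI:0000020``.
    """
    mondo_root = TermId.parse("MONDO:0000001")
    pato_root = TermId.parse("PATO:0000461")
    child = TermId.parse("MINI:0000010")
    grandchild = TermId.parse("MINI:0000011")
    outsider = TermId.parse("MINI:0000099")
    obsolete = TermId.parse("MINI:0000666")
    pato_child = TermId.parse("MINI:0000020")

    minimondo = OntologyGraph(ontology_id="minimondo")
    minimondo.terms = {
        mondo_root: OntologyTerm(mondo_root, "disease"),
        child: OntologyTerm(child, "fixture disease"),
        grandchild: OntologyTerm(grandchild, "fixture disease subtype"),
        outsider: OntologyTerm(outsider, "unrelated fixture term"),
        obsolete: OntologyTerm(
            obsolete, "retired fixture disease", obsolete=True,
            replaced_by=child,
        ),
    }
    minimondo.edges = {
        (child, SUBCLASS, mondo_root),
        (grandchild, SUBCLASS, child),
        (obsolete, SUBCLASS, mondo_root),
    }

    minipato = OntologyGraph(ontology_id="minipato")
    minipato.terms = {
        pato_root: OntologyTerm(pato_root, "normal"),
        pato_child: OntologyTerm(pato_child, "fixture quality"),
    }
    minipato.edges = {(pato_child, SUBCLASS, pato_root)}
    return {
        "minimondo": minimondo.validate(),
        "minipato": minipato.validate(),
    }


DISEASE_RESTRICTION: dict[str, Any] = {
    "ontologies": ["minimondo", "minipato"],
    "classes": ["MONDO:0000001", "PATO:0000461"],
    "relations": ["rdfs:subClassOf"],
    "direct": False,
    "include_self": False,
}


def disease_example_schema() -> dict:
    """Checklist constraining ``disease_ontology_id`` to disease terms."""
    return {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": "https://example.org/schemas/disease-sample.json",
        "type": "object",
        "properties": {
            "disease_ontology_id": {
                "type": "string",
                "graph_restriction": dict(DISEASE_RESTRICTION),
            }
        },
        "required": ["disease_ontology_id"],
    }


def disease_example_fixture() -> dict:
    """The full worked example: ontologies, schema, one passing and one
    failing document."""
    return {
        "ontologies": disease_example_ontologies(),
        "schema": disease_example_schema(),
        "valid_document": {"disease_ontology_id": "MINI:0000010"},
        "invalid_document": {"disease_ontology_id": "MINI:0000099"},
    }


# ---------------------------------------------------------------------
# Mini taxonomy

MINI_TAXONOMY_NODES = """\
1\t|\t1\t|\tno rank\t|
3701\t|\t1\t|\tgenus\t|
3702\t|\t3701\t|\tspecies\t|
59689\t|\t3701\t|\tspecies\t|
4530\t|\t1\t|\tspecies\t|
"""

MINI_TAXONOMY_NAMES = """\
1\t|\troot\t|\t\t|\tscientific name\t|
3701\t|\tArabidopsis\t|\t\t|\tscientific name\t|
3702\t|\tArabidopsis thaliana\t|\t\t|\tscientific name\t|
3702\t|\tthale cress\t|\t\t|\tcommon name\t|
3702\t|\trockcress\t|\t\t|\tsynonym\t|
59689\t|\tArabidopsis lyrata\t|\t\t|\tscientific name\t|
59689\t|\trockcress\t|\t\t|\tsynonym\t|
4530\t|\tOryza sativa\t|\t\t|\tscientific name\t|
"""


def mini_taxonomy() -> TaxonomyTable:
    """Five-taxon plant table; ``rockcress`` is deliberately ambiguous."""
    return load_taxonomy(MINI_TAXONOMY_NODES, MINI_TAXONOMY_NAMES)


def fixture_backend(cache: bool = True) -> LocalBackend:
    """Backend loaded with the disease ontologies and mini taxonomy."""
    return LocalBackend(
        disease_example_ontologies(), taxonomy=mini_taxonomy(), cache=cache
    )


# ---------------------------------------------------------------------
# MIAPPE-style checklist

DEFS_SCHEMA_ID = "https://example.org/schemas/defs.json"
CHECKLIST_SCHEMA_ID = "https://example.org/schemas/plant-sample.json"


def miappe_like_fixture() -> dict:
    """A plant-sample checklist with shared definitions and sample docs.

    Returns the definitions schema, the checklist schema (which ``$ref``s
    it), a populated :class:`SchemaRegistry`, and a list of
    ``(document, expected_valid, expected_keywords)`` cases covering a
    pass, a structural failure, an ontology failure and a taxonomy
    failure.
    """
    defs_schema = {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": DEFS_SCHEMA_ID,
        "definitions": {
            "nonEmptyString": {"type": "string", "minLength": 1}
        },
    }
    checklist = {
        "$schema": "http://json-schema.org/draft-07/schema#",
        "$id": CHECKLIST_SCHEMA_ID,
        "type": "object",
        "properties": {
            "sample_name": {
                "$ref": f"{DEFS_SCHEMA_ID}#/definitions/nonEmptyString"
            },
            "organism": {"isValidTaxonomy": True},
            "trait_ontology_id": {
                "type": "string",
                "graph_restriction": {
                    "ontologies": ["minipato"],
                    "classes": ["PATO:0000461"],
                    "relations": ["rdfs:subClassOf"],
                },
            },
            "disease_ontology_id": {
                "type": "string",
                "isChildTermOf": {
                    "parent": "MONDO:0000001",
                    "ontologies": ["minimondo"],
                },
            },
            "material_term": {
                "type": "string",
                "isValidTerm": {"ontologies": ["minimondo", "minipato"]},
            },
        },
        "required": ["sample_name", "organism", "trait_ontology_id"],
    }
    registry = SchemaRegistry()
    registry.register(defs_schema)
    registry.register(checklist)

    passing = {
        "sample_name": "plant-001",
        "organism": "Arabidopsis thaliana",
        "trait_ontology_id": "MINI:0000020",
        "disease_ontology_id": "MINI:0000011",
        "material_term": "MINI:0000010",
    }
    structural_fail = {
        "sample_name": "plant-002",
        "trait_ontology_id": "MINI:0000020",
    }
    ontology_fail = {
        "sample_name": "plant-003",
        "organism": 3702,
        "trait_ontology_id": "MINI:0000099",
    }
    taxonomy_fail = {
        "sample_name": "plant-004",
        "organism": "No Such Organism",
        "trait_ontology_id": "MINI:0000020",
    }
    cases = [
        (passing, True, []),
        (structural_fail, False, ["required"]),
        (ontology_fail, False, ["graph_restriction"]),
        (taxonomy_fail, False, ["isValidTaxonomy"]),
    ]
    return {
        "defs_schema": defs_schema,
        "schema": checklist,
        "registry": registry,
        "cases": cases,
    }


def write_fixture_files(directory: str | Path) -> dict[str, Path]:
    """Emit the fixture suite as files (OBO, dumps, JSON, config).

    Returns a name -> path map.  Used by CLI and service tests that need
    on-disk inputs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, graph in disease_example_ontologies().items():
        paths[f"{name}.obo"] = directory / f"{name}.obo"
        paths[f"{name}.obo"].write_text(write_obo(graph))
    paths["nodes.dmp"] = directory / "nodes.dmp"
    paths["nodes.dmp"].write_text(MINI_TAXONOMY_NODES)
    paths["names.dmp"] = directory / "names.dmp"
    paths["names.dmp"].write_text(MINI_TAXONOMY_NAMES)

    example = disease_example_fixture()
    miappe = miappe_like_fixture()
    for name, payload in [
        ("disease-schema.json", example["schema"]),
        ("disease-valid.json", example["valid_document"]),
        ("disease-invalid.json", example["invalid_document"]),
        ("defs-schema.json", miappe["defs_schema"]),
        ("plant-schema.json", miappe["schema"]),
    ]:
        paths[name] = directory / name
        paths[name].write_text(canonical_json(payload))
    for i, (doc, _, _) in enumerate(miappe["cases"]):
        name = f"plant-doc-{i}.json"
        paths[name] = directory / name
        paths[name].write_text(canonical_json(doc))

    config = "\n".join(
        [
            "ontologies:",
            "  - id: minimondo",
            "    path: minimondo.obo",
            "  - id: minipato",
            "    path: minipato.obo",
            "taxonomy:",
            "  nodes: nodes.dmp",
            "  names: names.dmp",
            "",
        ]
    )
    paths["config.yaml"] = directory / "config.yaml"
    paths["config.yaml"].write_text(config)
    return paths
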