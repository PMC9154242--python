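"""The four ontology/taxonomy JSON Schema keywords.

* ``isValidTerm`` — the instance must name an existing, non-obsolete
  ontology term.
* ``isChildTermOf`` — the instance must be a strict subclass descendant of
  a given parent term, within given ontologies.
* ``isValidTaxonomy`` — the instance must resolve to exactly one taxon by
  id or name.
* ``graph_restriction`` — the richest keyword: the instance must exist in
  at least one of the listed ontologies AND descend from at least one of
  the listed parent classes along the listed relations (OR-semantics
  across both lists), with ``direct`` and ``include_self`` toggles.

Each check is a pure function of (instance value, keyword parameters,
loaded backend content) returning a list of structured errors — at most
one per failing value, never an exception for bad data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Mapping

from .backend import OntologyBackend, TaxonStatus, TermStatus
from .curie import CurieError, TermId
from .ontology import SUBCLASS, normalize_relation

#: Relation spellings accepted in keyword blocks when no backend-declared
#: relations extend the vocabulary.
BASE_RELATION_SPELLINGS = ("rdfs:subClassOf", "is_a", "part_of")


@dataclass(frozen=True)
class KeywordError:
    """One structured validation failure from a custom keyword."""

    keyword: str
    instance_path: str
    message: str
    params: Any

    def to_dict(self) -> dict:
        return {
            "keyword": self.keyword,
            "instancePath": self.instance_path,
            "message": self.message,
            "params": self.params,
        }


@dataclass(frozen=True)
class ChildTermParams:
    parent: TermId
    ontologies: tuple[str, ...]

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "ChildTermParams":
        return cls(
            parent=TermId.parse(raw["parent"]),
            ontologies=tuple(o.lower() for o in raw["ontologies"]),
        )


@dataclass(frozen=True)
class GraphRestrictionParams:
    ontologies: tuple[str, ...]
    classes: tuple[TermId, ...]
    relations: tuple[str, ...] = (SUBCLASS,)
    direct: bool = False
    include_self: bool = False

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "GraphRestrictionParams":
        return cls(
            ontologies=tuple(o.lower() for o in raw["ontologies"]),
            classes=tuple(TermId.parse(c) for c in raw["classes"]),
            relations=tuple(
                normalize_relation(r)
                for r in raw.get("relations", ["rdfs:subClassOf"])
            ),
            direct=bool(raw.get("direct", False)),
            include_self=bool(raw.get("include_self", False)),
        )


def _malformed(keyword: str, value: Any, params: Any) -> list[KeywordError]:
    return [
        KeywordError(
            keyword=keyword,
            instance_path="",
            message=(
                f"malformed identifier: expected a PREFIX:LOCALID CURIE, "
                f"got {value!r}"
            ),
            params=params,
        )
    ]


def _parse_curie(value: Any) -> TermId | None:
    if not isinstance(value, str):
        return None
    try:
        return TermId.parse(value)
    except CurieError:
        return None


def check_is_valid_term(
    value: Any,
    ontologies: Iterable[str] | None,
    backend: OntologyBackend,
) -> list[KeywordError]:
    """Pass iff the value names an existing, non-obsolete term."""
    params = {"ontologies": list(ontologies)} if ontologies else True
    term = _parse_curie(value)
    if term is None:
        return _malformed("isValidTerm", value, params)
    verdict = backend.term_exists(term, ontologies)
    if verdict.status is TermStatus.FOUND:
        return []
    if verdict.status is TermStatus.OBSOLETE:
        message = f"term {term} is obsolete"
        if verdict.term is not None and verdict.term.replaced_by is not None:
            message += f" (replaced by {verdict.term.replaced_by})"
        return [KeywordError("isValidTerm", "", message, params)]
    where = (
        f"in ontologies {sorted(ontologies)}" if ontologies
        else "in any loaded ontology"
    )
    return [
        KeywordError(
            "isValidTerm", "", f"term {term} not found {where}", params
        )
    ]


def check_is_child_term_of(
    value: Any,
    params: ChildTermParams,
    backend: OntologyBackend,
) -> list[KeywordError]:
    """Pass iff the value is a strict subclass descendant of the parent.

    Non-reflexive and transitive: the parent itself fails, any depth of
    ``is_a`` chain passes.  The value must also exist in one of the
    parameter ontologies.
    """
    raw = {"parent": params.parent.curie, "ontologies": list(params.ontologies)}
    term = _parse_curie(value)
    if term is None:
        return _malformed("isChildTermOf", value, raw)
    verdict = backend.term_exists(term, params.ontologies)
    if verdict.status is TermStatus.NOT_FOUND:
        return [
            KeywordError(
                "isChildTermOf",
                "",
                f"term {term} not found in ontologies "
                f"{list(params.ontologies)}",
                raw,
            )
        ]
    if verdict.status is TermStatus.OBSOLETE:
        message = f"term {term} is obsolete"
        if verdict.term is not None and verdict.term.replaced_by is not None:
            message += f" (replaced by {verdict.term.replaced_by})"
        return [KeywordError("isChildTermOf", "", message, raw)]
    if backend.is_descendant(
        term, params.parent, (SUBCLASS,), include_self=False, direct=False
    ):
        return []
    return [
        KeywordError(
            "isChildTermOf",
            "",
            f"term {term} is not a subclass descendant of {params.parent}",
            raw,
        )
    ]


def check_is_valid_taxonomy(
    value: Any,
    backend: OntologyBackend,
) -> list[KeywordError]:
    """Pass iff the value resolves to exactly one taxon by id or name."""
    if not isinstance(value, (int, str)) or isinstance(value, bool) or (
        isinstance(value, str) and not value.strip()
    ):
        return [
            KeywordError(
                "isValidTaxonomy",
                "",
                f"malformed identifier: expected a taxon id or name, "
                f"got {value!r}",
                True,
            )
        ]
    verdict = backend.taxon_exists(value)
    if verdict.status is TaxonStatus.FOUND:
        return []
    if verdict.status is TaxonStatus.AMBIGUOUS:
        return [
            KeywordError(
                "isValidTaxonomy",
                "",
                f"name {value!r} is ambiguous between taxa "
                f"{list(verdict.tax_ids)}",
                True,
            )
        ]
    return [
        KeywordError(
            "isValidTaxonomy", "", f"taxon {value!r} not found", True
        )
    ]


def check_graph_restriction(
    value: Any,
    params: GraphRestrictionParams,
    backend: OntologyBackend,
) -> list[KeywordError]:
    """Pass iff the value is a member of a listed ontology and descends
    from at least one listed class (OR across ontologies and classes)."""
    raw = {
        "ontologies": list(params.ontologies),
        "classes": [c.curie for c in params.classes],
        "relations": list(params.relations),
        "direct": params.direct,
        "include_self": params.include_self,
    }
    term = _parse_curie(value)
    if term is None:
        return _malformed("graph_restriction", value, raw)
    membership = backend.term_exists(term, params.ontologies)
    if membership.status is TermStatus.NOT_FOUND:
        return [
            KeywordError(
                "graph_restriction",
                "",
                f"term {term} is not a member of any of the ontologies "
                f"{list(params.ontologies)}",
                raw,
            )
        ]
    if membership.status is TermStatus.OBSOLETE:
        message = f"term {term} is obsolete"
        rec = membership.term
        if rec is not None and rec.replaced_by is not None:
            message += f" (replaced by {rec.replaced_by})"
        return [KeywordError("graph_restriction", "", message, raw)]
    for root in params.classes:
        if backend.is_descendant(
            term,
            root,
            params.relations,
            include_self=params.include_self,
            direct=params.direct,
        ):
            return []
    return [
        KeywordError(
            "graph_restriction",
            "",
            f"term {term} does not descend from any of "
            f"{[c.curie for c in params.classes]} via relations "
            f"{list(params.relations)}",
            raw,
        )
    ]


@dataclass(frozen=True)
class KeywordSpec:
    """Registry entry: metaschema for the parameter block plus the check.

    ``check(value, raw_params, backend)`` parses the raw parameter block
    (already metaschema-validated at compile time) and runs the keyword.
    """

    name: str
    metaschema: Mapping
    check: Callable[[Any, Any, OntologyBackend], list[KeywordError]]


def _check_valid_term_entry(value, raw_params, backend):
    if raw_params is False:
        return []
    ontologies = None
    if isinstance(raw_params, Mapping):
        ontologies = [o.lower() for o in raw_params["ontologies"]]
    return check_is_valid_term(value, ontologies, backend)


def _check_child_term_entry(value, raw_params, backend):
    return check_is_child_term_of(
        value, ChildTermParams.from_mapping(raw_params), backend
    )


def _check_taxonomy_entry(value, raw_params, backend):
    if raw_params is False:
        return []
    return check_is_valid_taxonomy(value, backend)


def _check_graph_restriction_entry(value, raw_params, backend):
    return check_graph_restriction(
        value, GraphRestrictionParams.from_mapping(raw_params), backend
    )


_CURIE_PATTERN = r"^[^:\s]+:[^:\s]+$"


def keyword_registry(
    relation_vocabulary: Iterable[str] = (),
) -> dict[str, KeywordSpec]:
    """The four extended keywords, keyed by their schema spelling.

    *relation_vocabulary* extends the relation names that
    ``graph_restriction`` blocks may use beyond the base
    subclass/part_of spellings (e.g. relations declared by loaded
    ontologies); unknown relation names are rejected at compile time.
    """
    relations = sorted(
        set(BASE_RELATION_SPELLINGS) | set(relation_vocabulary)
    )
    ontology_list = {
        "type": "array",
        "items": {"type": "string", "minLength": 1},
        "minItems": 1,
    }
    return {
        "isValidTerm": KeywordSpec(
            name="isValidTerm",
            metaschema={
                "anyOf": [
                    {"type": "boolean"},
                    {
                        "type": "object",
                        "properties": {"ontologies": ontology_list},
                        "required": ["ontologies"],
                        "additionalProperties": False,
                    },
                ]
            },
            check=_check_valid_term_entry,
        ),
        "isChildTermOf": KeywordSpec(
            name="isChildTermOf",
            metaschema={
                "type": "object",
                "properties": {
                    "parent": {"type": "string", "pattern": _CURIE_PATTERN},
                    "ontologies": ontology_list,
                },
                "required": ["parent", "ontologies"],
                "additionalProperties": False,
            },
            check=_check_child_term_entry,
        ),
        "isValidTaxonomy": KeywordSpec(
            name="isValidTaxonomy",
            metaschema={"type": "boolean"},
            check=_check_taxonomy_entry,
        ),
        "graph_restriction": KeywordSpec(
            name="graph_restriction",
            metaschema={
                "type": "object",
                "properties": {
                    "ontologies": ontology_list,
                    "classes": {
                        "type": "array",
                        "items": {
                            "type": "string",
                            "pattern": _CURIE_PATTERN,
                        },
                        "minItems": 1,
                    },
                    "relations": {
                        "type": "array",
                        "items": {"enum": relations},
                        "minItems": 1,
                    },
                    "direct": {"type": "boolean"},
                    "include_self": {"type": "boolean"},
                },
                "required": ["ontologies", "classes"],
                "additionalProperties": False,
            },
            check=_check_graph_restriction_entry,
        ),
    }
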