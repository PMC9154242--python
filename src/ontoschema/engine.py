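"""Schema compilation and validation.

The standard draft-07 vocabulary is delegated to a conformant validator
core (:mod:`jsonschema`); the four ontology/taxonomy keywords are plugged
in as additional validators, so a schema with no custom keywords behaves
exactly like plain draft-07.  Compilation is strict: the dialect is pinned
to draft-07, every ``$ref`` must resolve against the local schema
registry (no network fetches), and every custom keyword block must satisfy
its parameter metaschema — violations are compile errors carrying the
schema path, never silent.

Validation collects *all* failures (no first-error short-circuit) into a
:class:`ValidationReport` whose error order is deterministic: document
order of instance paths, then schema path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterator, Mapping

import jsonschema
from jsonschema import Draft7Validator
from referencing import Registry, Resource
from referencing.exceptions import Unresolvable
from referencing.jsonschema import DRAFT7

from .backend import LocalBackend, OntologyBackend
from .keywords import KeywordSpec, keyword_registry

DRAFT7_URIS = frozenset(
    {
        "http://json-schema.org/draft-07/schema#",
        "http://json-schema.org/draft-07/schema",
    }
)

#: Draft-07 applicator keywords whose values are subschemas, by shape.
_SUBSCHEMA_MAP_KEYWORDS = (
    "properties",
    "patternProperties",
    "definitions",
    "$defs",
)
_SUBSCHEMA_LIST_KEYWORDS = ("allOf", "anyOf", "oneOf")
_SUBSCHEMA_VALUE_KEYWORDS = (
    "additionalProperties",
    "additionalItems",
    "items",
    "contains",
    "propertyNames",
    "not",
    "if",
    "then",
    "else",
)


class CompileError(ValueError):
    """Schema cannot be compiled (bad dialect, ref, or keyword block)."""


class RegistrationError(ValueError):
    """Schema cannot be added to the registry."""


def canonical_json(value: Any) -> str:
    """The one JSON serialization used for every report this package
    emits, so CLI and HTTP output are byte-comparable."""
    return json.dumps(value, indent=2, sort_keys=True, ensure_ascii=False)


def iter_subschemas(
    schema: Any, path: tuple = ()
) -> Iterator[tuple[tuple, Mapping]]:
    """Yield (schema_path, subschema) for every subschema position.

    Walks only positions where draft-07 places subschemas, so property
    *names* that collide with keyword spellings are never misread as
    keywords.
    """
    if not isinstance(schema, Mapping):
        return
    yield path, schema
    for kw in _SUBSCHEMA_MAP_KEYWORDS:
        if isinstance(schema.get(kw), Mapping):
            for name, sub in schema[kw].items():
                yield from iter_subschemas(sub, path + (kw, name))
    for kw in _SUBSCHEMA_LIST_KEYWORDS:
        if isinstance(schema.get(kw), list):
            for i, sub in enumerate(schema[kw]):
                yield from iter_subschemas(sub, path + (kw, i))
    for kw in _SUBSCHEMA_VALUE_KEYWORDS:
        value = schema.get(kw)
        if kw == "items" and isinstance(value, list):
            for i, sub in enumerate(value):
                yield from iter_subschemas(sub, path + (kw, i))
        elif isinstance(value, Mapping):
            yield from iter_subschemas(value, path + (kw,))
    deps = schema.get("dependencies")
    if isinstance(deps, Mapping):
        for name, sub in deps.items():
            if isinstance(sub, Mapping):
                yield from iter_subschemas(sub, path + ("dependencies", name))


def _json_pointer(path: tuple) -> str:
    return "".join(
        "/" + str(p).replace("~", "~0").replace("/", "~1") for p in path
    )


class SchemaRegistry:
    """Local store of schemas addressable by ``$id`` for ``$ref`` use.

    Registration is idempotent for identical content; re-registering a
    different schema under the same ``$id`` is an error.
    """

    def __init__(self) -> None:
        self.schemas: dict[str, Mapping] = {}

    def register(self, schema: Mapping) -> "SchemaRegistry":
        schema_id = schema.get("$id")
        if not schema_id:
            raise RegistrationError("schema has no $id; cannot register")
        existing = self.schemas.get(schema_id)
        if existing is not None and existing != schema:
            raise RegistrationError(
                f"$id {schema_id!r} already registered with different content"
            )
        self.schemas[schema_id] = schema
        return self

    def get(self, schema_id: str) -> Mapping | None:
        return self.schemas.get(schema_id)

    def referencing_registry(self) -> Registry:
        resources = [
            (sid, Resource.from_contents(s, default_specification=DRAFT7))
            for sid, s in self.schemas.items()
        ]
        return Registry().with_resources(resources)


@dataclass
class ValidationReport:
    """Overall verdict plus the ordered list of structured errors."""

    valid: bool
    errors: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"valid": self.valid, "errors": self.errors}

    def to_json(self) -> str:
        return canonical_json(self.to_dict())


def _path_sort_key(path_elems: tuple) -> tuple:
    # ints (array indices) compare numerically, names lexically
    return tuple(
        (0, e, "") if isinstance(e, int) else (1, 0, str(e))
        for e in path_elems
    )


def _report_from_errors(
    errors: list[jsonschema.exceptions.ValidationError],
) -> ValidationReport:
    def key(e: jsonschema.exceptions.ValidationError):
        return (
            _path_sort_key(tuple(e.absolute_path)),
            _path_sort_key(tuple(e.absolute_schema_path)),
            e.message,
        )

    records = []
    for e in sorted(errors, key=key):
        params = e.validator_value
        try:
            json.dumps(params)
        except (TypeError, ValueError):
            params = repr(params)
        records.append(
            {
                "keyword": str(e.validator),
                "instancePath": _json_pointer(tuple(e.absolute_path)),
                "message": e.message,
                "params": params,
            }
        )
    return ValidationReport(valid=not records, errors=records)


class CompiledValidator:
    """A schema compiled against draft-07 plus the custom keywords.

    Use :func:`compile_schema` to construct one.
    """

    def __init__(
        self,
        schema: Mapping | bool,
        validator: jsonschema.protocols.Validator,
        backend: OntologyBackend,
    ):
        self.schema = schema
        self._validator = validator
        self.backend = backend

    def validate(self, document: Any) -> ValidationReport:
        """Validate one document, collecting every failure."""
        return _report_from_errors(list(self._validator.iter_errors(document)))

    def validate_many(self, documents: list) -> list[ValidationReport]:
        """Batch validation: one report per document, order preserved."""
        return [self.validate(doc) for doc in documents]


def _make_keyword_validator(spec: KeywordSpec, backend: OntologyBackend):
    def kw_validator(validator, raw_params, instance, schema):
        for err in spec.check(instance, raw_params, backend):
            yield jsonschema.exceptions.ValidationError(err.message)

    return kw_validator


def _check_custom_blocks(
    schema: Any, keywords: Mapping[str, KeywordSpec]
) -> None:
    for path, sub in iter_subschemas(schema):
        for name, spec in keywords.items():
            if name not in sub:
                continue
            block = sub[name]
            problems = list(
                Draft7Validator(dict(spec.metaschema)).iter_errors(block)
            )
            if problems:
                where = _json_pointer(path + (name,)) or "/"
                raise CompileError(
                    f"invalid {name} block at schema path {where}: "
                    f"{problems[0].message}"
                )


def _check_refs(schema: Mapping, registry: Registry) -> None:
    root = Resource.from_contents(schema, default_specification=DRAFT7)
    resolver = registry.resolver_with_root(root)
    for path, sub in iter_subschemas(schema):
        ref = sub.get("$ref")
        if isinstance(ref, str):
            try:
                resolver.lookup(ref)
            except Unresolvable as exc:
                raise CompileError(
                    f"unresolvable $ref {ref!r} at schema path "
                    f"{_json_pointer(path + ('$ref',)) or '/'}"
                ) from exc


def compile_schema(
    schema: Mapping | bool,
    backend: OntologyBackend | None = None,
    registry: SchemaRegistry | None = None,
    keywords: Mapping[str, KeywordSpec] | None = None,
) -> CompiledValidator:
    """Compile a draft-07 schema with the custom keywords attached.

    Raises :class:`CompileError` for a non-draft-07 dialect marker, an
    unresolvable ``$ref``, a schema rejected by the draft-07 metaschema,
    or a custom keyword block violating its parameter metaschema.
    """
    if backend is None:
        backend = LocalBackend()
    if keywords is None:
        vocab = getattr(backend, "relation_vocabulary", frozenset())
        keywords = keyword_registry(vocab)

    if isinstance(schema, Mapping):
        dialect = schema.get("$schema")
        if dialect is not None and dialect not in DRAFT7_URIS:
            raise CompileError(
                f"unsupported schema dialect {dialect!r}; this validator "
                f"is pinned to draft-07"
            )
        try:
            Draft7Validator.check_schema(dict(schema))
        except jsonschema.exceptions.SchemaError as exc:
            raise CompileError(f"schema is not valid draft-07: {exc.message}")
        _check_custom_blocks(schema, keywords)
        ref_registry = (registry or SchemaRegistry()).referencing_registry()
        _check_refs(schema, ref_registry)
    elif not isinstance(schema, bool):
        raise CompileError("schema must be a JSON object or boolean")
    else:
        ref_registry = (registry or SchemaRegistry()).referencing_registry()

    extended = jsonschema.validators.extend(
        Draft7Validator,
        validators={
            name: _make_keyword_validator(spec, backend)
            for name, spec in keywords.items()
        },
    )
    validator = extended(schema, registry=ref_registry)
    return CompiledValidator(schema, validator, backend)
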