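"""Schema compilation, $ref resolution, report shape and ordering."""

import pytest
from jsonschema import Draft7Validator

from ontoschema import (
    CompileError,
    RegistrationError,
    SchemaRegistry,
    compile_schema,
)

DRAFT7 = "http://json-schema.org/draft-07/schema#"


class TestCompile:
    def test_standard_only_schema_behaves_like_plain_draft7(self, backend):
        schema = {"type": "object", "required": ["a"]}
        compiled = compile_schema(schema, backend=backend)
        plain = Draft7Validator(schema)
        for doc in ({}, {"a": 1}, {"b": 2}, [], "x"):
            assert compiled.validate(doc).valid == plain.is_valid(doc)

    def test_missing_classes_is_a_compile_error_at_the_path(self, backend):
        schema = {
            "properties": {
                "disease": {"graph_restriction": {"ontologies": ["minimondo"]}}
            }
        }
        with pytest.raises(CompileError, match="/properties/disease/graph_restriction"):
            compile_schema(schema, backend=backend)

    def test_unknown_relation_rejected_at_compile_time(self, backend):
        schema = {
            "graph_restriction": {
                "ontologies": ["minimondo"],
                "classes": ["MONDO:0000001"],
                "relations": ["develops_from"],
            }
        }
        with pytest.raises(CompileError, match="graph_restriction"):
            compile_schema(schema, backend=backend)

    def test_non_draft7_dialect_rejected(self, backend):
        schema = {"$schema": "https://json-schema.org/draft/2020-12/schema"}
        with pytest.raises(CompileError, match="draft-07"):
            compile_schema(schema, backend=backend)

    def test_unresolvable_ref_names_the_reference(self, backend):
        schema = {"$ref": "https://example.org/absent.json"}
        with pytest.raises(CompileError, match="absent.json"):
            compile_schema(schema, backend=backend)

    def test_property_named_like_a_keyword_is_not_a_keyword(self, backend):
        # "isValidTerm" here is a *property name*; its subschema block
        # must not be metaschema-checked as keyword parameters
        schema = {"properties": {"isValidTerm": {"type": "string"}}}
        compiled = compile_schema(schema, backend=backend)
        assert compiled.validate({"isValidTerm": "free text"}).valid

    def test_miappe_checklist_with_shared_ref_compiles_end_to_end(
        self, backend, miappe
    ):
        compiled = compile_schema(
            miappe["schema"], backend=backend, registry=miappe["registry"]
        )
        for doc, expected_valid, expected_keywords in miappe["cases"]:
            report = compiled.validate(doc)
            assert report.valid == expected_valid
            assert [e["keyword"] for e in report.errors] == expected_keywords


class TestValidate:
    def test_worked_disease_example_passes(self, backend, disease_example):
        compiled = compile_schema(disease_example["schema"], backend=backend)
        report = compiled.validate(disease_example["valid_document"])
        assert report.valid and report.errors == []

    def test_out_of_hierarchy_term_fails_with_one_keyword_error(
        self, backend, disease_example
    ):
        compiled = compile_schema(disease_example["schema"], backend=backend)
        report = compiled.validate(disease_example["invalid_document"])
        assert not report.valid
        assert len(report.errors) == 1
        err = report.errors[0]
        assert err["keyword"] == "graph_restriction"
        assert err["instancePath"] == "/disease_ontology_id"
        assert err["params"]["classes"] == ["MONDO:0000001", "PATO:0000461"]

    def test_standard_and_custom_failures_both_reported_in_order(
        self, backend
    ):
        schema = {
            "type": "object",
            "required": ["name"],
            "properties": {
                "disease": {
                    "graph_restriction": {
                        "ontologies": ["minimondo"],
                        "classes": ["MONDO:0000001"],
                    }
                }
            },
        }
        compiled = compile_schema(schema, backend=backend)
        report = compiled.validate({"disease": "MINI:0000099"})
        assert [e["keyword"] for e in report.errors] == [
            "required",
            "graph_restriction",
        ]
        assert report.errors[1]["instancePath"] == "/disease"

    def test_all_failures_collected_no_short_circuit(self, backend):
        schema = {
            "type": "object",
            "properties": {
                "a": {"type": "integer"},
                "b": {"type": "integer"},
                "c": {"isValidTerm": True},
            },
        }
        compiled = compile_schema(schema, backend=backend)
        report = compiled.validate({"a": "x", "b": "y", "c": "NOPE:1"})
        assert len(report.errors) == 3
        assert [e["instancePath"] for e in report.errors] == ["/a", "/b", "/c"]

    def test_custom_keyword_on_non_string_instance_reports_malformed(
        self, backend
    ):
        schema = {"properties": {"d": {"isValidTerm": True}}}
        compiled = compile_schema(schema, backend=backend)
        report = compiled.validate({"d": 42})
        assert not report.valid
        assert "malformed" in report.errors[0]["message"]

    def test_validation_is_idempotent(self, backend, disease_example):
        compiled = compile_schema(disease_example["schema"], backend=backend)
        doc = disease_example["invalid_document"]
        assert compiled.validate(doc).to_json() == compiled.validate(doc).to_json()


class TestSchemaRegistry:
    def test_register_then_resolve_ref(self, backend):
        registry = SchemaRegistry()
        registry.register(
            {"$id": "https://example.org/s.json", "type": "integer"}
        )
        compiled = compile_schema(
            {"$ref": "https://example.org/s.json"},
            backend=backend,
            registry=registry,
        )
        assert compiled.validate(3).valid
        assert not compiled.validate("3").valid

    def test_missing_id_is_registration_error(self):
        with pytest.raises(RegistrationError, match=r"\$id"):
            SchemaRegistry().register({"type": "integer"})

    def test_duplicate_identical_registration_is_idempotent(self):
        registry = SchemaRegistry()
        schema = {"$id": "https://example.org/s.json", "type": "integer"}
        registry.register(schema)
        registry.register(dict(schema))
        assert len(registry.schemas) == 1

    def test_duplicate_conflicting_registration_is_an_error(self):
        registry = SchemaRegistry()
        registry.register({"$id": "https://example.org/s.json", "type": "integer"})
        with pytest.raises(RegistrationError, match="different content"):
            registry.register(
                {"$id": "https://example.org/s.json", "type": "string"}
            )


class TestConservativity:
    def test_structural_corpus_verdicts_match_reference(
        self, draft7_corpus, backend
    ):
        """With the custom registry attached, purely structural schemas
        must validate exactly as plain draft-07 does, on every recorded
        case — and the recorded expectations themselves must match an
        unextended reference validator."""
        n_cases = 0
        for group in draft7_corpus:
            compiled = compile_schema(group["schema"], backend=backend)
            reference = Draft7Validator(group["schema"])
            for case in group["tests"]:
                n_cases += 1
                expected = case["valid"]
                assert reference.is_valid(case["data"]) == expected, (
                    group["description"], case["description"])
                assert compiled.validate(case["data"]).valid == expected, (
                    group["description"], case["description"])
        assert n_cases >= 100
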