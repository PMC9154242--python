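"""Semantics of the four custom keywords and their registry."""

import itertools

import pytest
from jsonschema import Draft7Validator

from ontoschema import (
    ChildTermParams,
    GraphRestrictionParams,
    LocalBackend,
    TermId,
    check_graph_restriction,
    check_is_child_term_of,
    check_is_valid_taxonomy,
    check_is_valid_term,
    keyword_registry,
)
from ontoschema.fixtures import DagSpec, generate_dag_ontology
from ontoschema.ontology import SUBCLASS


def tid(text):
    return TermId.parse(text)


class TestIsValidTerm:
    def test_present_term_passes(self, backend):
        assert check_is_valid_term("MINI:0000010", None, backend) == []

    def test_unknown_term_one_error_naming_it(self, backend):
        errors = check_is_valid_term("NOPE:0000001", None, backend)
        assert len(errors) == 1
        assert "NOPE:0000001" in errors[0].message

    def test_obsolete_term_mentions_replacement(self, backend):
        errors = check_is_valid_term("MINI:0000666", None, backend)
        assert len(errors) == 1
        assert "obsolete" in errors[0].message
        assert "MINI:0000010" in errors[0].message

    @pytest.mark.parametrize("bad", [42, None, "", "no-colon", ["MINI:1"]])
    def test_malformed_value_is_an_error_not_an_exception(self, bad, backend):
        errors = check_is_valid_term(bad, None, backend)
        assert len(errors) == 1
        assert "malformed" in errors[0].message

    def test_ontology_scoping_restricts_search(self, backend):
        assert check_is_valid_term("MINI:0000010", ["minimondo"], backend) == []
        assert len(check_is_valid_term("MINI:0000010", ["minipato"], backend)) == 1


class TestIsChildTermOf:
    def params(self, parent="MONDO:0000001", ontologies=("minimondo",)):
        return ChildTermParams.from_mapping(
            {"parent": parent, "ontologies": list(ontologies)}
        )

    def test_direct_child_passes(self, backend):
        assert check_is_child_term_of("MINI:0000010", self.params(), backend) == []

    def test_transitive_grandchild_passes(self, backend):
        assert check_is_child_term_of("MINI:0000011", self.params(), backend) == []

    def test_inverted_direction_fails(self, backend):
        errors = check_is_child_term_of(
            "MONDO:0000001", self.params(parent="MINI:0000010"), backend
        )
        assert len(errors) == 1

    def test_parent_itself_fails_non_reflexive_default(self, backend):
        errors = check_is_child_term_of("MONDO:0000001", self.params(), backend)
        assert len(errors) == 1

    def test_term_outside_listed_ontologies_fails(self, backend):
        errors = check_is_child_term_of(
            "MINI:0000010", self.params(ontologies=("minipato",)), backend
        )
        assert len(errors) == 1
        assert "not found" in errors[0].message


class TestIsValidTaxonomy:
    def test_species_id_and_name_pass(self, backend):
        assert check_is_valid_taxonomy(3702, backend) == []
        assert check_is_valid_taxonomy("Oryza sativa", backend) == []

    def test_unknown_name_fails(self, backend):
        assert len(check_is_valid_taxonomy("No Such Organism", backend)) == 1

    def test_colliding_synonym_lists_both_taxa(self, backend):
        errors = check_is_valid_taxonomy("rockcress", backend)
        assert len(errors) == 1
        assert "3702" in errors[0].message and "59689" in errors[0].message

    @pytest.mark.parametrize("bad", ["", "   ", None, True, {"id": 3702}])
    def test_malformed_values_fail_cleanly(self, bad, backend):
        assert len(check_is_valid_taxonomy(bad, backend)) == 1


class TestGraphRestriction:
    def params(self, **overrides):
        raw = {
            "ontologies": ["minimondo", "minipato"],
            "classes": ["PATO:0000461", "MONDO:0000001"],
            "relations": ["rdfs:subClassOf"],
        }
        raw.update(overrides)
        return GraphRestrictionParams.from_mapping(raw)

    def test_disease_subclass_passes_the_worked_constraint(self, backend):
        assert check_graph_restriction("MINI:0000010", self.params(), backend) == []
        assert check_graph_restriction("MINI:0000020", self.params(), backend) == []

    def test_root_passes_only_with_include_self(self, backend):
        root = "MONDO:0000001"
        assert check_graph_restriction(
            root, self.params(include_self=True), backend
        ) == []
        errors = check_graph_restriction(root, self.params(), backend)
        assert len(errors) == 1
        assert "descend" in errors[0].message

    def test_out_of_hierarchy_member_fails_on_descent(self, backend):
        errors = check_graph_restriction("MINI:0000099", self.params(), backend)
        assert len(errors) == 1
        assert "descend" in errors[0].message

    def test_non_member_fails_on_membership(self, backend):
        errors = check_graph_restriction(
            "MINI:0000010", self.params(ontologies=["minipato"]), backend
        )
        assert len(errors) == 1
        assert "member" in errors[0].message

    def test_obsolete_descendant_fails(self, backend):
        errors = check_graph_restriction("MINI:0000666", self.params(), backend)
        assert len(errors) == 1
        assert "obsolete" in errors[0].message

    def test_direct_flag_limits_to_single_hop(self, backend):
        assert (
            check_graph_restriction("MINI:0000011", self.params(direct=True), backend)
            != []
        )
        assert (
            check_graph_restriction("MINI:0000010", self.params(direct=True), backend)
            == []
        )

    def test_or_semantics_adding_a_class_never_breaks_a_pass(self, backend):
        base = self.params(classes=["MONDO:0000001"])
        widened = self.params(classes=["MONDO:0000001", "PATO:0000461"])
        for value in ("MINI:0000010", "MINI:0000011"):
            assert check_graph_restriction(value, base, backend) == []
            assert check_graph_restriction(value, widened, backend) == []

    def test_equivalent_to_is_child_term_of_on_single_class(self, backend):
        """graph_restriction with one class and default toggles is
        extensionally the isChildTermOf keyword."""
        gr = self.params(classes=["MONDO:0000001"], ontologies=["minimondo"])
        ct = ChildTermParams.from_mapping(
            {"parent": "MONDO:0000001", "ontologies": ["minimondo"]}
        )
        for graph in backend.graphs.values():
            for term in graph.terms:
                a = check_graph_restriction(term.curie, gr, backend) == []
                b = check_is_child_term_of(term.curie, ct, backend) == []
                assert a == b

    def test_exhaustive_verdicts_match_oracle_with_membership(self, oracle):
        g = generate_dag_ontology(DagSpec(n_terms=30, seed=7))
        backend = LocalBackend([g])
        order, index, adj = oracle["adjacency"](g, {SUBCLASS})
        closure = oracle["closure"](adj)
        for value, root in itertools.product(order, repeat=2):
            params = GraphRestrictionParams.from_mapping(
                {"ontologies": [g.ontology_id], "classes": [root.curie]}
            )
            verdict = check_graph_restriction(value.curie, params, backend) == []
            assert verdict == bool(closure[index[value], index[root]])


class TestRegistry:
    def test_exactly_the_four_extended_keywords(self):
        registry = keyword_registry()
        assert set(registry) == {
            "isValidTerm",
            "isChildTermOf",
            "isValidTaxonomy",
            "graph_restriction",
        }

    @pytest.mark.parametrize("name", list(keyword_registry()))
    def test_each_metaschema_rejects_an_empty_block(self, name):
        spec = keyword_registry()[name]
        assert not Draft7Validator(dict(spec.metaschema)).is_valid({})

    def test_graph_restriction_metaschema_rejects_unknown_relation(self):
        spec = keyword_registry()["graph_restriction"]
        block = {
            "ontologies": ["minimondo"],
            "classes": ["MONDO:0000001"],
            "relations": ["regulates"],
        }
        assert not Draft7Validator(dict(spec.metaschema)).is_valid(block)
        extended = keyword_registry(relation_vocabulary={"regulates"})
        assert Draft7Validator(
            dict(extended["graph_restriction"].metaschema)
        ).is_valid(block)

    def test_checks_are_deterministic(self, backend):
        params = GraphRestrictionParams.from_mapping(
            {"ontologies": ["minimondo"], "classes": ["MONDO:0000001"]}
        )
        runs = [
            check_graph_restriction("MINI:0000011", params, backend)
            for _ in range(3)
        ]
        assert runs[0] == runs[1] == runs[2]
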