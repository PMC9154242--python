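"""Shared fixtures and the independent reachability oracle.

The oracle computes transitive closure by repeated boolean
adjacency-matrix multiplication — a different algorithm and data
structure from the BFS the package uses — so graph-query tests compare
two independent routes to the same answer.
"""

import json
from pathlib import Path

import numpy as np
import pytest

from ontoschema import LocalBackend
from ontoschema.fixtures import (
    disease_example_fixture,
    fixture_backend,
    miappe_like_fixture,
    mini_taxonomy,
)
from ontoschema.ontology import normalize_relation

DATA_DIR = Path(__file__).parent / "data"


def adjacency_matrix(graph, relations):
    """Boolean child->parent adjacency restricted to a relation set."""
    order = sorted(graph.terms, key=lambda t: t.curie)
    index = {t: i for i, t in enumerate(order)}
    rels = {normalize_relation(r) for r in relations}
    a = np.zeros((len(order), len(order)), dtype=bool)
    for child, rel, parent in graph.edges:
        if normalize_relation(rel) in rels:
            a[index[child], index[parent]] = True
    return order, index, a


def matrix_closure(adjacency):
    """Transitive (non-reflexive) closure via boolean matrix powers."""
    reach = adjacency.copy()
    while True:
        step = reach | (reach @ adjacency)
        if np.array_equal(step, reach):
            return reach
        reach = step


@pytest.fixture(scope="session")
def oracle():
    return {"adjacency": adjacency_matrix, "closure": matrix_closure}


@pytest.fixture(scope="session")
def backend():
    return fixture_backend()


@pytest.fixture(scope="session")
def disease_example():
    return disease_example_fixture()


@pytest.fixture(scope="session")
def miappe():
    return miappe_like_fixture()


@pytest.fixture(scope="session")
def taxonomy():
    return mini_taxonomy()


@pytest.fixture(scope="session")
def draft7_corpus():
    with open(DATA_DIR / "draft7_cases.json") as fh:
        return json.load(fh)


@pytest.fixture()
def empty_backend():
    return LocalBackend()
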