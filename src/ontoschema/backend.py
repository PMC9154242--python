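"""Backend contract answering term-existence and subsumption queries.

Keyword checks never touch ontology graphs directly; they go through a
backend exposing four operations — ``term_exists``, ``find_term``,
``is_descendant`` and ``taxon_exists``.  Two interchangeable
implementations exist:

* :class:`LocalBackend` — graphs and a taxonomy table loaded from files;
  the default, fully offline.
* :class:`RemoteOLSBackend` — a thin client for an Ontology Lookup
  Service style HTTP API; optional, never required for local operation.

Backend answers are pure functions of the query and the loaded content, so
the local backend may cache ancestor sets transparently.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol

import yaml

from .curie import TermId
from .ontology import (
    SUBCLASS,
    OntologyGraph,
    OntologyTerm,
    parse_obo,
)
from .taxonomy import TaxonomyTable, load_taxonomy


class TermStatus(enum.Enum):
    FOUND = "found"
    OBSOLETE = "found-but-obsolete"
    NOT_FOUND = "not-found"


@dataclass(frozen=True)
class TermVerdict:
    status: TermStatus
    term: OntologyTerm | None = None
    ontology_id: str | None = None


class TaxonStatus(enum.Enum):
    FOUND = "found"
    NOT_FOUND = "not-found"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class TaxonVerdict:
    status: TaxonStatus
    tax_ids: tuple[int, ...] = ()


class OntologyBackend(Protocol):
    """Operations a keyword check may call; implementations interchangeable."""

    def term_exists(
        self, term: TermId, ontologies: Iterable[str] | None = None
    ) -> TermVerdict: ...

    def find_term(
        self, term: TermId, ontologies: Iterable[str] | None = None
    ) -> tuple[str, OntologyTerm] | None: ...

    def is_descendant(
        self,
        term: TermId,
        root: TermId,
        relations: Iterable[str] = (SUBCLASS,),
        include_self: bool = False,
        direct: bool = False,
    ) -> bool: ...

    def taxon_exists(self, query: int | str) -> TaxonVerdict: ...


class LocalBackend:
    """File-backed backend over loaded ontology graphs and a taxonomy.

    A term belongs to an ontology iff it is present in that ontology's
    loaded graph — not merely prefix-matched — because ontologies routinely
    import foreign terms.  Ancestor sets are memoised per
    (ontology, term, relations, direct) key; caching is transparent and can
    be disabled.
    """

    def __init__(
        self,
        graphs: Mapping[str, OntologyGraph] | Iterable[OntologyGraph] = (),
        taxonomy: TaxonomyTable | None = None,
        cache: bool = True,
    ):
        if isinstance(graphs, Mapping):
            self.graphs = dict(graphs)
        else:
            self.graphs = {g.ontology_id: g for g in graphs}
        self.taxonomy = taxonomy
        self.cache_enabled = cache
        self._ancestor_cache: dict[tuple, frozenset[TermId]] = {}

    # -- ontology -----------------------------------------------------

    def find_term(
        self, term: TermId, ontologies: Iterable[str] | None = None
    ) -> tuple[str, OntologyTerm] | None:
        names = (
            sorted(self.graphs)
            if ontologies is None
            else [o.lower() for o in ontologies]
        )
        for name in names:
            graph = self.graphs.get(name)
            if graph is not None and term in graph:
                return name, graph.terms[term]
        return None

    def term_exists(
        self, term: TermId, ontologies: Iterable[str] | None = None
    ) -> TermVerdict:
        hit = self.find_term(term, ontologies)
        if hit is None:
            return TermVerdict(TermStatus.NOT_FOUND)
        name, record = hit
        status = TermStatus.OBSOLETE if record.obsolete else TermStatus.FOUND
        return TermVerdict(status, term=record, ontology_id=name)

    def _ancestors(
        self,
        graph: OntologyGraph,
        term: TermId,
        relations: frozenset[str],
        direct: bool,
    ) -> frozenset[TermId]:
        key = (graph.ontology_id, term, relations, direct)
        if self.cache_enabled and key in self._ancestor_cache:
            return self._ancestor_cache[key]
        result = graph.ancestors(term, relations, direct=direct)
        if self.cache_enabled:
            self._ancestor_cache[key] = result
        return result

    def is_descendant(
        self,
        term: TermId,
        root: TermId,
        relations: Iterable[str] = (SUBCLASS,),
        include_self: bool = False,
        direct: bool = False,
    ) -> bool:
        """True iff *root* is an ancestor of *term* in any loaded graph.

        Absent terms yield False rather than an error; the keyword layer
        is responsible for reporting why.  ``include_self`` admits the
        term itself; ``direct`` restricts to single-edge parents.
        """
        if include_self and term == root and self.find_term(term) is not None:
            return True
        rels = frozenset(relations)
        for graph in self.graphs.values():
            if term in graph:
                if root in self._ancestors(graph, term, rels, direct):
                    return True
        return False

    # -- taxonomy -----------------------------------------------------

    def taxon_exists(self, query: int | str) -> TaxonVerdict:
        if self.taxonomy is None:
            return TaxonVerdict(TaxonStatus.NOT_FOUND)
        if isinstance(query, bool):
            return TaxonVerdict(TaxonStatus.NOT_FOUND)
        if isinstance(query, int):
            if query in self.taxonomy:
                return TaxonVerdict(TaxonStatus.FOUND, (query,))
            return TaxonVerdict(TaxonStatus.NOT_FOUND)
        text = str(query).strip()
        if text.isdigit():
            return self.taxon_exists(int(text))
        hits = tuple(sorted(self.taxonomy.lookup_name(text)))
        if not hits:
            return TaxonVerdict(TaxonStatus.NOT_FOUND)
        if len(hits) > 1:
            return TaxonVerdict(TaxonStatus.AMBIGUOUS, hits)
        return TaxonVerdict(TaxonStatus.FOUND, hits)

    # -- introspection ------------------------------------------------

    @property
    def relation_vocabulary(self) -> frozenset[str]:
        names: set[str] = set()
        for graph in self.graphs.values():
            names |= graph.relations
        return frozenset(names)


class RemoteOLSBackend:
    """Client for an Ontology Lookup Service style HTTP API.

    Interchangeable with :class:`LocalBackend` behind the same operation
    signatures.  Requires the optional ``requests`` dependency and network
    access; intended for production deployments, not for tests.
    """

    def __init__(self, base_url: str, timeout: float = 10.0):
        import requests  # optional dependency, imported lazily

        self.base_url = base_url.rstrip("/")
        self.timeout = timeout
        self._session = requests.Session()

    def _get(self, path: str, **params) -> dict | None:
        resp = self._session.get(
            f"{self.base_url}{path}", params=params, timeout=self.timeout
        )
        if resp.status_code == 404:
            return None
        resp.raise_for_status()
        return resp.json()

    def find_term(self, term, ontologies=None):
        names = list(ontologies) if ontologies else [term.prefix.lower()]
        for name in names:
            payload = self._get(
                f"/api/ontologies/{name}/terms", obo_id=term.curie
            )
            if not payload or "_embedded" not in payload:
                continue
            doc = payload["_embedded"]["terms"][0]
            record = OntologyTerm(
                id=term,
                label=doc.get("label", ""),
                synonyms=tuple(doc.get("synonyms") or ()),
                obsolete=bool(doc.get("is_obsolete", False)),
                replaced_by=(
                    TermId.parse(doc["term_replaced_by"])
                    if doc.get("is_obsolete") and doc.get("term_replaced_by")
                    else None
                ),
            )
            return name, record
        return None

    def term_exists(self, term, ontologies=None):
        hit = self.find_term(term, ontologies)
        if hit is None:
            return TermVerdict(TermStatus.NOT_FOUND)
        name, record = hit
        status = TermStatus.OBSOLETE if record.obsolete else TermStatus.FOUND
        return TermVerdict(status, term=record, ontology_id=name)

    def is_descendant(
        self, term, root, relations=(SUBCLASS,), include_self=False,
        direct=False,
    ):
        if include_self and term == root and self.find_term(term) is not None:
            return True
        hit = self.find_term(term)
        if hit is None:
            return False
        name = hit[0]
        rel_path = "parents" if direct else "hierarchicalAncestors"
        payload = self._get(
            f"/api/ontologies/{name}/terms/{term.curie.replace(':', '_')}/"
            f"{rel_path}", size=1000,
        )
        if not payload or "_embedded" not in payload:
            return False
        ancestors = {
            t.get("obo_id") for t in payload["_embedded"].get("terms", ())
        }
        return root.curie in ancestors

    def taxon_exists(self, query):
        payload = self._get("/api/taxa", q=str(query))
        if not payload:
            return TaxonVerdict(TaxonStatus.NOT_FOUND)
        hits = tuple(int(t["taxId"]) for t in payload.get("taxa", ()))
        if not hits:
            return TaxonVerdict(TaxonStatus.NOT_FOUND)
        if len(hits) > 1:
            return TaxonVerdict(TaxonStatus.AMBIGUOUS, hits)
        return TaxonVerdict(TaxonStatus.FOUND, hits)


def load_backend_from_config(config_path: str | Path) -> LocalBackend:
    """Build a :class:`LocalBackend` from a YAML/JSON config file.

    Config shape::

        ontologies:
          - id: minimondo          # optional; defaults to the OBO header
            path: minimondo.obo
        taxonomy:
          nodes: nodes.dmp
          names: names.dmp
        remote:                    # optional; returned backends stay local
          base_url: https://...
          timeout: 10

    Relative paths resolve against the config file's directory.
    """
    path = Path(config_path)
    text = path.read_text()
    config = (
        json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    ) or {}
    base = path.parent

    graphs: dict[str, OntologyGraph] = {}
    for entry in config.get("ontologies", ()):
        obo_text = (base / entry["path"]).read_text()
        graph = parse_obo(obo_text, ontology_id=entry.get("id"))
        graphs[graph.ontology_id] = graph

    taxonomy = None
    tax = config.get("taxonomy")
    if tax:
        taxonomy = load_taxonomy(
            (base / tax["nodes"]).read_text(),
            (base / tax["names"]).read_text(),
        )
    return LocalBackend(graphs, taxonomy=taxonomy)
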