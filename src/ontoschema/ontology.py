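"""In-memory ontology graphs loaded from OBO 1.2 flat files.

An :class:`OntologyGraph` is a multi-relation directed acyclic graph over
ontology terms: edges run child -> parent and are labelled with a relation
name (``is_a``, ``part_of``, or any relation declared in the source file).
All subsumption queries — "is term X a descendant of class Y?" — reduce to
reachability over edges restricted to a chosen relation subset.

OBO parsing is delegated to :mod:`obonet`; a light pre-scan adds the
line-numbered error reporting for malformed stanzas, and a serializer is
provided so generated fixture ontologies can round-trip through the flat
file format.
"""

from __future__ import annotations

import io
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .curie import CurieError, TermId

#: Spellings that normalize to the internal subclass relation.
SUBCLASS_ALIASES = frozenset({"is_a", "rdfs:subClassOf", "subClassOf"})
SUBCLASS = "is_a"
#: Relations every graph understands even if the source declares none.
BASE_RELATIONS = frozenset({SUBCLASS, "part_of"})


class OboParseError(ValueError):
    """Malformed OBO input (reported with a 1-based line number)."""


class OntologyLoadError(ValueError):
    """Structurally invalid ontology content (cycles, dangling edges)."""


class TermNotFoundError(KeyError):
    """A queried term id is absent from the graph."""

    def __init__(self, term: TermId):
        super().__init__(term.curie)
        self.term = term


def normalize_relation(name: str) -> str:
    """Map relation spellings to canonical internal names.

    ``rdfs:subClassOf`` and ``is_a`` are the same relation; everything
    else passes through unchanged.
    """
    return SUBCLASS if name in SUBCLASS_ALIASES else name


@dataclass(frozen=True)
class OntologyTerm:
    """One term record: id, primary label, synonyms, obsolescence."""

    id: TermId
    label: str = ""
    synonyms: tuple[str, ...] = ()
    obsolete: bool = False
    replaced_by: TermId | None = None

    def __post_init__(self) -> None:
        if not self.obsolete and self.replaced_by is not None:
            raise OntologyLoadError(
                f"{self.id}: replaced_by is only meaningful on obsolete terms"
            )


@dataclass
class OntologyGraph:
    """A multi-relation DAG of ontology terms.

    ``edges`` holds (child, relation, parent) triples; ``relations`` is the
    relation vocabulary (the base subclass/part_of set plus anything the
    source file declared).  Acyclicity over the union of all relations is
    checked at load time, which guarantees acyclicity of every relation
    subset.
    """

    ontology_id: str
    terms: dict[TermId, OntologyTerm] = field(default_factory=dict)
    edges: set[tuple[TermId, str, TermId]] = field(default_factory=set)
    relations: set[str] = field(default_factory=lambda: set(BASE_RELATIONS))

    # parent adjacency per relation, built on first query
    _parents: dict[str, dict[TermId, set[TermId]]] | None = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> "OntologyGraph":
        """Check structural invariants; raise :class:`OntologyLoadError`."""
        for child, rel, parent in self.edges:
            for endpoint in (child, parent):
                if endpoint not in self.terms:
                    raise OntologyLoadError(
                        f"edge ({child} -{rel}-> {parent}) references "
                        f"undeclared term {endpoint}"
                    )
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, _, p in self.edges)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return self
        path = " -> ".join(str(c) for c, _ in cycle) + f" -> {cycle[0][0]}"
        raise OntologyLoadError(
            f"ontology {self.ontology_id!r} contains a cycle: {path}"
        )

    def __contains__(self, term: TermId) -> bool:
        return term in self.terms

    def _adjacency(self, relation: str) -> dict[TermId, set[TermId]]:
        if self._parents is None:
            parents: dict[str, dict[TermId, set[TermId]]] = {}
            for child, rel, parent in self.edges:
                parents.setdefault(rel, {}).setdefault(child, set()).add(parent)
            object.__setattr__(self, "_parents", parents)
        assert self._parents is not None
        return self._parents.get(relation, {})

    def ancestors(
        self,
        term: TermId,
        relations: Iterable[str] = (SUBCLASS,),
        direct: bool = False,
    ) -> frozenset[TermId]:
        """Terms reachable from *term* along the given relations.

        With ``direct=True`` only single-edge parents are returned;
        otherwise the full transitive closure.  The queried term itself is
        never a member of its own ancestor set.
        """
        if term not in self.terms:
            raise TermNotFoundError(term)
        rels = {normalize_relation(r) for r in relations}
        if not rels:
            raise ValueError("relations must be non-empty")
        adjacencies = [self._adjacency(r) for r in rels]
        if direct:
            out: set[TermId] = set()
            for adj in adjacencies:
                out |= adj.get(term, set())
            return frozenset(out)
        seen: set[TermId] = set()
        queue = deque([term])
        while queue:
            node = queue.popleft()
            for adj in adjacencies:
                for parent in adj.get(node, ()):
                    if parent not in seen:
                        seen.add(parent)
                        queue.append(parent)
        return frozenset(seen)


def _prescan_stanzas(obo_text: str) -> set[str]:
    """Collect declared term ids; reject id-less [Term] stanzas by line."""
    declared: set[str] = set()
    stanza_line: int | None = None
    has_id = False
    for lineno, raw in enumerate(obo_text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("["):
            if stanza_line is not None and not has_id:
                raise OboParseError(
                    f"[Term] stanza at line {stanza_line} has no id"
                )
            stanza_line = lineno if line == "[Term]" else None
            has_id = False
        elif stanza_line is not None and line.startswith("id:"):
            has_id = True
            declared.add(line[3:].strip())
    if stanza_line is not None and not has_id:
        raise OboParseError(f"[Term] stanza at line {stanza_line} has no id")
    return declared


def _term_from_node(node_id: str, data: Mapping) -> OntologyTerm:
    try:
        tid = TermId.parse(node_id)
    except CurieError as exc:
        raise OboParseError(f"term id {node_id!r} is not a CURIE: {exc}") from exc
    synonyms = tuple(
        s.split('"')[1] if s.count('"') >= 2 else s
        for s in data.get("synonym", ())
    )
    obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
    replaced = data.get("replaced_by") or []
    replaced_by = TermId.parse(replaced[0]) if (obsolete and replaced) else None
    return OntologyTerm(
        id=tid,
        label=data.get("name", ""),
        synonyms=synonyms,
        obsolete=obsolete,
        replaced_by=replaced_by,
    )


def parse_obo(obo_text: str, ontology_id: str | None = None) -> OntologyGraph:
    """Parse OBO 1.2 flat-file text into an :class:`OntologyGraph`.

    The ontology id is taken from the ``ontology:`` header tag (lowercased)
    unless overridden.  Malformed stanzas raise :class:`OboParseError`
    naming the line; cycles raise :class:`OntologyLoadError` listing one
    cycle.
    """
    declared = _prescan_stanzas(obo_text)
    multigraph = obonet.read_obo(io.StringIO(obo_text), ignore_obsolete=False)
    oid = ontology_id or str(multigraph.graph.get("ontology", "")).lower()
    if not oid:
        raise OboParseError("no ontology header tag and no ontology_id given")

    graph = OntologyGraph(ontology_id=oid)
    # Edges are rebuilt from node attributes rather than obonet's edge list
    # so obsolete terms (which obonet keeps but does not always wire) are
    # handled uniformly.  obonet also auto-creates nodes for referenced but
    # undeclared parents; only declared stanzas become terms, so a dangling
    # reference surfaces as a load error in validate().
    for node_id, data in multigraph.nodes(data=True):
        if node_id not in declared:
            continue
        term = _term_from_node(node_id, data)
        graph.terms[term.id] = term
    for node_id, data in multigraph.nodes(data=True):
        if node_id not in declared:
            continue
        child = TermId.parse(node_id)
        for parent_id in data.get("is_a", ()):
            graph.edges.add((child, SUBCLASS, TermId.parse(parent_id)))
        for entry in data.get("relationship", ()):
            parts = entry.split()
            if len(parts) < 2:
                raise OboParseError(
                    f"malformed relationship line on {node_id}: {entry!r}"
                )
            rel = normalize_relation(parts[0])
            graph.relations.add(rel)
            graph.edges.add((child, rel, TermId.parse(parts[1])))
    return graph.validate()


def write_obo(graph: OntologyGraph) -> str:
    """Serialize a graph back to OBO 1.2 text (inverse of :func:`parse_obo`).

    Term stanzas are emitted in sorted id order and edge lines in sorted
    parent order, so serialization is deterministic.
    """
    by_child: dict[TermId, list[tuple[str, TermId]]] = {}
    for child, rel, parent in graph.edges:
        by_child.setdefault(child, []).append((rel, parent))

    lines = ["format-version: 1.2", f"ontology: {graph.ontology_id}"]
    for tid in sorted(graph.terms, key=lambda t: t.curie):
        term = graph.terms[tid]
        lines += ["", "[Term]", f"id: {tid.curie}"]
        if term.label:
            lines.append(f"name: {term.label}")
        for syn in term.synonyms:
            lines.append(f'synonym: "{syn}" EXACT []')
        for rel, parent in sorted(
            by_child.get(tid, []), key=lambda rp: (rp[0], rp[1].curie)
        ):
            if rel == SUBCLASS:
                lines.append(f"is_a: {parent.curie}")
            else:
                lines.append(f"relationship: {rel} {parent.curie}")
        if term.obsolete:
            lines.append("is_obsolete: true")
            if term.replaced_by is not None:
                lines.append(f"replaced_by: {term.replaced_by.curie}")
    return "\n".join(lines) + "\n"
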