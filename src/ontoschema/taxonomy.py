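"""Taxonomy lookup tables loaded from NCBI-style nodes/names dumps.

The dump dialect is the pipe-delimited taxdump format: ``nodes`` rows are
``tax_id | parent tax_id | rank |`` and ``names`` rows are
``tax_id | name | unique name | name class |``.  Parent pointers must form
a tree whose root is its own parent (the tax_id 1 convention).  Name lookup
is case-insensitive with internal whitespace collapsed, and resolves every
name class (scientific names, synonyms, common names alike).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


class TaxonomyLoadError(ValueError):
    """Structurally invalid taxonomy dump content."""


@dataclass(frozen=True)
class TaxonNode:
    tax_id: int
    scientific_name: str
    rank: str
    parent: int


def normalize_name(name: str) -> str:
    """Case-fold and collapse whitespace for name-index keys."""
    return re.sub(r"\s+", " ", name.strip()).lower()


@dataclass
class TaxonomyTable:
    """Id- and name-indexed taxon records."""

    nodes: dict[int, TaxonNode] = field(default_factory=dict)
    name_index: dict[str, set[int]] = field(default_factory=dict)

    def __contains__(self, tax_id: int) -> bool:
        return tax_id in self.nodes

    def lookup_name(self, name: str) -> frozenset[int]:
        return frozenset(self.name_index.get(normalize_name(name), ()))

    def lineage(self, tax_id: int) -> list[int]:
        """Path of tax_ids from *tax_id* up to (and including) the root."""
        if tax_id not in self.nodes:
            raise KeyError(tax_id)
        path = [tax_id]
        while True:
            parent = self.nodes[path[-1]].parent
            if parent == path[-1]:
                return path
            path.append(parent)


def _split_dump_row(line: str) -> list[str]:
    # taxdump rows end with a trailing delimiter; tolerate both "\t|\t"
    # and bare "|" separators
    return [f.strip() for f in line.rstrip("|\t\n ").split("|")]


def load_taxonomy(nodes_text: str, names_text: str) -> TaxonomyTable:
    """Build a :class:`TaxonomyTable` from nodes/names dump text.

    Raises :class:`TaxonomyLoadError` on duplicate tax_ids or parent
    references to missing nodes.
    """
    parents: dict[int, tuple[int, str]] = {}
    for line in nodes_text.splitlines():
        if not line.strip():
            continue
        fields = _split_dump_row(line)
        if len(fields) < 3:
            raise TaxonomyLoadError(f"nodes row too short: {line!r}")
        tax_id, parent_id = int(fields[0]), int(fields[1])
        if tax_id in parents:
            raise TaxonomyLoadError(f"duplicate tax_id {tax_id}")
        parents[tax_id] = (parent_id, fields[2])
    for tax_id, (parent_id, _) in parents.items():
        if parent_id not in parents:
            raise TaxonomyLoadError(
                f"tax_id {tax_id} references missing parent {parent_id}"
            )

    scientific: dict[int, str] = {}
    index: dict[str, set[int]] = {}
    for line in names_text.splitlines():
        if not line.strip():
            continue
        fields = _split_dump_row(line)
        if len(fields) < 4:
            raise TaxonomyLoadError(f"names row too short: {line!r}")
        tax_id, name, _unique, name_class = (
            int(fields[0]),
            fields[1],
            fields[2],
            fields[3],
        )
        if tax_id not in parents:
            raise TaxonomyLoadError(
                f"names row for unknown tax_id {tax_id}: {line!r}"
            )
        if name_class == "scientific name":
            scientific[tax_id] = name
        index.setdefault(normalize_name(name), set()).add(tax_id)

    table = TaxonomyTable(name_index=index)
    for tax_id, (parent_id, rank) in parents.items():
        table.nodes[tax_id] = TaxonNode(
            tax_id=tax_id,
            scientific_name=scientific.get(tax_id, ""),
            rank=rank,
            parent=parent_id,
        )
    return table
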