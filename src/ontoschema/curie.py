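"""Compact URI (CURIE) identifiers for ontology terms.

Ontology terms are referred to throughout by CURIEs of the form
``PREFIX:LOCALID`` (e.g. ``MONDO:0000001``).  The prefix names the issuing
ontology namespace and is matched case-insensitively; the local identifier
is matched case-sensitively.  A configurable prefix map expands CURIEs to
full IRIs (OBO PURL conventions by default), but all validation logic
compares CURIEs directly so that comparisons stay string-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class CurieError(ValueError):
    """Raised when text cannot be parsed as a PREFIX:LOCALID identifier."""


#: Default CURIE prefix -> IRI prefix expansions (OBO PURL style).
DEFAULT_PREFIX_MAP: dict[str, str] = {
    "obo": "http://purl.obolibrary.org/obo/",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
}


@dataclass(frozen=True)
class TermId:
    """An ontology term identifier in CURIE form.

    Equality and hashing use the case-folded prefix and the verbatim local
    id: ``mondo:0000001`` and ``MONDO:0000001`` denote the same term,
    while local ids that differ only in case do not.
    """

    prefix: str
    local_id: str

    def __post_init__(self) -> None:
        if not self.prefix or not self.local_id:
            raise CurieError(
                f"CURIE needs a non-empty prefix and local id, got "
                f"{self.curie!r}"
            )
        if ":" in self.prefix or ":" in self.local_id:
            raise CurieError(
                f"CURIE must contain exactly one colon, got {self.curie!r}"
            )

    @classmethod
    def parse(cls, text: str) -> "TermId":
        """Parse ``PREFIX:LOCALID`` text into a :class:`TermId`.

        Raises :class:`CurieError` if the text is not CURIE-shaped
        (exactly one colon separating two non-empty, whitespace-free
        parts).
        """
        if not isinstance(text, str):
            raise CurieError(f"CURIE must be text, got {type(text).__name__}")
        if text != text.strip() or any(c.isspace() for c in text):
            raise CurieError(f"CURIE may not contain whitespace: {text!r}")
        prefix, sep, local = text.partition(":")
        if not sep:
            raise CurieError(f"not a CURIE (no colon): {text!r}")
        return cls(prefix, local)

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local_id}"

    def __str__(self) -> str:
        return self.curie

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermId):
            return NotImplemented
        return (
            self.prefix.lower() == other.prefix.lower()
            and self.local_id == other.local_id
        )

    def __hash__(self) -> int:
        return hash((self.prefix.lower(), self.local_id))


def is_curie_shaped(value: object) -> bool:
    """True iff *value* parses as a CURIE (used for malformed-id checks)."""
    try:
        TermId.parse(value)  # type: ignore[arg-type]
    except CurieError:
        return False
    return True


@dataclass
class PrefixMap:
    """CURIE -> IRI expansion table with OBO PURL defaults.

    Only used when exporting identifiers; validation never round-trips
    through IRIs.
    """

    expansions: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PREFIX_MAP)
    )

    def add(self, prefix: str, iri_prefix: str) -> None:
        self.expansions[prefix.lower()] = iri_prefix

    def expand(self, term: TermId) -> str:
        """Expand a CURIE to an IRI.

        Unregistered OBO-style prefixes fall back to the OBO PURL pattern
        ``http://purl.obolibrary.org/obo/PREFIX_LOCALID``.
        """
        key = term.prefix.lower()
        if key in self.expansions:
            return self.expansions[key] + term.local_id
        return f"{DEFAULT_PREFIX_MAP['obo']}{term.prefix.upper()}_{term.local_id}"
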