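"""Origin labels: the per-marker annotation produced by the tracer.

Every cell of an origin matrix is one of four label kinds:

``SOURCE(id)``
    the marker was inherited from the named parent/ancestor (or a line's
    own self-class after multi-generation composition);
``AMBIGUOUS(id1, id2)``
    the marker could have come from either of two parents;
``CONFLICT``
    the progeny carries an allele neither parent could have contributed;
``MISSING``
    the progeny call is heterozygous or missing, so nothing can be said.

Labels are immutable and hashable so they can live in numpy object arrays
and be used as dict/group keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "OriginLabel",
    "source",
    "ambiguous",
    "CONFLICT",
    "MISSING",
    "RESERVED_ID_CHARS",
]

#: characters that may not appear in line/parent identifiers because the
#: TSV serialisation of labels uses them
RESERVED_ID_CHARS = ("|", "!", "\t", "\n")

_CONFLICT_TOKEN = "!"
_MISSING_TOKEN = "."
_AMBIG_SEP = "|"


@dataclass(frozen=True, slots=True)
class OriginLabel:
    """One origin annotation. Use :func:`source`, :func:`ambiguous`,
    :data:`CONFLICT` or :data:`MISSING` rather than the constructor."""

    kind: str  # "source" | "ambiguous" | "conflict" | "missing"
    ids: tuple[str, ...] = field(default=())

    # -- predicates ------------------------------------------------------
    @property
    def is_source(self) -> bool:
        return self.kind == "source"

    @property
    def is_ambiguous(self) -> bool:
        return self.kind == "ambiguous"

    @property
    def is_conflict(self) -> bool:
        return self.kind == "conflict"

    @property
    def is_missing(self) -> bool:
        return self.kind == "missing"

    @property
    def source_id(self) -> str:
        if not self.is_source:
            raise ValueError(f"label {self} has no single source id")
        return self.ids[0]

    # -- serialisation ---------------------------------------------------
    def encode(self) -> str:
        """Render the label as its TSV cell token."""
        if self.is_source:
            return self.ids[0]
        if self.is_ambiguous:
            return _AMBIG_SEP.join(self.ids)
        if self.is_conflict:
            return _CONFLICT_TOKEN
        return _MISSING_TOKEN

    @classmethod
    def decode(cls, token: str) -> "OriginLabel":
        """Parse a TSV cell token back into a label."""
        if token == _MISSING_TOKEN or token == "":
            return MISSING
        if token == _CONFLICT_TOKEN:
            return CONFLICT
        if _AMBIG_SEP in token:
            a, b = token.split(_AMBIG_SEP, 1)
            return ambiguous(a, b)
        return source(token)

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return self.encode()


def source(parent_id: str) -> OriginLabel:
    """Label a marker as conclusively inherited from ``parent_id``."""
    return OriginLabel("source", (parent_id,))


def ambiguous(id1: str, id2: str) -> OriginLabel:
    """Label a marker as attributable to either parent; ids are stored in
    canonical sorted order so ``ambiguous(a, b) == ambiguous(b, a)``."""
    if id1 == id2:
        raise ValueError("ambiguous label requires two distinct parent ids")
    a, b = sorted((id1, id2))
    return OriginLabel("ambiguous", (a, b))


CONFLICT = OriginLabel("conflict")
MISSING = OriginLabel("missing")


def validate_identifier(name: str) -> None:
    """Reject ids that would collide with the label serialisation."""
    if not name:
        raise ValueError("identifier must be non-empty")
    if name == _MISSING_TOKEN or name == _CONFLICT_TOKEN:
        raise ValueError(f"identifier {name!r} is a reserved label token")
    for ch in RESERVED_ID_CHARS:
        if ch in name:
            raise ValueError(f"identifier {name!r} contains reserved character {ch!r}")
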