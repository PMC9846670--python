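"""Codelist containers.

A codelist is the unit of exchange in EHR phenotyping: a named set of
terminology concepts that defines a phenotype. Here each entry carries an
include/exclude status and a provenance tag recording *why* it is in the
list (the seed concept, a hierarchy descendant, an attribute-linked
situation, an inactive legacy concept, a keyword hit, or a manual
decision), and a codelist built by an intensional method also carries the
definition that generated it so it can be rebuilt deterministically on any
terminology release.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

INCLUDE = "include"
EXCLUDE = "exclude"
_STATUSES = frozenset({INCLUDE, EXCLUDE})

#: Methods a codelist can be built by.
METHODS = ("primary", "extended", "valueset", "read-derived", "manual")


@dataclass(frozen=True)
class CodelistEntry:
    """One concept in a codelist.

    provenance_tag is one of: ``primary``, ``descendant``,
    ``attribute:<relationship>``, ``inactive-history:<0-3>``, ``search``,
    ``manual``.
    """

    concept_id: int
    term: str
    status: str
    provenance_tag: str
    active: bool = True

    def __post_init__(self) -> None:
        if self.status not in _STATUSES:
            raise ValueError(f"invalid entry status {self.status!r}")
        if not self.provenance_tag:
            raise ValueError("provenance_tag must be set")


@dataclass(frozen=True)
class CodelistDefinition:
    """The intensional definition that generated a codelist.

    Rebuilding from the same definition on the same release must yield an
    identical entry set.
    """

    primary_concepts: frozenset[int] = frozenset()
    exclusion_concepts: frozenset[int] = frozenset()
    search_patterns: tuple[str, ...] = ()


@dataclass
class Codelist:
    """A named phenotype codelist."""

    name: str
    method: str = "manual"
    entries: list[CodelistEntry] = field(default_factory=list)
    definition: Optional[CodelistDefinition] = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown codelist method {self.method!r}")

    @property
    def inclusion_ids(self) -> set[int]:
        """Concept ids with include status (the expanded inclusion set)."""
        return {e.concept_id for e in self.entries if e.status == INCLUDE}

    @property
    def exclusion_ids(self) -> set[int]:
        return {e.concept_id for e in self.entries if e.status == EXCLUDE}

    @property
    def active_inclusion_ids(self) -> set[int]:
        """Include entries that are active in the source release."""
        return {
            e.concept_id
            for e in self.entries
            if e.status == INCLUDE and e.active
        }

    def sorted_entries(self) -> list[CodelistEntry]:
        """Entries in canonical order: includes first, then by concept id."""
        return sorted(
            self.entries, key=lambda e: (e.status != INCLUDE, e.concept_id)
        )

    def with_entries(self, entries: Iterable[CodelistEntry]) -> "Codelist":
        return Codelist(
            name=self.name,
            method=self.method,
            entries=list(entries),
            definition=self.definition,
        )

    def copy(self) -> "Codelist":
        return self.with_entries(replace(e) for e in self.entries)
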