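"""Construction of phenotype codelists.

Three methods, in increasing order of breadth:

* **primary** — a small set of seed disorder concepts and all their is-a
  descendants, minus the hierarchies of any exclusion concepts (e.g. a
  diabetes phenotype that excludes the gestational-diabetes subtree).
* **extended** — the primary set plus concepts linked *into* the primary
  hierarchy by "Due to" or "Associated with" attributes, plus situation
  concepts linked by "Associated finding" whose "Finding context" is
  Confirmed/Known present and whose "Subject relationship context" is
  Subject of record (e.g. "History of heart failure"), which are not
  is-a descendants of the disorder.
* **value set** — a keyword search over all descriptions, expanded by
  descendants, minimized by subsumption for human review, and filtered by
  recorded review decisions.

After any method, inactive legacy concepts are appended from the history
(query) table, because historic EHR data may have been recorded with
concepts that have since been inactivated.

Intensional definitions (primary/extended) serialize to a restricted
SNOMED CT Expression Constraint Language dialect: ``<<`` (descendants or
self), ``OR``, ``MINUS`` and parentheses — enough to express every
definition this toolkit creates — and parse back to the same concept set.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .codelist import (
    EXCLUDE,
    INCLUDE,
    Codelist,
    CodelistDefinition,
    CodelistEntry,
)
from .errors import EclParseError, FormatError
from .graph import AttributeConfig, ConceptGraph, DEFAULT_ATTRIBUTES, search_descriptions
from .rf2 import HistoryRow, Release

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReviewDecision:
    """A recorded human decision about one value-set candidate concept."""

    concept_id: int
    decision: str  # include | exclude
    reason: str = ""

    def __post_init__(self) -> None:
        if self.decision not in (INCLUDE, EXCLUDE):
            raise ValueError(f"invalid decision {self.decision!r}")


def read_decisions(path) -> list[ReviewDecision]:
    """Read a review-decision CSV (concept_id, decision, reason)."""
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "concept_id" not in reader.fieldnames:
            raise FormatError(f"decision file {path} must have a concept_id column")
        out = []
        for i, rec in enumerate(reader, start=2):
            try:
                out.append(
                    ReviewDecision(
                        int(rec["concept_id"]), rec["decision"], rec.get("reason", "")
                    )
                )
            except ValueError as exc:
                raise FormatError(f"decision file {path} row {i}: {exc}") from exc
    return out


def _entry(graph: ConceptGraph, cid: int, status: str, tag: str) -> CodelistEntry:
    return CodelistEntry(
        concept_id=cid,
        term=graph.fsn(cid) if cid in graph else "",
        status=status,
        provenance_tag=tag,
        active=cid in graph,
    )


def build_primary(
    graph: ConceptGraph,
    primary_concepts: Iterable[int],
    exclusions: Iterable[int] = (),
    name: str = "codelist",
) -> Codelist:
    """Build a primary codelist: descendants-or-self of the seed concepts
    minus descendants-or-self of the exclusion concepts.

    Exclusion is applied by set difference *after* full expansion, so an
    excluded subtree nested anywhere under an included concept is removed.
    Removed concepts are recorded as exclude entries.
    """
    primary = set(primary_concepts)
    if not primary:
        raise ValueError("primary_concepts must be non-empty")
    exclusions = set(exclusions)
    expanded = graph.descendants_or_self(primary)
    excluded = graph.descendants_or_self(exclusions) if exclusions else set()
    included = expanded - excluded
    if not included:
        logger.warning(
            "codelist %r: exclusions removed every primary concept; "
            "returning an empty codelist", name,
        )
    entries = [
        _entry(graph, cid, INCLUDE, "primary" if cid in primary else "descendant")
        for cid in sorted(included)
    ]
    entries += [
        _entry(graph, cid, EXCLUDE, "primary" if cid in exclusions else "descendant")
        for cid in sorted(excluded & expanded)
    ]
    return Codelist(
        name=name,
        method="primary",
        entries=entries,
        definition=CodelistDefinition(
            primary_concepts=frozenset(primary),
            exclusion_concepts=frozenset(exclusions),
        ),
    )


#: provenance tags for the three extended-method attribute routes, in the
#: priority order used when a concept qualifies via more than one
_EXTENDED_ROUTES = ("due-to", "associated-with", "associated-finding")


def build_extended(
    graph: ConceptGraph,
    base: Codelist,
    config: Optional[AttributeConfig] = None,
) -> Codelist:
    """Extend a primary codelist with attribute-linked concepts.

    Adds (1) concepts linked into the base hierarchy by "Due to", (2) by
    "Associated with", and (3) situation concepts linked by "Associated
    finding" whose Finding context is Confirmed present or Known present
    and whose Subject relationship context is Subject of record. The base
    exclusions still apply; the extended set is always a superset of the
    base inclusion set.
    """
    if base.method != "primary":
        raise ValueError("build_extended requires a primary codelist as base")
    config = config or graph.config
    targets = base.inclusion_ids
    excluded = (
        graph.descendants_or_self(base.definition.exclusion_concepts)
        if base.definition and base.definition.exclusion_concepts
        else set()
    )

    situation_filters = {
        config.finding_context_type_id: {
            config.confirmed_present_value_id,
            config.known_present_value_id,
        },
        config.subject_relationship_context_type_id: {
            config.subject_of_record_value_id
        },
    }
    by_route = {
        "due-to": graph.attribute_sources(targets, config.due_to_type_id),
        "associated-with": graph.attribute_sources(
            targets, config.associated_with_type_id
        ),
        "associated-finding": graph.attribute_sources(
            targets, config.associated_finding_type_id, situation_filters
        ),
    }

    entries = [e for e in base.entries]
    seen = targets | base.exclusion_ids
    for route in _EXTENDED_ROUTES:
        for cid in sorted(by_route[route] - seen - excluded):
            entries.append(_entry(graph, cid, INCLUDE, f"attribute:{route}"))
            seen.add(cid)
    return Codelist(
        name=base.name, method="extended", entries=entries, definition=base.definition
    )


def valueset_candidates(
    graph: ConceptGraph, release: Release, patterns: Sequence[str]
) -> tuple[set[int], set[int]]:
    """(candidate set, subsumption-minimal review set) for a keyword search.

    The candidate set is every active concept with a matching description,
    expanded by descendants-or-self; the review set is its minimization by
    subsumption — the list a human reviews.
    """
    hits = search_descriptions(release, list(patterns)) & graph.nodes
    candidates = graph.descendants_or_self(hits) if hits else set()
    review = graph.simplify_by_subsumption(candidates) if candidates else set()
    return candidates, review


def build_valueset(
    graph: ConceptGraph,
    release: Release,
    patterns: Sequence[str],
    decisions: Iterable[ReviewDecision],
    config: Optional[AttributeConfig] = None,
    name: str = "codelist",
) -> Codelist:
    """Build a value-set codelist from keyword search plus review decisions.

    Decisions recorded on a candidate cascade to its candidate descendants
    (review happens on the subsumption-minimal list); a decision on the
    concept itself overrides an inherited one, and an inherited exclude
    beats an inherited include. Candidates left undecided are flagged and
    *not* silently included. A decision naming a concept outside the
    candidate set is honoured as a manual entry, with a warning.
    """
    if not patterns:
        raise ValueError("patterns must be non-empty")
    candidates, _review = valueset_candidates(graph, release, patterns)
    decision_by_id = {}
    for d in decisions:
        if d.concept_id in decision_by_id:
            raise ValueError(f"duplicate decision for concept {d.concept_id}")
        decision_by_id[d.concept_id] = d

    # cascade decisions down the hierarchy within the candidate set
    inherited: dict[int, str] = {}
    for d in decision_by_id.values():
        if d.concept_id not in graph:
            continue
        for cid in graph.descendants_or_self({d.concept_id}) & candidates:
            prev = inherited.get(cid)
            if prev is None or (prev == INCLUDE and d.decision == EXCLUDE):
                inherited[cid] = d.decision

    entries: list[CodelistEntry] = []
    undecided = []
    for cid in sorted(candidates):
        own = decision_by_id.get(cid)
        status = own.decision if own else inherited.get(cid)
        if status is None:
            undecided.append(cid)
            continue
        entries.append(_entry(graph, cid, status, "search"))
    if undecided:
        logger.warning(
            "value set %r: %d candidate concept(s) have no review decision "
            "and were not included: %s%s",
            name, len(undecided), undecided[:10], "..." if len(undecided) > 10 else "",
        )
    for cid, d in sorted(decision_by_id.items()):
        if cid not in candidates:
            logger.warning(
                "value set %r: decision for concept %d outside the candidate "
                "set; recorded as manual", name, cid,
            )
            entries.append(_entry(graph, cid, d.decision, "manual"))
    return Codelist(
        name=name,
        method="valueset",
        entries=entries,
        definition=CodelistDefinition(search_patterns=tuple(patterns)),
    )


def expand_inactive(
    codelist: Codelist,
    history: Iterable[HistoryRow],
    max_provenance: int = 3,
) -> Codelist:
    """Append inactive legacy concepts whose active supertype is included.

    A history row contributes when its current concept is in the inclusion
    set and its provenance does not exceed ``max_provenance`` (default 3,
    include all; provenance 3 concepts had at least two distinct
    meanings). Never removes entries; idempotent.
    """
    if not 0 <= max_provenance <= 3:
        raise ValueError("max_provenance must be between 0 and 3")
    inclusion = codelist.inclusion_ids
    present = {e.concept_id for e in codelist.entries}
    new_entries = list(codelist.entries)
    for row in sorted(
        history, key=lambda r: (r.legacy_concept_id, r.current_concept_id)
    ):
        if (
            row.current_concept_id in inclusion
            and row.provenance <= max_provenance
            and row.legacy_concept_id not in present
        ):
            new_entries.append(
                CodelistEntry(
                    concept_id=row.legacy_concept_id,
                    term="",
                    status=INCLUDE,
                    provenance_tag=f"inactive-history:{row.provenance}",
                    active=False,
                )
            )
            present.add(row.legacy_concept_id)
    return codelist.with_entries(new_entries)


# ---------------------------------------------------------------------------
# ECL serialization (restricted dialect: <<, OR, MINUS, parentheses)


def to_ecl(codelist: Codelist) -> str:
    """Serialize an intensional definition as an expression constraint.

    Each seed concept becomes ``<< id`` (descendants or self); seeds are
    joined by OR and exclusions subtracted with MINUS. Attribute-linked
    concepts in an extended codelist are not hierarchy members, so they
    are enumerated as bare concept ids OR-ed into the expression.
    """
    d = codelist.definition
    if d is None or not d.primary_concepts:
        raise ValueError(
            "to_ecl requires a codelist with an intensional definition "
            "(method primary or extended)"
        )
    parts = [f"<< {c}" for c in sorted(d.primary_concepts)]
    parts += [
        str(e.concept_id)
        for e in sorted(codelist.entries, key=lambda e: e.concept_id)
        if e.status == INCLUDE
        and e.active
        and e.provenance_tag.startswith("attribute:")
    ]
    inc = " OR ".join(parts)
    if len(parts) > 1 and d.exclusion_concepts:
        inc = f"({inc})"
    if not d.exclusion_concepts:
        return inc
    exc = " OR ".join(f"<< {c}" for c in sorted(d.exclusion_concepts))
    if len(d.exclusion_concepts) > 1:
        exc = f"({exc})"
    return f"{inc} MINUS {exc}"


_TOKEN_RE = re.compile(r"\s*(<<|OR\b|MINUS\b|\(|\)|\d+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            if text[pos:].strip():
                raise EclParseError(
                    f"unexpected character {text[pos:].strip()[0]!r}", pos
                )
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _EclParser:
    """Recursive-descent parser for the restricted constraint grammar:

    expression := disjunction (MINUS disjunction)*
    disjunction := atom (OR atom)*
    atom := '<<'? integer | '(' expression ')'
    """

    def __init__(self, text: str, graph: ConceptGraph):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0
        self.graph = graph

    def _peek(self) -> Optional[str]:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def _pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.text)

    def parse(self) -> set[int]:
        result = self.expression()
        if self.i < len(self.tokens):
            raise EclParseError(
                f"unexpected token {self._peek()!r}", self._pos()
            )
        return result

    def expression(self) -> set[int]:
        result = self.disjunction()
        while self._peek() == "MINUS":
            self.i += 1
            result = result - self.disjunction()
        return result

    def disjunction(self) -> set[int]:
        result = self.atom()
        while self._peek() == "OR":
            self.i += 1
            result = result | self.atom()
        return result

    def atom(self) -> set[int]:
        tok = self._peek()
        if tok == "(":
            self.i += 1
            inner = self.expression()
            if self._peek() != ")":
                raise EclParseError("expected ')'", self._pos())
            self.i += 1
            return inner
        descend = False
        if tok == "<<":
            descend = True
            self.i += 1
            tok = self._peek()
        if tok is None or not tok.isdigit():
            raise EclParseError(
                f"expected a concept id, got {tok!r}", self._pos()
            )
        cid = int(tok)
        self.i += 1
        return self.graph.descendants_or_self({cid}) if descend else {cid}


def parse_ecl(text: str, graph: ConceptGraph) -> set[int]:
    """Evaluate an expression constraint (restricted dialect) on a graph,
    returning the active concept ids it selects."""
    if not text.strip():
        raise EclParseError("empty expression", 0)
    return _EclParser(text, graph).parse()
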