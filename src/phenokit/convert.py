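"""Semiautomated conversion of legacy Read V2 codelists to SNOMED CT.

Legacy UK primary-care phenotype definitions are flat lists of Read V2
codes. To convert one into a parsimonious SNOMED CT definition, the Read
codes are first mapped to SNOMED concepts (the "mapped set"); then every
mapped concept, every direct parent of a mapped concept, and every
descendant of a mapped concept is considered as a *candidate* whose
descendants-or-self hierarchy could stand for the whole codelist. Each
candidate hierarchy is scored at the concept level:

    precision = |hierarchy ∩ mapped| / |hierarchy|
    recall    = |hierarchy ∩ mapped| / |mapped|
    F1        = 2 · precision · recall / (precision + recall)

(F1 = 0 when both are 0). Candidates are ranked by descending F1 and the
best is selected automatically; the full ranked table is emitted for
clinical review, since whether the winning concept really means the same
thing as the phenotype is a human judgement. The final codelist is the
selected hierarchy plus linked personal-history/confirmed situation
concepts and inactive legacy concepts from the history table; if no
candidate clears the F1 floor, the mapped set itself is kept
("read-derived").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence

import pandas as pd

from .builder import expand_inactive
from .codelist import INCLUDE, Codelist, CodelistDefinition
from .errors import UnknownConceptError
from .graph import AttributeConfig, ConceptGraph
from .rf2 import HistoryRow, MappingRow

logger = logging.getLogger(__name__)

#: origin priority when a concept is reachable more than one way
_ORIGIN_PRIORITY = {"mapped": 0, "parent": 1, "descendant": 2}


def format_score(value: float) -> str:
    """Display rounding for report tables: half-up to 2 decimals, trailing
    zeros trimmed (0.095 prints as "0.1", 1.0 as "1")."""
    q = Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    text = format(q, "f")
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text or "0"


def round_score(value: float) -> float:
    """Half-up rounding of a score to 2 decimals, as a float."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CandidateScore:
    """Concept-level performance of one candidate hierarchy against the
    mapped reference set. Unrounded values are retained; rounding is a
    display concern."""

    concept_id: int
    hierarchy_size: int
    true_positives: int
    precision: float
    recall: float
    f1: float
    origin: str  # mapped | parent | descendant

    @property
    def display(self) -> tuple[str, str, str]:
        """(precision, recall, f1) as the report prints them."""
        return (
            format_score(self.precision),
            format_score(self.recall),
            format_score(self.f1),
        )


@dataclass
class ConversionReport:
    """Everything the conversion pipeline produces for one phenotype."""

    mapped_concepts: set[int]
    unmapped_read_codes: list[str]
    candidates: list[CandidateScore] = field(default_factory=list)
    selected: Optional[int] = None
    final_codelist: Optional[Codelist] = None

    def to_frame(self, graph: Optional[ConceptGraph] = None) -> pd.DataFrame:
        """The ranked candidate table, one row per candidate, scores
        rounded for display, mirroring the review-report columns."""
        rows = []
        for c in self.candidates:
            p, r, f = c.display
            rows.append(
                {
                    "concept_id": c.concept_id,
                    "fsn": graph.fsn(c.concept_id) if graph else "",
                    "origin": c.origin,
                    "precision": p,
                    "recall": r,
                    "f1": f,
                    "selected": c.concept_id == self.selected,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "concept_id", "fsn", "origin", "precision", "recall", "f1",
                "selected",
            ],
        )


def map_read_to_snomed(
    read_codes: Sequence[str], mappings: Iterable[MappingRow]
) -> tuple[set[int], list[str]]:
    """Map Read codes to a deduplicated SNOMED concept set.

    Several Read codes commonly map to the same concept ("Bronchiectasis"
    and "Bronchiectasis NOS" both map to the bronchiectasis disorder), and
    one code may map to several concepts. Codes without any mapping row
    are returned, in first-seen order, rather than dropped silently.
    """
    if not read_codes:
        raise ValueError("read_codes must be non-empty")
    by_code: dict[str, set[int]] = {}
    for m in mappings:
        if m.read_code:
            by_code.setdefault(m.read_code, set()).add(m.concept_id)
    mapped: set[int] = set()
    unmapped: list[str] = []
    seen_unmapped = set()
    for code in read_codes:
        hit = by_code.get(code)
        if hit:
            mapped |= hit
        elif code not in seen_unmapped:
            unmapped.append(code)
            seen_unmapped.add(code)
    if unmapped:
        logger.warning("%d Read code(s) had no SNOMED map: %s", len(unmapped), unmapped)
    return mapped, unmapped


def enumerate_candidates(
    graph: ConceptGraph, mapped: set[int]
) -> list[tuple[int, str]]:
    """Candidate concepts: the mapped set, its direct parents, and all
    descendants of mapped concepts; origin priority mapped > parent >
    descendant when a concept qualifies more than one way."""
    if not mapped:
        raise ValueError("mapped set must be non-empty")
    origin: dict[int, str] = {}
    for cid in graph.descendants_or_self(mapped) - mapped:
        origin[cid] = "descendant"
    for cid in graph.parents(mapped) - mapped:
        origin[cid] = "parent"
    for cid in mapped:
        origin[cid] = "mapped"
    return sorted(
        origin.items(), key=lambda kv: (_ORIGIN_PRIORITY[kv[1]], kv[0])
    )


def score_candidate(
    graph: ConceptGraph,
    candidate: int,
    mapped: set[int],
    origin: str = "mapped",
) -> CandidateScore:
    """Score one candidate hierarchy against the mapped set (concept-level
    precision/recall/F1; the hierarchy includes the candidate itself)."""
    if not mapped:
        raise ValueError("mapped set must be non-empty")
    if candidate not in graph:
        raise UnknownConceptError(f"candidate {candidate} not in graph")
    hierarchy = graph.descendants_or_self({candidate})
    tp = len(hierarchy & mapped)
    precision = tp / len(hierarchy)
    recall = tp / len(mapped)
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return CandidateScore(
        concept_id=candidate,
        hierarchy_size=len(hierarchy),
        true_positives=tp,
        precision=precision,
        recall=recall,
        f1=f1,
        origin=origin,
    )


def rank_and_select(
    candidates: Sequence[CandidateScore], f1_floor: float = 0.0
) -> tuple[list[CandidateScore], Optional[int]]:
    """Rank candidates by descending F1 and pick the best.

    Ties break by higher precision, then smaller hierarchy, then lower
    concept id (deterministic; in practice ties go to human review). The
    top candidate is selected only if its F1 reaches ``f1_floor``;
    otherwise no single hierarchy represents the phenotype.
    """
    if not candidates:
        raise ValueError("no candidates to rank")
    ranked = sorted(
        candidates,
        key=lambda c: (-c.f1, -c.precision, c.hierarchy_size, c.concept_id),
    )
    best = ranked[0]
    # floor 0 (the default) means "always select, leave acceptance to review"
    selected = best.concept_id if best.f1 >= f1_floor else None
    return ranked, selected


def convert_codelist(
    read_codelist: Sequence[tuple[str, str]],
    mappings: Iterable[MappingRow],
    graph: ConceptGraph,
    history: Iterable[HistoryRow] = (),
    config: Optional[AttributeConfig] = None,
    f1_floor: float = 0.0,
    include_history_concepts: bool = True,
    max_provenance: int = 3,
    name: str = "converted",
) -> ConversionReport:
    """Full conversion pipeline: map, enumerate, score, rank, select,
    expand.

    When a candidate is selected, the final codelist is its
    descendants-or-self hierarchy plus linked personal-history/confirmed
    situation concepts (via Associated finding with Confirmed/Known
    present context and Subject of record) and inactive legacy concepts
    from the history table. When none is selected the mapped set itself is
    kept, expanded the same way ("read-derived"). Pass
    ``include_history_concepts=False`` for incident-disease definitions,
    which should not contain personal-history concepts.
    """
    config = config or graph.config
    codes = [code for code, _ in read_codelist]
    mapped_all, unmapped = map_read_to_snomed(codes, mappings)
    mapped = mapped_all & graph.nodes
    dropped = mapped_all - mapped
    if dropped:
        logger.warning(
            "%d mapped concept(s) are not active in this release: %s",
            len(dropped), sorted(dropped),
        )
    if not mapped:
        raise ValueError("no Read code mapped to an active concept")

    scored = [
        score_candidate(graph, cid, mapped, origin)
        for cid, origin in enumerate_candidates(graph, mapped)
    ]
    ranked, selected = rank_and_select(scored, f1_floor)

    from .builder import _entry  # shared entry constructor

    if selected is not None:
        inclusion = graph.descendants_or_self({selected})
        entries = [
            _entry(
                graph, cid, INCLUDE, "primary" if cid == selected else "descendant"
            )
            for cid in sorted(inclusion)
        ]
        definition = CodelistDefinition(primary_concepts=frozenset({selected}))
        method = "primary"
    else:
        inclusion = set(mapped)
        entries = [_entry(graph, cid, INCLUDE, "manual") for cid in sorted(inclusion)]
        definition = None
        method = "read-derived"

    if include_history_concepts:
        situation_filters = {
            config.finding_context_type_id: {
                config.confirmed_present_value_id,
                config.known_present_value_id,
            },
            config.subject_relationship_context_type_id: {
                config.subject_of_record_value_id
            },
        }
        situations = graph.attribute_sources(
            inclusion, config.associated_finding_type_id, situation_filters
        )
        for cid in sorted(situations - inclusion):
            entries.append(_entry(graph, cid, INCLUDE, "attribute:associated-finding"))

    codelist = Codelist(name=name, method=method, entries=entries, definition=definition)
    codelist = expand_inactive(codelist, list(history), max_provenance)
    return ConversionReport(
        mapped_concepts=mapped,
        unmapped_read_codes=unmapped,
        candidates=ranked,
        selected=selected,
        final_codelist=codelist,
    )
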