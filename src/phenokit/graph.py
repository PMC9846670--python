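"""Typed concept graph over a SNOMED CT release.

The terminology is polyhierarchical: concepts are linked to supertypes by
"is a" relationships (a concept may have several parents) and to other
concepts by attribute relationships ("Due to", "Associated with",
"Associated finding", context attributes, ...). This module builds a
:class:`ConceptGraph` from the active rows of a :class:`~phenokit.rf2.Release`
and answers the queries the codelist methods need: transitive descendants,
direct parents, attribute-linked sources with context filtering, keyword
search over descriptions, and subsumption-based minimization of a concept
set.

Is-a edges are stored child -> parent, so "descendants of X" are the nodes
from which X is reachable. The is-a relation must be acyclic; a cycle is a
release defect and raises at build time.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import networkx as nx

from .errors import IntegrityError, UnknownConceptError
from .rf2 import FSN_TYPE_ID, Release

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AttributeConfig:
    """Concept ids of the relationship types and context values used by the
    codelist methods.

    Defaults are the standard SNOMED CT metadata concepts; fixtures may
    override them with small ids.
    """

    isa_type_id: int = 116680003
    due_to_type_id: int = 42752001
    associated_with_type_id: int = 47429007
    associated_finding_type_id: int = 246090004
    finding_context_type_id: int = 408729009
    subject_relationship_context_type_id: int = 408732007
    has_focus_type_id: int = 363702006
    known_present_value_id: int = 410515003
    confirmed_present_value_id: int = 410605003
    subject_of_record_value_id: int = 410604004

    def __post_init__(self) -> None:
        ids = [
            self.isa_type_id, self.due_to_type_id, self.associated_with_type_id,
            self.associated_finding_type_id, self.finding_context_type_id,
            self.subject_relationship_context_type_id, self.has_focus_type_id,
            self.known_present_value_id, self.confirmed_present_value_id,
            self.subject_of_record_value_id,
        ]
        if any(i <= 0 for i in ids) or len(set(ids)) != len(ids):
            raise ValueError("attribute ids must be positive and distinct")


DEFAULT_ATTRIBUTES = AttributeConfig()

_TAG_RE = re.compile(r"\(([^()]*)\)\s*$")


def semantic_tag(fsn: Optional[str]) -> str:
    """The semantic tag of an FSN: the text inside its final parentheses
    (e.g. "disorder", "situation"), or "unknown" when absent."""
    if not fsn:
        return "unknown"
    m = _TAG_RE.search(fsn)
    return m.group(1) if m else "unknown"


class ConceptGraph:
    """Active concepts with is-a and attribute edges.

    Not constructed directly; use :func:`build_graph`.
    """

    def __init__(
        self,
        isa: nx.DiGraph,
        attributes: nx.MultiDiGraph,
        config: AttributeConfig,
    ):
        self._isa = isa
        self._attr = attributes
        self.config = config

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> set[int]:
        return set(self._isa.nodes)

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self._isa

    def __len__(self) -> int:
        return self._isa.number_of_nodes()

    def fsn(self, concept_id: int) -> str:
        self._check_known([concept_id])
        return self._isa.nodes[concept_id]["fsn"]

    def tag(self, concept_id: int) -> str:
        self._check_known([concept_id])
        return self._isa.nodes[concept_id]["tag"]

    def _check_known(self, ids: Iterable[int]) -> None:
        unknown = [i for i in ids if i not in self._isa]
        if unknown:
            raise UnknownConceptError(
                f"concept id(s) not in graph: {sorted(unknown)[:5]}"
            )

    # -- hierarchy queries -------------------------------------------------

    def descendants_or_self(self, roots: Iterable[int]) -> set[int]:
        """roots plus all transitive is-a descendants. Idempotent and
        monotone in roots."""
        roots = set(roots)
        self._check_known(roots)
        out = set(roots)
        for r in roots:
            # edges run child -> parent, so descendants are graph ancestors
            out |= nx.ancestors(self._isa, r)
        return out

    def parents(self, ids: Iterable[int]) -> set[int]:
        """Union of direct (one-step) is-a parents of ids, excluding the
        inputs themselves unless a parent is also an input."""
        ids = set(ids)
        self._check_known(ids)
        out: set[int] = set()
        for i in ids:
            out.update(self._isa.successors(i))
        return out - (ids - out)

    def children(self, concept_id: int) -> set[int]:
        self._check_known([concept_id])
        return set(self._isa.predecessors(concept_id))

    # -- attribute queries -------------------------------------------------

    def attribute_sources(
        self,
        targets: Iterable[int],
        type_id: int,
        context_filters: Optional[Mapping[int, Iterable[int]]] = None,
        reverse: bool = False,
    ) -> set[int]:
        """Concepts with an attribute edge of ``type_id`` into ``targets``.

        With ``context_filters`` (mapping of attribute type id to allowed
        destination value ids), a source qualifies only if for *every*
        filter attribute it has at least one edge of that type into the
        allowed set (OR within a set, AND across attributes). Relationship
        groups are ignored (flat matching). A target is returned only if
        it independently qualifies as a source.

        ``reverse=True`` follows edges in the opposite direction: concepts
        that members of ``targets`` point to with ``type_id``.
        """
        targets = set(targets)
        self._check_known(targets)
        if not targets:
            return set()
        found: set[int] = set()
        if reverse:
            for t in targets:
                if t not in self._attr:
                    continue
                for _, dest, data in self._attr.out_edges(t, data=True):
                    if data["type_id"] == type_id:
                        found.add(dest)
        else:
            for t in targets:
                if t not in self._attr:
                    continue
                for src, _, data in self._attr.in_edges(t, data=True):
                    if data["type_id"] == type_id:
                        found.add(src)
        if context_filters:
            found = {
                s for s in found
                if all(
                    self._has_edge_into(s, ftype, set(allowed))
                    for ftype, allowed in context_filters.items()
                )
            }
        # a member of targets appears only if it independently qualifies,
        # i.e. it was added above via its own qualifying edge
        return found

    def _has_edge_into(self, source: int, type_id: int, allowed: set[int]) -> bool:
        if source not in self._attr:
            return False
        return any(
            data["type_id"] == type_id and dest in allowed
            for _, dest, data in self._attr.out_edges(source, data=True)
        )

    # -- set minimization --------------------------------------------------

    def simplify_by_subsumption(self, ids: Iterable[int]) -> set[int]:
        """The minimal subset M of ids whose hierarchies cover ids.

        A member of ids is dropped exactly when it is a proper descendant
        of another member; the survivors are the subsumption-maximal
        elements, so descendants_or_self(M) covers all of ids and no member
        of M subsumes another.
        """
        ids = set(ids)
        self._check_known(ids)
        covered: set[int] = set()
        for j in ids:
            covered |= (self.descendants_or_self({j}) - {j}) & ids
        return ids - covered

    # -- export ------------------------------------------------------------

    def export_edges(self, path) -> None:
        """Debug export: one TSV row per edge (source, target, kind, type_id)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source_id\ttarget_id\tkind\ttype_id\n")
            for child, parent in sorted(self._isa.edges):
                fh.write(f"{child}\t{parent}\tis-a\t{self.config.isa_type_id}\n")
            for src, dest, data in sorted(
                self._attr.edges(data=True), key=lambda e: (e[0], e[1], e[2]["type_id"])
            ):
                fh.write(f"{src}\t{dest}\tattribute\t{data['type_id']}\n")


def build_graph(
    release: Release, config: AttributeConfig = DEFAULT_ATTRIBUTES
) -> ConceptGraph:
    """Build a ConceptGraph from the active rows of a release.

    Only active concepts become nodes and only active relationships whose
    endpoints are both active become edges; skipped relationship rows are
    counted and logged. An is-a cycle raises an IntegrityError listing one
    cycle.
    """
    active_ids = release.active_concept_ids

    isa = nx.DiGraph()
    d = release.descriptions
    fsn_rows = d[d["active"] & (d["typeId"] == FSN_TYPE_ID)]
    fsn_by_id = dict(zip(fsn_rows["conceptId"], fsn_rows["term"]))
    for cid in active_ids:
        fsn = fsn_by_id.get(cid)
        isa.add_node(cid, fsn=fsn or "", tag=semantic_tag(fsn))

    attr = nx.MultiDiGraph()
    rel = release.relationships
    active_rel = rel[rel["active"]]
    skipped = 0
    for row in active_rel.itertuples(index=False):
        src, dest = row.sourceId, row.destinationId
        if src not in active_ids or dest not in active_ids:
            skipped += 1
            continue
        if row.typeId == config.isa_type_id:
            if src == dest:
                raise IntegrityError(f"is-a self-loop on concept {src}")
            isa.add_edge(src, dest)
        else:
            attr.add_edge(
                src, dest, type_id=row.typeId, group=row.relationshipGroup
            )
    if skipped:
        logger.info(
            "skipped %d active relationship rows with inactive endpoints",
            skipped,
        )

    if not nx.is_directed_acyclic_graph(isa):
        cycle = nx.find_cycle(isa)
        raise IntegrityError(
            "is-a hierarchy contains a cycle: "
            + " -> ".join(str(a) for a, _ in cycle)
            + f" -> {cycle[-1][1]}"
        )
    return ConceptGraph(isa, attr, config)


def search_descriptions(
    release: Release,
    patterns: list[str],
    case_sensitive: bool = False,
    regex: bool = False,
) -> set[int]:
    """Active concepts with at least one active description matching any
    pattern.

    Matching is plain substring by default (case-insensitive), over *all*
    descriptions — synonyms as well as FSNs — so a concept is found even
    when only a synonym contains the keyword. ``regex=True`` switches to
    regular-expression search.
    """
    patterns = [p for p in patterns if p]
    if not patterns:
        raise ValueError("at least one non-empty search pattern is required")
    d = release.descriptions
    cand = d[d["active"]]
    terms = cand["term"].astype(str)
    if regex:
        flags = 0 if case_sensitive else re.IGNORECASE
        mask = terms.str.contains(patterns[0], flags=flags, regex=True)
        for p in patterns[1:]:
            mask |= terms.str.contains(p, flags=flags, regex=True)
    else:
        mask = terms.str.contains(
            re.escape(patterns[0]), case=case_sensitive, regex=True
        )
        for p in patterns[1:]:
            mask |= terms.str.contains(re.escape(p), case=case_sensitive, regex=True)
    hits = set(cand.loc[mask, "conceptId"])
    return hits & release.active_concept_ids
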