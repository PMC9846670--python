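"""Licence-free synthetic terminology releases, mappings and patient data.

SNOMED CT itself cannot be redistributed, so every algorithm in this
toolkit is exercised on synthetic releases with the structural properties
the algorithms assume: a rooted is-a DAG, FSNs with semantic tags,
attribute relationships with context values, a history table for inactive
concepts, Read-to-SNOMED mappings and simulated patient event data.

:func:`generate_table1_fixture` builds the canonical worked example — a
bronchiectasis Read V2 codelist of six codes mapping to five disorder
concepts, embedded in a hierarchy whose candidate scores round to the
published two-decimal values: the bronchiectasis hierarchy has 6 members
(five mapped plus Kartagener syndrome, so precision 5/6 = 0.83), the
"sequelae of tuberculosis" parent has 6 members with one mapped, the
"disorder of bronchus" parent has 100 members containing all five, and
the "post-infectious disorder" parent has 120 members containing two.
Filler concepts carry synthetic FSNs and ids from 10^6 upward so they can
never collide with the real SCTIDs of the named concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd

from .graph import DEFAULT_ATTRIBUTES, build_graph
from .rf2 import (
    CONCEPT_COLUMNS,
    DESCRIPTION_COLUMNS,
    FSN_TYPE_ID,
    RELATIONSHIP_COLUMNS,
    SYNONYM_TYPE_ID,
    HistoryRow,
    MappingRow,
    Release,
)

_EFFECTIVE_TIME = "20200801"
_PRIMITIVE = 900000000000074008  # definition status: primitive

#: id of the suspected qualifier value (used as a finding-context value
#: that the confirmed/known-present filter must reject)
SUSPECTED_VALUE_ID = 415684004

_METADATA_FSNS = {
    DEFAULT_ATTRIBUTES.isa_type_id: "Is a (attribute)",
    DEFAULT_ATTRIBUTES.due_to_type_id: "Due to (attribute)",
    DEFAULT_ATTRIBUTES.associated_with_type_id: "Associated with (attribute)",
    DEFAULT_ATTRIBUTES.associated_finding_type_id: "Associated finding (attribute)",
    DEFAULT_ATTRIBUTES.finding_context_type_id: "Finding context (attribute)",
    DEFAULT_ATTRIBUTES.subject_relationship_context_type_id:
        "Subject relationship context (attribute)",
    DEFAULT_ATTRIBUTES.has_focus_type_id: "Has focus (attribute)",
    DEFAULT_ATTRIBUTES.known_present_value_id: "Known present (qualifier value)",
    DEFAULT_ATTRIBUTES.confirmed_present_value_id:
        "Confirmed present (qualifier value)",
    DEFAULT_ATTRIBUTES.subject_of_record_value_id: "Subject of record (person)",
    SUSPECTED_VALUE_ID: "Suspected (qualifier value)",
}

# the named concepts of the worked example
BRONCHIECTASIS = 12295008
TUBERCULOUS = 23022004
CONGENITAL = 77593006
RECURRENT = 195984007
POST_INFECTIVE = 195985008
KARTAGENER = 42402006
SEQUELAE_TB = 187251001
DISORDER_OF_BRONCHUS = 41427001
POST_INFECTIOUS = 123976001

HISTORY_SITUATION = 1500001
SUSPECTED_SITUATION = 1500002
LEGACY_INACTIVE = 1600001

#: the five distinct concepts the six Read codes map to
TABLE1_MAPPED = frozenset(
    {BRONCHIECTASIS, TUBERCULOUS, CONGENITAL, RECURRENT, POST_INFECTIVE}
)

TABLE1_READ_CODELIST = [
    ("H34.00", "Bronchiectasis"),
    ("H34z.00", "Bronchiectasis NOS"),
    ("A115.00", "Tuberculous bronchiectasis"),
    ("P861.00", "Congenital bronchiectasis"),
    ("H340.00", "Recurrent bronchiectasis"),
    ("H341.00", "Postinfective bronchiectasis"),
]


class _ReleaseBuilder:
    """Accumulates rows and assembles a Release with valid snapshot ids."""

    def __init__(self) -> None:
        self.concepts: list[dict] = []
        self.descriptions: list[dict] = []
        self.relationships: list[dict] = []
        self._next_desc = 20_000_001
        self._next_rel = 30_000_001

    def concept(self, cid: int, fsn: str, active: bool = True) -> None:
        self.concepts.append(
            {
                "id": cid,
                "effectiveTime": _EFFECTIVE_TIME,
                "active": int(active),
                "definitionStatusId": _PRIMITIVE,
            }
        )
        self.description(cid, fsn, FSN_TYPE_ID)

    def description(self, cid: int, term: str, type_id: int = SYNONYM_TYPE_ID) -> None:
        self.descriptions.append(
            {
                "id": self._next_desc,
                "effectiveTime": _EFFECTIVE_TIME,
                "active": 1,
                "conceptId": cid,
                "languageCode": "en",
                "typeId": type_id,
                "term": term,
            }
        )
        self._next_desc += 1

    def relationship(
        self, source: int, destination: int, type_id: int, group: int = 0
    ) -> None:
        self.relationships.append(
            {
                "id": self._next_rel,
                "effectiveTime": _EFFECTIVE_TIME,
                "active": 1,
                "sourceId": source,
                "destinationId": destination,
                "relationshipGroup": group,
                "typeId": type_id,
            }
        )
        self._next_rel += 1

    def isa(self, child: int, parent: int) -> None:
        self.relationship(child, parent, DEFAULT_ATTRIBUTES.isa_type_id)

    def metadata_concepts(self) -> None:
        for cid, fsn in _METADATA_FSNS.items():
            self.concept(cid, fsn)

    def build(self) -> Release:
        concepts = pd.DataFrame(self.concepts, columns=list(CONCEPT_COLUMNS))
        descriptions = pd.DataFrame(self.descriptions, columns=list(DESCRIPTION_COLUMNS))
        relationships = pd.DataFrame(
            self.relationships, columns=list(RELATIONSHIP_COLUMNS)
        )
        for df in (concepts, descriptions, relationships):
            df["active"] = df["active"].astype(bool)
        return Release(concepts, descriptions, relationships)


def generate_table1_fixture() -> tuple[
    Release, list[tuple[str, str]], list[MappingRow], list[HistoryRow]
]:
    """The canonical bronchiectasis conversion fixture.

    Returns (release, read codelist, mappings, history rows). Fully
    deterministic: no randomness is involved. The release also carries the
    mappings and history so it can be written to disk as one bundle.
    """
    b = _ReleaseBuilder()
    b.metadata_concepts()

    b.concept(BRONCHIECTASIS, "Bronchiectasis (disorder)")
    b.concept(TUBERCULOUS, "Tuberculous bronchiectasis (disorder)")
    b.concept(CONGENITAL, "Congenital bronchiectasis (disorder)")
    b.concept(RECURRENT, "Recurrent bronchiectasis (disorder)")
    b.concept(POST_INFECTIVE, "Post-infective bronchiectasis (disorder)")
    b.concept(KARTAGENER, "Kartagener syndrome (disorder)")
    # synonym-only keyword match: the FSN lacks "bronchiect"
    b.description(KARTAGENER, "Bronchiectasis with situs inversus")
    b.concept(SEQUELAE_TB, "Sequelae of tuberculosis (disorder)")
    b.concept(DISORDER_OF_BRONCHUS, "Disorder of bronchus (disorder)")
    b.concept(POST_INFECTIOUS, "Post-infectious disorder (disorder)")

    # the 6-member bronchiectasis hierarchy
    for child in (TUBERCULOUS, CONGENITAL, RECURRENT, POST_INFECTIVE, KARTAGENER):
        b.isa(child, BRONCHIECTASIS)
    b.isa(BRONCHIECTASIS, DISORDER_OF_BRONCHUS)
    b.isa(TUBERCULOUS, SEQUELAE_TB)
    b.isa(TUBERCULOUS, POST_INFECTIOUS)
    b.isa(POST_INFECTIVE, POST_INFECTIOUS)

    # fillers sized so each parent hierarchy rounds to the printed scores:
    # sequelae-of-tuberculosis 6 (1 mapped), disorder-of-bronchus 100 (all
    # 5 mapped), post-infectious 120 (2 mapped)
    def fillers(parent: int, start: int, count: int, stem: str) -> None:
        for i in range(count):
            cid = start + i
            b.concept(cid, f"Synthetic {stem} {i + 1} (disorder)")
            b.isa(cid, parent)

    fillers(SEQUELAE_TB, 1_000_001, 4, "sequela disorder")
    fillers(DISORDER_OF_BRONCHUS, 1_001_001, 93, "bronchus disorder")
    fillers(POST_INFECTIOUS, 1_002_001, 117, "post-infectious disorder")

    # situation concepts: one qualifying (history of, known present,
    # subject of record) and one that the context filter must reject
    cfg = DEFAULT_ATTRIBUTES
    b.concept(HISTORY_SITUATION, "History of bronchiectasis (situation)")
    b.relationship(HISTORY_SITUATION, BRONCHIECTASIS, cfg.associated_finding_type_id)
    b.relationship(
        HISTORY_SITUATION, cfg.known_present_value_id, cfg.finding_context_type_id
    )
    b.relationship(
        HISTORY_SITUATION,
        cfg.subject_of_record_value_id,
        cfg.subject_relationship_context_type_id,
    )
    b.concept(SUSPECTED_SITUATION, "Suspected bronchiectasis (situation)")
    b.relationship(SUSPECTED_SITUATION, BRONCHIECTASIS, cfg.associated_finding_type_id)
    b.relationship(
        SUSPECTED_SITUATION, SUSPECTED_VALUE_ID, cfg.finding_context_type_id
    )
    b.relationship(
        SUSPECTED_SITUATION,
        cfg.subject_of_record_value_id,
        cfg.subject_relationship_context_type_id,
    )

    # an inactive legacy concept reachable only through the history table
    b.concept(LEGACY_INACTIVE, "Bronchiectasis NOS (disorder)", active=False)
    history = [HistoryRow(LEGACY_INACTIVE, BRONCHIECTASIS, 0)]

    mappings = [
        MappingRow("H34.00", BRONCHIECTASIS, "m100001"),
        MappingRow("H34z.00", BRONCHIECTASIS, "m100002"),
        MappingRow("A115.00", TUBERCULOUS, "m100003"),
        MappingRow("P861.00", CONGENITAL, "m100004"),
        MappingRow("H340.00", RECURRENT, "m100005"),
        MappingRow("H341.00", POST_INFECTIVE, "m100006"),
    ]

    release = b.build()
    release.history = history
    release.mappings = mappings
    return release, list(TABLE1_READ_CODELIST), mappings, history


_TAGS = ("disorder", "finding", "situation", "procedure", "regime/therapy")


@dataclass
class FixtureSpec:
    """Parameters for random synthetic releases and patient populations.

    The patient-population defaults emulate the structure of a UK
    primary-care research sample: an adult-skewed birth-year range,
    registration intervals inside a 2000-2018 window, a six-year study
    window, sex balanced, and chronic-disease prevalences of a few
    percent. A fixed seed makes every output byte-identical.
    """

    n_concepts: int = 50
    max_children: int = 8
    n_attribute_edges: int = 0
    n_situations: int = 0
    n_inactive_history: int = 0
    seed: int = 0
    prevalence_by_concept: dict[int, float] = dc_field(default_factory=dict)
    n_patients: int = 1000
    birth_year_range: tuple[int, int] = (1930, 2004)
    reg_window: tuple[str, str] = ("2000-01-01", "2018-12-31")

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if any(not 0 <= p <= 1 for p in self.prevalence_by_concept.values()):
            raise ValueError("prevalences must be in [0, 1]")


#: first concept id used for randomly generated concepts
RANDOM_ID_BASE = 1_100_001


def generate_random_ontology(spec: FixtureSpec) -> Release:
    """A random rooted is-a DAG with attribute edges and situations.

    Concept 0 is the root; each later concept receives 1-2 parents drawn
    from earlier concepts (acyclic by construction, polyhierarchy
    whenever 2 parents are drawn), with a soft cap of ``max_children``
    children per parent. Semantic tags are drawn per concept; situation
    concepts get the Associated finding / Finding context / Subject
    relationship context attribute pattern with a random context value.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    b = _ReleaseBuilder()
    b.metadata_concepts()
    cfg = DEFAULT_ATTRIBUTES

    ids = [RANDOM_ID_BASE + i for i in range(spec.n_concepts)]
    n_children = {cid: 0 for cid in ids}
    tags = [
        "disorder" if i == 0 else _TAGS[rng.integers(0, len(_TAGS))]
        for i in range(spec.n_concepts)
    ]
    for i, cid in enumerate(ids):
        tag = tags[i]
        b.concept(cid, f"Synthetic {tag} {i} ({tag})")
        if i == 0:
            continue
        k = min(int(rng.integers(1, 3)), i)
        pool = ids[:i]
        chosen: set[int] = set()
        for _ in range(k):
            for _attempt in range(4):  # soft max_children cap
                p = pool[int(rng.integers(0, len(pool)))]
                if p not in chosen and n_children[p] < spec.max_children:
                    break
            else:
                p = pool[int(rng.integers(0, len(pool)))]
            if p in chosen:
                continue
            chosen.add(p)
            n_children[p] += 1
            b.isa(cid, p)

    for _ in range(spec.n_attribute_edges):
        type_id = (
            cfg.due_to_type_id
            if rng.random() < 0.5
            else cfg.associated_with_type_id
        )
        src, dest = rng.choice(len(ids), size=2, replace=False)
        b.relationship(ids[int(src)], ids[int(dest)], type_id)

    context_values = [
        cfg.known_present_value_id,
        cfg.confirmed_present_value_id,
        SUSPECTED_VALUE_ID,
    ]
    sit_base = RANDOM_ID_BASE + spec.n_concepts
    for j in range(spec.n_situations):
        sid = sit_base + j
        b.concept(sid, f"Synthetic situation {j} (situation)")
        target = ids[int(rng.integers(0, len(ids)))]
        b.relationship(sid, target, cfg.associated_finding_type_id)
        b.relationship(
            sid,
            context_values[int(rng.integers(0, len(context_values)))],
            cfg.finding_context_type_id,
        )
        b.relationship(
            sid, cfg.subject_of_record_value_id,
            cfg.subject_relationship_context_type_id,
        )

    history: list[HistoryRow] = []
    legacy_base = sit_base + spec.n_situations
    for j in range(spec.n_inactive_history):
        lid = legacy_base + j
        b.concept(lid, f"Synthetic legacy concept {j} (disorder)", active=False)
        history.append(
            HistoryRow(
                lid,
                ids[int(rng.integers(0, len(ids)))],
                int(rng.integers(0, 4)),
            )
        )

    release = b.build()
    release.history = history
    return release


def generate_patients(
    release: Release, spec: FixtureSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a patient population and coded events for a release.

    Demographics: sex Bernoulli(0.5), birth years uniform over the spec
    range, registration intervals of 1-15 years placed uniformly inside
    the registration window. Events: for each (concept, prevalence) pair
    each patient independently develops the condition with that
    probability, receiving 1-3 events whose concepts are drawn uniformly
    from the concept's descendants-or-self and dated uniformly within the
    patient's registration interval. Event codes are concept ids (use a
    mapping dictionary for local-code workflows). Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    graph = build_graph(release)
    n = spec.n_patients
    patient_ids = np.arange(1, n + 1)

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    birth_year = rng.integers(
        spec.birth_year_range[0], spec.birth_year_range[1] + 1, size=n
    )
    win_start = pd.Timestamp(spec.reg_window[0])
    win_end = pd.Timestamp(spec.reg_window[1])
    win_days = (win_end - win_start).days
    start_offset = rng.integers(0, max(win_days - 365, 1), size=n)
    length_days = rng.integers(365, 15 * 365 + 1, size=n)
    reg_start = pd.Series(win_start + pd.to_timedelta(start_offset, unit="D"))
    reg_end = (reg_start + pd.to_timedelta(length_days, unit="D")).clip(
        upper=win_end
    )
    demographics = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": sex,
            "birth_year": birth_year,
            "reg_start": pd.Series(reg_start).dt.strftime("%Y-%m-%d"),
            "reg_end": pd.Series(reg_end).dt.strftime("%Y-%m-%d"),
        }
    )

    rows: list[dict] = []
    for concept in sorted(spec.prevalence_by_concept):
        prevalence = spec.prevalence_by_concept[concept]
        hierarchy = sorted(graph.descendants_or_self({concept}))
        has = rng.random(n) < prevalence
        for idx in np.flatnonzero(has):
            n_events = int(rng.integers(1, 4))
            span = max((reg_end[idx] - reg_start[idx]).days, 1)
            for _ in range(n_events):
                cid = hierarchy[int(rng.integers(0, len(hierarchy)))]
                day = int(rng.integers(0, span))
                rows.append(
                    {
                        "patient_id": int(patient_ids[idx]),
                        "code": str(cid),
                        "event_date": (
                            reg_start[idx] + pd.Timedelta(days=day)
                        ).strftime("%Y-%m-%d"),
                    }
                )
    events = pd.DataFrame(rows, columns=["patient_id", "code", "event_date"])
    return events, demographics
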