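# Methods

This note documents the algorithms `phenokit` implements, the choices
made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Terminology model

A SNOMED CT snapshot release is three tab-delimited tables: concepts,
descriptions (FSNs and synonyms; a concept's semantic tag is the text in
the final parentheses of its FSN), and relationships. Loading is strict:
duplicate component ids, dangling references and missing FSNs on active
concepts are errors, and inactive rows are retained but flagged, because
historic EHR data may reference them. Identifiers are 64-bit integers and
are always serialized as plain digit strings (SCTIDs exceed 32 bits).

The concept graph keeps only active concepts and active relationships
between them. Is-a edges are stored child → parent and must form a DAG; a
cycle aborts graph construction with the offending cycle listed.
"Descendants of X" always includes X itself — a leaf candidate's own
membership counts toward its recall, which is what makes a single mapped
leaf score recall 1/|M| rather than 0. "Parents" means direct (one-step)
parents; full ancestor enumeration is deliberately not used for candidate
generation (see below).

Attribute queries match flat edges: relationship groups are ignored, an
allowed-value set is a disjunction, and multiple context filters conjoin.
The situation filter used throughout (personal-history and confirmed
concepts) is: *Associated finding* into the codelist hierarchy AND
*Finding context* ∈ {Confirmed present, Known present} AND *Subject
relationship context* = Subject of record. This admits "History of X"
and "X confirmed" while rejecting "Suspected X". For *Due to* and
*Associated with* the traversal direction is **into** the hierarchy
(concepts whose attribute points at an included concept); the reverse
direction exists behind a flag, since for some modelling patterns the
edge runs the other way.

The attribute/value concept ids are configurable (`AttributeConfig`);
defaults are the standard metadata SCTIDs, and fixtures use the same ids
so tests exercise the production configuration.

## Codelist methods

* **primary** — descendants-or-self of the seed concepts minus
  descendants-or-self of the exclusion concepts. The difference is taken
  *after* full expansion, so an excluded subtree nested anywhere under an
  included concept is removed (the gestational-diabetes pattern). Removed
  concepts are recorded as explicit exclude entries for auditability.
* **extended** — the primary set plus the three attribute routes above.
  Each added entry is tagged `attribute:<route>`; when a concept
  qualifies via several routes the first of (due-to, associated-with,
  associated-finding) wins, purely for deterministic provenance.
  Extended ⊇ primary by construction.
* **value set** — substring search (case-insensitive by default; regex
  opt-in) over *all* active descriptions, so synonym-only matches are
  found; the hit set is closed under descendants, minimized by
  subsumption into the list a human reviews, and then filtered by
  recorded `ReviewDecision` rows. Decisions cascade to candidate
  descendants; a decision on the concept itself overrides an inherited
  one, and an inherited exclude beats an inherited include. Undecided
  candidates are flagged and *not* silently included. Review is
  file-driven rather than interactive: reproducibility over convenience.
  Closure runs before review and decisions are final; closure is not
  re-applied afterwards.

Inactive-concept expansion runs last: a history (query-table) row adds
its legacy concept when its active supertype is already included and its
provenance level (0 = subsumption always true … 3 = the original concept
had at least two distinct meanings) does not exceed `max_provenance`.
The default is 3 — include everything — because historic data may use any
of them; the threshold exists precisely because level-3 links are
ambiguous. The operation never removes entries and is idempotent. Where
both a query table and a history-substitution table exist, they are
merged by the caller into one table; the toolkit imposes no precedence.

Definitions serialize to a restricted expression-constraint dialect:
`<<` (descendants-or-self), bare ids, `OR`, `MINUS`, parentheses — enough
to express everything this toolkit creates. Attribute-added concepts in
extended codelists are not hierarchy members, so they are enumerated as
bare ids; this keeps `parse(serialize(c))` exactly equal to the active
inclusion set. History-added inactive entries are intentionally outside
the round trip (they are not resolvable on the active graph).

## Read V2 conversion

Pipeline: map codes → enumerate candidates (mapped ∪ direct parents ∪
descendants, with origin priority mapped > parent > descendant) → score
each candidate hierarchy by concept-level precision/recall/F1 against the
mapped set → rank by descending F1 → select. Concept-level (not
code-level, not patient-level) counting is the point: the denominator of
recall is the number of *distinct mapped concepts*, so two Read codes
mapping to one concept count once.

Numerical conventions: F1 = 0 when precision + recall = 0; unrounded
scores are retained and only the report rounds, half-up to 2 decimals
with trailing zeros trimmed ("0.1", "1"). Ties in F1 break by higher
precision, then smaller hierarchy, then lower concept id — an invented
but deterministic order; in practice tied candidates go to human review.
The `f1_floor` defaults to 0 (always select, always emit the report),
because accepting a candidate is ultimately a clinical judgement; with a
positive floor, phenotypes whose best candidate falls short are flagged
as not representable by a single hierarchy and the mapped set itself is
emitted ("read-derived"). Phenotypes that are collections of unrelated
diseases or defined by exclusion are out of scope for automatic
selection — they surface as low-F1 reports for manual definition.

The final codelist adds linked personal-history/confirmed situation
concepts (the filter above) and inactive concepts. For incident-disease
definitions, which must not contain personal-history concepts, the
situation step is disabled by a flag (`--no-history`).

## Cohort evaluation

A first-event cohort is every eligible patient with ≥ 1 event whose
concept is in the codelist's inclusion set, carrying the earliest such
date (no date filter on the event itself — the intended use is prevalent/
historic disease). Eligibility: age strictly over `min_age_years`
(default 18) at the registration midpoint, and at least
`min_followup_years` (default 1) between max(reg_start, study_start) and
min(reg_end, study_end). Birth dates are year-only (privacy), so age is
measured from the birth-year midpoint (July 2) in units of 365.25 days.
Events with codes the dictionary cannot resolve are counted and logged,
never fatal.

Cohorts are compared by membership (patient id only, not event-date
agreement). Interval/test methods are not dictated by the report format,
so standard epidemiological defaults are used and declared in the output
metadata: Wilson score intervals for precision and recall; F1 as a point
estimate only; Wald interval and two-sided pooled z test for the
difference in proportion female; Welch interval and t test for the
difference in mean age. Differences are oriented gold − test. Degenerate
inputs (empty cohorts, constant samples) yield zero metrics with
degenerate intervals and a warning, or p = 1 for identical cohorts,
rather than errors.

## Synthetic generators

The worked-example fixture encodes the bronchiectasis conversion: six
Read codes, five mapped concepts, and three parent hierarchies whose
sizes (6, 100, 120) are chosen so every candidate score reproduces the
published 2-decimal values — raw hierarchy sizes are not published, and
120 is the one size at which the post-infectious parent's precision
prints 0.02 *and* its F1 prints 0.03. Filler ids start at 10^6 so they
cannot collide with the real SCTIDs of the named concepts. The fixture
also carries one qualifying history situation, one suspected situation
(to exercise the context filter), and one inactive legacy concept at
provenance 0.

Random ontologies are rooted DAGs: each non-root concept draws 1–2
parents among earlier concepts (acyclic by construction), with a soft cap
on children per parent; semantic tags are drawn from the five common
ones; optional attribute edges, situation concepts and history rows give
the extended/value-set/expansion code something to find.

The patient simulator emulates the *structure* of a primary-care research
sample — balanced sex, uniform birth years 1930–2004, registration
intervals of 1–15 years inside 2000–2018, a 2013–2018 six-year study
window with adult-age and one-year-follow-up eligibility (matching common
practice), and per-concept disease prevalences set at a few percent, with
1–3 events per affected patient drawn uniformly from the concept's
hierarchy. It does **not** emulate multimorbidity correlation, calendar
trends in coding, miscoding, or differential code granularity by age and
sex — so passing tests demonstrate algorithmic correctness and the
qualitative precision/recall trade-offs of broader vs narrower
codelists, not empirical performance on real EHR data, which requires
licensed sources. Test and acceptance runs use populations of 2 000–
10 000 patients and ontologies of 10–60 concepts, sizes at which the
binomial checks are already tight.

## Known limitations

* Snapshot releases only; full/delta history processing, OWL axiom
  refsets and language-refset acceptability are out of scope.
* The expression dialect has no refinements or attribute constraints; it
  covers exactly what the builder emits.
* Description-logic classification and post-coordinated subsumption are
  not implemented; subsumption is the stated is-a graph.
* Automatic selection never proposes multi-concept unions; such
  phenotypes are flagged for manual definition.
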