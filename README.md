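# phenokit

Phenotype codelists — the lists of clinical terminology codes that define
"has diabetes", "has heart failure", … in electronic health record (EHR)
research — have historically been curated by hand as flat lists of UK Read
V2 codes. SNOMED CT, the terminology now used across UK primary care,
carries an ontology (is-a hierarchies plus attribute relationships) that
makes codelists definable *intensionally*: a handful of concepts plus
rules, instead of hundreds of enumerated codes.

`phenokit` is a toolkit for researchers and health-data engineers that:

* builds SNOMED CT disease codelists by three reproducible methods —
  **primary** (a seed disorder concept and its is-a descendants, minus
  excluded subtrees), **extended** (primary plus concepts linked into the
  hierarchy by *Due to* / *Associated with*, and confirmed/history
  *situation* concepts linked by *Associated finding*), and **value set**
  (keyword search over all term descriptions, minimized by subsumption for
  human review, filtered by recorded decisions);
* converts legacy Read V2 codelists to parsimonious SNOMED CT definitions
  by scoring candidate concept hierarchies against the mapped codes and
  ranking them by F1;
* expands codelists with inactive legacy concepts via a query/history
  table, serializes definitions as expression constraints
  (`<< 12295008 MINUS << 42402006`), and evaluates codelists against
  patient event data as first-event cohorts;
* ships synthetic release generators, so everything is testable without a
  SNOMED CT licence or access to patient data.

## The core statistic

To convert a Read codelist, its codes are mapped to a set *M* of SNOMED CT
concepts. Every mapped concept, direct parent of a mapped concept, and
descendant of a mapped concept is a *candidate* c whose hierarchy
H(c) = descendants-or-self(c) could stand for the whole codelist, scored
at the concept level:

```
precision(c) = |H(c) ∩ M| / |H(c)|
recall(c)    = |H(c) ∩ M| / |M|
F1(c)        = 2 · precision · recall / (precision + recall)
```

Candidates are ranked by descending F1 (ties: higher precision, smaller
hierarchy, lower id) and the full table is emitted for clinical review —
whether the winning concept really *means* the phenotype is a human
judgement the tool does not make.

## Worked example

The bundled synthetic release reproduces the classic bronchiectasis
conversion: six Read codes mapping to five disorder concepts.

```python
from phenokit import build_graph, convert_codelist, generate_table1_fixture

release, read_codes, mappings, history = generate_table1_fixture()
graph = build_graph(release)
report = convert_codelist(read_codes, mappings, graph, history)
print(report.to_frame(graph).to_string(index=False))
```

```
 concept_id                                      fsn     origin precision recall   f1  selected
   12295008                Bronchiectasis (disorder)     mapped      0.83      1 0.91      True
   23022004    Tuberculous bronchiectasis (disorder)     mapped         1    0.2 0.33     False
   77593006     Congenital bronchiectasis (disorder)     mapped         1    0.2 0.33     False
  195984007      Recurrent bronchiectasis (disorder)     mapped         1    0.2 0.33     False
  195985008 Post-infective bronchiectasis (disorder)     mapped         1    0.2 0.33     False
  187251001      Sequelae of tuberculosis (disorder)     parent      0.17    0.2 0.18     False
   41427001          Disorder of bronchus (disorder)     parent      0.05      1  0.1     False
  123976001      Post-infectious disorder (disorder)     parent      0.02    0.4 0.03     False
  42402006            Kartagener syndrome (disorder) descendant         0      0    0     False
```

The bronchiectasis hierarchy contains all five mapped concepts plus
Kartagener syndrome (a bronchiectasis subtype absent from the Read list),
so its precision is 5/6 = 0.83 rather than 1, with recall 1 and the
highest F1 (0.91) of the nine candidates — it is selected automatically.
The final codelist is its six-concept hierarchy plus the linked "History
of bronchiectasis" situation concept and one inactive legacy concept from
the history table.

The same workflow is available from a shell:

```bash
phenokit simulate --preset table1 --out fixture/
phenokit convert --read-codelist fixture/read_codelist.csv \
    --mapping fixture/mapping.tsv --release fixture/ \
    --out-report report.csv --out-codelist bronchiectasis.csv
```

See also `phenokit build` (primary/extended/value-set construction) and
`phenokit evaluate` (patient-level precision/recall/F1 and demographic
comparison of two codelists on an event table).

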