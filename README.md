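# lpstage

A staging database for longitudinal population-study mental-health survey
data: a snowflake-schema relational store that captures a study's entire
execution — vocabulary, metadata, population, and observations — as the
intermediate step between raw field exports and a common data model such as
OMOP CDM.

## Who this is for

Data engineers and epidemiologists harmonizing multi-wave household surveys
from health and demographic surveillance sites (HDSS). Such studies
administer standardized screening scales (PHQ-9 for depression, GAD-7 for
anxiety, BASIS-24 for psychosis symptoms, and others) repeatedly to a
population in which individuals join households, migrate between them, and
drop out of follow-up. The raw exports are wide CSV tables — one row per
respondent per wave, one column per item — with missing cells and missing
interview dates. Before such data can reach analysis workbenches it needs a
fully constrained relational home that preserves the longitudinal structure.

## The model

The store is a snowflake schema of 16 tables around a central fact table,
`LONGITUDINAL_POPULATION_STUDY_FACT`, whose grain is **one item response in
one interview**. Each fact carries foreign keys to the individual, the
interview, the resident episode active at the interview date, the population
study, the instrument item, and the concepts typing its question and value.
The dimensions fall into four groups:

- **Concept vocabulary** (`VOCABULARY`, `CONCEPT`, `INSTRUMENT`,
  `INSTRUMENT_ITEM`) — an OMOP-layout concept store. Terms with no standard
  equivalent are *minted* as local concepts under the `INSPIRE` vocabulary
  with ids allocated sequentially from 2,000,000,000 (the OHDSI convention
  for site-local concepts). Minting is stable: a code always maps to the id
  it received at first mint.
- **Study metadata** (`POPULATION_STUDY`, `METHODOLOGY`, `WAVE`,
  `DATA_CAPTURE_EVENT`) — a DDI-Lifecycle-aligned description of the study:
  waves with date ranges and a controlled `instrument_model_type`, capture
  events contained in their wave.
- **Population** (`LOCATION`, `HOUSEHOLD`, `HOUSEHOLD_CHARACTERISTICS`,
  `INDIVIDUAL`, `INDIVIDUAL_DEMOGRAPHICS`, `RESIDENT_EPISODE`, `INTERVIEW`)
  — individuals and GPS-tagged households linked by *resident episodes*,
  half-open intervals `[start, end)` that never overlap per individual.
  Opening a new episode auto-closes the previous one (out-migration).
  Interviews with no recorded date are approximated at the wave midpoint,
  `start + floor(span/2)`, and flagged.
- **Facts** — loaded by a declarative wide-to-long ETL: a mapping spec binds
  source columns to registered items; ordinal responses are coded to both a
  numeric value and a value concept; failures become report rows, never
  exceptions, and the run report reconciles
  `facts + rejects + blanks = mapped cells`.

A synthetic-data generator produces whole study bundles with known ground
truth (latent-severity ordinal responses, migration, item and date
missingness), four read-only validators check referential, temporal,
value-domain, and normalization quality, and a bridge exporter emits
OMOP CDM v5.4-layout `PERSON`, `OBSERVATION_PERIOD`, `OBSERVATION`,
`MEASUREMENT`, and `CONCEPT` files.

## Worked example

```bash
lpstage init --db demo.db
lpstage load-vocab --db demo.db
lpstage register-instruments --db demo.db
lpstage simulate --out bundle --seed 42
lpstage ingest --db demo.db --config bundle/pipeline.yaml
lpstage validate --db demo.db
lpstage export-omop --db demo.db --out omop
```

prints (abridged):

```
16 tables created (28 indexes)
60 concepts loaded
Patient Health Questionnaire (PHQ-9): 9 items
Generalized Anxiety Disorder (GAD-7): 7 items
...
wrote 9 data files to bundle
HOUSEHOLD: 50 rows
INDIVIDUAL: 199 rows
INTERVIEW: 1083 rows
LONGITUDINAL_POPULATION_STUDY_FACT: 12907 rows
RESIDENT_EPISODE: 204 rows
rejects: 0, blank cells: 1533
0 violations
199 persons, 12907 observations, 0 measurements -> omop
```

Reading the numbers: the seed-42 demo bundle simulates 50 households
(199 individuals, 204 resident episodes — five people migrated between the
two waves). Across 2 waves × 3 instruments, 1,083 interviews produced 12,907
item-response facts; 1,533 cells were blank in the source (≈ 10.6 % observed
item missingness against the configured rate of 0.10) and were tallied, not
loaded. All four validators pass, and every fact exports to exactly one
OMOP observation row (all screening items are ordinal; numeric items would
route to `MEASUREMENT`). Re-running `ingest` on the same bundle adds zero
rows to every table.

The same workflow is available as a library — see `lpstage.schema_core`,
`vocabulary`, `study_metadata`, `population`, `etl`, `synthetic_data`,
`validation`, and `omop_bridge`; `docs/methods.md` documents the design.

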