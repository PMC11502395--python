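# Methods

This note documents the modelling and engineering choices behind `lpstage`:
the relational design, the coding rules of the ETL, the synthetic-data
generator and what it does and does not emulate, numerical and tie-break
conventions, and known limitations.

## The staging model

The store is a snowflake schema: a central fact table at the grain of one
item response in one interview, with normalized dimensions for vocabulary,
study metadata, and population. Sixteen tables are fixed by design; the
per-item allowed-value sets (response anchors with numeric codes and value
concepts) are kept as a JSON column on `INSTRUMENT_ITEM` rather than a
seventeenth table, trading a little normalization for a closed table
inventory. The value concepts themselves are ordinary `CONCEPT` rows, so no
coded information lives only in JSON.

Surrogate integer primary keys are allocated by the package
(`MAX(pk)+1` inside the write transaction) rather than by the database, so a
load replayed from the same inputs assigns identical keys — a prerequisite
for the byte-level determinism checks. Natural keys (external ids,
instrument names, `(vocabulary, code)` pairs, `(individual, wave,
instrument)` triples) are enforced with unique constraints, and every
upsert-style operation resolves on the natural key first, which makes every
ingest replayable with zero row growth.

Dates are ISO-8601 text, timezone-naive. Residence intervals are half-open
`[start, end)`: an episode ending on a date does not cover it, the episode
starting that date does, so a same-day move is unambiguous. Episode
bookkeeping is "auto-close on move": opening an episode closes any open one
at the new start with reason `out-migration`. A move backdated before the
open episode's start is an error rather than a silent reorder.

### Concept handling

Standard concepts load verbatim from an OMOP-`CONCEPT`-layout delimited
file (comma or tab, auto-detected; `YYYYMMDD` or `YYYY-MM-DD` dates).
Loading is an upsert on `concept_id`; an id reappearing with a different
name or vocabulary is an error, not a merge. Local concepts are minted under
the `INSPIRE` vocabulary from id 2,000,000,000 upward in first-mint order;
the id space therefore partitions concepts into standard (< 2 × 10⁹) and
local (≥ 2 × 10⁹), and this partition is a database `CHECK`.

The packaged concept file (`fixtures/omop_concept_subset_synthetic.csv`,
60 rows) is a synthetic stand-in for an OMOP vocabulary subset: gender
concepts, LOINC-style question codes for PHQ-9/GAD-7/EPDS/CES-D, the shared
frequency answer list, and a few SNOMED-style findings. Instruments whose
codes are absent from it (DASS-21, PCL-5, BASIS-24) exercise the
local-minting path, which is the point of shipping a subset.

### Instruments

Seven screening instruments are packaged with canonical public item counts:
PHQ-9 (9), GAD-7 (7), DASS-21 (21), EPDS (10), PCL-5 (20), CES-D (20),
BASIS-24 (24) — 111 items. Item prompts are generic placeholders because the
instruments' item texts are licensed separately; response anchors follow the
public scale definitions (e.g. the four-level "Not at all … Nearly every
day" frequency scale shared by PHQ-9 and GAD-7). Each ordinal anchor carries
*both* a numeric code and a value concept so downstream facts can be scored
numerically or analysed concept-wise without re-joining the source.

### Interview-date approximation

Longitudinal collections routinely lack interview dates for some records.
A missing date is set to the wave midpoint — `start + floor(days(start,
end)/2)` — and flagged `date_approximated`. The floor convention makes the
rule exact calendar arithmetic with no fractional days; for a wave
`[2023-01-01, 2023-03-31]` (89-day span) the midpoint is 2023-02-14. The
midpoint always lies inside the wave, so approximation never creates a
temporal violation.

## ETL coding rules

A mapping spec names the instrument, the respondent-id column, the wave, an
optional date column, and the column→item binding; validation enumerates
*every* problem in the spec rather than failing on the first. The melt
emits one long record per non-blank mapped cell in input-row-then-item
order; blank and whitespace-only cells are tallied, not loaded (unanswered
items are absent facts, not explicit missing facts). Value coding:

- ordinal/categorical: the raw string is translated through the per-item
  `value_map` if one is given, then matched against the allowed values by
  raw string or numeric code; ordinal matches populate both
  `value_as_number` and `value_as_concept_id`;
- numeric: parsed and range-checked;
- text: passed through.

Unmatched values follow the spec's `on_unmapped` policy: `reject` (a report
row with a reason), `mint` (a new local value concept appended to the item's
allowed set), or `null` (skipped and tallied). Facts deduplicate on
`(interview, item)`; the first load wins and replays insert nothing. Every
run report satisfies `facts + rejects + skipped + blanks = mapped cells`.

The pipeline runs stages in a fixed order — vocabulary, study metadata,
population rosters, facts — and a stage failure aborts later stages while
returning the partial report with the failed stage named.

## The synthetic-data generator

The generator defines the study conditions the test suite and the
acceptance script measure against. Defaults (the "demo conditions"):
50 households, mean household size 4, two three-month waves in 2023, the
PHQ-9/GAD-7/BASIS-24 instrument set, response rate 0.9, item missingness
0.10, per-wave migration probability 0.05, interview-date missingness 0.2,
seed 42.

- **Households and people.** Household sizes are `1 + Poisson(mean − 1)`
  (guaranteeing non-empty households with the configured mean); individuals
  get a sex (fair coin) and a birth year uniform on 1940–2005; GPS
  coordinates cluster in a ~0.2° box of named villages.
- **Migration.** In every wave after the first, each individual moves to a
  different, uniformly chosen household with probability *m*; the old
  episode closes at the wave start and the new one opens the same day, so
  per-wave migration counts are Binomial(n, m) — a property test checks the
  goodness of fit.
- **Responses.** Each individual carries a latent severity `z ~ N(0, 1)`.
  An ordinal item with K levels is scored `cut(z + σ·ε)`, ε ~ N(0, 1)
  independent per item, with thresholds at the normal quantiles of a
  geometrically decaying category distribution (ratio 0.6 — most
  respondents endorse low categories, as screening data do). Item noise
  σ = 1.0 was calibrated once by Monte-Carlo so that PHQ-9 and GAD-7 sum
  scores have a Spearman correlation comfortably above 0.3 (measured ≈ 0.8
  at the default conditions) and then frozen; it is not adjusted per run.
- **Missingness.** Interviews happen with probability `response_rate`
  per resident per wave; answered cells blank with probability
  `item_missingness`; interview dates draw uniformly in the wave and blank
  with probability `date_missingness`. All three rates are recoverable from
  the written bundle, and ground truth (latent severities, interview
  rosters, migration and blank-cell counts) is written alongside the data.
- **Randomness.** One numpy `Generator` per (entity-type, wave), seeded as
  `(seed, stream, wave)`; adding instruments or waves therefore never
  perturbs roster generation, and a fixed seed reproduces bundles
  byte-for-byte (hashes in the bundle manifest).

What the generator does **not** emulate: realistic symptom prevalence or
severity distributions (the latent model is a correlation structure, not an
epidemiological calibration), mortality and fertility, household splits and
merges, interviewer effects, or instrument-specific skip logic. Passing
tests therefore demonstrate that the pipeline is lossless, constraint-sound
and deterministic under realistic *structure* (migration, missingness,
multi-instrument waves), not that any clinical quantity is estimated
correctly.

## Validation

Four read-only checkers: referential integrity (delegated to SQLite's
`foreign_key_check`, enumerating every dangling key), temporal consistency
(interviews inside waves and inside a covering episode, pairwise episode
non-overlap, capture events inside waves), fact values (a populated value
slot; ordinal/numeric values inside the item's domain; value-type concept
consistent with the populated slots — at most one finding per fact row, all
rows enumerated), and a normalization audit (duplicate natural keys and
identical attribute values restated on different dates — the redundancy
classes a 3NF design is meant to preclude). Violations sort by
(check, table, key) so reports diff stably. Checkers never repair.

The "clean-ingest theorem" — any generated bundle, ingested with default
policies, yields zero findings from all four checkers — is asserted across
seeds in the test suite, alongside a corruption catalogue (dangling keys,
overlapping episodes, out-of-wave interviews, out-of-domain and empty
values, duplicated rows) in which each injected fault is detected exactly
once.

## OMOP bridge

`PERSON` takes gender from the latest `sex` demographic (falling back to
the OMOP unknown-gender concept 8551) and year of birth from the latest
`birth_year`; individuals with neither episodes nor interviews are skipped
and tallied. `OBSERVATION_PERIOD` spans first episode start to the later of
last episode end and last interview date. Facts route by item value type —
numeric to `MEASUREMENT`, everything else to `OBSERVATION` (ordinal facts
keep both their concept and numeric value). Files carry CDM v5.4 headers;
a `staging_fact_id` provenance column makes the export verifiably lossless
(the exported id multiset equals the staging fact ids). This is a bridge
file set, not a certified CDM instance: only populated columns are
guaranteed non-null, local-concept domains are copied verbatim, and no
era/cohort derivation is attempted.

## Numerical and engineering conventions

- Embedded SQLite backend only (ANSI-compatible DDL, foreign keys enforced,
  `synchronous=OFF`/`journal_mode=MEMORY` since staging contents are always
  reproducible from sources). Document validation uses pydantic models.
- Exact string equality everywhere identity matters: concept lookup is
  case-sensitive; location dedup is exact `(name, lat, lon)` equality with
  no geodesic tolerance.
- Degenerate inputs are defined, not special-cased: empty source tables load
  zero facts successfully; an empty database validates clean and exports
  empty but well-formed CSV files; migration 0 and 1 produce exactly one and
  exactly one-per-wave episodes.
- Problem sizes: the demo bundle (50 households ≈ 200 people, 2 waves,
  3 instruments, ≈ 13k facts) drives the end-to-end and determinism checks;
  statistical-recovery checks use 150 households (≈ 600 people, ≈ 45k item
  cells, ≥ 500 complete interview pairs), chosen so the binomial standard
  errors are several times smaller than the tolerances being checked.

## Known limitations

- One interview per (individual, wave, instrument); re-administration
  within a wave is out of scope.
- No spreadsheet readers; sources are CSV (RFC 4180, UTF-8, header row).
- The normalization audit covers declared redundancy classes, not general
  functional-dependency discovery.
- No server database backend in this version; the module boundary
  (`StagingDB` + ANSI DDL) is where one would attach.
- Concept validity windows are stored but not enforced against observation
  dates.
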