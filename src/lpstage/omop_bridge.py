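"""Simplified export of staging facts toward OMOP CDM v5.4 tables.

Derives one PERSON row per individual (gender and year of birth from the
latest demographics, with an unknown-gender fallback) and one
OBSERVATION_PERIOD spanning the individual's first episode start to their
last episode end or last interview date.  Facts route to MEASUREMENT when
their item is numeric-typed and to OBSERVATION otherwise; ordinal facts
export with both ``value_as_concept_id`` and ``value_as_number``.  All
referenced concepts — standard and INSPIRE-local alike — are written to an
accompanying ``CONCEPT.csv``, the custom-vocabulary file set downstream
tooling would ingest.

The output is a bridge file set with CDM v5.4 headers, not a certified CDM
instance: only the columns this exporter populates are guaranteed non-null,
and each clinical-event row carries its staging ``fact_id`` in a provenance
column so no information is silently lost in translation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from .schema_core import StagingDB

__all__ = ["OmopExportManifest", "derive_person_and_periods", "export_clinical_events"]

UNKNOWN_GENDER_CONCEPT = 8551  # OMOP Gender vocabulary: UNKNOWN

PERSON_COLUMNS = [
    "person_id", "gender_concept_id", "year_of_birth", "month_of_birth", "day_of_birth",
    "birth_datetime", "race_concept_id", "ethnicity_concept_id", "location_id",
    "provider_id", "care_site_id", "person_source_value", "gender_source_value",
    "gender_source_concept_id", "race_source_value", "race_source_concept_id",
    "ethnicity_source_value", "ethnicity_source_concept_id",
]
OBSERVATION_PERIOD_COLUMNS = [
    "observation_period_id", "person_id", "observation_period_start_date",
    "observation_period_end_date", "period_type_concept_id",
]
OBSERVATION_COLUMNS = [
    "observation_id", "person_id", "observation_concept_id", "observation_date",
    "observation_datetime", "observation_type_concept_id", "value_as_number",
    "value_as_string", "value_as_concept_id", "qualifier_concept_id",
    "unit_concept_id", "provider_id", "visit_occurrence_id", "visit_detail_id",
    "observation_source_value", "observation_source_concept_id", "unit_source_value",
    "qualifier_source_value", "value_source_value", "observation_event_id",
    "obs_event_field_concept_id", "staging_fact_id",
]
MEASUREMENT_COLUMNS = [
    "measurement_id", "person_id", "measurement_concept_id", "measurement_date",
    "measurement_datetime", "measurement_time", "measurement_type_concept_id",
    "operator_concept_id", "value_as_number", "value_as_concept_id", "unit_concept_id",
    "range_low", "range_high", "provider_id", "visit_occurrence_id", "visit_detail_id",
    "measurement_source_value", "measurement_source_concept_id", "unit_source_value",
    "unit_source_concept_id", "value_source_value", "measurement_event_id",
    "meas_event_field_concept_id", "staging_fact_id",
]
CONCEPT_COLUMNS = [
    "concept_id", "concept_name", "domain_id", "vocabulary_id", "concept_class_id",
    "standard_concept", "concept_code", "valid_start_date", "valid_end_date",
    "invalid_reason",
]


@dataclass
class OmopExportManifest:
    files: list[dict] = field(default_factory=list)  # {name, rows, sha256}
    person_count: int = 0
    observation_count: int = 0
    measurement_count: int = 0
    skipped_individuals: int = 0

    def to_dict(self) -> dict:
        return {
            "files": self.files,
            "person_count": self.person_count,
            "observation_count": self.observation_count,
            "measurement_count": self.measurement_count,
            "skipped_individuals": self.skipped_individuals,
        }


def derive_person_and_periods(db: StagingDB) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """PERSON and OBSERVATION_PERIOD frames plus the skipped-individual tally.

    Individuals with neither episodes nor interviews carry no observable time
    and are skipped.
    """
    gender_map = {
        r["concept_id"]: r["concept_id"]
        for r in db.query("SELECT concept_id FROM CONCEPT WHERE domain_id = 'Gender'")
    }
    persons, periods = [], []
    skipped = 0
    for ind in db.query("SELECT * FROM INDIVIDUAL ORDER BY individual_id"):
        iid = ind["individual_id"]
        ep = db.one(
            "SELECT MIN(start_date) AS first_start, MAX(COALESCE(end_date, start_date)) AS last_end"
            " FROM RESIDENT_EPISODE WHERE individual_id = ?",
            (iid,),
        )
        last_interview = db.scalar(
            "SELECT MAX(interview_date) FROM INTERVIEW WHERE individual_id = ?", (iid,)
        )
        if ep["first_start"] is None and last_interview is None:
            skipped += 1
            continue

        # latest recorded gender/birth-year demographics
        sex_row = db.one(
            """
            SELECT d.value_as_concept_id FROM INDIVIDUAL_DEMOGRAPHICS d
            JOIN CONCEPT p ON p.concept_id = d.parameter_concept_id
            WHERE d.individual_id = ? AND p.concept_code = 'sex'
            ORDER BY d.observed_on DESC LIMIT 1
            """,
            (iid,),
        )
        gender = UNKNOWN_GENDER_CONCEPT
        if sex_row is not None and sex_row["value_as_concept_id"] in gender_map:
            gender = sex_row["value_as_concept_id"]
        birth_row = db.one(
            """
            SELECT d.value_as_number FROM INDIVIDUAL_DEMOGRAPHICS d
            JOIN CONCEPT p ON p.concept_id = d.parameter_concept_id
            WHERE d.individual_id = ? AND p.concept_code = 'birth_year'
            ORDER BY d.observed_on DESC LIMIT 1
            """,
            (iid,),
        )
        year = int(birth_row["value_as_number"]) if birth_row and birth_row["value_as_number"] else None

        candidates = [d for d in (ep["last_end"], last_interview) if d is not None]
        start = ep["first_start"] or last_interview
        end = max(candidates)
        persons.append(
            {
                "person_id": iid,
                "gender_concept_id": gender,
                "year_of_birth": year,
                "person_source_value": ind["external_id"],
            }
        )
        periods.append(
            {
                "observation_period_id": iid,
                "person_id": iid,
                "observation_period_start_date": start,
                "observation_period_end_date": end,
                "period_type_concept_id": 32879,  # "Registry" period type
            }
        )
    person_df = pd.DataFrame(persons).reindex(columns=PERSON_COLUMNS)
    period_df = pd.DataFrame(periods).reindex(columns=OBSERVATION_PERIOD_COLUMNS)
    return person_df, period_df, skipped


def export_clinical_events(db: StagingDB, out_dir: str | Path) -> OmopExportManifest:
    """Write PERSON, OBSERVATION_PERIOD, OBSERVATION, MEASUREMENT, CONCEPT CSVs.

    Routing rule: a fact whose instrument item is numeric-typed becomes a
    MEASUREMENT row, every other fact an OBSERVATION row.  The multiset of
    exported ``staging_fact_id`` values equals the staging fact ids — no
    loss, no duplication.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    person_df, period_df, skipped = derive_person_and_periods(db)

    facts = db.query(
        """
        SELECT f.*, it.value_type, it.item_code, iv.interview_date
        FROM LONGITUDINAL_POPULATION_STUDY_FACT f
        JOIN INSTRUMENT_ITEM it ON it.item_id = f.instrument_item_id
        JOIN INTERVIEW iv ON iv.interview_id = f.interview_id
        ORDER BY f.fact_id
        """
    )
    observations, measurements = [], []
    used_concepts: set[int] = set(int(g) for g in person_df["gender_concept_id"].dropna())
    for f in facts:
        used_concepts.add(f["question_concept_id"])
        used_concepts.add(f["value_type_concept_id"])
        if f["value_as_concept_id"] is not None:
            used_concepts.add(f["value_as_concept_id"])
        if f["value_type"] == "numeric":
            measurements.append(
                {
                    "measurement_id": len(measurements) + 1,
                    "person_id": f["individual_id"],
                    "measurement_concept_id": f["question_concept_id"],
                    "measurement_date": f["interview_date"],
                    "measurement_type_concept_id": f["value_type_concept_id"],
                    "value_as_number": f["value_as_number"],
                    "measurement_source_value": f["item_code"],
                    "staging_fact_id": f["fact_id"],
                }
            )
        else:
            observations.append(
                {
                    "observation_id": len(observations) + 1,
                    "person_id": f["individual_id"],
                    "observation_concept_id": f["question_concept_id"],
                    "observation_date": f["interview_date"],
                    "observation_type_concept_id": f["value_type_concept_id"],
                    "value_as_number": f["value_as_number"],
                    "value_as_string": f["value_as_text"],
                    "value_as_concept_id": f["value_as_concept_id"],
                    "observation_source_value": f["item_code"],
                    "staging_fact_id": f["fact_id"],
                }
            )

    concept_rows = [
        dict(r)
        for r in db.query(
            "SELECT concept_id, concept_name, domain_id, vocabulary_id, concept_class_id,"
            " standard_concept, concept_code, valid_start_date, valid_end_date, invalid_reason"
            " FROM CONCEPT ORDER BY concept_id"
        )
        if r["concept_id"] in used_concepts
    ]

    frames = {
        "PERSON.csv": person_df,
        "OBSERVATION_PERIOD.csv": period_df,
        "OBSERVATION.csv": pd.DataFrame(observations).reindex(columns=OBSERVATION_COLUMNS),
        "MEASUREMENT.csv": pd.DataFrame(measurements).reindex(columns=MEASUREMENT_COLUMNS),
        "CONCEPT.csv": pd.DataFrame(concept_rows).reindex(columns=CONCEPT_COLUMNS),
    }
    manifest = OmopExportManifest(
        person_count=len(person_df),
        observation_count=len(observations),
        measurement_count=len(measurements),
        skipped_individuals=skipped,
    )
    for name, frame in frames.items():
        path = out_dir / name
        frame.to_csv(path, index=False, lineterminator="\n")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest.files.append({"name": name, "rows": len(frame), "sha256": digest})
    return manifest
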