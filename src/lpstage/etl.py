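"""Wide-to-long ETL into the central FACT table.

A *mapping spec* declares, for one instrument and one wave, how the columns
of a wide survey export (one row per respondent, one column per item) map
onto registered instrument items, and how raw cell text translates into the
item's value domain.  The pipeline then

1. melts the wide table to long records (one per answered cell; blanks are
   skipped and tallied),
2. types and codes each raw value against the item definition — ordinal and
   categorical values resolve to a value concept (ordinals also carry the
   numeric code), numeric values are range-checked, text passes through,
3. loads one fact per accepted record, attached to the respondent's
   interview (created on demand, with date approximation when the export has
   no date) and the resident episode covering the interview date.

Every failure is a :class:`Reject` row in the run report, never an exception;
the report reconciles ``facts + rejects + blanks = mapped cells``.  Loading
is idempotent: facts deduplicate on (interview, item).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .schema_core import StagingDB, create_schema
from .study_metadata import PopulationStudy, get_waves, load_study_file
from .population import (
    PopulationError,
    episode_covering,
    load_rosters,
    record_interview,
    upsert_individual,
)
from .vocabulary import (
    ItemRecord,
    get_items,
    load_concepts,
    load_instrument_file,
    mint_local_concept,
)

__all__ = [
    "MappingSpec",
    "LongRecord",
    "TypedValue",
    "Reject",
    "RunReport",
    "EtlError",
    "parse_mapping_spec",
    "melt_wide_to_long",
    "type_and_code_value",
    "load_facts",
    "run_pipeline",
    "pivot_facts_wide",
]


class EtlError(RuntimeError):
    pass


class MappingSpec(BaseModel):
    """Declarative wide-to-long mapping for one instrument in one wave."""

    instrument: str
    id_column: str
    wave_label: str
    date_column: Optional[str] = None
    item_columns: dict[str, str] = Field(min_length=1)  # column -> item_code
    value_maps: dict[str, dict[str, str]] = Field(default_factory=dict)  # item_code -> raw -> canonical
    on_unmapped: str = "reject"  # reject | mint | null


@dataclass(frozen=True)
class LongRecord:
    external_id: str
    wave_label: str
    instrument: str
    item_code: str
    raw_value: str
    interview_date: Optional[date] = None


@dataclass(frozen=True)
class TypedValue:
    value_as_number: Optional[float]
    value_as_concept_id: Optional[int]
    value_as_text: Optional[str]
    value_type: str  # ordinal | numeric | categorical | text


@dataclass(frozen=True)
class Reject:
    row_ref: str
    item_code: str
    reason: str


@dataclass
class MeltResult:
    records: list[LongRecord]
    blank_cells: int


@dataclass
class RunReport:
    counts: dict[str, int] = field(default_factory=dict)
    rejects: list[Reject] = field(default_factory=list)
    blank_cells: int = 0
    skipped_cells: int = 0  # null policy
    started: float = 0.0
    finished: float = 0.0
    failed_stage: Optional[str] = None
    error: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.failed_stage is None

    def to_dict(self) -> dict:
        return {
            "counts": self.counts,
            "rejects": [vars(r) for r in self.rejects],
            "blank_cells": self.blank_cells,
            "skipped_cells": self.skipped_cells,
            "started": self.started,
            "finished": self.finished,
            "failed_stage": self.failed_stage,
            "error": self.error,
        }


# ---------------------------------------------------------------------------
# mapping spec

def parse_mapping_spec(db: StagingDB, source: Union[str, Path, dict]) -> MappingSpec:
    """Parse and validate a mapping spec against the registered instrument.

    All problems are collected and reported together, not first-failure.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    else:
        doc = source
    spec = MappingSpec(**doc)

    problems: list[str] = []
    if spec.on_unmapped not in ("reject", "mint", "null"):
        problems.append(f"on_unmapped must be reject|mint|null, got {spec.on_unmapped!r}")
    inst = db.one("SELECT instrument_id FROM INSTRUMENT WHERE name = ?", (spec.instrument,))
    if inst is None:
        problems.append(f"unknown instrument {spec.instrument!r}")
        raise EtlError("; ".join(problems))
    registered = {i.item_code for i in get_items(db, spec.instrument)}
    seen_targets: set[str] = set()
    for column, code in spec.item_columns.items():
        if code not in registered:
            problems.append(f"unknown item {code!r} (column {column!r})")
        if code in seen_targets:
            problems.append(f"duplicate target {code!r}")
        seen_targets.add(code)
    for code in spec.value_maps:
        if code not in registered:
            problems.append(f"value_map for unknown item {code!r}")
    if problems:
        raise EtlError("; ".join(problems))
    return spec


# ---------------------------------------------------------------------------
# melt

def melt_wide_to_long(wide: pd.DataFrame, spec: MappingSpec) -> MeltResult:
    """One LongRecord per non-blank mapped cell, in input-row then spec-item
    order; blank / whitespace-only cells are skipped and tallied."""
    missing = [c for c in [spec.id_column, *spec.item_columns] if c not in wide.columns]
    if missing:
        raise EtlError(f"wide table missing column(s): {missing}")
    if spec.date_column is not None and spec.date_column not in wide.columns:
        raise EtlError(f"wide table missing date column {spec.date_column!r}")

    records: list[LongRecord] = []
    blanks = 0
    for _, row in wide.iterrows():
        external_id = str(row[spec.id_column])
        when: Optional[date] = None
        if spec.date_column is not None:
            raw_date = row[spec.date_column]
            if not (pd.isna(raw_date) or str(raw_date).strip() == ""):
                when = date.fromisoformat(str(raw_date).strip())
        for column, item_code in spec.item_columns.items():
            cell = row[column]
            if pd.isna(cell) or str(cell).strip() == "":
                blanks += 1
                continue
            records.append(
                LongRecord(
                    external_id=external_id,
                    wave_label=spec.wave_label,
                    instrument=spec.instrument,
                    item_code=item_code,
                    raw_value=str(cell).strip(),
                    interview_date=when,
                )
            )
    return MeltResult(records=records, blank_cells=blanks)


# ---------------------------------------------------------------------------
# typing / coding

def _canonical_number(raw: str) -> Optional[float]:
    try:
        return float(raw)
    except ValueError:
        return None


def type_and_code_value(
    db: StagingDB,
    raw_value: str,
    item: ItemRecord,
    policy: str = "reject",
    value_map: Optional[dict[str, str]] = None,
    row_ref: str = "",
) -> Union[TypedValue, Reject, None]:
    """Code one raw cell against an item's value domain.

    Returns a :class:`TypedValue`, a :class:`Reject`, or ``None`` under the
    ``null`` policy (skipped-and-tallied).  Never raises for data errors.
    """
    raw = raw_value.strip()
    if value_map and raw in value_map:
        raw = value_map[raw]

    if item.value_type in ("ordinal", "categorical"):
        number = _canonical_number(raw)
        for entry in item.allowed_values:
            code = entry.get("code")
            if raw == entry["raw"] or (number is not None and code is not None and number == code):
                return TypedValue(
                    value_as_number=float(code) if (code is not None and item.value_type == "ordinal") else None,
                    value_as_concept_id=entry["value_concept_id"],
                    value_as_text=None,
                    value_type=item.value_type,
                )
        if policy == "mint":
            concept = mint_local_concept(
                db, f"{item.item_code}_RESP_{raw}", raw, domain="Meas Value"
            )
            entries = list(item.allowed_values) + [
                {"raw": raw, "code": None, "value_concept_id": concept.concept_id}
            ]
            with db.conn:
                db.execute(
                    "UPDATE INSTRUMENT_ITEM SET allowed_values = ? WHERE item_id = ?",
                    (json.dumps(entries), item.item_id),
                )
            return TypedValue(None, concept.concept_id, None, item.value_type)
        if policy == "null":
            return None
        return Reject(row_ref, item.item_code, f"value {raw_value!r} out of domain")

    if item.value_type == "numeric":
        number = _canonical_number(raw)
        if number is None:
            return Reject(row_ref, item.item_code, f"not numeric: {raw_value!r}")
        if item.range_min is not None and not (item.range_min <= number <= item.range_max):
            return Reject(
                row_ref, item.item_code,
                f"value {number} outside range [{item.range_min}, {item.range_max}]",
            )
        return TypedValue(number, None, None, "numeric")

    return TypedValue(None, None, raw, "text")


_VALUE_TYPE_CODES = {
    "ordinal": ("VALUE_TYPE_ORDINAL", "Ordinal-coded item response"),
    "categorical": ("VALUE_TYPE_CATEGORICAL", "Categorical item response"),
    "numeric": ("VALUE_TYPE_NUMERIC", "Numeric item response"),
    "text": ("VALUE_TYPE_TEXT", "Free-text item response"),
}


def _value_type_concept(db: StagingDB, value_type: str) -> int:
    code, name = _VALUE_TYPE_CODES[value_type]
    return mint_local_concept(db, code, name, domain="Type Concept").concept_id


# ---------------------------------------------------------------------------
# fact loading

def load_facts(
    db: StagingDB,
    records: Sequence[LongRecord],
    study: PopulationStudy | int,
    spec: MappingSpec,
    auto_upsert_individuals: bool = True,
    on_no_episode: str = "error",
) -> RunReport:
    """Load long records as facts; idempotent on (interview, item)."""
    report = RunReport(started=time.time())
    study_id = study.study_id if isinstance(study, PopulationStudy) else study
    waves = {w.label: w for w in get_waves(db, study_id)}
    items = {i.item_code: i for i in get_items(db, spec.instrument)}
    inst_row = db.one("SELECT instrument_id FROM INSTRUMENT WHERE name = ?", (spec.instrument,))
    if inst_row is None:
        raise EtlError(f"instrument {spec.instrument!r} not registered")
    instrument_id = inst_row["instrument_id"]

    value_type_ids = {vt: _value_type_concept(db, vt) for vt in _VALUE_TYPE_CODES}
    existing_pairs: set[tuple[int, int]] = {
        (r["interview_id"], r["instrument_item_id"])
        for r in db.query(
            "SELECT interview_id, instrument_item_id FROM LONGITUDINAL_POPULATION_STUDY_FACT"
        )
    }
    individual_cache: dict[str, Optional[int]] = {}
    interview_cache: dict[tuple[str, str], object] = {}
    episode_cache: dict[tuple[int, date], Optional[int]] = {}

    inserted = 0
    next_fact_id = db.next_id("LONGITUDINAL_POPULATION_STUDY_FACT", "fact_id")
    pending: list[tuple] = []
    for rec in records:
        row_ref = f"{rec.external_id}/{rec.wave_label}"
        wave = waves.get(rec.wave_label)
        if wave is None:
            report.rejects.append(Reject(row_ref, rec.item_code, f"unknown wave {rec.wave_label!r}"))
            continue
        item = items.get(rec.item_code)
        if item is None:
            report.rejects.append(Reject(row_ref, rec.item_code, "unknown item"))
            continue

        if rec.external_id not in individual_cache:
            row = db.one(
                "SELECT individual_id FROM INDIVIDUAL WHERE external_id = ?", (rec.external_id,)
            )
            if row is None and auto_upsert_individuals:
                individual_cache[rec.external_id] = upsert_individual(db, rec.external_id).individual_id
            else:
                individual_cache[rec.external_id] = row["individual_id"] if row else None
        individual_id = individual_cache[rec.external_id]
        if individual_id is None:
            report.rejects.append(Reject(row_ref, rec.item_code, "unresolvable external id"))
            continue

        ivkey = (rec.external_id, rec.wave_label)
        if ivkey not in interview_cache:
            try:
                interview_cache[ivkey] = record_interview(
                    db, individual_id, wave.wave_id, instrument_id,
                    rec.interview_date, on_no_episode=on_no_episode,
                )
            except PopulationError as exc:
                interview_cache[ivkey] = str(exc)
        interview = interview_cache[ivkey]
        if isinstance(interview, str):
            report.rejects.append(Reject(row_ref, rec.item_code, interview))
            continue

        epkey = (individual_id, interview.interview_date)
        if epkey not in episode_cache:
            episode = episode_covering(db, individual_id, interview.interview_date)
            if episode is not None:
                episode_cache[epkey] = episode.episode_id
            else:
                # fall back to any episode overlapping the wave
                erow = db.one(
                    "SELECT episode_id FROM RESIDENT_EPISODE WHERE individual_id = ?"
                    " AND start_date <= ? AND (end_date IS NULL OR end_date > ?)"
                    " ORDER BY start_date LIMIT 1",
                    (individual_id, wave.end_date.isoformat(), wave.start_date.isoformat()),
                )
                episode_cache[epkey] = erow["episode_id"] if erow else None
        episode_id = episode_cache[epkey]
        if episode_id is None:
            report.rejects.append(Reject(row_ref, rec.item_code, "no covering resident episode"))
            continue

        typed = type_and_code_value(
            db, rec.raw_value, item, policy=spec.on_unmapped,
            value_map=spec.value_maps.get(rec.item_code), row_ref=row_ref,
        )
        if typed is None:
            report.skipped_cells += 1
            continue
        if isinstance(typed, Reject):
            report.rejects.append(typed)
            continue

        pair = (interview.interview_id, item.item_id)
        if pair in existing_pairs:
            continue
        existing_pairs.add(pair)
        pending.append(
            (
                next_fact_id, study_id, individual_id, interview.interview_id, episode_id,
                item.item_id, item.question_concept_id, typed.value_as_number,
                typed.value_as_concept_id, typed.value_as_text,
                value_type_ids[typed.value_type],
            )
        )
        next_fact_id += 1
        inserted += 1

    with db.conn:
        db.executemany(
            "INSERT INTO LONGITUDINAL_POPULATION_STUDY_FACT"
            " (fact_id, study_id, individual_id, interview_id, episode_id,"
            "  instrument_item_id, question_concept_id, value_as_number,"
            "  value_as_concept_id, value_as_text, value_type_concept_id)"
            " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
            pending,
        )

    report.counts["LONGITUDINAL_POPULATION_STUDY_FACT"] = inserted
    report.finished = time.time()
    return report


# ---------------------------------------------------------------------------
# pipeline

class PipelineConfig(BaseModel):
    """Single-file pipeline configuration (paths relative to the config file)."""

    vocabulary: Optional[str] = None
    instruments: Optional[str] = None
    study: str
    individuals: str
    households: str
    sources: list[dict] = Field(default_factory=list)  # {table: csv path, mapping: spec path}


def run_pipeline(db: StagingDB, config_path: str | Path, strict: bool = False) -> RunReport:
    """Execute the staged load: vocabulary -> study metadata -> population
    rosters -> facts.  A stage failure aborts later stages; the partial
    report is returned with the failed stage marked (raised under
    ``strict``)."""
    config_path = Path(config_path)
    with config_path.open(encoding="utf-8") as fh:
        cfg = PipelineConfig(**yaml.safe_load(fh))
    base = config_path.parent

    def respath(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    report = RunReport(started=time.time())
    stage = "schema"
    try:
        if not db.has_schema():
            create_schema(db)

        stage = "vocabulary"
        if cfg.vocabulary:
            report.counts["CONCEPT"] = load_concepts(db, respath(cfg.vocabulary))
        if cfg.instruments:
            item_counts = load_instrument_file(db, respath(cfg.instruments))
            report.counts["INSTRUMENT_ITEM"] = sum(item_counts.values())
            report.counts["INSTRUMENT"] = len(item_counts)

        stage = "study_metadata"
        study = load_study_file(db, respath(cfg.study))
        waves = get_waves(db, study)
        report.counts["WAVE"] = len(waves)

        stage = "population"
        roster_counts = load_rosters(db, respath(cfg.individuals), respath(cfg.households), waves)
        report.counts["INDIVIDUAL"] = roster_counts["individuals"]
        report.counts["HOUSEHOLD"] = roster_counts["households"]
        report.counts["RESIDENT_EPISODE"] = roster_counts["episodes"]
        report.counts["INDIVIDUAL_DEMOGRAPHICS"] = roster_counts["demographics"]

        stage = "facts"
        total_facts = 0
        for source in cfg.sources:
            spec = parse_mapping_spec(db, respath(source["mapping"]))
            wide = pd.read_csv(respath(source["table"]), dtype=str)
            melt = melt_wide_to_long(wide, spec)
            sub = load_facts(db, melt.records, study, spec)
            report.rejects.extend(sub.rejects)
            report.blank_cells += melt.blank_cells
            report.skipped_cells += sub.skipped_cells
            total_facts += sub.counts.get("LONGITUDINAL_POPULATION_STUDY_FACT", 0)
        report.counts["LONGITUDINAL_POPULATION_STUDY_FACT"] = total_facts
        report.counts["INTERVIEW"] = db.count("INTERVIEW")
    except Exception as exc:  # staged-failure contract: partial report survives
        report.failed_stage = stage
        report.error = str(exc)
        if strict:
            raise
    report.finished = time.time()
    return report


# ---------------------------------------------------------------------------
# re-pivot (facts back to wide), used for round-trip verification

def pivot_facts_wide(
    db: StagingDB,
    study: PopulationStudy | int,
    instrument: str,
    wave_label: str,
) -> pd.DataFrame:
    """Rebuild the wide table of one instrument in one wave from loaded facts.

    Cells hold the canonical raw value: for ordinal/categorical items the
    ``raw`` string of the matched allowed value, for numeric items the number,
    for text items the stored text.  Indexed by respondent external id,
    columns in item-position order.
    """
    study_id = study.study_id if isinstance(study, PopulationStudy) else study
    items = get_items(db, instrument)
    by_id = {i.item_id: i for i in items}
    rows = db.query(
        """
        SELECT ind.external_id, f.instrument_item_id, f.value_as_number,
               f.value_as_concept_id, f.value_as_text
        FROM LONGITUDINAL_POPULATION_STUDY_FACT f
        JOIN INTERVIEW iv ON iv.interview_id = f.interview_id
        JOIN WAVE w ON w.wave_id = iv.wave_id
        JOIN INDIVIDUAL ind ON ind.individual_id = f.individual_id
        JOIN INSTRUMENT inst ON inst.instrument_id = iv.instrument_id
        WHERE f.study_id = ? AND w.label = ? AND inst.name = ?
        """,
        (study_id, wave_label, instrument),
    )
    data: dict[str, dict[str, str]] = {}
    for r in rows:
        item = by_id[r["instrument_item_id"]]
        if item.value_type in ("ordinal", "categorical"):
            value = None
            for entry in item.allowed_values:
                if r["value_as_concept_id"] == entry["value_concept_id"]:
                    value = entry["raw"]
                    break
        elif item.value_type == "numeric":
            num = r["value_as_number"]
            value = str(int(num)) if num == int(num) else str(num)
        else:
            value = r["value_as_text"]
        data.setdefault(r["external_id"], {})[item.item_code] = value
    frame = pd.DataFrame.from_dict(data, orient="index")
    frame = frame.reindex(columns=[i.item_code for i in items]).sort_index()
    frame.index.name = "external_id"
    return frame
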