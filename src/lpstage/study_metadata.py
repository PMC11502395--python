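"""Study-definition dimension: population studies, methodologies, data-collection
waves, and data-capture events.

The layout mirrors the DDI-Lifecycle view of a longitudinal study — a study
carries one or more methodologies, runs in waves (each with a date range and
an ``instrument_model_type`` drawn from a controlled vocabulary), and each
wave contains data-capture events (field visits, phone rounds).  Registration
is idempotent: replaying the same descriptors never duplicates rows, so study
metadata can be re-used across loads.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from .schema_core import StagingDB

__all__ = [
    "PopulationStudy",
    "Wave",
    "DataCaptureEvent",
    "MetadataError",
    "INSTRUMENT_MODEL_TYPES",
    "CAPTURE_MODES",
    "register_study",
    "register_wave",
    "register_capture_event",
    "load_study_file",
    "get_waves",
]

#: Controlled vocabulary for WAVE.instrument_model_type (extensible via config).
INSTRUMENT_MODEL_TYPES = (
    "screening-scale",
    "diagnostic-interview",
    "roster",
    "verbal-autopsy",
    "other",
)

CAPTURE_MODES = ("face-to-face", "telephone", "self-administered", "other")


class MetadataError(RuntimeError):
    pass


@dataclass(frozen=True)
class PopulationStudy:
    study_id: int
    title: str
    description: str
    site: str


@dataclass(frozen=True)
class Wave:
    wave_id: int
    study_id: int
    label: str
    start_date: date
    end_date: date
    instrument_model_type: str


@dataclass(frozen=True)
class DataCaptureEvent:
    event_id: int
    wave_id: int
    mode: str
    start_date: date
    end_date: date


def _as_date(value: date | str) -> date:
    return value if isinstance(value, date) else date.fromisoformat(value)


def register_study(
    db: StagingDB,
    title: str,
    description: str = "",
    site: str = "",
    methodology: Optional[dict] = None,
) -> PopulationStudy:
    """Create a study and its methodology atomically; duplicate titles return
    the existing study without adding a methodology row."""
    if not title:
        raise MetadataError("study title must be non-empty")
    row = db.one("SELECT * FROM POPULATION_STUDY WHERE title = ?", (title,))
    if row is not None:
        return PopulationStudy(row["study_id"], row["title"], row["description"] or "", row["site"] or "")
    sid = db.next_id("POPULATION_STUDY", "study_id")
    meth = methodology or {}
    with db.conn:
        db.execute(
            "INSERT INTO POPULATION_STUDY (study_id, title, description, site) VALUES (?, ?, ?, ?)",
            (sid, title, description, site),
        )
        db.execute(
            "INSERT INTO METHODOLOGY (methodology_id, study_id, design, sampling) VALUES (?, ?, ?, ?)",
            (
                db.next_id("METHODOLOGY", "methodology_id"),
                sid,
                meth.get("design", ""),
                meth.get("sampling", ""),
            ),
        )
    return PopulationStudy(sid, title, description, site)


def register_wave(
    db: StagingDB,
    study: PopulationStudy | int,
    label: str,
    start_date: date | str,
    end_date: date | str,
    instrument_model_type: str = "screening-scale",
) -> Wave:
    study_id = study.study_id if isinstance(study, PopulationStudy) else study
    start, end = _as_date(start_date), _as_date(end_date)
    if end < start:
        raise MetadataError(f"wave {label!r}: end {end} precedes start {start}")
    if instrument_model_type not in INSTRUMENT_MODEL_TYPES:
        raise MetadataError(
            f"unknown instrument_model_type {instrument_model_type!r};"
            f" allowed: {', '.join(INSTRUMENT_MODEL_TYPES)}"
        )
    if db.one("SELECT 1 FROM POPULATION_STUDY WHERE study_id = ?", (study_id,)) is None:
        raise MetadataError(f"study {study_id} not registered")
    row = db.one("SELECT * FROM WAVE WHERE study_id = ? AND label = ?", (study_id, label))
    if row is not None:
        return _wave_from_row(row)
    wid = db.next_id("WAVE", "wave_id")
    with db.conn:
        db.execute(
            "INSERT INTO WAVE (wave_id, study_id, label, start_date, end_date,"
            " instrument_model_type) VALUES (?, ?, ?, ?, ?, ?)",
            (wid, study_id, label, start.isoformat(), end.isoformat(), instrument_model_type),
        )
    return Wave(wid, study_id, label, start, end, instrument_model_type)


def register_capture_event(
    db: StagingDB,
    wave: Wave | int,
    mode: str,
    start_date: date | str,
    end_date: date | str,
) -> DataCaptureEvent:
    wave_id = wave.wave_id if isinstance(wave, Wave) else wave
    wrow = db.one("SELECT * FROM WAVE WHERE wave_id = ?", (wave_id,))
    if wrow is None:
        raise MetadataError(f"wave {wave_id} not registered")
    if mode not in CAPTURE_MODES:
        raise MetadataError(f"unknown capture mode {mode!r}; allowed: {', '.join(CAPTURE_MODES)}")
    start, end = _as_date(start_date), _as_date(end_date)
    if end < start:
        raise MetadataError("capture event end precedes start")
    wstart, wend = date.fromisoformat(wrow["start_date"]), date.fromisoformat(wrow["end_date"])
    if start < wstart or end > wend:
        raise MetadataError(
            f"capture event [{start}, {end}] outside wave {wrow['label']!r}"
            f" bounds [{wstart}, {wend}]"
        )
    eid = db.next_id("DATA_CAPTURE_EVENT", "event_id")
    with db.conn:
        db.execute(
            "INSERT INTO DATA_CAPTURE_EVENT (event_id, wave_id, mode, start_date, end_date)"
            " VALUES (?, ?, ?, ?, ?)",
            (eid, wave_id, mode, start.isoformat(), end.isoformat()),
        )
    return DataCaptureEvent(eid, wave_id, mode, start, end)


def _wave_from_row(row) -> Wave:
    return Wave(
        row["wave_id"],
        row["study_id"],
        row["label"],
        date.fromisoformat(row["start_date"]),
        date.fromisoformat(row["end_date"]),
        row["instrument_model_type"],
    )


def get_waves(db: StagingDB, study: PopulationStudy | int) -> list[Wave]:
    """Waves of one study, ordered by start date."""
    study_id = study.study_id if isinstance(study, PopulationStudy) else study
    rows = db.query(
        "SELECT * FROM WAVE WHERE study_id = ? ORDER BY start_date, wave_id", (study_id,)
    )
    return [_wave_from_row(r) for r in rows]


# ---------------------------------------------------------------------------
# descriptor file (validated before any write: all-or-nothing)

class _MethodologyDoc(BaseModel):
    design: str = ""
    sampling: str = ""


class _CaptureEventDoc(BaseModel):
    mode: str
    start_date: date
    end_date: date


class _WaveDoc(BaseModel):
    label: str = Field(min_length=1)
    start_date: date
    end_date: date
    instrument_model_type: str = "screening-scale"
    capture_events: list[_CaptureEventDoc] = Field(default_factory=list)


class StudyDoc(BaseModel):
    title: str = Field(min_length=1)
    description: str = ""
    site: str = ""
    methodology: _MethodologyDoc = _MethodologyDoc()
    waves: list[_WaveDoc] = Field(default_factory=list)


def load_study_file(db: StagingDB, path: str | Path) -> PopulationStudy:
    """Register a study plus its waves and capture events from a YAML/JSON
    descriptor.  The document is fully validated first; semantic errors
    (controlled-vocabulary or interval violations) abort before any write."""
    with open(path, encoding="utf-8") as fh:
        doc = StudyDoc(**yaml.safe_load(fh))
    for wave in doc.waves:
        if wave.end_date < wave.start_date:
            raise MetadataError(f"wave {wave.label!r}: end precedes start")
        if wave.instrument_model_type not in INSTRUMENT_MODEL_TYPES:
            raise MetadataError(
                f"unknown instrument_model_type {wave.instrument_model_type!r};"
                f" allowed: {', '.join(INSTRUMENT_MODEL_TYPES)}"
            )
        for ev in wave.capture_events:
            if ev.mode not in CAPTURE_MODES:
                raise MetadataError(f"unknown capture mode {ev.mode!r}")
            if ev.start_date < wave.start_date or ev.end_date > wave.end_date:
                raise MetadataError(f"capture event outside wave {wave.label!r}")
    study = register_study(db, doc.title, doc.description, doc.site, doc.methodology.model_dump())
    for wave_doc in doc.waves:
        wave = register_wave(
            db, study, wave_doc.label, wave_doc.start_date, wave_doc.end_date,
            wave_doc.instrument_model_type,
        )
        for ev in wave_doc.capture_events:
            existing = db.one(
                "SELECT 1 FROM DATA_CAPTURE_EVENT WHERE wave_id = ? AND mode = ?"
                " AND start_date = ? AND end_date = ?",
                (wave.wave_id, ev.mode, ev.start_date.isoformat(), ev.end_date.isoformat()),
            )
            if existing is None:
                register_capture_event(db, wave, ev.mode, ev.start_date, ev.end_date)
    return study
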