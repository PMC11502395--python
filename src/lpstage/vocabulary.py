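"""Concept dimension: OMOP-format vocabulary loading, local-concept minting,
and the instrument / instrument-item registry.

Concepts coming from standard vocabularies (LOINC, SNOMED, Gender, ...) are
loaded verbatim from a delimited file in the OMOP ``CONCEPT`` table layout.
Terms with no standard equivalent — screening-tool response anchors, site
parameters — are *minted* as local concepts under the ``INSPIRE`` vocabulary.
Local concept ids are allocated sequentially from 2,000,000,000 (the OHDSI
convention for site-local concepts), and minting is stable: re-minting an
existing code returns the id allocated at first mint.

Screening instruments (PHQ-9, GAD-7, BASIS-24, ...) are registered together
with their items; each item carries a value domain (ordinal / numeric /
categorical / text), a question concept, and — for ordinal and categorical
items — an allowed-value set in which every response anchor has both a
numeric code and a value concept.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Literal, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .schema_core import StagingDB

__all__ = [
    "Concept",
    "Instrument",
    "LOCAL_CONCEPT_BASE",
    "LOCAL_VOCABULARY",
    "VocabularyError",
    "load_concepts",
    "mint_local_concept",
    "resolve_concept",
    "register_instrument",
    "register_items",
    "load_instrument_file",
    "get_items",
    "packaged_fixture",
]

LOCAL_VOCABULARY = "INSPIRE"
LOCAL_CONCEPT_BASE = 2_000_000_000

_FIXTURE_DIR = Path(__file__).parent / "fixtures"

_CONCEPT_COLUMNS = (
    "concept_id",
    "concept_name",
    "domain_id",
    "vocabulary_id",
    "concept_class_id",
    "standard_concept",
    "concept_code",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
)


class VocabularyError(RuntimeError):
    pass


@dataclass(frozen=True)
class Concept:
    concept_id: int
    code: str
    name: str
    vocabulary_id: str
    domain: str
    concept_class: str
    valid_start: date
    valid_end: date
    is_local: bool


@dataclass(frozen=True)
class Instrument:
    instrument_id: int
    name: str
    description: str


def packaged_fixture(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return _FIXTURE_DIR / name


# ---------------------------------------------------------------------------
# concept loading / minting / lookup

def _parse_omop_date(raw: str, line: int) -> str:
    raw = raw.strip()
    for fmt in ("%Y%m%d", "%Y-%m-%d"):
        try:
            from datetime import datetime

            return datetime.strptime(raw, fmt).date().isoformat()
        except ValueError:
            continue
    raise VocabularyError(f"malformed date {raw!r} at line {line}")


def _ensure_vocabulary(db: StagingDB, vocabulary_id: str) -> None:
    db.execute(
        "INSERT OR IGNORE INTO VOCABULARY (vocabulary_id, vocabulary_name) VALUES (?, ?)",
        (vocabulary_id, vocabulary_id),
    )


def load_concepts(db: StagingDB, source: str | Path, format: str | None = None) -> int:
    """Load an OMOP-layout concept file; returns the number of NEW rows.

    The delimiter (comma or tab) is auto-detected from the header line unless
    ``format`` forces ``"csv"`` or ``"tsv"``.  Loading is an upsert on
    ``concept_id``: an already-present id with identical name and vocabulary
    is skipped, a conflicting one is an error.
    """
    source = Path(source)
    with source.open(newline="", encoding="utf-8") as fh:
        header_line = fh.readline()
        if format == "csv":
            delim = ","
        elif format == "tsv":
            delim = "\t"
        else:
            delim = "\t" if "\t" in header_line else ","
        header = [h.strip() for h in header_line.rstrip("\n").split(delim)]
        missing = [c for c in _CONCEPT_COLUMNS if c not in header]
        if missing:
            raise VocabularyError(f"concept file missing columns: {missing}")
        reader = csv.DictReader(fh, fieldnames=header, delimiter=delim)

        added = 0
        with db.conn:
            for lineno, row in enumerate(reader, start=2):
                cid = int(row["concept_id"])
                existing = db.one(
                    "SELECT concept_name, vocabulary_id FROM CONCEPT WHERE concept_id = ?",
                    (cid,),
                )
                if existing is not None:
                    if (
                        existing["concept_name"] != row["concept_name"]
                        or existing["vocabulary_id"] != row["vocabulary_id"]
                    ):
                        raise VocabularyError(f"conflicting concept {cid}")
                    continue
                vocab = row["vocabulary_id"]
                is_local = 1 if vocab == LOCAL_VOCABULARY else 0
                if is_local != (cid >= LOCAL_CONCEPT_BASE):
                    raise VocabularyError(
                        f"concept {cid}: id range inconsistent with vocabulary {vocab!r}"
                    )
                _ensure_vocabulary(db, vocab)
                db.execute(
                    "INSERT INTO CONCEPT (concept_id, concept_name, domain_id, vocabulary_id,"
                    " concept_class_id, standard_concept, concept_code, valid_start_date,"
                    " valid_end_date, invalid_reason, is_local)"
                    " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                    (
                        cid,
                        row["concept_name"],
                        row["domain_id"],
                        vocab,
                        row["concept_class_id"],
                        row["standard_concept"] or None,
                        row["concept_code"],
                        _parse_omop_date(row["valid_start_date"], lineno),
                        _parse_omop_date(row["valid_end_date"], lineno),
                        row["invalid_reason"] or None,
                        is_local,
                    ),
                )
                added += 1
        return added


def _row_to_concept(row) -> Concept:
    return Concept(
        concept_id=row["concept_id"],
        code=row["concept_code"],
        name=row["concept_name"],
        vocabulary_id=row["vocabulary_id"],
        domain=row["domain_id"],
        concept_class=row["concept_class_id"],
        valid_start=date.fromisoformat(row["valid_start_date"]),
        valid_end=date.fromisoformat(row["valid_end_date"]),
        is_local=bool(row["is_local"]),
    )


def resolve_concept(db: StagingDB, vocabulary_id: str, code: str) -> Optional[Concept]:
    """Exact, case-sensitive lookup on (vocabulary_id, concept_code)."""
    row = db.one(
        "SELECT * FROM CONCEPT WHERE vocabulary_id = ? AND concept_code = ?",
        (vocabulary_id, code),
    )
    # BINARY collation makes the lookup case-sensitive, matching the
    # exact-match contract; no normalisation is applied.
    if row is None:
        return None
    return _row_to_concept(row)


def mint_local_concept(
    db: StagingDB,
    code: str,
    name: str,
    domain: str = "Observation",
    concept_class: str = "INSPIRE local",
) -> Concept:
    """Mint (or retrieve) a local concept under the ``INSPIRE`` vocabulary.

    Stable: the same code always maps to the id allocated when first minted;
    ids run sequentially from :data:`LOCAL_CONCEPT_BASE` in first-mint order.
    """
    if not code:
        raise VocabularyError("local concept code must be non-empty")
    existing = resolve_concept(db, LOCAL_VOCABULARY, code)
    if existing is not None:
        return existing
    next_local = db.scalar(
        "SELECT COALESCE(MAX(concept_id), ?) + 1 FROM CONCEPT WHERE is_local = 1",
        (LOCAL_CONCEPT_BASE - 1,),
    )
    with db.conn:
        _ensure_vocabulary(db, LOCAL_VOCABULARY)
        db.execute(
            "INSERT INTO CONCEPT (concept_id, concept_name, domain_id, vocabulary_id,"
            " concept_class_id, standard_concept, concept_code, valid_start_date,"
            " valid_end_date, invalid_reason, is_local)"
            " VALUES (?, ?, ?, ?, ?, NULL, ?, '1970-01-01', '2099-12-31', NULL, 1)",
            (next_local, name, domain, LOCAL_VOCABULARY, concept_class, code),
        )
    return resolve_concept(db, LOCAL_VOCABULARY, code)


# ---------------------------------------------------------------------------
# instrument / item definitions

class ResponseDef(BaseModel):
    """One allowed response of an ordinal or categorical item."""

    raw: str
    label: str
    code: Optional[int] = None  # numeric code; required for ordinal scales
    concept_vocabulary: Optional[str] = None
    concept_code: Optional[str] = None


class ItemDef(BaseModel):
    item_code: str = Field(min_length=1)
    position: int = Field(ge=1)
    prompt: str = ""
    value_type: Literal["ordinal", "numeric", "categorical", "text"]
    responses: list[ResponseDef] = Field(default_factory=list)
    range_min: Optional[float] = None
    range_max: Optional[float] = None
    question_vocabulary: Optional[str] = None
    question_code: Optional[str] = None

    @model_validator(mode="after")
    def _domain_consistency(self) -> "ItemDef":
        if self.value_type in ("ordinal", "categorical"):
            if len(self.responses) < 2:
                raise ValueError(f"{self.item_code}: needs >= 2 allowed values")
            if self.value_type == "ordinal" and any(r.code is None for r in self.responses):
                raise ValueError(f"{self.item_code}: ordinal responses need numeric codes")
        elif self.value_type == "numeric":
            if self.range_min is None or self.range_max is None:
                raise ValueError(f"{self.item_code}: numeric item needs a (min, max) range")
            if self.responses:
                raise ValueError(f"{self.item_code}: numeric item cannot list responses")
        else:  # text
            if self.responses or self.range_min is not None or self.range_max is not None:
                raise ValueError(f"{self.item_code}: text item carries no value domain")
        return self


class InstrumentDef(BaseModel):
    name: str = Field(min_length=1)
    description: str = ""
    items: list[ItemDef]

    @field_validator("items")
    @classmethod
    def _positions_dense(cls, items: list[ItemDef]) -> list[ItemDef]:
        positions = sorted(i.position for i in items)
        if positions != list(range(1, len(items) + 1)):
            raise ValueError(f"position gap or duplicate: positions {positions}")
        codes = [i.item_code for i in items]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate item_code within instrument")
        return items


class InstrumentFile(BaseModel):
    """Top-level layout of an instrument-definition YAML/JSON document."""

    instruments: list[InstrumentDef]


def register_instrument(db: StagingDB, name: str, description: str = "") -> Instrument:
    """Register a screening instrument; duplicate names return the existing row."""
    if not name:
        raise VocabularyError("instrument name must be non-empty")
    row = db.one("SELECT * FROM INSTRUMENT WHERE name = ?", (name,))
    if row is not None:
        return Instrument(row["instrument_id"], row["name"], row["description"] or "")
    iid = db.next_id("INSTRUMENT", "instrument_id")
    with db.conn:
        db.execute(
            "INSERT INTO INSTRUMENT (instrument_id, name, description) VALUES (?, ?, ?)",
            (iid, name, description),
        )
    return Instrument(iid, name, description)


def register_items(
    db: StagingDB,
    instrument: Instrument | int | str,
    items: Sequence[ItemDef] | Sequence[dict],
    mint_missing: bool = True,
) -> int:
    """Register the items of one instrument; returns the number added.

    Question and response concepts are resolved against the loaded vocabulary;
    with ``mint_missing`` (default) unresolved ones are minted as local
    concepts (question code = item code, response code =
    ``<item_code>_RESP_<numeric code or position>``).
    """
    inst = _coerce_instrument(db, instrument)
    defs = [i if isinstance(i, ItemDef) else ItemDef(**i) for i in items]
    InstrumentDef(name=inst.name, description="", items=defs)  # re-check invariants

    added = 0
    for item in sorted(defs, key=lambda i: i.position):
        if db.one(
            "SELECT 1 FROM INSTRUMENT_ITEM WHERE instrument_id = ? AND item_code = ?",
            (inst.instrument_id, item.item_code),
        ):
            continue
        q_concept = _resolve_or_mint(
            db,
            item.question_vocabulary,
            item.question_code,
            fallback_code=item.item_code,
            fallback_name=item.prompt or item.item_code,
            domain="Observation",
            mint_missing=mint_missing,
        )
        allowed = None
        if item.value_type in ("ordinal", "categorical"):
            entries = []
            for pos, resp in enumerate(item.responses):
                v_concept = _resolve_or_mint(
                    db,
                    resp.concept_vocabulary,
                    resp.concept_code,
                    fallback_code=f"{item.item_code}_RESP_{resp.code if resp.code is not None else pos}",
                    fallback_name=resp.label,
                    domain="Meas Value",
                    mint_missing=mint_missing,
                )
                entries.append(
                    {"raw": resp.raw, "code": resp.code, "value_concept_id": v_concept.concept_id}
                )
            allowed = json.dumps(entries)
        item_id = db.next_id("INSTRUMENT_ITEM", "item_id")
        with db.conn:
            db.execute(
                "INSERT INTO INSTRUMENT_ITEM (item_id, instrument_id, item_code, position,"
                " prompt, value_type, question_concept_id, allowed_values, range_min, range_max)"
                " VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?, ?)",
                (
                    item_id,
                    inst.instrument_id,
                    item.item_code,
                    item.position,
                    item.prompt,
                    item.value_type,
                    q_concept.concept_id,
                    allowed,
                    item.range_min,
                    item.range_max,
                ),
            )
        added += 1
    return added


def _resolve_or_mint(
    db: StagingDB,
    vocabulary: Optional[str],
    code: Optional[str],
    fallback_code: str,
    fallback_name: str,
    domain: str,
    mint_missing: bool,
) -> Concept:
    if vocabulary and code:
        found = resolve_concept(db, vocabulary, code)
        if found is not None:
            return found
        if not mint_missing:
            raise VocabularyError(f"unresolved concept ({vocabulary}, {code})")
    local = resolve_concept(db, LOCAL_VOCABULARY, fallback_code)
    if local is not None:
        return local
    if not mint_missing:
        raise VocabularyError(f"unresolved concept for {fallback_code!r} and mint_missing=False")
    return mint_local_concept(db, fallback_code, fallback_name, domain=domain)


def _coerce_instrument(db: StagingDB, instrument: Instrument | int | str) -> Instrument:
    if isinstance(instrument, Instrument):
        return instrument
    col = "instrument_id" if isinstance(instrument, int) else "name"
    row = db.one(f"SELECT * FROM INSTRUMENT WHERE {col} = ?", (instrument,))
    if row is None:
        raise VocabularyError(f"instrument {instrument!r} not registered")
    return Instrument(row["instrument_id"], row["name"], row["description"] or "")


def load_instrument_file(
    db: StagingDB, path: str | Path, mint_missing: bool = True
) -> dict[str, int]:
    """Register every instrument (and its items) in a YAML/JSON definition file.

    Returns a mapping instrument name -> number of items registered this call.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    parsed = InstrumentFile(**doc)
    counts: dict[str, int] = {}
    for inst_def in parsed.instruments:
        inst = register_instrument(db, inst_def.name, inst_def.description)
        counts[inst.name] = register_items(db, inst, inst_def.items, mint_missing=mint_missing)
    return counts


@dataclass(frozen=True)
class ItemRecord:
    """An INSTRUMENT_ITEM row with its decoded allowed-value set."""

    item_id: int
    instrument_id: int
    item_code: str
    position: int
    prompt: str
    value_type: str
    question_concept_id: int
    allowed_values: tuple[dict, ...]
    range_min: Optional[float]
    range_max: Optional[float]


def get_items(db: StagingDB, instrument: Instrument | int | str) -> list[ItemRecord]:
    inst = _coerce_instrument(db, instrument)
    rows = db.query(
        "SELECT * FROM INSTRUMENT_ITEM WHERE instrument_id = ? ORDER BY position",
        (inst.instrument_id,),
    )
    return [
        ItemRecord(
            item_id=r["item_id"],
            instrument_id=r["instrument_id"],
            item_code=r["item_code"],
            position=r["position"],
            prompt=r["prompt"] or "",
            value_type=r["value_type"],
            question_concept_id=r["question_concept_id"],
            allowed_values=tuple(json.loads(r["allowed_values"]) if r["allowed_values"] else ()),
            range_min=r["range_min"],
            range_max=r["range_max"],
        )
        for r in rows
    ]
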