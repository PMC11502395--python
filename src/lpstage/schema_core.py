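"""Relational snowflake schema for the longitudinal-population-study staging database.

The staging store is a snowflake schema: a central fact table
(``LONGITUDINAL_POPULATION_STUDY_FACT``, one row per item response in one
interview) surrounded by normalized dimension tables for the concept
vocabulary, study metadata, and the surveyed population.  Sixteen tables in
total; every primary and foreign key column is indexed.

The reference backend is an embedded single-file SQLite database accessed
through :class:`StagingDB`.  All DDL is ANSI-compatible; surrogate integer
primary keys are allocated by the package (``MAX(pk)+1`` inside the write
transaction) so that repeated runs from the same inputs produce identical
key assignments.  Dates are stored as ISO-8601 text, timezone-naive;
residence intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "StagingDB",
    "SchemaReport",
    "SchemaError",
    "TABLES",
    "create_schema",
    "reset_schema",
    "ddl_statements",
]


class SchemaError(RuntimeError):
    """Raised for schema lifecycle errors (already present / absent / bad dialect)."""


#: The sixteen staging tables, in dependency (creation) order.
TABLES: tuple[str, ...] = (
    "VOCABULARY",
    "CONCEPT",
    "INSTRUMENT",
    "INSTRUMENT_ITEM",
    "POPULATION_STUDY",
    "METHODOLOGY",
    "WAVE",
    "DATA_CAPTURE_EVENT",
    "LOCATION",
    "INDIVIDUAL",
    "INDIVIDUAL_DEMOGRAPHICS",
    "HOUSEHOLD",
    "HOUSEHOLD_CHARACTERISTICS",
    "RESIDENT_EPISODE",
    "INTERVIEW",
    "LONGITUDINAL_POPULATION_STUDY_FACT",
)

# Exactly one of value_as_concept_id / value_as_number / value_as_text may be
# populated in the entity-attribute-value dimensions; the fact table requires
# at least one populated slot.
_ONE_VALUE_CHECK = (
    "((value_as_concept_id IS NOT NULL) + (value_as_number IS NOT NULL)"
    " + (value_as_text IS NOT NULL)) = 1"
)

_DDL: dict[str, str] = {
    "VOCABULARY": """
        CREATE TABLE VOCABULARY (
            vocabulary_id   TEXT PRIMARY KEY,
            vocabulary_name TEXT NOT NULL
        )""",
    "CONCEPT": """
        CREATE TABLE CONCEPT (
            concept_id       INTEGER PRIMARY KEY,
            concept_name     TEXT NOT NULL,
            domain_id        TEXT NOT NULL,
            vocabulary_id    TEXT NOT NULL REFERENCES VOCABULARY(vocabulary_id),
            concept_class_id TEXT NOT NULL,
            standard_concept TEXT,
            concept_code     TEXT NOT NULL,
            valid_start_date TEXT NOT NULL,
            valid_end_date   TEXT NOT NULL,
            invalid_reason   TEXT,
            is_local         INTEGER NOT NULL CHECK (is_local IN (0, 1)),
            UNIQUE (vocabulary_id, concept_code),
            CHECK (valid_start_date <= valid_end_date),
            CHECK ((is_local = 1) = (concept_id >= 2000000000)),
            CHECK ((is_local = 1) = (vocabulary_id = 'INSPIRE'))
        )""",
    "INSTRUMENT": """
        CREATE TABLE INSTRUMENT (
            instrument_id INTEGER PRIMARY KEY,
            name          TEXT NOT NULL UNIQUE CHECK (name <> ''),
            description   TEXT
        )""",
    "INSTRUMENT_ITEM": """
        CREATE TABLE INSTRUMENT_ITEM (
            item_id             INTEGER PRIMARY KEY,
            instrument_id       INTEGER NOT NULL REFERENCES INSTRUMENT(instrument_id),
            item_code           TEXT NOT NULL,
            position            INTEGER NOT NULL CHECK (position >= 1),
            prompt              TEXT,
            value_type          TEXT NOT NULL
                CHECK (value_type IN ('ordinal', 'numeric', 'categorical', 'text')),
            question_concept_id INTEGER NOT NULL REFERENCES CONCEPT(concept_id),
            allowed_values      TEXT,
            range_min           REAL,
            range_max           REAL,
            UNIQUE (instrument_id, item_code),
            UNIQUE (instrument_id, position)
        )""",
    "POPULATION_STUDY": """
        CREATE TABLE POPULATION_STUDY (
            study_id    INTEGER PRIMARY KEY,
            title       TEXT NOT NULL UNIQUE CHECK (title <> ''),
            description TEXT,
            site        TEXT
        )""",
    "METHODOLOGY": """
        CREATE TABLE METHODOLOGY (
            methodology_id INTEGER PRIMARY KEY,
            study_id       INTEGER NOT NULL REFERENCES POPULATION_STUDY(study_id),
            design         TEXT,
            sampling       TEXT
        )""",
    "WAVE": """
        CREATE TABLE WAVE (
            wave_id               INTEGER PRIMARY KEY,
            study_id              INTEGER NOT NULL REFERENCES POPULATION_STUDY(study_id),
            label                 TEXT NOT NULL,
            start_date            TEXT NOT NULL,
            end_date              TEXT NOT NULL,
            instrument_model_type TEXT NOT NULL,
            UNIQUE (study_id, label),
            CHECK (start_date <= end_date)
        )""",
    "DATA_CAPTURE_EVENT": """
        CREATE TABLE DATA_CAPTURE_EVENT (
            event_id   INTEGER PRIMARY KEY,
            wave_id    INTEGER NOT NULL REFERENCES WAVE(wave_id),
            mode       TEXT NOT NULL CHECK (mode IN
                ('face-to-face', 'telephone', 'self-administered', 'other')),
            start_date TEXT NOT NULL,
            end_date   TEXT NOT NULL,
            CHECK (start_date <= end_date)
        )""",
    "LOCATION": """
        CREATE TABLE LOCATION (
            location_id INTEGER PRIMARY KEY,
            name        TEXT NOT NULL,
            latitude    REAL NOT NULL CHECK (latitude BETWEEN -90 AND 90),
            longitude   REAL NOT NULL CHECK (longitude BETWEEN -180 AND 180),
            UNIQUE (name, latitude, longitude)
        )""",
    "INDIVIDUAL": """
        CREATE TABLE INDIVIDUAL (
            individual_id INTEGER PRIMARY KEY,
            external_id   TEXT NOT NULL UNIQUE CHECK (external_id <> '')
        )""",
    "INDIVIDUAL_DEMOGRAPHICS": """
        CREATE TABLE INDIVIDUAL_DEMOGRAPHICS (
            individual_id        INTEGER NOT NULL REFERENCES INDIVIDUAL(individual_id),
            parameter_concept_id INTEGER NOT NULL REFERENCES CONCEPT(concept_id),
            value_as_concept_id  INTEGER REFERENCES CONCEPT(concept_id),
            value_as_number      REAL,
            value_as_text        TEXT,
            observed_on          TEXT NOT NULL,
            CHECK (%s)
        )""" % _ONE_VALUE_CHECK,
    "HOUSEHOLD": """
        CREATE TABLE HOUSEHOLD (
            household_id INTEGER PRIMARY KEY,
            external_id  TEXT NOT NULL UNIQUE CHECK (external_id <> ''),
            location_id  INTEGER NOT NULL REFERENCES LOCATION(location_id)
        )""",
    "HOUSEHOLD_CHARACTERISTICS": """
        CREATE TABLE HOUSEHOLD_CHARACTERISTICS (
            household_id         INTEGER NOT NULL REFERENCES HOUSEHOLD(household_id),
            parameter_concept_id INTEGER NOT NULL REFERENCES CONCEPT(concept_id),
            value_as_concept_id  INTEGER REFERENCES CONCEPT(concept_id),
            value_as_number      REAL,
            value_as_text        TEXT,
            observed_on          TEXT NOT NULL,
            CHECK (%s)
        )""" % _ONE_VALUE_CHECK,
    "RESIDENT_EPISODE": """
        CREATE TABLE RESIDENT_EPISODE (
            episode_id    INTEGER PRIMARY KEY,
            individual_id INTEGER NOT NULL REFERENCES INDIVIDUAL(individual_id),
            household_id  INTEGER NOT NULL REFERENCES HOUSEHOLD(household_id),
            wave_id       INTEGER NOT NULL REFERENCES WAVE(wave_id),
            start_date    TEXT NOT NULL,
            end_date      TEXT,
            end_reason    TEXT CHECK (end_reason IS NULL OR end_reason IN
                ('out-migration', 'death', 'study-end', 'unknown')),
            CHECK (end_date IS NULL OR start_date < end_date)
        )""",
    "INTERVIEW": """
        CREATE TABLE INTERVIEW (
            interview_id      INTEGER PRIMARY KEY,
            individual_id     INTEGER NOT NULL REFERENCES INDIVIDUAL(individual_id),
            wave_id           INTEGER NOT NULL REFERENCES WAVE(wave_id),
            instrument_id     INTEGER NOT NULL REFERENCES INSTRUMENT(instrument_id),
            interview_date    TEXT NOT NULL,
            date_approximated INTEGER NOT NULL DEFAULT 0
                CHECK (date_approximated IN (0, 1)),
            UNIQUE (individual_id, wave_id, instrument_id)
        )""",
    "LONGITUDINAL_POPULATION_STUDY_FACT": """
        CREATE TABLE LONGITUDINAL_POPULATION_STUDY_FACT (
            fact_id               INTEGER PRIMARY KEY,
            study_id              INTEGER NOT NULL REFERENCES POPULATION_STUDY(study_id),
            individual_id         INTEGER NOT NULL REFERENCES INDIVIDUAL(individual_id),
            interview_id          INTEGER NOT NULL REFERENCES INTERVIEW(interview_id),
            episode_id            INTEGER NOT NULL REFERENCES RESIDENT_EPISODE(episode_id),
            instrument_item_id    INTEGER NOT NULL REFERENCES INSTRUMENT_ITEM(item_id),
            question_concept_id   INTEGER NOT NULL REFERENCES CONCEPT(concept_id),
            value_as_number       REAL,
            value_as_concept_id   INTEGER REFERENCES CONCEPT(concept_id),
            value_as_text         TEXT,
            value_type_concept_id INTEGER NOT NULL REFERENCES CONCEPT(concept_id),
            CHECK (value_as_number IS NOT NULL OR value_as_concept_id IS NOT NULL
                   OR value_as_text IS NOT NULL)
        )""",
}

# Natural-key uniqueness enforced through named unique indexes (declared
# separately from the table DDL so quality tooling can address them).
_UNIQUE_INDEXES: tuple[tuple[str, str, str], ...] = (
    (
        "uq_demographics_natural",
        "INDIVIDUAL_DEMOGRAPHICS",
        "individual_id, parameter_concept_id, observed_on",
    ),
    (
        "uq_hh_characteristics_natural",
        "HOUSEHOLD_CHARACTERISTICS",
        "household_id, parameter_concept_id, observed_on",
    ),
    (
        "uq_fact_interview_item",
        "LONGITUDINAL_POPULATION_STUDY_FACT",
        "interview_id, instrument_item_id",
    ),
)

# Explicit secondary indexes on every foreign-key column (primary keys are
# indexed implicitly by the storage engine).
_INDEXES: tuple[tuple[str, str, str], ...] = (
    ("idx_concept_vocabulary", "CONCEPT", "vocabulary_id"),
    ("idx_item_instrument", "INSTRUMENT_ITEM", "instrument_id"),
    ("idx_item_question_concept", "INSTRUMENT_ITEM", "question_concept_id"),
    ("idx_methodology_study", "METHODOLOGY", "study_id"),
    ("idx_wave_study", "WAVE", "study_id"),
    ("idx_event_wave", "DATA_CAPTURE_EVENT", "wave_id"),
    ("idx_demog_individual", "INDIVIDUAL_DEMOGRAPHICS", "individual_id"),
    ("idx_demog_parameter", "INDIVIDUAL_DEMOGRAPHICS", "parameter_concept_id"),
    ("idx_household_location", "HOUSEHOLD", "location_id"),
    ("idx_hhchar_household", "HOUSEHOLD_CHARACTERISTICS", "household_id"),
    ("idx_hhchar_parameter", "HOUSEHOLD_CHARACTERISTICS", "parameter_concept_id"),
    ("idx_episode_individual", "RESIDENT_EPISODE", "individual_id"),
    ("idx_episode_household", "RESIDENT_EPISODE", "household_id"),
    ("idx_episode_wave", "RESIDENT_EPISODE", "wave_id"),
    ("idx_interview_individual", "INTERVIEW", "individual_id"),
    ("idx_interview_wave", "INTERVIEW", "wave_id"),
    ("idx_interview_instrument", "INTERVIEW", "instrument_id"),
    ("idx_fact_study", "LONGITUDINAL_POPULATION_STUDY_FACT", "study_id"),
    ("idx_fact_individual", "LONGITUDINAL_POPULATION_STUDY_FACT", "individual_id"),
    ("idx_fact_interview", "LONGITUDINAL_POPULATION_STUDY_FACT", "interview_id"),
    ("idx_fact_episode", "LONGITUDINAL_POPULATION_STUDY_FACT", "episode_id"),
    ("idx_fact_item", "LONGITUDINAL_POPULATION_STUDY_FACT", "instrument_item_id"),
    ("idx_fact_question", "LONGITUDINAL_POPULATION_STUDY_FACT", "question_concept_id"),
    ("idx_fact_value_concept", "LONGITUDINAL_POPULATION_STUDY_FACT", "value_as_concept_id"),
    ("idx_fact_value_type", "LONGITUDINAL_POPULATION_STUDY_FACT", "value_type_concept_id"),
)

SUPPORTED_DIALECTS = ("sqlite",)


@dataclass
class SchemaReport:
    """Outcome of a schema create/reset call."""

    created_tables: list[str] = field(default_factory=list)
    created_indexes: int = 0
    dialect: str = "sqlite"
    pre_existing_tables: list[str] = field(default_factory=list)


def ddl_statements(dialect: str = "sqlite") -> list[str]:
    """Return the full DDL (tables then indexes) as plain SQL text statements."""
    if dialect not in SUPPORTED_DIALECTS:
        raise SchemaError(f"unsupported dialect {dialect!r}; supported: {SUPPORTED_DIALECTS}")
    stmts = [_DDL[t].strip() for t in TABLES]
    stmts += [
        f"CREATE UNIQUE INDEX {name} ON {table} ({cols})" for name, table, cols in _UNIQUE_INDEXES
    ]
    stmts += [f"CREATE INDEX {name} ON {table} ({col})" for name, table, col in _INDEXES]
    return stmts


class StagingDB:
    """Connection to one staging database file.

    Thin wrapper over :mod:`sqlite3` that turns foreign-key enforcement on,
    exposes query helpers, and allocates surrogate primary keys.
    """

    def __init__(self, path: str | Path):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.execute("PRAGMA foreign_keys = ON")
        # staging-database durability profile: contents are reproducible from
        # the sources, so trade fsync guarantees for load throughput
        self.conn.execute("PRAGMA synchronous = OFF")
        self.conn.execute("PRAGMA journal_mode = MEMORY")

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "StagingDB":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- query helpers -----------------------------------------------------

    def execute(self, sql: str, params: Sequence = ()) -> sqlite3.Cursor:
        return self.conn.execute(sql, params)

    def executemany(self, sql: str, rows: Iterable[Sequence]) -> sqlite3.Cursor:
        return self.conn.executemany(sql, rows)

    def query(self, sql: str, params: Sequence = ()) -> list[sqlite3.Row]:
        return self.conn.execute(sql, params).fetchall()

    def one(self, sql: str, params: Sequence = ()) -> sqlite3.Row | None:
        return self.conn.execute(sql, params).fetchone()

    def scalar(self, sql: str, params: Sequence = ()):
        row = self.one(sql, params)
        return None if row is None else row[0]

    def commit(self) -> None:
        self.conn.commit()

    def table_names(self) -> list[str]:
        rows = self.query(
            "SELECT name FROM sqlite_master WHERE type = 'table' AND name NOT LIKE 'sqlite_%'"
        )
        return [r["name"] for r in rows]

    def count(self, table: str) -> int:
        if table not in TABLES:
            raise ValueError(f"unknown staging table {table!r}")
        return self.scalar(f"SELECT COUNT(*) FROM {table}")

    def next_id(self, table: str, pk: str) -> int:
        """Package-side surrogate key allocation: MAX+1, starting at 1."""
        return (self.scalar(f"SELECT COALESCE(MAX({pk}), 0) FROM {table}") or 0) + 1

    def has_schema(self) -> bool:
        existing = set(self.table_names())
        return any(t in existing for t in TABLES)


def create_schema(
    target: str | Path | StagingDB,
    dialect: str = "sqlite",
    if_exists: str = "error",
) -> SchemaReport:
    """Create all 16 staging tables plus their indexes on *target*.

    ``if_exists`` controls behaviour when staging tables are already present:
    ``error`` raises, ``skip`` creates nothing and reports the tables as
    pre-existing, ``reset`` drops and recreates everything.
    """
    if dialect not in SUPPORTED_DIALECTS:
        raise SchemaError(f"unsupported dialect {dialect!r}; supported: {SUPPORTED_DIALECTS}")
    if if_exists not in ("error", "skip", "reset"):
        raise ValueError(f"if_exists must be error|skip|reset, got {if_exists!r}")

    db = target if isinstance(target, StagingDB) else StagingDB(target)
    existing = set(db.table_names()) & set(TABLES)

    if existing:
        if if_exists == "error":
            raise SchemaError(f"schema already present ({len(existing)} staging tables exist)")
        if if_exists == "skip":
            return SchemaReport(
                created_tables=[],
                created_indexes=0,
                dialect=dialect,
                pre_existing_tables=[t for t in TABLES if t in existing],
            )
        _drop_all(db)

    created = []
    with db.conn:
        for table in TABLES:
            db.execute(_DDL[table])
            created.append(table)
        for name, table, cols in _UNIQUE_INDEXES:
            db.execute(f"CREATE UNIQUE INDEX {name} ON {table} ({cols})")
        for name, table, col in _INDEXES:
            db.execute(f"CREATE INDEX {name} ON {table} ({col})")
    return SchemaReport(
        created_tables=created,
        created_indexes=len(_INDEXES) + len(_UNIQUE_INDEXES),
        dialect=dialect,
    )


def reset_schema(target: str | Path | StagingDB) -> SchemaReport:
    """Drop and recreate the staging schema; every table ends up empty."""
    db = target if isinstance(target, StagingDB) else StagingDB(target)
    if not db.has_schema():
        raise SchemaError("schema absent; nothing to reset")
    return create_schema(db, if_exists="reset")


def _drop_all(db: StagingDB) -> None:
    with db.conn:
        db.execute("PRAGMA foreign_keys = OFF")
        for table in reversed(TABLES):
            db.execute(f"DROP TABLE IF EXISTS {table}")
    db.execute("PRAGMA foreign_keys = ON")
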