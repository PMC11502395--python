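"""Population dimensions: individuals, demographics, locations, households,
household characteristics, resident episodes, and interviews.

Resident episodes are the temporal backbone of the design (the HDSS view of a
population: people join households, move between them, and leave the study
area).  Episodes are half-open intervals ``[start, end)``; per individual they
never overlap and at most one is open.  Opening a new episode automatically
closes any open one at the new start date with reason ``out-migration``.

Interviews are one administration of one instrument to one individual in one
wave.  When the field record has no interview date — a routine gap in
longitudinal collections — the date is approximated as the wave midpoint
(start + floor(span-in-days / 2)) and flagged ``date_approximated``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional

import pandas as pd

from .schema_core import StagingDB
from .study_metadata import Wave, _wave_from_row
from .vocabulary import Concept, mint_local_concept, resolve_concept

__all__ = [
    "Individual",
    "Household",
    "ResidentEpisode",
    "Interview",
    "PopulationError",
    "upsert_individual",
    "record_demographic",
    "upsert_household",
    "open_episode",
    "close_episode",
    "record_interview",
    "wave_midpoint",
    "episode_covering",
    "load_rosters",
]

END_REASONS = ("out-migration", "death", "study-end", "unknown")


class PopulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Individual:
    individual_id: int
    external_id: str


@dataclass(frozen=True)
class Household:
    household_id: int
    external_id: str
    location_id: int


@dataclass(frozen=True)
class ResidentEpisode:
    episode_id: int
    individual_id: int
    household_id: int
    wave_id: int
    start_date: date
    end_date: Optional[date]
    end_reason: Optional[str]


@dataclass(frozen=True)
class Interview:
    interview_id: int
    individual_id: int
    wave_id: int
    instrument_id: int
    interview_date: date
    date_approximated: bool


def _as_date(value: date | str) -> date:
    return value if isinstance(value, date) else date.fromisoformat(value)


def wave_midpoint(start: date, end: date) -> date:
    """Date-approximation rule: start + floor(days(start..end) / 2)."""
    return start + timedelta(days=(end - start).days // 2)


# ---------------------------------------------------------------------------
# individuals & demographics

def upsert_individual(db: StagingDB, external_id: str) -> Individual:
    if not external_id:
        raise PopulationError("external_id must be non-empty")
    row = db.one("SELECT * FROM INDIVIDUAL WHERE external_id = ?", (external_id,))
    if row is not None:
        return Individual(row["individual_id"], row["external_id"])
    iid = db.next_id("INDIVIDUAL", "individual_id")
    with db.conn:
        db.execute(
            "INSERT INTO INDIVIDUAL (individual_id, external_id) VALUES (?, ?)",
            (iid, external_id),
        )
    return Individual(iid, external_id)


def _resolve_parameter(db: StagingDB, parameter: Concept | int | str, mint: bool) -> int:
    if isinstance(parameter, Concept):
        return parameter.concept_id
    if isinstance(parameter, int):
        return parameter
    found = resolve_concept(db, "INSPIRE", parameter)
    if found is not None:
        return found.concept_id
    if not mint:
        raise PopulationError(f"parameter {parameter!r} does not resolve to a concept")
    return mint_local_concept(db, parameter, parameter, domain="Observation").concept_id


def record_demographic(
    db: StagingDB,
    individual: Individual | int,
    parameter: Concept | int | str,
    observed_on: date | str,
    value_concept: Concept | int | None = None,
    value_number: float | None = None,
    value_text: str | None = None,
    mint_parameter: bool = True,
) -> int:
    """Attach one demographic parameter/value pair; returns rows inserted (0|1).

    Exactly one of the three value slots must be given; replaying the same
    (individual, parameter, observed_on) record inserts nothing.
    """
    return _record_attribute(
        db, "INDIVIDUAL_DEMOGRAPHICS", "individual_id",
        individual.individual_id if isinstance(individual, Individual) else individual,
        parameter, observed_on, value_concept, value_number, value_text, mint_parameter,
    )


def record_household_characteristic(
    db: StagingDB,
    household: "Household | int",
    parameter: Concept | int | str,
    observed_on: date | str,
    value_concept: Concept | int | None = None,
    value_number: float | None = None,
    value_text: str | None = None,
    mint_parameter: bool = True,
) -> int:
    return _record_attribute(
        db, "HOUSEHOLD_CHARACTERISTICS", "household_id",
        household.household_id if isinstance(household, Household) else household,
        parameter, observed_on, value_concept, value_number, value_text, mint_parameter,
    )


def _record_attribute(
    db, table, entity_col, entity_id, parameter, observed_on,
    value_concept, value_number, value_text, mint_parameter,
) -> int:
    slots = [value_concept is not None, value_number is not None, value_text is not None]
    if sum(slots) != 1:
        raise PopulationError("exactly one of value_concept / value_number / value_text required")
    pid = _resolve_parameter(db, parameter, mint_parameter)
    vcid = value_concept.concept_id if isinstance(value_concept, Concept) else value_concept
    when = _as_date(observed_on).isoformat()
    exists = db.one(
        f"SELECT 1 FROM {table} WHERE {entity_col} = ? AND parameter_concept_id = ?"
        " AND observed_on = ?",
        (entity_id, pid, when),
    )
    if exists is not None:
        return 0
    with db.conn:
        db.execute(
            f"INSERT INTO {table} ({entity_col}, parameter_concept_id, value_as_concept_id,"
            " value_as_number, value_as_text, observed_on) VALUES (?, ?, ?, ?, ?, ?)",
            (entity_id, pid, vcid, value_number, value_text, when),
        )
    return 1


# ---------------------------------------------------------------------------
# households & locations

def upsert_household(
    db: StagingDB, external_id: str, location: dict | None = None
) -> Household:
    """Upsert a household on its external id; the location row is shared when
    an identical (name, lat, lon) triple already exists."""
    if not external_id:
        raise PopulationError("household external_id must be non-empty")
    row = db.one("SELECT * FROM HOUSEHOLD WHERE external_id = ?", (external_id,))
    if row is not None:
        return Household(row["household_id"], row["external_id"], row["location_id"])
    loc = location or {"name": "unknown", "lat": 0.0, "lon": 0.0}
    lat, lon = float(loc["lat"]), float(loc["lon"])
    if not -90 <= lat <= 90:
        raise PopulationError(f"latitude {lat} out of bounds [-90, 90]")
    if not -180 <= lon <= 180:
        raise PopulationError(f"longitude {lon} out of bounds [-180, 180]")
    lrow = db.one(
        "SELECT location_id FROM LOCATION WHERE name = ? AND latitude = ? AND longitude = ?",
        (loc["name"], lat, lon),
    )
    with db.conn:
        if lrow is None:
            location_id = db.next_id("LOCATION", "location_id")
            db.execute(
                "INSERT INTO LOCATION (location_id, name, latitude, longitude) VALUES (?, ?, ?, ?)",
                (location_id, loc["name"], lat, lon),
            )
        else:
            location_id = lrow["location_id"]
        hid = db.next_id("HOUSEHOLD", "household_id")
        db.execute(
            "INSERT INTO HOUSEHOLD (household_id, external_id, location_id) VALUES (?, ?, ?)",
            (hid, external_id, location_id),
        )
    return Household(hid, external_id, location_id)


# ---------------------------------------------------------------------------
# resident episodes

def _episode_from_row(row) -> ResidentEpisode:
    return ResidentEpisode(
        row["episode_id"],
        row["individual_id"],
        row["household_id"],
        row["wave_id"],
        date.fromisoformat(row["start_date"]),
        date.fromisoformat(row["end_date"]) if row["end_date"] else None,
        row["end_reason"],
    )


def _open_episode_row(db: StagingDB, individual_id: int):
    return db.one(
        "SELECT * FROM RESIDENT_EPISODE WHERE individual_id = ? AND end_date IS NULL",
        (individual_id,),
    )


def open_episode(
    db: StagingDB,
    individual: Individual | int,
    household: Household | int,
    wave: Wave | int,
    start_date: date | str,
) -> ResidentEpisode:
    """Open a residence episode; any open episode of the individual is closed
    at the new start with reason ``out-migration`` (auto-close on move)."""
    iid = individual.individual_id if isinstance(individual, Individual) else individual
    hid = household.household_id if isinstance(household, Household) else household
    wid = wave.wave_id if isinstance(wave, Wave) else wave
    start = _as_date(start_date)

    current = _open_episode_row(db, iid)
    with db.conn:
        if current is not None:
            open_start = date.fromisoformat(current["start_date"])
            if start <= open_start:
                raise PopulationError(
                    f"start {start} precedes open episode start {open_start}"
                )
            db.execute(
                "UPDATE RESIDENT_EPISODE SET end_date = ?, end_reason = 'out-migration'"
                " WHERE episode_id = ?",
                (start.isoformat(), current["episode_id"]),
            )
        eid = db.next_id("RESIDENT_EPISODE", "episode_id")
        db.execute(
            "INSERT INTO RESIDENT_EPISODE (episode_id, individual_id, household_id, wave_id,"
            " start_date, end_date, end_reason) VALUES (?, ?, ?, ?, ?, NULL, NULL)",
            (eid, iid, hid, wid, start.isoformat()),
        )
    return ResidentEpisode(eid, iid, hid, wid, start, None, None)


def close_episode(
    db: StagingDB,
    individual: Individual | int,
    end_date: date | str,
    end_reason: str = "unknown",
) -> ResidentEpisode:
    iid = individual.individual_id if isinstance(individual, Individual) else individual
    if end_reason not in END_REASONS:
        raise PopulationError(f"end_reason must be one of {END_REASONS}")
    current = _open_episode_row(db, iid)
    if current is None:
        raise PopulationError(f"individual {iid} has no open episode")
    end = _as_date(end_date)
    start = date.fromisoformat(current["start_date"])
    if end <= start:
        raise PopulationError(f"end {end} must follow start {start} (half-open, non-empty)")
    with db.conn:
        db.execute(
            "UPDATE RESIDENT_EPISODE SET end_date = ?, end_reason = ? WHERE episode_id = ?",
            (end.isoformat(), end_reason, current["episode_id"]),
        )
    return _episode_from_row(
        db.one("SELECT * FROM RESIDENT_EPISODE WHERE episode_id = ?", (current["episode_id"],))
    )


def episode_covering(
    db: StagingDB, individual_id: int, on: date
) -> Optional[ResidentEpisode]:
    """The episode whose half-open interval contains *on*, if any."""
    row = db.one(
        "SELECT * FROM RESIDENT_EPISODE WHERE individual_id = ? AND start_date <= ?"
        " AND (end_date IS NULL OR end_date > ?) ORDER BY start_date DESC LIMIT 1",
        (individual_id, on.isoformat(), on.isoformat()),
    )
    return None if row is None else _episode_from_row(row)


# ---------------------------------------------------------------------------
# interviews

def record_interview(
    db: StagingDB,
    individual: Individual | int,
    wave: Wave | int,
    instrument: int | str,
    interview_date: date | str | None = None,
    on_no_episode: str = "error",
) -> Interview:
    """Record one administration of one instrument in one wave.

    A missing date is approximated as the wave midpoint and flagged.  The
    individual must hold an episode overlapping the wave; with
    ``on_no_episode="warn"`` that requirement is relaxed to a load-time
    warning.  Duplicate (individual, wave, instrument) returns the existing
    interview.
    """
    iid = individual.individual_id if isinstance(individual, Individual) else individual
    wid = wave.wave_id if isinstance(wave, Wave) else wave
    wrow = db.one("SELECT * FROM WAVE WHERE wave_id = ?", (wid,))
    if wrow is None:
        raise PopulationError(f"wave {wid} not registered")
    wave_obj = _wave_from_row(wrow)

    if isinstance(instrument, str):
        irow = db.one("SELECT instrument_id FROM INSTRUMENT WHERE name = ?", (instrument,))
        if irow is None:
            raise PopulationError(f"instrument {instrument!r} not registered")
        instrument_id = irow["instrument_id"]
    else:
        instrument_id = instrument

    existing = db.one(
        "SELECT * FROM INTERVIEW WHERE individual_id = ? AND wave_id = ? AND instrument_id = ?",
        (iid, wid, instrument_id),
    )
    if existing is not None:
        return Interview(
            existing["interview_id"], iid, wid, instrument_id,
            date.fromisoformat(existing["interview_date"]), bool(existing["date_approximated"]),
        )

    if interview_date is None:
        when = wave_midpoint(wave_obj.start_date, wave_obj.end_date)
        approximated = True
    else:
        when = _as_date(interview_date)
        approximated = False
        if not (wave_obj.start_date <= when <= wave_obj.end_date):
            raise PopulationError(
                f"interview date {when} outside wave {wave_obj.label!r}"
                f" [{wave_obj.start_date}, {wave_obj.end_date}]"
            )

    overlap = db.one(
        "SELECT 1 FROM RESIDENT_EPISODE WHERE individual_id = ? AND start_date <= ?"
        " AND (end_date IS NULL OR end_date > ?)",
        (iid, wave_obj.end_date.isoformat(), wave_obj.start_date.isoformat()),
    )
    if overlap is None:
        if on_no_episode == "error":
            raise PopulationError(
                f"individual {iid} has no resident episode overlapping wave {wave_obj.label!r}"
            )
        # warn-and-load: accepted, surfaced later by the temporal validator

    interview_id = db.next_id("INTERVIEW", "interview_id")
    with db.conn:
        db.execute(
            "INSERT INTO INTERVIEW (interview_id, individual_id, wave_id, instrument_id,"
            " interview_date, date_approximated) VALUES (?, ?, ?, ?, ?, ?)",
            (interview_id, iid, wid, instrument_id, when.isoformat(), int(approximated)),
        )
    return Interview(interview_id, iid, wid, instrument_id, when, approximated)


# ---------------------------------------------------------------------------
# roster CSV ingest

def load_rosters(
    db: StagingDB,
    individuals_csv: str | Path,
    households_csv: str | Path,
    study_waves: list[Wave],
) -> dict[str, int]:
    """Ingest the roster pair (households.csv then individuals.csv).

    ``individuals.csv`` holds one row per resident episode (columns
    external_id, sex, birth_year, household_external_id, residence_start,
    residence_end); episodes of one individual must appear in start order.
    The episode's wave is the first study wave whose interval contains the
    episode start (falling back to the first wave).  Replaying the same pair
    leaves all row counts unchanged.
    """
    counts = {"households": 0, "individuals": 0, "episodes": 0, "demographics": 0}
    hh = pd.read_csv(households_csv, dtype=str)
    for rec in hh.itertuples(index=False):
        before = db.count("HOUSEHOLD")
        upsert_household(
            db,
            rec.external_id,
            {"name": rec.location_name, "lat": float(rec.latitude), "lon": float(rec.longitude)},
        )
        counts["households"] += db.count("HOUSEHOLD") - before

    if not study_waves:
        raise PopulationError("at least one wave must be registered before roster ingest")

    def wave_for(start: date) -> Wave:
        for w in study_waves:
            if w.start_date <= start <= w.end_date:
                return w
        return study_waves[0]

    ind = pd.read_csv(individuals_csv, dtype=str)
    for rec in ind.itertuples(index=False):
        before_i = db.count("INDIVIDUAL")
        person = upsert_individual(db, rec.external_id)
        counts["individuals"] += db.count("INDIVIDUAL") - before_i

        start = date.fromisoformat(rec.residence_start)
        end = (
            None
            if pd.isna(rec.residence_end) or rec.residence_end in ("", None)
            else date.fromisoformat(rec.residence_end)
        )
        household = db.one(
            "SELECT household_id FROM HOUSEHOLD WHERE external_id = ?",
            (rec.household_external_id,),
        )
        if household is None:
            raise PopulationError(f"unknown household {rec.household_external_id!r} in roster")
        dup = db.one(
            "SELECT 1 FROM RESIDENT_EPISODE WHERE individual_id = ? AND household_id = ?"
            " AND start_date = ?",
            (person.individual_id, household["household_id"], start.isoformat()),
        )
        if dup is None:
            open_episode(db, person, household["household_id"], wave_for(start).wave_id, start)
            if end is not None:
                close_episode(db, person, end, "out-migration")
            counts["episodes"] += 1

        # demographics are constant per individual in the roster layout:
        # record them once (at first residence), not per episode row
        observed_row = db.one(
            "SELECT MIN(observed_on) AS first FROM INDIVIDUAL_DEMOGRAPHICS WHERE individual_id = ?",
            (person.individual_id,),
        )
        observed = (
            date.fromisoformat(observed_row["first"])
            if observed_row is not None and observed_row["first"]
            else start
        )
        if not pd.isna(rec.sex) and rec.sex:
            sex_concept = resolve_concept(db, "Gender", rec.sex.upper()[:1])
            counts["demographics"] += record_demographic(
                db, person, "sex", observed,
                value_concept=sex_concept.concept_id if sex_concept else None,
                value_text=None if sex_concept else rec.sex,
            )
        if not pd.isna(rec.birth_year) and rec.birth_year:
            counts["demographics"] += record_demographic(
                db, person, "birth_year", observed, value_number=float(rec.birth_year)
            )
    return counts
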