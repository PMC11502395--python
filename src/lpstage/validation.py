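"""Executable quality checks over a populated staging database.

Four read-only checkers cover the staging-quality concerns of the design:
referential integrity (every foreign key resolves), temporal consistency
(interviews inside waves and resident episodes, episodes non-overlapping,
capture events inside waves), fact-value validity (value slots populated and
inside the item's declared domain), and a normalization audit (the redundancy
classes 3NF is meant to preclude).  Checkers enumerate *all* violations, not
the first, and never repair anything.

Output order is (check, table, key) lexicographic so reports diff stably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .schema_core import TABLES, StagingDB
from .vocabulary import LOCAL_VOCABULARY

__all__ = [
    "Violation",
    "SummaryReport",
    "check_referential_integrity",
    "check_temporal_consistency",
    "check_fact_values",
    "audit_normalization",
    "run_all_checks",
    "summary_report",
]


@dataclass(frozen=True, order=True)
class Violation:
    check: str
    table: str
    row_ref: str
    detail: str


def _sorted(violations: list[Violation]) -> list[Violation]:
    return sorted(violations)


def check_referential_integrity(db: StagingDB) -> list[Violation]:
    """Every declared foreign key must resolve; enumerates all danglers."""
    out = []
    for row in db.query("PRAGMA foreign_key_check"):
        out.append(
            Violation(
                check="referential_integrity",
                table=row[0],
                row_ref=str(row[1]),
                detail=f"dangling foreign key into {row[2]} (fk #{row[3]})",
            )
        )
    return _sorted(out)


def check_temporal_consistency(db: StagingDB) -> list[Violation]:
    out: list[Violation] = []

    # interviews outside their wave interval
    for r in db.query(
        """
        SELECT iv.interview_id, iv.interview_date, w.label, w.start_date, w.end_date
        FROM INTERVIEW iv JOIN WAVE w ON w.wave_id = iv.wave_id
        WHERE iv.interview_date < w.start_date OR iv.interview_date > w.end_date
        """
    ):
        out.append(
            Violation(
                "temporal_consistency", "INTERVIEW", str(r["interview_id"]),
                f"interview date {r['interview_date']} outside wave {r['label']!r}"
                f" [{r['start_date']}, {r['end_date']}]",
            )
        )

    # interviews not covered by any resident episode of the individual
    for r in db.query(
        """
        SELECT iv.interview_id, iv.individual_id, iv.interview_date
        FROM INTERVIEW iv
        WHERE NOT EXISTS (
            SELECT 1 FROM RESIDENT_EPISODE e
            WHERE e.individual_id = iv.individual_id
              AND e.start_date <= iv.interview_date
              AND (e.end_date IS NULL OR e.end_date > iv.interview_date)
        )
        """
    ):
        out.append(
            Violation(
                "temporal_consistency", "INTERVIEW", str(r["interview_id"]),
                f"interview date {r['interview_date']} outside every resident episode"
                f" of individual {r['individual_id']}",
            )
        )

    # overlapping episodes per individual (half-open interval intersection)
    for r in db.query(
        """
        SELECT a.episode_id AS ep_a, b.episode_id AS ep_b, a.individual_id
        FROM RESIDENT_EPISODE a JOIN RESIDENT_EPISODE b
          ON a.individual_id = b.individual_id AND a.episode_id < b.episode_id
        WHERE a.start_date < COALESCE(b.end_date, '9999-12-31')
          AND b.start_date < COALESCE(a.end_date, '9999-12-31')
        """
    ):
        out.append(
            Violation(
                "temporal_consistency", "RESIDENT_EPISODE", str(r["ep_a"]),
                f"episode overlap with episode {r['ep_b']}"
                f" (individual {r['individual_id']})",
            )
        )

    # capture events outside their wave
    for r in db.query(
        """
        SELECT ev.event_id, ev.start_date, ev.end_date, w.label, w.start_date AS ws, w.end_date AS we
        FROM DATA_CAPTURE_EVENT ev JOIN WAVE w ON w.wave_id = ev.wave_id
        WHERE ev.start_date < w.start_date OR ev.end_date > w.end_date
        """
    ):
        out.append(
            Violation(
                "temporal_consistency", "DATA_CAPTURE_EVENT", str(r["event_id"]),
                f"capture event [{r['start_date']}, {r['end_date']}] outside wave"
                f" {r['label']!r} [{r['ws']}, {r['we']}]",
            )
        )
    return _sorted(out)


def check_fact_values(db: StagingDB) -> list[Violation]:
    out: list[Violation] = []

    items = {
        r["item_id"]: r
        for r in db.query("SELECT * FROM INSTRUMENT_ITEM")
    }
    type_codes = {
        r["concept_id"]: r["concept_code"]
        for r in db.query("SELECT concept_id, concept_code FROM CONCEPT WHERE concept_code LIKE 'VALUE_TYPE_%'")
    }
    facts = db.query("SELECT * FROM LONGITUDINAL_POPULATION_STUDY_FACT")
    # one finding per fact row (the first applicable rule); all rows enumerated
    for f in facts:
        ref = str(f["fact_id"])
        if (
            f["value_as_number"] is None
            and f["value_as_concept_id"] is None
            and f["value_as_text"] is None
        ):
            out.append(
                Violation("fact_values", "LONGITUDINAL_POPULATION_STUDY_FACT",
                          ref, "no value slot populated")
            )
            continue
        item = items.get(f["instrument_item_id"])
        if item is None:
            continue  # surfaces under referential integrity
        vtype = item["value_type"]
        n_before = len(out)
        if vtype in ("ordinal", "categorical") and item["allowed_values"]:
            allowed = json.loads(item["allowed_values"])
            codes = {e["code"] for e in allowed if e["code"] is not None}
            concepts = {e["value_concept_id"] for e in allowed}
            if f["value_as_number"] is not None and f["value_as_number"] not in codes:
                out.append(
                    Violation("fact_values", "LONGITUDINAL_POPULATION_STUDY_FACT", ref,
                              f"ordinal value {f['value_as_number']} outside allowed codes"
                              f" of item {item['item_code']}")
                )
            elif f["value_as_concept_id"] is not None and f["value_as_concept_id"] not in concepts:
                out.append(
                    Violation("fact_values", "LONGITUDINAL_POPULATION_STUDY_FACT", ref,
                              f"value concept {f['value_as_concept_id']} not in the allowed"
                              f" set of item {item['item_code']}")
                )
        elif vtype == "numeric" and f["value_as_number"] is not None:
            lo, hi = item["range_min"], item["range_max"]
            if lo is not None and not (lo <= f["value_as_number"] <= hi):
                out.append(
                    Violation("fact_values", "LONGITUDINAL_POPULATION_STUDY_FACT", ref,
                              f"numeric value {f['value_as_number']} outside range [{lo}, {hi}]"
                              f" of item {item['item_code']}")
                )
        if len(out) > n_before:
            continue
        # value-type concept must agree with the populated slot(s)
        type_code = type_codes.get(f["value_type_concept_id"])
        if type_code is not None:
            slot_ok = {
                "VALUE_TYPE_ORDINAL": f["value_as_concept_id"] is not None,
                "VALUE_TYPE_CATEGORICAL": f["value_as_concept_id"] is not None,
                "VALUE_TYPE_NUMERIC": f["value_as_number"] is not None
                and f["value_as_concept_id"] is None,
                "VALUE_TYPE_TEXT": f["value_as_text"] is not None,
            }.get(type_code, True)
            if not slot_ok:
                out.append(
                    Violation("fact_values", "LONGITUDINAL_POPULATION_STUDY_FACT", ref,
                              f"value-type concept {type_code} inconsistent with populated slots")
                )
    return _sorted(out)


def audit_normalization(db: StagingDB) -> list[Violation]:
    """Flag the redundancy classes normalization to 3NF is meant to preclude."""
    out: list[Violation] = []

    for table, entity in (
        ("INDIVIDUAL_DEMOGRAPHICS", "individual_id"),
        ("HOUSEHOLD_CHARACTERISTICS", "household_id"),
    ):
        for r in db.query(
            f"""
            SELECT {entity} AS eid, parameter_concept_id, observed_on, COUNT(*) AS n
            FROM {table}
            GROUP BY {entity}, parameter_concept_id, observed_on HAVING n > 1
            """
        ):
            out.append(
                Violation("normalization", table, f"{r['eid']}/{r['parameter_concept_id']}",
                          f"{r['n']} rows share (entity, parameter, observed_on ="
                          f" {r['observed_on']})")
            )

        # identical parameter value restated on a different date (redundant row)
        for r in db.query(
            f"""
            SELECT {entity} AS eid, parameter_concept_id, COUNT(*) AS n
            FROM {table}
            GROUP BY {entity}, parameter_concept_id,
                     value_as_concept_id, value_as_number, value_as_text
            HAVING COUNT(DISTINCT observed_on) > 1
            """
        ):
            out.append(
                Violation("normalization", table, f"{r['eid']}/{r['parameter_concept_id']}",
                          f"identical value recorded {r['n']} times on different dates")
            )

    for r in db.query(
        """
        SELECT interview_id, instrument_item_id, COUNT(*) AS n
        FROM LONGITUDINAL_POPULATION_STUDY_FACT
        GROUP BY interview_id, instrument_item_id HAVING n > 1
        """
    ):
        out.append(
            Violation("normalization", "LONGITUDINAL_POPULATION_STUDY_FACT",
                      f"{r['interview_id']}/{r['instrument_item_id']}",
                      f"{r['n']} facts for one (interview, item)")
        )
    return _sorted(out)


def run_all_checks(db: StagingDB) -> list[Violation]:
    return (
        check_referential_integrity(db)
        + check_temporal_consistency(db)
        + check_fact_values(db)
        + audit_normalization(db)
    )


# ---------------------------------------------------------------------------
# summary reporting

@dataclass
class SummaryReport:
    table_counts: dict[str, int]
    concepts_by_vocabulary: dict[str, int]
    standard_concepts: int
    local_concepts: int
    studies: list[dict]
    interviews_per_wave: dict[str, dict[str, int]]  # wave label -> instrument -> count

    def to_dict(self) -> dict:
        return {
            "table_counts": self.table_counts,
            "concepts_by_vocabulary": self.concepts_by_vocabulary,
            "standard_concepts": self.standard_concepts,
            "local_concepts": self.local_concepts,
            "studies": self.studies,
            "interviews_per_wave": self.interviews_per_wave,
        }

    def to_text(self) -> str:
        lines = ["staging database summary", "-" * 40]
        for table in TABLES:
            lines.append(f"{table:<40} {self.table_counts[table]:>8}")
        lines.append("-" * 40)
        lines.append(f"standard concepts: {self.standard_concepts}")
        lines.append(f"{LOCAL_VOCABULARY} local concepts: {self.local_concepts}")
        for study in self.studies:
            lines.append(f"study {study['study_id']}: {study['title']} ({study['waves']} waves)")
        for wave, by_inst in self.interviews_per_wave.items():
            total = sum(by_inst.values())
            lines.append(f"{wave}: {total} interviews")
            for inst, n in sorted(by_inst.items()):
                lines.append(f"  {inst}: {n}")
        return "\n".join(lines)


def summary_report(db: StagingDB) -> SummaryReport:
    table_counts = {t: db.count(t) for t in TABLES}
    by_vocab = {
        r["vocabulary_id"]: r["n"]
        for r in db.query(
            "SELECT vocabulary_id, COUNT(*) AS n FROM CONCEPT GROUP BY vocabulary_id"
            " ORDER BY vocabulary_id"
        )
    }
    local = db.scalar("SELECT COUNT(*) FROM CONCEPT WHERE is_local = 1") or 0
    studies = [
        {
            "study_id": r["study_id"],
            "title": r["title"],
            "waves": db.scalar("SELECT COUNT(*) FROM WAVE WHERE study_id = ?", (r["study_id"],)),
        }
        for r in db.query("SELECT * FROM POPULATION_STUDY ORDER BY study_id")
    ]
    interviews: dict[str, dict[str, int]] = {}
    for r in db.query(
        """
        SELECT w.label, i.name, COUNT(*) AS n
        FROM INTERVIEW iv
        JOIN WAVE w ON w.wave_id = iv.wave_id
        JOIN INSTRUMENT i ON i.instrument_id = iv.instrument_id
        GROUP BY w.label, i.name ORDER BY w.label, i.name
        """
    ):
        interviews.setdefault(r["label"], {})[r["name"]] = r["n"]
    return SummaryReport(
        table_counts=table_counts,
        concepts_by_vocabulary=by_vocab,
        standard_concepts=table_counts["CONCEPT"] - local,
        local_concepts=local,
        studies=studies,
        interviews_per_wave=interviews,
    )
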