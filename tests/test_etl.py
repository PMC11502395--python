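import numpy as np
import pandas as pd
import pytest

from lpstage import etl
from lpstage.etl import (
    EtlError,
    MappingSpec,
    load_facts,
    melt_wide_to_long,
    parse_mapping_spec,
    pivot_facts_wide,
    type_and_code_value,
)
from lpstage.population import open_episode, upsert_household, upsert_individual
from lpstage.study_metadata import register_study, register_wave
from lpstage.vocabulary import get_items


@pytest.fixture
def ctx(vocab_db):
    """Vocabulary plus a study, one wave, and three resident respondents."""
    db = vocab_db
    study = register_study(db, "etl test study")
    wave = register_wave(db, study, "wave-1", "2023-01-01", "2023-03-31")
    hh = upsert_household(db, "HH-1", {"name": "v", "lat": 0.6, "lon": 33.4})
    for i in range(1, 4):
        person = upsert_individual(db, f"IG-{i}")
        open_episode(db, person, hh, wave, "2023-01-01")
    return {"db": db, "study": study, "wave": wave}


def phq9_spec(**overrides) -> dict:
    doc = {
        "instrument": "Patient Health Questionnaire (PHQ-9)",
        "id_column": "pid",
        "wave_label": "wave-1",
        "item_columns": {f"q{i}": f"PHQ9_{i}" for i in range(1, 10)},
        "on_unmapped": "reject",
    }
    doc.update(overrides)
    return doc


def phq9_wide(n=3, blank=()):
    rng = np.random.default_rng(0)
    data = {"pid": [f"IG-{i}" for i in range(1, n + 1)]}
    for i in range(1, 10):
        data[f"q{i}"] = [str(rng.integers(0, 4)) for _ in range(n)]
    frame = pd.DataFrame(data)
    for row, col in blank:
        frame.loc[row, col] = ""
    return frame


class TestMappingSpec:
    def test_valid_spec_passes(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        assert len(spec.item_columns) == 9

    def test_unknown_item_rejected(self, ctx):
        doc = phq9_spec()
        doc["item_columns"]["q10"] = "PHQ9_10"
        with pytest.raises(EtlError, match="unknown item 'PHQ9_10'"):
            parse_mapping_spec(ctx["db"], doc)

    def test_duplicate_target_rejected(self, ctx):
        doc = phq9_spec()
        doc["item_columns"]["q9b"] = "PHQ9_1"
        with pytest.raises(EtlError, match="duplicate target"):
            parse_mapping_spec(ctx["db"], doc)

    def test_all_problems_enumerated_not_first_failure(self, ctx):
        doc = phq9_spec()
        doc["item_columns"]["q10"] = "PHQ9_10"
        doc["item_columns"]["q11"] = "PHQ9_11"
        with pytest.raises(EtlError, match="PHQ9_10.*PHQ9_11"):
            parse_mapping_spec(ctx["db"], doc)


class TestMelt:
    def test_full_table_yields_rows_times_items(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        result = melt_wide_to_long(phq9_wide(3), spec)
        assert len(result.records) == 27
        assert result.blank_cells == 0

    def test_blank_cells_skipped_and_tallied(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        result = melt_wide_to_long(phq9_wide(3, blank=[(0, "q2"), (0, "q5")]), spec)
        assert len(result.records) == 25
        assert result.blank_cells == 2

    def test_missing_item_column_errors(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        with pytest.raises(EtlError, match="missing column"):
            melt_wide_to_long(phq9_wide(3).drop(columns=["q3"]), spec)

    def test_row_then_item_order_is_deterministic(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        records = melt_wide_to_long(phq9_wide(2), spec).records
        keys = [(r.external_id, r.item_code) for r in records]
        assert keys == [(f"IG-{i}", f"PHQ9_{j}") for i in (1, 2) for j in range(1, 10)]


class TestTypeAndCode:
    def test_ordinal_value_gets_number_and_concept(self, ctx):
        item = get_items(ctx["db"], "Patient Health Questionnaire (PHQ-9)")[0]
        typed = type_and_code_value(ctx["db"], "2", item)
        assert typed.value_as_number == 2
        matched = next(e for e in item.allowed_values if e["code"] == 2)
        assert typed.value_as_concept_id == matched["value_concept_id"]
        name = ctx["db"].scalar(
            "SELECT concept_name FROM CONCEPT WHERE concept_id = ?", (typed.value_as_concept_id,)
        )
        assert name == "More than half the days"

    def test_out_of_domain_value_rejected(self, ctx):
        item = get_items(ctx["db"], "Patient Health Questionnaire (PHQ-9)")[0]
        reject = type_and_code_value(ctx["db"], "7", item, policy="reject")
        assert isinstance(reject, etl.Reject)
        assert "out of domain" in reject.reason

    def test_value_map_translates_before_matching(self, ctx):
        item = get_items(ctx["db"], "Patient Health Questionnaire (PHQ-9)")[0]
        typed = type_and_code_value(ctx["db"], "sometimes", item, value_map={"sometimes": "1"})
        assert typed.value_as_number == 1

    def test_null_policy_skips(self, ctx):
        item = get_items(ctx["db"], "Patient Health Questionnaire (PHQ-9)")[0]
        assert type_and_code_value(ctx["db"], "junk", item, policy="null") is None

    def test_mint_policy_extends_the_value_set(self, ctx):
        item = get_items(ctx["db"], "Patient Health Questionnaire (PHQ-9)")[0]
        typed = type_and_code_value(ctx["db"], "declined", item, policy="mint")
        assert typed.value_as_concept_id >= 2_000_000_000
        refreshed = get_items(ctx["db"], "Patient Health Questionnaire (PHQ-9)")[0]
        assert any(e["raw"] == "declined" for e in refreshed.allowed_values)


class TestLoadFacts:
    def test_clean_load_conserves_counts(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        melt = melt_wide_to_long(phq9_wide(3), spec)
        report = load_facts(ctx["db"], melt.records, ctx["study"], spec)
        assert report.counts["LONGITUDINAL_POPULATION_STUDY_FACT"] == 27
        assert report.rejects == []

    def test_replay_inserts_nothing(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        melt = melt_wide_to_long(phq9_wide(3), spec)
        load_facts(ctx["db"], melt.records, ctx["study"], spec)
        replay = load_facts(ctx["db"], melt.records, ctx["study"], spec)
        assert replay.counts["LONGITUDINAL_POPULATION_STUDY_FACT"] == 0
        assert ctx["db"].count("LONGITUDINAL_POPULATION_STUDY_FACT") == 27

    def test_out_of_domain_record_becomes_reject_not_fact(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        wide = phq9_wide(3)
        wide.loc[1, "q4"] = "9"
        melt = melt_wide_to_long(wide, spec)
        report = load_facts(ctx["db"], melt.records, ctx["study"], spec)
        assert report.counts["LONGITUDINAL_POPULATION_STUDY_FACT"] == 26
        assert len(report.rejects) == 1
        assert report.rejects[0].item_code == "PHQ9_4"
        # conservation: facts + rejects + blanks == mapped cells
        assert 26 + 1 + melt.blank_cells == 27

    def test_full_three_instrument_interview_yields_40_facts(self, ctx):
        """One fully answered PHQ-9 + GAD-7 + BASIS-24 administration: 9+7+24 facts."""
        db = ctx["db"]
        specs = {
            "Patient Health Questionnaire (PHQ-9)": ("PHQ9", 9),
            "Generalized Anxiety Disorder (GAD-7)": ("GAD7", 7),
            "Behavior and Symptom Identification Scale (BASIS-24)": ("BASIS24", 24),
        }
        total = 0
        for name, (prefix, k) in specs.items():
            doc = {
                "instrument": name,
                "id_column": "pid",
                "wave_label": "wave-1",
                "item_columns": {f"{prefix}_{i}": f"{prefix}_{i}" for i in range(1, k + 1)},
                "on_unmapped": "reject",
            }
            spec = parse_mapping_spec(db, doc)
            wide = pd.DataFrame([{"pid": "IG-1", **{f"{prefix}_{i}": "1" for i in range(1, k + 1)}}])
            report = load_facts(db, melt_wide_to_long(wide, spec).records, ctx["study"], spec)
            total += report.counts["LONGITUDINAL_POPULATION_STUDY_FACT"]
        assert total == 40
        assert db.count("LONGITUDINAL_POPULATION_STUDY_FACT") == 40


class TestRoundTrip:
    def test_pivot_reproduces_source_cells(self, ctx):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        wide = phq9_wide(3, blank=[(2, "q7")])
        melt = melt_wide_to_long(wide, spec)
        load_facts(ctx["db"], melt.records, ctx["study"], spec)
        pivot = pivot_facts_wide(
            ctx["db"], ctx["study"], "Patient Health Questionnaire (PHQ-9)", "wave-1"
        )
        for _, row in wide.iterrows():
            for col, code in spec.item_columns.items():
                source = row[col] if str(row[col]).strip() else None
                got = pivot.loc[row["pid"], code]
                assert (got if pd.notna(got) else None) == source


class TestPipeline:
    def test_missing_roster_fails_at_population_stage_with_partial_report(
        self, demo_bundle, tmp_path
    ):
        import shutil
        import yaml

        broken = tmp_path / "broken"
        shutil.copytree(demo_bundle["dir"], broken)
        (broken / "individuals.csv").unlink()
        from lpstage.schema_core import StagingDB

        db = StagingDB(tmp_path / "b.db")
        report = etl.run_pipeline(db, broken / "pipeline.yaml")
        assert not report.ok
        assert report.failed_stage == "population"
        assert report.counts["CONCEPT"] == 60  # earlier stages still reported

    def test_empty_source_table_is_a_vacuous_success(self, ctx, tmp_path):
        spec = parse_mapping_spec(ctx["db"], phq9_spec())
        empty = phq9_wide(0)
        melt = melt_wide_to_long(empty, spec)
        report = load_facts(ctx["db"], melt.records, ctx["study"], spec)
        assert report.counts["LONGITUDINAL_POPULATION_STUDY_FACT"] == 0
        assert report.rejects == []
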