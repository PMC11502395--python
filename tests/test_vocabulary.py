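import pytest
import yaml

from lpstage.schema_core import StagingDB, create_schema
from lpstage.vocabulary import (
    LOCAL_CONCEPT_BASE,
    VocabularyError,
    get_items,
    load_concepts,
    load_instrument_file,
    mint_local_concept,
    packaged_fixture,
    register_instrument,
    register_items,
    resolve_concept,
)
from tests.conftest import CONCEPT_FIXTURE, INSTRUMENT_FIXTURE

FIXTURE_ROWS = sum(1 for _ in open(CONCEPT_FIXTURE)) - 1  # independent line count

TABLE2_INSTRUMENTS = [
    ("Patient Health Questionnaire (PHQ-9)", "Screening tool for depression"),
    ("Generalized Anxiety Disorder (GAD-7)", "Screening tool for anxiety"),
    ("Depression, Anxiety and Stress Scale (DASS-21)",
     "Screening tool for depression, anxiety, and stress"),
    ("Edinburgh Postnatal Depression Scale (EPDS)", "Screening tool for postnatal depression"),
    ("Posttraumatic Stress Disorder Checklist for DSM-5 (PCL-5)",
     "Symptom checklist for posttraumatic stress disorder"),
    ("Center for Epidemiologic Studies Depression Scale panel (CES-D)",
     "Screening tool for depression"),
    ("Behavior and Symptom Identification Scale (BASIS-24)", "Screening tool for psychosis"),
]


class TestConceptLoading:
    def test_packaged_fixture_loads_every_row(self, db):
        assert load_concepts(db, CONCEPT_FIXTURE) == FIXTURE_ROWS == 60

    def test_reload_is_an_upsert_returning_zero(self, db):
        load_concepts(db, CONCEPT_FIXTURE)
        assert load_concepts(db, CONCEPT_FIXTURE) == 0
        assert db.count("CONCEPT") == FIXTURE_ROWS

    def test_conflicting_concept_id_names_the_id(self, db, tmp_path):
        path = tmp_path / "bad.csv"
        header = ("concept_id,concept_name,domain_id,vocabulary_id,concept_class_id,"
                  "standard_concept,concept_code,valid_start_date,valid_end_date,invalid_reason\n")
        path.write_text(
            header
            + "12345,First name,Obs,LOINC,c,S,a,2000-01-01,2001-01-01,\n"
            + "12345,Other name,Obs,LOINC,c,S,b,2000-01-01,2001-01-01,\n"
        )
        with pytest.raises(VocabularyError, match="conflicting concept 12345"):
            load_concepts(db, path)

    def test_malformed_date_reports_line_number(self, db, tmp_path):
        path = tmp_path / "bad_date.csv"
        header = ("concept_id,concept_name,domain_id,vocabulary_id,concept_class_id,"
                  "standard_concept,concept_code,valid_start_date,valid_end_date,invalid_reason\n")
        path.write_text(header + "7,n,Obs,LOINC,c,S,a,not-a-date,2001-01-01,\n")
        with pytest.raises(VocabularyError, match="line 2"):
            load_concepts(db, path)

    def test_tab_delimited_layout_autodetected(self, db, tmp_path):
        path = tmp_path / "concepts.tsv"
        cols = ["concept_id", "concept_name", "domain_id", "vocabulary_id", "concept_class_id",
                "standard_concept", "concept_code", "valid_start_date", "valid_end_date",
                "invalid_reason"]
        row = ["42", "Answer", "Meas Value", "LOINC", "Answer", "S", "LA1-1", "20000101",
               "20991231", ""]
        path.write_text("\t".join(cols) + "\n" + "\t".join(row) + "\n")
        assert load_concepts(db, path) == 1
        assert resolve_concept(db, "LOINC", "LA1-1").concept_id == 42


class TestLocalMinting:
    def test_ids_allocated_sequentially_from_base(self, db):
        first = mint_local_concept(db, "BASIS24_Q7_RESP_3", "Quite a bit", "Meas Value")
        second = mint_local_concept(db, "BASIS24_Q8_RESP_0", "Not at all", "Meas Value")
        assert first.concept_id == LOCAL_CONCEPT_BASE == 2_000_000_000
        assert second.concept_id == LOCAL_CONCEPT_BASE + 1

    def test_reminting_is_stable(self, db):
        first = mint_local_concept(db, "BASIS24_Q7_RESP_3", "Quite a bit")
        n_before = db.count("CONCEPT")
        again = mint_local_concept(db, "BASIS24_Q7_RESP_3", "Quite a bit")
        assert again.concept_id == first.concept_id
        assert db.count("CONCEPT") == n_before

    def test_minting_replay_determinism(self, tmp_path):
        """Replaying the same mint sequence from empty stores yields identical maps."""
        codes = [f"CODE_{i}" for i in (3, 1, 4, 1, 5, 9, 2, 6)]
        maps = []
        for name in ("a", "b"):
            store = StagingDB(tmp_path / f"{name}.db")
            create_schema(store)
            maps.append({c: mint_local_concept(store, c, c).concept_id for c in codes})
        assert maps[0] == maps[1]

    def test_local_and_standard_concepts_partition(self, vocab_db):
        mx_standard = vocab_db.scalar("SELECT MAX(concept_id) FROM CONCEPT WHERE is_local = 0")
        mn_local = vocab_db.scalar("SELECT MIN(concept_id) FROM CONCEPT WHERE is_local = 1")
        assert mx_standard < 2_000_000_000 <= mn_local
        mismatch = vocab_db.scalar(
            "SELECT COUNT(*) FROM CONCEPT WHERE (is_local = 1) != (vocabulary_id = 'INSPIRE')"
        )
        assert mismatch == 0


class TestResolve:
    def test_resolves_minted_concept(self, db):
        minted = mint_local_concept(db, "BASIS24_Q7_RESP_3", "Quite a bit")
        assert resolve_concept(db, "INSPIRE", "BASIS24_Q7_RESP_3") == minted

    def test_absent_is_a_value_not_an_error(self, vocab_db):
        assert resolve_concept(vocab_db, "LOINC", "nonexistent-code") is None

    def test_lookup_is_case_sensitive(self, db):
        mint_local_concept(db, "BASIS24_Q7_RESP_3", "Quite a bit")
        assert resolve_concept(db, "inspire", "BASIS24_Q7_RESP_3") is None


class TestInstrumentRegistry:
    def test_table2_rows_register_in_order(self, db):
        for i, (name, desc) in enumerate(TABLE2_INSTRUMENTS, start=1):
            inst = register_instrument(db, name, desc)
            assert inst.instrument_id == i
        assert db.count("INSTRUMENT") == 7
        first = db.one("SELECT name FROM INSTRUMENT WHERE instrument_id = 1")
        assert first["name"] == "Patient Health Questionnaire (PHQ-9)"

    def test_duplicate_name_returns_existing(self, db):
        a = register_instrument(db, "Generalized Anxiety Disorder (GAD-7)", "")
        b = register_instrument(db, "Generalized Anxiety Disorder (GAD-7)", "")
        assert a.instrument_id == b.instrument_id
        assert db.count("INSTRUMENT") == 1

    def test_empty_name_rejected(self, db):
        with pytest.raises(VocabularyError):
            register_instrument(db, "")


class TestItemRegistry:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("Patient Health Questionnaire (PHQ-9)", 9),
            ("Generalized Anxiety Disorder (GAD-7)", 7),
            ("Behavior and Symptom Identification Scale (BASIS-24)", 24),
            ("Depression, Anxiety and Stress Scale (DASS-21)", 21),
            ("Edinburgh Postnatal Depression Scale (EPDS)", 10),
            ("Posttraumatic Stress Disorder Checklist for DSM-5 (PCL-5)", 20),
            ("Center for Epidemiologic Studies Depression Scale panel (CES-D)", 20),
        ],
    )
    def test_canonical_definitions_register_expected_item_counts(self, vocab_db, name, expected):
        items = get_items(vocab_db, name)
        assert len(items) == expected
        assert sorted(i.position for i in items) == list(range(1, expected + 1))

    def test_position_gap_rejected(self, db):
        inst = register_instrument(db, "gapped", "")
        responses = [{"raw": "0", "code": 0, "label": "no"}, {"raw": "1", "code": 1, "label": "yes"}]
        defs = [
            {"item_code": f"G_{p}", "position": p, "value_type": "ordinal", "responses": responses}
            for p in (1, 2, 4)
        ]
        with pytest.raises(ValueError, match="position"):
            register_items(db, inst, defs)

    def test_item_replay_adds_nothing(self, vocab_db):
        counts = load_instrument_file(vocab_db, INSTRUMENT_FIXTURE)
        assert all(n == 0 for n in counts.values())
        assert vocab_db.count("INSTRUMENT_ITEM") == 111

    def test_every_response_anchor_has_a_resolvable_value_concept(self, vocab_db):
        for name, _ in TABLE2_INSTRUMENTS:
            for item in get_items(vocab_db, name):
                assert len(item.allowed_values) >= 2
                for entry in item.allowed_values:
                    found = vocab_db.one(
                        "SELECT 1 FROM CONCEPT WHERE concept_id = ?",
                        (entry["value_concept_id"],),
                    )
                    assert found is not None

    def test_fixture_file_matches_published_layout(self):
        with open(INSTRUMENT_FIXTURE) as fh:
            doc = yaml.safe_load(fh)
        assert len(doc["instruments"]) == 7
        assert sum(len(i["items"]) for i in doc["instruments"]) == 111
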