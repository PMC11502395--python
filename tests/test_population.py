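from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpstage.population import (
    PopulationError,
    close_episode,
    open_episode,
    record_demographic,
    record_interview,
    upsert_household,
    upsert_individual,
    wave_midpoint,
)
from lpstage.study_metadata import register_study, register_wave
from lpstage.vocabulary import mint_local_concept


@pytest.fixture
def ctx(db):
    study = register_study(db, "s")
    wave1 = register_wave(db, study, "wave-1", "2023-01-01", "2023-03-31")
    wave2 = register_wave(db, study, "wave-2", "2023-07-01", "2023-09-30")
    hh = [upsert_household(db, f"HH-{i}", {"name": "Iganga", "lat": 0.615, "lon": 33.485})
          for i in range(1, 4)]
    return {"study": study, "waves": [wave1, wave2], "households": hh}


class TestIndividuals:
    def test_external_id_is_a_stable_identifier(self, db):
        first = upsert_individual(db, "IG-000017")
        for i in range(50):
            upsert_individual(db, f"IG-{i:06d}")
        assert upsert_individual(db, "IG-000017").individual_id == first.individual_id == 1

    def test_empty_external_id_rejected(self, db):
        with pytest.raises(PopulationError):
            upsert_individual(db, "")


class TestDemographics:
    def test_record_and_replay(self, db):
        person = upsert_individual(db, "IG-1")
        female = mint_local_concept(db, "female", "Female", "Gender")
        assert record_demographic(db, person, "sex", "2023-01-15", value_concept=female) == 1
        assert record_demographic(db, person, "sex", "2023-01-15", value_concept=female) == 0
        assert db.count("INDIVIDUAL_DEMOGRAPHICS") == 1

    def test_two_value_slots_rejected(self, db):
        person = upsert_individual(db, "IG-1")
        with pytest.raises(PopulationError, match="exactly one"):
            record_demographic(db, person, "age", "2023-01-15", value_number=34, value_text="34")


class TestHouseholds:
    def test_identical_locations_are_shared(self, db):
        a = upsert_household(db, "HH-0001", {"name": "Iganga", "lat": 0.615, "lon": 33.485})
        b = upsert_household(db, "HH-0002", {"name": "Iganga", "lat": 0.615, "lon": 33.485})
        assert (a.household_id, b.household_id) == (1, 2)
        assert a.location_id == b.location_id == 1
        assert db.count("LOCATION") == 1

    def test_out_of_bounds_latitude_rejected(self, db):
        with pytest.raises(PopulationError, match="latitude"):
            upsert_household(db, "HH-X", {"name": "nowhere", "lat": 95, "lon": 0})


class TestEpisodes:
    def test_move_auto_closes_open_episode(self, db, ctx):
        person = upsert_individual(db, "IG-1")
        first = open_episode(db, person, ctx["households"][0], ctx["waves"][0], "2023-01-01")
        assert first.end_date is None
        open_episode(db, person, ctx["households"][1], ctx["waves"][1], "2023-06-01")
        closed = db.one("SELECT * FROM RESIDENT_EPISODE WHERE episode_id = ?", (first.episode_id,))
        assert closed["end_date"] == "2023-06-01"
        assert closed["end_reason"] == "out-migration"
        n_open = db.scalar(
            "SELECT COUNT(*) FROM RESIDENT_EPISODE WHERE individual_id = ? AND end_date IS NULL",
            (person.individual_id,),
        )
        assert n_open == 1

    def test_backdated_move_rejected(self, db, ctx):
        person = upsert_individual(db, "IG-1")
        open_episode(db, person, ctx["households"][0], ctx["waves"][0], "2023-01-01")
        with pytest.raises(PopulationError, match="precedes"):
            open_episode(db, person, ctx["households"][2], ctx["waves"][1], "2022-12-01")

    def test_close_then_close_again_errors(self, db, ctx):
        person = upsert_individual(db, "IG-1")
        open_episode(db, person, ctx["households"][0], ctx["waves"][0], "2023-01-01")
        episode = close_episode(db, person, "2023-12-31", "study-end")
        assert episode.end_reason == "study-end"
        with pytest.raises(PopulationError, match="no open episode"):
            close_episode(db, person, "2024-01-01", "study-end")

    def test_empty_interval_rejected(self, db, ctx):
        person = upsert_individual(db, "IG-1")
        open_episode(db, person, ctx["households"][0], ctx["waves"][0], "2023-01-01")
        with pytest.raises(PopulationError, match="half-open"):
            close_episode(db, person, "2023-01-01", "study-end")

    @settings(max_examples=40, deadline=None)
    @given(moves=st.lists(st.integers(min_value=1, max_value=400), min_size=1, max_size=8))
    def test_individual_resides_in_at_most_one_household_at_any_date(self, tmp_path_factory, moves):
        """Episode partition: randomized move sequences never create overlap."""
        from lpstage.schema_core import StagingDB, create_schema

        store = StagingDB(tmp_path_factory.mktemp("hyp") / "e.db")
        create_schema(store)
        study = register_study(store, "s")
        wave = register_wave(store, study, "w", "2023-01-01", "2026-12-31")
        households = [
            upsert_household(store, f"HH-{i}", {"name": "v", "lat": 0.6, "lon": 33.4})
            for i in range(3)
        ]
        person = upsert_individual(store, "IG-1")
        start = date(2023, 1, 1)
        offset = 0
        for i, step in enumerate(moves):
            offset += step
            open_episode(store, person, households[i % 3], wave, start + timedelta(days=offset))
        rows = store.query(
            "SELECT start_date, end_date FROM RESIDENT_EPISODE WHERE individual_id = ?",
            (person.individual_id,),
        )
        # sample every episode boundary: at most one covering episode
        for probe_row in rows:
            probe = date.fromisoformat(probe_row["start_date"])
            covering = [
                r for r in rows
                if date.fromisoformat(r["start_date"]) <= probe
                and (r["end_date"] is None or date.fromisoformat(r["end_date"]) > probe)
            ]
            assert len(covering) <= 1
        assert sum(1 for r in rows if r["end_date"] is None) <= 1
        store.close()


class TestInterviews:
    def _person_with_episode(self, db, ctx):
        person = upsert_individual(db, "IG-1")
        open_episode(db, person, ctx["households"][0], ctx["waves"][0], "2023-01-01")
        return person

    def test_missing_date_approximated_at_wave_midpoint(self, db, ctx):
        person = self._person_with_episode(db, ctx)
        instrument_id = db.next_id("INSTRUMENT", "instrument_id")
        db.execute("INSERT INTO INSTRUMENT (instrument_id, name) VALUES (?, 'PHQ-9')", (instrument_id,))
        interview = record_interview(db, person, ctx["waves"][0], instrument_id)
        # calendar-arithmetic oracle, computed independently of the rule under test
        span = (date(2023, 3, 31) - date(2023, 1, 1)).days
        oracle = date(2023, 1, 1) + timedelta(days=span // 2)
        assert oracle == date(2023, 2, 14)
        assert interview.interview_date == oracle
        assert interview.date_approximated is True

    def test_explicit_date_stored_verbatim(self, db, ctx):
        person = self._person_with_episode(db, ctx)
        db.execute("INSERT INTO INSTRUMENT (instrument_id, name) VALUES (1, 'PHQ-9')")
        interview = record_interview(db, person, ctx["waves"][0], 1, "2023-02-01")
        assert interview.interview_date == date(2023, 2, 1)
        assert interview.date_approximated is False

    def test_date_outside_wave_rejected(self, db, ctx):
        person = self._person_with_episode(db, ctx)
        db.execute("INSERT INTO INSTRUMENT (instrument_id, name) VALUES (1, 'PHQ-9')")
        with pytest.raises(PopulationError, match="outside wave"):
            record_interview(db, person, ctx["waves"][0], 1, "2023-05-01")

    def test_duplicate_interview_returned_not_duplicated(self, db, ctx):
        person = self._person_with_episode(db, ctx)
        db.execute("INSERT INTO INSTRUMENT (instrument_id, name) VALUES (1, 'PHQ-9')")
        a = record_interview(db, person, ctx["waves"][0], 1, "2023-02-01")
        b = record_interview(db, person, ctx["waves"][0], 1)
        assert a.interview_id == b.interview_id
        assert db.count("INTERVIEW") == 1

    def test_interview_without_episode_configurable(self, db, ctx):
        person = upsert_individual(db, "IG-no-episode")
        db.execute("INSERT INTO INSTRUMENT (instrument_id, name) VALUES (1, 'PHQ-9')")
        with pytest.raises(PopulationError, match="episode"):
            record_interview(db, person, ctx["waves"][0], 1, "2023-02-01")
        interview = record_interview(
            db, person, ctx["waves"][0], 1, "2023-02-01", on_no_episode="warn"
        )
        assert interview.interview_id == 1


@pytest.mark.parametrize(
    "start, end, expected",
    [
        (date(2023, 1, 1), date(2023, 3, 31), date(2023, 2, 14)),
        (date(2023, 1, 1), date(2023, 1, 1), date(2023, 1, 1)),
        (date(2023, 1, 1), date(2023, 1, 2), date(2023, 1, 1)),
        (date(2024, 2, 1), date(2024, 3, 1), date(2024, 2, 15)),  # leap February
    ],
)
def test_wave_midpoint_calendar_arithmetic(start, end, expected):
    assert wave_midpoint(start, end) == expected
    assert start <= wave_midpoint(start, end) <= end
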