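"""Shared fixtures: fresh schemas, a vocabulary-loaded store, and one
session-scoped demo bundle ingested end to end (read-only for tests;
mutating tests copy the database file first)."""

from __future__ import annotations

import shutil
from pathlib import Path

import pytest

from lpstage import etl, synthetic_data
from lpstage.schema_core import StagingDB, create_schema
from lpstage.vocabulary import load_concepts, load_instrument_file, packaged_fixture

CONCEPT_FIXTURE = packaged_fixture("omop_concept_subset_synthetic.csv")
INSTRUMENT_FIXTURE = packaged_fixture("instruments.yaml")


@pytest.fixture
def db(tmp_path: Path) -> StagingDB:
    """Empty staging database with the full schema."""
    store = StagingDB(tmp_path / "staging.db")
    create_schema(store)
    return store


@pytest.fixture
def vocab_db(db: StagingDB) -> StagingDB:
    """Schema plus packaged concepts and all seven instruments."""
    load_concepts(db, CONCEPT_FIXTURE)
    load_instrument_file(db, INSTRUMENT_FIXTURE)
    return db


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory: pytest.TempPathFactory):
    """The demo study conditions (seed 42), written to disk once per session."""
    out = tmp_path_factory.mktemp("bundle")
    bundle = synthetic_data.generate_bundle(seed=42)
    manifest = synthetic_data.write_bundle(bundle, out)
    return {"dir": out, "bundle": bundle, "manifest": manifest}


@pytest.fixture(scope="session")
def ingested_path(demo_bundle, tmp_path_factory: pytest.TempPathFactory) -> Path:
    """Database file with the demo bundle fully ingested (treat as read-only)."""
    path = tmp_path_factory.mktemp("db") / "ingested.db"
    store = StagingDB(path)
    report = etl.run_pipeline(store, demo_bundle["dir"] / "pipeline.yaml", strict=True)
    assert report.ok and not report.rejects
    store.close()
    return path


@pytest.fixture
def ingested_db(ingested_path: Path) -> StagingDB:
    """Read-only handle on the shared ingested database."""
    return StagingDB(ingested_path)


@pytest.fixture
def ingested_copy(ingested_path: Path, tmp_path: Path) -> StagingDB:
    """Private mutable copy of the ingested database (for fault injection)."""
    target = tmp_path / "copy.db"
    shutil.copy(ingested_path, target)
    return StagingDB(target)
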