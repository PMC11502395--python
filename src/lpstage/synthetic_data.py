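"""Synthetic multi-wave household survey bundles with known ground truth.

The generator emulates a longitudinal HDSS-style mental-health survey of the
Iganga-Mayuge kind: households with GPS-tagged locations, individuals with
sex and birth-year demographics, residence episodes with between-household
migration across waves, and per-wave wide-format exports of screening
instruments (PHQ-9, GAD-7, BASIS-24 by default) with item-level missingness
and missing interview dates.

Ordinal responses come from a latent-severity threshold model: each
individual carries a latent severity ``z ~ N(0, 1)``; item ``j``'s response
is ``cut(z + sigma * eps_ij)`` with independent item noise and thresholds
placed at the normal quantiles of a geometrically decaying category
distribution (most respondents endorse low categories).  Because every item
of every instrument shares ``z``, instrument sum scores are positively
correlated — the structure real comorbidity data shows and the property the
statistical-recovery tests check.

Randomness is organised as one numpy Generator stream per (entity-type,
wave), so e.g. adding an instrument never perturbs roster generation, and a
fixed seed reproduces bundles byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .vocabulary import packaged_fixture

__all__ = [
    "SimConfig",
    "WaveSpec",
    "Bundle",
    "GroundTruth",
    "default_config",
    "simulate_population",
    "simulate_responses",
    "generate_bundle",
    "write_bundle",
]

#: Default item-noise scale sigma of the latent-threshold model, frozen after
#: a one-off Monte-Carlo calibration of the between-instrument sum-score rank
#: correlation (see docs/methods.md).
DEFAULT_ITEM_NOISE = 1.0

#: Geometric decay ratio of the category base distribution (P(k+1)/P(k)).
CATEGORY_DECAY = 0.6

DEFAULT_INSTRUMENTS = (
    "Patient Health Questionnaire (PHQ-9)",
    "Generalized Anxiety Disorder (GAD-7)",
    "Behavior and Symptom Identification Scale (BASIS-24)",
)


class WaveSpec(BaseModel):
    label: str
    start: date
    end: date


class SimConfig(BaseModel):
    """Study conditions of the generated bundle."""

    n_households: int = Field(default=50, ge=1)
    mean_household_size: float = Field(default=4.0, gt=1.0)
    waves: list[WaveSpec] = Field(
        default_factory=lambda: [
            WaveSpec(label="wave-1", start=date(2023, 1, 1), end=date(2023, 3, 31)),
            WaveSpec(label="wave-2", start=date(2023, 7, 1), end=date(2023, 9, 30)),
        ]
    )
    instruments: list[str] = Field(default_factory=lambda: list(DEFAULT_INSTRUMENTS))
    response_rate: float = Field(default=0.9, ge=0.0, le=1.0)
    item_missingness: float = Field(default=0.10, ge=0.0, le=1.0)
    migration_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    date_missingness: float = Field(default=0.2, ge=0.0, le=1.0)
    item_noise: float = Field(default=DEFAULT_ITEM_NOISE, gt=0.0)
    seed: int = 42

    @model_validator(mode="after")
    def _waves_ordered(self) -> "SimConfig":
        if not self.waves:
            raise ValueError("at least one wave required")
        for a, b in zip(self.waves, self.waves[1:]):
            if a.end >= b.start:
                raise ValueError(f"waves {a.label!r} and {b.label!r} overlap or are unordered")
        return self


def default_config(**overrides) -> SimConfig:
    """The demo study conditions: 50 households of mean size 4, two waves,
    the three use-case instruments."""
    return SimConfig(**overrides)


@dataclass
class GroundTruth:
    severity: dict[str, float]  # external_id -> latent z
    interviewed: dict[str, list[str]]  # wave label -> interviewed external ids
    migrations: dict[str, int]  # wave label -> migration count
    n_resident: dict[str, int]  # wave label -> residents eligible to migrate
    blank_cells: int = 0
    answered_cells: int = 0
    missing_dates: int = 0

    def to_dict(self) -> dict:
        return {
            "severity": {k: round(v, 6) for k, v in sorted(self.severity.items())},
            "interviewed": {k: sorted(v) for k, v in self.interviewed.items()},
            "migrations": self.migrations,
            "n_resident": self.n_resident,
            "blank_cells": self.blank_cells,
            "answered_cells": self.answered_cells,
            "missing_dates": self.missing_dates,
        }


@dataclass
class Bundle:
    config: SimConfig
    households: pd.DataFrame  # external_id, location_name, latitude, longitude
    individuals: pd.DataFrame  # one row per episode (roster layout)
    surveys: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)  # (instrument, wave)
    truth: GroundTruth | None = None


# ---------------------------------------------------------------------------
# instrument catalogue (item codes / category counts from the packaged fixture)

def _instrument_catalogue() -> dict[str, list[tuple[str, int]]]:
    with packaged_fixture("instruments.yaml").open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    catalogue: dict[str, list[tuple[str, int]]] = {}
    for inst in doc["instruments"]:
        catalogue[inst["name"]] = [
            (item["item_code"], len(item.get("responses", [])))
            for item in sorted(inst["items"], key=lambda i: i["position"])
        ]
    return catalogue


def _slug(item_codes: list[tuple[str, int]]) -> str:
    return item_codes[0][0].rsplit("_", 1)[0]


def _rng(seed: int, stream: int, wave_index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream, wave_index])


_STREAM_HOUSEHOLDS = 1
_STREAM_INDIVIDUALS = 2
_STREAM_MIGRATION = 3
_STREAM_RESPONSE = 4
_STREAM_ITEMS = 5
_STREAM_DATES = 6


# ---------------------------------------------------------------------------
# population

def simulate_population(config: SimConfig | None = None, seed: int | None = None) -> Bundle:
    """Draw households, individuals, demographics, and migration histories.

    Household sizes are ``1 + Poisson(mean - 1)``; in every wave after the
    first, each individual moves to a different household with the configured
    migration probability (the episode closes at the wave start and a new one
    opens the same day).
    """
    config = config or default_config()
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    s = config.seed

    rng_h = _rng(s, _STREAM_HOUSEHOLDS)
    n_hh = config.n_households
    hh_ids = [f"HH-{i:04d}" for i in range(1, n_hh + 1)]
    # village-style clustered GPS around the Iganga-Mayuge area
    lats = np.round(0.60 + 0.15 * rng_h.random(n_hh), 6)
    lons = np.round(33.40 + 0.20 * rng_h.random(n_hh), 6)
    villages = [f"village-{1 + i % 8}" for i in range(n_hh)]
    households = pd.DataFrame(
        {"external_id": hh_ids, "location_name": villages, "latitude": lats, "longitude": lons}
    )

    rng_i = _rng(s, _STREAM_INDIVIDUALS)
    sizes = 1 + rng_i.poisson(config.mean_household_size - 1.0, size=n_hh)
    people: list[dict] = []
    for hh_idx, size in enumerate(sizes):
        for _ in range(size):
            pid = len(people) + 1
            people.append(
                {
                    "external_id": f"IG-{pid:06d}",
                    "sex": "female" if rng_i.random() < 0.5 else "male",
                    "birth_year": int(1940 + rng_i.integers(0, 66)),
                    "household_idx": hh_idx,
                }
            )
    severity = {p["external_id"]: float(z) for p, z in zip(people, rng_i.normal(size=len(people)))}

    first_start = config.waves[0].start
    episodes: dict[str, list[dict]] = {
        p["external_id"]: [
            {"household_idx": p["household_idx"], "start": first_start, "end": None}
        ]
        for p in people
    }
    migrations: dict[str, int] = {config.waves[0].label: 0}
    n_resident: dict[str, int] = {config.waves[0].label: len(people)}
    for w_idx, wave in enumerate(config.waves[1:], start=1):
        rng_m = _rng(s, _STREAM_MIGRATION, w_idx)
        moved = 0
        n_resident[wave.label] = len(people)
        for p in people:
            if rng_m.random() < config.migration_rate:
                history = episodes[p["external_id"]]
                current = history[-1]
                current["end"] = wave.start
                choices = [i for i in range(n_hh) if i != current["household_idx"]]
                new_hh = int(choices[rng_m.integers(0, len(choices))]) if choices else current["household_idx"]
                history.append({"household_idx": new_hh, "start": wave.start, "end": None})
                moved += 1
        migrations[wave.label] = moved

    rows = []
    for p in people:
        for ep in episodes[p["external_id"]]:
            rows.append(
                {
                    "external_id": p["external_id"],
                    "sex": p["sex"],
                    "birth_year": p["birth_year"],
                    "household_external_id": hh_ids[ep["household_idx"]],
                    "residence_start": ep["start"].isoformat(),
                    "residence_end": "" if ep["end"] is None else ep["end"].isoformat(),
                }
            )
    individuals = pd.DataFrame(rows)

    truth = GroundTruth(
        severity=severity,
        interviewed={w.label: [] for w in config.waves},
        migrations=migrations,
        n_resident=n_resident,
    )
    return Bundle(config=config, households=households, individuals=individuals, truth=truth)


# ---------------------------------------------------------------------------
# responses

def _ordinal_thresholds(k: int, sigma: float) -> np.ndarray:
    """Cut points on the y* = z + sigma*eps scale for k categories whose base
    probabilities decay geometrically."""
    from scipy.stats import norm

    base = CATEGORY_DECAY ** np.arange(k)
    probs = base / base.sum()
    cum = np.cumsum(probs)[:-1]
    return norm.ppf(cum) * np.sqrt(1.0 + sigma**2)


def simulate_responses(bundle: Bundle, wave: WaveSpec | str, config: SimConfig | None = None) -> dict[str, pd.DataFrame]:
    """Generate the wide survey tables of one wave; also records ground truth.

    Each individual is interviewed with probability ``response_rate``; an
    interviewed individual answers every item of every configured instrument,
    after which each cell is blanked with probability ``item_missingness``
    and the interview date (uniform in the wave) is blanked with probability
    ``date_missingness``.
    """
    config = config or bundle.config
    if isinstance(wave, str):
        wave = next(w for w in config.waves if w.label == wave)
    w_idx = [w.label for w in config.waves].index(wave.label)
    s = config.seed

    catalogue = _instrument_catalogue()
    for name in config.instruments:
        if name not in catalogue:
            raise ValueError(f"instrument without item definitions: {name!r}")

    person_ids = sorted(bundle.individuals["external_id"].unique())
    rng_resp = _rng(s, _STREAM_RESPONSE, w_idx)
    interviewed = [pid for pid in person_ids if rng_resp.random() < config.response_rate]
    if bundle.truth is not None:
        bundle.truth.interviewed[wave.label] = list(interviewed)

    rng_dates = _rng(s, _STREAM_DATES, w_idx)
    span = (wave.end - wave.start).days
    dates: dict[str, str] = {}
    for pid in interviewed:
        when = wave.start + timedelta(days=int(rng_dates.integers(0, span + 1)))
        if rng_dates.random() < config.date_missingness:
            dates[pid] = ""
            if bundle.truth is not None:
                bundle.truth.missing_dates += 1
        else:
            dates[pid] = when.isoformat()

    rng_items = _rng(s, _STREAM_ITEMS, w_idx)
    sigma = config.item_noise
    n = len(interviewed)
    z = np.array([bundle.truth.severity[pid] if bundle.truth else 0.0 for pid in interviewed])
    tables: dict[str, pd.DataFrame] = {}
    for name in config.instruments:
        items = catalogue[name]
        slug = _slug(items)
        thresholds = {k: _ordinal_thresholds(k, sigma) for _, k in items}
        m = len(items)
        y_star = z[:, None] + sigma * rng_items.normal(size=(n, m))
        blank = rng_items.random(size=(n, m)) < config.item_missingness
        data = {"individual_id": interviewed, "interview_date": [dates[p] for p in interviewed]}
        for j, (code, k) in enumerate(items):
            categories = np.searchsorted(thresholds[k], y_star[:, j], side="right")
            col = categories.astype(str)
            col[blank[:, j]] = ""
            data[code] = col
        if bundle.truth is not None:
            bundle.truth.blank_cells += int(blank.sum())
            bundle.truth.answered_cells += int(n * m - blank.sum())
        columns = ["individual_id", "interview_date"] + [c for c, _ in items]
        tables[slug] = pd.DataFrame(data, columns=columns)
        bundle.surveys[(name, wave.label)] = tables[slug]
    return tables


def generate_bundle(config: SimConfig | None = None, seed: int | None = None) -> Bundle:
    """Population plus responses for every configured wave."""
    config = config or default_config()
    if seed is not None:
        config = config.model_copy(update={"seed": seed})
    bundle = simulate_population(config)
    for wave in config.waves:
        simulate_responses(bundle, wave, config)
    return bundle


# ---------------------------------------------------------------------------
# writing

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(bundle: Bundle, directory: str | Path) -> dict:
    """Write the bundle as CSV/JSON plus turnkey pipeline configuration.

    Emits ``households.csv``, ``individuals.csv``, one
    ``<instrument-slug>_<wave>.csv`` per instrument-wave pair,
    ``ground_truth.json``, mapping specs, a study descriptor, a pipeline
    config wired to the packaged vocabulary fixtures, and ``manifest.json``
    with SHA-256 hashes of every data file.  Deterministic: rerunning an
    identical bundle reproduces identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    config = bundle.config
    catalogue = _instrument_catalogue()

    files: list[Path] = []

    def write_csv(frame: pd.DataFrame, name: str) -> None:
        path = directory / name
        frame.to_csv(path, index=False, lineterminator="\n")
        files.append(path)

    write_csv(bundle.households, "households.csv")
    write_csv(bundle.individuals, "individuals.csv")

    aux: list[Path] = []
    sources = []
    for (inst_name, wave_label), frame in sorted(bundle.surveys.items()):
        slug = _slug(catalogue[inst_name])
        survey_name = f"{slug}_{wave_label}.csv"
        write_csv(frame, survey_name)

        mapping = {
            "instrument": inst_name,
            "id_column": "individual_id",
            "wave_label": wave_label,
            "date_column": "interview_date",
            "item_columns": {code: code for code, _ in catalogue[inst_name]},
            "on_unmapped": "reject",
        }
        mapping_name = f"mapping_{slug}_{wave_label}.yaml"
        with (directory / mapping_name).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(mapping, fh, sort_keys=True)
        aux.append(directory / mapping_name)
        sources.append({"table": survey_name, "mapping": mapping_name})

    study_doc = {
        "title": "Synthetic Iganga-Mayuge-style mental health survey",
        "description": "Generated longitudinal household survey bundle",
        "site": "synthetic-HDSS",
        "methodology": {"design": "longitudinal panel", "sampling": "household census"},
        "waves": [
            {
                "label": w.label,
                "start_date": w.start.isoformat(),
                "end_date": w.end.isoformat(),
                "instrument_model_type": "screening-scale",
                "capture_events": [
                    {
                        "mode": "face-to-face",
                        "start_date": w.start.isoformat(),
                        "end_date": w.end.isoformat(),
                    }
                ],
            }
            for w in config.waves
        ],
    }
    with (directory / "study.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(study_doc, fh, sort_keys=True)
    aux.append(directory / "study.yaml")

    pipeline = {
        "vocabulary": str(packaged_fixture("omop_concept_subset_synthetic.csv")),
        "instruments": str(packaged_fixture("instruments.yaml")),
        "study": "study.yaml",
        "individuals": "individuals.csv",
        "households": "households.csv",
        "sources": sources,
    }
    with (directory / "pipeline.yaml").open("w", encoding="utf-8") as fh:
        yaml.safe_dump(pipeline, fh, sort_keys=True)
    aux.append(directory / "pipeline.yaml")

    if bundle.truth is not None:
        truth_path = directory / "ground_truth.json"
        truth_path.write_text(
            json.dumps(bundle.truth.to_dict(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        files.append(truth_path)

    manifest = {
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "files": [
            {"name": p.name, "rows": _row_count(p), "sha256": _sha256(p)} for p in files
        ],
        "aux": [p.name for p in aux],
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def _row_count(path: Path) -> int | None:
    if path.suffix != ".csv":
        return None
    with path.open(encoding="utf-8") as fh:
        return sum(1 for _ in fh) - 1
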