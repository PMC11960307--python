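"""Shared fixtures: one session-scoped synthetic study reused across tests."""

from __future__ import annotations

from pathlib import Path

import pytest

import faerspv as fv

TARGET_PATTERNS = ["ETELCALCETIDE", "AMG 416", "PARSABIV"]

#: The session fixture's planted drug–event signal (PT, relative risk).
FIXTURE_SIGNAL = ("PT_0015", 6.0)


@pytest.fixture(scope="session")
def fixture_config() -> fv.GeneratorConfig:
    return fv.GeneratorConfig(
        n_cases=800,
        n_pts=60,
        planted_signals=[FIXTURE_SIGNAL],
        target_fraction=0.12,
        duplicate_rate=0.3,
        quarters=("2023q1", "2023q2"),
        seed=11,
    )


@pytest.fixture(scope="session")
def fixture_run(fixture_config, tmp_path_factory) -> tuple[Path, fv.GroundTruth]:
    out = tmp_path_factory.mktemp("faers_fixture")
    gt = fv.generate_quarters(fixture_config, out)
    return out, gt


@pytest.fixture(scope="session")
def fixture_raw(fixture_run) -> fv.RawTables:
    out, _ = fixture_run
    return fv.load_quarters(sorted(p for p in out.iterdir() if p.is_dir()))


@pytest.fixture(scope="session")
def fixture_cases(fixture_raw) -> fv.CaseSet:
    return fv.deduplicate(fixture_raw)


@pytest.fixture(scope="session")
def fixture_marked(fixture_cases) -> fv.CaseSet:
    return fv.mark_target(fixture_cases, TARGET_PATTERNS)


@pytest.fixture(scope="session")
def fixture_events(fixture_run, fixture_marked):
    out, _ = fixture_run
    mapping = fv.load_dictionary(out / "synthetic_meddra.txt")
    return fv.map_events(fixture_marked, mapping)


@pytest.fixture(scope="session")
def fixture_tables(fixture_events):
    return fv.build_tables(fixture_events, unit="PT")
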