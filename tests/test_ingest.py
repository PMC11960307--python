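"""Reader, FDA deduplication rule and target-drug screening."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import faerspv as fv
from faerspv.ingest import RawTables, TABLE_COLUMNS

from oracles import count_file_rows

TARGET_PATTERNS = ["ETELCALCETIDE", "AMG 416", "PARSABIV"]


def _write_quarter(path, rows_by_table):
    path.mkdir(parents=True, exist_ok=True)
    for name, cols in TABLE_COLUMNS.items():
        lines = ["$".join(cols)]
        for row in rows_by_table.get(name, []):
            lines.append("$".join(str(row.get(c, "")) for c in cols))
        (path / f"{name.upper()}.txt").write_text("\n".join(lines) + "\n")


def _demo_row(pid, cid, fda=20200101, **kw):
    row = {"primaryid": pid, "caseid": cid, "caseversion": 1, "fda_dt": fda, "sex": "M"}
    row.update(kw)
    return row


# ---------------------------------------------------------------------------
# reading


def test_read_quarter_round_trips_generated_counts(fixture_run, fixture_raw):
    out, _ = fixture_run
    qdirs = [p for p in out.iterdir() if p.is_dir()]
    assert len(fixture_raw.demo) == sum(count_file_rows(q / "DEMO.txt") for q in qdirs)
    assert len(fixture_raw.reac) == sum(count_file_rows(q / "REAC.txt") for q in qdirs)
    assert all(v == 0 for v in fixture_raw.skipped.values())


def test_malformed_row_is_skipped_and_counted(tmp_path):
    q = tmp_path / "2020q1"
    _write_quarter(q, {"demo": [_demo_row(1, 1)], "reac": [{"primaryid": 1, "caseid": 1, "pt": "Nausea"}]})
    with (q / "REAC.txt").open("a") as fh:
        fh.write("2$1$Bad$Extra$Field\n")  # embedded extra `$`
    raw = fv.read_quarter(q)
    assert raw.skipped["reac"] == 1
    assert len(raw.reac) == 1


def test_missing_tables_raise_naming_them(tmp_path):
    q = tmp_path / "2020q1"
    q.mkdir()
    (q / "DEMO.txt").write_text("$".join(TABLE_COLUMNS["demo"]) + "\n")
    with pytest.raises(FileNotFoundError) as err:
        fv.read_quarter(q)
    for name in ("DRUG", "REAC", "THER", "OUTC"):
        assert name in str(err.value)


def test_empty_table_file_warns_and_yields_empty(tmp_path):
    q = tmp_path / "2020q1"
    _write_quarter(q, {"demo": [_demo_row(1, 1)]})
    (q / "OUTC.txt").write_text("")
    with pytest.warns(UserWarning, match="OUTC"):
        raw = fv.read_quarter(q)
    assert raw.outc.empty


# ---------------------------------------------------------------------------
# deduplication


def test_dedup_keeps_highest_fda_dt_then_highest_primaryid():
    # later FDA_DT wins even when its PRIMARYID is smaller
    demo = pd.DataFrame(
        [_demo_row(90, 9, fda=20180101), _demo_row(88, 9, fda=20180401)]
    ).reindex(columns=TABLE_COLUMNS["demo"])
    raw = RawTables(
        demo=demo,
        drug=pd.DataFrame(columns=TABLE_COLUMNS["drug"]),
        reac=pd.DataFrame(columns=TABLE_COLUMNS["reac"]),
        ther=pd.DataFrame(columns=TABLE_COLUMNS["ther"]),
        outc=pd.DataFrame(columns=TABLE_COLUMNS["outc"]),
    )
    cases = fv.deduplicate(raw)
    assert cases.demo["primaryid"].tolist() == [88]


def test_dedup_recovers_ground_truth_ledger_exactly(fixture_run, fixture_cases):
    _, gt = fixture_run
    survivors = set(fixture_cases.demo["primaryid"].astype(int))
    assert survivors == set(gt.retained.values())
    assert fixture_cases.demo["caseid"].is_unique


def test_dedup_is_idempotent(fixture_cases):
    again = fv.deduplicate(fixture_cases)
    assert set(again.demo["primaryid"].astype(int)) == set(
        fixture_cases.demo["primaryid"].astype(int)
    )
    assert len(again.reac) == len(fixture_cases.reac)


def test_dedup_is_order_independent(fixture_raw):
    rng = np.random.default_rng(1)
    shuffled = RawTables(
        demo=fixture_raw.demo.sample(frac=1, random_state=rng.integers(2**31)).reset_index(drop=True),
        drug=fixture_raw.drug.sample(frac=1, random_state=rng.integers(2**31)).reset_index(drop=True),
        reac=fixture_raw.reac,
        ther=fixture_raw.ther,
        outc=fixture_raw.outc,
    )
    a = fv.deduplicate(fixture_raw)
    b = fv.deduplicate(shuffled)
    assert set(a.demo["primaryid"].astype(int)) == set(b.demo["primaryid"].astype(int))


def test_dedup_relinks_children_to_survivor_only(fixture_cases):
    survivors = set(fixture_cases.demo["primaryid"].astype(int))
    for tbl in ("drug", "reac", "ther", "outc"):
        pids = set(getattr(fixture_cases, tbl)["primaryid"].astype(int))
        assert pids <= survivors


def test_reactions_deduplicated_per_case(fixture_cases):
    assert not fixture_cases.reac.duplicated(["primaryid", "pt"]).any()


def test_age_normalization_and_bands():
    demo = pd.DataFrame(
        [
            _demo_row(1, 1, age=70, age_cod="YR"),
            _demo_row(2, 2, age=120, age_cod="MON"),  # 10 years -> <18
            _demo_row(3, 3, age=5.0, age_cod="DEC"),  # 50 years
            _demo_row(4, 4, age=44, age_cod="XXX"),  # unknown unit -> missing
            _demo_row(5, 5),
        ]
    ).reindex(columns=TABLE_COLUMNS["demo"])
    empty = {t: pd.DataFrame(columns=TABLE_COLUMNS[t]) for t in ("drug", "reac", "ther", "outc")}
    cases = fv.deduplicate(RawTables(demo=demo, **empty))
    bands = dict(zip(cases.demo["primaryid"].astype(int), cases.demo["age_band"]))
    assert bands == {1: ">=65", 2: "<18", 3: "45-64", 4: "UNK", 5: "UNK"}


# ---------------------------------------------------------------------------
# screening


def _toy_cases(drug_rows):
    n = len(drug_rows)
    demo = pd.DataFrame([_demo_row(i + 1, i + 1) for i in range(n)]).reindex(
        columns=TABLE_COLUMNS["demo"]
    )
    drug = pd.DataFrame(
        [
            {"primaryid": i + 1, "caseid": i + 1, "drug_seq": 1, **row}
            for i, row in enumerate(drug_rows)
        ]
    ).reindex(columns=TABLE_COLUMNS["drug"])
    reac = pd.DataFrame(
        [{"primaryid": i + 1, "caseid": i + 1, "pt": "Nausea"} for i in range(n)]
    ).reindex(columns=TABLE_COLUMNS["reac"])
    empty = {t: pd.DataFrame(columns=TABLE_COLUMNS[t]) for t in ("ther", "outc")}
    return fv.deduplicate(RawTables(demo=demo, drug=drug, reac=reac, **empty))


def test_screen_matches_substring_and_case_insensitively():
    cases = _toy_cases(
        [
            {"role_cod": "PS", "drugname": "PARSABIV 5MG", "prod_ai": ""},
            {"role_cod": "PS", "drugname": "amg 416", "prod_ai": ""},
            {"role_cod": "PS", "drugname": "CINACALCET", "prod_ai": "ETELCALCETIDE"},
            {"role_cod": "PS", "drugname": "CINACALCET", "prod_ai": ""},
        ]
    )
    out = fv.screen_target_drug(cases, TARGET_PATTERNS)
    assert sorted(out.demo["caseid"].astype(int)) == [1, 2, 3]


def test_screen_role_filter_ps_versus_ps_ss():
    cases = _toy_cases(
        [
            {"role_cod": "PS", "drugname": "PARSABIV", "prod_ai": ""},
            {"role_cod": "SS", "drugname": "PARSABIV", "prod_ai": ""},
            {"role_cod": "C", "drugname": "PARSABIV", "prod_ai": ""},
        ]
    )
    assert fv.screen_target_drug(cases, ["PARSABIV"]).n_cases == 1
    assert fv.screen_target_drug(cases, ["PARSABIV"], role_filter=("PS", "SS")).n_cases == 2


def test_screen_count_matches_ground_truth(fixture_run, fixture_cases):
    _, gt = fixture_run
    out = fv.screen_target_drug(fixture_cases, TARGET_PATTERNS)
    assert sorted(out.demo["caseid"].astype(int)) == sorted(gt.target_caseids)


def test_screen_is_monotone_in_patterns(fixture_cases):
    n1 = fv.screen_target_drug(fixture_cases, ["PARSABIV"]).n_cases
    n2 = fv.screen_target_drug(fixture_cases, ["PARSABIV", "AMG 416"]).n_cases
    n3 = fv.screen_target_drug(fixture_cases, TARGET_PATTERNS).n_cases
    assert n1 <= n2 <= n3


def test_screen_empty_pattern_list_errors(fixture_cases):
    with pytest.raises(ValueError, match="non-empty"):
        fv.screen_target_drug(fixture_cases, [])


def test_apply_deleted_list(fixture_cases):
    assert fv.apply_deleted_list(fixture_cases, []) is fixture_cases
    one = int(fixture_cases.demo["caseid"].iloc[0])
    with pytest.warns(UserWarning, match="removed 1"):
        fewer = fv.apply_deleted_list(fixture_cases, [one])
    assert fewer.n_cases == fixture_cases.n_cases - 1
    with pytest.warns(UserWarning, match="none of the"):
        same = fv.apply_deleted_list(fixture_cases, [-1, -2])
    assert same.n_cases == fixture_cases.n_cases
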