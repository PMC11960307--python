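"""Subgroup disproportionality and time-to-onset analysis."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import faerspv as fv
from faerspv.ingest import RawTables, TABLE_COLUMNS

TARGET_PATTERNS = ["ETELCALCETIDE", "AMG 416", "PARSABIV"]
NOSHRINK = fv.AnalysisConfig(shrinkage_mode="none")


# ---------------------------------------------------------------------------
# subgroup disproportionality


def test_constant_stratification_variable_equals_unstratified(fixture_events):
    ev = fixture_events.copy()
    ev["sex"] = "M"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per = fv.subgroup_signals(ev, "sex", NOSHRINK)
    full = fv.evaluate_tables(fv.build_tables(ev), NOSHRINK)
    sub = per["M"].drop(columns=["stratum", "evaluable"])
    pd.testing.assert_frame_equal(
        sub.sort_values("term").reset_index(drop=True),
        full.sort_values("term").reset_index(drop=True),
    )


def test_disjoint_strata_a_counts_sum_to_unstratified(fixture_events):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per = fv.subgroup_signals(fixture_events, "sex", NOSHRINK)
    total = {
        t.term: t.a for t in fv.build_tables(fixture_events)
    }
    summed: dict[str, int] = {}
    for df in per.values():
        if df.empty:
            continue
        for term, a in zip(df["term"], df["a"]):
            summed[term] = summed.get(term, 0) + int(a)
    assert summed == total


def test_small_strata_marked_not_evaluable(fixture_events):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per = fv.subgroup_signals(fixture_events, "age_band", NOSHRINK)
    for df in per.values():
        if not df.empty:
            assert ((df["a"] >= 3) == df["evaluable"]).all()


def test_empty_stratum_warns_and_yields_empty_table(fixture_events):
    ev = fixture_events[fixture_events["sex"] != "F"]
    with pytest.warns(UserWarning, match="sex=F"):
        per = fv.subgroup_signals(ev, "sex", NOSHRINK, levels=("M", "F"))
    assert per["F"].empty


def test_sex_specific_planted_signal_found_in_males_only(tmp_path):
    """A male-only planted RR flags in the male stratum, not the female one."""
    hits = 0
    n_rep = 50
    for i in range(n_rep):
        cfg = fv.GeneratorConfig(
            n_cases=1000,
            n_pts=50,
            planted_signals=[fv.PlantedSignal("PT_0003", 6.0, sex="M")],
            missing_sex_rate=0.10,
            duplicate_rate=0.0,
            missing_date_rate=0.0,
            quarters=("2022q1",),
            seed=1000 + i,
        )
        run = tmp_path / f"rep{i}"
        fv.generate_quarters(cfg, run)
        raw = fv.load_quarters([run / "2022q1"])
        marked = fv.mark_target(fv.deduplicate(raw), TARGET_PATTERNS)
        ev = fv.map_events(marked, fv.load_dictionary(run / "synthetic_meddra.txt"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per = fv.subgroup_signals(ev, "sex", NOSHRINK, levels=("M", "F"))

        def _flag(df):
            row = df[df["term"] == "PT_0003"] if not df.empty else df
            return bool(row["ror_sig"].iloc[0]) if len(row) else False

        if _flag(per["M"]) and not _flag(per["F"]):
            hits += 1
    assert hits >= int(0.9 * n_rep)


# ---------------------------------------------------------------------------
# time to onset


def _tto_caseset(rows):
    """rows: (pid, event_dt, start_dt, pts)"""
    demo = pd.DataFrame(
        [
            {
                "primaryid": pid,
                "caseid": pid,
                "caseversion": 1,
                "fda_dt": 20210101,
                "event_dt": event,
                "sex": "M",
            }
            for pid, event, start, pts in rows
        ]
    ).reindex(columns=TABLE_COLUMNS["demo"])
    drug = pd.DataFrame(
        [
            {
                "primaryid": pid,
                "caseid": pid,
                "drug_seq": 1,
                "role_cod": "PS",
                "drugname": "PARSABIV",
                "prod_ai": "",
            }
            for pid, *_ in rows
        ]
    ).reindex(columns=TABLE_COLUMNS["drug"])
    reac = pd.DataFrame(
        [
            {"primaryid": pid, "caseid": pid, "pt": pt}
            for pid, event, start, pts in rows
            for pt in pts
        ]
    ).reindex(columns=TABLE_COLUMNS["reac"])
    ther = pd.DataFrame(
        [
            {"primaryid": pid, "caseid": pid, "dsg_drug_seq": 1, "start_dt": start}
            for pid, event, start, pts in rows
        ]
    ).reindex(columns=TABLE_COLUMNS["ther"])
    empty = {"outc": pd.DataFrame(columns=TABLE_COLUMNS["outc"])}
    cases = fv.deduplicate(RawTables(demo=demo, drug=drug, reac=reac, ther=ther, **empty))
    return fv.screen_target_drug(cases, ["PARSABIV"])


def test_tto_date_arithmetic_and_exclusions():
    cases = _tto_caseset(
        [
            (1, 20180111, 20180101, ["PT A"]),  # 10 days
            (2, 20180101, 20180111, ["PT A"]),  # event before start -> implausible
            (3, 20180100, 20180101, ["PT A"]),  # partial event date -> unspecified
            (4, 20180111, 20180100, ["PT A"]),  # partial start date -> unspecified
            (5, 20180111, 20180101, ["PT A", "PT B"]),  # two events, one case
        ]
    )
    records, tally = fv.compute_tto(cases)
    assert tally == {"known": 3, "unspecified": 2, "implausible": 1}
    assert sorted(records["days"]) == [10, 10, 10]
    n_events = len(cases.reac.drop_duplicates(["caseid", "pt"]))
    assert tally["known"] + tally["unspecified"] + tally["implausible"] == n_events


def test_tto_uses_earliest_target_start_date():
    cases = _tto_caseset([(1, 20180201, 20180115, ["PT A"])])
    # add a second, earlier target-drug course
    extra_drug = pd.DataFrame(
        [{"primaryid": 1, "caseid": 1, "drug_seq": 2, "role_cod": "PS", "drugname": "PARSABIV", "prod_ai": "", "is_target": True}]
    )
    cases.drug = pd.concat([cases.drug, extra_drug], ignore_index=True)
    cases.ther = pd.concat(
        [cases.ther, pd.DataFrame([{"primaryid": 1, "caseid": 1, "dsg_drug_seq": 2, "start_dt": 20180101}])],
        ignore_index=True,
    )
    records, _ = fv.compute_tto(cases)
    assert records["days"].tolist() == [31]


def test_histogram_enumeration_and_contracts():
    hist = fv.tto_histogram(pd.DataFrame({"days": [5, 40, 400]}))
    assert hist["count"].tolist() == [1, 1, 0, 0, 0, 1]
    assert hist["percent"].sum() == pytest.approx(100.0, abs=0.01)

    one_bin = fv.tto_histogram(pd.DataFrame({"days": [5, 7, 11]}))
    assert one_bin["percent_2dp"].tolist()[0] == 100.0

    with pytest.raises(ValueError, match="overlap"):
        fv.tto_histogram(pd.DataFrame({"days": [5]}), bin_edges=(30, 30, 90))


def test_histogram_reproduces_printed_tail_percentages():
    # 136 of 780 known-TTO events beyond 360 d and 118 in 181-360 d
    days = [10] * 526 + [200] * 118 + [400] * 136
    hist = fv.tto_histogram(pd.DataFrame({"days": days}))
    by_bin = dict(zip(hist["bin"], hist["percent_2dp"]))
    assert by_bin[">360"] == 17.44
    assert by_bin["181-360"] == 15.13


def test_tto_median_recovery_from_generator(tmp_path):
    cfg = fv.GeneratorConfig(
        n_cases=1600,
        target_fraction=0.75,
        duplicate_rate=0.0,
        missing_date_rate=0.10,
        quarters=("2021q1",),
        seed=21,
    )
    fv.generate_quarters(cfg, tmp_path)
    raw = fv.load_quarters([tmp_path / "2021q1"])
    screened = fv.screen_target_drug(fv.deduplicate(raw), TARGET_PATTERNS)
    records, tally = fv.compute_tto(screened)
    assert tally["known"] >= 1000
    median = float(records["days"].median())
    assert abs(median - 82.0) / 82.0 <= 0.10


def test_group_comparison_power_and_contracts():
    rng = np.random.default_rng(5)
    short = np.round(rng.lognormal(np.log(30), 1.0, 200))
    long = np.round(rng.lognormal(np.log(300), 1.0, 200))
    df = pd.DataFrame(
        {"days": np.concatenate([short, long]), "sex": ["M"] * 200 + ["F"] * 200}
    )
    res = fv.compare_tto(df, "sex")
    assert res.test == "mann-whitney"
    assert res.pvalue < 1e-3
    assert res.sizes == {"M": 200, "F": 200}

    with pytest.raises(ValueError, match=">= 2"):
        fv.compare_tto(pd.DataFrame({"days": [1, 2, 3], "sex": ["M"] * 3}), "sex")


def test_group_comparison_kruskal_for_three_groups():
    rng = np.random.default_rng(6)
    df = pd.DataFrame(
        {
            "days": np.round(rng.lognormal(np.log(80), 1.0, 300)),
            "age_band": ["18-44"] * 100 + ["45-64"] * 100 + [">=65"] * 100,
        }
    )
    res = fv.compare_tto(df, "age_band")
    assert res.test == "kruskal-wallis"
    assert 0 <= res.pvalue <= 1


def test_group_comparison_null_pvalues_are_uniform():
    """With permuted labels the rank-sum p-value is U(0,1) (KS at alpha=0.01)."""
    rng = np.random.default_rng(7)
    base = np.round(rng.lognormal(np.log(82), 1.2, 120))
    pvals = []
    for _ in range(200):
        labels = np.array(["M"] * 60 + ["F"] * 60)
        rng.shuffle(labels)
        df = pd.DataFrame({"days": base, "sex": labels})
        pvals.append(fv.compare_tto(df, "sex").pvalue)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01
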