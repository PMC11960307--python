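"""Time-to-onset (TTO) analysis: days from therapy start to the event.

TTO for a case is ``event_dt − min(start_dt over its target-drug records)``
— the earliest exposure to the drug of interest. Records whose event or
start date is missing or partial (FAERS pads unknown month/day with 00) are
excluded and tallied as ``unspecified``; negative differences (event before
therapy start) are tallied as ``implausible``. One TTO record is produced
per (case, PT) pair, carrying sex and age band for subgroup comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from faerspv._util import round_half_up, yyyymmdd_to_date
from faerspv.ingest import CaseSet

__all__ = ["GroupComparison", "compare_tto", "compute_tto", "tto_histogram"]

DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)


def compute_tto(cases: CaseSet) -> tuple[pd.DataFrame, dict[str, int]]:
    """TTO records for a target-screened case set, plus an exclusion tally.

    Requires the DRUG table to carry the ``is_target`` flag set by
    :func:`faerspv.ingest.mark_target` / ``screen_target_drug``. Returns a
    DataFrame with columns (caseid, pt, days, sex, age_band) — one row per
    (case, PT) with a computable onset time — and a tally with keys
    ``known``, ``unspecified`` and ``implausible`` that partitions the
    screened case-event rows.
    """
    if "is_target" not in cases.drug.columns:
        raise ValueError("cases must be screened/marked for the target drug before compute_tto()")
    tgt = cases.drug[cases.drug["is_target"]][["primaryid", "drug_seq"]]
    ther = cases.ther.merge(
        tgt, left_on=["primaryid", "dsg_drug_seq"], right_on=["primaryid", "drug_seq"], how="inner"
    )
    # earliest valid target-drug start date per report
    start_dates = {}
    partial_start = set()
    for r in ther.itertuples():
        pid = int(r.primaryid)
        d = yyyymmdd_to_date(r.start_dt)
        if d is None:
            partial_start.add(pid)
            continue
        if pid not in start_dates or d < start_dates[pid]:
            start_dates[pid] = d

    events = cases.reac[["primaryid", "caseid", "pt"]].drop_duplicates(["caseid", "pt"])
    demo = cases.demo.set_index("primaryid")
    rows = []
    tally = {"known": 0, "unspecified": 0, "implausible": 0}
    for r in events.itertuples():
        pid = int(r.primaryid)
        event_date = yyyymmdd_to_date(demo.at[pid, "event_dt"])
        start_date = start_dates.get(pid)
        if event_date is None or start_date is None:
            tally["unspecified"] += 1
            continue
        days = (event_date - start_date).days
        if days < 0:
            tally["implausible"] += 1
            continue
        tally["known"] += 1
        rows.append(
            {
                "caseid": int(r.caseid),
                "pt": r.pt,
                "days": days,
                "sex": demo.at[pid, "sex_norm"],
                "age_band": demo.at[pid, "age_band"],
            }
        )
    records = pd.DataFrame(rows, columns=["caseid", "pt", "days", "sex", "age_band"])
    return records, tally


def tto_histogram(records, bin_edges=DEFAULT_BIN_EDGES) -> pd.DataFrame:
    """Bin TTO days into contiguous intervals plus an open top bin.

    ``bin_edges=(30, 60, 90, 180, 360)`` produces the bins 0–30, 31–60,
    61–90, 91–180, 181–360 and >360 days (edges inclusive on the right).
    Returns counts and percentages of the known-TTO records; the percentages
    sum to 100 within 0.01.
    """
    edges = list(bin_edges)
    if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])) or (edges and edges[0] < 0):
        raise ValueError("bin edges must be strictly increasing and non-negative (bins must not overlap)")
    days = np.asarray(records["days"] if isinstance(records, pd.DataFrame) else records, dtype=float)
    bounds = [-np.inf, *edges, np.inf]
    labels = []
    lo = 0
    for e in edges:
        labels.append(f"{lo}-{e}")
        lo = e + 1
    labels.append(f">{edges[-1]}" if edges else "all")
    counts = [
        int(((days > bounds[i]) & (days <= bounds[i + 1])).sum()) for i in range(len(bounds) - 1)
    ]
    total = int(sum(counts))
    pct = [100.0 * c / total if total else float("nan") for c in counts]
    return pd.DataFrame(
        {
            "bin": labels,
            "count": counts,
            "percent": pct,
            "percent_2dp": [round_half_up(p, 2) for p in pct],
        }
    )


@dataclass
class GroupComparison:
    """Result of a rank-based k-sample comparison of onset times."""

    test: str
    statistic: float
    pvalue: float
    medians: dict[str, float]
    sizes: dict[str, int]
    excluded: list[str]


def compare_tto(
    records: pd.DataFrame,
    variable: str,
    include_unknown: bool = False,
    min_group_size: int = 3,
) -> GroupComparison:
    """Compare TTO distributions across the levels of ``variable``.

    Two groups → two-sided Wilcoxon rank-sum (Mann–Whitney U); more than two
    → Kruskal–Wallis. Onset times are heavily right-skewed, so rank-based
    tests are used throughout. Groups smaller than ``min_group_size`` are
    excluded with a warning; fewer than two usable groups is an error.
    """
    df = records
    if not include_unknown:
        df = df[df[variable] != "UNK"]
    groups = {str(level): sub["days"].to_numpy(float) for level, sub in df.groupby(variable, sort=True)}
    excluded = [lvl for lvl, v in groups.items() if len(v) < min_group_size]
    for lvl in excluded:
        warnings.warn(f"compare_tto: group {variable}={lvl} has n < {min_group_size}; excluded", stacklevel=2)
        del groups[lvl]
    if len(groups) < 2:
        raise ValueError(f"compare_tto needs >= 2 non-empty groups of {variable}, got {len(groups)}")
    values = list(groups.values())
    if len(values) == 2:
        res = stats.mannwhitneyu(values[0], values[1], alternative="two-sided", method="asymptotic")
        test = "mann-whitney"
    else:
        res = stats.kruskal(*values)
        test = "kruskal-wallis"
    return GroupComparison(
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        medians={lvl: float(np.median(v)) for lvl, v in groups.items()},
        sizes={lvl: int(len(v)) for lvl, v in groups.items()},
        excluded=excluded,
    )
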