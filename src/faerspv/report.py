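"""Summaries and exports: demographics, signal ranking, CSV/JSON output.

Percentages use the total case count as the base — including unknown levels,
which is how spontaneous-report studies print their demographic tables (the
known-level percentages then do not sum to 100) — and are rounded half-up to
two decimals through one shared helper so printed values are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from faerspv._util import round_half_up
from faerspv.ingest import CaseReport, CaseSet

__all__ = ["demographics_summary", "export_results", "rank_signals"]

_DIMENSIONS = ("sex", "age_band", "reporter", "year", "country", "seriousness", "outcome")


def _level_table(pairs: list[tuple[str, int]], total: int) -> pd.DataFrame:
    df = pd.DataFrame(pairs, columns=["level", "count"])
    df["percent"] = [round_half_up(100.0 * c / total, 2) if total else float("nan") for c in df["count"]]
    return df


def demographics_summary(cases: CaseSet | Sequence[CaseReport]) -> dict[str, pd.DataFrame]:
    """One (level, count, percent-of-total-cases) table per dimension.

    Dimensions: sex, age_band, reporter, year (of FDA receipt), country,
    seriousness, outcome. Outcome counts cases per outcome code, so a case
    with several codes appears under each; every percent uses the total case
    count as its base.
    """
    reports = cases.to_case_reports() if isinstance(cases, CaseSet) else list(cases)
    total = len(reports)

    def _count(keyfun) -> list[tuple[str, int]]:
        counts: dict[str, int] = {}
        for rep in reports:
            k = keyfun(rep)
            counts[k] = counts.get(k, 0) + 1
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    out = {
        "sex": _level_table(_count(lambda r: r.sex), total),
        "age_band": _level_table(_count(lambda r: r.age_band), total),
        "reporter": _level_table(_count(lambda r: r.reporter), total),
        "year": _level_table(_count(lambda r: str(r.fda_dt // 10000)), total),
        "country": _level_table(_count(lambda r: r.country), total),
        "seriousness": _level_table(
            _count(lambda r: "serious" if r.serious else "non-serious"), total
        ),
    }
    outcome_counts: dict[str, int] = {}
    for rep in reports:
        for code in sorted(rep.outcomes):
            outcome_counts[code] = outcome_counts.get(code, 0) + 1
    out["outcome"] = _level_table(
        sorted(outcome_counts.items(), key=lambda kv: (-kv[1], kv[0])), total
    )
    return out


def rank_signals(signal_table: pd.DataFrame, by: str = "ebgm", top_n: int | None = 30) -> pd.DataFrame:
    """Rank four-algorithm signals by a chosen statistic.

    Rows failing any of the four algorithms (``all_four`` false) are dropped,
    then sorted descending by ``by`` (one of ebgm, ror, prr, ic, a); ties are
    broken by larger ``a``, then term lexicographically.
    """
    if by not in ("ebgm", "ror", "prr", "ic", "a"):
        raise ValueError(f"cannot rank by {by!r}; choose one of ebgm, ror, prr, ic, a")
    if by not in signal_table.columns:
        raise ValueError(f"signal table has no computed column {by!r}")
    df = signal_table[signal_table["all_four"]].copy()
    df = df.sort_values(
        by=[by, "a", "term"], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        df = df.head(top_n)
    return df


def _config_hash(metadata: Mapping) -> str:
    return hashlib.sha256(json.dumps(metadata, sort_keys=True, default=str).encode()).hexdigest()[:16]


def export_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    formats: Sequence[str] = ("csv", "json"),
    metadata: Mapping | None = None,
) -> list[Path]:
    """Write each table as CSV and/or JSON, plus a run-metadata JSON.

    Output is deterministic: identical inputs produce byte-identical files.
    The metadata file carries a hash of the run configuration, the per-table
    row counts, and whatever the caller supplies (seed, quarter list, ...).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory {out} is not writable: {exc}") from exc
    written: list[Path] = []
    for name, df in tables.items():
        if "csv" in formats:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False, lineterminator="\n")
            written.append(p)
        if "json" in formats:
            p = out / f"{name}.json"
            p.write_text(json.dumps(df.to_dict(orient="records"), indent=1, sort_keys=True, default=str))
            written.append(p)
    meta = dict(metadata or {})
    meta["row_counts"] = {name: int(len(df)) for name, df in tables.items()}
    meta["config_hash"] = _config_hash(meta)
    p = out / "run_metadata.json"
    p.write_text(json.dumps(meta, indent=1, sort_keys=True, default=str))
    written.append(p)
    return written
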