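"""Reading FAERS-style quarterly extracts, deduplication and drug screening.

FAERS quarterly data ships as five ``$``-delimited ASCII tables per quarter
(DEMO, DRUG, REAC, THER, OUTC). The reader here is deliberately strict about
shape — a row whose field count disagrees with the header is skipped and
counted, never silently mangled — because spontaneous-report extracts
routinely contain stray delimiters.

Deduplication follows the FDA-recommended rule: a case (CASEID) may appear as
several report versions (PRIMARYIDs); keep the version with the highest
FDA_DT, breaking ties on (CASEID, FDA_DT) by the highest PRIMARYID. All child
tables are re-linked to the surviving version only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from faerspv._util import age_bands_vector, normalize_age_years

__all__ = [
    "TABLE_COLUMNS",
    "CaseReport",
    "CaseSet",
    "RawTables",
    "apply_deleted_list",
    "deduplicate",
    "load_quarters",
    "mark_target",
    "read_quarter",
    "screen_target_drug",
]

TABLE_COLUMNS = {
    "demo": [
        "primaryid",
        "caseid",
        "caseversion",
        "fda_dt",
        "event_dt",
        "sex",
        "age",
        "age_cod",
        "occp_cod",
        "occr_country",
    ],
    "drug": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "reac": ["primaryid", "caseid", "pt"],
    "ther": ["primaryid", "caseid", "dsg_drug_seq", "start_dt"],
    "outc": ["primaryid", "caseid", "outc_cod"],
}

_INT_COLUMNS = {"primaryid", "caseid", "caseversion", "fda_dt", "event_dt", "drug_seq", "dsg_drug_seq", "start_dt"}

#: Outcome codes FAERS uses; any code other than OT marks a serious case.
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


@dataclass
class RawTables:
    """The five quarterly tables plus per-table skipped-row counts."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    skipped: dict[str, int] = field(default_factory=dict)
    quarters: list[str] = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)


@dataclass
class CaseReport:
    """One deduplicated safety report."""

    primaryid: int
    caseid: int
    fda_dt: int
    event_dt: int | None
    sex: str  # M, F or UNK
    age_years: float | None
    age_band: str
    reporter: str
    country: str
    serious: bool
    outcomes: frozenset[str]
    drugs: list[tuple]  # (drugname, prod_ai, role_cod, drug_seq, start_dt)
    reactions: list[str]


@dataclass
class CaseSet:
    """Deduplicated cases as linked DataFrames (one DEMO row per CASEID)."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame

    @property
    def n_cases(self) -> int:
        return len(self.demo)

    def filter_primaryids(self, primaryids: Iterable[int]) -> "CaseSet":
        keep = set(int(p) for p in primaryids)
        return CaseSet(
            demo=self.demo[self.demo["primaryid"].isin(keep)].reset_index(drop=True),
            drug=self.drug[self.drug["primaryid"].isin(keep)].reset_index(drop=True),
            reac=self.reac[self.reac["primaryid"].isin(keep)].reset_index(drop=True),
            ther=self.ther[self.ther["primaryid"].isin(keep)].reset_index(drop=True),
            outc=self.outc[self.outc["primaryid"].isin(keep)].reset_index(drop=True),
        )

    def to_case_reports(self) -> list[CaseReport]:
        drugs_by_pid: dict[int, list] = {}
        start_by = {
            (int(r.primaryid), int(r.dsg_drug_seq)): (None if pd.isna(r.start_dt) else int(r.start_dt))
            for r in self.ther.itertuples()
        }
        for r in self.drug.itertuples():
            drugs_by_pid.setdefault(int(r.primaryid), []).append(
                (r.drugname, r.prod_ai, r.role_cod, int(r.drug_seq), start_by.get((int(r.primaryid), int(r.drug_seq))))
            )
        reac_by_pid: dict[int, list[str]] = {}
        for r in self.reac.itertuples():
            lst = reac_by_pid.setdefault(int(r.primaryid), [])
            if r.pt not in lst:
                lst.append(r.pt)
        outc_by_pid: dict[int, set[str]] = {}
        for r in self.outc.itertuples():
            outc_by_pid.setdefault(int(r.primaryid), set()).add(r.outc_cod)
        reports = []
        for r in self.demo.itertuples():
            pid = int(r.primaryid)
            outcomes = frozenset(outc_by_pid.get(pid, set()))
            reports.append(
                CaseReport(
                    primaryid=pid,
                    caseid=int(r.caseid),
                    fda_dt=int(r.fda_dt),
                    event_dt=None if pd.isna(r.event_dt) else int(r.event_dt),
                    sex=r.sex_norm,
                    age_years=None if pd.isna(r.age_years) else float(r.age_years),
                    age_band=r.age_band,
                    reporter=r.occp_cod if isinstance(r.occp_cod, str) and r.occp_cod else "UNK",
                    country=r.occr_country if isinstance(r.occr_country, str) and r.occr_country else "UNK",
                    serious=bool(outcomes - {"OT"}),
                    outcomes=outcomes,
                    drugs=drugs_by_pid.get(pid, []),
                    reactions=reac_by_pid.get(pid, []),
                )
            )
        return reports


# ---------------------------------------------------------------------------
# reading


def _parse_table(path: Path, name: str) -> tuple[pd.DataFrame, int]:
    text = path.read_text()
    lines = text.splitlines()
    if not lines:
        warnings.warn(f"{name.upper()} table at {path} is empty", stacklevel=3)
        return pd.DataFrame(columns=TABLE_COLUMNS[name]), 0
    header = [h.strip().lower() for h in lines[0].split("$")]
    n_fields = len(header)
    rows, skipped = [], 0
    for line in lines[1:]:
        if not line:
            continue
        parts = line.split("$")
        if len(parts) != n_fields:
            skipped += 1
            continue
        rows.append(parts)
    df = pd.DataFrame(rows, columns=header)
    for col in df.columns:
        if col in _INT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        else:
            df[col] = df[col].astype(object).where(df[col] != "", other=np.nan)
    return df, skipped


def _find_table_file(path: Path, name: str) -> Path | None:
    for cand in sorted(path.iterdir()):
        if cand.is_file() and cand.stem.lower().startswith(name):
            return cand
    return None


def read_quarter(path: str | Path) -> RawTables:
    """Load one quarter directory containing the five ``$``-delimited tables.

    Malformed rows (wrong field count) are skipped and counted in
    ``RawTables.skipped``. A missing table file is a hard error naming every
    missing table.
    """
    p = Path(path)
    files = {name: _find_table_file(p, name) for name in TABLE_COLUMNS}
    missing = [name.upper() for name, f in files.items() if f is None]
    if missing:
        raise FileNotFoundError(f"quarter {p} is missing table file(s): {', '.join(missing)}")
    tables, skipped = {}, {}
    for name, f in files.items():
        tables[name], skipped[name] = _parse_table(f, name)
        tables[name]["quarter"] = p.name
    return RawTables(**tables, skipped=skipped, quarters=[p.name])


def load_quarters(paths: Sequence[str | Path]) -> RawTables:
    """Read and concatenate several quarter directories."""
    parts = [read_quarter(p) for p in paths]
    if len(parts) == 1:
        return parts[0]
    skipped: dict[str, int] = {}
    for part in parts:
        for k, v in part.skipped.items():
            skipped[k] = skipped.get(k, 0) + v
    return RawTables(
        demo=pd.concat([p.demo for p in parts], ignore_index=True),
        drug=pd.concat([p.drug for p in parts], ignore_index=True),
        reac=pd.concat([p.reac for p in parts], ignore_index=True),
        ther=pd.concat([p.ther for p in parts], ignore_index=True),
        outc=pd.concat([p.outc for p in parts], ignore_index=True),
        skipped=skipped,
        quarters=[q for p in parts for q in p.quarters],
    )


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(raw: RawTables | CaseSet) -> CaseSet:
    """Keep one report version per CASEID (max FDA_DT, then max PRIMARYID).

    Child-table records are re-linked to the surviving PRIMARYID only.
    Partial FDA_DT values compare as plain YYYYMMDD integers (unknown month
    or day padded with 00), which preserves the ordering of the rule. The
    operation is idempotent and independent of input row order. Derived
    columns (normalised sex, age in years, age band) are added to DEMO.
    """
    demo = raw.demo
    if demo.empty:
        empty = {name: pd.DataFrame(columns=TABLE_COLUMNS[name]) for name in TABLE_COLUMNS}
        return CaseSet(**empty)
    order = demo.sort_values(["caseid", "fda_dt", "primaryid"], kind="mergesort")
    survivors = order.groupby("caseid", sort=True).tail(1).reset_index(drop=True)
    keep = set(survivors["primaryid"].astype(int))

    survivors = survivors.copy()
    sex = survivors.get("sex", pd.Series(np.nan, index=survivors.index))
    sex = sex.fillna("").astype(str).str.strip().str.upper()
    survivors["sex_norm"] = sex.where(sex.isin(["M", "F"]), "UNK")
    survivors["age_years"] = normalize_age_years(survivors["age"], survivors["age_cod"])
    survivors["age_band"] = age_bands_vector(survivors["age_years"])

    def _children(df: pd.DataFrame, name: str) -> pd.DataFrame:
        if df.empty:
            return df.copy()
        out = df[df["primaryid"].isin(keep)].reset_index(drop=True)
        if name == "reac":  # a PT appears at most once per case
            out = out.drop_duplicates(["primaryid", "pt"]).reset_index(drop=True)
        return out

    return CaseSet(
        demo=survivors.sort_values("primaryid", kind="mergesort").reset_index(drop=True),
        drug=_children(raw.drug, "drug"),
        reac=_children(raw.reac, "reac"),
        ther=_children(raw.ther, "ther"),
        outc=_children(raw.outc, "outc"),
    )


# ---------------------------------------------------------------------------
# screening


def _match_mask(drug: pd.DataFrame, patterns: Sequence[str], roles: Sequence[str] | None) -> pd.Series:
    if not patterns:
        raise ValueError("pattern list must be non-empty")
    name = drug["drugname"].fillna("").astype(str).str.upper()
    ai = drug["prod_ai"].fillna("").astype(str).str.upper()
    hit = pd.Series(False, index=drug.index)
    for pat in patterns:
        pu = str(pat).upper()
        hit |= name.str.contains(pu, regex=False) | ai.str.contains(pu, regex=False)
    if roles is not None:
        hit &= drug["role_cod"].fillna("").astype(str).str.upper().isin([r.upper() for r in roles])
    return hit


def mark_target(
    cases: CaseSet, name_patterns: Sequence[str], role_filter: Sequence[str] = ("PS",)
) -> CaseSet:
    """Flag target-drug records without dropping any case.

    Adds ``is_target`` to DRUG (pattern matched in drugname or prod_ai as a
    case-insensitive substring, role within ``role_filter``) and
    ``is_target_case`` to DEMO. ``role_filter`` defaults to primary suspect
    only; pass ``("PS", "SS")`` to widen.
    """
    hit = _match_mask(cases.drug, name_patterns, role_filter)
    drug = cases.drug.copy()
    drug["is_target"] = hit
    target_pids = set(drug.loc[hit, "primaryid"].astype(int))
    demo = cases.demo.copy()
    demo["is_target_case"] = demo["primaryid"].astype(int).isin(target_pids)
    return CaseSet(demo=demo, drug=drug, reac=cases.reac, ther=cases.ther, outc=cases.outc)


def screen_target_drug(
    cases: CaseSet, name_patterns: Sequence[str], role_filter: Sequence[str] = ("PS",)
) -> CaseSet:
    """Retain only the cases naming the target drug (see :func:`mark_target`)."""
    marked = mark_target(cases, name_patterns, role_filter)
    keep = marked.demo.loc[marked.demo["is_target_case"], "primaryid"].astype(int)
    out = marked.filter_primaryids(keep)
    return out


def apply_deleted_list(cases: CaseSet, deleted_caseids: Iterable[int]) -> CaseSet:
    """Drop cases whose CASEID appears on an FDA deleted-case list."""
    deleted = set(int(c) for c in deleted_caseids)
    if not deleted:
        return cases
    present = set(cases.demo["caseid"].astype(int))
    unknown = deleted - present
    if unknown and not (deleted & present):
        warnings.warn(f"deleted-case list: none of the {len(deleted)} CASEIDs are present", stacklevel=2)
        return cases
    keep = cases.demo.loc[~cases.demo["caseid"].astype(int).isin(deleted), "primaryid"]
    removed = cases.n_cases - len(keep)
    if removed:
        warnings.warn(f"deleted-case list removed {removed} case(s)", stacklevel=2)
    return cases.filter_primaryids(keep)
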