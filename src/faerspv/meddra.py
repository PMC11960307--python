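"""Preferred Term → System Organ Class mapping via a pluggable dictionary.

MedDRA itself is licensed, so the package ships a synthetic dictionary
(``data/synthetic_meddra.txt``) covering the 26 SOCs with representative PT
names; a real MedDRA export in the same ``pt $ soc_name $ soc_code`` file
format can be dropped in without code changes. FAERS REAC rows are already
MedDRA-coded PT strings, so matching is exact after trimming and
case-folding.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from faerspv.ingest import CaseSet

__all__ = ["MedDRAMap", "load_dictionary", "map_events", "packaged_dictionary"]

UNMAPPED_SOC = ("UNMAPPED", "")


def _key(pt: str) -> str:
    return str(pt).strip().casefold()


@dataclass
class MedDRAMap:
    """A total PT → primary-SOC mapping over a declared vocabulary."""

    pt_to_soc: dict[str, tuple[str, str]]
    version: str = "synthetic"

    def lookup(self, pt: str) -> tuple[str, str]:
        """SOC (name, code) of a PT; unknown PTs map to ``UNMAPPED``."""
        return self.pt_to_soc.get(_key(pt), UNMAPPED_SOC)

    def __contains__(self, pt: str) -> bool:
        return _key(pt) in self.pt_to_soc

    def __len__(self) -> int:
        return len(self.pt_to_soc)

    @property
    def soc_names(self) -> set[str]:
        return {name for name, _ in self.pt_to_soc.values()}


def load_dictionary(path: str | Path, version: str | None = None) -> MedDRAMap:
    """Load a ``pt $ soc_name [$ soc_code]`` delimited dictionary file.

    Duplicate PT rows are allowed only when they agree; conflicting rows
    raise with the offending PTs listed.
    """
    p = Path(path)
    mapping: dict[str, tuple[str, str]] = {}
    conflicts: dict[str, set[tuple[str, str]]] = {}
    n_rows = 0
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("pt$"):
            continue
        parts = [f.strip() for f in line.split("$")]
        if len(parts) == 2:
            pt, soc_name, soc_code = parts[0], parts[1], ""
        elif len(parts) == 3:
            pt, soc_name, soc_code = parts
        else:
            raise ValueError(f"dictionary {p}: row {line!r} does not have 2 or 3 fields")
        n_rows += 1
        k = _key(pt)
        soc = (soc_name, soc_code)
        if k in mapping and mapping[k] != soc:
            conflicts.setdefault(pt, {mapping[k]}).add(soc)
        mapping[k] = mapping.get(k, soc)
    if conflicts:
        detail = "; ".join(f"{pt!r} -> {sorted(socs)}" for pt, socs in sorted(conflicts.items()))
        raise ValueError(f"dictionary {p} maps PT(s) to more than one SOC: {detail}")
    if n_rows == 0:
        raise ValueError(f"dictionary {p} is empty")
    return MedDRAMap(pt_to_soc=mapping, version=version or p.stem)


def packaged_dictionary() -> MedDRAMap:
    """The synthetic dictionary shipped with the package (26 SOCs)."""
    ref = resources.files("faerspv").joinpath("data/synthetic_meddra.txt")
    with resources.as_file(ref) as path:
        return load_dictionary(path, version="synthetic-26soc")


def map_events(cases: CaseSet, mapping: MedDRAMap) -> pd.DataFrame:
    """One event row per (case, distinct PT) — the "distinct AEs" convention.

    A report listing several PTs contributes one row per PT; a PT repeated
    within one report counts once. Each row carries the case's target flag
    and stratification attributes, plus the PT's primary SOC (``UNMAPPED``
    for PTs absent from the dictionary — counted, never dropped).

    Requires :func:`faerspv.ingest.mark_target` to have been applied first,
    since downstream 2×2 tables need the target/other flag per event row.
    """
    if "is_target_case" not in cases.demo.columns:
        raise ValueError("cases must be passed through mark_target() before map_events()")
    ev = cases.reac[["primaryid", "caseid", "pt"]].copy()
    ev["pt"] = ev["pt"].astype(str).str.strip()
    ev["_ptkey"] = ev["pt"].str.casefold()
    ev = ev.drop_duplicates(["caseid", "_ptkey"]).drop(columns="_ptkey").reset_index(drop=True)
    socs = [mapping.lookup(pt) for pt in ev["pt"]]
    ev["soc_name"] = [s[0] for s in socs]
    ev["soc_code"] = [s[1] for s in socs]
    demo_cols = cases.demo.set_index("primaryid")[["is_target_case", "sex_norm", "age_band"]]
    ev = ev.join(demo_cols, on="primaryid")
    ev = ev.rename(columns={"is_target_case": "is_target", "sex_norm": "sex"})
    return ev
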