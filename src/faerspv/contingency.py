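"""2×2 contingency tables for each term versus all other drugs.

For a term (PT or SOC) and the target drug, the table is

=============  ==============  ==============
               term            other terms
=============  ==============  ==============
target drug    a               b
other drugs    c               d
=============  ==============  ==============

with N = a+b+c+d. The default margin convention is EVENT-level: each
(case, PT) row counts once, so a+b is the target drug's total distinct
event count, not its case count. A ``margins="case"`` switch counts
distinct cases instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["ContingencyTable", "build_tables", "tables_to_frame"]


@dataclass(frozen=True)
class ContingencyTable:
    unit: str  # "PT" or "SOC"
    term: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValueError(f"contingency cell {cell} is negative for term {self.term!r}")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Expected count under independence, E = (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.N

    @property
    def raw_rr(self) -> float:
        """Relative report rate a/E (the unshrunk observed/expected ratio)."""
        return self.a / self.expected_a


def build_tables(
    event_table: pd.DataFrame, unit: str = "PT", margins: str = "event"
) -> list[ContingencyTable]:
    """Build one table per distinct term with a ≥ 1.

    ``event_table`` is the output of :func:`faerspv.meddra.map_events`: one
    row per (case, PT) with an ``is_target`` flag. SOC-level ``a`` counts
    event rows whose PT maps to the SOC (``margins="case"``: distinct cases).
    The c/d background is always the full comparator, so Σa over terms equals
    the total target event count and Σc the non-target event count.
    """
    if unit not in ("PT", "SOC"):
        raise ValueError(f"unit must be 'PT' or 'SOC', got {unit!r}")
    if margins not in ("event", "case"):
        raise ValueError(f"margins must be 'event' or 'case', got {margins!r}")
    term_col = "pt" if unit == "PT" else "soc_name"
    ev = event_table
    if not ev["is_target"].any():
        warnings.warn("event table has no target-drug rows; no tables built", stacklevel=2)
        return []
    if margins == "event":
        rows = ev[[term_col, "is_target"]]
        if unit == "SOC":
            # one row per (case, SOC-linked PT) — keep event rows as-is
            pass
        n_target = int(rows["is_target"].sum())
        n_other = len(rows) - n_target
        counts = rows.groupby([term_col, "is_target"], sort=True).size().unstack(fill_value=0)
    else:
        rows = ev[["caseid", term_col, "is_target"]].drop_duplicates(["caseid", term_col])
        case_flags = ev[["caseid", "is_target"]].drop_duplicates("caseid")
        n_target = int(case_flags["is_target"].sum())
        n_other = len(case_flags) - n_target
        counts = rows.groupby([term_col, "is_target"], sort=True).size().unstack(fill_value=0)
    for flag in (False, True):
        if flag not in counts.columns:
            counts[flag] = 0
    tables = []
    for term, row in counts.iterrows():
        a, c = int(row[True]), int(row[False])
        if a < 1:
            continue
        tables.append(
            ContingencyTable(unit=unit, term=str(term), a=a, b=n_target - a, c=c, d=n_other - c)
        )
    return tables


def tables_to_frame(tables: list[ContingencyTable]) -> pd.DataFrame:
    """Flatten tables to a DataFrame (columns unit, term, a, b, c, d, N)."""
    return pd.DataFrame(
        [
            {"unit": t.unit, "term": t.term, "a": t.a, "b": t.b, "c": t.c, "d": t.d, "N": t.N}
            for t in tables
        ],
        columns=["unit", "term", "a", "b", "c", "d", "N"],
    )
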