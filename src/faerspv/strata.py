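"""Subgroup disproportionality: rerun the whole analysis inside a stratum.

Both the target-drug events and the all-other-drugs comparator are restricted
to the stratum (sex or age band) before the 2×2 tables are rebuilt and all
four statistics recomputed, so a subgroup signal reflects the stratum's own
background reporting, not the overall one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from faerspv.contingency import build_tables
from faerspv.disprop import AnalysisConfig, evaluate_tables

__all__ = ["StratumSpec", "subgroup_signals"]

_VOCAB = {
    "sex": ("M", "F", "UNK"),
    "age_band": ("<18", "18-44", "45-64", ">=65", "UNK"),
}


@dataclass(frozen=True)
class StratumSpec:
    variable: str  # "sex" or "age_band"
    level: str

    def __post_init__(self) -> None:
        if self.variable not in _VOCAB:
            raise ValueError(f"unknown stratification variable {self.variable!r}")
        if self.level not in _VOCAB[self.variable]:
            raise ValueError(f"level {self.level!r} not in vocabulary of {self.variable!r}")


def subgroup_signals(
    event_table: pd.DataFrame,
    variable: str,
    cfg: AnalysisConfig = AnalysisConfig(),
    unit: str = "PT",
    levels: tuple[str, ...] | None = None,
    min_a: int = 3,
) -> dict[str, pd.DataFrame]:
    """Per-stratum signal tables for each level of ``variable``.

    Terms with a < ``min_a`` inside a stratum are kept in the table but
    marked ``evaluable=False`` (their statistics are too unstable to call).
    Empty strata yield an empty table with a warning.
    """
    if variable not in _VOCAB:
        raise ValueError(f"unknown stratification variable {variable!r}")
    if levels is None:
        levels = _VOCAB[variable]
    for level in levels:
        StratumSpec(variable, level)  # validates
    out: dict[str, pd.DataFrame] = {}
    for level in levels:
        sub = event_table[event_table[variable] == level]
        if sub.empty or not sub["is_target"].any():
            warnings.warn(f"stratum {variable}={level} has no (target) events", stacklevel=2)
            out[level] = pd.DataFrame()
            continue
        tables = build_tables(sub, unit=unit)
        df = evaluate_tables(tables, cfg)
        df.insert(0, "stratum", level)
        df["evaluable"] = df["a"] >= min_a
        out[level] = df
    return out
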