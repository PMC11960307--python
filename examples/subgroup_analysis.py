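"""Subgroup disproportionality: a male-only signal shows up only in males.

The generator plants a relative risk of 6 for one PT restricted to male
reports. Rebuilding the 2×2 tables inside each sex stratum (target AND
comparator restricted) localises the signal.
"""

import tempfile
import warnings
from pathlib import Path

import faerspv as fv

PATTERNS = ["ETELCALCETIDE", "AMG 416", "PARSABIV"]

cfg = fv.GeneratorConfig(
    n_cases=3000,
    n_pts=50,
    planted_signals=[fv.PlantedSignal("PT_0003", 6.0, sex="M")],
    missing_sex_rate=0.10,
    duplicate_rate=0.0,
    quarters=("2022q1",),
    seed=13,
)

with tempfile.TemporaryDirectory() as td:
    fv.generate_quarters(cfg, td)
    raw = fv.load_quarters([Path(td) / "2022q1"])
    marked = fv.mark_target(fv.deduplicate(raw), PATTERNS)
    events = fv.map_events(marked, fv.load_dictionary(Path(td) / "synthetic_meddra.txt"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_stratum = fv.subgroup_signals(
            events, "sex", fv.AnalysisConfig(shrinkage_mode="none"), levels=("M", "F")
        )

for level, df in per_stratum.items():
    row = df[df["term"] == "PT_0003"].iloc[0]
    print(
        f"sex={level}: a={int(row.a):3d}  ROR={row.ror:5.2f} "
        f"(95% CI {row.ror_lo95:.2f}–{row.ror_hi95:.2f})  signal={bool(row.ror_sig)}"
    )
print("\nThe male stratum should flag PT_0003 (lower CI > 1); the female one should not.")
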