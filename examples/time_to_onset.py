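"""Time-to-onset analysis: histogram, median and a sex comparison.

Onset time is the number of days from the earliest target-drug therapy start
to the adverse event. The generator plants a lognormal onset distribution
with an 82-day median; the analysis recovers it and bins the onsets the way
pharmacovigilance studies report them.
"""

import tempfile
from pathlib import Path

import faerspv as fv

PATTERNS = ["ETELCALCETIDE", "AMG 416", "PARSABIV"]

cfg = fv.GeneratorConfig(
    n_cases=1500,
    target_fraction=0.6,
    duplicate_rate=0.0,
    missing_date_rate=0.1,
    quarters=("2022q1",),
    seed=8,
)

with tempfile.TemporaryDirectory() as td:
    fv.generate_quarters(cfg, td)
    raw = fv.load_quarters([Path(td) / "2022q1"])
    screened = fv.screen_target_drug(fv.deduplicate(raw), PATTERNS)
    records, tally = fv.compute_tto(screened)

print(f"case-event rows: {sum(tally.values())}  known TTO: {tally['known']}  "
      f"unspecified dates: {tally['unspecified']}  implausible (event before start): {tally['implausible']}")
print(f"median onset: {records['days'].median():.0f} days (generator truth: 82)")
print("\nonset-time distribution (% of known-TTO events):")
print(fv.tto_histogram(records)[["bin", "count", "percent_2dp"]].to_string(index=False))

res = fv.compare_tto(records, "sex")
print(f"\n{res.test} across sexes: statistic={res.statistic:.1f}, p={res.pvalue:.3f}")
print(f"group medians (days): {res.medians}  sizes: {res.sizes}")
print("The generator draws onset independently of sex, so p should be unremarkable.")
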