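# faerspv

Pharmacovigilance signal detection on FAERS-style spontaneous adverse-event
reports, built as a reusable, fully tested Python library.

Spontaneous-report databases such as the FDA Adverse Event Reporting System
(FAERS) are the main post-marketing source for detecting unexpected
drug–adverse-event associations — for example, for a drug like etelcalcetide
(an intravenous calcimimetic used in hemodialysis patients with secondary
hyperparathyroidism), where shunt-related complications and mineral-metabolism
abnormalities dominate the reporting. Working with such data means solving the
same chain of problems every time: quarterly `$`-delimited extracts, duplicate
report versions, free-text drug-name variants, MedDRA coding, and
disproportionality statistics whose small-count behaviour matters. `faerspv`
packages that chain end to end, together with a synthetic FAERS generator with
planted signals so that every stage can be validated against known ground
truth.

## What it computes

For each drug–event pair a 2×2 table is built against all other drugs in the
loaded extract (event-level margins by default: one row per case × distinct
preferred term):

|              | event  | other events |
|--------------|--------|--------------|
| target drug  | *a*    | *b*          |
| other drugs  | *c*    | *d*          |

with *N = a+b+c+d* and expected count *E = (a+b)(a+c)/N*. Four
disproportionality statistics are computed:

* **ROR** = *ad/bc*, CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
  signal: *a* ≥ 3 and CI lower bound > 1.
* **PRR** = `[a/(a+b)] / [c/(c+d)]` with its log-normal CI and the
  Yates-corrected χ² of the table; signal: PRR ≥ 2, χ² ≥ 4, *a* ≥ 3.
* **BCPNN IC** = `log2 P(drug,event)/(P(drug)P(event))` with Beta priors on
  the three reporting probabilities (closed-form posterior moments);
  signal: IC025 > 0.
* **MGPS EBGM** — empirical-Bayes geometric mean of λ = *a/E* under a
  two-component gamma-mixture prior fitted by maximum marginal likelihood
  over all tables (each component marginal is negative-binomial);
  signal: EB05 > 2.

A term is a *four-algorithm signal* when all four criteria hold. On top of
that the package provides FDA-rule deduplication (per CASEID keep the highest
FDA_DT, ties broken by the highest PRIMARYID), target-drug screening by
case-insensitive substring over DRUGNAME/PROD_AI with role filtering,
PT→SOC mapping through a pluggable dictionary, demographic summaries,
subgroup (sex / age-band) disproportionality, and time-to-onset analysis
(days from earliest therapy start to the event, with rank-based group
comparisons).

## Worked example

`examples/end_to_end_signal_mining.py` generates two synthetic quarters
(3,000 cases, one planted signal with relative risk 6), runs the whole
pipeline and prints:

```
report versions loaded : 3443
deduplicated cases     : 3000
distinct (case, PT) AEs: 6532 (620 for the target drug)

PTs meeting all four signal criteria, ranked by EBGM:
   term  a  ror  prr  chi2_yates  ic  ebgm  eb05
PT_0005 82 4.97 4.44      152.68 1.7  3.33  3.32
```

Reading: 3,443 report versions collapse to 3,000 unique cases after FDA-rule
deduplication; the target drug accounts for 620 of 6,532 distinct
case-events. Exactly one PT — the planted one — passes all four algorithms:
it was reported 82 times with the target drug, is ~5-fold over-represented by
odds (ROR 4.97), and keeps EB05 = 3.32 > 2 after empirical-Bayes shrinkage.
The observed ROR sits below the planted relative risk of 6 because the
target drug's own reports contribute to the comparator margins.

Other example scripts cover the individual statistics on a single table
(`disproportionality_statistics.py`), subgroup analysis with a male-only
planted signal (`subgroup_analysis.py`), and time-to-onset recovery of a
median-82-day lognormal onset profile (`time_to_onset.py`).

## Layout

* `src/faerspv/synthetic.py` — FAERS-shaped generator with ground truth
* `src/faerspv/ingest.py` — `$`-dialect reader, deduplication, screening
* `src/faerspv/meddra.py` — PT→SOC mapping (synthetic dictionary included)
* `src/faerspv/contingency.py` — 2×2 table construction
* `src/faerspv/disprop.py` — ROR / PRR+χ² / BCPNN / MGPS and classification
* `src/faerspv/strata.py`, `src/faerspv/onset.py` — subgroups, time to onset
* `src/faerspv/report.py` — summaries, ranking, exports
* `docs/methods.md` — models, assumptions, parameter choices, limitations
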