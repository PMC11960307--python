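# Methods

This note documents the statistical models, the synthetic-data model, the
numerical choices and the known limitations of `faerspv`.

## Data model and deduplication

A *case* is one patient's safety report; FAERS distributes cases as one or
more report *versions* (PRIMARYIDs) sharing a CASEID across quarterly
extracts. Deduplication keeps, per CASEID, the version with the highest
FDA_DT and breaks FDA_DT ties by the highest PRIMARYID; all child-table rows
(drugs, reactions, therapy dates, outcomes) are re-linked to the surviving
version. The operation is idempotent and order-independent (both are tested).
Dates are compared as YYYYMMDD integers; partial dates pad unknown month/day
with 00 and remain comparable, which preserves the rule on real extracts.

Screening retains cases where any drug record's DRUGNAME or PROD_AI contains
one of the configured name patterns as a case-insensitive substring. The
role filter defaults to primary suspect (PS) only — the convention for
"adverse events mainly suspected to be the drug" — and can be widened to
PS+SS. Age is normalised to years (YR as-is, MON/12, DEC×10; unknown unit
codes become missing) and banded at 18/45/65 years. A case is *serious* iff
it carries at least one outcome code other than OT; this rule is stated
explicitly because public summaries rarely define it.

Events follow the *distinct AEs* convention: one analysis row per
(case, distinct PT). A PT repeated within one report counts once; several
PTs in one report are separate events.

## Margin convention for the 2×2 tables

Margins are EVENT-level by default: a+b is the target drug's total distinct
case-event count, and N the total event count of the extract. This choice is
deliberate: in published FAERS signal tables the printed ROR/PRR pairs are
mutually consistent only under event-level margins (the acceptance suite
verifies this arithmetic on two SOC rows: a printed ROR of 2.53 at a=1207
with a+b=5435 implies PRR 2.19, and 0.51 at a=529 implies 0.56). Case-level
margins (`margins="case"`) are provided as a switch. Terms with a=0 are not
emitted — they carry no evidence for the target drug — while c and d are
always computed against the full background.

## Disproportionality statistics

Formulas are given in the README. Additional detail:

* **χ²** uses the Yates continuity correction with deviations clipped at
  zero, matching the standard contingency-test implementation (cross-checked
  against `scipy.stats.chi2_contingency(correction=True)`); a flag disables
  the correction.
* **Zero cells** make ROR/PRR undefined. The default reports
  undefined-with-reason and classifies the flag as false; an opt-in
  Haldane–Anscombe 0.5 correction exists but is off by default because
  silent corrections distort rankings.
* **BCPNN** uses the closed-form posterior moments with hyperparameters
  γ11 = 1, α1 = β1 = 1, α = β = 2. The point estimate is log2 of the ratio
  of posterior means of the three Beta-distributed reporting probabilities;
  the 95% interval is the delta-method variance of the same closed form with
  z = 1.96. The tests verify the point estimate against brute-force
  numerical integration of the Beta posteriors (tolerance 1e-3) and the
  large-count limit IC → log2(a·N/((a+b)(a+c))).
* **MGPS** fits the five prior parameters (α1, β1, α2, β2, w) by maximising
  the summed log marginal likelihood of the observed a's given E's, each
  component marginal being negative-binomial. Optimisation is L-BFGS-B on
  log-transformed shapes/rates and logit weight, from the classic starting
  point (0.2, 0.1, 2.0, 4.0, w=1/3) plus a fixed ladder of two auxiliary
  starts (the surface can be multimodal on small table collections); the
  best optimum is kept, so the fit is deterministic. Parameters are bounded
  to e^±12 because the likelihood is flat along the ridge where a component
  degenerates to a point mass (α, β → ∞ at fixed mean); the cap ends that
  drift without affecting non-degenerate optima. Below ~50 tables the prior
  is poorly determined and a warning is emitted.
* **EBGM** = 2^{E[log2 λ | a]} with the posterior a two-component gamma
  mixture (shapes α_j + a, rates β_j + E, weights proportional to prior
  weight × marginal). The expectation uses the digamma closed form; EB05 and
  EB95 solve the mixture CDF by Brent's method. The tests verify EBGM
  against grid quadrature of the full posterior (tolerance 0.5%) and the
  large-count limit EBGM → a/E. `shrinkage_mode="none"` returns the raw
  relative report rate a/E with a log-normal interval (variance 1/a) — the
  regime that published large-count SOC rows sit in, where EBGM ≈ PRR.
  Whether a published EBGM column is full MGPS or a raw relative rate is
  often not stated; both modes are provided and `full` is the default.

Signal thresholds are the field-standard ones: ROR (a ≥ 3, CI low > 1),
PRR (PRR ≥ 2, χ² ≥ 4, a ≥ 3), IC025 > 0, EB05 > 2; the four-algorithm
intersection is the headline filter. All thresholds sit in `AnalysisConfig`
and are immutable during a run.

## Subgroups and time to onset

Subgroup analysis restricts *both* the target and the comparator events to
the stratum (sex or age band), rebuilds the tables and recomputes all four
statistics, so a stratum is compared against its own background. Terms with
a < 3 in a stratum are kept but marked not evaluable.

Time to onset is event_dt − min(start_dt over the case's target-drug
records) in days — earliest exposure. Records with missing or partial dates
are excluded and tallied as `unspecified`; negative differences as
`implausible`; tallies plus known records partition the screened case-event
rows. The default histogram bins are 0–30 / 31–60 / 61–90 / 91–180 /
181–360 / >360 days. Group comparisons use rank-based tests (Mann–Whitney
for two groups, Kruskal–Wallis beyond), chosen because onset times are
heavily right-skewed and no parametric family is assumed; the null
calibration of the two-group p-value is tested (KS uniformity check over
permuted labels). Weibull shape/scale modelling of onset times is out of
scope.

## The synthetic generator

The generator emits the five `$`-delimited quarterly tables with header
rows, duplicate case versions, drug-name variants, partial dates, age-unit
codes and outcome codes, plus a JSON ground truth. Design:

* Each case names one primary-suspect drug (the target with probability
  `target_fraction`, default 0.10 — a small target share keeps the
  all-other-drugs background dominant, as in a real database-wide
  comparison) and 0–2 concomitants. Reaction count per case is
  1 + Poisson(1.2), giving the ~2.2 distinct AEs per case that
  calcimimetic safety reporting shows.
* PTs are drawn i.i.d. from a skewed baseline (p_k ∝ 1/(k+10)); for
  target-drug cases each planted signal multiplies its PT's probability by
  the configured relative risk, optionally within one sex/age stratum, and
  the vector is renormalised. The expected a of every planted pair is
  therefore known in closed form — including the correction for duplicate
  (case, PT) draws collapsing: P(hit) = 1 − (1−p)·exp(−(μ−1)p) per case.
* Demographic mixes default to a dialysis-population profile: sex M/F ≈
  54/46 among known with 26% missing, age mass at 45–64/≥65 with 45%
  missing, physician-dominated reporters, US/Japan-dominated countries,
  ~47% serious outcomes. Onset times are lognormal with median 82 days and
  σ = 1.2 (configurable family hook; median and σ are parameters).
* Duplicate versions: a configured fraction of cases gains 1–2 extra
  versions with fresh PRIMARYIDs and FDA_DT shifts of −20…+60 days, about a
  third of them exact ties so the PRIMARYID tie-break is genuinely
  exercised. The ground-truth ledger records every version and the retained
  one.
* One master seed; per-quarter child seeds are derived as (seed, quarter
  index), so adding quarters never changes earlier ones, and identical
  configurations are byte-identical on disk.

What the generator does *not* emulate: reporting-bias mechanisms (Weber
effect, stimulated reporting), free-text drug-name noise beyond the
configured variant list, correlated comorbidity structure, or any real
joint distribution of demographics and events. Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and the recovery
of known planted structure — not epidemiological realism.

## MedDRA stand-in

MedDRA is licensed, so the packaged dictionary (`data/synthetic_meddra.txt`)
is synthetic: it covers the 26 System Organ Classes with representative
calcimimetic-domain PT names, in a `pt $ soc_name $ soc_code` format that a
real MedDRA export can replace without code changes. PT matching is exact
after trimming and case-folding (FAERS REAC strings are already
MedDRA-coded); unmapped PTs are kept under an `UNMAPPED` SOC and counted.
The dictionary version is surfaced as metadata only.

## Problem sizes used in the test and acceptance runs

The validation suite works at desk scale, chosen so the whole suite runs in
about a minute: fixtures of 800–1,600 cases, 100-replicate planted-signal
recovery at 1,000 cases per replicate (planted RR 6, expected a ≈ 40),
MGPS parameter recovery at 5,000 simulated tables, Bayesian-oracle
equivalence on 200 random small tables, and the acceptance pipeline at
4,000 cases over four quarters. Full-scale archives (millions of reports)
are supported by the same I/O layer but not exercised in tests; published
full-archive statistics are checked only through their internal arithmetic
(see the margin-convention section).

## Known limitations

* The comparator is "all other drugs in the loaded extract"; active-
  comparator and Mantel–Haenszel-stratified designs are out of scope.
* No multiple-comparison control beyond the four-algorithm intersection —
  deliberately, since that intersection is itself the conventional filter.
* Counts of cases versus events can legitimately differ between summaries
  (a deduplicated case count versus an event-table denominator); the
  package reports a single deduplicated count and does not reconcile
  inconsistent published figures.
* LLT→PT coding, SMQ expansion and RxNorm/ATC drug-name normalisation are
  not implemented.
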