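"""The four disproportionality statistics on a single 2×2 table.

A drug–event pair reported 10 times among the drug's 100 events, against a
background of 100/10,000, is ~11-fold over-represented by odds (ROR) and
~10-fold by proportion (PRR); the Bayesian estimators shrink toward
independence when counts are small.
"""

import faerspv as fv
from faerspv.contingency import ContingencyTable

t = ContingencyTable(unit="PT", term="Example PT", a=10, b=90, c=100, d=9900)
cfg = fv.AnalysisConfig()

ror, ror_lo, ror_hi, _ = fv.ror_stats(t, cfg)
prr, prr_lo, prr_hi, chi2, _ = fv.prr_chi2_stats(t, cfg)
ic, ic_lo, ic_hi = fv.bcpnn_ic(t, cfg)

# a diffuse empirical-Bayes prior, as fitted on a large table collection
prior = fv.GammaMixturePrior(alpha1=0.2, beta1=0.1, alpha2=2.0, beta2=4.0, w=1 / 3)
ebgm, eb05, eb95, _ = fv.ebgm_stats(t, prior, cfg)

print(f"table: a={t.a} b={t.b} c={t.c} d={t.d}  (N={t.N}, E={t.expected_a:.2f})")
print(f"ROR  = {ror:6.2f}  (95% CI {ror_lo:.2f}–{ror_hi:.2f})   odds ratio of reporting")
print(f"PRR  = {prr:6.2f}  (95% CI {prr_lo:.2f}–{prr_hi:.2f})   proportion ratio; χ²(Yates) = {chi2:.1f}")
print(f"IC   = {ic:6.2f}  (95% CI {ic_lo:.2f}–{ic_hi:.2f})     log2 observed/expected, Bayesian-shrunk")
print(f"EBGM = {ebgm:6.2f}  (EB05 {eb05:.2f}, EB95 {eb95:.2f})    empirical-Bayes geometric mean of a/E")
print(f"raw a/E = {t.raw_rr:.2f}; EBGM sits below it — that gap is the shrinkage.")
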