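"""The four disproportionality algorithms and signal classification.

For a 2×2 table (a, b, c, d; N = a+b+c+d):

* **ROR** — reporting odds ratio ``ad/(bc)`` with the log-normal 95% CI
  ``exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with CI
  ``exp(ln PRR ± z·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)))``, accompanied by the
  Yates-corrected χ² of the table.
* **BCPNN IC** — the information component ``log2 P(drug, event) /
  (P(drug)·P(event))`` under independent Beta priors on the three
  probabilities, using the closed-form posterior moments (point estimate from
  the ratio of posterior means, delta-method variance).
* **MGPS EBGM** — the empirical-Bayes geometric mean of the observed/expected
  ratio λ = a/E with E = (a+b)(a+c)/N, under a two-component gamma-mixture
  prior fitted by maximum marginal likelihood over the whole set of tables
  (each component marginal is negative-binomial). EB05/EB95 are posterior
  percentiles of the gamma-mixture posterior.

Signal thresholds (field conventions): ROR — a ≥ 3 and CI lower bound > 1;
PRR — a ≥ 3, PRR ≥ 2 and χ² ≥ 4; BCPNN — IC025 > 0; MGPS — EB05 > 2. A term
is a four-algorithm signal when all four flags hold.

Zero cells make ROR/PRR undefined; by default they are reported as
undefined-with-reason (flag false) rather than silently corrected. An opt-in
Haldane–Anscombe 0.5 correction is available.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from faerspv.contingency import ContingencyTable

__all__ = [
    "AnalysisConfig",
    "GammaMixturePrior",
    "SignalEstimates",
    "bcpnn_ic",
    "classify",
    "ebgm_stats",
    "evaluate_tables",
    "mgps_fit_prior",
    "prr_chi2_stats",
    "ror_stats",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class AnalysisConfig:
    """Formula constants and signal thresholds for one analysis run."""

    z_level: float = 1.96  # normal quantile for 95% intervals
    # BCPNN hyperparameters (Bate-style defaults)
    gamma11: float = 1.0
    alpha1_h: float = 1.0
    beta1_h: float = 1.0
    alpha_h: float = 2.0
    beta_h: float = 2.0
    # signal thresholds
    ror_min_a: int = 3
    prr_min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    eb05_min: float = 2.0
    # numerical behaviour
    yates: bool = True
    haldane: bool = False  # opt-in 0.5 correction for zero cells
    shrinkage_mode: str = "full"  # "full" (MGPS) or "none" (raw relative report rate)

    def __post_init__(self) -> None:
        if self.z_level <= 0:
            raise ValueError("z_level must be > 0")
        if self.shrinkage_mode not in ("full", "none"):
            raise ValueError("shrinkage_mode must be 'full' or 'none'")


@dataclass
class GammaMixturePrior:
    """Fitted two-component gamma prior for λ = observed/expected."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float  # weight of component 1
    loglik: float = float("nan")
    converged: bool = False

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma mixture shape/rate parameters must be > 0")
        if not 0.0 < self.w < 1.0:
            raise ValueError("gamma mixture weight must lie in (0, 1)")

    @property
    def mean(self) -> float:
        """Prior mean of λ."""
        return self.w * self.alpha1 / self.beta1 + (1 - self.w) * self.alpha2 / self.beta2

    def component_means(self) -> tuple[float, float]:
        return (self.alpha1 / self.beta1, self.alpha2 / self.beta2)


@dataclass
class SignalEstimates:
    """All four algorithms' statistics and signal flags for one table."""

    unit: str
    term: str
    a: int
    ror: float = float("nan")
    ror_lo95: float = float("nan")
    ror_hi95: float = float("nan")
    ror_reason: str | None = None
    prr: float = float("nan")
    prr_lo95: float = float("nan")
    prr_hi95: float = float("nan")
    chi2_yates: float = float("nan")
    prr_reason: str | None = None
    ic: float = float("nan")
    ic_lo95: float = float("nan")
    ic_hi95: float = float("nan")
    ebgm: float = float("nan")
    eb05: float = float("nan")
    eb95: float = float("nan")
    ebgm_reason: str | None = None
    ror_sig: bool = False
    prr_sig: bool = False
    ic_sig: bool = False
    ebgm_sig: bool = False
    all_four: bool = False


# ---------------------------------------------------------------------------
# frequentist statistics


def _cells(t: ContingencyTable, cfg: AnalysisConfig) -> tuple[float, float, float, float]:
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if cfg.haldane and min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def ror_stats(t: ContingencyTable, cfg: AnalysisConfig = AnalysisConfig()):
    """Reporting odds ratio with its 95% log-normal CI.

    Returns ``(ror, lo95, hi95, reason)``; the first three are NaN (and the
    reason set) when a zero cell makes the statistic undefined and the
    Haldane correction is off.
    """
    a, b, c, d = _cells(t, cfg)
    if min(a, b, c, d) == 0.0:
        zero = [n for n, v in zip("abcd", (a, b, c, d)) if v == 0.0]
        return math.nan, math.nan, math.nan, f"zero cell(s) {','.join(zero)}: ROR undefined"
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-cfg.z_level * se), ror * math.exp(cfg.z_level * se), None


def prr_chi2_stats(t: ContingencyTable, cfg: AnalysisConfig = AnalysisConfig()):
    """PRR with its 95% CI and the (Yates-corrected) χ² of the table.

    Returns ``(prr, lo95, hi95, chi2, reason)``.
    """
    a, b, c, d = _cells(t, cfg)
    N = a + b + c + d
    chi2 = math.nan
    if N > 0 and (a + b) > 0 and (c + d) > 0 and (a + c) > 0 and (b + d) > 0:
        chi2 = 0.0
        for obs, rm, cm in ((a, a + b, a + c), (b, a + b, b + d), (c, c + d, a + c), (d, c + d, b + d)):
            exp = rm * cm / N
            dev = abs(obs - exp) - 0.5 if cfg.yates else abs(obs - exp)
            chi2 += max(dev, 0.0) ** 2 / exp
    if a == 0.0 or c == 0.0 or (a + b) == 0.0 or (c + d) == 0.0:
        return math.nan, math.nan, math.nan, chi2, "zero margin or cell: PRR undefined"
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return prr, prr * math.exp(-cfg.z_level * se), prr * math.exp(cfg.z_level * se), chi2, None


# ---------------------------------------------------------------------------
# BCPNN information component


def bcpnn_ic(t: ContingencyTable, cfg: AnalysisConfig = AnalysisConfig()):
    """Closed-form BCPNN information component with 95% interval.

    Point estimate is log2 of the ratio of posterior means of P(drug, event),
    P(drug) and P(event) under their Beta posteriors; the interval uses the
    delta-method variance of the same closed form.
    """
    a, N = float(t.a), float(t.N)
    if N <= 0:
        raise ValueError("bcpnn_ic requires N > 0")
    ab = float(t.a + t.b)
    ac = float(t.a + t.c)
    g11, a1, b1, al, be = cfg.gamma11, cfg.alpha1_h, cfg.beta1_h, cfg.alpha_h, cfg.beta_h
    gamma = g11 * (N + al) * (N + be) / ((ab + a1) * (ac + b1))
    ic = math.log2((a + g11) * (N + al) * (N + be) / ((N + gamma) * (ab + a1) * (ac + b1)))
    var = (
        (N - a + gamma - g11) / ((a + g11) * (1 + N + gamma))
        + (N - ab + al - a1) / ((ab + a1) * (1 + N + al))
        + (N - ac + be - b1) / ((ac + b1) * (1 + N + be))
    ) / (_LN2**2)
    half = cfg.z_level * math.sqrt(var)
    return ic, ic - half, ic + half


# ---------------------------------------------------------------------------
# MGPS: empirical-Bayes gamma-Poisson shrinkage


def _mixture_logmarginal(a: np.ndarray, E: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Per-table log marginal P(a | E) under the gamma-mixture prior.

    Each component's marginal is negative binomial with size alpha_j and
    success probability beta_j/(beta_j + E).
    """
    la1, lb1, la2, lb2, logit_w = theta
    al1, be1, al2, be2 = np.exp([la1, lb1, la2, lb2])
    w = special.expit(logit_w)
    lm1 = stats.nbinom.logpmf(a, al1, be1 / (be1 + E))
    lm2 = stats.nbinom.logpmf(a, al2, be2 / (be2 + E))
    return np.logaddexp(np.log(w) + lm1, np.log1p(-w) + lm2)


def mgps_fit_prior(
    tables,
    start: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0),
    max_iter: int = 4000,
) -> GammaMixturePrior:
    """Fit the two-component gamma prior by maximum marginal likelihood.

    ``tables`` is a list of :class:`ContingencyTable` (or a pair of arrays
    ``(a, E)``). Optimisation is Nelder–Mead on log-transformed shapes/rates
    and logit weight from the classic starting point ``(0.2, 0.1, 2.0, 4.0,
    w=1/3)``; a fixed start makes the fit deterministic. Non-convergence
    returns the best iterate with ``converged=False`` and a warning.
    """
    if isinstance(tables, tuple) and len(tables) == 2:
        a = np.asarray(tables[0], dtype=float)
        E = np.asarray(tables[1], dtype=float)
    else:
        a = np.array([t.a for t in tables], dtype=float)
        E = np.array([t.expected_a for t in tables], dtype=float)
    ok = E > 0
    a, E = a[ok], E[ok]
    if a.size == 0:
        raise ValueError("mgps_fit_prior: no tables with positive expected counts")
    if a.size < 50:
        warnings.warn(
            f"mgps_fit_prior: only {a.size} table(s); the empirical-Bayes prior "
            "is poorly determined below ~50 tables",
            stacklevel=2,
        )
    def negll(theta: np.ndarray) -> float:
        with np.errstate(over="ignore"):
            ll = _mixture_logmarginal(a, E, theta)
        return -float(np.sum(ll))

    # Shapes/rates are bounded to [e^-12, e^12]: the marginal likelihood is
    # flat along the ridge where a component degenerates to a point mass
    # (alpha, beta -> inf at fixed mean), and the cap ends that drift without
    # affecting any non-degenerate optimum. The surface can be multimodal on
    # small table sets, so a fixed ladder of auxiliary starts is tried and
    # the best optimum kept — still deterministic.
    starts = [start, (1.0, 1.0, 2.0, 0.2, 0.5), (5.0, 5.0, 1.0, 0.1, 0.8)]
    bounds = [(-12.0, 12.0)] * 5
    res = None
    for a0, b0, a1, b1, w0 in starts:
        theta0 = np.array([math.log(a0), math.log(b0), math.log(a1), math.log(b1), special.logit(w0)])
        cand = optimize.minimize(
            negll,
            np.clip(theta0, -12.0, 12.0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter},
        )
        if res is None or cand.fun < res.fun:
            res = cand
    la1, lb1, la2, lb2, lw = res.x
    prior = GammaMixturePrior(
        alpha1=float(np.exp(la1)),
        beta1=float(np.exp(lb1)),
        alpha2=float(np.exp(la2)),
        beta2=float(np.exp(lb2)),
        w=float(special.expit(lw)),
        loglik=-float(res.fun),
        converged=bool(res.success),
    )
    if not res.success:
        warnings.warn("mgps_fit_prior did not converge; returning best iterate", stacklevel=2)
    return prior


def _posterior_mixture(a: float, E: float, prior: GammaMixturePrior):
    """Posterior over λ: gamma mixture with updated shapes/rates and weights."""
    shapes = np.array([prior.alpha1 + a, prior.alpha2 + a])
    rates = np.array([prior.beta1 + E, prior.beta2 + E])
    lm1 = stats.nbinom.logpmf(round(a), prior.alpha1, prior.beta1 / (prior.beta1 + E))
    lm2 = stats.nbinom.logpmf(round(a), prior.alpha2, prior.beta2 / (prior.beta2 + E))
    lw = np.array([math.log(prior.w) + lm1, math.log1p(-prior.w) + lm2])
    lw -= special.logsumexp(lw)
    return shapes, rates, np.exp(lw)


def _mixture_ppf(q: float, shapes: np.ndarray, rates: np.ndarray, weights: np.ndarray) -> float:
    dists = [stats.gamma(s, scale=1.0 / r) for s, r in zip(shapes, rates)]

    def cdf(x: float) -> float:
        return float(sum(w * d.cdf(x) for w, d in zip(weights, dists)))

    lo = min(d.ppf(q) for d in dists)
    hi = max(d.ppf(q) for d in dists)
    if hi <= lo:
        return lo
    return float(optimize.brentq(lambda x: cdf(x) - q, lo * 0.999999, hi * 1.000001, xtol=1e-10, rtol=1e-12))


def ebgm_stats(
    t: ContingencyTable,
    prior: GammaMixturePrior | None,
    cfg: AnalysisConfig = AnalysisConfig(),
):
    """EBGM with its 5th/95th posterior percentiles.

    EBGM = 2^{E[log2 λ | a]} from the digamma closed form of the posterior
    gamma mixture; EB05/EB95 solve the mixture CDF. With
    ``cfg.shrinkage_mode == "none"`` the raw relative report rate
    a·N/((a+b)(a+c)) is returned with a log-normal interval instead — the
    no-shrinkage regime that large-count tables converge to.

    Returns ``(ebgm, eb05, eb95, reason)``.
    """
    E = t.expected_a
    if E <= 0:
        return math.nan, math.nan, math.nan, "expected count E = 0: EBGM undefined"
    if cfg.shrinkage_mode == "none":
        if t.a == 0:
            return math.nan, math.nan, math.nan, "a = 0: raw relative report rate undefined"
        rr = t.a / E
        se = math.sqrt(1.0 / t.a)
        return rr, rr * math.exp(-cfg.z_level * se), rr * math.exp(cfg.z_level * se), None
    if prior is None:
        raise ValueError("ebgm_stats requires a fitted prior unless shrinkage_mode='none'")
    shapes, rates, weights = _posterior_mixture(float(t.a), E, prior)
    elog2 = float(np.sum(weights * (special.digamma(shapes) - np.log(rates)))) / _LN2
    ebgm = 2.0**elog2
    eb05 = _mixture_ppf(0.05, shapes, rates, weights)
    eb95 = _mixture_ppf(0.95, shapes, rates, weights)
    return ebgm, eb05, eb95, None


# ---------------------------------------------------------------------------
# classification and batch evaluation


def classify(est: SignalEstimates, cfg: AnalysisConfig = AnalysisConfig()) -> SignalEstimates:
    """Apply the per-algorithm signal thresholds (undefined ⇒ flag false)."""

    def _ok(x: float) -> bool:
        return x == x and math.isfinite(x)

    ror_sig = est.a >= cfg.ror_min_a and _ok(est.ror_lo95) and est.ror_lo95 > 1.0
    prr_sig = (
        est.a >= cfg.prr_min_a
        and _ok(est.prr)
        and est.prr >= cfg.prr_min
        and _ok(est.chi2_yates)
        and est.chi2_yates >= cfg.chi2_min
    )
    ic_sig = _ok(est.ic_lo95) and est.ic_lo95 > 0.0
    ebgm_sig = _ok(est.eb05) and est.eb05 > cfg.eb05_min
    return replace(
        est,
        ror_sig=ror_sig,
        prr_sig=prr_sig,
        ic_sig=ic_sig,
        ebgm_sig=ebgm_sig,
        all_four=ror_sig and prr_sig and ic_sig and ebgm_sig,
    )


def signal_estimates(
    t: ContingencyTable,
    prior: GammaMixturePrior | None,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> SignalEstimates:
    """Compute all four algorithms' statistics and flags for one table."""
    ror, ror_lo, ror_hi, ror_reason = ror_stats(t, cfg)
    prr, prr_lo, prr_hi, chi2, prr_reason = prr_chi2_stats(t, cfg)
    ic, ic_lo, ic_hi = bcpnn_ic(t, cfg)
    ebgm, eb05, eb95, ebgm_reason = ebgm_stats(t, prior, cfg)
    est = SignalEstimates(
        unit=t.unit,
        term=t.term,
        a=t.a,
        ror=ror,
        ror_lo95=ror_lo,
        ror_hi95=ror_hi,
        ror_reason=ror_reason,
        prr=prr,
        prr_lo95=prr_lo,
        prr_hi95=prr_hi,
        chi2_yates=chi2,
        prr_reason=prr_reason,
        ic=ic,
        ic_lo95=ic_lo,
        ic_hi95=ic_hi,
        ebgm=ebgm,
        eb05=eb05,
        eb95=eb95,
        ebgm_reason=ebgm_reason,
    )
    return classify(est, cfg)


def evaluate_tables(
    tables,
    cfg: AnalysisConfig = AnalysisConfig(),
    prior: GammaMixturePrior | None = None,
) -> pd.DataFrame:
    """Evaluate every table; fit the MGPS prior on the full set if needed.

    Returns one row per table with all statistics, intervals and flags.
    """
    tables = list(tables)
    if not tables:
        return pd.DataFrame(columns=[f.name for f in SignalEstimates.__dataclass_fields__.values()])
    if prior is None and cfg.shrinkage_mode == "full":
        prior = mgps_fit_prior(tables)
    rows = [signal_estimates(t, prior, cfg).__dict__ for t in tables]
    return pd.DataFrame(rows)
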