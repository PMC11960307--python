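"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own code paths: files are
parsed with plain string splitting, and Bayesian quantities are computed by
brute-force numerical integration on grids rather than closed forms.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np


def parse_dollar_file(path: Path) -> list[dict]:
    """Minimal `$`-delimited parser: header row + well-formed rows only."""
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("$")
    rows = []
    for line in lines[1:]:
        parts = line.split("$")
        if len(parts) == len(header):
            rows.append(dict(zip(header, parts)))
    return rows


def count_file_rows(path: Path) -> int:
    """Data rows in a `$` file (header excluded, blank lines ignored)."""
    return sum(1 for line in Path(path).read_text().splitlines()[1:] if line)


def distinct_case_pt_pairs(run_dir: Path, retained_pids: set[int]) -> set[tuple[int, str]]:
    """All distinct (caseid, pt) pairs among retained report versions."""
    pairs = set()
    for qdir in sorted(p for p in Path(run_dir).iterdir() if p.is_dir()):
        for row in parse_dollar_file(qdir / "REAC.txt"):
            if int(row["primaryid"]) in retained_pids:
                pairs.add((int(row["caseid"]), row["pt"]))
    return pairs


# ---------------------------------------------------------------------------
# numerical posterior integration oracles


def _beta_mean_numeric(shape1: float, shape2: float, n_grid: int = 40001) -> float:
    """Mean of a Beta distribution by trapezoidal integration (no closed form).

    The grid is restricted to the distribution's extreme quantiles so that
    sharply peaked posteriors (large N) are resolved.
    """
    from scipy.stats import beta as beta_dist

    lo = beta_dist.ppf(1e-13, shape1, shape2)
    hi = beta_dist.ppf(1.0 - 1e-13, shape1, shape2)
    x = np.linspace(max(lo, 1e-300), min(hi, 1.0 - 1e-16), n_grid)
    logpdf = (shape1 - 1) * np.log(x) + (shape2 - 1) * np.log1p(-x)
    logpdf -= logpdf.max()
    pdf = np.exp(logpdf)
    z = np.trapezoid(pdf, x)
    return float(np.trapezoid(x * pdf, x) / z)


def ic_numeric(a: int, b: int, c: int, d: int, *, gamma11=1.0, alpha1=1.0, beta1=1.0, alpha=2.0, beta=2.0) -> float:
    """BCPNN information component from numerically integrated Beta posteriors.

    The three reporting probabilities have independent Beta posteriors:
    p11 ~ Beta(a+gamma11, N-a+gamma-gamma11) with the data-dependent gamma,
    p1. ~ Beta(a+b+alpha1, N-(a+b)+alpha-alpha1),
    p.1 ~ Beta(a+c+beta1,  N-(a+c)+beta-beta1).
    The point estimate is log2 of the ratio of their (numerically computed)
    posterior means.
    """
    N = a + b + c + d
    gamma = gamma11 * (N + alpha) * (N + beta) / ((a + b + alpha1) * (a + c + beta1))
    m11 = _beta_mean_numeric(a + gamma11, N - a + gamma - gamma11)
    m1 = _beta_mean_numeric(a + b + alpha1, N - (a + b) + alpha - alpha1)
    m2 = _beta_mean_numeric(a + c + beta1, N - (a + c) + beta - beta1)
    return math.log2(m11 / (m1 * m2))


def _gamma_logpdf(lam: np.ndarray, shape: float, rate: float) -> np.ndarray:
    return shape * math.log(rate) + (shape - 1) * np.log(lam) - rate * lam - math.lgamma(shape)


def ebgm_numeric(a: int, E: float, prior, n_grid: int = 120001):
    """(EBGM, EB05, EB95) by brute-force integration over a lambda grid.

    The posterior over lambda is proportional to
    Poisson(a | lambda*E) * [w g(lambda; a1,b1) + (1-w) g(lambda; a2,b2)];
    the mixture marginals, the posterior mean of log2(lambda) and the
    posterior percentiles are all computed on the grid — no conjugate
    shortcuts shared with the implementation.
    """
    hi = max(20.0, 20.0 * (a + 1) / max(E, 1e-9), 10.0 * prior.alpha2 / prior.beta2, 10.0 * prior.alpha1 / prior.beta1)
    # the prior can put non-trivial mass arbitrarily close to 0 when a shape
    # is < 1 and a = 0, so the log-grid must reach far into the left tail
    lam = np.exp(np.linspace(math.log(1e-25), math.log(hi), n_grid))
    log_pois = a * (np.log(lam) + math.log(E)) - lam * E - math.lgamma(a + 1)
    log_prior = np.logaddexp(
        math.log(prior.w) + _gamma_logpdf(lam, prior.alpha1, prior.beta1),
        math.log1p(-prior.w) + _gamma_logpdf(lam, prior.alpha2, prior.beta2),
    )
    log_post = log_pois + log_prior
    log_post -= log_post.max()
    post = np.exp(log_post)
    z = np.trapezoid(post, lam)
    post /= z
    elog2 = float(np.trapezoid(np.log2(lam) * post, lam))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (post[1:] + post[:-1]) * np.diff(lam))])
    cdf /= cdf[-1]
    eb05 = float(np.interp(0.05, cdf, lam))
    eb95 = float(np.interp(0.95, cdf, lam))
    return 2.0**elog2, eb05, eb95
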