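"""Disproportionality estimators and signal classification.

Four standard algorithms over a 2x2 report-count table (a, b, c, d):

* **ROR** — reporting odds ratio ``(a*d)/(b*c)`` with a log-normal 95% CI,
  ``exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.
* **PRR** — proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]`` with the
  Pearson chi-squared statistic ``n(ad-bc)^2 / [(a+b)(c+d)(a+c)(b+d)]``.
* **BCPNN information component** — ``IC = log2(RRR)`` where
  ``RRR = a*n / [(a+b)(a+c)]`` is the observed-over-expected reporting ratio;
  IC025 uses the Noren credibility-interval approximation by default.
* **MGPS** — the simplified surface reports ``EBGM = RRR`` with a log-normal
  lower bound; :func:`mgps_full` provides the full DuMouchel empirical-Bayes
  gamma-Poisson shrinker (two-component gamma prior fitted by marginal
  maximum likelihood, posterior geometric mean and 5th percentile).

Signal rules (all thresholds configurable): ROR requires N >= 3 and CI lower
bound > 1; PRR requires PRR >= 2, chi2 >= 4 and N >= 3; BCPNN requires
IC025 > 0; MGPS requires EBGM05 > 2. A term is *positive* when the ROR
criterion holds and *significant* when two or more criteria hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .contingency import ContingencyTable

Z95 = 1.959963984540054  # two-sided 95% normal quantile
Z90 = 1.6448536269514722  # one-sided 5% normal quantile


class DegenerateTableError(ZeroDivisionError):
    """A zero cell makes the requested estimator undefined without correction."""


def _cells(table: ContingencyTable, continuity: bool) -> tuple[float, float, float, float]:
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if continuity:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return a, b, c, d


def _require_nonzero(table: ContingencyTable, cells: str, continuity: bool) -> None:
    if continuity:
        return
    for name in cells:
        if getattr(table, name) == 0:
            raise DegenerateTableError(
                f"cell {name}=0 for term {table.term!r}; enable the continuity "
                "correction to evaluate this table"
            )


def ror(table: ContingencyTable, continuity: bool = False) -> tuple[float, float, float]:
    """Reporting odds ratio with 95% CI. Returns ``(ror, low, high)``."""
    _require_nonzero(table, "abcd", continuity)
    a, b, c, d = _cells(table, continuity)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, point * math.exp(-Z95 * se), point * math.exp(Z95 * se)


def prr(table: ContingencyTable, continuity: bool = False, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-squared.

    The chi-squared is uncorrected by default; ``yates=True`` applies the
    continuity-corrected variant.
    """
    _require_nonzero(table, "c", continuity)
    if table.a + table.b == 0:
        raise DegenerateTableError(f"no exposed reports for term {table.term!r}")
    a, b, c, d = _cells(table, continuity)
    n = a + b + c + d
    point = (a / (a + b)) / (c / (c + d))
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2, 0.0)
    chi2 = n * num * num / ((a + b) * (c + d) * (a + c) * (b + d))
    return point, chi2


def rrr(table: ContingencyTable, continuity: bool = False) -> float:
    """Relative reporting ratio: observed over expected, ``a*n/[(a+b)(a+c)]``."""
    a, b, c, d = _cells(table, continuity)
    if a + b == 0 or a + c == 0:
        raise DegenerateTableError(f"empty margin for term {table.term!r}")
    n = a + b + c + d
    return a * n / ((a + b) * (a + c))


def information_component(
    table: ContingencyTable,
    continuity: bool = False,
    ic025_mode: str = "noren",
    fixed_gap: float = 1.66,
) -> tuple[float, float]:
    """BCPNN information component in bits with its lower 95% bound.

    ``IC = log2(RRR)``. The default lower bound is the Noren closed-form
    credibility-interval approximation
    ``IC025 = IC - 3.3*(a+0.5)^(-1/2) - 2.0*(a+0.5)^(-3/2)``. A non-standard
    fixed-width compatibility mode (``IC - fixed_gap``) is available for
    matching outputs that subtract a constant.
    """
    point = math.log2(rrr(table, continuity))
    a = table.a
    if ic025_mode == "noren":
        ic025 = point - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    elif ic025_mode == "fixed":
        ic025 = point - fixed_gap
    else:
        raise ValueError(f"unknown ic025_mode {ic025_mode!r}")
    return point, ic025


def ebgm_simple(table: ContingencyTable, continuity: bool = False) -> tuple[float, float]:
    """Simplified empirical-Bayes geometric mean surface: ``EBGM = RRR`` with
    a one-sided log-normal 5% lower bound.

    Returns ``(ebgm, ebgm05)`` where
    ``ebgm05 = exp(ln RRR - 1.645*sqrt(1/a + 1/b + 1/c + 1/d))``.
    """
    _require_nonzero(table, "abcd", continuity)
    point = rrr(table, continuity)
    a, b, c, d = _cells(table, continuity)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, point * math.exp(-Z90 * se)


# ---------------------------------------------------------------------------
# full DuMouchel gamma-Poisson shrinker
# ---------------------------------------------------------------------------

@dataclass
class MgpsFit:
    """Fitted two-component gamma-mixture prior and per-table shrunken ratios."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    weight: float  # mixing weight on component 1
    log_likelihood: float
    converged: bool
    terms: list[str]
    ebgm: np.ndarray
    eb05: np.ndarray


class MgpsFitError(RuntimeError):
    """The marginal-likelihood optimiser failed to converge."""


def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # marginal of a | lambda~Gamma(alpha, rate beta), a~Poisson(lambda*E)
    return (
        special.gammaln(alpha + a) - special.gammaln(alpha) - special.gammaln(a + 1)
        + alpha * np.log(beta / (beta + e))
        + a * np.log(e / (beta + e))
    )


def _mixture_loglik(theta: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_w = theta
    w = 1.0 / (1.0 + math.exp(-logit_w))
    l1 = _nb_logpmf(a, math.exp(la1), math.exp(lb1), e)
    l2 = _nb_logpmf(a, math.exp(la2), math.exp(lb2), e)
    m = np.maximum(l1, l2)
    return float(np.sum(m + np.log(w * np.exp(l1 - m) + (1 - w) * np.exp(l2 - m))))


def fit_gamma_mixture(
    a: np.ndarray,
    e: np.ndarray,
    init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
) -> tuple[tuple[float, float, float, float, float], float]:
    """Maximise the marginal negative-binomial-mixture likelihood of counts
    ``a`` with expectations ``e``.

    Returns ``((alpha1, beta1, alpha2, beta2, weight), log_likelihood)``.
    Raises :class:`MgpsFitError` on non-convergence or if the optimum is worse
    than the initial point.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one count")
    if np.any(e <= 0):
        raise ValueError("every table needs a positive expected count")
    a1, b1, a2, b2, w = init
    theta0 = np.array([math.log(a1), math.log(b1), math.log(a2), math.log(b2),
                       math.log(w / (1 - w))])
    ll0 = _mixture_loglik(theta0, a, e)
    res = optimize.minimize(
        lambda th: -_mixture_loglik(th, a, e), theta0, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    ll = -res.fun
    if not res.success or not np.isfinite(ll):
        raise MgpsFitError(f"optimiser did not converge: {res.message} (loglik={ll!r})")
    if ll < ll0 - 1e-9:
        raise MgpsFitError("optimum worse than initialisation")
    la1, lb1, la2, lb2, logit_w = res.x
    params = (math.exp(la1), math.exp(lb1), math.exp(la2), math.exp(lb2),
              1.0 / (1.0 + math.exp(-logit_w)))
    return params, ll


def gamma_mixture_posterior(
    a: np.ndarray,
    e: np.ndarray,
    params: tuple[float, float, float, float, float],
    quantile: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior geometric mean and lower quantile of the rate multiplier.

    Under the prior ``w*Gamma(alpha1,beta1) + (1-w)*Gamma(alpha2,beta2)`` and
    ``a ~ Poisson(lambda * e)``, the posterior is again a two-gamma mixture
    with components ``Gamma(alpha_j + a, beta_j + e)``. Returns
    ``(exp(E[ln lambda | a]), posterior quantile)`` elementwise.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    alpha1, beta1, alpha2, beta2, w = params
    l1 = _nb_logpmf(a, alpha1, beta1, e) + math.log(w)
    l2 = _nb_logpmf(a, alpha2, beta2, e) + math.log(1 - w)
    m = np.maximum(l1, l2)
    q1 = np.exp(l1 - m) / (np.exp(l1 - m) + np.exp(l2 - m))
    q2 = 1.0 - q1
    mean_log = (
        q1 * (special.digamma(alpha1 + a) - np.log(beta1 + e))
        + q2 * (special.digamma(alpha2 + a) - np.log(beta2 + e))
    )
    geo_mean = np.exp(mean_log)

    lower = np.empty_like(geo_mean)
    for i in range(len(a)):
        g1 = stats.gamma(alpha1 + a[i], scale=1.0 / (beta1 + e[i]))
        g2 = stats.gamma(alpha2 + a[i], scale=1.0 / (beta2 + e[i]))

        def cdf(x: float) -> float:
            return q1[i] * g1.cdf(x) + q2[i] * g2.cdf(x) - quantile

        hi = max(g1.ppf(0.9999), g2.ppf(0.9999))
        lo = min(g1.ppf(1e-12), g2.ppf(1e-12), hi * 1e-12)
        lower[i] = optimize.brentq(cdf, lo, hi)
    return geo_mean, lower


def mgps_full(
    tables: Sequence[ContingencyTable],
    init: tuple[float, float, float, float, float] = (0.2, 0.1, 2.0, 4.0, 1 / 3),
) -> MgpsFit:
    """Fit the DuMouchel empirical-Bayes gamma-Poisson shrinker.

    The prior on the reporting-rate multiplier lambda is a two-component gamma
    mixture ``w*Gamma(alpha1, beta1) + (1-w)*Gamma(alpha2, beta2)`` (shape/rate).
    Hyperparameters maximise the marginal likelihood of the observed counts
    ``a`` given expectations ``E = (a+b)(a+c)/n``; per-table shrunken values
    are the posterior geometric mean ``EBGM = exp(E[ln lambda | a])`` and the
    5th posterior percentile EB05.

    Stable hyperparameter estimates need on the order of >= 50 tables.
    """
    if not tables:
        raise ValueError("mgps_full requires at least one table")
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([(t.a + t.b) * (t.a + t.c) / t.n for t in tables], dtype=float)
    params, ll = fit_gamma_mixture(a, e, init)
    ebgm, eb05 = gamma_mixture_posterior(a, e, params)
    return MgpsFit(
        alpha1=params[0], beta1=params[1], alpha2=params[2], beta2=params[3],
        weight=params[4], log_likelihood=ll, converged=True,
        terms=[t.term for t in tables], ebgm=ebgm, eb05=eb05,
    )


# ---------------------------------------------------------------------------
# signal classification
# ---------------------------------------------------------------------------

@dataclass
class SignalCriteria:
    """Per-algorithm signal thresholds (defaults are the common criteria)."""

    min_cases: int = 3
    ror_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0
    #: if True, "significant" additionally requires the ROR criterion
    require_ror_for_significant: bool = False

    def __post_init__(self):
        for name in ("min_cases", "ror_ci_low", "prr_min", "chi2_min", "ebgm05_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SignalResult:
    term: str
    level: str
    n: int  # case count (= a)
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    flags: frozenset[str] = frozenset()
    classification: str = "none"


def evaluate_flags(result: SignalResult, criteria: SignalCriteria) -> frozenset[str]:
    flags = set()
    if result.n >= criteria.min_cases and result.ror_low > criteria.ror_ci_low:
        flags.add("ror")
    if (result.prr >= criteria.prr_min and result.chi2 >= criteria.chi2_min
            and result.n >= criteria.min_cases):
        flags.add("prr")
    if result.ic025 > criteria.ic025_min:
        flags.add("bcpnn")
    if result.ebgm05 > criteria.ebgm05_min:
        flags.add("mgps")
    return frozenset(flags)


def classify_signal(result: SignalResult, criteria: SignalCriteria | None = None) -> SignalResult:
    """Attach flags and the positive/significant classification.

    *positive*: the ROR criterion holds. *significant*: two or more criteria
    hold (optionally with ROR required among them). Returns a new result; the
    input is not mutated.
    """
    criteria = criteria or SignalCriteria()
    flags = evaluate_flags(result, criteria)
    significant = len(flags) >= 2 and (
        "ror" in flags if criteria.require_ror_for_significant else True
    )
    classification = "significant" if significant else ("positive" if "ror" in flags else "none")
    return SignalResult(
        term=result.term, level=result.level, n=result.n,
        ror=result.ror, ror_low=result.ror_low, ror_high=result.ror_high,
        prr=result.prr, chi2=result.chi2, ic=result.ic, ic025=result.ic025,
        ebgm=result.ebgm, ebgm05=result.ebgm05,
        flags=flags, classification=classification,
    )


def compute_signal(
    table: ContingencyTable,
    criteria: SignalCriteria | None = None,
    continuity: bool = False,
    yates: bool = False,
    ic025_mode: str = "noren",
    fixed_gap: float = 1.66,
) -> SignalResult:
    """All four estimators plus classification for one table."""
    r, lo, hi = ror(table, continuity)
    p, chi2 = prr(table, continuity, yates)
    ic, ic025 = information_component(table, continuity, ic025_mode, fixed_gap)
    eb, eb05 = ebgm_simple(table, continuity)
    raw = SignalResult(
        term=table.term, level=table.level, n=table.a,
        ror=r, ror_low=lo, ror_high=hi, prr=p, chi2=chi2,
        ic=ic, ic025=ic025, ebgm=eb, ebgm05=eb05,
    )
    return classify_signal(raw, criteria)


def compute_signals(
    tables: Iterable[ContingencyTable],
    criteria: SignalCriteria | None = None,
    ebgm_mode: str = "simple",
    **kwargs,
) -> list[SignalResult]:
    """Evaluate every table; ``ebgm_mode='dumouchel'`` replaces the simplified
    EBGM/EB05 columns with the full shrinker's posterior values."""
    tables = list(tables)
    results = [compute_signal(t, criteria, **kwargs) for t in tables]
    if ebgm_mode == "dumouchel":
        fit = mgps_full(tables)
        updated = []
        for res, eb, eb05 in zip(results, fit.ebgm, fit.eb05):
            updated.append(classify_signal(SignalResult(
                term=res.term, level=res.level, n=res.n,
                ror=res.ror, ror_low=res.ror_low, ror_high=res.ror_high,
                prr=res.prr, chi2=res.chi2, ic=res.ic, ic025=res.ic025,
                ebgm=float(eb), ebgm05=float(eb05),
            ), criteria))
        results = updated
    elif ebgm_mode != "simple":
        raise ValueError(f"unknown ebgm_mode {ebgm_mode!r}")
    return results


def results_to_frame(results: Iterable[SignalResult], round_to: int = 2) -> pd.DataFrame:
    """Tabulate results in the conventional column layout (rounded for
    reporting; compute on :class:`SignalResult` objects for full precision)."""
    rows = []
    for r in results:
        rows.append({
            "term": r.term, "level": r.level, "N": r.n,
            "ROR": round(r.ror, round_to), "ROR_low": round(r.ror_low, round_to),
            "ROR_high": round(r.ror_high, round_to),
            "PRR": round(r.prr, round_to), "chi2": round(r.chi2, round_to),
            "IC": round(r.ic, round_to), "IC025": round(r.ic025, round_to),
            "EBGM": round(r.ebgm, round_to), "EBGM05": round(r.ebgm05, round_to),
            "flags": ",".join(sorted(r.flags)), "classification": r.classification,
        })
    return pd.DataFrame(rows)
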