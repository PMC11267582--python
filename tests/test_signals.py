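"""Disproportionality estimators: closed forms against independent direct
evaluation, algebraic orderings by brute force, published-row consistency,
signal classification, and the empirical-Bayes shrinker."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from pvsignal.contingency import ContingencyTable
from pvsignal.signals import (
    DegenerateTableError,
    SignalCriteria,
    SignalResult,
    classify_signal,
    compute_signal,
    ebgm_simple,
    evaluate_flags,
    fit_gamma_mixture,
    gamma_mixture_posterior,
    information_component,
    mgps_full,
    prr,
    ror,
    rrr,
)


def T(a, b, c, d):
    return ContingencyTable("t", "PT", a, b, c, d)


class TestClosedForms:
    @pytest.mark.parametrize("k", [1, 3, 17])
    def test_balanced_table_is_null(self, k):
        t = T(k, k, k, k)
        assert ror(t)[0] == pytest.approx(1.0)
        p, chi2 = prr(t)
        assert p == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)
        assert rrr(t) == pytest.approx(1.0)
        assert information_component(t)[0] == pytest.approx(0.0)
        assert ebgm_simple(t)[0] == pytest.approx(1.0)

    def test_reference_table_points(self):
        t = T(10, 90, 100, 9900)
        assert ror(t)[0] == pytest.approx(11.0)
        assert prr(t)[0] == pytest.approx(10.0)
        assert rrr(t) == pytest.approx(101_000 / 11_000)
        assert information_component(t)[0] == pytest.approx(math.log2(101_000 / 11_000))
        assert ebgm_simple(t)[0] == pytest.approx(101_000 / 11_000)

    def test_ror_ci_against_direct_evaluation(self):
        t = T(10, 90, 100, 9900)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        lo = math.exp(math.log(11.0) - 1.959963984540054 * se)
        hi = math.exp(math.log(11.0) + 1.959963984540054 * se)
        _, got_lo, got_hi = ror(t)
        assert got_lo == pytest.approx(lo, rel=1e-12)
        assert got_hi == pytest.approx(hi, rel=1e-12)

    def test_ebgm05_against_direct_evaluation(self):
        t = T(10, 90, 100, 9900)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        expected = math.exp(math.log(101_000 / 11_000) - 1.6448536269514722 * se)
        assert ebgm_simple(t)[1] == pytest.approx(expected, rel=1e-12)

    def test_independence_gives_zero_chi2(self):
        # ad = bc
        assert prr(T(2, 4, 3, 6))[1] == pytest.approx(0.0)

    def test_rrr_algebraic_limit_b_c_zero(self):
        # b=c=0: RRR = a*n/(a*a) = n/a
        t = T(4, 0, 0, 6)
        assert rrr(t) == pytest.approx(10 / 4)


class TestAlgebraicProperties:
    def test_brute_force_ordering_and_identities(self):
        """Over all 4-cell tables with entries 1..6: closed forms agree with
        direct evaluation, IC == log2(RRR), and ROR/PRR/RRR order follows the
        sign of ad - bc."""
        for a, b, c, d in itertools.product(range(1, 7), repeat=4):
            t = T(a, b, c, d)
            n = a + b + c + d
            r = ror(t)[0]
            p, chi2 = prr(t)
            q = rrr(t)
            assert r == pytest.approx(a * d / (b * c), rel=1e-12)
            assert p == pytest.approx((a / (a + b)) / (c / (c + d)), rel=1e-12)
            assert q == pytest.approx(a * n / ((a + b) * (a + c)), rel=1e-12)
            assert chi2 == pytest.approx(
                n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d)),
                rel=1e-12)
            assert information_component(t)[0] == pytest.approx(math.log2(q), rel=1e-12)
            if a * d > b * c:
                assert r > p > q
            elif a * d == b * c:
                assert r == pytest.approx(1.0) and p == pytest.approx(1.0) and q == pytest.approx(1.0)
            else:
                assert r < p < q

    def test_cell_doubling_leaves_ratios_doubles_chi2(self):
        t = T(10, 90, 100, 9900)
        t2 = t.scaled(2)
        assert ror(t2)[0] == pytest.approx(ror(t)[0])
        assert prr(t2)[0] == pytest.approx(prr(t)[0])
        assert rrr(t2) == pytest.approx(rrr(t))
        assert prr(t2)[1] == pytest.approx(2 * prr(t)[1])

    def test_ic025_below_ic(self):
        for a, b, c, d in [(3, 7, 11, 500), (30, 300, 100, 9000), (5, 5, 5, 5)]:
            ic, ic025 = information_component(T(a, b, c, d))
            assert ic025 < ic

    def test_ebgm05_below_point(self):
        eb, eb05 = ebgm_simple(T(10, 90, 100, 9900))
        assert eb05 < eb


class TestPublishedRowConsistency:
    """Printed safety-table rows satisfy IC == log2(EBGM) to 2 decimals —
    the identity our simplified Bayesian surface is built on."""

    @pytest.mark.parametrize("ebgm, ic", [
        (1.06, 0.08), (3.32, 1.73), (2.17, 1.12), (9.41, 3.23), (120.28, 6.91),
    ])
    def test_ic_is_log2_ebgm(self, ebgm, ic):
        assert abs(round(math.log2(ebgm), 2) - ic) <= 0.01


class TestDegenerateTables:
    def test_zero_cell_raises_without_correction(self):
        with pytest.raises(DegenerateTableError):
            ror(T(3, 0, 10, 100))
        with pytest.raises(DegenerateTableError):
            prr(T(3, 5, 0, 100))

    def test_continuity_correction_evaluates(self):
        r, lo, hi = ror(T(3, 0, 10, 100), continuity=True)
        assert math.isfinite(r) and lo < r < hi

    def test_yates_chi2_not_larger_than_pearson(self):
        t = T(10, 90, 100, 9900)
        assert prr(t, yates=True)[1] <= prr(t)[1]


def _result(n=5, ror_low=2.0, prr_v=3.0, chi2=10.0, ic025=1.0, ebgm05=3.0):
    return SignalResult(term="x", level="PT", n=n, ror=ror_low * 2,
                        ror_low=ror_low, ror_high=ror_low * 4, prr=prr_v,
                        chi2=chi2, ic=2.0, ic025=ic025, ebgm=3.0, ebgm05=ebgm05)


class TestClassification:
    def test_published_vulvovaginal_candidiasis_row_all_four(self):
        """N=5, ROR low 50.39, PRR 121.42 (chi2 591.50), IC025 5.24,
        EB05 57.52: every criterion holds -> significant."""
        res = classify_signal(SignalResult(
            term="Vulvovaginal candidiasis", level="PT", n=5,
            ror=121.70, ror_low=50.39, ror_high=293.92,
            prr=121.42, chi2=591.50, ic=6.91, ic025=5.24,
            ebgm=120.28, ebgm05=57.52))
        assert res.flags == {"ror", "prr", "bcpnn", "mgps"}
        assert res.classification == "significant"

    def test_case_count_gate(self):
        res = classify_signal(_result(n=2, ror_low=100, prr_v=100, chi2=1e3,
                                      ic025=5, ebgm05=50))
        assert "ror" not in res.flags and "prr" not in res.flags
        # Bayesian criteria have no explicit N gate
        assert res.classification in ("none", "significant")

    def test_ror_only_is_positive(self):
        res = classify_signal(_result(n=3, ror_low=1.2, prr_v=1.5, chi2=1.0,
                                      ic025=-0.5, ebgm05=1.0))
        assert res.flags == {"ror"}
        assert res.classification == "positive"

    def test_two_criteria_without_ror_significant_by_default(self):
        res = classify_signal(_result(n=5, ror_low=0.9, prr_v=3.0, chi2=10.0,
                                      ic025=0.5, ebgm05=1.0))
        assert res.flags == {"prr", "bcpnn"}
        assert res.classification == "significant"
        strict = classify_signal(res, SignalCriteria(require_ror_for_significant=True))
        assert strict.classification == "none"

    def test_relaxing_thresholds_never_removes_flags(self):
        base = SignalCriteria()
        relaxed = SignalCriteria(min_cases=1, ror_ci_low=0.5, prr_min=1.0,
                                 chi2_min=1.0, ic025_min=-1.0, ebgm05_min=1.0)
        rng = np.random.default_rng(0)
        for _ in range(200):
            res = _result(n=int(rng.integers(1, 10)),
                          ror_low=float(rng.uniform(0.2, 5)),
                          prr_v=float(rng.uniform(0.2, 5)),
                          chi2=float(rng.uniform(0, 10)),
                          ic025=float(rng.uniform(-2, 2)),
                          ebgm05=float(rng.uniform(0.2, 5)))
            assert evaluate_flags(res, base) <= evaluate_flags(res, relaxed)


class TestMgps:
    def test_point_mass_prior_shrinks_to_one(self):
        a = np.array([5.0, 50.0, 0.0])
        e = np.array([1.0, 10.0, 2.0])
        eb, _ = gamma_mixture_posterior(a, e, (1e6, 1e6, 1e6, 1e6, 0.5))
        assert np.allclose(eb, 1.0, atol=1e-3)

    def test_likelihood_dominance_large_count(self):
        eb, eb05 = gamma_mixture_posterior(
            np.array([1e4]), np.array([1e2]), (0.2, 0.1, 2.0, 4.0, 1 / 3))
        assert eb[0] == pytest.approx(100.0, rel=0.02)
        assert eb05[0] < eb[0]

    def test_posterior_quantile_below_mean_and_positive(self):
        a = np.array([3.0, 10.0, 30.0])
        e = np.array([1.0, 5.0, 10.0])
        eb, eb05 = gamma_mixture_posterior(a, e, (0.2, 0.1, 2.0, 4.0, 1 / 3))
        assert np.all(eb05 > 0) and np.all(eb05 < eb)

    def test_hyperparameter_recovery_from_known_mixture(self):
        """Counts simulated from a known two-gamma mixture: the fitted prior
        mean is within 10% of the truth at 1e4 tables."""
        a1, b1, a2, b2, w = 2.0, 4.0, 1.0, 0.5, 0.7
        rng = np.random.default_rng(42)
        n = 10_000
        comp = rng.random(n) < w
        lam = np.where(comp, rng.gamma(a1, 1 / b1, n), rng.gamma(a2, 1 / b2, n))
        e = rng.uniform(0.5, 20, n)
        a = rng.poisson(lam * e)
        params, ll = fit_gamma_mixture(a, e)
        mean_true = w * a1 / b1 + (1 - w) * a2 / b2
        mean_fit = params[4] * params[0] / params[1] + (1 - params[4]) * params[2] / params[3]
        assert abs(mean_fit - mean_true) / mean_true < 0.10
        assert math.isfinite(ll)

    def test_mgps_full_on_tables_shrinks_small_counts(self):
        rng = np.random.default_rng(7)
        tables = []
        for i in range(200):
            a = int(rng.integers(1, 20))
            tables.append(ContingencyTable(f"t{i}", "PT", a, 100 - a,
                                           int(rng.integers(50, 500)), 50_000))
        fit = mgps_full(tables)
        assert fit.converged
        raw = np.array([rrr(t) for t in tables])
        # shrinkage: geometric mean moves toward the prior, spread shrinks
        assert np.std(np.log(fit.ebgm)) < np.std(np.log(raw))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mgps_full([])


def test_compute_signal_roundtrip():
    t = T(10, 90, 100, 9900)
    res = compute_signal(t)
    assert res.n == 10
    assert res.ror == pytest.approx(11.0)
    assert res.ic == pytest.approx(math.log2(rrr(t)))
    assert res.classification == "significant"
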