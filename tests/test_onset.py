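"""Time-to-onset: calendar arithmetic and exclusions, binning partition,
growth rates, Weibull MLE recovery and CI coverage, KS and Kruskal-Wallis
against brute-force/hand oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from pvsignal.onset import (
    BinScheme,
    WeibullFit,
    WeibullFitError,
    bin_counts,
    compute_tto,
    compute_ttos,
    fit_weibull,
    growth_rate,
    kruskal_wallis,
    ks_test,
    summarize,
)

from conftest import make_case


class TestComputeTto:
    def test_calendar_arithmetic(self):
        case = make_case(1, ["Rash"], therapy_start="20200101", event_dt="20200711")
        rec, reason = compute_tto(case)
        assert reason is None
        assert rec.tto_days == 192

    def test_event_before_start_excluded(self):
        case = make_case(1, ["Rash"], therapy_start="20200711", event_dt="20200101")
        rec, reason = compute_tto(case)
        assert rec is None and reason == "negative"

    def test_partial_start_excluded(self):
        case = make_case(1, ["Rash"], therapy_start="202001", event_dt="20200711")
        rec, reason = compute_tto(case)
        assert rec is None and reason == "partial date"

    def test_missing_event_excluded(self):
        case = make_case(1, ["Rash"], therapy_start="20200101", event_dt="")
        assert compute_tto(case) == (None, "partial date")

    def test_non_target_start_ignored(self):
        # therapy date on a concomitant drug does not qualify
        case = make_case(1, ["Rash"], drug="IBUPROFEN", role="PS",
                         therapy_start="20200101", event_dt="20200711")
        assert compute_tto(case) == (None, "partial date")

    def test_included_plus_excluded_equals_input(self, shared_clean):
        target, _, _ = shared_clean
        records, exclusions = compute_ttos(target)
        assert len(records) + sum(exclusions.values()) == len(target)
        assert all(r.tto_days >= 0 for r in records)

    def test_usable_count_matches_ledger(self, shared_clean, shared_ledger_cases):
        target, _, _ = shared_clean
        records, _ = compute_ttos(target)
        # ledger rows for target cases that kept full dates
        expected = shared_ledger_cases.query("is_target_ps == 1 and tto_usable == 1")
        # cases whose only reactions were excluded terms are no longer present
        kept_ids = {c.primaryid for c in target}
        expected = expected[expected["canonical_primaryid"].isin(kept_ids)]
        assert len(records) == len(expected)
        got = {r.primaryid: r.tto_days for r in records}
        truth = dict(zip(expected["canonical_primaryid"], expected["tto_days"]))
        assert got == truth


class TestSummarize:
    def test_single_value(self):
        s = summarize([10])
        assert (s["median"], s["q1"], s["q3"]) == (10, 10, 10)

    def test_even_length_interpolation(self):
        assert summarize([1, 2, 3, 4])["median"] == 2.5

    def test_empty_marker(self):
        assert summarize([]) is None

    def test_weibull_median_closed_form(self):
        rng = np.random.default_rng(1)
        t = 269.56 * rng.weibull(0.89, 100_000)
        expected = 269.56 * math.log(2) ** (1 / 0.89)
        assert summarize(t)["median"] == pytest.approx(expected, rel=0.02)


class TestBins:
    def test_example_assignment(self):
        bins = bin_counts([5, 35, 400])
        assert bins.monthly[0] == 1 and bins.monthly[1] == 1
        assert bins.over_year == 1
        assert bins.quarterly[0] == 2

    def test_empty(self):
        bins = bin_counts([])
        assert sum(bins.monthly) == 0 and bins.over_year == 0

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 1000, 500)
        bins = bin_counts(vals)
        assert sum(bins.monthly) + bins.over_year == len(vals)
        assert sum(bins.quarterly) + bins.over_year == len(vals)

    def test_year_cutoff_boundary_inclusive(self):
        bins = bin_counts([365, 366])
        assert bins.quarterly[-1] == 1 and bins.over_year == 1

    def test_invalid_scheme(self):
        with pytest.raises(ValueError):
            BinScheme(month_days=0)
        with pytest.raises(ValueError):
            BinScheme(year_cutoff=100)


class TestGrowthRate:
    @pytest.mark.parametrize("counts, expected", [
        ([89, 72], [-19.1]),
        ([64, 32], [-50.0]),
        ([89, 72, 64, 32], [-19.1, -11.1, -50.0]),
        ([7, 7], [0.0]),
    ])
    def test_values(self, counts, expected):
        assert growth_rate(counts) == expected

    def test_zero_previous_is_undefined(self):
        assert growth_rate([0, 5]) == [None]

    def test_too_short(self):
        with pytest.raises(ValueError):
            growth_rate([5])


class TestWeibullFit:
    def test_exponential_special_case_recovery(self):
        rng = np.random.default_rng(0)
        t = 100.0 * rng.weibull(1.0, 100_000)
        fit = fit_weibull(t)
        assert 0.98 <= fit.shape <= 1.02
        assert fit.scale == pytest.approx(100.0, rel=0.02)

    def test_cdf_at_scale_is_632_exactly(self):
        rng = np.random.default_rng(5)
        fit = fit_weibull(269.56 * rng.weibull(0.89, 500))
        assert fit.cdf(fit.scale) == pytest.approx(1 - math.exp(-1), abs=1e-12)

    def test_matches_scipy_mle(self):
        rng = np.random.default_rng(8)
        t = 269.56 * rng.weibull(0.89, 2000)
        fit = fit_weibull(t)
        c, loc, scale = stats.weibull_min.fit(t, floc=0)
        assert fit.shape == pytest.approx(c, rel=1e-3)
        assert fit.scale == pytest.approx(scale, rel=1e-3)

    def test_ci_coverage_at_study_sample_size(self):
        """Over 200 replicates of n=335 at shape 0.89, scale 269.56, the 95%
        CI for the shape covers the truth 90-99% of the time."""
        hits = 0
        for seed in range(1, 201):
            rng = np.random.default_rng(seed)
            fit = fit_weibull(269.56 * rng.weibull(0.89, 335))
            hits += fit.shape_ci[0] <= 0.89 <= fit.shape_ci[1]
        assert 0.90 <= hits / 200 <= 0.99

    def test_early_type_hazard_strictly_decreasing(self):
        rng = np.random.default_rng(2)
        fit = fit_weibull(269.56 * rng.weibull(0.89, 5000))
        assert fit.shape < 1
        assert fit.onset_type == "early"
        grid = np.linspace(1.0, 1000.0, 100)
        hz = fit.hazard(grid)
        assert np.all(np.diff(hz) < 0)

    def test_zero_shift_recorded(self):
        t = np.concatenate([[0.0, 0.0], 100 * np.random.default_rng(1).weibull(1.0, 100)])
        fit = fit_weibull(t)
        assert fit.n_zero_shifted == 2

    def test_too_few_values(self):
        with pytest.raises(WeibullFitError):
            fit_weibull([1.0] * 5)

    def test_negative_rejected(self):
        with pytest.raises(WeibullFitError):
            fit_weibull([-1.0] + [1.0] * 20)


class TestKsTest:
    def test_statistic_matches_brute_force(self):
        rng = np.random.default_rng(4)
        t = np.sort(269.56 * rng.weibull(0.89, 50))
        fit = fit_weibull(t)
        stat, _ = ks_test(t, fit)
        n = len(t)
        cdf = fit.cdf(t)
        d = 0.0
        for i in range(n):  # direct sup-distance
            d = max(d, abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i]))
        assert stat == pytest.approx(d, rel=1e-12)

    def test_null_behavior(self):
        rng = np.random.default_rng(6)
        t = 269.56 * rng.weibull(0.89, 2000)
        fit = fit_weibull(t)
        _, p = ks_test(t, fit)
        assert p > 0.05

    def test_gross_misfit_rejected(self):
        rng = np.random.default_rng(6)
        data = rng.uniform(0, 1, 500) * 10
        fit = WeibullFit(shape=0.89, shape_ci=(0.8, 1.0), scale=269.56,
                         scale_ci=(230, 310), log_likelihood=0.0, n=500)
        _, p = ks_test(data, fit)
        assert p < 1e-6


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_two_groups(self):
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 21 = 27/7
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, rel=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(h, 1)), rel=1e-12)

    def test_shift_invariance(self):
        g = [[1.0, 2.5, 3.0], [4.0, 5.5], [0.5, 6.0, 7.0]]
        shifted = [[x + 100 for x in grp] for grp in g]
        assert kruskal_wallis(g) == kruskal_wallis(shifted)

    def test_fewer_than_two_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
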