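"""Exact Mann-Whitney U, variance-ratio F-test, significance profiles.

Independent oracles: brute-force enumeration over all sample splits for
the Mann-Whitney p-value, and numerical integration of the F density
(log-gamma form, scipy.integrate.quad) for the F-test p-value.
"""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy.integrate import quad

from tardisperm import (
    collect_series,
    f_test_variance,
    mann_whitney_exact,
    percent_significant,
    simulate_sperm,
    single_cell_truth,
    station_significance,
)
from tardisperm.waveform import StationCurvatureSeries


def enumerate_mwu_p(a, b):
    """Two-sided Mann-Whitney p by exhaustive enumeration of all splits of
    the combined sample into groups of sizes |a| and |b| (tie-free data)."""
    a, b = list(a), list(b)
    combined = a + b
    n1 = len(a)

    def u_stat(first):
        rest = [v for v in combined if v not in first]
        return sum(1 for x in first for y in rest if x > y)

    u_obs = sum(1 for x in a for y in b if x > y)
    us = [u_stat(list(c)) for c in combinations(combined, n1)]
    lo = sum(1 for u in us if u <= u_obs)
    hi = sum(1 for u in us if u >= u_obs)
    return min(1.0, 2.0 * min(lo, hi) / len(us))


def f_cdf_by_quadrature(x, d1, d2):
    """F CDF by numerical integration of the density in log-gamma form."""
    lognorm = (
        math.lgamma((d1 + d2) / 2) - math.lgamma(d1 / 2) - math.lgamma(d2 / 2)
        + (d1 / 2) * math.log(d1 / d2)
    )

    def pdf(t):
        return math.exp(
            lognorm + (d1 / 2 - 1) * math.log(t)
            - ((d1 + d2) / 2) * math.log1p(d1 * t / d2)
        )

    val, _ = quad(pdf, 0.0, x, epsabs=1e-13, epsrel=1e-13, limit=200)
    return val


class TestFTest:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.5, 4.0])
        r = f_test_variance(a, a)
        assert r.statistic == 1.0
        assert r.p_value == 1.0

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 2, 8), rng.normal(0, 1, 12)
        assert f_test_variance(a, b).p_value == pytest.approx(
            f_test_variance(b, a).p_value, abs=1e-12
        )

    def test_ninefold_variance_significant_at_n10(self):
        rng = np.random.default_rng(2)
        b = rng.normal(0, 1, 10)
        a = 3.0 * (b - b.mean()) + b.mean()  # exactly 9x the variance
        r = f_test_variance(a, b)
        assert r.statistic == pytest.approx(9.0)
        assert r.p_value < 0.01

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            f_test_variance([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_p_matches_quadrature_oracle(self):
        """p agrees with an independent numerical-integration F-CDF oracle
        to 1e-9 over a grid of (F, df) pairs."""
        rng = np.random.default_rng(9)

        def sample_with_variance(n, var):
            x = rng.normal(size=n)
            return (x - x.mean()) / x.std(ddof=1) * math.sqrt(var)

        for d1, d2 in [(3, 5), (9, 9), (2, 10), (20, 7), (29, 29)]:
            for fval in (0.05, 0.3, 1.0, 2.5, 9.0):
                cdf = f_cdf_by_quadrature(fval, d1, d2)
                expected = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
                a = sample_with_variance(d1 + 1, fval)
                b = sample_with_variance(d2 + 1, 1.0)
                got = f_test_variance(a, b).p_value
                assert got == pytest.approx(expected, abs=1e-9)


class TestMannWhitney:
    def test_worked_example(self):
        r = mann_whitney_exact([1, 2], [3, 4])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 3, abs=1e-12)
        assert "exact" in r.method

    def test_swap_invariance(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 6), rng.normal(0.5, 1, 5)
        assert mann_whitney_exact(a, b).p_value == pytest.approx(
            mann_whitney_exact(b, a).p_value, abs=1e-12
        )

    @pytest.mark.parametrize("n1", [1, 2, 3, 4, 5, 6])
    @pytest.mark.parametrize("n2", [1, 2, 3, 4, 5, 6])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        a, b = vals[:n1], vals[n1:]
        assert mann_whitney_exact(a, b).p_value == pytest.approx(
            enumerate_mwu_p(a, b), abs=1e-12
        )

    def test_exact_agrees_with_scipy(self):
        import scipy.stats

        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        ours = mann_whitney_exact(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_ties_use_approximation(self):
        r = mann_whitney_exact([1, 1, 2], [2, 3, 3])
        assert "approximation" in r.method
        assert 0 <= r.p_value <= 1

    def test_large_samples_use_approximation(self):
        rng = np.random.default_rng(5)
        r = mann_whitney_exact(rng.normal(0, 1, 15), rng.normal(0, 1, 15))
        assert "approximation" in r.method

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_species_speed_cohorts_differ(self):
        """Simulated speed cohorts at the two species means (n=26, sd 15)
        are significantly different at p < 0.01, the faster cohort first."""
        rng = np.random.default_rng(11)
        fast = rng.normal(259.3, 15.0, 26)
        slow = rng.normal(207.6, 15.0, 26)
        r = mann_whitney_exact(fast, slow)
        assert r.p_value < 0.01
        assert r.statistic > 26 * 26 / 2  # direction: first cohort larger


class TestPercentSignificant:
    @pytest.mark.parametrize(
        "k,n,expected",
        [(36, 59, 61.0), (6, 31, 19.4), (3, 13, 23.1),
         (12, 21, 57.1), (7, 11, 63.6), (5, 19, 26.3), (0, 7, 0.0)],
    )
    def test_reported_fractions(self, k, n, expected):
        flags = [True] * k + [False] * (n - k)
        assert percent_significant(flags) == expected

    def test_rounding_is_half_up(self):
        assert percent_significant([True] + [False] * 15) == 6.3  # 6.25 -> 6.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_significant([])


def series_from_samples(samples, part="tail", stations=None):
    samples = np.asarray(samples, float)
    if stations is None:
        stations = np.arange(1.0, samples.shape[0] + 1)
    return StationCurvatureSeries(
        part=part, stations=np.asarray(stations, float), samples=samples,
        window_frames=samples.shape[1],
    )


class TestStationSignificance:
    def test_identical_series_nothing_significant(self):
        rng = np.random.default_rng(7)
        s = series_from_samples(rng.normal(0, 0.1, (12, 10)))
        prof = station_significance(s, s, alpha=0.01)
        assert prof.n_significant == 0
        assert prof.percent_significant == 0.0
        assert np.allclose(prof.f_statistic, 1.0)

    def test_zero_variance_stations_not_significant(self):
        s = series_from_samples(np.zeros((4, 10)))
        prof = station_significance(s, s, alpha=0.01)
        assert prof.n_significant == 0
        assert np.all(prof.p_value == 1.0)

    def test_station_order_permutation_invariant(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 0.1, (15, 10))
        b = rng.normal(0, 0.3, (15, 10))
        p0 = station_significance(series_from_samples(a), series_from_samples(b))
        perm = rng.permutation(15)
        stations = np.arange(1.0, 16)
        pp = station_significance(
            series_from_samples(a[perm], stations=stations[perm]),
            series_from_samples(b[perm], stations=stations[perm]),
        )
        assert pp.percent_significant == p0.percent_significant
        assert np.allclose(np.sort(pp.p_value), np.sort(p0.p_value))

    def test_empty_intersection_rejected(self):
        a = series_from_samples(np.zeros((3, 5)), stations=[1.0, 2, 3])
        b = series_from_samples(np.zeros((3, 5)), stations=[10.0, 11, 12])
        with pytest.raises(ValueError, match="common"):
            station_significance(a, b)

    def test_turn_amplitude_boost_detected(self):
        """A 3x curvature amplitude during turning (9x variance) makes most
        tail stations significant at alpha=0.01 with 10-frame windows."""
        straight = single_cell_truth(duration=0.1, tail_amplitude=0.05)
        turning = single_cell_truth(duration=0.1, tail_amplitude=0.15)
        ts, _ = simulate_sperm(straight)
        tt, _ = simulate_sperm(turning)
        prof = station_significance(
            collect_series(ts, "tail", 0, 10), collect_series(tt, "tail", 0, 10),
            alpha=0.01,
        )
        assert prof.percent_significant > 50.0

    def test_head_trembles_less_all_stations(self):
        """head_amplitude_factor=0.3 -> head-vs-tail variance ratio ~0.09:
        significant at every compared station with >=30 pooled frames."""
        truth = single_cell_truth(duration=0.2, head_amplitude_factor=0.3)
        trace, _ = simulate_sperm(truth)
        head = collect_series(trace, "head", 0, 30)
        tail = collect_series(trace, "tail", 0, 30)
        prof = station_significance(head, tail, alpha=0.01)
        assert prof.part == "head vs tail"
        assert prof.n_significant == prof.n_stations
        assert prof.percent_significant == 100.0


class TestTypeICalibration:
    @pytest.mark.parametrize("alpha", [0.05, 0.01])
    def test_f_test_calibrated(self, alpha):
        rng = np.random.default_rng(1234)
        n_rep = 2000
        x = rng.normal(0, 1, (n_rep, 10))
        y = rng.normal(0, 1, (n_rep, 10))
        rej = sum(f_test_variance(x[i], y[i]).p_value < alpha for i in range(n_rep))
        assert abs(rej / n_rep - alpha) <= 0.3 * alpha + 2 * math.sqrt(alpha / n_rep)

    @pytest.mark.parametrize("alpha", [0.05, 0.01])
    def test_mwu_calibrated(self, alpha):
        rng = np.random.default_rng(4321)
        n_rep = 2000
        x = rng.normal(0, 1, (n_rep, 10))
        y = rng.normal(0, 1, (n_rep, 10))
        rej = sum(mann_whitney_exact(x[i], y[i]).p_value <= alpha for i in range(n_rep))
        assert abs(rej / n_rep - alpha) <= 0.3 * alpha + 2 * math.sqrt(alpha / n_rep)
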