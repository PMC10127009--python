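"""Statistical layer: exact Mann-Whitney U, variance-ratio F-tests, and
per-station significance profiles.

Speed and beat-frequency cohorts are compared with a Mann-Whitney U test
(exact by full enumeration of the U null distribution for small tie-free
samples, matching R's ``wilcox.exact``; mid-rank normal approximation with
tie correction otherwise).  Waveform amplitude is compared station by
station with a two-sided variance-ratio F-test on signed curvature samples
(matching R's ``var.test``), and a significance profile reports, per
arc-length station, the F statistic, p-value and a flag at the chosen
level, plus the percentage of significant stations.  Following the source
analysis, per-station p-values are NOT corrected for multiple testing by
default (a Benjamini-Hochberg option is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "TestResult",
    "SignificanceProfile",
    "f_test_variance",
    "mann_whitney_exact",
    "station_significance",
    "percent_significant",
]

#: Combined-sample-size bound below which the Mann-Whitney test is exact
#: (full enumeration); beyond it, or with ties, the mid-rank normal
#: approximation is used.
EXACT_MWU_MAX_N = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


@dataclass
class SignificanceProfile:
    """Per-station variance-comparison results between two conditions."""

    part: str
    stations: np.ndarray
    f_statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray  # bool, at `alpha`
    n_a: int
    n_b: int
    alpha: float
    label: str = ""

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))

    @property
    def percent_significant(self) -> float:
        return percent_significant(self.significant)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_um": self.stations,
                "f_stat": self.f_statistic,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )

    def summary(self) -> dict:
        return {
            "comparison": self.label,
            "part": self.part,
            "alpha": self.alpha,
            "n_stations": self.n_stations,
            "n_significant": self.n_significant,
            "percent_significant": self.percent_significant,
            "n_a": self.n_a,
            "n_b": self.n_b,
        }


def f_test_variance(a, b) -> TestResult:
    """Two-sided variance-ratio F-test (the contract of R's ``var.test``).

    F = s2_a / s2_b with unbiased sample variances; two-sided
    p = 2 * min(P(F <= f), P(F >= f)) under F(len(a)-1, len(b)-1), capped
    at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("F-test needs at least 2 observations per sample")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    if va == 0.0 and vb == 0.0:
        raise ValueError("degenerate samples: both variances are zero")
    dfa, dfb = len(a) - 1, len(b) - 1
    if vb == 0.0:
        stat, p = float("inf"), 0.0
    else:
        stat = va / vb
        if stat == 1.0 and dfa == dfb:
            p = 1.0  # symmetry point: two-sided p is exactly 1
        else:
            dist = scipy.stats.f(dfa, dfb)
            p = float(min(1.0, 2.0 * min(dist.cdf(stat), dist.sf(stat))))
    return TestResult(statistic=stat, p_value=p, method="F test (variance ratio)",
                      n_a=len(a), n_b=len(b))


@lru_cache(maxsize=64)
def _u_null_counts(n1: int, n2: int):
    """Exact null distribution of the Mann-Whitney U statistic.

    Counts, for each rank sum of an n1-subset of ranks {1..n1+n2}, the
    number of subsets attaining it (subset-sum dynamic programme over all
    C(n1+n2, n1) assignments), shifted to U = ranksum - n1(n1+1)/2.
    Returns (pmf_counts, total) as Python integers via object arrays.
    """
    n = n1 + n2
    max_sum = sum(range(n - n1 + 1, n + 1))
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    dp[0, 0] = 1
    for j in range(1, n + 1):
        for k in range(min(j, n1), 0, -1):
            dp[k, j:] = dp[k, j:] + dp[k - 1, : max_sum + 1 - j]
    counts = dp[n1]
    shift = n1 * (n1 + 1) // 2
    pmf = counts[shift : shift + n1 * n2 + 1]
    total = int(sum(pmf))
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]
    return cdf, sf, total


def _exact_two_sided_p(u: int, n1: int, n2: int) -> float:
    cdf, sf, total = _u_null_counts(n1, n2)
    lo = int(cdf[u])
    hi = int(sf[u])
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney_exact(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The statistic is U of the first sample (number of (a, b) pairs with
    a > b, counting ties as 1/2).  For tie-free data with combined size at
    most ``EXACT_MWU_MAX_N`` the p-value is exact, by full enumeration of
    the U null distribution; otherwise the mid-rank normal approximation
    with tie correction and continuity correction is used.  The method
    actually applied is recorded in the result.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("Mann-Whitney test needs non-empty samples")
    n1, n2 = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 + n2 <= EXACT_MWU_MAX_N and not has_ties:
        p = _exact_two_sided_p(int(round(u1)), n1, n2)
        method = "Mann-Whitney U (exact enumeration)"
    else:
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
        method = "Mann-Whitney U (normal approximation, tie-corrected)"
    return TestResult(statistic=float(u1), p_value=p, method=method, n_a=n1, n_b=n2)


def percent_significant(flags) -> float:
    """Percentage of true flags, rounded half-up to one decimal."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        raise ValueError("percent_significant of an empty flag set")
    frac = Decimal(100 * int(flags.sum())) / Decimal(int(flags.size))
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def station_significance(
    series_a,
    series_b,
    alpha: float = 0.01,
    label: str = "",
    adjust: str = "none",
) -> SignificanceProfile:
    """Per-station variance-ratio F-tests between two curvature series.

    Tests run on the intersection of the two station grids.  The series
    normally cover the same part; comparing head against tail at matched
    stations is also supported (the profile's part is then recorded as
    ``"head vs tail"``).  Stations where both sides have exactly zero
    variance are reported with F = NaN, p = 1 (no detectable amplitude on
    either side).  ``adjust='bh'`` applies a Benjamini-Hochberg correction
    before flagging; the default is none.
    """
    part = (
        series_a.part
        if series_a.part == series_b.part
        else f"{series_a.part} vs {series_b.part}"
    )
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    common, ia, ib = np.intersect1d(
        series_a.stations, series_b.stations, return_indices=True
    )
    if len(common) == 0:
        raise ValueError("no common stations between the series")
    f_stat = np.empty(len(common))
    p_val = np.empty(len(common))
    for k, (i, j) in enumerate(zip(ia, ib)):
        sa = series_a.samples[i]
        sb = series_b.samples[j]
        if np.var(sa, ddof=1) == 0.0 and np.var(sb, ddof=1) == 0.0:
            f_stat[k], p_val[k] = float("nan"), 1.0
        else:
            res = f_test_variance(sa, sb)
            f_stat[k], p_val[k] = res.statistic, res.p_value
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        significant = multipletests(p_val, alpha=alpha, method="fdr_bh")[0]
    elif adjust == "none":
        significant = p_val < alpha
    else:
        raise ValueError(f"unknown adjustment {adjust!r}; use 'none' or 'bh'")
    return SignificanceProfile(
        part=part,
        stations=common,
        f_statistic=f_stat,
        p_value=p_val,
        significant=significant,
        n_a=series_a.samples.shape[1],
        n_b=series_b.samples.shape[1],
        alpha=alpha,
        label=label,
    )
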