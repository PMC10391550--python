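"""Group statistics for cohort comparisons.

Two tests cover everything the cohort workflow reports: Fisher's exact test for
categorical phenotype counts (A-type vs B-type cells, bursting vs non-bursting
cells, by sex) and Welch's unequal-variance two-sample t-test for continuous
per-cell metrics.  Both are implemented here from first principles; scipy is
used only for the t-distribution tail probability.

The two-sided Fisher p-value follows the minimum-likelihood convention (as in
R's ``fisher.test``): sum the hypergeometric probabilities of every table with
the observed margins whose probability does not exceed that of the observed
table.  A doubling rule (twice the smaller tail, capped at 1) is available for
cross-checks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact_2x2",
    "welch_t",
    "welch_t_from_samples",
    "cohort_compare",
]

# Relative tolerance when comparing hypergeometric probabilities in the
# minimum-likelihood rule; guards against ties lost to floating point.
_REL_TIE_TOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are groups, columns are categories."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) == 0:
            raise ValueError("contingency table is empty")

    @property
    def odds_ratio(self) -> float:
        """Sample odds ratio (a*d)/(b*c); inf/nan for zero cells."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sided hypothesis test."""

    statistic: float
    p_two_sided: float
    df: float | None = None
    test: str = ""
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_two_sided) or 0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_two_sided}")


def _log_hypergeom_pmf(k: int, row1: int, col1: int, n: int) -> float:
    """log P(X = k) for X ~ Hypergeom(n, col1, row1) via lgamma."""

    def lchoose(m: int, j: int) -> float:
        if j < 0 or j > m:
            return -math.inf
        return math.lgamma(m + 1) - math.lgamma(j + 1) - math.lgamma(m - j + 1)

    return lchoose(col1, k) + lchoose(n - col1, row1 - k) - lchoose(n, row1)


def fisher_exact_2x2(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    *,
    rule: str = "min-likelihood",
) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Enumerates every table compatible with the observed margins in log space.
    ``rule='min-likelihood'`` sums probabilities <= that of the observed table
    (the R convention); ``rule='doubling'`` doubles the smaller one-sided tail.

    A zero margin admits only the observed table, so p = 1 by convention
    (a warning is emitted).
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    a, b, c, d = table.a, table.b, table.c, table.d
    row1, col1, n = a + b, a + c, a + b + c + d

    if min(row1, col1, c + d, b + d) == 0:
        warnings.warn("a margin of the 2x2 table is zero; p = 1 by convention")
        return TestResult(table.odds_ratio, 1.0, test="fisher_exact",
                          detail={"rule": rule, "table": (a, b, c, d)})

    k_min = max(0, row1 - (n - col1))
    k_max = min(row1, col1)
    log_probs = {k: _log_hypergeom_pmf(k, row1, col1, n) for k in range(k_min, k_max + 1)}
    log_p_obs = log_probs[a]

    if rule == "min-likelihood":
        cutoff = log_p_obs + math.log1p(_REL_TIE_TOL)
        terms = [lp for lp in log_probs.values() if lp <= cutoff]
    elif rule == "doubling":
        lower = [lp for k, lp in log_probs.items() if k <= a]
        upper = [lp for k, lp in log_probs.items() if k >= a]
        tail = min(_logsumexp(lower), _logsumexp(upper))
        p = min(1.0, 2.0 * math.exp(tail))
        return TestResult(table.odds_ratio, p, test="fisher_exact",
                          detail={"rule": rule, "table": (a, b, c, d)})
    else:
        raise ValueError(f"unknown two-sided rule: {rule!r}")

    p = min(1.0, math.exp(_logsumexp(terms)))
    return TestResult(table.odds_ratio, p, test="fisher_exact",
                      detail={"rule": rule, "table": (a, b, c, d)})


def _logsumexp(terms: Sequence[float]) -> float:
    m = max(terms)
    if m == -math.inf:
        return -math.inf
    return m + math.log(sum(math.exp(t - m) for t in terms))


def welch_t(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
) -> TestResult:
    """Welch's two-sample t-test from summary statistics.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2) with Welch–Satterthwaite degrees
    of freedom; the two-sided p comes from the central t-distribution.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        if mean1 == mean2:
            return TestResult(0.0, 1.0, df=math.nan, test="welch_t")
        warnings.warn("zero variance in both groups with unequal means; p = 0")
        return TestResult(math.copysign(math.inf, mean1 - mean2), 0.0,
                          df=math.nan, test="welch_t")
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2 ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TestResult(t, min(1.0, p), df=df, test="welch_t")


def welch_t_from_samples(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch's t-test from raw samples (ddof=1 summary statistics)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return welch_t(float(x.mean()), float(x.std(ddof=1)), x.size,
                   float(y.mean()), float(y.std(ddof=1)), y.size)


# Continuous per-cell metrics compared between groups by cohort_compare, and
# which of them are log-transformed first (event frequency and duration, to
# stabilise variance and approximate normality).
DEFAULT_CONTINUOUS_METRICS = (
    "capacitance_pf",
    "membrane_potential_mv",
    "event_freq_hz",
    "event_duration_ms",
    "burst_factor",
)
DEFAULT_LOG_METRICS = ("event_freq_hz", "event_duration_ms")


def cohort_compare(
    summaries: pd.DataFrame,
    *,
    group_col: str = "sex",
    groups: tuple[str, str] | None = None,
    class_col: str = "cell_class",
    bursting_col: str = "spontaneous_bursting",
    continuous_metrics: Sequence[str] = DEFAULT_CONTINUOUS_METRICS,
    log_metrics: Sequence[str] = DEFAULT_LOG_METRICS,
) -> pd.DataFrame:
    """Run the cohort-level test battery on a per-cell summary table.

    Fisher's exact test is applied to the A-vs-B phenotype counts (cells
    labelled neither A nor B are excluded) and, when ``bursting_col`` is
    present, to bursting vs non-bursting counts.  Welch's t-test is applied to
    each named continuous metric, log-transforming the declared columns first
    (zeros are handled with a half-minimum offset).  Returns a tidy table with
    one row per test: test, metric, group1, group2, n1, n2, statistic, df, p.
    """
    if groups is None:
        found = list(pd.unique(summaries[group_col]))
        if len(found) != 2:
            raise ValueError(f"need exactly 2 groups in {group_col!r}, found {found}")
        groups = (found[0], found[1])
    g1 = summaries[summaries[group_col] == groups[0]]
    g2 = summaries[summaries[group_col] == groups[1]]

    rows: list[dict] = []

    def _fisher_row(metric: str, a: int, b: int, c: int, d: int) -> None:
        res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        rows.append({"test": "fisher_exact", "metric": metric,
                     "group1": groups[0], "group2": groups[1],
                     "n1": a + b, "n2": c + d,
                     "statistic": res.statistic, "df": math.nan,
                     "p": res.p_two_sided})

    if class_col in summaries.columns:
        _fisher_row("A_vs_B",
                    int((g1[class_col] == "A").sum()), int((g1[class_col] == "B").sum()),
                    int((g2[class_col] == "A").sum()), int((g2[class_col] == "B").sum()))
    if bursting_col in summaries.columns:
        _fisher_row("bursting_vs_not",
                    int(g1[bursting_col].astype(bool).sum()),
                    int((~g1[bursting_col].astype(bool)).sum()),
                    int(g2[bursting_col].astype(bool).sum()),
                    int((~g2[bursting_col].astype(bool)).sum()))

    for metric in continuous_metrics:
        if metric not in summaries.columns:
            continue
        x = g1[metric].dropna().to_numpy(dtype=float)
        y = g2[metric].dropna().to_numpy(dtype=float)
        row = {"test": "welch_t", "metric": metric,
               "group1": groups[0], "group2": groups[1],
               "n1": x.size, "n2": y.size}
        if x.size < 2 or y.size < 2:
            row.update(statistic=math.nan, df=math.nan, p=math.nan)
            rows.append(row)
            continue
        if metric in log_metrics:
            pooled = np.concatenate([x, y])
            positive = pooled[pooled > 0]
            eps = positive.min() / 2.0 if (pooled <= 0).any() and positive.size else 0.0
            x, y = np.log(x + eps), np.log(y + eps)
        res = welch_t_from_samples(x, y)
        row.update(statistic=res.statistic, df=res.df, p=res.p_two_sided)
        rows.append(row)

    return pd.DataFrame(rows)
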