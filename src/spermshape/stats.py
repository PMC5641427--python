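"""Group-comparison statistics for head measurements.

Classic tests (two-sample t with pooled variance by default, one-sample
t, the F ratio test of variances, the two-sample Kolmogorov–Smirnov test
with asymptotic p, and Shapiro–Wilk normality) are thin wrappers over
scipy.stats.  The Steel–Dwass all-pairs nonparametric comparison is
implemented here: pairwise Wilcoxon rank sums on joint mid-ranks with
tie correction, the standardized statistic referred to the studentized
range distribution with k groups and infinite degrees of freedom,
``p = P(Q_{k,inf} >= sqrt(2) |z|)``.

Significance labels follow the convention: p > 0.05 not significant
(n.s.); p < 0.05 (*), < 0.01 (**), < 0.001 (***).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "significance_label",
    "classic_tests",
    "steel_dwass",
    "steel_dwass_table",
    "percent_difference",
]


def significance_label(p: float) -> str:
    if not 0.0 <= p <= 1.0 + 1e-12:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclass
class TestResult:
    """One hypothesis test: statistic, p-value, and significance label."""

    __test__ = False          # not a pytest collection target

    test_name: str
    statistic: float
    p_value: float
    tails: str
    groups: tuple
    significance_label: str = ""

    def __post_init__(self) -> None:
        if not self.significance_label:
            self.significance_label = significance_label(self.p_value)


_TAILS = {"two-sided", "less", "greater"}


def _check_sample(x, name: str, test: str, min_n: int = 2) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.size < min_n:
        raise ValueError(f"{test}: sample '{name}' needs >= {min_n} values, "
                         f"got {v.size}")
    if not np.isfinite(v).all():
        raise ValueError(f"{test}: sample '{name}' contains non-finite values")
    return v


def classic_tests(x, y=None, kind: str = "t_two", tail: str = "two-sided",
                  equal_var: bool = True, popmean: float = 0.0,
                  groups: tuple = ("x", "y")) -> TestResult:
    """Dispatch one classic test; see the module docstring for definitions.

    ``kind``: ``t_two`` (two-sample t; pooled variance unless
    ``equal_var=False`` selects Welch), ``t_one`` (one-sample t against
    ``popmean``), ``f_var`` (variance ratio F), ``ks_two`` (two-sample
    KS, asymptotic p), ``shapiro`` (normality; 3 <= n <= 5000).
    """
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {sorted(_TAILS)}, got {tail!r}")
    if kind == "t_two":
        xv = _check_sample(x, groups[0], kind)
        yv = _check_sample(y, groups[1], kind)
        if xv.std(ddof=1) == 0 and yv.std(ddof=1) == 0:
            raise ValueError("t_two: both samples are constant "
                             "(zero pooled variance)")
        res = sps.ttest_ind(xv, yv, equal_var=equal_var, alternative=tail)
        name = "t (pooled)" if equal_var else "t (Welch)"
        return TestResult(name, float(res.statistic), float(res.pvalue),
                          tail, groups)
    if kind == "t_one":
        xv = _check_sample(x, groups[0], kind)
        if xv.std(ddof=1) == 0:
            raise ValueError("t_one: sample is constant")
        res = sps.ttest_1samp(xv, popmean, alternative=tail)
        return TestResult("t (one-sample)", float(res.statistic),
                          float(res.pvalue), tail, groups)
    if kind == "f_var":
        xv = _check_sample(x, groups[0], kind)
        yv = _check_sample(y, groups[1], kind)
        v1, v2 = xv.var(ddof=1), yv.var(ddof=1)
        if v2 == 0:
            raise ValueError("f_var: second sample has zero variance")
        F = v1 / v2
        dist = sps.f(xv.size - 1, yv.size - 1)
        if tail == "two-sided":
            p = 2.0 * min(dist.cdf(F), dist.sf(F))
            p = min(p, 1.0)
        elif tail == "greater":
            p = dist.sf(F)
        else:
            p = dist.cdf(F)
        return TestResult("F (variance ratio)", float(F), float(p), tail, groups)
    if kind == "ks_two":
        xv = _check_sample(x, groups[0], kind)
        yv = _check_sample(y, groups[1], kind)
        res = sps.ks_2samp(xv, yv, alternative=tail, method="exact")
        D = float(res.statistic)
        en = np.sqrt(xv.size * yv.size / (xv.size + yv.size))
        # plain Kolmogorov asymptotic (no small-sample correction)
        if tail == "two-sided":
            p = float(sps.kstwobign.sf(en * D))
        else:
            p = float(np.exp(-2.0 * (en * D) ** 2))
        return TestResult("KS (two-sample)", D, min(max(p, 0.0), 1.0),
                          tail, groups)
    if kind == "shapiro":
        xv = _check_sample(x, groups[0], kind, min_n=3)
        if xv.size > 5000:
            raise ValueError(f"shapiro: n = {xv.size} exceeds 5000")
        if xv.std(ddof=1) == 0:
            raise ValueError("shapiro: sample is constant")
        res = sps.shapiro(xv)
        return TestResult("Shapiro-Wilk", float(res.statistic),
                          float(res.pvalue), "two-sided", (groups[0],))
    raise ValueError(f"unknown test kind {kind!r}")


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum statistic with mid-rank tie correction."""
    n1, n2 = x.size, y.size
    joint = np.concatenate([x, y])
    ranks = sps.rankdata(joint)                # mid-ranks
    W = ranks[:n1].sum()
    N = n1 + n2
    E = n1 * (N + 1) / 2.0
    _, counts = np.unique(joint, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1.0))
    var = n1 * n2 / 12.0 * (N + 1.0 - tie_term)
    if var <= 0:
        raise ValueError("steel_dwass: a pair of groups is entirely tied")
    return float((W - E) / np.sqrt(var))


def steel_dwass(groups: dict | list, labels=None) -> list[TestResult]:
    """All-pairs Steel–Dwass comparison of k >= 3 groups.

    For each pair, joint mid-ranks give a standardized rank-sum z;
    ``p = P(Q_{k,inf} >= sqrt(2) |z|)`` under the studentized range
    distribution, which controls the family-wise error across pairs.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        samples = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        if labels is None:
            labels = [f"group{i + 1}" for i in range(len(samples))]
    k = len(samples)
    if k < 3:
        raise ValueError("steel_dwass needs k >= 3 groups; for two groups "
                         "use a rank-sum (Mann-Whitney) test instead")
    for lab, s in zip(labels, samples):
        _check_sample(s, str(lab), "steel_dwass")
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            z = _rank_sum_z(samples[i], samples[j])
            q = np.sqrt(2.0) * abs(z)
            p = float(sps.studentized_range.sf(q, k, np.inf))
            p = min(max(p, 0.0), 1.0)
            results.append(TestResult("Steel-Dwass", z, p, "two-sided",
                                      (labels[i], labels[j])))
    return results


def steel_dwass_table(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "group1": r.groups[0], "group2": r.groups[1],
        "statistic": r.statistic, "p_value": r.p_value,
        "label": r.significance_label,
    } for r in results])


def percent_difference(reference_mean: float, test_mean: float) -> float:
    """100 * (reference - test) / reference; positive = test is smaller."""
    if reference_mean <= 0:
        raise ValueError(f"reference mean must be > 0, got {reference_mean}")
    return 100.0 * (reference_mean - test_mean) / reference_mean
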