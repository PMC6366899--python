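"""Statistical kernel: the four tests used across assays, plus Bonferroni.

Every species contrast in the package funnels through these wrappers so
that the report always carries the same fields: statistic, raw p,
Bonferroni-adjusted p, group sizes, and an effect summary (mean
difference for t tests, rank-biserial correlation for Mann-Whitney,
r for correlation).  Tests are two-sided unless stated otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "mann_whitney_u",
    "welch_t",
    "student_t",
    "pearson_regression",
    "one_way_anova",
    "bonferroni_adjust",
]


@dataclass
class ComparisonResult:
    """One statistical contrast between two groups (or one regression)."""

    contrast: str
    test: str
    statistic: float
    p: float
    n: tuple[int, ...]
    effect: float
    p_adjusted: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "test": self.test,
            "statistic": self.statistic,
            "p": self.p,
            "p_adjusted": self.p_adjusted,
            "n": list(self.n),
            "effect": self.effect,
            "flags": list(self.flags),
        }


def _as_arrays(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    return a, b


def _exact_mwu_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact permutation Mann-Whitney p via full enumeration (handles ties)."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2.0
    n = len(pooled)
    u_all = []
    for idx in itertools.combinations(range(n), n_a):
        u_all.append(ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0)
    u_all = np.asarray(u_all)
    mean_u = n_a * (n - n_a) / 2.0
    if alternative == "greater":
        p = np.mean(u_all >= u_obs)
    elif alternative == "less":
        p = np.mean(u_all <= u_obs)
    else:
        # two-sided: as extreme in either direction, measured from the mean
        p = np.mean(np.abs(u_all - mean_u) >= abs(u_obs - mean_u) - 1e-12)
    return float(u_obs), float(min(1.0, p))


def mann_whitney_u(
    a, b, alternative: str = "two-sided", contrast: str = "", exact_max_n: int = 12
) -> ComparisonResult:
    """Mann-Whitney U test.

    Uses full permutation enumeration when the pooled sample size is at
    most *exact_max_n* (exact even with ties); otherwise the normal
    approximation with tie correction.  The effect summary is the
    rank-biserial correlation ``2*U/(n_a*n_b) - 1``.
    """
    a, b = _as_arrays(a, b)
    if len(a) + len(b) <= exact_max_n:
        u, p = _exact_mwu_p(a, b, alternative)
    else:
        res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        u, p = float(res.statistic), float(res.pvalue)
    effect = 2.0 * u / (len(a) * len(b)) - 1.0
    return ComparisonResult(contrast, "mann_whitney_u", u, p, (len(a), len(b)), effect)


def _t_test(a, b, equal_var: bool, name: str, contrast: str) -> ComparisonResult:
    a, b = _as_arrays(a, b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t tests need at least 2 observations per group")
    flags = []
    effect = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate variance: identical constants -> no evidence;
        # different constants -> complete separation
        if effect == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = math.copysign(math.inf, effect), 0.0
        flags.append("degenerate_variance")
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(contrast, name, stat, p, (len(a), len(b)), effect, flags=flags)


def welch_t(a, b, contrast: str = "") -> ComparisonResult:
    """Welch's unequal-variance t test (Welch-Satterthwaite df)."""
    return _t_test(a, b, equal_var=False, name="welch_t", contrast=contrast)


def student_t(a, b, contrast: str = "") -> ComparisonResult:
    """Student's pooled-variance unpaired t test."""
    return _t_test(a, b, equal_var=True, name="student_t", contrast=contrast)


@dataclass
class RegressionResult:
    """OLS of y on x with the Pearson correlation test."""

    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    n: int
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "r_squared": self.r_squared,
            "p": self.p,
            "n": self.n,
            "flags": list(self.flags),
        }


def pearson_regression(x, y) -> RegressionResult:
    """Least-squares line plus the two-sided Pearson correlation test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched x/y with at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has no variation; slope undefined")
    if np.ptp(y) == 0:
        # constant response: flat line, correlation undefined
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 1.0, len(x), ["constant_y"])
    res = sps.linregress(x, y)
    return RegressionResult(
        float(res.slope),
        float(res.intercept),
        float(res.rvalue),
        float(res.rvalue**2),
        float(res.pvalue),
        len(x),
    )


def one_way_anova(*groups, contrast: str = "") -> ComparisonResult:
    """One-way ANOVA across two or more groups (thin utility)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    res = sps.f_oneway(*arrays)
    grand = np.concatenate(arrays).mean()
    effect = float(max(abs(g.mean() - grand) for g in arrays))
    return ComparisonResult(
        contrast,
        "one_way_anova",
        float(res.statistic),
        float(res.pvalue),
        tuple(len(g) for g in arrays),
        effect,
    )


def bonferroni_adjust(results: list[ComparisonResult]) -> list[ComparisonResult]:
    """Set ``p_adjusted = min(1, m * p)`` over the family *results* (in place)."""
    m = len(results)
    for r in results:
        r.p_adjusted = min(1.0, m * r.p)
    return results
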