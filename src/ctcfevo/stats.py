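"""Shared statistical procedures and the common JSON-serialisable result type.

Exact two-sided binomial test, chi-square goodness-of-fit, Mann-Whitney U
(exact for small samples, tie-corrected normal approximation otherwise,
cutover at combined n = 40), Kruskal-Wallis with tie correction, and
Bonferroni adjustment.  Computation is delegated to scipy.stats; this module
fixes the small-sample behaviour and the result schema used by every
analysis stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "binom_test",
    "chisq_gof",
    "mwu",
    "kruskal",
    "bonferroni",
]

MWU_EXACT_CUTOVER = 40  # combined sample size below which the exact MWU is used


@dataclass(frozen=True)
class TestResult:
    __test__ = False  # not a pytest collection target

    test: str
    statistic: float
    p: float
    p_adjusted: float = field(default=float("nan"))
    n_comparisons: int = 1

    def __post_init__(self):
        if np.isnan(self.p_adjusted):
            object.__setattr__(self, "p_adjusted", self.p)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "p": float(self.p),
            "p_adjusted": float(self.p_adjusted),
            "n_comparisons": self.n_comparisons,
        }


def binom_test(k: int, n: int, p0: float) -> TestResult:
    """Exact two-sided binomial test of ``k`` successes in ``n`` trials.

    Two-sided p sums the probabilities of all outcomes no more likely than
    the observed one.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0 < p0 < 1):
        raise ValueError("require 0 < p0 < 1")
    res = _sps.binomtest(k, n, p0, alternative="two-sided")
    return TestResult("binomial", float(k), min(res.pvalue, 1.0))


def chisq_gof(observed: Sequence[float], expected: Sequence[float]) -> TestResult:
    """Chi-square goodness-of-fit with df = categories - 1.

    ``expected`` may be counts or proportions; it is rescaled to the observed
    total.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.ndim != 1:
        raise ValueError("observed and expected must be 1-D and equal length")
    if obs.sum() <= 0 or exp.sum() <= 0:
        raise ValueError("totals must be positive")
    exp = exp * obs.sum() / exp.sum()
    stat, p = _sps.chisquare(obs, exp)
    return TestResult("chisq_gof", float(stat), float(min(p, 1.0)))


def mwu(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when the combined sample size is below the cutover and
    there are no ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    flat = np.concatenate([x, y])
    if np.all(flat == flat[0]):
        # total tie: U at its null mean, no evidence either way
        return TestResult("mannwhitneyu", float(x.size * y.size / 2), 1.0)
    method = "exact" if x.size + y.size < MWU_EXACT_CUTOVER else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mannwhitneyu", float(res.statistic), float(min(res.pvalue, 1.0)))


def kruskal(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups, tie-corrected."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return TestResult("kruskal", 0.0, 1.0)
    stat, p = _sps.kruskal(*arrays)
    return TestResult("kruskal", float(stat), float(min(p, 1.0)))


def bonferroni(results: Sequence[TestResult]) -> list[TestResult]:
    """Bonferroni-adjust a family of test results."""
    m = len(results)
    return [
        replace(r, p_adjusted=min(1.0, r.p * m), n_comparisons=m) for r in results
    ]
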