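"""Two-sample comparison of plateau datasets (Method1 vs Method2).

When the same variable's plateau is extracted by two procedures — e.g.
visually on the sorted plot versus by the automated minimal-difference
algorithm — the two point sets usually differ in size and membership.
Agreement is assessed with three two-sided tests at α = 0.05:

* Welch's unequal-variance t-test on the means,
* the Mann-Whitney U test on the rank distributions (midrank ties),
* Levene's test on the variances (absolute deviations from the mean).

No multiple-testing correction is applied across the three tests; the
report says so explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Any, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "ComparisonReport",
    "welch_t",
    "mann_whitney_u",
    "levene",
    "compare_methods",
]

SIG = "Sig Diff"
NO_SIG = "No Sig Diff"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    verdict: str = NO_SIG

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        self.verdict = SIG if self.p_value < self.alpha else NO_SIG

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class ComparisonReport:
    """Descriptives and three test verdicts for a Method1/Method2 pair."""

    label: str
    n1: int
    n2: int
    descriptives1: dict[str, float]
    descriptives2: dict[str, float]
    t_test: TestResult
    mann_whitney: TestResult
    levene: TestResult
    note: str = "No multiple-testing correction applied across the three tests."

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        for key in ("t_test", "mann_whitney", "levene"):
            d[key] = getattr(self, key).to_dict()
        return d


def _clean(x: Sequence[float], name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]  # drop NaN/inf before testing
    if arr.size < min_n:
        raise ValueError(f"{name}: need at least {min_n} finite values, got {arr.size}")
    return arr


def welch_t(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> TestResult:
    """Welch's unequal-variance t-test of the two means (two-sided).

    Degrees of freedom by Welch–Satterthwaite.  Two identical constant
    samples give t = 0, p = 1 by convention.
    """
    a = _clean(a, "sample 1", 2)
    b = _clean(b, "sample 2", 2)
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TestResult("Welch t-test", 0.0, 1.0, alpha)
        raise ValueError("both samples constant with different means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult("Welch t-test", float(res.statistic), float(res.pvalue), alpha)


def mann_whitney_u(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> TestResult:
    """Mann-Whitney U test (two-sided), U reported for the first sample.

    Ties get midranks (each tied cross-pair contributes ½ to U).  The
    p-value uses exact enumeration for small tie-free samples
    (n1·n2 <= 200) and the tie-corrected normal approximation otherwise.
    """
    a = _clean(a, "sample 1", 1)
    b = _clean(b, "sample 2", 1)
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 200 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("Mann-Whitney U", float(res.statistic), float(res.pvalue), alpha)


def levene(
    a: Sequence[float],
    b: Sequence[float],
    center: str = "mean",
    alpha: float = 0.05,
) -> TestResult:
    """Levene's test of equal variances (two-sided F on |deviations|).

    ``center='mean'`` is the classic Levene statistic; ``'median'``
    selects the Brown–Forsythe variant.  Identical samples give W = 0,
    p = 1.
    """
    a = _clean(a, "sample 1", 2)
    b = _clean(b, "sample 2", 2)
    dev_a = np.abs(a - (np.mean(a) if center == "mean" else np.median(a)))
    dev_b = np.abs(b - (np.mean(b) if center == "mean" else np.median(b)))
    if np.var(dev_a, ddof=1) == 0.0 and np.var(dev_b, ddof=1) == 0.0 and math.isclose(
        dev_a.mean(), dev_b.mean()
    ):
        return TestResult("Levene", 0.0, 1.0, alpha)
    res = sps.levene(a, b, center=center)
    return TestResult("Levene", float(res.statistic), float(res.pvalue), alpha)


def _descriptives(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "min": float(np.min(x)),
        "max": float(np.max(x)),
    }


def compare_methods(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    label: str = "Method1 vs Method2",
    levene_center: str = "mean",
) -> ComparisonReport:
    """Full comparison report for two plateau datasets.

    The vectors may differ in length (the two plateau extractions need
    not pick the same number of points); missing values are dropped per
    vector before testing.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    a = _clean(a, "Method1", 2)
    b = _clean(b, "Method2", 2)
    return ComparisonReport(
        label=label,
        n1=int(a.size),
        n2=int(b.size),
        descriptives1=_descriptives(a),
        descriptives2=_descriptives(b),
        t_test=welch_t(a, b, alpha=alpha),
        mann_whitney=mann_whitney_u(a, b, alpha=alpha),
        levene=levene(a, b, center=levene_center, alpha=alpha),
    )
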