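"""Reporting statistics: two-group and multi-group tests with star labels.

The conventions follow common practice in preclinical scaffold studies:
two-sided Student's t (parametric) or Mann-Whitney U (nonparametric) for
two groups; one-way ANOVA with Bonferroni post-hoc or Kruskal-Wallis with
Dunn's post-hoc for three or more; significance stars at p < 0.05 (*),
p < 0.01 (**) and p < 0.001 (***).

Parametric vs nonparametric is always an explicit caller choice — the
toolkit never auto-detects normality.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import InsufficientGroupError, InvalidPValueError

MIN_GROUP_N = 3
#: Largest per-group size at which the exact Mann-Whitney U distribution is used.
EXACT_MW_MAX_N = 8


def star_label(p: float) -> str:
    """Map a p-value to the star convention: ***, **, *, or ns.

    Thresholds are strict: p = 0.05 exactly is 'ns'.
    """
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise InvalidPValueError(f"p-value must lie in [0, 1], got {p!r}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison: method, statistic, p, and its star label."""

    comparison: tuple[str, str]
    method: str
    statistic: float
    p_value: float

    @property
    def stars(self) -> str:
        return star_label(self.p_value)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def _check_sizes(*samples, min_n: int = MIN_GROUP_N) -> list[np.ndarray]:
    arrays = [np.asarray(s, dtype=float).ravel() for s in samples]
    for arr in arrays:
        if arr.size < min_n:
            raise InsufficientGroupError(
                f"each group needs at least {min_n} observations, got {arr.size}"
            )
    return arrays


def two_group_test(
    a,
    b,
    parametric: bool,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> TestResult:
    """Two-sided two-group comparison.

    Parametric: Student's t-test (equal variances assumed, as in classical
    reporting; ``welch=True`` switches to Welch's correction).
    Nonparametric: Mann-Whitney U, using the exact U distribution when
    both groups have n <= 8 and the data are tie-free, and the
    tie-corrected normal approximation otherwise.
    """
    x, y = _check_sizes(a, b)
    if parametric:
        stat, p = sps.ttest_ind(x, y, equal_var=not welch)
        method = "t_test_two_sided" if not welch else "welch_t_two_sided"
    else:
        pooled = np.concatenate([x, y])
        has_ties = np.unique(pooled).size < pooled.size
        use_exact = (x.size <= EXACT_MW_MAX_N and y.size <= EXACT_MW_MAX_N) and not has_ties
        stat, p = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if use_exact else "asymptotic"
        )
        method = "mann_whitney"
    return TestResult(labels, method, float(stat), float(min(p, 1.0)))


def bonferroni(p_raw: float, m: int) -> float:
    """Bonferroni family correction: min(1, m * p)."""
    return min(1.0, m * p_raw)


def _dunn_pairwise(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Dunn's rank-sum post-hoc with Bonferroni family correction.

    All observations are ranked jointly (mid-ranks on ties); the pairwise
    z statistic compares mean ranks with the tie-corrected null variance
    N(N+1)/12 - T/(12(N-1)), T = sum(t^3 - t) over tie groups.
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    offsets = np.cumsum([0] + [groups[g].size for g in names])
    mean_ranks = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    results = []
    for g1, g2 in pairs:
        se = math.sqrt(var_base * (1.0 / groups[g1].size + 1.0 / groups[g2].size))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        results.append(TestResult((g1, g2), "kruskal_dunn", float(z), bonferroni(p_raw, m)))
    return results


def multi_group_test(groups: dict[str, "np.ndarray | list"], parametric: bool) -> dict:
    """Omnibus multi-group test plus corrected pairwise post-hoc comparisons.

    Parametric: one-way ANOVA followed by pairwise t-tests with Bonferroni
    correction. Nonparametric: Kruskal-Wallis followed by Dunn's post-hoc
    (Bonferroni family correction). Returns ``{"omnibus": TestResult,
    "posthoc": [TestResult, ...]}``.
    """
    if len(groups) < 3:
        raise InsufficientGroupError(f"need >= 3 groups, got {len(groups)}")
    names = list(groups)
    arrays = dict(zip(names, _check_sizes(*[groups[g] for g in names])))
    values = [arrays[g] for g in names]
    if parametric:
        stat, p = sps.f_oneway(*values)
        omnibus = TestResult(("omnibus",) * 2, "anova_bonferroni", float(stat), float(p))
        pairs = list(itertools.combinations(names, 2))
        posthoc = []
        for g1, g2 in pairs:
            t, p_raw = sps.ttest_ind(arrays[g1], arrays[g2])
            posthoc.append(
                TestResult((g1, g2), "anova_bonferroni", float(t), bonferroni(float(p_raw), len(pairs)))
            )
    else:
        stat, p = sps.kruskal(*values)
        omnibus = TestResult(("omnibus",) * 2, "kruskal_dunn", float(stat), float(p))
        posthoc = _dunn_pairwise(arrays)
    return {"omnibus": omnibus, "posthoc": posthoc}
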