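"""Nonparametric strain comparisons and fold-change epistasis analysis.

Rate distributions from fluctuation assays are heavy-tailed and the field
compares them nonparametrically: Mann--Whitney U between two strains,
Kruskal--Wallis followed by Bonferroni-corrected pairwise U tests for three
or more, and a plain Pearson chi-square for contingency tables of counted
cells.  Genetic interactions are read off fold changes: the double mutant's
fold increase over wild type is compared with an additive expectation
combined from the two single-mutant folds, and called synergistic,
additive, or suppressive.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.special import comb

from .rates import RateEstimate

__all__ = [
    "TestResult",
    "InteractionResult",
    "FoldChange",
    "EXACT_ENUMERATION_LIMIT",
    "mann_whitney",
    "kruskal_wallis",
    "posthoc_pairwise",
    "fold_change",
    "additive_expectation",
    "classify_interaction",
    "interaction_analysis",
    "chi_square_contingency",
]

#: Exact Mann-Whitney p-values are computed whenever the number of label
#: assignments C(n1+n2, n1) does not exceed this; beyond it the
#: tie-corrected, continuity-corrected normal approximation is used.
EXACT_ENUMERATION_LIMIT = 200_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    exact: bool
    p_adjusted: float | None = None
    df: int | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-15:
            raise ValueError("p_adjusted must be >= p_value")


@dataclass(frozen=True)
class InteractionResult:
    """Fold-change epistasis call for a double mutant."""

    fold_a: float
    fold_b: float
    fold_double: float
    expected_additive: float
    convention: str
    label: str
    tolerance: float


class FoldChange(NamedTuple):
    fold: float
    qualifier: str  # "exact" or "lower_bound"


# ---------------------------------------------------------------------------
# Mann–Whitney U
# ---------------------------------------------------------------------------

_ALTERNATIVES = {"two_sided": "two-sided", "less": "less", "greater": "greater"}


@lru_cache(maxsize=8)
def _combination_indices(n: int, n1: int) -> np.ndarray:
    """All C(n, n1) index subsets, as an array of shape (C, n1)."""
    return np.array(list(itertools.combinations(range(n), n1)), dtype=np.intp)


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    """U of the first sample from midranks of the pooled data."""
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def _exact_p_enumeration(
    ranks: np.ndarray, n1: int, u_obs: float, alternative: str
) -> float:
    """Conditional permutation p by full enumeration of label assignments.

    Conditions on the observed pooled multiset (midranks), so ties are
    handled exactly.  Two-sided p doubles the smaller tail, capped at 1.
    """
    n = len(ranks)
    combos = _combination_indices(n, n1)
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2
    eps = 1e-9
    p_greater = float(np.mean(u_all >= u_obs - eps))
    p_less = float(np.mean(u_all <= u_obs + eps))
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Mann--Whitney U test between two samples.

    The p-value is exact (conditional permutation given the pooled
    multiset) whenever C(n1+n2, n1) <= ``EXACT_ENUMERATION_LIMIT``: full
    enumeration when ties are present, the standard exact count distribution
    otherwise.  Larger problems use the normal approximation with tie and
    continuity corrections.  The reported statistic is U of ``x``.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {sorted(_ALTERNATIVES)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    u_x = _u_statistic(ranks, n1)
    has_ties = len(np.unique(pooled)) < len(pooled)
    n_assignments = comb(n1 + n2, n1, exact=True)
    exact = n_assignments <= EXACT_ENUMERATION_LIMIT
    if exact and has_ties:
        p = _exact_p_enumeration(ranks, n1, u_x, alternative)
        detail = "exact enumeration conditional on ties"
    elif exact:
        res = stats.mannwhitneyu(
            x, y, alternative=_ALTERNATIVES[alternative], method="exact"
        )
        p, detail = float(res.pvalue), "exact count distribution"
    else:
        res = stats.mannwhitneyu(
            x,
            y,
            alternative=_ALTERNATIVES[alternative],
            method="asymptotic",
            use_continuity=True,
        )
        p, detail = float(res.pvalue), "normal approximation, tie + continuity corrected"
    return TestResult(
        method="mann_whitney_u",
        statistic=u_x,
        p_value=min(1.0, p),
        group_sizes=(n1, n2),
        exact=exact,
        detail=detail,
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal--Wallis H test across k groups (chi-square with k-1 df).

    By convention H = 0 and p = 1 when every pooled value is identical
    (the tie correction is otherwise undefined there).
    """
    if len(groups) < 2:
        raise ValueError("kruskal_wallis requires at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("all groups must be nonempty")
    sizes = tuple(len(a) for a in arrays)
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult(
            method="kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            group_sizes=sizes,
            exact=False,
            df=df,
            detail="all values tied",
        )
    h, p = stats.kruskal(*arrays)
    return TestResult(
        method="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        group_sizes=sizes,
        exact=False,
        df=df,
    )


def posthoc_pairwise(
    groups: Sequence[Sequence[float]], alternative: str = "two_sided"
) -> dict[tuple[int, int], TestResult]:
    """Pairwise Mann--Whitney tests with Bonferroni-adjusted p-values.

    Returns a dict keyed by group-index pairs (i, j), i < j; each result
    carries ``p_adjusted = min(1, p * number_of_pairs)``.
    """
    if len(groups) < 2:
        raise ValueError("posthoc_pairwise requires at least 2 groups")
    pairs = list(itertools.combinations(range(len(groups)), 2))
    out: dict[tuple[int, int], TestResult] = {}
    for i, j in pairs:
        res = mann_whitney(groups[i], groups[j], alternative=alternative)
        out[(i, j)] = TestResult(
            method=res.method,
            statistic=res.statistic,
            p_value=res.p_value,
            group_sizes=res.group_sizes,
            exact=res.exact,
            p_adjusted=min(1.0, res.p_value * len(pairs)),
            detail=res.detail,
        )
    return out


# ---------------------------------------------------------------------------
# Fold changes and epistasis
# ---------------------------------------------------------------------------


def fold_change(numerator: RateEstimate, denominator: RateEstimate) -> FoldChange:
    """Ratio of two rate estimates.

    If the denominator is itself a detection-limit upper bound the ratio is
    only a lower bound on the true fold (qualifier ``"lower_bound"``); an
    upper-bound numerator has no defined direction and is an error.
    """
    if numerator.is_upper_bound:
        raise ValueError("fold change with an upper-bound numerator is undefined")
    if denominator.mu <= 0:
        raise ValueError("denominator rate must be positive")
    qualifier = "lower_bound" if denominator.is_upper_bound else "exact"
    return FoldChange(numerator.mu / denominator.mu, qualifier)


def additive_expectation(
    fold_a: float, fold_b: float, convention: str = "sum"
) -> float:
    """Expected double-mutant fold if the two effects combine additively.

    ``sum`` simply adds the two single-mutant folds (the convention used in
    this assay literature: 4-fold + 38-fold -> 42-fold expected); note its
    quirk that two neutral alleles (1, 1) "expect" 2.  ``increments`` adds
    fold increments above baseline, fold_a + fold_b - 1.
    """
    if convention not in ("sum", "increments"):
        raise ValueError("convention must be 'sum' or 'increments'")
    if fold_a < 1 or fold_b < 1:
        warnings.warn(
            "single-mutant fold < 1 (suppressor allele); additive expectation "
            "computed anyway",
            stacklevel=2,
        )
    if convention == "sum":
        return fold_a + fold_b
    return fold_a + fold_b - 1


def classify_interaction(
    fold_double: float, expected_additive: float, tolerance: float = 0.10
) -> str:
    """Label a genetic interaction from folds.

    ``synergistic`` if the double-mutant fold exceeds the additive
    expectation by more than the relative tolerance, ``suppressive`` if it
    falls short by more, else ``additive``.
    """
    if fold_double <= 0 or expected_additive <= 0:
        raise ValueError("folds must be positive")
    if fold_double > expected_additive * (1 + tolerance):
        return "synergistic"
    if fold_double < expected_additive * (1 - tolerance):
        return "suppressive"
    return "additive"


def interaction_analysis(
    fold_a: float,
    fold_b: float,
    fold_double: float,
    convention: str = "sum",
    tolerance: float = 0.10,
) -> InteractionResult:
    """Combine :func:`additive_expectation` and :func:`classify_interaction`."""
    expected = additive_expectation(fold_a, fold_b, convention=convention)
    return InteractionResult(
        fold_a=fold_a,
        fold_b=fold_b,
        fold_double=fold_double,
        expected_additive=expected,
        convention=convention,
        label=classify_interaction(fold_double, expected, tolerance=tolerance),
        tolerance=tolerance,
    )


def chi_square_contingency(table: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-square test on an r x c contingency table.

    No continuity correction; df = (r-1)(c-1).  All row and column
    marginals must be positive.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must have at least 2 rows and 2 columns")
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("all row and column marginals must be positive")
    res = stats.chi2_contingency(arr, correction=False)
    return TestResult(
        method="chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=tuple(int(s) for s in arr.sum(axis=1)),
        exact=False,
        df=int(res.dof),
    )
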