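"""Mutation-rate estimation from fluctuation experiments via the Drake equation.

The estimator is the median-frequency method of Drake: the per-replication
mutation rate mu solves the implicit equation

    mu = f / ln(N * mu)

where f is the mutant frequency of a culture (selective colony count,
corrected for the plated fraction, divided by the total population size N
inferred from the nonselective titer).  The default strategy solves the
equation per culture and takes the median of the per-culture rates; a
distribution-free order-statistic confidence interval for the median
accompanies the point estimate.  When no mutants are observed at all, the
rate is reported as an upper bound ("<") implied by a one-colony detection
limit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CultureObservation",
    "FluctuationExperiment",
    "RateEstimate",
    "MedianCI",
    "mutant_frequency",
    "solve_drake",
    "median_ci",
    "estimate_rate",
    "upper_bound_rate",
]

logger = logging.getLogger(__name__)

#: Paper-style display convention: rates are usually quoted x 1e-8.
RATE_DISPLAY_SCALE = 1e8


@dataclass(frozen=True)
class CultureObservation:
    """Plating counts of one culture.

    ``sel_colonies`` is the colony count on the selective (5-FOA) plate and
    ``sel_plating_fraction`` the fraction of the culture that was plated on
    it; ``ns_colonies`` is the nonselective titer count at effective
    dilution ``ns_dilution_fraction``.  Counts may be nonintegral (averaged
    replicate plates, plating-efficiency corrections, or analytic fixtures).
    """

    culture_id: str
    sel_colonies: float
    sel_plating_fraction: float
    ns_colonies: float
    ns_dilution_fraction: float

    def __post_init__(self) -> None:
        if self.sel_colonies < 0 or self.ns_colonies < 0:
            raise ValueError(f"colony counts must be >= 0 ({self.culture_id})")
        for name in ("sel_plating_fraction", "ns_dilution_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(
                    f"{name} must be in (0, 1], got {v} ({self.culture_id})"
                )


@dataclass(frozen=True)
class FluctuationExperiment:
    """All cultures of one strain x tract fluctuation assay."""

    strain: str
    tract_id: str
    cultures: tuple[CultureObservation, ...]
    genotype_tags: frozenset[str] = frozenset()
    temperature_c: float = 23.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cultures", tuple(self.cultures))
        object.__setattr__(self, "genotype_tags", frozenset(self.genotype_tags))
        if not self.cultures:
            raise ValueError("experiment must contain at least one culture")
        if len(self.cultures) < 10:
            # convention in this assay family is >= 10 parallel cultures
            logger.warning(
                "experiment %s/%s has only %d cultures (< 10); median CI will be wide",
                self.strain,
                self.tract_id,
                len(self.cultures),
            )


@dataclass(frozen=True)
class RateEstimate:
    """Point mutation rate per round of replication, with uncertainty.

    ``is_upper_bound`` marks detection-limit estimates reported with "<";
    those carry no confidence interval.
    """

    mu: float
    n_cultures: int
    method: str
    ci_low: float | None = None
    ci_high: float | None = None
    is_upper_bound: bool = False
    achieved_ci_level: float | None = None

    def __post_init__(self) -> None:
        if self.is_upper_bound:
            if self.ci_low is not None or self.ci_high is not None:
                raise ValueError("upper-bound estimates carry no CI")
        elif self.ci_low is not None and self.ci_high is not None:
            if not (0 <= self.ci_low <= self.mu <= self.ci_high):
                raise ValueError(
                    f"need ci_low <= mu <= ci_high, got "
                    f"({self.ci_low}, {self.mu}, {self.ci_high})"
                )

    def display(self, scale: float = RATE_DISPLAY_SCALE) -> str:
        """Render like the field's figures, e.g. ``'<0.54 x 10^-8'``."""
        power = -round(math.log10(scale))
        if self.is_upper_bound:
            return f"<{self.mu * scale:.3g} x 10^{power}"
        return f"{self.mu * scale:.3g} x 10^{power}"


class MedianCI(NamedTuple):
    low: float
    high: float
    achieved_level: float
    below_nominal: bool


class FrequencyResult(NamedTuple):
    f: float
    n_total: float


def mutant_frequency(obs: CultureObservation) -> FrequencyResult:
    """Mutant frequency f and population size N of one culture.

    N = ns_colonies / ns_dilution_fraction; the mutant count is the
    selective colony count scaled up by the plated fraction; f = mutants/N.
    """
    if obs.ns_colonies == 0:
        raise ValueError(
            f"population size undeterminable: culture {obs.culture_id} has "
            "no colonies on the nonselective plate"
        )
    n_total = obs.ns_colonies / obs.ns_dilution_fraction
    mutants = obs.sel_colonies / obs.sel_plating_fraction
    return FrequencyResult(f=mutants / n_total, n_total=n_total)


def solve_drake(f: float, n_total: float) -> float:
    """Solve mu * ln(N * mu) = f for the mutation rate mu.

    The objective is strictly increasing on mu > 1/N and the equation has a
    unique root there for any f > 0; bisection (Brent) runs on the bracket
    [(1+eps)/N, 2*max(f, e/N)].
    """
    if not (math.isfinite(f) and math.isfinite(n_total)):
        raise ValueError("f and N must be finite")
    if f <= 0:
        raise ValueError("f must be > 0 (zero-frequency cultures take the upper-bound path)")
    if n_total <= 1:
        raise ValueError("N must be > 1")

    def g(mu: float) -> float:
        return mu * math.log(n_total * mu) - f

    lo = (1 + 1e-12) / n_total
    hi = 2 * max(f, math.e / n_total)
    mu = optimize.brentq(g, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=200)
    if abs(mu * math.log(n_total * mu) - f) > 1e-10 * f:
        raise RuntimeError(f"Drake solver residual too large at f={f}, N={n_total}")
    return mu


def median_ci(values: Sequence[float], level: float = 0.95) -> MedianCI:
    """Distribution-free order-statistic confidence interval for the median.

    With sorted values x_(1..n), the interval is (x_(l), x_(n+1-l)) where l
    is the largest integer with BinomCDF(l-1; n, 1/2) <= (1-level)/2; the
    achieved coverage 1 - 2*BinomCDF(l-1; n, 1/2) is at least nominal.  For
    n too small to reach the nominal level (n < 6 at 95%) the full range is
    returned and flagged ``below_nominal``.
    """
    vals = np.sort(np.asarray(values, dtype=float))
    n = len(vals)
    if n == 0:
        raise ValueError("median_ci requires at least one value")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    alpha2 = (1 - level) / 2
    ls = np.arange(1, n // 2 + 1)
    ok = ls[stats.binom.cdf(ls - 1, n, 0.5) <= alpha2] if len(ls) else np.array([])
    if len(ok) == 0:
        achieved = 1 - 2 * stats.binom.cdf(0, n, 0.5)
        return MedianCI(vals[0], vals[-1], float(achieved), True)
    l = int(ok.max())
    achieved = 1 - 2 * stats.binom.cdf(l - 1, n, 0.5)
    return MedianCI(vals[l - 1], vals[n - l], float(achieved), False)


def _per_culture_rates(
    exp: FluctuationExperiment,
) -> tuple[list[float], list[float], list[float]]:
    """(mu_i, f_i, N_i) over usable cultures (those with a nonselective count)."""
    mus, fs, ns = [], [], []
    skipped = 0
    for obs in exp.cultures:
        if obs.ns_colonies == 0:
            skipped += 1
            continue
        f, n_total = mutant_frequency(obs)
        fs.append(f)
        ns.append(n_total)
        # zero selective colonies = below detection; contributes rate 0
        # rather than being dropped (dropping would bias the median upward)
        mus.append(0.0 if f == 0 else solve_drake(f, n_total))
    if skipped:
        logger.warning(
            "experiment %s/%s: skipped %d cultures with ns_colonies=0",
            exp.strain,
            exp.tract_id,
            skipped,
        )
    if not mus:
        raise ValueError(
            f"experiment {exp.strain}/{exp.tract_id} has no culture with a "
            "usable nonselective count"
        )
    return mus, fs, ns


def estimate_rate(
    exp: FluctuationExperiment,
    variant: str = "per_culture_median",
    level: float = 0.95,
) -> RateEstimate:
    """Estimate the mutation rate of one experiment.

    ``per_culture_median`` (default): solve the Drake equation for each
    culture and take the median of the per-culture rates, with an
    order-statistic CI.  ``median_frequency``: the classical single solve at
    the median frequency and median population size (no CI; provided for
    sensitivity analysis).  If the median frequency is zero the estimate is
    delegated to :func:`upper_bound_rate`.
    """
    mus, fs, ns = _per_culture_rates(exp)
    if variant == "per_culture_median":
        point = float(np.median(mus))
        if point == 0:
            return upper_bound_rate(exp)
        ci = median_ci(mus, level=level)
        return RateEstimate(
            mu=point,
            ci_low=ci.low,
            ci_high=ci.high,
            achieved_ci_level=ci.achieved_level,
            n_cultures=len(mus),
            method="drake_per_culture_median",
        )
    if variant == "median_frequency":
        f_med = float(np.median(fs))
        n_med = float(np.median(ns))
        if f_med == 0:
            return upper_bound_rate(exp)
        return RateEstimate(
            mu=solve_drake(f_med, n_med),
            n_cultures=len(fs),
            method="drake_median_frequency",
        )
    raise ValueError(f"unknown estimator variant {variant!r}")


def upper_bound_rate(exp: FluctuationExperiment) -> RateEstimate:
    """Detection-limit upper bound when the median mutant frequency is zero.

    The limiting frequency is one colony among the cells actually plated on
    selective medium, f* = 1 / (median N * median plated fraction); the
    bound is the Drake solution at f*.
    """
    _, fs, ns = _per_culture_rates(exp)
    if float(np.median(fs)) > 0:
        raise ValueError(
            "upper_bound_rate applies only when the median mutant frequency is 0"
        )
    n_med = float(np.median(ns))
    sel_frac_med = float(
        np.median([c.sel_plating_fraction for c in exp.cultures if c.ns_colonies > 0])
    )
    f_star = 1.0 / (n_med * sel_frac_med)
    return RateEstimate(
        mu=solve_drake(f_star, n_med),
        n_cultures=len(fs),
        method="drake_detection_limit",
        is_upper_bound=True,
    )
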