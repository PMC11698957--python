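"""Exact and asymptotic statistics for single-arm trial endpoints.

Implements the statistical core of a single-stage phase II design with a
binary progression-free endpoint: the exact binomial design search, exact
binomial tests and Clopper-Pearson intervals for response tables, Fisher's
exact test, the Cochran-Armitage trend test over ordered risk groups, and
Kaplan-Meier machinery (curves, log-rank comparison, reverse-KM follow-up).

Exact binomial quantities use :mod:`scipy.stats`; survival quantities are
backed by :mod:`lifelines`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "DesignSpec",
    "DesignResult",
    "SurvivalSample",
    "DesignSearchError",
    "design_single_stage",
    "critical_value",
    "exact_binomial_test",
    "clopper_pearson_ci",
    "fisher_exact_test",
    "cochran_armitage_trend",
    "TrendResult",
    "KMResult",
    "km_curve",
    "LogrankResult",
    "logrank_test",
    "reverse_km_median",
]


class DesignSearchError(RuntimeError):
    """No feasible sample size below the search cap."""


@dataclass(frozen=True)
class DesignSpec:
    """Error specification for a single-stage exact binomial design.

    Parameters
    ----------
    p0 : null progression-free rate (reject if the true rate is above).
    p1 : alternative rate the design must detect.
    alpha : one-sided type-I error bound.
    beta : type-II error bound (power >= 1 - beta at ``p1``).
    """

    p0: float
    p1: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < self.p1 < 1.0:
            raise ValueError(f"need 0 < p0 < p1 < 1, got p0={self.p0}, p1={self.p1}")
        if not (0.0 < self.alpha <= 1.0 and 0.0 < self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in (0, 1]")


@dataclass(frozen=True)
class DesignResult:
    """Sample size ``n`` and critical value ``r`` (reject if successes >= r)."""

    n: int
    r: int
    attained_alpha: float
    attained_power: float


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data: times (months), event indicators, groups."""

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)
        if self.group is None:
            object.__setattr__(self, "group", np.zeros(time.shape, dtype=int))
        else:
            object.__setattr__(self, "group", np.asarray(self.group))
        if not (len(time) == len(event) == len(self.group)):
            raise ValueError("time, event and group must have equal lengths")
        if len(time) == 0:
            raise ValueError("empty survival sample")
        if not np.all(np.isfinite(time)) or np.any(time < 0):
            raise ValueError("times must be finite and non-negative")


def critical_value(n: int, p0: float, alpha: float) -> int:
    """Smallest ``r`` with exact upper tail P(X >= r | n, p0) <= alpha.

    Returns ``n + 1`` if even ``r = n`` exceeds alpha (never reject).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    r_grid = np.arange(0, n + 2)
    tails = stats.binom.sf(r_grid - 1, n, p0)  # P(X >= r); r = n+1 gives 0
    feasible = np.nonzero(tails <= alpha)[0]
    return int(r_grid[feasible[0]])


def design_single_stage(spec: DesignSpec, n_max: int = 1000) -> DesignResult:
    """Exact single-stage binomial design search.

    Finds the smallest sample size ``n`` admitting a critical value ``r``
    such that the exact one-sided type-I error P(X >= r | n, p0) is at most
    ``alpha`` while the power P(X >= r | n, p1) is at least ``1 - beta``.
    For each ``n`` the smallest feasible ``r`` is taken (it maximizes
    power among alpha-feasible thresholds). Exact binomial tails only.
    """
    for n in range(1, n_max + 1):
        r = critical_value(n, spec.p0, spec.alpha)
        if r > n + 1:  # pragma: no cover - unreachable, critical_value caps at n+1
            continue
        attained_alpha = float(stats.binom.sf(r - 1, n, spec.p0))
        attained_power = float(stats.binom.sf(r - 1, n, spec.p1))
        if attained_power >= 1.0 - spec.beta:
            return DesignResult(n=n, r=r, attained_alpha=attained_alpha,
                                attained_power=attained_power)
    raise DesignSearchError(f"no feasible design with n <= {n_max}")


def exact_binomial_test(
    x: int, n: int, p0: float,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
) -> float:
    """Exact binomial tail probability for ``x`` successes out of ``n``."""
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    return float(stats.binomtest(x, n, p0, alternative=alternative).pvalue)


def clopper_pearson_ci(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Two-sided exact (Clopper-Pearson) binomial confidence interval.

    The lower bound is 0 when ``x == 0`` and the upper bound 1 when
    ``x == n``; otherwise the bounds invert the binomial tails at
    ``(1 - conf) / 2`` on each side.
    """
    if not 0 <= x <= n:
        raise ValueError(f"x must be in [0, n], got x={x}, n={n}")
    ci = stats.binomtest(x, n).proportion_ci(confidence_level=conf, method="exact")
    return float(ci.low), float(ci.high)


def fisher_exact_test(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Two-sided p by the probability-mass rule: the sum of hypergeometric
    probabilities of every table with the observed margins whose
    probability does not exceed the observed table's. The odds ratio is
    the sample odds ratio ``ad / bc`` (``inf`` when ``bc == 0``).
    """
    table = np.array([[a, b], [c, d]])
    if np.any(table < 0):
        raise ValueError("cell counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    res = stats.fisher_exact(table, alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    return float(odds), float(res.pvalue)


@dataclass(frozen=True)
class TrendResult:
    z: float
    p_value: float
    degenerate: bool = False


def cochran_armitage_trend(
    successes: Sequence[int],
    totals: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> TrendResult:
    """Cochran-Armitage test for trend in proportions over ordered groups.

    Asymptotic score test with equally spaced default scores and no
    continuity correction; two-sided normal p-value. Degenerate tables
    (zero variance: all successes or all failures) return ``p = 1`` with
    the ``degenerate`` flag set.
    """
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    if s.shape != t.shape or s.ndim != 1 or len(s) < 2:
        raise ValueError("need >= 2 ordered groups with matching shapes")
    if np.any(s < 0) or np.any(t < s):
        raise ValueError("need 0 <= successes <= totals")
    x = np.arange(len(s), dtype=float) if scores is None else np.asarray(scores, float)
    n_tot = t.sum()
    p_bar = s.sum() / n_tot
    var = p_bar * (1.0 - p_bar) * ((t * x**2).sum() - (t * x).sum() ** 2 / n_tot)
    if var <= 0:
        return TrendResult(z=0.0, p_value=1.0, degenerate=True)
    z = float((x * (s - t * p_bar)).sum() / np.sqrt(var))
    return TrendResult(z=z, p_value=float(2.0 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class KMResult:
    """Product-limit estimate with a log-log confidence band.

    ``median`` is the earliest time with S(t) <= 0.5, or ``None`` when the
    curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: Optional[float]

    def at(self, t: float) -> float:
        """Survival probability at time ``t`` (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(sample: SurvivalSample, conf: float = 0.95) -> KMResult:
    """Kaplan-Meier product-limit estimate with exponential-Greenwood
    (log-log) confidence band and the median survival time."""
    kmf = KaplanMeierFitter(alpha=1.0 - conf)
    kmf.fit(sample.time, event_observed=sample.event)
    surv = kmf.survival_function_
    ci = kmf.confidence_interval_
    median = kmf.median_survival_time_
    return KMResult(
        times=surv.index.to_numpy(dtype=float),
        survival=surv.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        median=None if np.isinf(median) else float(median),
    )


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p_value: float
    degenerate: bool = False


def logrank_test(sample: SurvivalSample) -> LogrankResult:
    """Standard (unweighted) log-rank comparison of survival distributions.

    Requires at least two groups. A sample with no events at all is
    degenerate and reported as ``chi2 = 0, p = 1`` with a flag.
    """
    groups = pd.unique(pd.Series(sample.group))
    if len(groups) < 2:
        raise ValueError("log-rank test requires >= 2 groups")
    if sample.event.sum() == 0:
        return LogrankResult(chi2=0.0, p_value=1.0, degenerate=True)
    res = multivariate_logrank_test(sample.time, sample.group, sample.event)
    return LogrankResult(chi2=float(res.test_statistic), p_value=float(res.p_value))


def reverse_km_median(sample: SurvivalSample) -> Optional[float]:
    """Median follow-up by the reverse Kaplan-Meier method.

    The event/censoring indicators are swapped (censoring becomes the
    event of interest) and the KM median of the flipped sample returned.
    """
    flipped = SurvivalSample(time=sample.time, event=1 - sample.event,
                             group=sample.group)
    return km_curve(flipped).median
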