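"""Fixed-control-arm power and sample-size projection for burden tests.

The projected study compares a case-arm collective carrier frequency against
a fixed reference panel (e.g. a gnomAD ancestry) of size ``n0`` and
background frequency ``p0``.  The assumed effect is an odds ratio applied on
the odds scale, and power is the pooled-variance normal approximation to the
Pearson chi-squared two-proportion test.  Because the control arm is fixed,
power has a finite supremum as the case arm grows: panels whose asymptotic
power falls below the target can never reach significance, however many
cases are sequenced.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "PowerQuery",
    "PowerResult",
    "SolveStatus",
    "p1_from_or",
    "power_two_prop",
    "power_limit",
    "solve_n",
    "solve_panel",
]


class SolveStatus(str, enum.Enum):
    ATTAINABLE = "attainable"
    #: the asymptotic (infinite-case-arm) power never reaches the target
    UNATTAINABLE = "unattainable"
    #: the limit reaches the target but no case arm within n_max does
    CEILING = "ceiling"


@dataclass(frozen=True)
class PowerQuery:
    """One sample-size question against a fixed reference panel."""

    p0: float
    n0: int
    odds_ratio: float
    target_power: float
    alpha: float = 0.05
    n_max: int = 10**7
    population: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError(f"p0 must lie in (0, 1), got {self.p0}")
        if self.n0 < 1:
            raise ValueError("n0 must be a positive integer")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        if self.n_max < 1:
            raise ValueError("n_max must be a positive integer")


@dataclass(frozen=True)
class PowerResult:
    """Outcome of :func:`solve_n` for one query."""

    query: PowerQuery
    status: SolveStatus
    p1: float
    asymptotic_power: float
    n_required: int | None = None
    achieved_power: float | None = None

    @property
    def attainable(self) -> bool:
        return self.status is SolveStatus.ATTAINABLE


def p1_from_or(p0: float, odds_ratio: float) -> float:
    """Case-arm proportion implied by applying an odds ratio to ``p0``.

    Exact on the odds scale: odds1 = OR * odds0, so
    p1 = OR*p0 / (1 - p0 + OR*p0).  OR = 1 returns ``p0`` unchanged.
    """
    if not 0 < p0 < 1:
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    if odds_ratio <= 0:
        raise ValueError("odds_ratio must be positive")
    return odds_ratio * p0 / (1.0 - p0 + odds_ratio * p0)


def power_two_prop(n1, n0: int, p0: float, p1: float, alpha: float = 0.05):
    """Power of the two-sided pooled-variance two-proportion z (chi-squared) test.

    Accepts a scalar or array case-arm size ``n1``.  The rejection threshold
    uses the pooled variance under H0; the alternative uses the unpooled
    variance — the standard large-sample approximation to the Pearson
    chi-squared test for two independent proportions.
    """
    n1 = np.asarray(n1, dtype=float)
    if np.any(n1 < 1) or n0 < 1:
        raise ValueError("arm sizes must be at least 1")
    for name, p in (("p0", p0), ("p1", p1)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie in (0, 1), got {p}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    delta = p1 - p0
    p_bar = (n1 * p1 + n0 * p0) / (n1 + n0)
    q_bar = 1.0 - p_bar
    se0 = np.sqrt(p_bar * q_bar * (1.0 / n1 + 1.0 / n0))
    se1 = np.sqrt(p1 * (1.0 - p1) / n1 + p0 * (1.0 - p0) / n0)
    power = stats.norm.cdf((delta - z_alpha * se0) / se1)
    return float(power) if power.ndim == 0 else power


def power_limit(n0: int, p0: float, p1: float, alpha: float = 0.05) -> float:
    """Supremum of :func:`power_two_prop` as the case arm grows without bound.

    With n1 -> infinity the case-arm sampling noise vanishes and the pooled
    proportion tends to p1, leaving
    Phi( (p1 - p0 - z * sqrt(p1 q1 / n0)) / sqrt(p0 q0 / n0) ).
    """
    for name, p in (("p0", p0), ("p1", p1)):
        if not 0 < p < 1:
            raise ValueError(f"{name} must lie in (0, 1), got {p}")
    if n0 < 1:
        raise ValueError("n0 must be a positive integer")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    num = (p1 - p0) - z_alpha * math.sqrt(p1 * (1.0 - p1) / n0)
    den = math.sqrt(p0 * (1.0 - p0) / n0)
    return float(stats.norm.cdf(num / den))


def solve_n(query: PowerQuery) -> PowerResult:
    """Smallest integer case-arm size meeting the target power, if any.

    Exponential bracketing from n1 = 1 followed by integer bisection on the
    first target crossing, which lies in the increasing region of the power
    curve, so minimality (power(n*-1) < target <= power(n*)) holds.  Queries
    that never reach the target within ``n_max`` are flagged UNATTAINABLE
    when the asymptotic limit is below target, CEILING when only the search
    ceiling was too small.
    """
    if query.odds_ratio <= 1:
        raise ValueError("solve_n requires odds_ratio > 1 (an enrichment to detect)")
    p1 = p1_from_or(query.p0, query.odds_ratio)
    limit = power_limit(query.n0, query.p0, p1, query.alpha)
    base = PowerResult(
        query=query, status=SolveStatus.UNATTAINABLE, p1=p1, asymptotic_power=limit
    )

    def power_at(n1: int) -> float:
        return power_two_prop(n1, query.n0, query.p0, p1, query.alpha)

    # Exponential bracketing from n1 = 1.  The search runs even when the
    # asymptotic limit is below target: for sparse panels power peaks at a
    # finite n1 and then declines toward the limit from above, so a finite
    # overshoot above target must not be missed.
    lo, hi = 0, 1
    found = False
    while hi <= query.n_max:
        if power_at(hi) >= query.target_power:
            found = True
            break
        lo, hi = hi, hi * 2
    if not found and power_at(query.n_max) >= query.target_power:
        lo, hi, found = min(lo, query.n_max - 1), query.n_max, True
    if not found:
        # guard against a target-crossing bump between doubling points
        grid = np.unique(np.geomspace(1, query.n_max, 512).astype(np.int64))
        above = np.nonzero(
            power_two_prop(grid, query.n0, query.p0, p1, query.alpha)
            >= query.target_power
        )[0]
        if above.size:
            first = int(above[0])
            lo = 0 if first == 0 else int(grid[first - 1])
            hi, found = int(grid[first]), True
    if not found:
        status = SolveStatus.CEILING if limit >= query.target_power else SolveStatus.UNATTAINABLE
        return replace(base, status=status)
    # first crossing lies in the increasing region, so bisection is valid
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= query.target_power:
            hi = mid
        else:
            lo = mid
    return replace(
        base, status=SolveStatus.ATTAINABLE, n_required=hi, achieved_power=power_at(hi)
    )


@dataclass(frozen=True)
class PanelRow:
    """Solved sample sizes for one reference panel at several power targets."""

    population: str
    n0: int
    p0: float
    results: tuple[PowerResult, ...] = field(default_factory=tuple)


def solve_panel(
    panels: list[tuple[str, int, float]],
    odds_ratio: float = 3.0,
    alpha: float = 0.05,
    power_targets: tuple[float, ...] = (0.80, 0.90),
    n_max: int = 10**7,
) -> list[PanelRow]:
    """Solve every (population, n0, p0) panel at each power target, in order."""
    rows = []
    for population, n0, p0 in panels:
        results = tuple(
            solve_n(
                PowerQuery(
                    p0=p0,
                    n0=n0,
                    odds_ratio=odds_ratio,
                    target_power=target,
                    alpha=alpha,
                    n_max=n_max,
                    population=population,
                )
            )
            for target in power_targets
        )
        rows.append(PanelRow(population=population, n0=n0, p0=p0, results=results))
    return rows
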