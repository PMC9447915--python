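"""Case-control enrichment statistics for collective rare-variant burdens.

Carriers are totalled per cohort into a single 2x2 table (carrier /
non-carrier by case / control); enrichment is summarised by the sample odds
ratio with a Woolf (log-scale) confidence interval, and a p-value from the
Pearson chi-squared test — switched to the two-sided Fisher exact test when
either carrier cell is small, mirroring the convention of reporting Fisher
for cohorts with carrier counts below five.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy import stats

from .catalog import CohortCounts, Convention, collective_frequency

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "AssociationConfig",
    "TestKind",
    "ZeroCellPolicy",
    "build_table",
    "odds_ratio",
    "woolf_ci",
    "pearson_chi2",
    "fisher_exact",
    "gart_log_odds_ratio",
    "select_test",
    "associate",
]


class TestKind(str, enum.Enum):
    PEARSON_CHI2 = "pearson_chi2"
    FISHER_EXACT = "fisher_exact"


class ZeroCellPolicy(str, enum.Enum):
    HALDANE = "haldane"
    ERROR = "error"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: a/b case carriers/non-carriers, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell, value in zip("abcd", (self.a, self.b, self.c, self.d)):
            if value < 0:
                raise ValueError(f"cell {cell} must be non-negative, got {value}")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("both margins (cases and controls) must be non-empty")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls

    def has_zero_cell(self) -> bool:
        return 0 in (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    ci_level: float
    p_value: float
    test_used: TestKind
    case_frequency: float
    control_frequency: float
    correction_applied: bool
    table: ContingencyTable


@dataclass(frozen=True)
class AssociationConfig:
    """Options for :func:`associate`.

    ``small_count_threshold`` routes a table to the Fisher exact test when
    either carrier cell is strictly below it (default 5).
    """

    ci_level: float = 0.95
    small_count_threshold: int = 5
    continuity: bool = False
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.HALDANE


def build_table(cases: CohortCounts, controls: CohortCounts) -> ContingencyTable:
    """Derive the 2x2 carrier table from case and control cohort counts."""
    for arm in (cases, controls):
        if arm.convention is not Convention.CARRIER_PROPORTION:
            raise ValueError(
                f"cohort {arm.cohort_name!r} uses {arm.convention.value}; convert with "
                "convert_convention to carrier_proportion before building a 2x2 table"
            )
    return ContingencyTable(
        a=cases.n_carriers,
        b=cases.n_individuals - cases.n_carriers,
        c=controls.n_carriers,
        d=controls.n_individuals - controls.n_carriers,
    )


def _effective_cells(
    table: ContingencyTable, policy: ZeroCellPolicy
) -> tuple[float, float, float, float, bool]:
    if table.has_zero_cell():
        if ZeroCellPolicy(policy) is ZeroCellPolicy.ERROR:
            raise ValueError(
                f"table {table} has an empty cell; use the haldane policy to add 0.5 to all cells"
            )
        return table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5, True
    return float(table.a), float(table.b), float(table.c), float(table.d), False


def odds_ratio(
    table: ContingencyTable, zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.HALDANE
) -> float:
    """Sample odds ratio (a*d)/(b*c), Haldane-Anscombe corrected on zero cells."""
    a, b, c, d, _ = _effective_cells(table, zero_cell_policy)
    return (a * d) / (b * c)


def woolf_ci(
    table: ContingencyTable,
    level: float = 0.95,
    zero_cell_policy: ZeroCellPolicy = ZeroCellPolicy.HALDANE,
) -> tuple[float, float]:
    """Woolf confidence interval for the odds ratio.

    Built on the log scale with standard error sqrt(1/a + 1/b + 1/c + 1/d)
    and the exact normal quantile for the requested level.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    a, b, c, d, _ = _effective_cells(table, zero_cell_policy)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def pearson_chi2(table: ContingencyTable, continuity: bool = False) -> tuple[float, float]:
    """Pearson chi-squared statistic and p-value (1 df) for a 2x2 table.

    Without continuity correction the statistic equals the square of the
    pooled-variance two-proportion z statistic.  A degenerate carrier margin
    (no carriers, or everyone a carrier) returns (0, 1).
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(diff - n / 2, 0.0)
    statistic = n * diff * diff / margins
    return statistic, float(stats.chi2.sf(statistic, df=1))


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (probability-mass definition).

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    """
    p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    ).pvalue
    return min(float(p), 1.0)


def gart_log_odds_ratio(table: ContingencyTable) -> float:
    """Gart-corrected log odds ratio: log((a+.5)(d+.5) / ((b+.5)(c+.5))).

    Adding one half to every cell removes the leading O(1/count) small-sample
    bias of the sample log odds ratio; use this estimator when assessing
    log-scale unbiasedness (e.g. simulation recovery studies).
    """
    return math.log(
        ((table.a + 0.5) * (table.d + 0.5)) / ((table.b + 0.5) * (table.c + 0.5))
    )


def select_test(table: ContingencyTable, threshold: int = 5) -> TestKind:
    """Fisher exact when either carrier cell is below ``threshold``, else chi-squared."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if min(table.a, table.c) < threshold:
        return TestKind.FISHER_EXACT
    return TestKind.PEARSON_CHI2


def associate(
    cases: CohortCounts,
    controls: CohortCounts,
    config: AssociationConfig | None = None,
) -> AssociationResult:
    """Full collective-burden association for one case/control cohort pair."""
    config = config or AssociationConfig()
    table = build_table(cases, controls)
    test = select_test(table, config.small_count_threshold)
    if test is TestKind.FISHER_EXACT:
        p_value = fisher_exact(table)
    else:
        _, p_value = pearson_chi2(table, continuity=config.continuity)
    _, _, _, _, corrected = _effective_cells(table, config.zero_cell_policy)
    low, high = woolf_ci(table, config.ci_level, config.zero_cell_policy)
    return AssociationResult(
        odds_ratio=odds_ratio(table, config.zero_cell_policy),
        ci_low=low,
        ci_high=high,
        ci_level=config.ci_level,
        p_value=p_value,
        test_used=test,
        case_frequency=collective_frequency(cases),
        control_frequency=collective_frequency(controls),
        correction_applied=corrected,
        table=table,
    )
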