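"""Synthetic cohorts with the statistical structure the burden analysis assumes.

The generator draws, for every individual, at most one catalogued variant
(mutual exclusivity by construction) from a categorical distribution over
``{none} + variants``.  Case arms inflate the *collective* carrier odds by a
configured odds ratio while preserving the relative per-variant proportions,
matching an enrichment model that acts on the burden as a whole.  All
carriers are heterozygous, so simulated carrier sites have expected variant
allele fraction one half; non-carrier sites carry binomial read noise at a
configured per-base error rate.

Monte-Carlo oracles built on the generator — :func:`empirical_power` and
:func:`ci_coverage` — validate the analytic power formula and the Woolf
interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationConfig, AssociationResult, associate
from .catalog import CohortCounts, Convention, noise_filter_frame

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_reads",
    "run_end_to_end",
    "empirical_power",
    "ci_coverage",
    "EmpiricalPower",
]

#: mean per-base quality used when synthesising quality sums
_MEAN_QUAL = 30.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``variant_frequencies`` are per-variant background *carrier*
    probabilities; their sum is the collective control-arm carrier frequency
    and must leave room for the non-carrier outcome.  ``collective_or``
    multiplies the collective carrier odds in the case arm.  Read simulation
    uses ``read_depth`` (mean amplicon depth) and ``error_rate`` (post-filter
    per-base error).
    """

    variant_frequencies: tuple[float, ...]
    n_cases: int
    n_controls: int
    collective_or: float = 1.0
    seed: int = 0
    read_depth: int = 1000
    error_rate: float = 1e-4

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.variant_frequencies)
        object.__setattr__(self, "variant_frequencies", freqs)
        if not freqs:
            raise ValueError("variant_frequencies must be non-empty")
        if any(not 0 <= f < 1 for f in freqs):
            raise ValueError("each variant frequency must lie in [0, 1)")
        if sum(freqs) >= 1:
            raise ValueError("variant frequencies must sum to below 1")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("arm sizes must be positive")
        if self.collective_or <= 0:
            raise ValueError("collective_or must be positive")
        if self.read_depth < 1:
            raise ValueError("read_depth must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")

    @property
    def control_collective_frequency(self) -> float:
        return math.fsum(self.variant_frequencies)

    @property
    def case_collective_frequency(self) -> float:
        """Collective case-arm carrier frequency: odds scaled by collective_or."""
        f0 = self.control_collective_frequency
        odds = self.collective_or * f0 / (1.0 - f0)
        return odds / (1.0 + odds)

    def case_variant_frequencies(self) -> tuple[float, ...]:
        """Per-variant case frequencies: collective inflation, proportions kept."""
        f0 = self.control_collective_frequency
        if f0 == 0:
            return self.variant_frequencies
        scale = self.case_collective_frequency / f0
        return tuple(f * scale for f in self.variant_frequencies)


@dataclass(frozen=True)
class SyntheticCohort:
    """Per-individual carrier assignments for a simulated case/control study.

    ``case_variant`` / ``control_variant`` hold, per individual, the index of
    the carried variant or -1 for non-carriers; at most one variant per
    individual by construction.
    """

    config: SimulationConfig
    case_variant: np.ndarray
    control_variant: np.ndarray
    variant_ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.variant_ids:
            ids = tuple(f"v{i + 1}" for i in range(len(self.config.variant_frequencies)))
            object.__setattr__(self, "variant_ids", ids)

    def counts(self, arm: str) -> CohortCounts:
        assignments = self.case_variant if arm == "case" else self.control_variant
        return CohortCounts(
            cohort_name=f"synthetic {arm}s",
            n_individuals=len(assignments),
            n_carriers=int((assignments >= 0).sum()),
            convention=Convention.CARRIER_PROPORTION,
        )

    def per_variant_counts(self, arm: str) -> dict[str, int]:
        assignments = self.case_variant if arm == "case" else self.control_variant
        counts = np.bincount(assignments[assignments >= 0], minlength=len(self.variant_ids))
        return dict(zip(self.variant_ids, counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        """Per-individual long table (arm, individual, carried variant or none)."""
        frames = []
        for arm, assignments in (("case", self.case_variant), ("control", self.control_variant)):
            carried = np.where(
                assignments >= 0,
                np.asarray(self.variant_ids, dtype=object)[np.maximum(assignments, 0)],
                "none",
            )
            frames.append(
                pd.DataFrame(
                    {
                        "arm": arm,
                        "individual": [f"{arm}_{i + 1}" for i in range(len(assignments))],
                        "variant_id": carried,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _draw_assignments(rng: np.random.Generator, n: int, freqs: tuple[float, ...]) -> np.ndarray:
    """Categorical draw over {variants..., none}; returns index or -1."""
    edges = np.cumsum(np.asarray(freqs, dtype=float))
    u = rng.random(n)
    idx = np.searchsorted(edges, u, side="right")
    return np.where(idx < len(freqs), idx, -1).astype(np.int64)


def _arm_rngs(seed: int) -> tuple[np.random.Generator, ...]:
    streams = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(s) for s in streams)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a fully reproducible synthetic case/control cohort."""
    control_rng, case_rng, _ = _arm_rngs(config.seed)
    control = _draw_assignments(control_rng, config.n_controls, config.variant_frequencies)
    case = _draw_assignments(case_rng, config.n_cases, config.case_variant_frequencies())
    return SyntheticCohort(config=config, case_variant=case, control_variant=control)


def simulate_reads(cohort: SyntheticCohort, config: SimulationConfig | None = None) -> pd.DataFrame:
    """Synthesise one amplicon read-count record per individual.

    Carriers draw alternate reads from Binomial(depth, 0.5) at their variant
    site (heterozygous); non-carriers draw Binomial(depth, error_rate) noise.
    Quality sums are proportional to read counts at mean per-base quality, so
    the quality-ratio guard of the noise filter is neutral for clean data.
    The returned frame matches the read-count TSV layout plus ``arm`` and
    ``individual`` columns.
    """
    config = config or cohort.config
    _, _, read_rng = _arm_rngs(config.seed)
    frames = []
    for arm, assignments in (("case", cohort.case_variant), ("control", cohort.control_variant)):
        n = len(assignments)
        carrier = assignments >= 0
        prob = np.where(carrier, 0.5, config.error_rate)
        alt = read_rng.binomial(config.read_depth, prob)
        site = np.where(
            carrier,
            np.asarray(cohort.variant_ids, dtype=object)[np.maximum(assignments, 0)],
            "panel_background",
        )
        frames.append(
            pd.DataFrame(
                {
                    "site_id": site,
                    "depth": config.read_depth,
                    "alt_count": alt,
                    "alt_qual_sum": alt * _MEAN_QUAL,
                    "total_qual_sum": config.read_depth * _MEAN_QUAL,
                    "error_rate": max(config.error_rate, 1e-12),
                    "arm": arm,
                    "individual": [f"{arm}_{i + 1}" for i in range(n)],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def run_end_to_end(
    config: SimulationConfig,
    alpha: float = 0.05,
    assoc_config: AssociationConfig | None = None,
) -> AssociationResult:
    """Simulate, noise-filter, aggregate and associate one synthetic study.

    Individuals whose read record survives the noise filter are counted as
    collective carriers (called positives, whether true carriers or residual
    noise), per arm; the filtered counts feed the association statistics.
    """
    cohort = simulate_cohort(config)
    reads = noise_filter_frame(simulate_reads(cohort), alpha=alpha)
    counts = {}
    for arm, n in (("case", config.n_cases), ("control", config.n_controls)):
        called = int(reads.loc[reads["arm"] == arm, "accepted"].sum())
        counts[arm] = CohortCounts(
            cohort_name=f"synthetic {arm}s (filtered)",
            n_individuals=n,
            n_carriers=called,
            convention=Convention.CARRIER_PROPORTION,
        )
    return associate(counts["case"], counts["control"], assoc_config)


@dataclass(frozen=True)
class EmpiricalPower:
    power: float
    stderr: float
    replicates: int


def _collective_counts_rng(
    config: SimulationConfig, rng: np.random.Generator, replicates: int
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate collective carrier counts per arm.

    Collapsing mutually exclusive carriers to carrier/non-carrier makes the
    collective count exactly Binomial(n, collective frequency), so counts are
    drawn directly at that level for Monte-Carlo speed; ``simulate_cohort``
    keeps the per-individual construction and a test pins their agreement.
    """
    a = rng.binomial(config.n_cases, config.case_collective_frequency, size=replicates)
    c = rng.binomial(config.n_controls, config.control_collective_frequency, size=replicates)
    return a, c


def empirical_power(
    config: SimulationConfig,
    alpha: float = 0.05,
    replicates: int = 10_000,
    seed: int | None = None,
    assoc_config: AssociationConfig | None = None,
) -> EmpiricalPower:
    """Monte-Carlo power of the collective burden test under ``config``.

    Fraction of replicates whose :func:`~burdenscope.association.associate`
    p-value falls below ``alpha``, with its binomial standard error.
    """
    if replicates < 100:
        raise ValueError("use at least 100 replicates")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    a_draws, c_draws = _collective_counts_rng(config, rng, replicates)
    hits = 0
    for a, c in zip(a_draws, c_draws):
        result = associate(
            CohortCounts("sim cases", config.n_cases, int(a)),
            CohortCounts("sim controls", config.n_controls, int(c)),
            assoc_config,
        )
        if result.p_value < alpha:
            hits += 1
    power = hits / replicates
    return EmpiricalPower(
        power=power,
        stderr=math.sqrt(power * (1.0 - power) / replicates),
        replicates=replicates,
    )


def ci_coverage(
    config: SimulationConfig,
    level: float = 0.95,
    replicates: int = 2_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo coverage of the Woolf interval at the true collective OR."""
    from .association import ContingencyTable, woolf_ci

    if replicates < 100:
        raise ValueError("use at least 100 replicates")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    a_draws, c_draws = _collective_counts_rng(config, rng, replicates)
    true_or = config.collective_or
    covered = 0
    for a, c in zip(a_draws, c_draws):
        table = ContingencyTable(
            a=int(a), b=config.n_cases - int(a), c=int(c), d=config.n_controls - int(c)
        )
        low, high = woolf_ci(table, level)
        if low <= true_or <= high:
            covered += 1
    return covered / replicates
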