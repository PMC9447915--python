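"""Rare-variant catalog: loading, validation, rarity filtering and aggregation.

The catalog holds one record per rare-variant genotype, with per-population
allele-count evidence in the gnomAD "observed AF" convention (detected minor
alleles over reliably sequenced alleles).  Aggregation assumes carriers of
distinct catalogued genotypes are mutually exclusive, so collective
frequencies are plain sums; all carriers are modelled as heterozygous.
Coordinates are 1-based on hg19/GRCh37.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Category",
    "Convention",
    "FrequencyEvidence",
    "VariantRecord",
    "VariantCatalog",
    "CohortCounts",
    "ReadCountRecord",
    "FilterDecision",
    "DiversityResult",
    "load_catalog",
    "load_cohorts",
    "load_read_counts",
    "filter_rare",
    "collective_frequency",
    "sum_collective_maf",
    "convert_convention",
    "diversity_fraction",
    "noise_filter",
    "noise_filter_frame",
]

_PROTEIN_CHANGE_RE = re.compile(r"^p\.[A-Z][a-z]{2}\d+([A-Z][a-z]{2}|Ter)$")

CATALOG_BASE_COLUMNS = ["variant_id", "gene", "chrom", "pos", "protein_change", "category"]
COHORT_COLUMNS = ["cohort", "n_individuals", "n_carriers", "convention"]
READ_COUNT_COLUMNS = [
    "site_id", "depth", "alt_count", "alt_qual_sum", "total_qual_sum", "error_rate",
]


class Category(str, enum.Enum):
    """Functional class of a catalogued genotype; collective burden uses type1."""

    TYPE1 = "type1"
    TYPE2 = "type2"
    TYPE3 = "type3"
    OTHER = "other"


class Convention(str, enum.Enum):
    """Whether a cohort count is per individual (carrier) or per allele."""

    CARRIER_PROPORTION = "carrier_proportion"
    ALLELE_FREQUENCY = "allele_frequency"


@dataclass(frozen=True)
class FrequencyEvidence:
    """Allele-count evidence for one variant in one population.

    ``maf`` is the observed allele frequency: detected minor-allele count over
    the number of reliably sequenced alleles.
    """

    allele_count: int
    allele_number: int
    carrier_count: int | None = None

    def __post_init__(self) -> None:
        if self.allele_number <= 0:
            raise ValueError("allele_number must be positive")
        if not 0 <= self.allele_count <= self.allele_number:
            raise ValueError(
                f"allele_count {self.allele_count} outside [0, allele_number={self.allele_number}]"
            )
        if self.carrier_count is not None and not 0 <= self.carrier_count <= self.allele_count:
            raise ValueError("carrier_count must lie in [0, allele_count]")

    @property
    def maf(self) -> float:
        return self.allele_count / self.allele_number


@dataclass(frozen=True)
class VariantRecord:
    """One rare-variant genotype with per-population frequency evidence."""

    variant_id: str
    gene: str
    chrom: str
    pos: int
    protein_change: str
    category: Category
    per_population: Mapping[str, FrequencyEvidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"position must be a positive integer, got {self.pos}")
        if not _PROTEIN_CHANGE_RE.match(self.protein_change):
            raise ValueError(
                f"protein_change {self.protein_change!r} does not match 'p.<Aaa><int><Aaa|Ter>'"
            )

    def maf(self, population: str) -> float:
        return self.per_population[population].maf


class VariantCatalog(Sequence):
    """Ordered, duplicate-free sequence of :class:`VariantRecord`."""

    def __init__(self, records: Sequence[VariantRecord]):
        seen: set[str] = set()
        for rec in records:
            if rec.variant_id in seen:
                raise ValueError(f"duplicate variant_id {rec.variant_id!r}")
            seen.add(rec.variant_id)
        self._records = list(records)

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return VariantCatalog(self._records[idx])
        return self._records[idx]

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self._records)

    @property
    def populations(self) -> list[str]:
        labels: dict[str, None] = {}
        for rec in self._records:
            for pop in rec.per_population:
                labels.setdefault(pop)
        return list(labels)

    def __repr__(self) -> str:
        return f"VariantCatalog({len(self)} records, populations={self.populations})"


@dataclass(frozen=True)
class CohortCounts:
    """A cohort's size and collective carrier (or allele) count."""

    cohort_name: str
    n_individuals: int
    n_carriers: int
    convention: Convention = Convention.CARRIER_PROPORTION

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_carriers < 0:
            raise ValueError("n_carriers must be non-negative")
        cap = (
            self.n_individuals
            if self.convention is Convention.CARRIER_PROPORTION
            else 2 * self.n_individuals
        )
        if self.n_carriers > cap:
            raise ValueError(
                f"n_carriers {self.n_carriers} exceeds maximum {cap} for {self.convention.value}"
            )


@dataclass(frozen=True)
class ReadCountRecord:
    """Per-site amplicon read evidence used by the sequencing-noise filter."""

    site_id: str
    depth: int
    alt_count: int
    alt_qual_sum: float
    total_qual_sum: float
    error_rate: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("alt_count must lie in [0, depth]")
        if self.total_qual_sum <= 0:
            raise ValueError("total_qual_sum must be positive")
        if not 0 <= self.alt_qual_sum <= self.total_qual_sum:
            raise ValueError("alt_qual_sum must lie in [0, total_qual_sum]")
        if not 0 < self.error_rate < 1:
            raise ValueError(f"error_rate must lie in (0, 1), got {self.error_rate}")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


class FilterDecision(NamedTuple):
    accepted: bool
    reason: str
    p_value: float | None


class DiversityResult(NamedTuple):
    """Genotype diversity of a catalog within one population."""

    observed: int
    total: int
    fraction: float

    @property
    def percent(self) -> int:
        """Percentage rounded to the nearest integer (0.5 rounds up)."""
        return int(math.floor(100.0 * self.fraction + 0.5))


class SchemaError(ValueError):
    """A tabular input is missing required columns or malformed."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def load_catalog(path: str | Path) -> VariantCatalog:
    """Read a variant-catalog TSV into a validated :class:`VariantCatalog`.

    Layout: columns ``variant_id, gene, chrom, pos, protein_change, category``
    followed by per-population evidence columns named ``POP.allele_count`` and
    ``POP.allele_number`` (optionally ``POP.carrier_count``).  Row order is
    preserved; a duplicate ``variant_id`` or a count violating its invariants
    is an error naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, CATALOG_BASE_COLUMNS, path)

    pops: dict[str, None] = {}
    for col in df.columns:
        if col.endswith(".allele_count"):
            pops.setdefault(col[: -len(".allele_count")])
    for pop in pops:
        if f"{pop}.allele_number" not in df.columns:
            raise SchemaError(f"{path}: population {pop!r} has allele_count but no allele_number")

    def _int(value, row: int, col: str) -> int:
        try:
            return int(value)
        except (TypeError, ValueError):
            raise SchemaError(f"{path}: row {row}: non-integer value {value!r} in column {col!r}")

    records = []
    for idx in range(len(df)):
        # dotted population columns rule out itertuples; index positionally
        values = dict(zip(df.columns, df.iloc[idx], strict=True))
        i = idx + 1  # 1-based row number in error messages
        evidence = {}
        for pop in pops:
            ac = values.get(f"{pop}.allele_count")
            if ac is None or (isinstance(ac, float) and math.isnan(ac)) or ac == "":
                continue  # population not assayed for this variant
            carrier_raw = values.get(f"{pop}.carrier_count")
            has_carrier = carrier_raw not in (None, "") and not (
                isinstance(carrier_raw, float) and math.isnan(carrier_raw)
            )
            try:
                evidence[pop] = FrequencyEvidence(
                    allele_count=_int(ac, i, f"{pop}.allele_count"),
                    allele_number=_int(values[f"{pop}.allele_number"], i, f"{pop}.allele_number"),
                    carrier_count=_int(carrier_raw, i, f"{pop}.carrier_count")
                    if has_carrier
                    else None,
                )
            except ValueError as exc:
                if isinstance(exc, SchemaError):
                    raise
                raise SchemaError(f"{path}: row {i}: {exc}") from exc
        try:
            records.append(
                VariantRecord(
                    variant_id=str(values["variant_id"]),
                    gene=str(values["gene"]),
                    chrom=str(values["chrom"]),
                    pos=_int(values["pos"], i, "pos"),
                    protein_change=str(values["protein_change"]),
                    category=Category(str(values["category"])),
                    per_population=evidence,
                )
            )
        except ValueError as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{path}: row {i}: {exc}") from exc
    return VariantCatalog(records)


def load_cohorts(path: str | Path) -> list[CohortCounts]:
    """Read a cohort-counts TSV (``cohort, n_individuals, n_carriers, convention``)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, COHORT_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CohortCounts(
                    cohort_name=str(row["cohort"]),
                    n_individuals=int(row["n_individuals"]),
                    n_carriers=int(row["n_carriers"]),
                    convention=Convention(str(row["convention"])),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 1}: {exc}") from exc
    return out


def load_read_counts(path: str | Path) -> list[ReadCountRecord]:
    """Read a per-site read-count TSV into :class:`ReadCountRecord` objects."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, READ_COUNT_COLUMNS, path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ReadCountRecord(
                    site_id=str(row["site_id"]),
                    depth=int(row["depth"]),
                    alt_count=int(row["alt_count"]),
                    alt_qual_sum=float(row["alt_qual_sum"]),
                    total_qual_sum=float(row["total_qual_sum"]),
                    error_rate=float(row["error_rate"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 1}: {exc}") from exc
    return out


def _check_population(catalog: VariantCatalog, population: str) -> None:
    available = catalog.populations
    if population not in available:
        raise KeyError(
            f"unknown population {population!r}; available: {', '.join(available) or '(none)'}"
        )


def filter_rare(
    catalog: VariantCatalog, threshold: float = 0.01, population: str = "nfe"
) -> VariantCatalog:
    """Keep records with MAF <= ``threshold`` in the given background population.

    Records with no evidence for that population are retained with a warning
    (reference-panel coverage differs by population), never silently dropped.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    _check_population(catalog, population)
    kept = []
    for rec in catalog:
        ev = rec.per_population.get(population)
        if ev is None:
            warnings.warn(
                f"variant {rec.variant_id}: no evidence for population {population!r}; retained",
                stacklevel=2,
            )
            kept.append(rec)
        elif ev.maf <= threshold:
            kept.append(rec)
    return VariantCatalog(kept)


def collective_frequency(counts: CohortCounts) -> float:
    """Collective carrier (or allele) frequency of a cohort.

    Carriers of distinct catalogued genotypes are assumed mutually exclusive,
    so the collective count is the plain total.
    """
    if counts.convention is Convention.CARRIER_PROPORTION:
        return counts.n_carriers / counts.n_individuals
    return counts.n_carriers / (2 * counts.n_individuals)


def sum_collective_maf(catalog: VariantCatalog, population: str) -> float:
    """Collective MAF: sum of per-genotype MAFs (mutual exclusivity assumed)."""
    if len(catalog) == 0:
        return 0.0
    _check_population(catalog, population)
    terms = []
    for rec in catalog:
        if population not in rec.per_population:
            raise KeyError(
                f"variant {rec.variant_id} lacks evidence for population {population!r}"
            )
        terms.append(rec.maf(population))
    return math.fsum(terms)


def convert_convention(freq: float, from_convention: Convention, to_convention: Convention) -> float:
    """Convert between allele frequency and carrier proportion.

    Uses Hardy-Weinberg with heterozygous-only carriers: allele frequency p
    maps to carrier proportion 2p(1-p), whose exact inverse is
    (1 - sqrt(1 - 2c))/2 (valid for c <= 0.5, the range of the forward map).
    Round-trips are exact to ~1e-12; for rare variants the carrier
    proportion is approximately 2p.
    """
    from_convention = Convention(from_convention)
    to_convention = Convention(to_convention)
    if from_convention is to_convention:
        if not 0 <= freq <= 1:
            raise ValueError(f"frequency {freq} outside [0, 1]")
        return freq
    if from_convention is Convention.ALLELE_FREQUENCY:
        if not 0 <= freq <= 0.5:
            raise ValueError(f"allele frequency {freq} outside [0, 0.5]")
        return 2.0 * freq * (1.0 - freq)
    if not 0 <= freq <= 0.5:
        raise ValueError(
            f"carrier proportion {freq} outside [0, 0.5] (heterozygote-only carriers)"
        )
    return (1.0 - math.sqrt(1.0 - 2.0 * freq)) / 2.0


def diversity_fraction(catalog: VariantCatalog, population: str) -> DiversityResult:
    """Fraction of catalogued genotypes observed (allele_count > 0) in a population."""
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    _check_population(catalog, population)
    observed = sum(
        1
        for rec in catalog
        if population in rec.per_population and rec.per_population[population].allele_count > 0
    )
    total = len(catalog)
    return DiversityResult(observed=observed, total=total, fraction=observed / total)


# --- amplicon sequencing-noise filter ---------------------------------------

#: candidate thresholds: a call needs more than this many alt reads ...
MIN_ALT_COUNT = 5
#: ... and a variant allele fraction above this to be considered at all
MIN_VAF = 0.005
#: calls above this VAF are accepted regardless of the noise model
HIGH_VAF = 0.02


def noise_filter(
    record: ReadCountRecord,
    alpha: float = 0.05,
    qual_ratio_bounds: tuple[float, float] = (0.5, 2.0),
) -> FilterDecision:
    """Classify one amplicon site call as real signal or sequencing noise.

    Decision sequence:

    1. candidate thresholds — reject unless alt_count > 5 and VAF > 0.5%;
    2. high-VAF override — accept calls with VAF > 2% without a noise test;
    3. binomial noise test — one-sided tail p = P(X >= alt_count) under
       X ~ Binomial(depth, error_rate), accept iff p < ``alpha``;
    4. quality-ratio guard — (alt_count/depth) / (alt_qual_sum/total_qual_sum)
       must fall inside ``qual_ratio_bounds`` for any acceptance to stand.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    low, high = qual_ratio_bounds
    if not 0 < low < high:
        raise ValueError("qual_ratio_bounds must satisfy 0 < low < high")

    if record.alt_count <= MIN_ALT_COUNT or record.vaf <= MIN_VAF:
        return FilterDecision(False, "candidate-threshold", None)

    p_value: float | None = None
    if record.vaf > HIGH_VAF:
        reason = "high-vaf"
    else:
        p_value = float(stats.binom.sf(record.alt_count - 1, record.depth, record.error_rate))
        if p_value >= alpha:
            return FilterDecision(False, "binomial-noise", p_value)
        reason = "binomial"

    qual_fraction = record.alt_qual_sum / record.total_qual_sum
    if qual_fraction <= 0:
        return FilterDecision(False, "quality-ratio", p_value)
    ratio = record.vaf / qual_fraction
    if not low <= ratio <= high:
        return FilterDecision(False, "quality-ratio", p_value)
    return FilterDecision(True, reason, p_value)


def noise_filter_frame(
    reads: pd.DataFrame,
    alpha: float = 0.05,
    qual_ratio_bounds: tuple[float, float] = (0.5, 2.0),
) -> pd.DataFrame:
    """Vectorised :func:`noise_filter` over a read-count table.

    ``reads`` must carry the read-count TSV columns; returns a copy with
    ``accepted``, ``reason`` and ``p_value`` columns appended.  Semantics are
    identical to the scalar filter (a test asserts this record-by-record).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    low, high = qual_ratio_bounds
    if not 0 < low < high:
        raise ValueError("qual_ratio_bounds must satisfy 0 < low < high")

    depth = reads["depth"].to_numpy(dtype=np.int64)
    alt = reads["alt_count"].to_numpy(dtype=np.int64)
    err = reads["error_rate"].to_numpy(dtype=float)
    if np.any((err <= 0) | (err >= 1)):
        raise ValueError("error_rate must lie in (0, 1)")
    vaf = alt / depth

    candidate = (alt > MIN_ALT_COUNT) & (vaf > MIN_VAF)
    high_vaf = candidate & (vaf > HIGH_VAF)
    testable = candidate & ~high_vaf

    p_value = np.full(len(reads), np.nan)
    if testable.any():
        p_value[testable] = stats.binom.sf(alt[testable] - 1, depth[testable], err[testable])
    noise_pass = testable & (p_value < alpha)

    qual_fraction = reads["alt_qual_sum"].to_numpy(dtype=float) / reads[
        "total_qual_sum"
    ].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(qual_fraction > 0, vaf / qual_fraction, np.inf)
    qual_ok = (ratio >= low) & (ratio <= high)

    accepted = (high_vaf | noise_pass) & qual_ok
    reason = np.full(len(reads), "candidate-threshold", dtype=object)
    reason[testable & ~noise_pass] = "binomial-noise"
    reason[(high_vaf | noise_pass) & ~qual_ok] = "quality-ratio"
    reason[accepted & high_vaf] = "high-vaf"
    reason[accepted & noise_pass] = "binomial"

    out = reads.copy()
    out["accepted"] = accepted
    out["reason"] = reason
    out["p_value"] = p_value
    return out
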