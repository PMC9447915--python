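import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from burdenscope import (
    Category,
    FrequencyEvidence,
    VariantCatalog,
    VariantRecord,
)

AMINO = ["Ala", "Gly", "Arg", "Ser", "Thr", "Val", "Leu", "Ile", "Pro", "Met"]


def make_record(i, per_population, category=Category.TYPE1):
    """Synthetic variant record with a plausible protein-change label."""
    return VariantRecord(
        variant_id=f"var{i:03d}",
        gene="CFI",
        chrom="4",
        pos=110_000_000 + i,
        protein_change=f"p.{AMINO[i % 10]}{100 + i}{AMINO[(i + 3) % 10]}",
        category=category,
        per_population=per_population,
    )


@pytest.fixture
def small_catalog():
    """18-record catalog with seeded per-population allele counts."""
    rng = np.random.default_rng(20230814)
    records = []
    for i in range(18):
        an = 100_000
        ev = {
            "nfe": FrequencyEvidence(int(rng.integers(0, 300)), an),
            "eas": FrequencyEvidence(int(rng.integers(0, 2)), an),
        }
        records.append(make_record(i, ev))
    return VariantCatalog(records)


def catalog_tsv_text(rows):
    """Render catalog rows (dicts) into the catalog TSV layout."""
    header = [
        "variant_id", "gene", "chrom", "pos", "protein_change", "category",
        "nfe.allele_count", "nfe.allele_number",
    ]
    lines = ["\t".join(header)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in header))
    return "\n".join(lines) + "\n"


def default_row(i, allele_count=10, allele_number=100_000):
    return {
        "variant_id": f"var{i:03d}",
        "gene": "CFI",
        "chrom": "4",
        "pos": 110_000_000 + i,
        "protein_change": f"p.{AMINO[i % 10]}{100 + i}{AMINO[(i + 3) % 10]}",
        "category": "type1",
        "nfe.allele_count": allele_count,
        "nfe.allele_number": allele_number,
    }
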