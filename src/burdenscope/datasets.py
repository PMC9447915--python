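"""Published summary inputs for the CFI Type 1 collective-burden analysis.

Two small built-in tables drive the worked examples, the CLI demo and the
reproduction script:

* ``AMD_COHORTS`` — collective Type 1 CFI rare-variant carrier totals for
  five European advanced-AMD case/control datasets (SCOPE, the UK Biobank
  pheWAS release, the IAMDGC meta-GWAS, the FINBB dry-AMD biobank cohort and
  the Kavanagh et al. 2015 targeted-sequencing study).
* ``GNOMAD_PANELS`` — per-ancestry gnomAD reference panels: panel size and
  the collective Type 1 CFI rare-variant background frequency (as a
  fraction), used as the fixed control arm in power projections.
"""

from __future__ import annotations

from .catalog import CohortCounts, Convention

__all__ = ["AMD_COHORTS", "GNOMAD_PANELS"]


def _pair(name: str, n_cases: int, case_carriers: int, n_controls: int, control_carriers: int):
    return (
        CohortCounts(f"{name} cases", n_cases, case_carriers, Convention.CARRIER_PROPORTION),
        CohortCounts(f"{name} controls", n_controls, control_carriers, Convention.CARRIER_PROPORTION),
    )


#: cohort name -> (case CohortCounts, control CohortCounts), carrier convention
AMD_COHORTS: dict[str, tuple[CohortCounts, CohortCounts]] = {
    "SCOPE": _pair("SCOPE", 3243, 84, 64603, 221),
    "UK Biobank": _pair("UK Biobank", 3770, 38, 234829, 764),
    "IAMDGC": _pair("IAMDGC", 16144, 197, 17832, 53),
    "FINBB": _pair("FINBB", 943, 2, 12562, 3),
    "Kavanagh 2015": _pair("Kavanagh 2015", 2266, 54, 1400, 3),
}

#: (population, gnomAD release, panel size n0, collective background frequency)
GNOMAD_PANELS: list[tuple[str, str, int, float]] = [
    ("Ashkenazi Jewish", "V2.1.1", 5185, 0.00550),
    ("Latino/Admixed American", "V2.1.1", 17720, 0.00198),
    ("Non-Finnish European", "V2.1.1", 64562, 0.00174),
    ("South Asian", "V2.1.1", 15308, 0.00052),
    ("African/African-American", "V3.1.1", 20744, 0.00019),
    ("Finnish", "V2.1.1", 12562, 0.00012),
    ("East Asian", "V2.1.1", 9977, 0.00005),
]
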