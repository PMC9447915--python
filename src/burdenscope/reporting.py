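"""Rendering of association and power-projection reports.

Display rounding mirrors the conventions of published burden tables: odds
ratios and CI bounds to two decimals, p-values to three significant figures
in scientific notation, collective frequencies as percentages to three
decimals.  Rounding is presentation-only — the JSON mirrors carry full
precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .association import AssociationResult
from .power import PanelRow, SolveStatus

__all__ = [
    "format_p",
    "association_frame",
    "association_records",
    "power_frame",
    "power_records",
    "write_report",
    "run_metadata",
]

#: rendering of a power entry whose asymptotic limit is below the target
UNATTAINABLE_MARK = "*"


def format_p(p: float) -> str:
    """Three significant figures, scientific notation (e.g. ``4.20E-02``)."""
    return f"{p:.2E}"


def association_frame(results: Mapping[str, AssociationResult]) -> pd.DataFrame:
    """Human-readable association table, one row per cohort."""
    rows = []
    for name, res in results.items():
        t = res.table
        rows.append(
            {
                "cohort": name,
                "cases": t.n_cases,
                "case_carriers": t.a,
                "case_frequency_pct": f"{100 * res.case_frequency:.3f}%",
                "controls": t.n_controls,
                "control_carriers": t.c,
                "control_frequency_pct": f"{100 * res.control_frequency:.3f}%",
                "p_value": format_p(res.p_value),
                "test": res.test_used.value,
                "odds_ratio": f"{res.odds_ratio:.2f}",
                "ci_low": f"{res.ci_low:.2f}",
                "ci_high": f"{res.ci_high:.2f}",
            }
        )
    return pd.DataFrame(rows)


def association_records(results: Mapping[str, AssociationResult]) -> list[dict]:
    """Full-precision JSON-ready association records."""
    out = []
    for name, res in results.items():
        t = res.table
        out.append(
            {
                "cohort": name,
                "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
                "odds_ratio": res.odds_ratio,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "ci_level": res.ci_level,
                "p_value": res.p_value,
                "test_used": res.test_used.value,
                "case_frequency": res.case_frequency,
                "control_frequency": res.control_frequency,
                "correction_applied": res.correction_applied,
            }
        )
    return out


def _render_n(result) -> str:
    if result.status is SolveStatus.ATTAINABLE:
        return str(result.n_required)
    return UNATTAINABLE_MARK


def power_frame(rows: Sequence[PanelRow]) -> pd.DataFrame:
    """Panel-by-panel projected sample sizes; unattainable entries starred."""
    records = []
    for row in rows:
        rec = {
            "population": row.population,
            "panel_n": row.n0,
            "background_frequency_pct": f"{100 * row.p0:.3f}%",
        }
        for res in row.results:
            rec[f"n_at_{int(round(100 * res.query.target_power))}pct_power"] = _render_n(res)
        rec["asymptotic_power"] = f"{row.results[0].asymptotic_power:.4f}"
        rec["attainable"] = all(r.attainable for r in row.results)
        records.append(rec)
    return pd.DataFrame(records)


def power_records(rows: Sequence[PanelRow]) -> list[dict]:
    out = []
    for row in rows:
        out.append(
            {
                "population": row.population,
                "n0": row.n0,
                "p0": row.p0,
                "results": [
                    {
                        "target_power": res.query.target_power,
                        "odds_ratio": res.query.odds_ratio,
                        "alpha": res.query.alpha,
                        "status": res.status.value,
                        "attainable": res.attainable,
                        "n_required": res.n_required,
                        "achieved_power": res.achieved_power,
                        "asymptotic_power": res.asymptotic_power,
                        "p1": res.p1,
                    }
                    for res in row.results
                ],
            }
        )
    return out


def write_report(frame: pd.DataFrame, records, out_dir: str | Path, stem: str) -> tuple[Path, Path]:
    """Write the TSV rendering and its full-precision JSON mirror."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / f"{stem}.tsv"
    json_path = out_dir / f"{stem}.json"
    frame.to_csv(tsv_path, sep="\t", index=False)
    json_path.write_text(json.dumps(records, indent=2) + "\n")
    return tsv_path, json_path


def run_metadata(subcommand: str, options: Mapping, inputs: Mapping) -> dict:
    from . import __version__

    return {
        "tool": "burdenscope",
        "version": __version__,
        "subcommand": subcommand,
        "inputs": dict(inputs),
        "options": dict(options),
    }
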