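"""Per-device / per-phase study report mirroring a method-comparison table.

The canonical report is JSON: a provenance block (config echo, package
version) plus, per device, one block for the pooled data and one per
clinical phase, each holding the agreement statistics, the error-grid
zone percentages (with an explicit suppression reason when the phase has
too few delta pairs) and the four-quadrant concordance.  A flattened CSV
view is provided for spreadsheet use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .agreement import AgreementOptions, AgreementResult, analyze_agreement
from .measurements import DEFAULT_PHASES, CohortDataset, filter_phase
from .trending import delta_pairs, error_grid, four_quadrant

__all__ = ["AnalysisConfig", "build_study_report", "write_report", "report_to_frame"]

STUDY_PHASES: tuple[str, ...] = DEFAULT_PHASES[:4]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the analysis pipeline needs besides the data itself."""

    phases: tuple[str, ...] = STUDY_PHASES
    z: float = 1.96
    level: float = 0.95
    pe_denominator: str = "reference"
    loa_ci_method: str = "mover"
    bootstrap_b: int = 2000
    seed: int = 0
    exclusion_threshold: float = 10.0
    exclusion_mode: str = "percent"
    grid_min_n: int = 30

    def agreement_options(self) -> AgreementOptions:
        return AgreementOptions(
            z=self.z,
            level=self.level,
            pe_denominator=self.pe_denominator,  # type: ignore[arg-type]
            loa_ci_method=self.loa_ci_method,  # type: ignore[arg-type]
            bootstrap_b=self.bootstrap_b,
            seed=self.seed,
        )


def _agreement_block(r: AgreementResult) -> dict:
    d = asdict(r)
    return d


def _trending_block(deltas, config: AnalysisConfig) -> dict:
    if not deltas:
        return {
            "n_deltas": 0,
            "four_quadrant": None,
            "error_grid": None,
            "suppressed_reason": "no delta pairs",
        }
    fq = four_quadrant(
        deltas, exclusion=config.exclusion_threshold, mode=config.exclusion_mode
    )
    grid = error_grid(deltas, min_n=config.grid_min_n)
    block: dict = {
        "n_deltas": len(deltas),
        "four_quadrant": asdict(fq),
        "error_grid": None,
        "suppressed_reason": None,
    }
    if grid.reported:
        block["error_grid"] = asdict(grid)
    else:
        block["suppressed_reason"] = (
            f"n below error-grid minimum ({grid.n_deltas} < {grid.min_n})"
        )
    return block


def build_study_report(
    datasets: Sequence[CohortDataset], config: AnalysisConfig | None = None
) -> dict:
    """Assemble the full study report for one or more device datasets.

    Deltas are formed on the whole series (changes may span phase
    boundaries); phase-level trending keeps the pairs whose later
    endpoint lies in the phase.
    """
    config = config or AnalysisConfig()
    devices = {}
    for ds in datasets:
        ag = analyze_agreement(ds, phases=config.phases,
                               options=config.agreement_options())
        all_deltas = delta_pairs(ds)
        rows = {}
        for r in ag:
            if r.phase == "all":
                deltas = all_deltas
            else:
                deltas = [p for p in all_deltas if p.phase == r.phase]
            rows[r.phase] = {
                "agreement": _agreement_block(r),
                "trending": _trending_block(deltas, config),
            }
        devices[ds.device_name] = {
            "reference": ds.reference_name,
            "n_measurements": ds.n_measurements,
            "n_patients": ds.n_patients,
            "phases": rows,
        }
    return {
        "provenance": {
            "package": "coagree",
            "version": __version__,
            "config": asdict(config),
        },
        "devices": devices,
    }


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flatten the JSON report into one row per device × phase."""
    rows = []
    for device, block in report["devices"].items():
        for phase, cell in block["phases"].items():
            a = cell["agreement"]
            t = cell["trending"]
            row = {
                "device": device,
                "phase": phase,
                "n": a["n"],
                "bias": a["bias"],
                "bias_ci_low": _ci(a["bias_ci"], 0),
                "bias_ci_high": _ci(a["bias_ci"], 1),
                "loa_lower": a["loa_lower"],
                "loa_lower_ci_low": _ci(a["loa_lower_ci"], 0),
                "loa_lower_ci_high": _ci(a["loa_lower_ci"], 1),
                "loa_upper": a["loa_upper"],
                "loa_upper_ci_low": _ci(a["loa_upper_ci"], 0),
                "loa_upper_ci_high": _ci(a["loa_upper_ci"], 1),
                "percentage_error": a["percentage_error"],
                "pe_ci_low": _ci(a["percentage_error_ci"], 0),
                "pe_ci_high": _ci(a["percentage_error_ci"], 1),
                "prop_bias_slope": a["prop_bias_slope"],
                "prop_bias_ci_low": _ci(a["prop_bias_ci"], 0),
                "prop_bias_ci_high": _ci(a["prop_bias_ci"], 1),
                "n_deltas": t["n_deltas"],
                "concordance_rate": (t["four_quadrant"] or {}).get("concordance_rate"),
            }
            grid = t["error_grid"]
            for z in range(4):
                row[f"grid_zone{z + 1}_pct"] = (
                    grid["zone_percentages"][z] if grid else None
                )
            row["grid_suppressed_reason"] = t["suppressed_reason"]
            rows.append(row)
    return pd.DataFrame(rows)


def _ci(pair, idx):
    return None if pair is None else pair[idx]


def write_report(report: dict, out_dir, *, stem: str = "report") -> dict[str, Path]:
    """Write the JSON report and its CSV flattening; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    json_path = out / f"{stem}.json"
    csv_path = out / f"{stem}.csv"
    json_path.write_text(json.dumps(report, indent=2, default=float) + "\n")
    report_to_frame(report).to_csv(csv_path, index=False, float_format="%.12g")
    return {"json": json_path, "csv": csv_path}
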