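"""End-to-end orchestration: evidence -> fractions -> burden -> reports.

``run_analysis`` wires the registry gates, the fraction sweep and the DALY
application into one deterministic pass and returns a
:class:`BurdenReport`; ``write_report`` renders it to CSV/JSON/markdown and
``verify_against_golden`` rechecks every cell against the published tables.

Every exclusion (non-significant estimate, outcome without a burden entry,
superseded duplicate) is logged with the rule that triggered it, so the
inclusion funnel is auditable from the log alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import datasets
from .daly_engine import (
    BurdenResult,
    CauseBurden,
    attributable_dalys,
    load_daly_table,
    preventable_dalys,
)
from .evidence_registry import (
    EvidenceBase,
    build_analysis_set,
    is_protective_significant,
    load_evidence,
)
from .formatting import format_dalys, format_percent, round_half_up
from .risk_fractions import (
    DEFAULT_PREVALENCE_GRID,
    FractionResult,
    IntervalFractions,
    PrevalenceScenario,
    interval_fractions,
    sweep_fractions,
)

__all__ = [
    "AnalysisConfig",
    "BurdenReport",
    "GoldenComparison",
    "run_analysis",
    "write_report",
    "verify_against_golden",
]

logger = logging.getLogger(__name__)

_FORMATS = ("csv", "json", "markdown")


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs, prevalence grid and output options for one pipeline run."""

    evidence_path: Path = field(default_factory=datasets.canonical_evidence_path)
    daly_path: Path = field(default_factory=datasets.canonical_daly_path)
    prevalence_grid: tuple[float, ...] = DEFAULT_PREVALENCE_GRID
    output_dir: Path = Path("results")
    report_formats: tuple[str, ...] = ("csv",)
    include_intervals: bool = False
    random_seed: int = 0

    def __post_init__(self) -> None:
        grid = tuple(float(p) for p in self.prevalence_grid)
        if not grid:
            raise ValueError("prevalence grid must be non-empty")
        if any(not 0 < p <= 1 for p in grid):
            raise ValueError(f"grid values must be in (0, 1]: {grid}")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError(f"grid must be strictly increasing: {grid}")
        unknown = set(self.report_formats) - set(_FORMATS)
        if unknown:
            raise ValueError(f"unknown report formats: {sorted(unknown)}")
        object.__setattr__(self, "prevalence_grid", grid)
        object.__setattr__(self, "evidence_path", Path(self.evidence_path))
        object.__setattr__(self, "daly_path", Path(self.daly_path))
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load a YAML config file; keyword arguments override file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("prevalence_grid", "report_formats"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def scenarios(self) -> tuple[PrevalenceScenario, ...]:
        return tuple(PrevalenceScenario(p) for p in self.prevalence_grid)


@dataclass(frozen=True)
class BurdenReport:
    """All fraction and burden cells from one run, plus provenance."""

    fractions: tuple[FractionResult, ...]
    burdens: tuple[BurdenResult, ...]
    intervals: tuple[IntervalFractions, ...] = ()
    provenance: dict = field(default_factory=dict)

    def fractions_frame(self) -> pd.DataFrame:
        """Fraction cells with 2-decimal percent strings and numeric twins."""
        rows = [
            {
                "outcome_id": f.outcome_id,
                "exposure_category": f.exposure_category,
                "pr": f.pr,
                "rr": f.rr,
                "rr_inverse": f.rr_inverse,
                "preventive_fraction_pct": format_percent(f.preventive_fraction),
                "parp_pct": format_percent(f.parp),
                "preventive_fraction": f.preventive_fraction,
                "parp": f.parp,
            }
            for f in self.fractions
        ]
        return pd.DataFrame(rows)

    def burden_frame(self) -> pd.DataFrame:
        """Burden cells with 1-decimal display strings and numeric twins."""
        rows = [
            {
                "outcome_id": b.outcome_id,
                "exposure_category": b.exposure_category,
                "pr": b.pr,
                "preventable_dalys_display": format_dalys(b.preventable_dalys),
                "attributable_dalys_display": format_dalys(b.attributable_dalys),
                "preventable_dalys": b.preventable_dalys,
                "attributable_dalys": b.attributable_dalys,
            }
            for b in self.burdens
        ]
        return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_analysis(cfg: AnalysisConfig | None = None) -> BurdenReport:
    """Run the full deterministic analysis described by ``cfg``.

    Estimates failing the significance gate or lacking a DALY entry are
    dropped with a logged warning; an empty analysis set is an error.
    """
    cfg = cfg or AnalysisConfig()
    base = load_evidence(cfg.evidence_path)
    burdens_by_cause = load_daly_table(cfg.daly_path)

    for e in base:
        if not is_protective_significant(e):
            logger.warning(
                "excluded %s/%s (%s %s): 95%% CI %.2f-%.2f not significantly protective",
                e.outcome_id, e.exposure_category, e.first_author, e.pub_year,
                e.ci_lower, e.ci_upper,
            )
        elif e.outcome_id not in burdens_by_cause:
            logger.warning(
                "excluded %s/%s (%s %s): no cause-level DALY estimate",
                e.outcome_id, e.exposure_category, e.first_author, e.pub_year,
            )

    analysis_set: EvidenceBase = build_analysis_set(base, burdens_by_cause)
    if len(analysis_set) == 0:
        raise ValueError(
            "analysis set is empty: no estimate is both significantly "
            "protective and matched to a DALY entry — check outcome_id "
            "values against the DALY table and the CI bounds"
        )

    scenarios = cfg.scenarios()
    fractions: list[FractionResult] = []
    burdens: list[BurdenResult] = []
    intervals: list[IntervalFractions] = []
    for e in analysis_set:
        cause = burdens_by_cause[e.outcome_id]
        for cell in sweep_fractions(e, scenarios):
            fractions.append(cell)
            burdens.append(
                BurdenResult(
                    outcome_id=cell.outcome_id,
                    exposure_category=cell.exposure_category,
                    pr=cell.pr,
                    preventable_dalys=preventable_dalys(
                        cell.preventive_fraction, cause
                    ),
                    attributable_dalys=attributable_dalys(cell.parp, cause),
                )
            )
        if cfg.include_intervals:
            intervals.extend(interval_fractions(e, s) for s in scenarios)

    provenance = {
        "evidence_path": str(cfg.evidence_path),
        "evidence_sha256": _digest(cfg.evidence_path),
        "daly_path": str(cfg.daly_path),
        "daly_sha256": _digest(cfg.daly_path),
        "prevalence_grid": list(cfg.prevalence_grid),
        "n_estimates": len(analysis_set),
    }
    return BurdenReport(
        fractions=tuple(fractions),
        burdens=tuple(burdens),
        intervals=tuple(intervals),
        provenance=provenance,
    )


def _markdown_table(report: BurdenReport) -> str:
    prs = sorted({f.pr for f in report.fractions})
    header = ["Outcome", "Exposure"]
    header += [f"PF Pr {p:.0%}" for p in prs] + [f"PARP Pr {p:.0%}" for p in prs]
    lines = ["| " + " | ".join(header) + " |", "|" + "---|" * len(header)]
    cells: dict[tuple[str, str], dict[float, FractionResult]] = {}
    order: list[tuple[str, str]] = []
    for f in report.fractions:
        key = (f.outcome_id, f.exposure_category)
        if key not in cells:
            cells[key] = {}
            order.append(key)
        cells[key][f.pr] = f
    for outcome, exposure in order:
        row = [outcome, exposure]
        row += [format_percent(cells[(outcome, exposure)][p].preventive_fraction) for p in prs]
        row += [format_percent(cells[(outcome, exposure)][p].parp) for p in prs]
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines) + "\n"


def write_report(report: BurdenReport, cfg: AnalysisConfig) -> list[Path]:
    """Write the report in each requested format; returns paths written.

    CSV output is byte-identical across runs with identical inputs; the
    JSON document adds provenance (input digests) for auditability.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "csv" in cfg.report_formats:
        fpath, bpath = out / "fractions.csv", out / "burden.csv"
        report.fractions_frame().to_csv(fpath, index=False)
        report.burden_frame().to_csv(bpath, index=False)
        written += [fpath, bpath]
    if "json" in cfg.report_formats:
        jpath = out / "report.json"
        payload = {
            "provenance": report.provenance,
            "fractions": report.fractions_frame().to_dict(orient="records"),
            "burden": report.burden_frame().to_dict(orient="records"),
        }
        jpath.write_text(json.dumps(payload, indent=2) + "\n")
        written.append(jpath)
    if "markdown" in cfg.report_formats:
        mpath = out / "report.md"
        mpath.write_text(_markdown_table(report))
        written.append(mpath)
    return written


@dataclass(frozen=True)
class GoldenComparison:
    """Outcome of a golden-table check: unexplained vs documented cells."""

    unexplained: tuple[dict, ...]
    known_discrepancies: tuple[dict, ...]

    @property
    def clean(self) -> bool:
        return not self.unexplained


def verify_against_golden(
    report: BurdenReport, golden: str | Path | None = None
) -> GoldenComparison:
    """Compare every report cell with the published golden tables.

    Cells are compared after display rounding (2-decimal percent for
    fractions, 1-decimal person-years for burden). Cells flagged
    ``known_discrepancy`` in the golden file — where the published number
    is inconsistent with the published formula — are reported separately
    with the formula value alongside and do not count as failures.
    """
    path = Path(golden) if golden is not None else datasets.golden_table_path()
    gdf = pd.read_csv(path)
    required = {"outcome_id", "exposure_category", "pr", "metric", "value", "known_discrepancy"}
    if not required.issubset(gdf.columns):
        raise ValueError(
            f"malformed golden file {path}: needs columns {sorted(required)}"
        )

    computed: dict[tuple[str, str, float, str], float] = {}
    for f in report.fractions:
        key = (f.outcome_id, f.exposure_category, f.pr)
        computed[(*key, "pf")] = round_half_up(f.preventive_fraction * 100, 2)
        computed[(*key, "parp")] = round_half_up(f.parp * 100, 2)
    for b in report.burdens:
        key = (b.outcome_id, b.exposure_category, b.pr)
        computed[(*key, "preventable_dalys")] = round_half_up(b.preventable_dalys, 1)
        computed[(*key, "attributable_dalys")] = round_half_up(b.attributable_dalys, 1)

    unexplained: list[dict] = []
    known: list[dict] = []
    for row in gdf.itertuples(index=False):
        key = (row.outcome_id, row.exposure_category, float(row.pr), row.metric)
        got = computed.get(key)
        record = {
            "outcome_id": row.outcome_id,
            "exposure_category": row.exposure_category,
            "pr": float(row.pr),
            "metric": row.metric,
            "published": float(row.value),
            "computed": got,
        }
        if bool(row.known_discrepancy):
            known.append(record)
            continue
        if got is None or abs(got - float(row.value)) > 1e-9:
            unexplained.append(record)
    return GoldenComparison(
        unexplained=tuple(unexplained), known_discrepancies=tuple(known)
    )
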