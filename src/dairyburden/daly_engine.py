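"""DALY decomposition and application of fractions to cause-level burden.

A disability-adjusted life year (DALY) is one lost year of healthy life.
For a cause c, sex s, age a and year t:

    DALY(c,s,a,t) = YLL(c,s,a,t) + YLD(c,s,a,t)
    YLL = N x L        (deaths x standard-loss-function years remaining)
    YLD = I x DW x L   (incident cases x disability weight x mean duration)

The engine accepts either pre-aggregated cause-level DALY totals (the
published-table pathway: WHO Global Health Estimates are inputs, never
recomputed here) or stratified YLL/YLD component tables that it aggregates
itself. Preventable and attributable burden are the unrounded fractions
times the cause total; rounding the fraction first does not reproduce the
published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "CauseBurden",
    "YllInputs",
    "YldInputs",
    "BurdenResult",
    "compute_yll",
    "compute_yld",
    "compose_daly",
    "preventable_dalys",
    "attributable_dalys",
    "load_daly_table",
    "aggregate_strata",
]

_REL_TOL = 1e-9


@dataclass(frozen=True)
class YllInputs:
    """Years-of-life-lost inputs: deaths N and standard loss years L(s,a)."""

    n_deaths: float
    loss_years: float

    def __post_init__(self) -> None:
        if self.n_deaths < 0 or self.loss_years < 0:
            raise ValueError("YLL inputs must be non-negative")


@dataclass(frozen=True)
class YldInputs:
    """Years-lived-with-disability inputs: incidence I, weight DW, duration L."""

    incident_cases: float
    disability_weight: float
    duration_years: float

    def __post_init__(self) -> None:
        if self.incident_cases < 0 or self.duration_years < 0:
            raise ValueError("YLD inputs must be non-negative")
        if not 0 <= self.disability_weight <= 1:
            raise ValueError(
                f"disability weight must be in [0, 1] "
                f"(0 = perfect health, 1 = death-equivalent), got {self.disability_weight}"
            )


@dataclass(frozen=True)
class CauseBurden:
    """Cause-level DALY total, optionally with its YLL/YLD split and stratum key."""

    outcome_id: str
    dalys: float
    yll: float | None = None
    yld: float | None = None
    stratum: tuple | None = None

    def __post_init__(self) -> None:
        if self.dalys < 0:
            raise ValueError("DALYs must be non-negative")
        if (self.yll is None) != (self.yld is None):
            raise ValueError("provide both YLL and YLD components or neither")
        if self.yll is not None:
            if self.yll < 0 or self.yld < 0:
                raise ValueError("YLL and YLD must be non-negative")
            if abs(self.dalys - (self.yll + self.yld)) > _REL_TOL * max(
                1.0, self.dalys
            ):
                raise ValueError(
                    f"DALY total {self.dalys} does not equal YLL + YLD = "
                    f"{self.yll + self.yld}"
                )


@dataclass(frozen=True)
class BurdenResult:
    """Preventable and attributable DALYs for one (outcome, exposure, Pr) cell."""

    outcome_id: str
    exposure_category: str
    pr: float
    preventable_dalys: float
    attributable_dalys: float

    def __post_init__(self) -> None:
        if self.preventable_dalys < 0 or self.attributable_dalys < 0:
            raise ValueError("burden results must be non-negative")


def compute_yll(x: YllInputs) -> float:
    """YLL = N x L."""
    return x.n_deaths * x.loss_years


def compute_yld(x: YldInputs) -> float:
    """YLD = I x DW x L."""
    return x.incident_cases * x.disability_weight * x.duration_years


def compose_daly(yll: float, yld: float) -> float:
    """DALY = YLL + YLD."""
    if yll < 0 or yld < 0:
        raise ValueError("YLL and YLD must be non-negative")
    return yll + yld


def preventable_dalys(pf: float, burden: CauseBurden) -> float:
    """Burden avertable at preventive fraction ``pf``: pf x DALYs."""
    if not 0 <= pf < 1:
        raise ValueError(f"preventive fraction must be in [0, 1), got {pf}")
    return pf * burden.dalys


def attributable_dalys(parp: float, burden: CauseBurden) -> float:
    """Burden attributable at attributable fraction ``parp``: parp x DALYs."""
    if not 0 <= parp < 1:
        raise ValueError(f"attributable fraction must be in [0, 1), got {parp}")
    return parp * burden.dalys


def load_daly_table(table_source: str | Path) -> dict[str, CauseBurden]:
    """Read a cause-level DALY CSV (columns outcome_id, dalys)."""
    path = Path(table_source)
    df = pd.read_csv(path)
    missing = [c for c in ("outcome_id", "dalys") if c not in df.columns]
    if missing:
        raise ValueError(
            f"DALY table {path} is missing required columns: {', '.join(missing)}"
        )
    dup = df["outcome_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate outcome_id rows in {path}: "
            f"{sorted(df.loc[dup, 'outcome_id'])}"
        )
    return {
        str(r.outcome_id): CauseBurden(outcome_id=str(r.outcome_id), dalys=float(r.dalys))
        for r in df.itertuples(index=False)
    }


def aggregate_strata(strata: pd.DataFrame) -> dict[str, CauseBurden]:
    """Aggregate a stratified component table to cause-level burdens.

    Expects columns ``outcome_id, sex, age_group, year, n_deaths,
    loss_years, incident_cases, disability_weight, duration_years``; each
    stratum contributes N x L person-years of YLL and I x DW x L of YLD.
    """
    required = (
        "outcome_id",
        "n_deaths",
        "loss_years",
        "incident_cases",
        "disability_weight",
        "duration_years",
    )
    missing = [c for c in required if c not in strata.columns]
    if missing:
        raise ValueError(f"stratified table missing columns: {', '.join(missing)}")
    out: dict[str, CauseBurden] = {}
    for outcome_id, group in strata.groupby("outcome_id", sort=True):
        yll = sum(
            compute_yll(YllInputs(r.n_deaths, r.loss_years))
            for r in group.itertuples(index=False)
        )
        yld = sum(
            compute_yld(YldInputs(r.incident_cases, r.disability_weight, r.duration_years))
            for r in group.itertuples(index=False)
        )
        out[str(outcome_id)] = CauseBurden(
            outcome_id=str(outcome_id), dalys=compose_daly(yll, yld), yll=yll, yld=yld
        )
    return out
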