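"""Preventive fractions and population attributable risk proportions.

For a protective exposure with relative risk RR < 1 held by a fraction Pr
of the population, the preventive fraction

    PF = Pr (1 - RR)

is the share of disease that would be averted if that prevalence of the
population were exposed. Flipping the reference group — treating LOW
intake as the harmful exposure with RR_I = 1/RR — gives the Levin-style
population attributable risk proportion

    PARP = Pr (RR_I - 1) / [1 + Pr (RR_I - 1)],

the share of disease attributable to low intake. PARP >= PF always, with
equality only at the null; both are zero at RR = 1.

All functions keep full floating precision: percent rounding belongs to
the report layer (:mod:`dairyburden.formatting`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .evidence_registry import EffectEstimate

__all__ = [
    "DEFAULT_PREVALENCE_GRID",
    "PrevalenceScenario",
    "FractionResult",
    "IntervalFractions",
    "default_grid",
    "preventive_fraction",
    "invert_rr",
    "parp",
    "sweep_fractions",
    "interval_fractions",
]

#: conservative prevalence-of-high-intake scenarios used throughout
DEFAULT_PREVALENCE_GRID = (0.15, 0.25, 0.35, 0.50)


@dataclass(frozen=True)
class PrevalenceScenario:
    """A prevalence-of-exposure value Pr in (0, 1] with a display label."""

    pr: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.pr <= 1:
            raise ValueError(f"prevalence must be in (0, 1], got {self.pr}")
        if not self.label:
            object.__setattr__(self, "label", f"Pr {self.pr:.0%}")


def default_grid() -> tuple[PrevalenceScenario, ...]:
    """The default four-scenario prevalence grid (15/25/35/50%)."""
    return tuple(PrevalenceScenario(pr) for pr in DEFAULT_PREVALENCE_GRID)


@dataclass(frozen=True)
class FractionResult:
    """PF and PARP for one (outcome, exposure, prevalence) cell."""

    outcome_id: str
    exposure_category: str
    pr: float
    rr: float
    rr_inverse: float
    preventive_fraction: float
    parp: float


@dataclass(frozen=True)
class IntervalFractions:
    """CI-substitution bounds around a point :class:`FractionResult`.

    Not part of the published-table workflow (which reports point estimates
    only): the SRRE's CI bounds are pushed through the same formulas to give
    a (conservative, optimistic) pair. When the CI upper bound reaches 1.0
    the conservative fractions are clamped to 0 and ``clamped`` is set.
    """

    point: FractionResult
    conservative: FractionResult
    optimistic: FractionResult
    clamped: bool = False


def preventive_fraction(pr: float, rr: float) -> float:
    """Pr (1 - RR) for a protective (or null) relative risk."""
    if not 0 < pr <= 1:
        raise ValueError(f"prevalence must be in (0, 1], got {pr}")
    if not 0 < rr <= 1:
        raise ValueError(
            f"preventive fraction is defined for protective rr in (0, 1], got {rr}"
        )
    return pr * (1.0 - rr)


def invert_rr(rr: float) -> float:
    """Reference-group flip: the relative risk of LOW intake, 1/RR."""
    if not rr > 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    return 1.0 / rr


def parp(pr: float, rr_inverse: float) -> float:
    """Pr (RR_I - 1) / [1 + Pr (RR_I - 1)] for a harmful exposure RR_I >= 1."""
    if not 0 < pr <= 1:
        raise ValueError(f"prevalence must be in (0, 1], got {pr}")
    if rr_inverse < 1:
        raise ValueError(
            f"attributable fraction requires rr_inverse >= 1, got {rr_inverse}"
        )
    excess = pr * (rr_inverse - 1.0)
    return excess / (1.0 + excess)


def _fraction_cell(e: EffectEstimate, pr: float, rr: float) -> FractionResult:
    rr_i = invert_rr(rr)
    return FractionResult(
        outcome_id=e.outcome_id,
        exposure_category=e.exposure_category,
        pr=pr,
        rr=rr,
        rr_inverse=rr_i,
        preventive_fraction=preventive_fraction(pr, rr),
        parp=parp(pr, rr_i),
    )


def sweep_fractions(
    e: EffectEstimate, grid: Sequence[PrevalenceScenario]
) -> tuple[FractionResult, ...]:
    """Evaluate PF and PARP for one estimate over a prevalence grid."""
    if not grid:
        raise ValueError("prevalence grid must be non-empty")
    return tuple(_fraction_cell(e, s.pr, e.srre) for s in grid)


def interval_fractions(
    e: EffectEstimate, scenario: PrevalenceScenario
) -> IntervalFractions:
    """CI-substitution bounds for one estimate at one prevalence.

    The conservative member uses ``ci_upper`` (weakest protection), the
    optimistic member ``ci_lower``. A CI upper bound at or above 1.0 is
    clamped to the null rather than raising, flagged via ``clamped``.
    """
    point = _fraction_cell(e, scenario.pr, e.srre)
    clamped = e.ci_upper >= 1.0
    conservative = _fraction_cell(e, scenario.pr, min(e.ci_upper, 1.0))
    optimistic = _fraction_cell(e, scenario.pr, e.ci_lower)
    return IntervalFractions(
        point=point, conservative=conservative, optimistic=optimistic, clamped=clamped
    )
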