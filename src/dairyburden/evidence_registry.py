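"""Meta-analytic evidence registry: loading, validation, and inclusion logic.

The evidence base is a table of summary relative risk estimates (SRREs)
from published meta-analyses of dairy intake and chronic disease, one row
per (outcome, exposure category, source). Estimates enter the
preventive-fraction workflow only if they are statistically significant in
the protective direction (95% CI entirely below 1.0) and the outcome has a
cause-level DALY entry; when several meta-analyses cover the same cell the
most recent, then largest, one is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "EXPOSURE_CATEGORIES",
    "EffectEstimate",
    "EvidenceBase",
    "EvidenceSchemaError",
    "EvidenceValidationError",
    "load_evidence",
    "is_protective_significant",
    "select_primary",
    "build_analysis_set",
]

#: canonical ordering of exposure strata in reports
EXPOSURE_CATEGORIES = ("total_dairy", "milk", "low_fat_dairy", "high_fat_dairy")

REQUIRED_COLUMNS = (
    "outcome_id",
    "exposure_category",
    "comparison",
    "srre",
    "ci_lower",
    "ci_upper",
    "n_studies",
    "first_author",
    "pub_year",
)

OPTIONAL_COLUMNS = ("i_squared", "p_heterogeneity", "funding_source")


class EvidenceSchemaError(ValueError):
    """The evidence table is missing required columns."""


class EvidenceValidationError(ValueError):
    """One or more evidence rows violate the estimate invariants."""

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        lines = "; ".join(f"row {i}: {msg}" for i, msg in self.problems)
        super().__init__(f"invalid evidence rows: {lines}")


@dataclass(frozen=True)
class EffectEstimate:
    """One meta-analytic summary relative risk estimate with its 95% CI.

    ``srre`` is the pooled high-vs-low relative risk; ``i_squared`` (percent
    of between-study variance due to heterogeneity) and ``p_heterogeneity``
    are carried as metadata and never enter any computation.
    """

    outcome_id: str
    exposure_category: str
    comparison: str
    srre: float
    ci_lower: float
    ci_upper: float
    n_studies: int
    first_author: str
    pub_year: int
    i_squared: float | None = None
    p_heterogeneity: float | None = None
    funding_source: str | None = None

    def __post_init__(self) -> None:
        if self.exposure_category not in EXPOSURE_CATEGORIES:
            raise ValueError(
                f"unknown exposure_category {self.exposure_category!r}; "
                f"expected one of {EXPOSURE_CATEGORIES}"
            )
        if not self.srre > 0:
            raise ValueError(f"srre must be > 0, got {self.srre}")
        if not self.ci_lower > 0:
            raise ValueError(f"ci_lower must be > 0, got {self.ci_lower}")
        if not (self.ci_lower <= self.srre <= self.ci_upper):
            raise ValueError(
                f"CI must bracket the estimate: "
                f"{self.ci_lower} <= {self.srre} <= {self.ci_upper} fails"
            )
        if self.n_studies < 1:
            raise ValueError(f"n_studies must be >= 1, got {self.n_studies}")
        if self.i_squared is not None and not 0 <= self.i_squared <= 100:
            raise ValueError(f"i_squared must be in [0, 100], got {self.i_squared}")
        if self.p_heterogeneity is not None and not 0 <= self.p_heterogeneity <= 1:
            raise ValueError(
                f"p_heterogeneity must be in [0, 1], got {self.p_heterogeneity}"
            )


@dataclass(frozen=True)
class EvidenceBase:
    """An ordered, validated collection of effect estimates."""

    estimates: tuple[EffectEstimate, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.estimates)

    def __iter__(self) -> Iterator[EffectEstimate]:
        return iter(self.estimates)

    def restrict(self, exposure_categories: Iterable[str]) -> "EvidenceBase":
        """Keep only estimates whose exposure category is in the given set."""
        keep = set(exposure_categories)
        return replace(
            self,
            estimates=tuple(e for e in self.estimates if e.exposure_category in keep),
        )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def load_evidence(table_source: str | Path) -> EvidenceBase:
    """Read an evidence CSV and validate every row.

    Raises :class:`EvidenceSchemaError` if required columns are missing and
    :class:`EvidenceValidationError` (listing 0-based row indices) if any
    row violates the estimate invariants.
    """
    path = Path(table_source)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise EvidenceSchemaError(
            f"evidence table {path} is missing required columns: {', '.join(missing)}"
        )

    estimates: list[EffectEstimate] = []
    problems: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            estimates.append(
                EffectEstimate(
                    outcome_id=str(row.outcome_id),
                    exposure_category=str(row.exposure_category),
                    comparison=str(row.comparison),
                    srre=float(row.srre),
                    ci_lower=float(row.ci_lower),
                    ci_upper=float(row.ci_upper),
                    n_studies=int(row.n_studies),
                    first_author=str(row.first_author),
                    pub_year=int(row.pub_year),
                    i_squared=_opt_float(getattr(row, "i_squared", None)),
                    p_heterogeneity=_opt_float(getattr(row, "p_heterogeneity", None)),
                    funding_source=(
                        None
                        if pd.isna(getattr(row, "funding_source", None))
                        else str(row.funding_source)
                    ),
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append((i, str(exc)))
    if problems:
        raise EvidenceValidationError(problems)
    return EvidenceBase(estimates=tuple(estimates), provenance=str(path))


def is_protective_significant(estimate: EffectEstimate) -> bool:
    """Significance gate: the 95% CI lies entirely below the null.

    Strict inequality — a CI upper bound touching 1.0 exactly (only
    "marginally" significant) does not pass, and harmful-direction
    estimates never do.
    """
    return estimate.ci_upper < 1.0


def select_primary(candidates: Sequence[EffectEstimate]) -> EffectEstimate:
    """Pick the primary estimate for one (outcome, exposure) cell.

    Most recent publication year wins; ties go to the meta-analysis pooling
    the most studies; any remaining tie is broken by lexicographically
    smallest first author, so the choice is a pure deterministic function
    of the candidate set.
    """
    if not candidates:
        raise ValueError("select_primary requires at least one candidate")
    keys = {(e.outcome_id, e.exposure_category) for e in candidates}
    if len(keys) > 1:
        raise ValueError(
            f"candidates must share (outcome_id, exposure_category); got {sorted(keys)}"
        )
    return min(
        candidates, key=lambda e: (-e.pub_year, -e.n_studies, e.first_author)
    )


def build_analysis_set(
    base: EvidenceBase, daly_catalog: Iterable[str] | Mapping[str, object]
) -> EvidenceBase:
    """Apply the two inclusion gates and per-cell primary selection.

    Keeps estimates that (1) pass :func:`is_protective_significant` and
    (2) have a cause-level burden entry in ``daly_catalog``; then reduces
    each (outcome, exposure) cell to its primary estimate. Output order is
    canonical (exposure stratum, then outcome), so the result is invariant
    to input row order.
    """
    catalog = set(daly_catalog)
    eligible = [
        e
        for e in base
        if is_protective_significant(e) and e.outcome_id in catalog
    ]
    cells: dict[tuple[str, str], list[EffectEstimate]] = {}
    for e in eligible:
        cells.setdefault((e.outcome_id, e.exposure_category), []).append(e)
    primaries = [select_primary(group) for group in cells.values()]
    primaries.sort(
        key=lambda e: (EXPOSURE_CATEGORIES.index(e.exposure_category), e.outcome_id)
    )
    return EvidenceBase(
        estimates=tuple(primaries),
        provenance=f"{base.provenance} [analysis set]",
    )
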