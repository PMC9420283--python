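"""Canonical data files shipped with the package.

Three small CSVs: the published evidence table of meta-analytic SRREs
(including the two considered-but-excluded prostate-cancer estimates), the
WHO US 2019 cause-level DALY totals for the six outcomes in the analysis,
and the golden fraction/burden tables used by the regression harness.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = ["canonical_evidence_path", "canonical_daly_path", "golden_table_path"]


def _data_path(name: str) -> Path:
    return Path(resources.files("dairyburden").joinpath("data", name))


def canonical_evidence_path() -> Path:
    """Evidence table: 16 meta-analytic SRREs (14 analysed + 2 considered)."""
    return _data_path("table1_evidence.csv")


def canonical_daly_path() -> Path:
    """WHO Global Health Estimates: US 2019 DALYs for the six outcomes."""
    return _data_path("us_dalys_2019.csv")


def golden_table_path() -> Path:
    """Published fraction and burden tables, cell by cell, with
    known-discrepancy flags and formula twins."""
    return _data_path("golden_tables.csv")
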