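import pytest

from dairyburden import AnalysisConfig, run_analysis
from dairyburden.datasets import canonical_daly_path, canonical_evidence_path
from dairyburden.daly_engine import load_daly_table
from dairyburden.evidence_registry import build_analysis_set, load_evidence


@pytest.fixture(scope="session")
def evidence_base():
    """The packaged registry: 14 analysed + 2 considered estimates."""
    return load_evidence(canonical_evidence_path())


@pytest.fixture(scope="session")
def daly_catalog():
    return load_daly_table(canonical_daly_path())


@pytest.fixture(scope="session")
def analysis_set(evidence_base, daly_catalog):
    return build_analysis_set(evidence_base, daly_catalog)


@pytest.fixture(scope="session")
def canonical_report():
    """One full default-configuration pipeline run, shared across tests."""
    return run_analysis(AnalysisConfig())


@pytest.fixture()
def estimate_by_cell(analysis_set):
    return {(e.outcome_id, e.exposure_category): e for e in analysis_set}
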