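import datetime as dt

import pytest

from pvsignal.records import AnalysisConfig, DrugExposure, ReportRecord


def make_record(case_id, drug="aspirin", role="PS", pts=("Subdural hematoma",),
                version=1, receipt=dt.date(2020, 6, 1), start=None, event=None,
                sex="male", age=70.0, reporter="physician", country="United States",
                serious=True, outcomes=("hospitalization",)):
    """Compact report-record factory for fixtures."""
    return ReportRecord(
        case_id=case_id, version_id=version, receipt_date=receipt,
        drugs=[DrugExposure(drug, role=role, start_date=start)],
        reactions=frozenset(pts), event_date=event, sex=sex, age_years=age,
        reporter=reporter, country=country, serious=serious,
        outcomes=frozenset(outcomes))


@pytest.fixture
def analysis_config():
    return AnalysisConfig()


@pytest.fixture
def tiny_corpus():
    """Four records spanning the 2x2 cells for (aspirin, subdural hematoma)."""
    return [
        make_record("C1", drug="aspirin", pts=("Subdural hematoma",)),
        make_record("C2", drug="aspirin", pts=("Nausea",)),
        make_record("C3", drug="other-drug", pts=("Subdural hematoma",)),
        make_record("C4", drug="other-drug", pts=("Nausea",)),
    ]
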