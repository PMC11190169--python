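import datetime as dt
from pathlib import Path

import pandas as pd
import pytest

from faerspv.io import DrugEntry, ReportStore, SafetyReport

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def printed_pt() -> pd.DataFrame:
    """Published PT-level counts and statistics (46 adverse-reaction terms)."""
    return pd.read_csv(DATA / "printed_pt_signals.tsv", sep="\t")


@pytest.fixture(scope="session")
def printed_soc() -> pd.DataFrame:
    """Published SOC-level counts and statistics (8 organ classes)."""
    return pd.read_csv(DATA / "printed_soc_signals.tsv", sep="\t")


def make_report(i: int, drugs=(), reactions=(), sex="UNK", age=None,
                country="UNK", outcomes=(), indications=(),
                date=dt.date(2023, 2, 1), version=1, case=None) -> SafetyReport:
    return SafetyReport(
        primary_id=f"{i}{version}", case_id=case or f"C{i}",
        case_version=version, receipt_date=date, sex=sex, age_years=age,
        country=country,
        drugs=[DrugEntry(verbatim_name=d.upper(), ingredient=d, role=role)
               for d, role in drugs],
        reactions=list(reactions), outcomes=list(outcomes),
        indications=list(indications))


@pytest.fixture
def toy_store() -> ReportStore:
    """4 reports: 2 exposed (1 with the event), 1 unexposed with the event,
    1 with neither — the (1,1,1,1) contingency configuration."""
    return ReportStore(reports=[
        make_report(1, drugs=[("tirzepatide", "PS")], reactions=["Nausea"]),
        make_report(2, drugs=[("tirzepatide", "PS")], reactions=["Headache"]),
        make_report(3, drugs=[("metformin", "PS")], reactions=["Nausea"]),
        make_report(4, drugs=[("metformin", "PS")], reactions=["Headache"]),
    ])
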