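import pandas as pd
import pytest

from pipn.report_model import ReportSet, make_report


@pytest.fixture
def toy_reports() -> ReportSet:
    """Six paclitaxel reports whose 2x2 table vs tamsulosin is (1, 1, 1, 3)."""
    return ReportSet(
        [
            make_report("r1", ["paclitaxel", "tamsulosin"], ["peripheral neuropathy"]),
            make_report("r2", ["paclitaxel", "tamsulosin"]),
            make_report("r3", ["paclitaxel"], ["peripheral sensory neuropathy"]),
            make_report("r4", ["paclitaxel"]),
            make_report("r5", ["paclitaxel"]),
            make_report("r6", ["paclitaxel"]),
        ]
    )


@pytest.fixture
def toy_tables(tmp_path):
    """The same six reports as $-delimited drug/reaction files."""
    drug = tmp_path / "drug.txt"
    reac = tmp_path / "reac.txt"
    drug.write_text(
        "report_id$drug_name\n"
        "r1$paclitaxel\nr1$tamsulosin\nr2$paclitaxel\nr2$tamsulosin\n"
        "r3$paclitaxel\nr4$paclitaxel\nr5$paclitaxel\nr6$paclitaxel\n"
    )
    reac.write_text(
        "report_id$event_term\nr1$peripheral neuropathy\nr3$peripheral sensory neuropathy\n"
    )
    return drug, reac
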