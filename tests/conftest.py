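import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from scarsignal import (
    AdverseEventReport,
    DrugMention,
    DrugRole,
    Outcome,
    Reporter,
    ReportSet,
    Sex,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_report(
    report_id="R1",
    reactions=("Headache",),
    suspects=(),
    other_drugs=(),
    date=dt.date(2020, 6, 1),
    **kwargs,
):
    """Compact report factory: suspects are generic-name strings (None = missing)."""
    drugs = [
        DrugMention(DrugRole.PRIMARY_SUSPECT, generic_name=s, raw_product_name="X")
        for s in suspects
    ]
    drugs += [DrugMention(DrugRole.CONCOMITANT, generic_name=s) for s in other_drugs]
    return AdverseEventReport(
        report_id=report_id,
        reactions=list(reactions),
        drugs=drugs,
        receive_date=date,
        **kwargs,
    )


@pytest.fixture
def four_report_set():
    """The canonical 2x2 fixture: two drugs crossed with SJS vs headache."""
    return ReportSet(
        [
            make_report("R1", ["Stevens–Johnson syndrome"], ["drugX"]),
            make_report("R2", ["Headache"], ["drugX"]),
            make_report("R3", ["Stevens–Johnson syndrome"], ["drugY"]),
            make_report("R4", ["Headache"], ["drugY"]),
        ]
    )


@pytest.fixture
def rich_report():
    return make_report(
        "R42",
        reactions=["Toxic epidermal necrolysis", "Pyrexia"],
        suspects=["Lamotrigine"],
        other_drugs=["valproate"],
        reporter=Reporter.HEALTH_PROFESSIONAL,
        country="FR",
        sex=Sex.FEMALE,
        age_years=64.0,
        outcomes={Outcome.DEATH, Outcome.HOSPITALIZATION},
    )
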