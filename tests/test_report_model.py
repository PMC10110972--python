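import datetime as dt
import json

import pytest
from hypothesis import given, strategies as st

from scarsignal import (
    AdverseEventReport,
    DrugMention,
    DrugRole,
    Outcome,
    Reporter,
    ReportSet,
    Sex,
    deduplicate_reports,
    read_reports,
    write_reports,
)
from scarsignal.report_model import ReportIOError

from conftest import make_report


OPENFDA_RECORD = {
    "safetyreportid": "10001",
    "receivedate": "20190315",
    "occurcountry": "US",
    "seriousnessdeath": "1",
    "primarysource": {"qualification": "1"},
    "patient": {
        "patientsex": "2",
        "patientonsetage": "63",
        "patientonsetageunit": "801",
        "reaction": [
            {"reactionmeddrapt": "Stevens–Johnson syndrome"},
            {"reactionmeddrapt": "Pyrexia"},
        ],
        "drug": [
            {
                "drugcharacterization": "1",
                "medicinalproduct": "LAMICTAL",
                "openfda": {"generic_name": ["LAMOTRIGINE"]},
            },
            {"drugcharacterization": "2", "medicinalproduct": "DEPAKOTE"},
        ],
    },
}


class TestOpenFDAReader:
    def test_single_record_maps_every_field(self, tmp_path):
        path = tmp_path / "one.json"
        path.write_text(json.dumps({"results": [OPENFDA_RECORD]}))
        rs = read_reports(path, "openfda_json")
        assert len(rs) == 1
        r = rs[0]
        assert r.report_id == "10001"
        assert r.receive_date == dt.date(2019, 3, 15)
        assert r.reporter is Reporter.HEALTH_PROFESSIONAL
        assert r.country == "US"
        assert r.sex is Sex.FEMALE
        assert r.age_years == 63.0
        assert r.outcomes == {Outcome.DEATH}
        assert r.reactions == ["Stevens–Johnson syndrome", "Pyrexia"]
        assert r.drugs[0].role is DrugRole.PRIMARY_SUSPECT
        assert r.drugs[0].generic_name == "LAMOTRIGINE"
        # concomitant drug without openfda block: generic name explicitly absent
        assert r.drugs[1].role is DrugRole.CONCOMITANT
        assert r.drugs[1].generic_name is None

    def test_empty_results_array(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text(json.dumps({"results": []}))
        assert len(read_reports(path, "openfda_json")) == 0

    def test_record_without_reactions_is_skipped_and_tallied(self, tmp_path):
        rec = {"safetyreportid": "1", "patient": {"reaction": []}}
        path = tmp_path / "skip.json"
        path.write_text(json.dumps({"results": [rec, OPENFDA_RECORD]}))
        rs = read_reports(path, "openfda_json")
        assert len(rs) == 1
        assert rs.skipped_no_reactions == 1

    def test_ndjson_form_is_accepted(self, tmp_path):
        path = tmp_path / "reports.ndjson"
        path.write_text("\n".join(json.dumps(OPENFDA_RECORD) for _ in range(3)))
        assert len(read_reports(path, "openfda_json")) == 3

    def test_unparseable_file_names_the_location(self, tmp_path):
        path = tmp_path / "bad.ndjson"
        path.write_text('{"safetyreportid": "1"}\n{not json')
        with pytest.raises(ReportIOError, match="line 2"):
            read_reports(path, "openfda_json")

    def test_unknown_fields_stay_unknown(self, tmp_path):
        rec = {
            "safetyreportid": "7",
            "patient": {"reaction": [{"reactionmeddrapt": "Rash"}]},
        }
        path = tmp_path / "minimal.json"
        path.write_text(json.dumps({"results": [rec]}))
        r = read_reports(path, "openfda_json")[0]
        assert r.sex is Sex.UNKNOWN
        assert r.reporter is Reporter.UNKNOWN
        assert r.age_years is None and r.country is None
        assert r.receive_date is None and r.outcomes == set()


# hypothesis strategy for arbitrary valid reports (dialect-expressible values)
_names = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz ", min_size=1, max_size=12
).map(lambda s: s.strip() or "x")
_mentions = st.builds(
    DrugMention,
    role=st.sampled_from(list(DrugRole)),
    generic_name=st.none() | _names,
    raw_product_name=st.none() | _names,
)
_reports = st.builds(
    AdverseEventReport,
    report_id=st.uuids().map(str),
    reactions=st.lists(_names, min_size=1, max_size=4),
    drugs=st.lists(_mentions, max_size=3),
    receive_date=st.none() | st.dates(dt.date(2004, 1, 1), dt.date(2021, 12, 31)),
    reporter=st.sampled_from(list(Reporter)),
    country=st.none() | st.sampled_from(["US", "FR", "JP"]),
    sex=st.sampled_from(list(Sex)),
    age_years=st.none() | st.floats(0, 119).map(lambda x: round(x, 1)),
    outcomes=st.sets(st.sampled_from([o for o in Outcome if o is not Outcome.UNKNOWN])),
)


@pytest.mark.parametrize("dialect", ["openfda_json", "flat_table"])
@given(reports=st.lists(_reports, max_size=5))
def test_write_read_round_trip(tmp_path_factory, dialect, reports):
    """Any valid ReportSet survives write→read field-identically."""
    rs = ReportSet(reports)
    path = tmp_path_factory.mktemp("rt") / "reports.dat"
    write_reports(rs, path, dialect)
    back = read_reports(path, dialect)
    assert len(back) == len(rs)
    for orig, re_read in zip(rs, back):
        assert re_read.report_id == orig.report_id
        assert re_read.reactions == orig.reactions
        assert re_read.drugs == orig.drugs
        assert re_read.receive_date == orig.receive_date
        assert re_read.reporter == orig.reporter
        assert re_read.country == orig.country
        assert re_read.sex == orig.sex
        assert re_read.age_years == orig.age_years
        assert re_read.outcomes == orig.outcomes


class TestDeduplication:
    def test_latest_receive_date_wins(self):
        old = make_report("A", date=dt.date(2019, 1, 1), suspects=["x"])
        new = make_report("A", date=dt.date(2020, 1, 1), suspects=["y"])
        rs = deduplicate_reports(ReportSet([old, new]))
        assert len(rs) == 1 and rs[0].drugs[0].generic_name == "y"
        rs = deduplicate_reports(ReportSet([new, old]))
        assert len(rs) == 1 and rs[0].drugs[0].generic_name == "y"

    def test_distinct_ids_pass_through(self):
        rs = ReportSet([make_report(f"R{i}") for i in range(5)])
        assert deduplicate_reports(rs).reports == rs.reports

    def test_equal_dates_keep_last_occurrence(self):
        copies = [make_report("A", suspects=[f"v{i}"]) for i in range(3)]
        rs = deduplicate_reports(ReportSet(copies))
        assert len(rs) == 1 and rs[0].drugs[0].generic_name == "v2"

    @given(ids=st.lists(st.sampled_from("abc"), max_size=8))
    def test_idempotent(self, ids):
        rs = ReportSet([make_report(i + str(k % 2)) for k, i in enumerate(ids)])
        once = deduplicate_reports(rs)
        twice = deduplicate_reports(once)
        assert once.reports == twice.reports
        assert len({r.report_id for r in once}) == len(once)


class TestValidation:
    def test_empty_reactions_rejected(self):
        with pytest.raises(ValueError, match="no reactions"):
            AdverseEventReport(report_id="R", reactions=[])

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="age_years"):
            make_report(age_years=150.0)
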