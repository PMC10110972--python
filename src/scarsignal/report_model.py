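"""Domain types and I/O for spontaneous adverse-event reports.

The in-memory model mirrors the fields of the openFDA drug-event record that
matter for culprit-drug signal detection: reaction preferred terms (PTs),
drug mentions with their reported role, and the demographics/outcome fields
used in descriptive summaries.  Two serializations are supported:

* ``openfda_json`` — the openFDA drug-event dialect (a ``{"results": [...]}``
  array or newline-delimited JSON records) restricted to the modeled fields.
* ``flat_table`` — a UTF-8 tab-delimited table with one row per
  (report, drug, reaction), convenient for fixtures and spreadsheets.

Unknown or missing source values are always represented explicitly (``None``,
``Sex.UNKNOWN``, ...) — the readers never invent defaults.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "DrugRole",
    "Reporter",
    "Sex",
    "Outcome",
    "PTTerm",
    "DrugMention",
    "AdverseEventReport",
    "ReportSet",
    "ReportIOError",
    "read_reports",
    "write_reports",
    "deduplicate_reports",
]


class ReportIOError(Exception):
    """Raised when a report file cannot be parsed or written."""


class DrugRole(enum.Enum):
    """Reported role of a drug in an adverse event (``drugcharacterization``)."""

    PRIMARY_SUSPECT = "primary_suspect"  # dialect code 1
    CONCOMITANT = "concomitant"          # dialect code 2
    INTERACTING = "interacting"          # dialect code 3
    UNKNOWN = "unknown"

    @classmethod
    def from_code(cls, code: object) -> "DrugRole":
        try:
            value = int(str(code))
        except (TypeError, ValueError):
            return cls.UNKNOWN
        return _ROLE_BY_CODE.get(value, cls.UNKNOWN)

    @property
    def code(self) -> int:
        """Dialect code; 0 stands for unknown."""
        return {_r: c for c, _r in _ROLE_BY_CODE.items()}.get(self, 0)


_ROLE_BY_CODE = {
    1: DrugRole.PRIMARY_SUSPECT,
    2: DrugRole.CONCOMITANT,
    3: DrugRole.INTERACTING,
}


class Reporter(enum.Enum):
    HEALTH_PROFESSIONAL = "health_professional"
    CONSUMER_OR_LAWYER = "consumer_or_lawyer"
    UNKNOWN = "unknown"


class Sex(enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class Outcome(enum.Enum):
    DEATH = "death"
    LIFE_THREATENING = "life_threatening"
    HOSPITALIZATION = "hospitalization"
    DISABILITY = "disability"
    CONGENITAL_ANOMALY = "congenital_anomaly"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PTTerm:
    """A MedDRA preferred term: display name plus 8-digit numeric code."""

    name: str
    code: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("PTTerm.name must be nonempty")
        if not 10_000_000 <= self.code <= 99_999_999:
            raise ValueError(f"PTTerm.code {self.code} is not an 8-digit MedDRA code")


@dataclass(frozen=True)
class DrugMention:
    """One drug record inside a report.

    ``generic_name`` is the openFDA-normalized ingredient name and may be
    absent; ``raw_product_name`` is the verbatim product string as reported.
    """

    role: DrugRole
    generic_name: str | None = None
    raw_product_name: str | None = None


@dataclass
class AdverseEventReport:
    """One spontaneous adverse-event report."""

    report_id: str
    reactions: list[str]
    drugs: list[DrugMention] = field(default_factory=list)
    receive_date: dt.date | None = None
    reporter: Reporter = Reporter.UNKNOWN
    country: str | None = None
    sex: Sex = Sex.UNKNOWN
    age_years: float | None = None
    outcomes: set[Outcome] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be nonempty")
        if not self.reactions:
            raise ValueError(f"report {self.report_id!r} has no reactions")
        if self.age_years is not None and not 0 <= self.age_years < 150:
            raise ValueError(
                f"report {self.report_id!r}: age_years {self.age_years} out of range"
            )


@dataclass
class ReportSet:
    """An ordered collection of reports with provenance and reader bookkeeping."""

    reports: list[AdverseEventReport] = field(default_factory=list)
    provenance: str = ""
    skipped_no_reactions: int = 0

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[AdverseEventReport]:
        return iter(self.reports)

    def __getitem__(self, i):
        return self.reports[i]


# --------------------------------------------------------------------------
# openFDA drug-event dialect
# --------------------------------------------------------------------------

_QUALIFICATION_TO_REPORTER = {
    1: Reporter.HEALTH_PROFESSIONAL,  # physician
    2: Reporter.HEALTH_PROFESSIONAL,  # pharmacist
    3: Reporter.HEALTH_PROFESSIONAL,  # other health professional
    4: Reporter.CONSUMER_OR_LAWYER,   # lawyer
    5: Reporter.CONSUMER_OR_LAWYER,   # consumer / non-health professional
}
_REPORTER_TO_QUALIFICATION = {
    Reporter.HEALTH_PROFESSIONAL: "1",
    Reporter.CONSUMER_OR_LAWYER: "5",
}

# patientonsetageunit codes → factor converting to years
_AGE_UNIT_TO_YEARS = {800: 10.0, 801: 1.0, 802: 1 / 12, 803: 7 / 365.25, 804: 1 / 365.25}

_OUTCOME_FLAGS = [
    ("seriousnessdeath", Outcome.DEATH),
    ("seriousnesslifethreatening", Outcome.LIFE_THREATENING),
    ("seriousnesshospitalization", Outcome.HOSPITALIZATION),
    ("seriousnessdisabling", Outcome.DISABILITY),
    ("seriousnesscongenitalanomali", Outcome.CONGENITAL_ANOMALY),
    ("seriousnessother", Outcome.OTHER),
]


def _parse_int(value: object) -> int | None:
    try:
        return int(str(value))
    except (TypeError, ValueError):
        return None


def _report_from_openfda(rec: dict, index: int) -> AdverseEventReport | None:
    """Build a report from one openFDA record; None if it has no reactions."""
    patient = rec.get("patient") or {}

    reactions = [
        r["reactionmeddrapt"]
        for r in patient.get("reaction") or []
        if isinstance(r, dict) and r.get("reactionmeddrapt")
    ]
    if not reactions:
        return None

    drugs: list[DrugMention] = []
    for d in patient.get("drug") or []:
        if not isinstance(d, dict):
            continue
        generic = None
        openfda = d.get("openfda") or {}
        gn = openfda.get("generic_name")
        if isinstance(gn, list) and gn:
            generic = str(gn[0])
        elif isinstance(gn, str) and gn:
            generic = gn
        drugs.append(
            DrugMention(
                role=DrugRole.from_code(d.get("drugcharacterization")),
                generic_name=generic,
                raw_product_name=d.get("medicinalproduct") or None,
            )
        )

    receive_date = None
    raw_date = rec.get("receivedate")
    if raw_date:
        try:
            receive_date = dt.datetime.strptime(str(raw_date), "%Y%m%d").date()
        except ValueError:
            receive_date = None

    qualification = _parse_int((rec.get("primarysource") or {}).get("qualification"))
    reporter = _QUALIFICATION_TO_REPORTER.get(qualification, Reporter.UNKNOWN)

    sex_code = _parse_int(patient.get("patientsex"))
    sex = {1: Sex.MALE, 2: Sex.FEMALE}.get(sex_code, Sex.UNKNOWN)

    age_years = None
    raw_age = patient.get("patientonsetage")
    if raw_age is not None:
        try:
            age_value = float(raw_age)
        except (TypeError, ValueError):
            age_value = None
        unit = _parse_int(patient.get("patientonsetageunit"))
        factor = _AGE_UNIT_TO_YEARS.get(unit if unit is not None else 801)
        if age_value is not None and factor is not None:
            candidate = age_value * factor
            if 0 <= candidate < 150:
                age_years = candidate

    outcomes = {o for flag, o in _OUTCOME_FLAGS if str(rec.get(flag, "")) == "1"}

    country = rec.get("occurcountry") or rec.get("primarysourcecountry") or None

    report_id = str(rec.get("safetyreportid") or "")
    if not report_id:
        raise ReportIOError(f"record {index}: missing safetyreportid")

    return AdverseEventReport(
        report_id=report_id,
        reactions=reactions,
        drugs=drugs,
        receive_date=receive_date,
        reporter=reporter,
        country=country,
        sex=sex,
        age_years=age_years,
        outcomes=outcomes,
    )


def _report_to_openfda(report: AdverseEventReport) -> dict:
    rec: dict = {"safetyreportid": report.report_id}
    if report.receive_date is not None:
        rec["receivedate"] = report.receive_date.strftime("%Y%m%d")
    qual = _REPORTER_TO_QUALIFICATION.get(report.reporter)
    if qual is not None:
        rec["primarysource"] = {"qualification": qual}
    if report.country is not None:
        rec["occurcountry"] = report.country
    for flag, outcome in _OUTCOME_FLAGS:
        if outcome in report.outcomes:
            rec[flag] = "1"

    patient: dict = {}
    if report.sex is not Sex.UNKNOWN:
        patient["patientsex"] = "1" if report.sex is Sex.MALE else "2"
    if report.age_years is not None:
        patient["patientonsetage"] = repr(report.age_years)
        patient["patientonsetageunit"] = "801"
    patient["reaction"] = [{"reactionmeddrapt": r} for r in report.reactions]
    drug_recs = []
    for m in report.drugs:
        d: dict = {"drugcharacterization": str(m.role.code)}
        if m.raw_product_name is not None:
            d["medicinalproduct"] = m.raw_product_name
        if m.generic_name is not None:
            d["openfda"] = {"generic_name": [m.generic_name]}
        drug_recs.append(d)
    patient["drug"] = drug_recs
    rec["patient"] = patient
    return rec


def _load_openfda_records(path: Path) -> list[dict]:
    text = path.read_text(encoding="utf-8")
    stripped = text.strip()
    if not stripped:
        return []
    # results-array / bare-list form first, then newline-delimited JSON
    try:
        doc = json.loads(stripped)
    except json.JSONDecodeError:
        doc = None
    if isinstance(doc, dict) and isinstance(doc.get("results"), list):
        return doc["results"]
    if isinstance(doc, list):
        return doc
    if isinstance(doc, dict):
        return [doc]
    records = []
    for lineno, line in enumerate(stripped.splitlines(), start=1):
        if not line.strip():
            continue
        try:
            records.append(json.loads(line))
        except json.JSONDecodeError as exc:
            raise ReportIOError(
                f"{path}: unparseable JSON at line {lineno}, column {exc.colno}"
            ) from exc
    return records


# --------------------------------------------------------------------------
# flat tab-delimited dialect
# --------------------------------------------------------------------------

_FLAT_COLUMNS = [
    "record_index",
    "report_id",
    "receive_date",
    "reporter",
    "country",
    "sex",
    "age_years",
    "outcomes",
    "reaction_index",
    "reaction",
    "drug_index",
    "drug_role",
    "generic_name",
    "raw_product_name",
]


def _flat_rows(report: AdverseEventReport, record_index: int) -> list[dict]:
    base = {
        "record_index": record_index,
        "report_id": report.report_id,
        "receive_date": report.receive_date.isoformat() if report.receive_date else "",
        "reporter": report.reporter.value,
        "country": report.country or "",
        "sex": report.sex.value,
        "age_years": "" if report.age_years is None else repr(report.age_years),
        "outcomes": "|".join(sorted(o.value for o in report.outcomes)),
    }
    rows = []
    drug_slots: list[tuple[int | str, DrugMention | None]] = (
        list(enumerate(report.drugs)) if report.drugs else [("", None)]
    )
    for ri, reaction in enumerate(report.reactions):
        for di, mention in drug_slots:
            row = dict(base)
            row["reaction_index"] = ri
            row["reaction"] = reaction
            row["drug_index"] = di
            row["drug_role"] = mention.role.value if mention else ""
            row["generic_name"] = (mention.generic_name or "") if mention else ""
            row["raw_product_name"] = (mention.raw_product_name or "") if mention else ""
            rows.append(row)
    return rows


def _report_from_flat_group(group: pd.DataFrame) -> AdverseEventReport:
    first = group.iloc[0]
    reactions = (
        group[["reaction_index", "reaction"]]
        .drop_duplicates("reaction_index")
        .sort_values("reaction_index", key=lambda s: s.astype(int))["reaction"]
        .tolist()
    )
    drugs = []
    drug_rows = group[group["drug_index"] != ""]
    if not drug_rows.empty:
        drug_rows = drug_rows.drop_duplicates("drug_index").sort_values(
            "drug_index", key=lambda s: s.astype(int)
        )
        for _, row in drug_rows.iterrows():
            drugs.append(
                DrugMention(
                    role=DrugRole(row["drug_role"]),
                    generic_name=row["generic_name"] or None,
                    raw_product_name=row["raw_product_name"] or None,
                )
            )
    return AdverseEventReport(
        report_id=first["report_id"],
        reactions=reactions,
        drugs=drugs,
        receive_date=dt.date.fromisoformat(first["receive_date"])
        if first["receive_date"]
        else None,
        reporter=Reporter(first["reporter"]),
        country=first["country"] or None,
        sex=Sex(first["sex"]),
        age_years=float(first["age_years"]) if first["age_years"] else None,
        outcomes={Outcome(v) for v in first["outcomes"].split("|") if v},
    )


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def read_reports(path: str | Path, dialect: str = "openfda_json") -> ReportSet:
    """Read a report file in the named dialect.

    Records without any reaction are skipped and counted in
    ``ReportSet.skipped_no_reactions`` rather than raising — real FAERS
    extracts contain such records.
    """
    path = Path(path)
    if not path.exists():
        raise ReportIOError(f"{path}: no such file")

    if dialect == "openfda_json":
        records = _load_openfda_records(path)
        reports, skipped = [], 0
        for i, rec in enumerate(records):
            if not isinstance(rec, dict):
                raise ReportIOError(f"{path}: record {i} is not a JSON object")
            report = _report_from_openfda(rec, i)
            if report is None:
                skipped += 1
            else:
                reports.append(report)
        return ReportSet(reports, provenance=str(path), skipped_no_reactions=skipped)

    if dialect == "flat_table":
        try:
            frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        except Exception as exc:  # pandas raises several parser error types
            raise ReportIOError(f"{path}: unparseable flat table ({exc})") from exc
        if frame.empty:
            return ReportSet([], provenance=str(path))
        missing = set(_FLAT_COLUMNS) - set(frame.columns)
        if missing:
            raise ReportIOError(f"{path}: flat table missing columns {sorted(missing)}")
        reports = []
        for _, group in frame.groupby(frame["record_index"].astype(int), sort=True):
            reports.append(_report_from_flat_group(group))
        return ReportSet(reports, provenance=str(path))

    raise ValueError(f"unknown dialect {dialect!r}")


def write_reports(rs: ReportSet, path: str | Path, dialect: str = "openfda_json") -> None:
    """Write a ReportSet so that :func:`read_reports` round-trips every field."""
    path = Path(path)
    if dialect == "openfda_json":
        doc = {"results": [_report_to_openfda(r) for r in rs]}
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return
    if dialect == "flat_table":
        rows: list[dict] = []
        for i, report in enumerate(rs):
            rows.extend(_flat_rows(report, i))
        frame = pd.DataFrame(rows, columns=_FLAT_COLUMNS)
        frame.to_csv(path, sep="\t", index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def deduplicate_reports(rs: ReportSet) -> ReportSet:
    """Collapse reports sharing a ``report_id`` to a single representative.

    Among duplicates the report with the latest ``receive_date`` wins; a
    missing date sorts earliest; exact date ties keep the last occurrence in
    input order.  Output order follows the first occurrence of each id.
    Idempotent by construction.
    """
    best: dict[str, tuple[dt.date, int]] = {}
    chosen: dict[str, AdverseEventReport] = {}
    order: list[str] = []
    for i, report in enumerate(rs):
        key = report.report_id
        date = report.receive_date or dt.date.min
        if key not in best:
            order.append(key)
        if key not in best or (date, i) >= best[key]:
            best[key] = (date, i)
            chosen[key] = report
    return ReportSet(
        [chosen[k] for k in order],
        provenance=rs.provenance,
        skipped_no_reactions=rs.skipped_no_reactions,
    )
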