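"""Patient-chart data model and chart interchange I/O.

The chart model mirrors what a primary-care EMR exposes to rule-based
case-finding: free-text cumulative patient profile (CPP) entries (problem
list and past medical history), dated diagnostic billing events, dated
prescription texts, structured smoking-history records, basic demographics,
a flag for the presence of a pulmonary function test (PFT) on the chart,
and an optional reference label produced by manual chart abstraction.

Charts travel as JSON Lines: one patient per line, dates as ISO "YYYY-MM-DD",
enums as lowercase strings.
"""

from __future__ import annotations

import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

from .errors import ChartParseError, ChartValidationError, CohortIntegrityError


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class CPPSection(str, enum.Enum):
    PROBLEM_LIST = "problem_list"
    PAST_MEDICAL_HISTORY = "past_medical_history"


class PrescriptionStatus(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"
    UNKNOWN = "unknown"


class SmokingStatus(str, enum.Enum):
    CURRENT = "current"
    EX = "ex"
    NON = "non"
    UNSPECIFIED = "unspecified"


class ReferenceLabel(str, enum.Enum):
    """Outcome of manual chart abstraction; ``definite_copd`` is the
    reference standard, everything else counts as reference negative."""

    DEFINITE_COPD = "definite_copd"
    POSSIBLE_COPD = "possible_copd"
    COPD_RULED_OUT = "copd_ruled_out"
    NO_MENTION = "no_mention"


def normalize_billing_code(code: str) -> str:
    """Normalize a diagnostic billing code for comparison.

    Trims whitespace, uppercases, and strips any decimal subcode so that
    subcoded claims ("491.2") match their 3-character stem ("491").
    Idempotent. The original string is retained on the event for audit.
    """
    stem = code.strip().upper()
    if "." in stem:
        stem = stem.split(".", 1)[0]
    return stem


@dataclass(frozen=True)
class CPPEntry:
    section: CPPSection
    text: str = ""
    date: Optional[_dt.date] = None


@dataclass(frozen=True)
class BillingEvent:
    code: str
    date: _dt.date

    @property
    def normalized_code(self) -> str:
        return normalize_billing_code(self.code)


@dataclass(frozen=True)
class Prescription:
    raw_text: str
    date: _dt.date
    status: PrescriptionStatus = PrescriptionStatus.UNKNOWN


@dataclass(frozen=True)
class SmokingRecord:
    status: SmokingStatus
    date: _dt.date


@dataclass
class PatientChart:
    """One patient's EMR content.

    All event dates must be on or after ``birth_date``; lists may be empty.
    A chart without ``reference_label`` can be classified but cannot enter
    evaluation against the reference standard.
    """

    patient_id: str
    birth_date: _dt.date
    sex: Sex = Sex.UNKNOWN
    cpp_entries: list[CPPEntry] = field(default_factory=list)
    billing_events: list[BillingEvent] = field(default_factory=list)
    prescriptions: list[Prescription] = field(default_factory=list)
    smoking_records: list[SmokingRecord] = field(default_factory=list)
    pft_on_chart: bool = False
    reference_label: Optional[ReferenceLabel] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ChartValidationError("patient_id must be a non-empty string")
        self.validate()

    def validate(self) -> None:
        for ev in self.billing_events:
            if not ev.normalized_code:
                raise ChartValidationError(
                    f"{self.patient_id}: billing code empty after normalization"
                )
        for name, dates in (
            ("cpp_entries", [e.date for e in self.cpp_entries if e.date]),
            ("billing_events", [e.date for e in self.billing_events]),
            ("prescriptions", [p.date for p in self.prescriptions]),
            ("smoking_records", [s.date for s in self.smoking_records]),
        ):
            for d in dates:
                if d < self.birth_date:
                    raise ChartValidationError(
                        f"{self.patient_id}: {name} date {d} precedes "
                        f"birth_date {self.birth_date}"
                    )

    def age_at(self, index_date: _dt.date) -> float:
        """Age in years at an index date (365.25-day years)."""
        return (index_date - self.birth_date).days / 365.25

    def latest_event_date(self) -> Optional[_dt.date]:
        dates = (
            [e.date for e in self.cpp_entries if e.date]
            + [e.date for e in self.billing_events]
            + [p.date for p in self.prescriptions]
            + [s.date for s in self.smoking_records]
        )
        return max(dates) if dates else None


# ---------------------------------------------------------------------------
# JSON Lines interchange


def _date(value: object, line: int, fieldname: str) -> _dt.date:
    if not isinstance(value, str):
        raise ChartParseError(line, fieldname, f"expected ISO date string, got {value!r}")
    try:
        return _dt.date.fromisoformat(value)
    except ValueError as exc:
        raise ChartParseError(line, fieldname, str(exc)) from None


def _enum(cls, value: object, line: int, fieldname: str):
    try:
        return cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ChartParseError(
            line, fieldname, f"{value!r} is not one of: {allowed}"
        ) from None


def chart_from_dict(record: dict, line: int = 0) -> PatientChart:
    """Build a PatientChart from a decoded interchange record."""
    if "patient_id" not in record or not record["patient_id"]:
        raise ChartParseError(line, "patient_id", "missing or empty")
    if "birth_date" not in record:
        raise ChartParseError(line, "birth_date", "missing (a valid date of birth is required)")

    cpp = []
    for e in record.get("cpp_entries", []):
        if "section" not in e:
            raise ChartParseError(line, "cpp_entries.section", "missing")
        cpp.append(
            CPPEntry(
                section=_enum(CPPSection, e["section"], line, "cpp_entries.section"),
                text=e.get("text", ""),
                date=_date(e["date"], line, "cpp_entries.date") if e.get("date") else None,
            )
        )
    billing = [
        BillingEvent(code=b.get("code", ""), date=_date(b.get("date"), line, "billing_events.date"))
        for b in record.get("billing_events", [])
    ]
    rx = [
        Prescription(
            raw_text=p.get("raw_text", ""),
            date=_date(p.get("date"), line, "prescriptions.date"),
            status=_enum(PrescriptionStatus, p.get("status", "unknown"), line, "prescriptions.status"),
        )
        for p in record.get("prescriptions", [])
    ]
    smoking = [
        SmokingRecord(
            status=_enum(SmokingStatus, s.get("status"), line, "smoking_records.status"),
            date=_date(s.get("date"), line, "smoking_records.date"),
        )
        for s in record.get("smoking_records", [])
    ]
    label = record.get("reference_label")
    return PatientChart(
        patient_id=str(record["patient_id"]),
        birth_date=_date(record["birth_date"], line, "birth_date"),
        sex=_enum(Sex, record.get("sex", "unknown"), line, "sex"),
        cpp_entries=cpp,
        billing_events=billing,
        prescriptions=rx,
        smoking_records=smoking,
        pft_on_chart=bool(record.get("pft_on_chart", False)),
        reference_label=_enum(ReferenceLabel, label, line, "reference_label") if label else None,
    )


def chart_to_dict(chart: PatientChart) -> dict:
    rec: dict = {
        "patient_id": chart.patient_id,
        "birth_date": chart.birth_date.isoformat(),
        "sex": chart.sex.value,
        "cpp_entries": [
            {
                "section": e.section.value,
                "text": e.text,
                **({"date": e.date.isoformat()} if e.date else {}),
            }
            for e in chart.cpp_entries
        ],
        "billing_events": [
            {"code": b.code, "date": b.date.isoformat()} for b in chart.billing_events
        ],
        "prescriptions": [
            {"raw_text": p.raw_text, "date": p.date.isoformat(), "status": p.status.value}
            for p in chart.prescriptions
        ],
        "smoking_records": [
            {"status": s.status.value, "date": s.date.isoformat()}
            for s in chart.smoking_records
        ],
        "pft_on_chart": chart.pft_on_chart,
    }
    if chart.reference_label is not None:
        rec["reference_label"] = chart.reference_label.value
    return rec


def read_charts(stream: IO[str] | Iterable[str]) -> list[PatientChart]:
    """Read a JSON Lines chart stream into an ordered list of charts.

    Raises :class:`ChartParseError` on a malformed record (naming the line
    and field), :class:`CohortIntegrityError` on duplicate patient ids, and
    :class:`ChartValidationError` on model invariant violations.
    """
    charts: list[PatientChart] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(stream, start=1):
        if not raw.strip():
            continue
        try:
            record = json.loads(raw)
        except json.JSONDecodeError as exc:
            raise ChartParseError(lineno, "<record>", f"invalid JSON: {exc}") from None
        if not isinstance(record, dict):
            raise ChartParseError(lineno, "<record>", "record is not a JSON object")
        chart = chart_from_dict(record, line=lineno)
        if chart.patient_id in seen:
            raise CohortIntegrityError(
                f"duplicate patient_id {chart.patient_id!r} at line {lineno}"
            )
        seen.add(chart.patient_id)
        charts.append(chart)
    return charts


def write_charts(charts: Sequence[PatientChart], stream: IO[str]) -> None:
    """Write charts as JSON Lines (inverse of :func:`read_charts`)."""
    for chart in charts:
        stream.write(json.dumps(chart_to_dict(chart), separators=(",", ":")) + "\n")


def read_charts_path(path) -> list[PatientChart]:
    with open(path, "r", encoding="utf-8") as fh:
        return read_charts(fh)


def write_charts_path(charts: Sequence[PatientChart], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        write_charts(charts, fh)
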