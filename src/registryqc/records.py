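"""Record and event data model with explicit three-valued missingness.

Research-registry fields commonly overload a single NULL to mean both "value
unknown" and "not applicable to this patient", which hides omission errors.
This module de-overloads the empty cell into two distinct missingness states
and builds deterministic, chronologically ordered patient timelines from the
treatment/outcome events in a record.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Sequence

__all__ = [
    "FieldState",
    "FieldValue",
    "EventType",
    "ClinicalEvent",
    "VitalStatus",
    "PatientRecord",
    "Timeline",
    "TimelineEntry",
    "TimelineGap",
    "LoadReport",
    "CohortLoadError",
    "read_cohort",
    "write_cohort",
    "build_timeline",
    "FIELD_VALUE_FIELDS",
    "NA_SENTINEL",
]

#: CSV token that marks a cell as *not applicable* (as opposed to the empty
#: cell, which means *unknown*).
NA_SENTINEL = "NA!"


class FieldState(str, enum.Enum):
    PRESENT = "present"
    UNKNOWN = "unknown"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class FieldValue:
    """A field payload together with its missingness state.

    ``value`` is defined iff ``state`` is :attr:`FieldState.PRESENT`.  The two
    missing states are distinct values that never compare equal to any present
    payload.
    """

    state: FieldState
    value: Any = None

    def __post_init__(self) -> None:
        if self.state is FieldState.PRESENT:
            if self.value is None:
                raise ValueError("present FieldValue requires a value")
        elif self.value is not None:
            raise ValueError(f"{self.state.value} FieldValue must carry no value")

    @classmethod
    def present(cls, value: Any) -> "FieldValue":
        return cls(FieldState.PRESENT, value)

    @classmethod
    def unknown(cls) -> "FieldValue":
        return cls(FieldState.UNKNOWN)

    @classmethod
    def not_applicable(cls) -> "FieldValue":
        return cls(FieldState.NOT_APPLICABLE)

    @property
    def is_present(self) -> bool:
        return self.state is FieldState.PRESENT

    def render(self) -> str:
        """Canonical display string (``UNKNOWN`` / ``N/A`` markers)."""
        if self.state is FieldState.UNKNOWN:
            return "UNKNOWN"
        if self.state is FieldState.NOT_APPLICABLE:
            return "N/A"
        if isinstance(self.value, dt.date):
            return self.value.isoformat()
        return str(self.value)


class EventType(str, enum.Enum):
    SURGERY = "surgery"
    XRT_START = "xrt_start"
    XRT_END = "xrt_end"
    CHEMO_START = "chemo_start"
    CHEMO_END = "chemo_end"
    RELAPSE = "relapse"
    REMISSION = "remission"
    FOLLOW_UP = "follow_up"
    DEATH = "death"


#: Fixed priority for ordering same-date timeline entries.  Any fixed total
#: order makes the timeline deterministic; this one follows a clinically
#: plausible same-day sequence (diagnosis precedes treatment, treatment starts
#: precede outcome events, ends and follow-up come last).
EVENT_TIE_PRIORITY: dict[str, int] = {
    "diagnosis": 0,
    EventType.SURGERY.value: 1,
    EventType.XRT_START.value: 2,
    EventType.CHEMO_START.value: 3,
    EventType.RELAPSE.value: 4,
    EventType.REMISSION.value: 5,
    EventType.XRT_END.value: 6,
    EventType.CHEMO_END.value: 7,
    EventType.FOLLOW_UP.value: 8,
    EventType.DEATH.value: 9,
}


@dataclass(frozen=True)
class ClinicalEvent:
    """A dated treatment or outcome event.

    ``attrs`` carries event-specific payload: surgeries must have a
    ``procedure_code``; radiation starts may have ``planned_duration_days``.
    """

    event_type: EventType
    date: dt.date
    attrs: tuple[tuple[str, Any], ...] = ()
    source_form: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.date, dt.date) or isinstance(self.date, dt.datetime):
            raise TypeError("event date must be a datetime.date")
        if isinstance(self.attrs, dict):  # accept dicts for convenience
            object.__setattr__(self, "attrs", tuple(sorted(self.attrs.items())))
        if self.event_type is EventType.SURGERY and "procedure_code" not in dict(self.attrs):
            raise ValueError("surgery event requires a procedure_code attribute")

    @property
    def attr_map(self) -> dict[str, Any]:
        return dict(self.attrs)


class VitalStatus(str, enum.Enum):
    ALIVE = "alive"
    DIED_FROM_DISEASE = "died_from_disease"
    DIED_OTHER_CAUSE = "died_other_cause"
    UNKNOWN = "unknown"


#: Record attributes stored as :class:`FieldValue`, in schema order.
FIELD_VALUE_FIELDS = (
    "gender",
    "dob",
    "cancer_site",
    "diagnosis_date",
    "tumor_grade",
    "t_stage",
    "relapse_date",
)

_DATE_FIELDS = {"dob", "diagnosis_date", "relapse_date"}


@dataclass
class PatientRecord:
    """One research-database record: demographics, diagnosis, events, outcome."""

    record_id: str
    gender: FieldValue = field(default_factory=FieldValue.unknown)
    dob: FieldValue = field(default_factory=FieldValue.unknown)
    cancer_site: FieldValue = field(default_factory=FieldValue.unknown)
    diagnosis_date: FieldValue = field(default_factory=FieldValue.unknown)
    tumor_grade: FieldValue = field(default_factory=FieldValue.unknown)
    t_stage: FieldValue = field(default_factory=FieldValue.unknown)
    vital_status: VitalStatus = VitalStatus.UNKNOWN
    relapse_date: FieldValue = field(default_factory=FieldValue.unknown)
    remission_documented: bool = False
    events: list[ClinicalEvent] = field(default_factory=list)
    is_new: bool = False

    def events_of(self, *types: EventType) -> list[ClinicalEvent]:
        wanted = set(types)
        return sorted(
            (e for e in self.events if e.event_type in wanted),
            key=lambda e: (e.date, EVENT_TIE_PRIORITY[e.event_type.value]),
        )

    def copy(self) -> "PatientRecord":
        return replace(self, events=list(self.events))


@dataclass(frozen=True)
class TimelineEntry:
    date: dt.date
    event_type: str  # EventType value or "diagnosis"
    label: str


@dataclass(frozen=True)
class TimelineGap:
    start: dt.date
    end: dt.date
    span_days: int


@dataclass(frozen=True)
class Timeline:
    entries: tuple[TimelineEntry, ...]
    gaps: tuple[TimelineGap, ...]


class CohortLoadError(Exception):
    """Hard failure while loading a cohort file (e.g. missing record_id)."""


@dataclass
class LoadReport:
    """Per-load bookkeeping: row counts, skipped rows, synchronization notes."""

    rows_read: int = 0
    rows_rejected: int = 0
    errors: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# serialization helpers

def _encode_field(fv: FieldValue) -> str:
    if fv.state is FieldState.UNKNOWN:
        return ""
    if fv.state is FieldState.NOT_APPLICABLE:
        return NA_SENTINEL
    if isinstance(fv.value, dt.date):
        return fv.value.isoformat()
    return str(fv.value)


def _decode_field(cell: str, name: str) -> FieldValue:
    cell = cell.strip()
    if cell == "":
        return FieldValue.unknown()
    if cell == NA_SENTINEL:
        return FieldValue.not_applicable()
    if name in _DATE_FIELDS:
        return FieldValue.present(dt.date.fromisoformat(cell))
    return FieldValue.present(cell)


_RECORD_COLUMNS = [
    "record_id",
    *FIELD_VALUE_FIELDS[:6],
    "vital_status",
    "relapse_date",
    "remission_documented",
    "is_new",
]
_EVENT_COLUMNS = [
    "record_id",
    "event_type",
    "date",
    "procedure_code",
    "planned_duration_days",
    "source_form",
]


def _events_path(path: Path) -> Path:
    return path.with_suffix(".events.csv")


def _record_to_row(rec: PatientRecord) -> dict[str, str]:
    row = {"record_id": rec.record_id}
    for name in FIELD_VALUE_FIELDS:
        row[name] = _encode_field(getattr(rec, name))
    row["vital_status"] = rec.vital_status.value
    row["remission_documented"] = "true" if rec.remission_documented else "false"
    row["is_new"] = "true" if rec.is_new else "false"
    return row


def _event_to_row(rec_id: str, ev: ClinicalEvent) -> dict[str, str]:
    attrs = ev.attr_map
    return {
        "record_id": rec_id,
        "event_type": ev.event_type.value,
        "date": ev.date.isoformat(),
        "procedure_code": str(attrs.get("procedure_code", "")),
        "planned_duration_days": str(attrs.get("planned_duration_days", "")),
        "source_form": ev.source_form,
    }


def _event_from_fields(fields: dict[str, Any]) -> ClinicalEvent:
    etype = EventType(fields["event_type"])
    date = dt.date.fromisoformat(str(fields["date"]))
    attrs: dict[str, Any] = {}
    code = fields.get("procedure_code")
    if code not in (None, ""):
        attrs["procedure_code"] = str(code)
    dur = fields.get("planned_duration_days")
    if dur not in (None, ""):
        attrs["planned_duration_days"] = int(dur)
    return ClinicalEvent(
        event_type=etype,
        date=date,
        attrs=tuple(sorted(attrs.items())),
        source_form=str(fields.get("source_form", "") or ""),
    )


def _synchronize_relapse(rec: PatientRecord, report: LoadReport) -> None:
    """Keep the relapse-date field and the relapse events consistent.

    The date field and the clinical fact of relapse are one concept: when only
    one side of the pair is recorded at load time, the other is materialized
    and the reconciliation is noted in the load report.
    """
    relapse_events = rec.events_of(EventType.RELAPSE)
    if rec.relapse_date.is_present:
        d = rec.relapse_date.value
        if not any(e.date == d for e in relapse_events):
            rec.events.append(ClinicalEvent(EventType.RELAPSE, d, (), "sync"))
            report.notes.append(
                f"{rec.record_id}: relapse event materialized from relapse_date {d.isoformat()}"
            )
    elif relapse_events and rec.relapse_date.state is FieldState.UNKNOWN:
        first = relapse_events[0].date
        rec.relapse_date = FieldValue.present(first)
        report.notes.append(
            f"{rec.record_id}: relapse_date filled from relapse event {first.isoformat()}"
        )


def _build_record(
    fields: dict[str, Any],
    events: Iterable[ClinicalEvent],
    report: LoadReport,
) -> PatientRecord:
    rid = fields.get("record_id")
    if rid in (None, ""):
        raise CohortLoadError("record with missing record_id")
    rec = PatientRecord(record_id=str(rid))
    for name in FIELD_VALUE_FIELDS:
        setattr(rec, name, _decode_field(str(fields.get(name, "") or ""), name))
    rec.vital_status = VitalStatus(str(fields.get("vital_status") or "unknown"))
    rec.remission_documented = str(fields.get("remission_documented", "false")).lower() in (
        "true",
        "1",
    )
    rec.is_new = str(fields.get("is_new", "false")).lower() in ("true", "1")
    rec.events = sorted(
        events, key=lambda e: (e.date, EVENT_TIE_PRIORITY[e.event_type.value])
    )
    _synchronize_relapse(rec, report)
    return rec


def read_cohort(
    path: str | Path,
    format: str = "csv",
    events_path: str | Path | None = None,
) -> tuple[list[PatientRecord], LoadReport]:
    """Load a cohort from CSV (record file + companion events file) or JSON.

    Empty cells map to *unknown*; the literal ``NA!`` sentinel maps to
    *not applicable*.  Rows with unparseable dates or unknown event types are
    skipped and counted in the returned :class:`LoadReport`; a missing
    ``record_id`` aborts the load with :class:`CohortLoadError`.
    """
    path = Path(path)
    report = LoadReport()
    records: list[PatientRecord] = []

    if format == "json":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        for obj in payload:
            report.rows_read += 1
            try:
                evs = [_event_from_fields(e) for e in obj.get("events", [])]
                records.append(_build_record(obj, evs, report))
            except CohortLoadError:
                raise
            except (ValueError, KeyError) as exc:
                report.rows_rejected += 1
                report.errors.append(f"{obj.get('record_id', '?')}: {exc}")
        return records, report

    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    ev_path = Path(events_path) if events_path is not None else _events_path(path)
    events_by_record: dict[str, list[ClinicalEvent]] = {}
    bad_event_records: set[str] = set()
    if ev_path.exists():
        with open(ev_path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                rid = row.get("record_id", "")
                try:
                    events_by_record.setdefault(rid, []).append(_event_from_fields(row))
                except ValueError as exc:
                    bad_event_records.add(rid)
                    report.errors.append(f"{rid}: bad event row ({exc})")

    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            report.rows_read += 1
            rid = row.get("record_id", "")
            if rid in bad_event_records:
                report.rows_rejected += 1
                continue
            try:
                records.append(
                    _build_record(row, events_by_record.get(rid, []), report)
                )
            except CohortLoadError:
                raise
            except (ValueError, KeyError) as exc:
                report.rows_rejected += 1
                report.errors.append(f"{rid or '?'}: {exc}")
    return records, report


def write_cohort(
    records: Sequence[PatientRecord],
    path: str | Path,
    format: str = "csv",
    events_path: str | Path | None = None,
) -> int:
    """Write a cohort losslessly (all three missingness states survive).

    Returns the number of records written.  CSV output is a record file plus a
    companion ``<stem>.events.csv``; JSON is a single array of objects with a
    nested ``events`` list.
    """
    path = Path(path)
    if format == "json":
        payload = []
        for rec in records:
            obj: dict[str, Any] = _record_to_row(rec)
            obj["events"] = [_event_to_row(rec.record_id, e) for e in rec.events]
            payload.append(obj)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return len(records)

    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_RECORD_COLUMNS)
        writer.writeheader()
        for rec in records:
            writer.writerow(_record_to_row(rec))
    ev_path = Path(events_path) if events_path is not None else _events_path(path)
    with open(ev_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_EVENT_COLUMNS)
        writer.writeheader()
        for rec in records:
            for ev in rec.events:
                writer.writerow(_event_to_row(rec.record_id, ev))
    return len(records)


# ---------------------------------------------------------------------------
# timeline

def _event_label(ev: ClinicalEvent) -> str:
    attrs = ev.attr_map
    base = ev.event_type.value.replace("_", " ")
    if ev.event_type is EventType.SURGERY:
        return f"surgery: {attrs['procedure_code']}"
    if ev.event_type is EventType.XRT_START and "planned_duration_days" in attrs:
        return f"xrt start (planned {attrs['planned_duration_days']} d)"
    return base


def build_timeline(record: PatientRecord, gap_threshold_days: int = 365) -> Timeline:
    """Assemble the chronologically ordered clinical course of one record.

    Entries are all events plus the diagnosis date (when present); same-date
    ties are broken by the fixed event-type priority so that any permutation
    of the input events yields the identical timeline.  Spans between
    consecutive entries strictly exceeding ``gap_threshold_days`` are reported
    as gaps.
    """
    if gap_threshold_days <= 0:
        raise ValueError("gap_threshold_days must be positive")
    raw: list[TimelineEntry] = []
    if record.diagnosis_date.is_present:
        raw.append(
            TimelineEntry(record.diagnosis_date.value, "diagnosis", "diagnosis")
        )
    for ev in record.events:
        raw.append(TimelineEntry(ev.date, ev.event_type.value, _event_label(ev)))
    raw.sort(key=lambda e: (e.date, EVENT_TIE_PRIORITY[e.event_type], e.label))
    gaps: list[TimelineGap] = []
    for prev, nxt in zip(raw, raw[1:]):
        span = (nxt.date - prev.date).days
        if span > gap_threshold_days:
            gaps.append(TimelineGap(prev.date, nxt.date, span))
    return Timeline(entries=tuple(raw), gaps=tuple(gaps))
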