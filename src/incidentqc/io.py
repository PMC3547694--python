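"""Readers and writers for the incident log formats.

Two equivalent on-disk dialects are supported:

* **JSON lines** — one incident per line::

    {"incident_id": "mi-001", "category": "accident",
     "alert_time": "2008-03-01T10:00:00+00:00",
     "events": [{"kind": "declare_major_incident", "minutes": 0.5},
                {"kind": "designate_receiving_hospitals",
                 "time": "2008-03-01T10:07:00+00:00"}],
     "staffing_extent": "ddo_only", "active_minutes": 60,
     "casualties": 5, "receiving_hospitals": 2,
     "hospital_plan_activated": false}

  Each event carries either ``minutes`` (latency from alert) or ``time``
  (absolute ISO 8601, converted to minutes from ``alert_time``); an event
  with neither is a documented decision without a usable timestamp.

* **flat CSV** — one row per event with the incident header columns
  repeated; an incident without events occupies a single row with empty
  event columns.

All absolute times are normalised to UTC on read.  Naive timestamps are
accepted only if the whole record is naive (then read as UTC); mixing
naive and offset-aware times within a record is an error.
"""

from __future__ import annotations

import csv
import datetime
import io as _stdio
import json
from pathlib import Path
from typing import Iterable, TextIO

from .model import (
    DecisionEvent,
    DecisionKind,
    IncidentCategory,
    IncidentRecord,
    StaffingExtent,
)

_CSV_HEADER = [
    "incident_id",
    "category",
    "alert_time",
    "staffing_extent",
    "active_minutes",
    "casualties",
    "receiving_hospitals",
    "hospital_plan_activated",
    "applicable_override",
    "event_kind",
    "event_minutes",
    "event_note",
]


class LogParseError(ValueError):
    """Malformed or invalid incident log input, with the offending line."""

    def __init__(self, line: int, message: str) -> None:
        super().__init__(f"line {line}: {message}")
        self.line = line


def _parse_iso(text: str, line: int, what: str) -> datetime.datetime:
    try:
        return datetime.datetime.fromisoformat(text)
    except ValueError as exc:
        raise LogParseError(line, f"bad {what} timestamp {text!r}: {exc}") from None


def _to_utc(
    dt: datetime.datetime, anchor_aware: bool, line: int, what: str
) -> datetime.datetime:
    aware = dt.tzinfo is not None
    if aware != anchor_aware:
        raise LogParseError(
            line,
            f"{what}: naive and offset-aware timestamps mixed within one record",
        )
    if aware:
        return dt.astimezone(datetime.timezone.utc)
    return dt.replace(tzinfo=datetime.timezone.utc)


def _event_from_mapping(
    obj: dict, alert: datetime.datetime | None, line: int
) -> DecisionEvent:
    kind_raw = obj.get("kind")
    try:
        kind = DecisionKind(kind_raw)
    except ValueError:
        raise LogParseError(line, f"unknown decision kind {kind_raw!r}") from None
    minutes: float | None = None
    if obj.get("minutes") is not None:
        minutes = float(obj["minutes"])
        if minutes < 0:
            raise LogParseError(
                line, f"event {kind.value!r}: negative minutes-from-alert {minutes}"
            )
    elif obj.get("time") is not None:
        if alert is None:
            raise LogParseError(
                line,
                f"event {kind.value!r} has an absolute time but the record "
                "has no alert_time",
            )
        ts = _to_utc(
            _parse_iso(str(obj["time"]), line, "event"),
            alert.tzinfo is not None,
            line,
            f"event {kind.value!r}",
        )
        anchor = (
            alert
            if alert.tzinfo is not None
            else alert.replace(tzinfo=datetime.timezone.utc)
        )
        delta = (ts - anchor).total_seconds()
        if delta < 0:
            raise LogParseError(
                line,
                f"event {kind.value!r}: timestamp precedes the alert "
                f"({delta / 60:.2f} min)",
            )
        # store at one-second resolution
        minutes = round(delta) / 60.0
    return DecisionEvent(kind=kind, minutes=minutes, note=obj.get("note"))


def _record_from_mapping(obj: dict, line: int) -> IncidentRecord:
    try:
        incident_id = str(obj["incident_id"])
        category = IncidentCategory(obj["category"])
        staffing = StaffingExtent(obj.get("staffing_extent", "ddo_only"))
    except KeyError as exc:
        raise LogParseError(line, f"missing required field {exc.args[0]!r}") from None
    except ValueError as exc:
        raise LogParseError(line, str(exc)) from None

    alert: datetime.datetime | None = None
    if obj.get("alert_time") is not None:
        alert = _parse_iso(str(obj["alert_time"]), line, "alert_time")

    events = [_event_from_mapping(e, alert, line) for e in obj.get("events", [])]
    if alert is not None and alert.tzinfo is not None:
        alert = alert.astimezone(datetime.timezone.utc)
    elif alert is not None:
        alert = alert.replace(tzinfo=datetime.timezone.utc)

    try:
        return IncidentRecord(
            incident_id=incident_id,
            category=category,
            alert_time=alert,
            events=events,
            staffing_extent=staffing,
            active_minutes=float(obj.get("active_minutes", 0.0)),
            casualties=None if obj.get("casualties") is None else int(obj["casualties"]),
            receiving_hospitals=(
                None
                if obj.get("receiving_hospitals") is None
                else int(obj["receiving_hospitals"])
            ),
            hospital_plan_activated=obj.get("hospital_plan_activated"),
            applicable_override=obj.get("applicable_override"),
        )
    except ValueError as exc:
        raise LogParseError(line, str(exc)) from None


def _check_unique_ids(records: list[IncidentRecord]) -> None:
    seen: dict[str, int] = {}
    for i, rec in enumerate(records, start=1):
        if rec.incident_id in seen:
            raise LogParseError(
                i, f"duplicate incident_id {rec.incident_id!r}"
            )
        seen[rec.incident_id] = i


def read_jsonl(source: str | Path | TextIO) -> list[IncidentRecord]:
    """Parse a JSON-lines incident log into validated records."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            return read_jsonl(fh)
    records: list[IncidentRecord] = []
    for line_no, line in enumerate(source, start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise LogParseError(line_no, f"invalid JSON: {exc}") from None
        if not isinstance(obj, dict):
            raise LogParseError(line_no, "each line must be a JSON object")
        records.append(_record_from_mapping(obj, line_no))
    _check_unique_ids(records)
    return records


def _record_to_mapping(rec: IncidentRecord) -> dict:
    obj: dict = {
        "incident_id": rec.incident_id,
        "category": rec.category.value,
    }
    if rec.alert_time is not None:
        obj["alert_time"] = rec.alert_time.isoformat()
    obj["events"] = [
        {
            "kind": ev.kind.value,
            **({"minutes": ev.minutes} if ev.minutes is not None else {}),
            **({"note": ev.note} if ev.note is not None else {}),
        }
        for ev in rec.events
    ]
    obj["staffing_extent"] = rec.staffing_extent.value
    obj["active_minutes"] = rec.active_minutes
    for key in ("casualties", "receiving_hospitals", "hospital_plan_activated"):
        val = getattr(rec, key)
        if val is not None:
            obj[key] = val
    if rec.applicable_override is not None:
        obj["applicable_override"] = rec.applicable_override
    return obj


def write_jsonl(records: Iterable[IncidentRecord], dest: str | Path | TextIO) -> None:
    """Write records as JSON lines (one incident per line)."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8") as fh:
            write_jsonl(records, fh)
        return
    for rec in records:
        dest.write(json.dumps(_record_to_mapping(rec)) + "\n")


def read_csv(source: str | Path | TextIO) -> list[IncidentRecord]:
    """Parse the flat CSV dialect (one row per event, headers repeated)."""
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_csv(fh)
    reader = csv.DictReader(source)
    if reader.fieldnames is None:
        return []
    missing = set(_CSV_HEADER[:5]) - set(reader.fieldnames)
    if missing:
        raise LogParseError(1, f"missing CSV columns: {sorted(missing)}")

    grouped: dict[str, dict] = {}
    order: list[str] = []
    for row in reader:
        line = reader.line_num
        iid = row["incident_id"]
        if not iid:
            raise LogParseError(line, "empty incident_id")
        if iid not in grouped:
            obj: dict = {"incident_id": iid, "events": []}
            for col in (
                "category",
                "alert_time",
                "staffing_extent",
                "active_minutes",
                "casualties",
                "receiving_hospitals",
                "hospital_plan_activated",
                "applicable_override",
            ):
                val = row.get(col)
                if val not in (None, ""):
                    if col in ("hospital_plan_activated", "applicable_override"):
                        obj[col] = val.strip().lower() in ("1", "true", "yes")
                    else:
                        obj[col] = val
                else:
                    obj.setdefault(col, None)
            grouped[iid] = obj
            order.append(iid)
        if row.get("event_kind"):
            ev: dict = {"kind": row["event_kind"]}
            if row.get("event_minutes") not in (None, ""):
                ev["minutes"] = float(row["event_minutes"])
            if row.get("event_note") not in (None, ""):
                ev["note"] = row["event_note"]
            grouped[iid]["events"].append(ev)
        grouped[iid].setdefault("_line", line)

    records = [
        _record_from_mapping(grouped[iid], grouped[iid]["_line"]) for iid in order
    ]
    _check_unique_ids(records)
    return records


def write_csv(records: Iterable[IncidentRecord], dest: str | Path | TextIO) -> None:
    """Write records in the flat CSV dialect."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_csv(records, fh)
        return
    writer = csv.writer(dest)
    writer.writerow(_CSV_HEADER)
    for rec in records:
        head = [
            rec.incident_id,
            rec.category.value,
            rec.alert_time.isoformat() if rec.alert_time is not None else "",
            rec.staffing_extent.value,
            rec.active_minutes,
            "" if rec.casualties is None else rec.casualties,
            "" if rec.receiving_hospitals is None else rec.receiving_hospitals,
            "" if rec.hospital_plan_activated is None else rec.hospital_plan_activated,
            "" if rec.applicable_override is None else rec.applicable_override,
        ]
        if not rec.events:
            writer.writerow(head + ["", "", ""])
        for ev in rec.events:
            writer.writerow(
                head
                + [
                    ev.kind.value,
                    "" if ev.minutes is None else ev.minutes,
                    ev.note or "",
                ]
            )


def read_log(path: str | Path) -> list[IncidentRecord]:
    """Read a log file, dispatching on extension (.jsonl/.json vs .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_csv(path)
    return read_jsonl(path)


def loads_jsonl(text: str) -> list[IncidentRecord]:
    """Parse JSON-lines log content from a string."""
    return read_jsonl(_stdio.StringIO(text))
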