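"""Domain model for smart-pump record (SPR) event logs and drug libraries.

A smart infusion pump writes one record for every action it undergoes:
programming an infusion start, raising a dose-limit alert, recording the
clinician's response to that alert, and stopping. Records sharing an
``infusion_id`` describe the life of one bag or syringe; because a bag may be
paused and restarted, the number of infusion-start events is at least the
number of unique infusions.

The canonical interchange format is a flat UTF-8 CSV with one event per row
(see :data:`SPR_COLUMNS`). Drug libraries are CSVs mapping each medication to
its soft/hard minimum/maximum dosing limits in a declared unit; absent limits
are blank cells. Dose limits govern the quantity expressed in ``dose_unit``
(entries in mL/hr are rate-governed).
"""

from __future__ import annotations

import csv
import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DoseUnit",
    "Mode",
    "EventType",
    "AlertType",
    "ResponseAction",
    "SmartPumpRecord",
    "DrugLibraryEntry",
    "InfusionRecord",
    "AlertEvent",
    "SPRError",
    "SPRParseError",
    "SPRValidationError",
    "DrugLibraryError",
    "SPR_COLUMNS",
    "LIBRARY_COLUMNS",
    "read_spr_log",
    "write_spr_log",
    "read_drug_library",
    "write_drug_library",
    "build_infusions",
    "validate_log",
    "records_to_frame",
    "frame_to_records",
]


class SPRError(Exception):
    """Base class for SPR log and library errors."""


class SPRParseError(SPRError):
    """A row of an SPR log file could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class SPRValidationError(SPRError):
    """A record or record sequence violates a domain invariant."""


class DrugLibraryError(SPRError):
    """A drug-library entry or file violates a limit-ordering invariant."""


class DoseUnit(str, Enum):
    MCG_KG_HR = "mcg/kg/hr"
    MCG_KG_MIN = "mcg/kg/min"
    MG_KG_HR = "mg/kg/hr"
    UNITS_KG_HR = "units/kg/hr"
    ML_HR = "mL/hr"


class Mode(str, Enum):
    DERS = "DERS"
    BASIC = "basic"


class EventType(str, Enum):
    INFUSION_START = "infusion_start"
    ALERT = "alert"
    RESPONSE = "response"
    STOP = "stop"


class AlertType(str, Enum):
    SOFT_MIN = "soft_min"
    SOFT_MAX = "soft_max"
    HARD_MIN = "hard_min"
    HARD_MAX = "hard_max"
    NONE = "none"

    @property
    def is_hard(self) -> bool:
        return self in (AlertType.HARD_MIN, AlertType.HARD_MAX)

    @property
    def is_max(self) -> bool:
        return self in (AlertType.SOFT_MAX, AlertType.HARD_MAX)


class ResponseAction(str, Enum):
    OVERRIDE = "override"
    CANCEL = "cancel"
    REPROGRAM = "reprogram"
    NONE = "none"


SPR_COLUMNS = (
    "timestamp",
    "pump_unit_id",
    "module_id",
    "infusion_id",
    "patient_id",
    "drug_name",
    "dose_value",
    "dose_unit",
    "rate_ml_hr",
    "weight_kg",
    "mode",
    "event_type",
    "alert_type",
    "response_action",
)

LIBRARY_COLUMNS = ("drug_name", "dose_unit", "soft_min", "soft_max", "hard_min", "hard_max")


@dataclass(frozen=True)
class SmartPumpRecord:
    """One timestamped pump event.

    Invariants enforced at construction:

    * ``alert_type`` is non-``none`` exactly when ``event_type`` is ``alert``;
    * ``response_action`` is non-``none`` exactly when ``event_type`` is
      ``response``;
    * dose and rate are non-negative, weight is positive.

    Cross-record invariants (non-decreasing timestamps per infusion, basic
    mode never alerting) are checked by :func:`validate_log`.
    """

    timestamp: datetime
    pump_unit_id: str
    module_id: str
    infusion_id: str
    patient_id: str
    drug_name: str
    dose_value: float
    dose_unit: DoseUnit
    rate_ml_hr: float
    weight_kg: float
    mode: Mode
    event_type: EventType
    alert_type: AlertType = AlertType.NONE
    response_action: ResponseAction = ResponseAction.NONE

    def __post_init__(self) -> None:
        if self.dose_value < 0:
            raise SPRValidationError(f"dose_value must be non-negative, got {self.dose_value}")
        if self.rate_ml_hr < 0:
            raise SPRValidationError(f"rate_ml_hr must be non-negative, got {self.rate_ml_hr}")
        if self.weight_kg <= 0:
            raise SPRValidationError(f"weight_kg must be positive, got {self.weight_kg}")
        is_alert = self.event_type is EventType.ALERT
        if (self.alert_type is not AlertType.NONE) != is_alert:
            raise SPRValidationError(
                f"alert_type={self.alert_type.value!r} inconsistent with "
                f"event_type={self.event_type.value!r}"
            )
        is_response = self.event_type is EventType.RESPONSE
        if (self.response_action is not ResponseAction.NONE) != is_response:
            raise SPRValidationError(
                f"response_action={self.response_action.value!r} inconsistent with "
                f"event_type={self.event_type.value!r}"
            )


@dataclass(frozen=True)
class DrugLibraryEntry:
    """Soft/hard dosing limits for one medication, in ``dose_unit``.

    Any limit may be absent (``None``); absent limits never alert. Roughly
    60% of entries in a typical neonatal library carry a hard maximum, so a
    missing ``hard_max`` is the norm rather than the exception.
    """

    drug_name: str
    dose_unit: DoseUnit
    soft_min: float | None = None
    soft_max: float | None = None
    hard_min: float | None = None
    hard_max: float | None = None

    def __post_init__(self) -> None:
        for name in ("soft_min", "soft_max", "hard_min", "hard_max"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DrugLibraryError(f"{self.drug_name}: {name} must be non-negative, got {v}")
        pairs = [
            ("hard_min", self.hard_min, "soft_min", self.soft_min),
            ("soft_min", self.soft_min, "soft_max", self.soft_max),
            ("soft_max", self.soft_max, "hard_max", self.hard_max),
            ("hard_min", self.hard_min, "hard_max", self.hard_max),
        ]
        for lo_name, lo, hi_name, hi in pairs:
            if lo is not None and hi is not None and lo > hi:
                raise DrugLibraryError(
                    f"{self.drug_name}: {lo_name}={lo} exceeds {hi_name}={hi}"
                )
        if self.soft_max is not None and self.soft_max <= 0:
            raise DrugLibraryError(f"{self.drug_name}: soft_max must be positive")
        if self.hard_max is not None and self.hard_max <= 0:
            raise DrugLibraryError(f"{self.drug_name}: hard_max must be positive")


@dataclass
class InfusionRecord:
    """All events belonging to one bag/syringe (one ``infusion_id``)."""

    infusion_id: str
    patient_id: str
    drug_name: str
    mode: Mode
    events: list[SmartPumpRecord] = field(default_factory=list)

    @property
    def n_starts(self) -> int:
        return sum(1 for e in self.events if e.event_type is EventType.INFUSION_START)

    @property
    def n_alerts(self) -> int:
        return sum(1 for e in self.events if e.event_type is EventType.ALERT)


@dataclass
class AlertEvent:
    """A threshold violation together with its (eventual) resolution.

    ``resolved_response`` is ``None`` for alerts left unresolved at the end of
    a truncated log; hard-limit alerts, when resolved, are always cancelled
    because the pump forces cancellation.
    """

    record: SmartPumpRecord
    attempted_dose: float
    violated_limit: float
    resolved_response: ResponseAction | None = None
    resolution_timestamp: datetime | None = None

    def __post_init__(self) -> None:
        if self.record.event_type is not EventType.ALERT:
            raise SPRValidationError("AlertEvent requires an alert record")
        if (
            self.record.alert_type.is_hard
            and self.resolved_response is not None
            and self.resolved_response is not ResponseAction.CANCEL
        ):
            raise SPRValidationError(
                f"hard-limit alert resolved by {self.resolved_response.value}; "
                "pumps force cancellation on hard limits"
            )
        if (
            self.resolution_timestamp is not None
            and self.resolution_timestamp < self.record.timestamp
        ):
            raise SPRValidationError("resolution precedes the alert it resolves")


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def _parse_enum(enum_cls, raw: str, column: str):
    value = raw.strip()
    if value == "" and enum_cls in (AlertType, ResponseAction):
        return enum_cls.NONE
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(e.value for e in enum_cls)
        raise SPRValidationError(f"unknown {column} value {raw!r} (allowed: {allowed})")


def _parse_float(raw: str, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise SPRValidationError(f"cannot parse {column} value {raw!r} as a number")


def _record_from_row(row: Mapping[str, str]) -> SmartPumpRecord:
    try:
        ts = datetime.fromisoformat(row["timestamp"])
    except ValueError:
        raise SPRValidationError(f"cannot parse timestamp {row['timestamp']!r} as ISO-8601")
    return SmartPumpRecord(
        timestamp=ts,
        pump_unit_id=row["pump_unit_id"],
        module_id=row["module_id"],
        infusion_id=row["infusion_id"],
        patient_id=row["patient_id"],
        drug_name=row["drug_name"],
        dose_value=_parse_float(row["dose_value"], "dose_value"),
        dose_unit=_parse_enum(DoseUnit, row["dose_unit"], "dose_unit"),
        rate_ml_hr=_parse_float(row["rate_ml_hr"], "rate_ml_hr"),
        weight_kg=_parse_float(row["weight_kg"], "weight_kg"),
        mode=_parse_enum(Mode, row["mode"], "mode"),
        event_type=_parse_enum(EventType, row["event_type"], "event_type"),
        alert_type=_parse_enum(AlertType, row["alert_type"], "alert_type"),
        response_action=_parse_enum(ResponseAction, row["response_action"], "response_action"),
    )


def read_spr_log(path: str | Path, validate_sequence: bool = True) -> list[SmartPumpRecord]:
    """Read an SPR log CSV into an ordered list of records.

    Row order is preserved. Raises :class:`SPRParseError` (naming the line)
    for malformed rows and :class:`SPRValidationError` for sequence-level
    invariant violations when ``validate_sequence`` is true.
    """
    path = Path(path)
    records: list[SmartPumpRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != SPR_COLUMNS:
            raise SPRParseError(
                f"unexpected header {reader.fieldnames!r}; expected {list(SPR_COLUMNS)}", line=1
            )
        for row in reader:
            if None in row or any(v is None for v in row.values()):
                raise SPRParseError("wrong number of fields", line=reader.line_num)
            try:
                records.append(_record_from_row(row))
            except SPRValidationError as exc:
                raise SPRParseError(str(exc), line=reader.line_num) from exc
    if validate_sequence:
        validate_log(records)
    return records


def _enum_cell(value: Enum) -> str:
    return "" if value.value == "none" else value.value


def write_spr_log(records: Iterable[SmartPumpRecord], path: str | Path) -> None:
    """Write records to the canonical CSV dialect (lossless round trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SPR_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.timestamp.isoformat(),
                    r.pump_unit_id,
                    r.module_id,
                    r.infusion_id,
                    r.patient_id,
                    r.drug_name,
                    repr(r.dose_value),
                    r.dose_unit.value,
                    repr(r.rate_ml_hr),
                    repr(r.weight_kg),
                    r.mode.value,
                    r.event_type.value,
                    _enum_cell(r.alert_type),
                    _enum_cell(r.response_action),
                ]
            )


def validate_log(records: Sequence[SmartPumpRecord]) -> None:
    """Check cross-record invariants of an ordered log.

    * timestamps are non-decreasing within each infusion_id;
    * a basic-mode infusion never alerts (basic mode bypasses every safety
      feature of the pump except volume to be infused).
    """
    last_ts: dict[str, datetime] = {}
    modes: dict[str, Mode] = {}
    for i, r in enumerate(records):
        prev = last_ts.get(r.infusion_id)
        if prev is not None and r.timestamp < prev:
            raise SPRValidationError(
                f"record {i}: timestamp goes backwards within infusion {r.infusion_id!r}"
            )
        last_ts[r.infusion_id] = r.timestamp
        mode = modes.setdefault(r.infusion_id, r.mode)
        if r.mode is not mode:
            raise SPRValidationError(
                f"record {i}: infusion {r.infusion_id!r} changes mode mid-log"
            )
        if mode is Mode.BASIC and r.event_type is EventType.ALERT:
            raise SPRValidationError(
                f"record {i}: basic-mode infusion {r.infusion_id!r} has an alert"
            )


def build_infusions(records: Sequence[SmartPumpRecord]) -> list[InfusionRecord]:
    """Group an ordered log into one :class:`InfusionRecord` per infusion_id.

    Grouping keeps within-infusion event order and first-seen infusion order,
    so it is stable under re-interleaving of events across distinct infusions.
    A response event with no preceding unresolved alert in its infusion is
    retained but logged as a consistency warning.
    """
    groups: "OrderedDict[str, InfusionRecord]" = OrderedDict()
    open_alerts: dict[str, int] = {}
    for r in records:
        rec = groups.get(r.infusion_id)
        if rec is None:
            rec = InfusionRecord(
                infusion_id=r.infusion_id,
                patient_id=r.patient_id,
                drug_name=r.drug_name,
                mode=r.mode,
            )
            groups[r.infusion_id] = rec
            open_alerts[r.infusion_id] = 0
        rec.events.append(r)
        if r.event_type is EventType.ALERT:
            open_alerts[r.infusion_id] += 1
        elif r.event_type is EventType.RESPONSE:
            if open_alerts[r.infusion_id] == 0:
                logger.warning(
                    "infusion %s: response event with no preceding alert (retained)",
                    r.infusion_id,
                )
            else:
                open_alerts[r.infusion_id] -= 1
    return list(groups.values())


# ---------------------------------------------------------------------------
# Drug library I/O
# ---------------------------------------------------------------------------

def read_drug_library(path: str | Path) -> dict[str, DrugLibraryEntry]:
    """Read a drug-library CSV into a mapping drug_name -> entry.

    Blank limit cells are absent limits. Duplicate drug names and limit
    orderings such as soft_max > hard_max raise :class:`DrugLibraryError`.
    """
    path = Path(path)
    library: dict[str, DrugLibraryEntry] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or tuple(reader.fieldnames) != LIBRARY_COLUMNS:
            raise DrugLibraryError(
                f"unexpected header {reader.fieldnames!r}; expected {list(LIBRARY_COLUMNS)}"
            )
        for row in reader:
            name = row["drug_name"].strip()
            if name in library:
                raise DrugLibraryError(f"duplicate drug_name {name!r}")

            def limit(col: str) -> float | None:
                raw = (row[col] or "").strip()
                if raw == "":
                    return None
                try:
                    return float(raw)
                except ValueError:
                    raise DrugLibraryError(f"{name}: cannot parse {col} value {raw!r}")

            library[name] = DrugLibraryEntry(
                drug_name=name,
                dose_unit=_parse_enum(DoseUnit, row["dose_unit"], "dose_unit"),
                soft_min=limit("soft_min"),
                soft_max=limit("soft_max"),
                hard_min=limit("hard_min"),
                hard_max=limit("hard_max"),
            )
    return library


def write_drug_library(library: Mapping[str, DrugLibraryEntry], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LIBRARY_COLUMNS)
        for entry in library.values():
            writer.writerow(
                [
                    entry.drug_name,
                    entry.dose_unit.value,
                    *(
                        "" if v is None else repr(v)
                        for v in (entry.soft_min, entry.soft_max, entry.hard_min, entry.hard_max)
                    ),
                ]
            )


# ---------------------------------------------------------------------------
# DataFrame bridge (canonical in-memory container for the metrics layer)
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[SmartPumpRecord]) -> pd.DataFrame:
    """Convert a record list to a DataFrame with one row per event.

    Enumerations become their string values; timestamps become
    ``datetime64[ns]``. Row order matches record order.
    """
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime([r.timestamp for r in records]),
            "pump_unit_id": [r.pump_unit_id for r in records],
            "module_id": [r.module_id for r in records],
            "infusion_id": [r.infusion_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "drug_name": [r.drug_name for r in records],
            "dose_value": [r.dose_value for r in records],
            "dose_unit": [r.dose_unit.value for r in records],
            "rate_ml_hr": [r.rate_ml_hr for r in records],
            "weight_kg": [r.weight_kg for r in records],
            "mode": [r.mode.value for r in records],
            "event_type": [r.event_type.value for r in records],
            "alert_type": [r.alert_type.value for r in records],
            "response_action": [r.response_action.value for r in records],
        },
        columns=list(SPR_COLUMNS),
    )


def frame_to_records(frame: pd.DataFrame) -> list[SmartPumpRecord]:
    """Convert a DataFrame in the canonical dialect back to records."""
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SmartPumpRecord(
                timestamp=row.timestamp.to_pydatetime()
                if hasattr(row.timestamp, "to_pydatetime")
                else row.timestamp,
                pump_unit_id=row.pump_unit_id,
                module_id=row.module_id,
                infusion_id=row.infusion_id,
                patient_id=row.patient_id,
                drug_name=row.drug_name,
                dose_value=float(row.dose_value),
                dose_unit=DoseUnit(row.dose_unit),
                rate_ml_hr=float(row.rate_ml_hr),
                weight_kg=float(row.weight_kg),
                mode=Mode(row.mode),
                event_type=EventType(row.event_type),
                alert_type=AlertType(row.alert_type),
                response_action=ResponseAction(row.response_action),
            )
        )
    return records
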