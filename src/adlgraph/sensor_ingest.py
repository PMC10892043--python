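"""Parse raw smart-home sensor streams and segment them into events.

A smart home emits two kinds of raw time series. *Signal* devices (motion,
door/drawer/cabinet, panic) report boolean state transitions as
(old_value, new_value) pairs: a 0→1 transition opens an interval and the
next 1→0 transition closes it. *Consumption* devices (wall plugs) report
instantaneous wattage; an appliance is considered in use while its draw is
at or above a configurable threshold (5 W by default), and each excursion
above the threshold is one consumption event.

The module also applies a validity normalization: implausibly long signal
events (e.g., a cabinet that never quite closed, so the sensor missed the
closing transition) are truncated to a configurable maximum duration and
flagged as unterminated.
"""

from __future__ import annotations

import csv
import json
import logging
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence, Union

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .timeutil import add_seconds, format_instant, parse_instant, seconds_between

logger = logging.getLogger(__name__)


class IngestError(ValueError):
    """Raised for malformed readings, registry mismatches or contract breaches."""


class DeviceKind(str, Enum):
    motion = "motion"
    door = "door"
    panic = "panic"
    wall_plug = "wall_plug"


#: kinds whose devices emit boolean Signal readings (everything but wall plugs)
SIGNAL_KINDS = frozenset({DeviceKind.motion, DeviceKind.door, DeviceKind.panic})


class DeviceRecord(BaseModel):
    """One row of the installed-device registry."""

    model_config = {"frozen": True}

    device_id: str
    name: str
    kind: DeviceKind
    room: str

    @property
    def is_signal(self) -> bool:
        return self.kind in SIGNAL_KINDS


class DeviceRegistry(BaseModel):
    """The set of devices installed in the home, indexed by id and by name."""

    devices: tuple[DeviceRecord, ...]

    @model_validator(mode="after")
    def _unique(self) -> "DeviceRegistry":
        ids = [d.device_id for d in self.devices]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate device_id in registry")
        names = [d.name for d in self.devices]
        if len(set(names)) != len(names):
            raise ValueError("duplicate device name in registry")
        return self

    def __iter__(self):
        return iter(self.devices)

    def __len__(self) -> int:
        return len(self.devices)

    def by_id(self, device_id: str) -> DeviceRecord:
        for d in self.devices:
            if d.device_id == device_id:
                return d
        raise IngestError(f"unknown device_id {device_id!r} (not in registry)")

    def by_name(self, name: str) -> DeviceRecord:
        for d in self.devices:
            if d.name == name:
                return d
        raise IngestError(f"unknown device name {name!r} (not in registry)")

    def __contains__(self, device_id: str) -> bool:
        return any(d.device_id == device_id for d in self.devices)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeviceRegistry":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or []
        return cls(devices=tuple(DeviceRecord(**row) for row in raw))

    def to_yaml(self, path: str | Path) -> None:
        rows = [d.model_dump(mode="json") for d in self.devices]
        with open(path, "w") as fh:
            yaml.safe_dump(rows, fh, sort_keys=True)


class SignalPayload(BaseModel):
    model_config = {"frozen": True}

    old_value: Literal[0, 1]
    new_value: Literal[0, 1]


class ConsumptionPayload(BaseModel):
    model_config = {"frozen": True}

    watts: float = Field(ge=0.0)


class RawReading(BaseModel):
    """One timestamped datum from one device."""

    model_config = {"frozen": True}

    device_id: str
    timestamp: datetime
    payload: Union[SignalPayload, ConsumptionPayload]

    @field_validator("timestamp")
    @classmethod
    def _utc(cls, v: datetime) -> datetime:
        return parse_instant(v)


class SignalEvent(BaseModel):
    """A closed interval during which a signal device was active/open.

    ``terminated`` is False when the closing transition was never observed
    and the end was synthesized (stream end or plausibility truncation).
    """

    model_config = {"frozen": True}

    device_id: str
    start: datetime
    end: datetime
    terminated: bool = True

    @model_validator(mode="after")
    def _ordered(self) -> "SignalEvent":
        if self.end < self.start:
            raise ValueError("event end precedes start")
        return self

    @property
    def duration_s(self) -> float:
        return seconds_between(self.start, self.end)


class ConsumptionEvent(BaseModel):
    """An interval during which an appliance drew at least threshold watts."""

    model_config = {"frozen": True}

    device_id: str
    start: datetime
    end: datetime
    max_watts: float
    mean_watts: float

    @model_validator(mode="after")
    def _ordered(self) -> "ConsumptionEvent":
        if self.end < self.start:
            raise ValueError("event end precedes start")
        return self

    @property
    def duration_s(self) -> float:
        return seconds_between(self.start, self.end)


SensorEvent = Union[SignalEvent, ConsumptionEvent]


class IngestConfig(BaseModel):
    """Segmentation policy knobs.

    consumption_threshold_watts
        Minimum draw marking an appliance as in use. Readings at or above
        the threshold are "on"; strictly below is idle.
    unterminated_policy
        What to do with a 0→1 transition never followed by 1→0.
    max_plausible_signal_duration_s
        Signal events longer than this are treated as sensor false
        negatives (a closing transition that was never reported) and
        truncated.
    """

    consumption_threshold_watts: float = Field(default=5.0, gt=0.0)
    unterminated_policy: Literal["close_at_stream_end", "drop"] = "close_at_stream_end"
    max_plausible_signal_duration_s: float = Field(default=7200.0, gt=0.0)


# ---------------------------------------------------------------------------
# reading I/O

_CSV_COLUMNS = ("device_id", "timestamp", "old_value", "new_value", "watts")


def _build_reading(
    row: Mapping[str, object], registry: DeviceRegistry, where: str
) -> RawReading:
    device_id = str(row.get("device_id") or "")
    if not device_id:
        raise IngestError(f"{where}: missing device_id")
    device = registry.by_id(device_id)

    ts_raw = row.get("timestamp")
    try:
        timestamp = parse_instant(str(ts_raw))
    except ValueError as exc:
        raise IngestError(f"{where}: {exc}") from exc

    def _cell(key: str) -> str | None:
        v = row.get(key)
        if v is None:
            return None
        s = str(v).strip()
        return s or None

    old_v, new_v, watts = _cell("old_value"), _cell("new_value"), _cell("watts")
    if device.is_signal:
        if old_v is None or new_v is None or watts is not None:
            raise IngestError(
                f"{where}: device {device_id!r} is a {device.kind.value} sensor "
                "and must carry old_value/new_value (and no watts)"
            )
        if old_v not in {"0", "1"} or new_v not in {"0", "1"}:
            raise IngestError(f"{where}: signal values must be 0 or 1")
        payload: SignalPayload | ConsumptionPayload = SignalPayload(
            old_value=int(old_v), new_value=int(new_v)
        )
    else:
        if watts is None or old_v is not None or new_v is not None:
            raise IngestError(
                f"{where}: device {device_id!r} is a wall plug and must carry "
                "watts (and no old/new values)"
            )
        try:
            w = float(watts)
        except ValueError as exc:
            raise IngestError(f"{where}: unparseable wattage {watts!r}") from exc
        if w < 0:
            raise IngestError(f"{where}: negative wattage {w}")
        payload = ConsumptionPayload(watts=w)
    return RawReading(device_id=device_id, timestamp=timestamp, payload=payload)


def read_readings(path: str | Path, registry: DeviceRegistry) -> list[RawReading]:
    """Read raw readings from CSV or JSON-lines, sorted by (device, time).

    CSV files must carry the header ``device_id,timestamp,old_value,
    new_value,watts`` with unused cells left empty; JSON-lines objects use
    the same keys. Readings for devices absent from the registry, or whose
    payload does not match the device kind, are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IngestError(f"no such file: {path}")
    readings: list[RawReading] = []
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            unknown = set(reader.fieldnames) - set(_CSV_COLUMNS)
            if unknown:
                raise IngestError(f"{path}: unexpected columns {sorted(unknown)}")
            for lineno, row in enumerate(reader, start=2):
                readings.append(_build_reading(row, registry, f"{path}:{lineno}"))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise IngestError(f"{path}:{lineno}: invalid JSON") from exc
                readings.append(_build_reading(row, registry, f"{path}:{lineno}"))
    readings.sort(key=lambda r: (r.device_id, r.timestamp))
    return readings


# ---------------------------------------------------------------------------
# segmentation


def _check_one_device(readings: Sequence[RawReading]) -> None:
    ids = {r.device_id for r in readings}
    if len(ids) > 1:
        raise IngestError(f"readings span multiple devices: {sorted(ids)}")
    for a, b in zip(readings, readings[1:]):
        if b.timestamp < a.timestamp:
            raise IngestError("readings are not time-ordered")


def extract_signal_events(
    readings: Sequence[RawReading],
    config: IngestConfig,
    stream_end: datetime | None = None,
) -> list[SignalEvent]:
    """Pair 0→1 / 1→0 transitions of one signal device into events.

    Readings with old_value == new_value are no-ops and discarded. Repeated
    identical transitions (0→1 while already open) are ignored with a
    warning, since the pairing rule assumes alternation. An interval still
    open at the end of the stream is handled per ``unterminated_policy``:
    closed at ``stream_end`` (default: the last reading's timestamp) with
    ``terminated=False``, or dropped.
    """
    _check_one_device(readings)
    events: list[SignalEvent] = []
    open_start: datetime | None = None
    for r in readings:
        if not isinstance(r.payload, SignalPayload):
            raise IngestError(f"non-signal payload for device {r.device_id!r}")
        old, new = r.payload.old_value, r.payload.new_value
        if old == new:
            continue  # no state change
        if new == 1:
            if open_start is not None:
                logger.warning(
                    "device %s: repeated 0->1 at %s ignored (already open)",
                    r.device_id,
                    format_instant(r.timestamp),
                )
                continue
            open_start = r.timestamp
        else:
            if open_start is None:
                logger.warning(
                    "device %s: 1->0 at %s without a prior opening ignored",
                    r.device_id,
                    format_instant(r.timestamp),
                )
                continue
            events.append(
                SignalEvent(
                    device_id=r.device_id,
                    start=open_start,
                    end=r.timestamp,
                    terminated=True,
                )
            )
            open_start = None
    if open_start is not None and config.unterminated_policy == "close_at_stream_end":
        end = stream_end if stream_end is not None else readings[-1].timestamp
        if end < open_start:
            end = open_start
        events.append(
            SignalEvent(
                device_id=readings[-1].device_id,
                start=open_start,
                end=end,
                terminated=False,
            )
        )
    return events


def extract_consumption_events(
    readings: Sequence[RawReading], config: IngestConfig
) -> list[ConsumptionEvent]:
    """Segment one wall plug's wattage series into consumption events.

    An event opens at the first reading at or above the threshold while
    idle and closes at the first subsequent reading strictly below it (the
    sub-threshold reading's timestamp is the event end). Max/mean wattage
    are computed over the in-event (>= threshold) readings. An event still
    open at stream end is closed at the last reading's timestamp.
    """
    _check_one_device(readings)
    thr = config.consumption_threshold_watts
    events: list[ConsumptionEvent] = []
    start: datetime | None = None
    in_watts: list[float] = []
    for r in readings:
        if not isinstance(r.payload, ConsumptionPayload):
            raise IngestError(f"non-consumption payload for device {r.device_id!r}")
        w = r.payload.watts
        if w < 0:
            raise IngestError(f"negative wattage {w} for device {r.device_id!r}")
        if start is None:
            if w >= thr:
                start = r.timestamp
                in_watts = [w]
        else:
            if w < thr:
                events.append(
                    ConsumptionEvent(
                        device_id=r.device_id,
                        start=start,
                        end=r.timestamp,
                        max_watts=max(in_watts),
                        mean_watts=sum(in_watts) / len(in_watts),
                    )
                )
                start = None
                in_watts = []
            else:
                in_watts.append(w)
    if start is not None:
        events.append(
            ConsumptionEvent(
                device_id=readings[-1].device_id,
                start=start,
                end=readings[-1].timestamp,
                max_watts=max(in_watts),
                mean_watts=sum(in_watts) / len(in_watts),
            )
        )
    return events


def normalize_events(
    events: Sequence[SensorEvent], config: IngestConfig
) -> list[SensorEvent]:
    """Apply validity normalization to one device's events.

    Signal events longer than ``max_plausible_signal_duration_s`` are
    assumed to be unreported closings (false negatives) and truncated to
    that duration with ``terminated=False``. Everything else passes
    through unchanged.
    """
    out: list[SensorEvent] = []
    for ev in events:
        if (
            isinstance(ev, SignalEvent)
            and ev.duration_s > config.max_plausible_signal_duration_s
        ):
            out.append(
                SignalEvent(
                    device_id=ev.device_id,
                    start=ev.start,
                    end=add_seconds(ev.start, config.max_plausible_signal_duration_s),
                    terminated=False,
                )
            )
        else:
            out.append(ev)
    return out


def extract_all_events(
    readings: Iterable[RawReading],
    registry: DeviceRegistry,
    config: IngestConfig | None = None,
    stream_end: datetime | None = None,
) -> list[SensorEvent]:
    """Segment a mixed multi-device stream into normalized events.

    Convenience wrapper: groups readings per device, dispatches to the
    signal or consumption extractor by device kind, normalizes, and
    returns all events sorted by (start, device_id).
    """
    config = config or IngestConfig()
    per_device: dict[str, list[RawReading]] = {}
    for r in readings:
        per_device.setdefault(r.device_id, []).append(r)
    events: list[SensorEvent] = []
    for device_id in sorted(per_device):
        device = registry.by_id(device_id)
        rs = sorted(per_device[device_id], key=lambda r: r.timestamp)
        if device.is_signal:
            evs: list[SensorEvent] = list(
                extract_signal_events(rs, config, stream_end=stream_end)
            )
        else:
            evs = list(extract_consumption_events(rs, config))
        events.extend(normalize_events(evs, config))
    events.sort(key=lambda e: (e.start, e.device_id))
    return events


# ---------------------------------------------------------------------------
# event I/O (JSON-lines, byte-stable for fixed input)


def _event_to_json(ev: SensorEvent) -> dict:
    d: dict = {
        "device_id": ev.device_id,
        "start": format_instant(ev.start),
        "end": format_instant(ev.end),
    }
    if isinstance(ev, SignalEvent):
        d["kind"] = "signal"
        d["terminated"] = ev.terminated
    else:
        d["kind"] = "consumption"
        d["max_watts"] = round(ev.max_watts, 3)
        d["mean_watts"] = round(ev.mean_watts, 3)
    return d


def write_events_jsonl(events: Iterable[SensorEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(_event_to_json(ev), sort_keys=True) + "\n")


def read_events_jsonl(path: str | Path) -> list[SensorEvent]:
    events: list[SensorEvent] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith('{"_meta"'):
                continue
            d = json.loads(line)
            if d["kind"] == "signal":
                events.append(
                    SignalEvent(
                        device_id=d["device_id"],
                        start=parse_instant(d["start"]),
                        end=parse_instant(d["end"]),
                        terminated=d["terminated"],
                    )
                )
            else:
                events.append(
                    ConsumptionEvent(
                        device_id=d["device_id"],
                        start=parse_instant(d["start"]),
                        end=parse_instant(d["end"]),
                        max_watts=d["max_watts"],
                        mean_watts=d["mean_watts"],
                    )
                )
    return events
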