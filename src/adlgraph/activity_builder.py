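"""Compose sensor events into observations and ADL activities.

An *observation* wraps one sensor event with the feature of interest its
device measures (motion presence, door state, panic state, power
consumption). Observations are then clustered into named activities using
protocol templates: for each template, observations on member devices (or
motion in the template's room) are chained while consecutive starts are
within ``max_gap_s``, and a cluster becomes an activity only if it contains
at least one trigger-device observation — the appliance that distinguishes
the task (cooker for a hot meal, kettle for a hot beverage, toaster for a
cold meal). This replaces manual inspection of the raw streams with a
deterministic, template-driven recognizer; it assumes a single occupant.
"""

from __future__ import annotations

import json
import re
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

from .sensor_ingest import (
    ConsumptionEvent,
    DeviceKind,
    DeviceRegistry,
    SensorEvent,
    SignalEvent,
)
from .timeutil import epoch_ms, format_instant, parse_instant, seconds_between


class FeatureOfInterest(str, Enum):
    MotionFeature = "MotionFeature"
    DoorFeature = "DoorFeature"
    PanicFeature = "PanicFeature"
    ConsumptionFeature = "ConsumptionFeature"


KIND_TO_FEATURE = {
    DeviceKind.motion: FeatureOfInterest.MotionFeature,
    DeviceKind.door: FeatureOfInterest.DoorFeature,
    DeviceKind.panic: FeatureOfInterest.PanicFeature,
    DeviceKind.wall_plug: FeatureOfInterest.ConsumptionFeature,
}

ACTIVITY_NAMES = (
    "Hot Meal Preparation",
    "Hot Beverage Preparation",
    "Cold Meal Preparation",
)


class ObservationRecord(BaseModel):
    model_config = {"frozen": True}

    observation_id: str
    device_id: str
    start: datetime
    end: datetime
    feature_of_interest: FeatureOfInterest
    observed_values: dict[str, object] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _ordered(self) -> "ObservationRecord":
        if self.end < self.start:
            raise ValueError("observation end precedes start")
        return self


class ActivityRecord(BaseModel):
    """A named ADL spanning the observations it consists of."""

    model_config = {"frozen": True}

    pk: str
    name: str
    start: datetime
    end: datetime
    observations: tuple[ObservationRecord, ...] = Field(min_length=1)
    participant_id: str

    @model_validator(mode="after")
    def _span(self) -> "ActivityRecord":
        lo = min(o.start for o in self.observations)
        hi = max(o.end for o in self.observations)
        if self.start != lo or self.end != hi:
            raise ValueError("activity start/end must span its observations")
        return self

    @property
    def duration_s(self) -> float:
        return seconds_between(self.start, self.end)


class ProtocolTemplate(BaseModel):
    """Recognition template for one protocol task."""

    activity_name: str
    room: str
    trigger_devices: frozenset[str]
    member_devices: frozenset[str]
    max_gap_s: float = Field(default=900.0, gt=0.0)
    ordered_protocol: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _subsets(self) -> "ProtocolTemplate":
        if not self.trigger_devices <= self.member_devices:
            raise ValueError("trigger_devices must be a subset of member_devices")
        if not set(self.ordered_protocol) <= self.member_devices:
            raise ValueError("ordered_protocol must be a subset of member_devices")
        return self


class ParticipantRecord(BaseModel):
    model_config = {"frozen": True}

    participant_id: str
    group: Literal["HC", "SCD", "MCI"]


def load_templates_yaml(path: str | Path) -> list[ProtocolTemplate]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [ProtocolTemplate(**row) for row in raw]


def save_templates_yaml(templates: Sequence[ProtocolTemplate], path: str | Path) -> None:
    rows = []
    for t in templates:
        d = t.model_dump(mode="json")
        d["trigger_devices"] = sorted(t.trigger_devices)
        d["member_devices"] = sorted(t.member_devices)
        d["ordered_protocol"] = list(t.ordered_protocol)
        rows.append(d)
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=True)


def load_roster_yaml(path: str | Path) -> list[ParticipantRecord]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [ParticipantRecord(**row) for row in raw]


def save_roster_yaml(roster: Sequence[ParticipantRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump([p.model_dump(mode="json") for p in roster], fh, sort_keys=True)


# ---------------------------------------------------------------------------


def events_to_observations(
    events: Sequence[SensorEvent], registry: DeviceRegistry
) -> list[ObservationRecord]:
    """Wrap each sensor event in an observation with its feature of interest.

    Observation ids are minted deterministically from (device, start), which
    is unique because one device's events never overlap.
    """
    observations: list[ObservationRecord] = []
    for ev in events:
        device = registry.by_id(ev.device_id)
        feature = KIND_TO_FEATURE[device.kind]
        values: dict[str, object] = {
            "start_time": format_instant(ev.start),
            "end_time": format_instant(ev.end),
        }
        if isinstance(ev, SignalEvent):
            values["switch"] = "0->1"
            values["terminated"] = ev.terminated
        elif isinstance(ev, ConsumptionEvent):
            values["max_watts"] = round(ev.max_watts, 3)
            values["mean_watts"] = round(ev.mean_watts, 3)
        observations.append(
            ObservationRecord(
                observation_id=f"{ev.device_id}-{epoch_ms(ev.start)}",
                device_id=ev.device_id,
                start=ev.start,
                end=ev.end,
                feature_of_interest=feature,
                observed_values=values,
            )
        )
    observations.sort(key=lambda o: (o.start, o.observation_id))
    return observations


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "-", name.lower()).strip("-")


def segment_activities(
    observations: Sequence[ObservationRecord],
    templates: Sequence[ProtocolTemplate],
    participant_id: str,
    registry: DeviceRegistry,
) -> list[ActivityRecord]:
    """Cluster one participant's observations into activities.

    For each template, candidate observations (member devices, plus motion
    sensors located in the template's room) are chained whenever
    consecutive starts differ by at most ``max_gap_s``. Chains with at
    least one trigger-device observation become activities. When clusters
    from different templates compete for an observation, the earlier
    cluster wins (ties broken by template order); clusters are re-checked
    after claiming so every observation ends up in at most one activity.
    """
    obs_sorted = sorted(observations, key=lambda o: (o.start, o.observation_id))

    def device(o: ObservationRecord):
        return registry.by_id(o.device_id)

    # raw candidate chains per template
    chains: list[tuple[datetime, int, list[ObservationRecord]]] = []
    for ti, tpl in enumerate(templates):
        cand = [
            o
            for o in obs_sorted
            if device(o).name in tpl.member_devices
            or (device(o).kind == DeviceKind.motion and device(o).room == tpl.room)
        ]
        current: list[ObservationRecord] = []
        for o in cand:
            if current and seconds_between(current[-1].start, o.start) > tpl.max_gap_s:
                chains.append((current[0].start, ti, current))
                current = []
            current.append(o)
        if current:
            chains.append((current[0].start, ti, current))

    chains.sort(key=lambda c: (c[0], c[1]))

    claimed: set[str] = set()
    per_template_count: dict[int, int] = {}
    activities: list[ActivityRecord] = []
    for _, ti, chain in chains:
        tpl = templates[ti]
        kept = [o for o in chain if o.observation_id not in claimed]
        if not kept:
            continue
        if not any(device(o).name in tpl.trigger_devices for o in kept):
            continue
        claimed.update(o.observation_id for o in kept)
        seq = per_template_count.get(ti, 0) + 1
        per_template_count[ti] = seq
        activities.append(
            ActivityRecord(
                pk=f"{participant_id}-{_slug(tpl.activity_name)}-{seq:03d}",
                name=tpl.activity_name,
                start=min(o.start for o in kept),
                end=max(o.end for o in kept),
                observations=tuple(kept),
                participant_id=participant_id,
            )
        )
    activities.sort(key=lambda a: (a.start, a.pk))
    return activities


# ---------------------------------------------------------------------------
# activity / observation I/O


def _obs_to_json(o: ObservationRecord) -> dict:
    return {
        "observation_id": o.observation_id,
        "device_id": o.device_id,
        "start": format_instant(o.start),
        "end": format_instant(o.end),
        "feature_of_interest": o.feature_of_interest.value,
        "observed_values": o.observed_values,
    }


def _obs_from_json(d: dict) -> ObservationRecord:
    return ObservationRecord(
        observation_id=d["observation_id"],
        device_id=d["device_id"],
        start=parse_instant(d["start"]),
        end=parse_instant(d["end"]),
        feature_of_interest=FeatureOfInterest(d["feature_of_interest"]),
        observed_values=d.get("observed_values", {}),
    )


def write_observations_jsonl(
    observations: Sequence[ObservationRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for o in observations:
            fh.write(json.dumps(_obs_to_json(o), sort_keys=True) + "\n")


def read_observations_jsonl(path: str | Path) -> list[ObservationRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith('{"_meta"'):
                continue
            out.append(_obs_from_json(json.loads(line)))
    return out


def write_activities_jsonl(
    activities: Sequence[ActivityRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for a in activities:
            fh.write(
                json.dumps(
                    {
                        "pk": a.pk,
                        "name": a.name,
                        "start": format_instant(a.start),
                        "end": format_instant(a.end),
                        "participant_id": a.participant_id,
                        "observation_ids": [o.observation_id for o in a.observations],
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def read_activities_jsonl(
    path: str | Path, observations: Sequence[ObservationRecord]
) -> list[ActivityRecord]:
    """Rehydrate exported activities, resolving observation ids."""
    index = {o.observation_id: o for o in observations}
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith('{"_meta"'):
                continue
            d = json.loads(line)
            try:
                obs = tuple(index[i] for i in d["observation_ids"])
            except KeyError as exc:
                raise ValueError(
                    f"activity {d['pk']!r} references unknown observation {exc}"
                ) from exc
            out.append(
                ActivityRecord(
                    pk=d["pk"],
                    name=d["name"],
                    start=parse_instant(d["start"]),
                    end=parse_instant(d["end"]),
                    observations=obs,
                    participant_id=d["participant_id"],
                )
            )
    return out
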