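"""Seeded synthetic smart-home streams for a three-group cohort.

No public dataset accompanies this problem domain, so the simulator
emulates the pilot-study conditions: a cohort of healthy controls (HC),
participants with subjective cognitive decline (SCD) and participants
with mild cognitive impairment (MCI) — 13/14/13 by default — who each
perform one "Hot Meal Preparation" session in an instrumented kitchen.
Per-group activity durations follow truncated normals with the published
group means (1782.36 / 2179.81 / 2399 s); per-group step counts follow
rounded normals with means 15.72 / 15.63 / 18.37; divergence from the
cabinet→cooker→fridge protocol order is injected with per-group
probability 0.81 / 0.81 / 1.0.

Every sampled session is returned both as a ground-truth plan and as raw
Signal/Consumption readings: a kitchen motion interval spanning the
activity, door open/close pairs and a cooker wattage excursion for the
protocol steps, and idle wall-plug noise. A plan's ``step_count`` counts
all observations of the resulting activity, including the spanning motion
observation, so the generator emits ``step_count - 1`` device events.
Streams are constructed so the ingest → activity → rules pipeline recovers
the planned duration, step count and divergence flag exactly.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .activity_builder import ParticipantRecord, ProtocolTemplate, save_roster_yaml, save_templates_yaml
from .sensor_ingest import (
    ConsumptionPayload,
    DeviceKind,
    DeviceRecord,
    DeviceRegistry,
    RawReading,
    SignalPayload,
)
from .timeutil import add_seconds, format_instant, parse_instant

GROUPS = ("HC", "SCD", "MCI")

#: first session instant; successive participants get successive days
BASE_START = datetime(2024, 3, 4, 10, 0, 0, tzinfo=timezone.utc)

#: protocol devices of the hot-meal task, in prescribed order
PROTOCOL_ORDER = ("Cabinet (Food)", "Cooker", "Fridge Door1")

#: member devices used to fill non-protocol steps
_NEUTRAL_DEVICES = ("Drawer 1", "Drawer 2", "Cabinet (Utensils)")


class CohortSpec(BaseModel):
    """Study conditions of the simulated cohort.

    Group sizes and the duration/step means mirror the published cohort;
    the spreads (duration sd 400 s, step sd 4) are simulator choices since
    only means were published. ``step_floor`` is 4 so that the motion
    observation plus the three protocol devices are always representable.
    """

    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"HC": 13, "SCD": 14, "MCI": 13}
    )
    duration_mean_s: dict[str, float] = Field(
        default_factory=lambda: {"HC": 1782.36, "SCD": 2179.81, "MCI": 2399.0}
    )
    duration_sd_s: float = Field(default=400.0, gt=0.0)
    duration_floor_s: float = Field(default=300.0, gt=0.0)
    step_mean: dict[str, float] = Field(
        default_factory=lambda: {"HC": 15.72, "SCD": 15.63, "MCI": 18.37}
    )
    step_sd: float = Field(default=4.0, gt=0.0)
    step_floor: int = Field(default=4, ge=4)
    divergence_prob: dict[str, float] = Field(
        default_factory=lambda: {"HC": 0.81, "SCD": 0.81, "MCI": 1.0}
    )
    participation_fraction: float = Field(default=1.0, gt=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "CohortSpec":
        for mapping in (
            self.group_sizes,
            self.duration_mean_s,
            self.step_mean,
            self.divergence_prob,
        ):
            missing = set(GROUPS) - set(mapping)
            if missing:
                raise ValueError(f"missing groups {sorted(missing)}")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if any(m <= 0 for m in self.duration_mean_s.values()):
            raise ValueError("duration means must be > 0")
        if any(not 0.0 <= p <= 1.0 for p in self.divergence_prob.values()):
            raise ValueError("divergence probabilities must be in [0, 1]")
        return self


class GeneratedActivityPlan(BaseModel):
    """Ground truth for one simulated session (round-trip test anchor)."""

    model_config = {"frozen": True}

    participant_id: str
    activity_name: str
    start: datetime
    duration_s: float
    step_count: int
    divergent: bool
    device_order: tuple[str, ...]


def default_registry() -> DeviceRegistry:
    """The installed-device registry of the simulated smart home."""
    rows = [
        ("m1", "Kitchen Motion", DeviceKind.motion, "Kitchen"),
        ("m2", "Living Room Motion", DeviceKind.motion, "Living Room"),
        ("d1", "Cabinet (Food)", DeviceKind.door, "Kitchen"),
        ("d2", "Cabinet (Utensils)", DeviceKind.door, "Kitchen"),
        ("d3", "Drawer 1", DeviceKind.door, "Kitchen"),
        ("d4", "Drawer 2", DeviceKind.door, "Kitchen"),
        ("d5", "Fridge Door1", DeviceKind.door, "Kitchen"),
        ("p1", "Panic Button", DeviceKind.panic, "Living Room"),
        ("w1", "Cooker", DeviceKind.wall_plug, "Kitchen"),
        ("w2", "Kettle", DeviceKind.wall_plug, "Kitchen"),
        ("w3", "Toaster", DeviceKind.wall_plug, "Kitchen"),
    ]
    return DeviceRegistry(
        devices=tuple(
            DeviceRecord(device_id=i, name=n, kind=k, room=r) for i, n, k, r in rows
        )
    )


def default_templates() -> list[ProtocolTemplate]:
    """Recognition templates for the three protocol tasks."""
    kitchen_doors = {
        "Cabinet (Food)",
        "Cabinet (Utensils)",
        "Drawer 1",
        "Drawer 2",
        "Fridge Door1",
    }
    return [
        ProtocolTemplate(
            activity_name="Hot Meal Preparation",
            room="Kitchen",
            trigger_devices=frozenset({"Cooker"}),
            member_devices=frozenset(kitchen_doors | {"Cooker"}),
            max_gap_s=900.0,
            ordered_protocol=PROTOCOL_ORDER,
        ),
        ProtocolTemplate(
            activity_name="Hot Beverage Preparation",
            room="Kitchen",
            trigger_devices=frozenset({"Kettle"}),
            member_devices=frozenset(kitchen_doors | {"Kettle"}),
            max_gap_s=900.0,
        ),
        ProtocolTemplate(
            activity_name="Cold Meal Preparation",
            room="Kitchen",
            trigger_devices=frozenset({"Toaster"}),
            member_devices=frozenset(kitchen_doors | {"Toaster"}),
            max_gap_s=900.0,
        ),
    ]


def generate_cohort(spec: CohortSpec) -> list[ParticipantRecord]:
    """Deterministic roster with exactly the specified group sizes."""
    roster = []
    for group in GROUPS:
        for i in range(spec.group_sizes[group]):
            roster.append(
                ParticipantRecord(
                    participant_id=f"{group.lower()}-{i + 1:02d}", group=group
                )
            )
    return roster


def _sample_duration(rng: np.random.Generator, mean: float, sd: float, floor: float) -> float:
    a = (floor - mean) / sd
    return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def sample_plans(
    roster: Sequence[ParticipantRecord],
    spec: CohortSpec,
    activity_name: str = "Hot Meal Preparation",
) -> list[GeneratedActivityPlan]:
    """Sample one session plan per participating participant."""
    rng = np.random.default_rng(spec.seed)
    plans: list[GeneratedActivityPlan] = []
    for idx, participant in enumerate(roster):
        g = participant.group
        participates = rng.random() < spec.participation_fraction
        duration = round(
            _sample_duration(
                rng, spec.duration_mean_s[g], spec.duration_sd_s, spec.duration_floor_s
            ),
            3,
        )
        steps = max(spec.step_floor, int(round(rng.normal(spec.step_mean[g], spec.step_sd))))
        divergent = bool(rng.random() < spec.divergence_prob[g])
        if not participates:
            continue
        start = add_seconds(BASE_START, idx * 86400.0)
        plans.append(
            GeneratedActivityPlan(
                participant_id=participant.participant_id,
                activity_name=activity_name,
                start=start,
                duration_s=duration,
                step_count=steps,
                divergent=divergent,
                device_order=_device_order(steps - 1, divergent),
            )
        )
    return plans


def _device_order(n_device_steps: int, divergent: bool) -> tuple[str, ...]:
    """Assign devices to the n device-step slots of a session.

    Conformant sessions place Cabinet (Food) first, the Cooker second and
    Fridge Door1 last, so the single protocol combination satisfies
    t_cabinet < t_cooker < t_fridge. Divergent sessions swap the fridge
    before the cabinet — the minimal permutation the order rule detects.
    """
    if n_device_steps < 3:
        raise ValueError("need at least 3 device steps for the protocol devices")
    cabinet, cooker, fridge = PROTOCOL_ORDER
    order: list[str] = [""] * n_device_steps
    if divergent:
        order[0], order[1], order[-1] = fridge, cooker, cabinet
    else:
        order[0], order[1], order[-1] = cabinet, cooker, fridge
    fill = 0
    for i in range(n_device_steps):
        if not order[i]:
            order[i] = _NEUTRAL_DEVICES[fill % len(_NEUTRAL_DEVICES)]
            fill += 1
    return tuple(order)


def _plan_readings(
    plan: GeneratedActivityPlan,
    registry: DeviceRegistry,
    rng: np.random.Generator,
    emit_panic: bool,
) -> list[RawReading]:
    readings: list[RawReading] = []
    t0, dur = plan.start, plan.duration_s
    motion = registry.by_name("Kitchen Motion")

    def sig(device: DeviceRecord, ts, old: int, new: int) -> None:
        readings.append(
            RawReading(
                device_id=device.device_id,
                timestamp=ts,
                payload=SignalPayload(old_value=old, new_value=new),
            )
        )

    def watt(device: DeviceRecord, ts, w: float) -> None:
        readings.append(
            RawReading(
                device_id=device.device_id,
                timestamp=ts,
                payload=ConsumptionPayload(watts=round(w, 1)),
            )
        )

    # motion presence spanning the whole session
    sig(motion, t0, 0, 1)
    sig(motion, add_seconds(t0, dur), 1, 0)

    # device steps at slots 1..S-1 (slot 0 is the motion observation)
    n = len(plan.device_order)
    spacing = min(dur / (n + 1), 850.0)
    for i, name in enumerate(plan.device_order, start=1):
        device = registry.by_name(name)
        ts = add_seconds(t0, round(i * spacing, 3))
        if device.kind == DeviceKind.wall_plug:
            active = float(rng.uniform(800.0, 1500.0))
            cook_end = min(add_seconds(t0, dur - 1.0), add_seconds(ts, 300.0))
            watt(device, ts, active)
            watt(device, cook_end, 0.6)
        else:
            sig(device, ts, 0, 1)
            close = max(ts, min(add_seconds(t0, dur - 0.5), add_seconds(ts, 4.0)))
            sig(device, close, 1, 0)

    # idle wall-plug noise outside the session window
    for plug_name in ("Cooker", "Kettle", "Toaster"):
        watt(registry.by_name(plug_name), add_seconds(t0, -300.0), float(rng.uniform(0.1, 2.0)))

    # occasional no-op panic press, well before the session
    if emit_panic:
        panic = registry.by_name("Panic Button")
        sig(panic, add_seconds(t0, -3600.0), 0, 1)
        sig(panic, add_seconds(t0, -3595.0), 1, 0)

    readings.sort(key=lambda r: (r.device_id, r.timestamp))
    return readings


def generate_streams(
    roster: Sequence[ParticipantRecord],
    spec: CohortSpec,
    templates: Sequence[ProtocolTemplate] | None = None,
) -> tuple[dict[str, list[RawReading]], list[GeneratedActivityPlan]]:
    """Raw readings per participant plus the ground-truth plans."""
    templates = list(templates) if templates is not None else default_templates()
    names = {t.activity_name for t in templates}
    if "Hot Meal Preparation" not in names:
        raise ValueError("templates must include the Hot Meal Preparation task")
    registry = default_registry()
    plans = sample_plans(roster, spec)
    rng = np.random.default_rng(spec.seed + 1)  # wattage/noise stream
    readings: dict[str, list[RawReading]] = {}
    for i, plan in enumerate(plans):
        readings[plan.participant_id] = _plan_readings(
            plan, registry, rng, emit_panic=(i % 7 == 0)
        )
    return readings, plans


# ---------------------------------------------------------------------------
# file export


def write_plans_json(plans: Sequence[GeneratedActivityPlan], path: str | Path) -> None:
    rows = []
    for p in plans:
        d = p.model_dump(mode="json")
        d["start"] = format_instant(p.start)
        d["device_order"] = list(p.device_order)
        rows.append(d)
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_plans_json(path: str | Path) -> list[GeneratedActivityPlan]:
    with open(path) as fh:
        rows = json.load(fh)
    return [
        GeneratedActivityPlan(**{**row, "start": parse_instant(row["start"])})
        for row in rows
    ]


def write_simulation(outdir: str | Path, spec: CohortSpec) -> dict[str, object]:
    """Write a complete simulated study to disk; returns the manifest.

    Produces one readings CSV per participant (the readings schema carries
    no participant column — the home is single-occupancy, one session per
    file), the device registry, roster and templates as YAML, the
    ground-truth plans as JSON, and a manifest mapping participants to
    their readings files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    templates = default_templates()
    roster = generate_cohort(spec)
    readings, plans = generate_streams(roster, spec, templates)

    registry.to_yaml(outdir / "devices.yaml")
    save_templates_yaml(templates, outdir / "templates.yaml")
    save_roster_yaml(roster, outdir / "roster.yaml")
    write_plans_json(plans, outdir / "plans.json")

    readings_dir = outdir / "readings"
    readings_dir.mkdir(exist_ok=True)
    files: dict[str, str] = {}
    for pid, rs in sorted(readings.items()):
        path = readings_dir / f"{pid}.csv"
        with open(path, "w") as fh:
            fh.write("device_id,timestamp,old_value,new_value,watts\n")
            for r in rs:
                if isinstance(r.payload, SignalPayload):
                    fh.write(
                        f"{r.device_id},{format_instant(r.timestamp)},"
                        f"{r.payload.old_value},{r.payload.new_value},\n"
                    )
                else:
                    fh.write(
                        f"{r.device_id},{format_instant(r.timestamp)},,,"
                        f"{r.payload.watts}\n"
                    )
        files[pid] = str(path.relative_to(outdir))
    manifest = {
        "seed": spec.seed,
        "devices": "devices.yaml",
        "templates": "templates.yaml",
        "roster": "roster.yaml",
        "plans": "plans.json",
        "readings": files,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
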