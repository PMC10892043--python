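"""Shared fixtures: device registry, templates, and record factories."""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from adlgraph.activity_builder import (
    ActivityRecord,
    FeatureOfInterest,
    ObservationRecord,
    ParticipantRecord,
)
from adlgraph.problem_rules import RuleConfig
from adlgraph.sensor_ingest import (
    ConsumptionPayload,
    DeviceKind,
    IngestConfig,
    RawReading,
    SignalPayload,
)
from adlgraph.synthetic_data import default_registry, default_templates

T0 = datetime(2024, 3, 4, 10, 0, 0, tzinfo=timezone.utc)


def at(seconds: float) -> datetime:
    """Instant ``seconds`` after the reference origin."""
    return T0 + timedelta(milliseconds=round(seconds * 1000))


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def templates():
    return default_templates()


@pytest.fixture
def ingest_config():
    return IngestConfig()


@pytest.fixture
def rule_config():
    return RuleConfig()


def signal_reading(device_id: str, ts: datetime, old: int, new: int) -> RawReading:
    return RawReading(
        device_id=device_id,
        timestamp=ts,
        payload=SignalPayload(old_value=old, new_value=new),
    )


def watt_reading(device_id: str, ts: datetime, watts: float) -> RawReading:
    return RawReading(
        device_id=device_id, timestamp=ts, payload=ConsumptionPayload(watts=watts)
    )


_FEATURE_BY_KIND = {
    DeviceKind.motion: FeatureOfInterest.MotionFeature,
    DeviceKind.door: FeatureOfInterest.DoorFeature,
    DeviceKind.panic: FeatureOfInterest.PanicFeature,
    DeviceKind.wall_plug: FeatureOfInterest.ConsumptionFeature,
}


def make_observation(registry, device_name: str, start: datetime, dur_s: float = 5.0,
                     suffix: str = "") -> ObservationRecord:
    device = registry.by_name(device_name)
    oid = f"{device.device_id}-{round(start.timestamp() * 1000)}{suffix}"
    return ObservationRecord(
        observation_id=oid,
        device_id=device.device_id,
        start=start,
        end=start + timedelta(milliseconds=round(dur_s * 1000)),
        feature_of_interest=_FEATURE_BY_KIND[device.kind],
    )


def make_activity(
    registry,
    pk: str,
    participant_id: str,
    start: datetime,
    duration_s: float,
    device_steps: list[tuple[str, float]],
    name: str = "Hot Meal Preparation",
) -> tuple[ActivityRecord, list[ObservationRecord]]:
    """An activity spanning [start, start+duration] with the given steps.

    ``device_steps`` are (device name, offset seconds) pairs; a kitchen
    motion observation spanning the whole interval is always included.
    """
    observations = [
        make_observation(registry, "Kitchen Motion", start, duration_s, suffix=f"-{pk}")
    ]
    for i, (dev, offset) in enumerate(device_steps):
        observations.append(
            make_observation(
                registry, dev, start + timedelta(milliseconds=round(offset * 1000)),
                suffix=f"-{pk}-{i}",
            )
        )
    activity = ActivityRecord(
        pk=pk,
        name=name,
        start=min(o.start for o in observations),
        end=max(o.end for o in observations),
        observations=tuple(observations),
        participant_id=participant_id,
    )
    return activity, observations


def random_activity_set(rng: np.random.Generator, registry, n_max: int = 8,
                        obs_max: int = 14):
    """Random activities/observations/participants for oracle-equivalence runs.

    Durations straddle the 2100 s threshold, observation counts straddle
    both step thresholds, and protocol-device placement is shuffled so the
    divergence rule fires on some activities and not others.
    """
    device_pool = [
        "Cabinet (Food)", "Cooker", "Fridge Door1",
        "Drawer 1", "Drawer 2", "Cabinet (Utensils)",
    ]
    activities, observations, participants = [], [], []
    n_act = int(rng.integers(1, n_max + 1))
    for i in range(n_act):
        pid = f"p{int(rng.integers(1, 5)):02d}"
        if pid not in {p.participant_id for p in participants}:
            participants.append(
                ParticipantRecord(
                    participant_id=pid,
                    group=["HC", "SCD", "MCI"][int(rng.integers(0, 3))],
                )
            )
        start = T0 + timedelta(hours=float(i * 24))
        duration = float(rng.uniform(600.0, 3600.0))
        n_obs = int(rng.integers(1, obs_max + 1))
        name = (
            "Hot Meal Preparation" if rng.random() < 0.85 else "Cold Meal Preparation"
        )
        steps = []
        for j in range(n_obs):
            dev = device_pool[int(rng.integers(0, len(device_pool)))]
            offset = float(rng.uniform(1.0, duration - 1.0))
            steps.append((dev, round(offset, 3)))
        act, obs = make_activity(
            registry, f"act-{i:03d}", pid, start, round(duration, 3), steps, name=name
        )
        activities.append(act)
        observations.extend(obs)
    return activities, observations, participants
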