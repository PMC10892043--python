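"""Per-group problem statistics and dashboard-ready exports.

``summarize`` aggregates detected problems into group-level tables: for
each cognitive-status group, the percentage of participants with at least
one problem of each type, plus average activity duration and step count.
The denominator is the number of participants in the group with at least
one activity of the target name (not the group size — participants who
never performed the task cannot be flagged). A participant with several
problems of one type counts once.

``export_dashboard`` emits the three dashboard sections as a pure,
byte-stable JSON bundle: an event log, an activity log and a
problems-over-time series. Rendering is left to a front end.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Sequence

from pydantic import BaseModel, Field

from .activity_builder import ActivityRecord, ParticipantRecord
from .problem_rules import ProblemRecord
from .sensor_ingest import ConsumptionEvent, SensorEvent, SignalEvent
from .timeutil import format_instant

PROBLEM_TYPES = (
    "TooLongDuration",
    "DivergenceFromProtocol",
    "ExtraSteps",
    "MissingSteps",
)

_GROUP_ORDER = ("HC", "SCD", "MCI")


class GroupSummary(BaseModel):
    model_config = {"frozen": True}

    group: str
    n_participants: int
    n_with_activity: int
    problem_pct: dict[str, float] = Field(default_factory=dict)
    avg_duration_s: float = 0.0
    avg_steps: float = 0.0


def summarize(
    problems: Sequence[ProblemRecord],
    activities: Sequence[ActivityRecord],
    roster: Sequence[ParticipantRecord],
    activity_name: str = "Hot Meal Preparation",
) -> list[GroupSummary]:
    """Aggregate problems into one summary row per group (HC, SCD, MCI)."""
    group_of = {p.participant_id: p.group for p in roster}
    for prob in problems:
        if prob.patient_id not in group_of:
            raise ValueError(
                f"problem {prob.problem_iri} references unknown participant "
                f"{prob.patient_id!r}"
            )
    for act in activities:
        if act.participant_id not in group_of:
            raise ValueError(
                f"activity {act.pk!r} references unknown participant "
                f"{act.participant_id!r}"
            )

    target_acts = [a for a in activities if a.name == activity_name]
    active: dict[str, set[str]] = {g: set() for g in _GROUP_ORDER}
    for a in target_acts:
        active[group_of[a.participant_id]].add(a.participant_id)

    # participants flagged at least once, per (group, problem type)
    flagged: dict[tuple[str, str], set[str]] = {}
    for prob in problems:
        key = (group_of[prob.patient_id], prob.type)
        flagged.setdefault(key, set()).add(prob.patient_id)

    summaries = []
    for g in _GROUP_ORDER:
        denom = len(active[g])
        pct = {}
        for t in PROBLEM_TYPES:
            num = len(flagged.get((g, t), set()) & active[g])
            pct[t] = round(100.0 * num / denom, 2) if denom else 0.0
        acts = [a for a in target_acts if group_of[a.participant_id] == g]
        summaries.append(
            GroupSummary(
                group=g,
                n_participants=sum(1 for p in roster if p.group == g),
                n_with_activity=denom,
                problem_pct=pct,
                avg_duration_s=round(sum(a.duration_s for a in acts) / len(acts), 2)
                if acts
                else 0.0,
                avg_steps=round(
                    sum(len(a.observations) for a in acts) / len(acts), 2
                )
                if acts
                else 0.0,
            )
        )
    return summaries


_CSV_COLUMNS = (
    "group",
    "n_participants",
    "n_with_activity",
    "too_long_pct",
    "divergence_pct",
    "extra_steps_pct",
    "missing_steps_pct",
    "avg_duration_s",
    "avg_steps",
)


def write_summary_csv(
    summaries: Sequence[GroupSummary], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for s in summaries:
            writer.writerow(
                [
                    s.group,
                    s.n_participants,
                    s.n_with_activity,
                    f"{s.problem_pct['TooLongDuration']:.2f}",
                    f"{s.problem_pct['DivergenceFromProtocol']:.2f}",
                    f"{s.problem_pct['ExtraSteps']:.2f}",
                    f"{s.problem_pct['MissingSteps']:.2f}",
                    f"{s.avg_duration_s:.2f}",
                    f"{s.avg_steps:.2f}",
                ]
            )


def export_dashboard(
    events: Sequence[tuple[str, SensorEvent]] | Sequence[SensorEvent],
    activities: Sequence[ActivityRecord],
    problems: Sequence[ProblemRecord],
) -> dict:
    """Assemble the three dashboard sections as a plain dict.

    ``events`` may be bare sensor events or (participant_id, event) pairs.
    The output has deterministic ordering and key order, so identical
    inputs serialize to byte-identical JSON.
    """
    event_rows = []
    for item in events:
        pid, ev = item if isinstance(item, tuple) else (None, item)
        row = {
            "device_id": ev.device_id,
            "start": format_instant(ev.start),
            "end": format_instant(ev.end),
            "participant_id": pid,
            "kind": "signal" if isinstance(ev, SignalEvent) else "consumption",
        }
        if isinstance(ev, ConsumptionEvent):
            row["max_watts"] = round(ev.max_watts, 3)
        event_rows.append(row)
    event_rows.sort(key=lambda r: (r["start"], r["device_id"]))

    activity_rows = [
        {
            "pk": a.pk,
            "name": a.name,
            "participant_id": a.participant_id,
            "start": format_instant(a.start),
            "end": format_instant(a.end),
            "duration_s": round(a.duration_s, 3),
            "observation_ids": [o.observation_id for o in a.observations],
        }
        for a in sorted(activities, key=lambda a: (a.start, a.pk))
    ]

    problem_rows = [
        {
            "type": p.type,
            "participant_id": p.patient_id,
            "date": format_instant(p.date),
            "rate": p.rate,
            "activity_pk": p.activity_pk,
        }
        for p in sorted(problems, key=lambda p: (p.date, p.activity_pk, p.type))
    ]

    return {
        "events": event_rows,
        "activities": activity_rows,
        "problems": problem_rows,
    }


def write_dashboard_json(
    bundle: dict, path: str | Path, seed: int | None = None
) -> None:
    doc = dict(bundle)
    if seed is not None:
        doc = {"meta": {"seed": seed}, **bundle}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
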