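"""Rule-based detection of problems in ADL execution.

Four rules, executed as SPARQL CONSTRUCT queries over the knowledge
graph, flag deviations from a normal execution of a target activity:

* **TooLongDuration** — total duration strictly above a threshold
  (default 2100 s, i.e. 35 min).
* **ExtraSteps** — strictly more than a threshold count of distinct
  observations (default 20).
* **MissingSteps** — strictly fewer than a threshold count of distinct
  observations (default 10).
* **DivergenceFromProtocol** — the protocol prescribes opening the food
  cabinet, then the cooker, then the fridge door; the rule fires when the
  activity contains at least one observation on each protocol device and
  some combination of them violates that chronological order.

Each fired rule mints a deterministic problem IRI from (rule, activity
pk), asserts the problem triples back into the graph, and is therefore
idempotent under re-runs. A plain-Python ``brute_force_oracle`` implements
the same four rules as direct loops over activity records; it exists so
the SPARQL engine can be checked against an independent implementation.
"""

from __future__ import annotations

import itertools
from datetime import datetime
from importlib import resources
from string import Template
from typing import Literal as TypingLiteral, Sequence
from urllib.parse import quote

from pydantic import BaseModel, Field, model_validator
from rdflib import Graph, Literal, RDF, URIRef

from .activity_builder import ActivityRecord
from .ontology_kg import (
    ADL,
    RESOURCE_BASE,
    KnowledgeGraph,
    patient_id_from_iri,
)
from .sensor_ingest import DeviceRecord

RULE_ORDER = ("too_long_duration", "extra_steps", "missing_steps", "divergence")

_RULE_CLASS = {
    "too_long_duration": "TooLongDuration",
    "extra_steps": "ExtraSteps",
    "missing_steps": "MissingSteps",
    "divergence": "DivergenceFromProtocol",
}
_CLASS_RULE = {v: k for k, v in _RULE_CLASS.items()}

_RULE_IRI_SEGMENT = {
    "too_long_duration": "too-long-duration",
    "extra_steps": "extra-steps",
    "missing_steps": "missing-steps",
    "divergence": "divergence",
}


class RuleConfig(BaseModel):
    """Thresholds and protocol order for the four problem rules."""

    activity_name: str = "Hot Meal Preparation"
    duration_threshold_s: float = Field(default=2100.0, gt=0.0)
    extra_steps_threshold: int = Field(default=20, gt=0)
    missing_steps_threshold: int = Field(default=10, gt=0)
    protocol_order: tuple[str, ...] = ("Cabinet (Food)", "Cooker", "Fridge Door1")

    @model_validator(mode="after")
    def _consistent(self) -> "RuleConfig":
        if self.missing_steps_threshold > self.extra_steps_threshold:
            raise ValueError("missing_steps_threshold must be <= extra_steps_threshold")
        if len(self.protocol_order) != len(set(self.protocol_order)):
            raise ValueError("protocol_order devices must be distinct")
        return self


class ProblemRecord(BaseModel):
    """One detected problem instance."""

    model_config = {"frozen": True}

    problem_iri: str
    type: TypingLiteral[
        "TooLongDuration", "DivergenceFromProtocol", "ExtraSteps", "MissingSteps"
    ]
    patient_id: str
    date: datetime
    rate: float | int | None = None
    activity_pk: str


def problem_iri(rule: str, activity_pk: str) -> str:
    segment = _RULE_IRI_SEGMENT[rule]
    return f"{RESOURCE_BASE}problem/{segment}/{quote(activity_pk, safe='')}"


# ---------------------------------------------------------------------------
# SPARQL engine


def _sparql_string(value: str) -> str:
    escaped = value.replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def load_query(rule: str, config: RuleConfig) -> str:
    """Load a rule's CONSTRUCT query template and fill in its parameters."""
    if rule not in RULE_ORDER:
        raise ValueError(f"unknown rule {rule!r}")
    text = (
        resources.files("adlgraph.queries").joinpath(f"{rule}.rq").read_text()
    )
    mapping = {
        "activity_name": _sparql_string(config.activity_name),
        "duration_threshold": f"{config.duration_threshold_s:.3f}",
        "extra_steps_threshold": str(config.extra_steps_threshold),
        "missing_steps_threshold": str(config.missing_steps_threshold),
        "resource_base": RESOURCE_BASE,
    }
    if rule == "divergence":
        if len(config.protocol_order) != 3:
            raise ValueError(
                "the shipped divergence query covers a three-device protocol; "
                f"got {len(config.protocol_order)} devices"
            )
        for i, name in enumerate(config.protocol_order, start=1):
            mapping[f"device_{i}"] = _sparql_string(name)
    return Template(text).substitute(mapping)


def _records_from_construct(g: Graph, rule: str) -> list[ProblemRecord]:
    cls = ADL[_RULE_CLASS[rule]]
    records = []
    for prob in g.subjects(RDF.type, cls):
        patient = g.value(prob, ADL.isProblemOf)
        date = g.value(prob, ADL.problem_date)
        rate_lit = g.value(prob, ADL.problem_rate)
        act = g.value(prob, ADL.problematicActivity)
        rate: float | int | None = None
        if rate_lit is not None:
            py = rate_lit.toPython()
            rate = int(py) if rule in ("extra_steps", "missing_steps") else float(py)
        prefix = f"{RESOURCE_BASE}problem/{_RULE_IRI_SEGMENT[rule]}/"
        pk = str(prob)[len(prefix):]
        from urllib.parse import unquote

        records.append(
            ProblemRecord(
                problem_iri=str(prob),
                type=_RULE_CLASS[rule],  # type: ignore[arg-type]
                patient_id=patient_id_from_iri(patient),
                date=date.toPython(),
                rate=rate,
                activity_pk=unquote(pk),
            )
        )
    records.sort(key=lambda r: r.activity_pk)
    return records


def _run_rule(kg: KnowledgeGraph, rule: str, config: RuleConfig) -> tuple[Graph, list[ProblemRecord]]:
    result = kg.query(load_query(rule, config))
    constructed = Graph()
    for t in result:
        constructed.add(t)
    return constructed, _records_from_construct(constructed, rule)


def rule_too_long_duration(kg: KnowledgeGraph, config: RuleConfig) -> list[ProblemRecord]:
    return _run_rule(kg, "too_long_duration", config)[1]


def rule_extra_steps(kg: KnowledgeGraph, config: RuleConfig) -> list[ProblemRecord]:
    return _run_rule(kg, "extra_steps", config)[1]


def rule_missing_steps(kg: KnowledgeGraph, config: RuleConfig) -> list[ProblemRecord]:
    return _run_rule(kg, "missing_steps", config)[1]


def rule_divergence(kg: KnowledgeGraph, config: RuleConfig) -> list[ProblemRecord]:
    return _run_rule(kg, "divergence", config)[1]


def run_rules(
    kg: KnowledgeGraph, config: RuleConfig | None = None
) -> tuple[KnowledgeGraph, list[ProblemRecord]]:
    """Execute all four rules, enrich the graph, and return the problems.

    The constructed problem triples are asserted into ``kg`` (triples are a
    set, so re-running on an enriched graph adds nothing new). Output is
    ordered by (activity pk, rule order).
    """
    config = config or RuleConfig()
    records: list[ProblemRecord] = []
    for rule in RULE_ORDER:
        constructed, recs = _run_rule(kg, rule, config)
        kg.add_triples(constructed)
        records.extend(recs)
    rule_rank = {name: i for i, name in enumerate(RULE_ORDER)}
    records.sort(key=lambda r: (r.activity_pk, rule_rank[_CLASS_RULE[r.type]]))
    return kg, records


# ---------------------------------------------------------------------------
# independent oracle (plain loops; used in tests only)


def write_problems_json(
    problems: Sequence[ProblemRecord], path, seed: int | None = None
) -> None:
    """Serialize problem records deterministically (sorted keys, ms instants)."""
    import json

    from .timeutil import format_instant

    rows = []
    for p in problems:
        rows.append(
            {
                "problem_iri": p.problem_iri,
                "type": p.type,
                "patient_id": p.patient_id,
                "date": format_instant(p.date),
                "rate": p.rate,
                "activity_pk": p.activity_pk,
            }
        )
    doc: dict = {"problems": rows}
    if seed is not None:
        doc = {"meta": {"seed": seed}, "problems": rows}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_problems_json(path) -> list[ProblemRecord]:
    import json

    from .timeutil import parse_instant

    with open(path) as fh:
        doc = json.load(fh)
    return [
        ProblemRecord(**{**row, "date": parse_instant(row["date"])})
        for row in doc["problems"]
    ]


def brute_force_oracle(
    activities: Sequence[ActivityRecord],
    config: RuleConfig | None = None,
    devices: Sequence[DeviceRecord] = (),
) -> list[ProblemRecord]:
    """The four rules as direct filters over activity records (no RDF).

    ``devices`` maps device ids to names for the divergence rule; the
    other rules need only the records themselves.
    """
    config = config or RuleConfig()
    name_of = {d.device_id: d.name for d in devices}
    records: list[ProblemRecord] = []

    for a in activities:
        if a.name != config.activity_name:
            continue
        duration = round(a.duration_s, 3)
        if duration > config.duration_threshold_s:
            records.append(
                ProblemRecord(
                    problem_iri=problem_iri("too_long_duration", a.pk),
                    type="TooLongDuration",
                    patient_id=a.participant_id,
                    date=a.start,
                    rate=duration,
                    activity_pk=a.pk,
                )
            )
        steps = len({o.observation_id for o in a.observations})
        if steps > config.extra_steps_threshold:
            records.append(
                ProblemRecord(
                    problem_iri=problem_iri("extra_steps", a.pk),
                    type="ExtraSteps",
                    patient_id=a.participant_id,
                    date=a.start,
                    rate=steps,
                    activity_pk=a.pk,
                )
            )
        if steps < config.missing_steps_threshold:
            records.append(
                ProblemRecord(
                    problem_iri=problem_iri("missing_steps", a.pk),
                    type="MissingSteps",
                    patient_id=a.participant_id,
                    date=a.start,
                    rate=steps,
                    activity_pk=a.pk,
                )
            )
        # divergence: brute force over all (e1, .., en) combinations
        per_device_starts = [
            [o.start for o in a.observations if name_of.get(o.device_id) == dev]
            for dev in config.protocol_order
        ]
        if all(per_device_starts):
            fires = any(
                not all(t1 < t2 for t1, t2 in zip(combo, combo[1:]))
                for combo in itertools.product(*per_device_starts)
            )
            if fires:
                records.append(
                    ProblemRecord(
                        problem_iri=problem_iri("divergence", a.pk),
                        type="DivergenceFromProtocol",
                        patient_id=a.participant_id,
                        date=a.start,
                        rate=None,
                        activity_pk=a.pk,
                    )
                )

    rule_rank = {name: i for i, name in enumerate(RULE_ORDER)}
    records.sort(key=lambda r: (r.activity_pk, rule_rank[_CLASS_RULE[r.type]]))
    return records
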