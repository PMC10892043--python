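"""End-to-end orchestration: simulate → ingest → build → detect → report.

Shared by the command-line ``demo`` and by scripted analyses. All stages
are deterministic for a fixed cohort seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .activity_builder import (
    ActivityRecord,
    ObservationRecord,
    ParticipantRecord,
    ProtocolTemplate,
    events_to_observations,
    segment_activities,
)
from .ontology_kg import KnowledgeGraph, build_ontology, to_rdf
from .problem_rules import ProblemRecord, RuleConfig, run_rules
from .report import GroupSummary, summarize
from .sensor_ingest import (
    DeviceRegistry,
    IngestConfig,
    RawReading,
    SensorEvent,
    extract_all_events,
)
from .synthetic_data import (
    CohortSpec,
    GeneratedActivityPlan,
    default_registry,
    default_templates,
    generate_cohort,
    generate_streams,
)


@dataclass
class PipelineResult:
    roster: list[ParticipantRecord]
    plans: list[GeneratedActivityPlan]
    registry: DeviceRegistry
    events_by_participant: dict[str, list[SensorEvent]] = field(default_factory=dict)
    observations: list[ObservationRecord] = field(default_factory=list)
    activities: list[ActivityRecord] = field(default_factory=list)
    kg: KnowledgeGraph | None = None
    problems: list[ProblemRecord] = field(default_factory=list)
    summaries: list[GroupSummary] = field(default_factory=list)


def process_participant(
    readings: list[RawReading],
    registry: DeviceRegistry,
    templates: list[ProtocolTemplate],
    participant_id: str,
    ingest_config: IngestConfig | None = None,
) -> tuple[list[SensorEvent], list[ObservationRecord], list[ActivityRecord]]:
    """Run ingest → observation → activity composition for one session."""
    events = extract_all_events(readings, registry, ingest_config)
    observations = events_to_observations(events, registry)
    activities = segment_activities(observations, templates, participant_id, registry)
    return events, observations, activities


def run_cohort(
    spec: CohortSpec | None = None,
    rule_config: RuleConfig | None = None,
    ingest_config: IngestConfig | None = None,
) -> PipelineResult:
    """Simulate a cohort and run the full pipeline over it."""
    spec = spec or CohortSpec()
    rule_config = rule_config or RuleConfig()
    registry = default_registry()
    templates = default_templates()
    roster = generate_cohort(spec)
    readings_by_pid, plans = generate_streams(roster, spec, templates)

    result = PipelineResult(roster=roster, plans=plans, registry=registry)
    for pid in sorted(readings_by_pid):
        events, observations, activities = process_participant(
            readings_by_pid[pid], registry, templates, pid, ingest_config
        )
        result.events_by_participant[pid] = events
        result.observations.extend(observations)
        result.activities.extend(activities)

    schema = build_ontology()
    kg = to_rdf(
        result.activities,
        result.observations,
        roster,
        list(registry),
        schema,
    )
    kg, problems = run_rules(kg, rule_config)
    result.kg = kg
    result.problems = problems
    result.summaries = summarize(
        problems, result.activities, roster, rule_config.activity_name
    )
    return result
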