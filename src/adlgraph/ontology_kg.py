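"""The ADL Recognition Ontology and the RDF knowledge graph.

The ontology adapts and extends the W3C SSN/SOSA sensor vocabularies with
classes for activities of daily living, the participants who perform them
and the execution problems a rule engine can detect. Instance data
(activities, observations, devices, participants) is converted to RDF with
deterministic IRIs so that two runs over identical inputs produce
identical graphs. The store is an embedded in-memory rdflib graph;
reasoning is limited to subclass closure plus schema-conformance checks.
"""

from __future__ import annotations

import re
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Sequence
from urllib.parse import quote, unquote

from pydantic import BaseModel
from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef, XSD

from .activity_builder import (
    ActivityRecord,
    FeatureOfInterest,
    ObservationRecord,
    ParticipantRecord,
)
from .sensor_ingest import DeviceKind, DeviceRecord

#: schema namespace of the ADL Recognition Ontology
ADL = Namespace("http://example.org/adl/ontology#")
#: base for minted instance IRIs
RESOURCE_BASE = "http://example.org/adl/resource/"

SOSA = Namespace("http://www.w3.org/ns/sosa/")
SSN = Namespace("http://www.w3.org/ns/ssn/")

PROBLEM_CLASSES = (
    "TooLongDuration",
    "DivergenceFromProtocol",
    "ExtraSteps",
    "MissingSteps",
)

FEATURE_CLASSES = tuple(f.value for f in FeatureOfInterest)

SENSOR_CLASS_BY_KIND = {
    DeviceKind.motion: "MotionSensor",
    DeviceKind.door: "DoorSensor",
    DeviceKind.panic: "PanicButton",
    DeviceKind.wall_plug: "WallPlug",
}

#: feature of interest implied by the sensor class of an observation's device
FEATURE_BY_SENSOR_CLASS = {
    "MotionSensor": "MotionFeature",
    "DoorSensor": "DoorFeature",
    "PanicButton": "PanicFeature",
    "WallPlug": "ConsumptionFeature",
}

_OBJECT_PROPERTIES = {
    "consistsOf": ("Activity", "Observation"),
    "refersToUser": ("Activity", "Patient"),
    "refersToDevice": ("Observation", "Device"),
    "isProblemOf": ("Problem", "Patient"),
    "problematicActivity": ("Problem", "Activity"),
}

_DATA_PROPERTIES = {
    "problem_date": ("Problem", XSD.dateTime),
    "problem_rate": ("Problem", XSD.decimal),
    "activity_pk": ("Activity", XSD.string),
    "activity_start": ("Activity", XSD.dateTime),
    "activity_end": ("Activity", XSD.dateTime),
    "activity_duration": ("Activity", XSD.decimal),
    "activity_name": ("Activity", XSD.string),
    "observation_start_time": ("Observation", XSD.dateTime),
    "device_name": ("Device", XSD.string),
}

#: every predicate an instance graph may legitimately use
DECLARED_PREDICATES = frozenset(
    {ADL[p] for p in _OBJECT_PROPERTIES} | {ADL[p] for p in _DATA_PROPERTIES} | {RDF.type}
)


class IntegrityError(ValueError):
    """Raised when instance data references entities that were not supplied."""


class Violation(BaseModel):
    """One schema-conformance defect found in a knowledge graph."""

    model_config = {"frozen": True}

    subject: str
    message: str


class KnowledgeGraph:
    """Ontology plus instance triples, queryable with SPARQL 1.1."""

    def __init__(self, graph: Graph | None = None):
        self.graph = graph if graph is not None else Graph()
        self.graph.bind("adl", ADL)
        self.graph.bind("sosa", SOSA)
        self.graph.bind("ssn", SSN)

    def __len__(self) -> int:
        return len(self.graph)

    def query(self, q, **kwargs):
        return self.graph.query(q, **kwargs)

    def add_triples(self, triples: Iterable) -> None:
        for t in triples:
            self.graph.add(t)

    def serialize(self, destination=None, format: str = "turtle"):
        return self.graph.serialize(destination=destination, format=format)

    @classmethod
    def parse(cls, source: str | Path, format: str | None = None) -> "KnowledgeGraph":
        g = Graph()
        g.parse(source, format=format)
        return cls(g)

    def copy(self) -> "KnowledgeGraph":
        g = Graph()
        for t in self.graph:
            g.add(t)
        return KnowledgeGraph(g)

    def instances_of(self, cls: URIRef) -> set[URIRef]:
        """Instances of a class, closed over rdfs:subClassOf."""
        rows = self.graph.query(
            "SELECT ?i WHERE { ?i a ?c . ?c rdfs:subClassOf* ?cls . }",
            initNs={"rdfs": RDFS},
            initBindings={"cls": cls},
        )
        return {row[0] for row in rows}


# ---------------------------------------------------------------------------
# IRI minting


def _slug(name: str) -> str:
    return quote(re.sub(r"[^A-Za-z0-9]+", "-", name).strip("-").lower(), safe="")


def activity_iri(pk: str) -> URIRef:
    return URIRef(f"{RESOURCE_BASE}activity/{quote(pk, safe='')}")


def observation_iri(observation_id: str) -> URIRef:
    return URIRef(f"{RESOURCE_BASE}observation/{quote(observation_id, safe='')}")


def patient_iri(participant_id: str) -> URIRef:
    return URIRef(f"{RESOURCE_BASE}patient/{quote(participant_id, safe='')}")


def patient_id_from_iri(iri: URIRef) -> str:
    return unquote(str(iri).rsplit("/", 1)[-1])


def device_iri(name: str) -> URIRef:
    return URIRef(f"{RESOURCE_BASE}device/{_slug(name)}")


# ---------------------------------------------------------------------------
# schema


def build_ontology() -> KnowledgeGraph:
    """Build the schema-only ADL Recognition Ontology graph.

    Declares the class hierarchy (Sensor with one subclass per device kind,
    Observation, Activity, FeatureOfInterest with four subclasses,
    ObservableProperty, Patient, Device, Problem with exactly four
    subclasses) and all instance-level properties, and aligns the
    sensor-centric classes with the public SSN/SOSA IRIs without fetching
    anything at run time.
    """
    kg = KnowledgeGraph()
    g = kg.graph

    top_classes = (
        "Device",
        "Sensor",
        "Observation",
        "Activity",
        "FeatureOfInterest",
        "ObservableProperty",
        "Patient",
        "Problem",
    )
    for name in top_classes:
        g.add((ADL[name], RDF.type, OWL.Class))
    g.add((ADL.Sensor, RDFS.subClassOf, ADL.Device))
    for name in SENSOR_CLASS_BY_KIND.values():
        g.add((ADL[name], RDF.type, OWL.Class))
        g.add((ADL[name], RDFS.subClassOf, ADL.Sensor))
    for name in FEATURE_CLASSES:
        g.add((ADL[name], RDF.type, OWL.Class))
        g.add((ADL[name], RDFS.subClassOf, ADL.FeatureOfInterest))
    for name in PROBLEM_CLASSES:
        g.add((ADL[name], RDF.type, OWL.Class))
        g.add((ADL[name], RDFS.subClassOf, ADL.Problem))

    # SSN/SOSA alignment (local names, public IRIs; no network fetch)
    g.add((ADL.Sensor, OWL.equivalentClass, SOSA.Sensor))
    g.add((ADL.Observation, RDFS.subClassOf, SOSA.Observation))
    g.add((ADL.FeatureOfInterest, OWL.equivalentClass, SOSA.FeatureOfInterest))
    g.add((ADL.ObservableProperty, OWL.equivalentClass, SOSA.ObservableProperty))

    for prop, (domain, rng) in _OBJECT_PROPERTIES.items():
        g.add((ADL[prop], RDF.type, OWL.ObjectProperty))
        g.add((ADL[prop], RDFS.domain, ADL[domain]))
        g.add((ADL[prop], RDFS.range, ADL[rng]))
    for prop, (domain, rng) in _DATA_PROPERTIES.items():
        g.add((ADL[prop], RDF.type, OWL.DatatypeProperty))
        g.add((ADL[prop], RDFS.domain, ADL[domain]))
        g.add((ADL[prop], RDFS.range, rng))
    return kg


# ---------------------------------------------------------------------------
# instance conversion


def _duration_literal(seconds: float) -> Literal:
    return Literal(Decimal(f"{seconds:.3f}"), datatype=XSD.decimal)


def to_rdf(
    activities: Sequence[ActivityRecord],
    observations: Sequence[ObservationRecord],
    participants: Sequence[ParticipantRecord],
    devices: Sequence[DeviceRecord],
    schema: KnowledgeGraph | None = None,
) -> KnowledgeGraph:
    """Convert validated records into an RDF knowledge graph.

    Per activity: a type triple, the activity_pk / start / end / name /
    duration literals, one refersToUser and one consistsOf edge per
    observation. Per observation: type, observation_start_time and
    refersToDevice. Per device: a sensor-class type triple and its
    device_name. Per participant: a Patient type triple. IRIs are minted
    deterministically from the records' identifiers.
    """
    schema = schema if schema is not None else build_ontology()
    kg = schema.copy()
    g = kg.graph

    obs_index = {o.observation_id: o for o in observations}
    device_index = {d.device_id: d for d in devices}
    participant_ids = {p.participant_id for p in participants}

    for d in devices:
        node = device_iri(d.name)
        g.add((node, RDF.type, ADL[SENSOR_CLASS_BY_KIND[d.kind]]))
        g.add((node, ADL.device_name, Literal(d.name)))

    for p in participants:
        g.add((patient_iri(p.participant_id), RDF.type, ADL.Patient))

    for o in observations:
        if o.device_id not in device_index:
            raise IntegrityError(
                f"observation {o.observation_id!r} references unknown device "
                f"{o.device_id!r}"
            )
        node = observation_iri(o.observation_id)
        g.add((node, RDF.type, ADL.Observation))
        g.add(
            (node, ADL.observation_start_time, Literal(o.start, datatype=XSD.dateTime))
        )
        g.add((node, ADL.refersToDevice, device_iri(device_index[o.device_id].name)))

    for a in activities:
        if a.participant_id not in participant_ids:
            raise IntegrityError(
                f"activity {a.pk!r} references unknown participant "
                f"{a.participant_id!r}"
            )
        node = activity_iri(a.pk)
        g.add((node, RDF.type, ADL.Activity))
        g.add((node, ADL.activity_pk, Literal(a.pk)))
        g.add((node, ADL.activity_start, Literal(a.start, datatype=XSD.dateTime)))
        g.add((node, ADL.activity_end, Literal(a.end, datatype=XSD.dateTime)))
        g.add((node, ADL.activity_name, Literal(a.name)))
        g.add((node, ADL.activity_duration, _duration_literal(a.duration_s)))
        g.add((node, ADL.refersToUser, patient_iri(a.participant_id)))
        for o in a.observations:
            if o.observation_id not in obs_index:
                raise IntegrityError(
                    f"activity {a.pk!r} references unknown observation "
                    f"{o.observation_id!r}"
                )
            g.add((node, ADL.consistsOf, observation_iri(o.observation_id)))
    return kg


# ---------------------------------------------------------------------------
# conformance


_REQUIRED_ACTIVITY_PROPS = (
    "activity_pk",
    "activity_start",
    "activity_end",
    "activity_name",
    "activity_duration",
    "refersToUser",
    "consistsOf",
)

_SCHEMA_PREDICATES = frozenset(
    {RDF.type, RDFS.subClassOf, RDFS.domain, RDFS.range, OWL.equivalentClass}
)


def check_conformance(kg: KnowledgeGraph) -> list[Violation]:
    """Report schema violations in a knowledge graph; empty when valid.

    Checks that activities carry their required properties, that
    observations have a start time and resolve to a feature of interest
    through their device's sensor class, that problems name a patient, and
    that no undeclared predicate appears on instance data.
    """
    g = kg.graph
    violations: list[Violation] = []

    for pred in set(g.predicates()):
        if pred not in DECLARED_PREDICATES and pred not in _SCHEMA_PREDICATES:
            violations.append(
                Violation(subject=str(pred), message="undeclared predicate")
            )

    for act in g.subjects(RDF.type, ADL.Activity):
        for prop in _REQUIRED_ACTIVITY_PROPS:
            if g.value(act, ADL[prop]) is None:
                violations.append(
                    Violation(subject=str(act), message=f"activity missing {prop}")
                )

    for obs in g.subjects(RDF.type, ADL.Observation):
        if g.value(obs, ADL.observation_start_time) is None:
            violations.append(
                Violation(
                    subject=str(obs),
                    message="observation missing observation_start_time",
                )
            )
        dev = g.value(obs, ADL.refersToDevice)
        if dev is None:
            violations.append(
                Violation(subject=str(obs), message="observation missing refersToDevice")
            )
            continue
        sensor_classes = {
            str(c).rsplit("#", 1)[-1] for c in g.objects(dev, RDF.type)
        }
        if not sensor_classes & set(FEATURE_BY_SENSOR_CLASS):
            violations.append(
                Violation(
                    subject=str(obs),
                    message="observation's feature of interest cannot be resolved "
                    "(device has no sensor class)",
                )
            )

    for cls_name in PROBLEM_CLASSES:
        for prob in g.subjects(RDF.type, ADL[cls_name]):
            if g.value(prob, ADL.isProblemOf) is None:
                violations.append(
                    Violation(subject=str(prob), message="problem missing isProblemOf")
                )

    violations.sort(key=lambda v: (v.subject, v.message))
    return violations
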