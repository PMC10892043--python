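"""The four problem rules: SPARQL engine behavior and oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from adlgraph.activity_builder import ParticipantRecord
from adlgraph.ontology_kg import ADL, build_ontology, to_rdf
from adlgraph.problem_rules import (
    RuleConfig,
    brute_force_oracle,
    rule_divergence,
    rule_extra_steps,
    rule_missing_steps,
    rule_too_long_duration,
    run_rules,
)

from conftest import at, make_activity, random_activity_set

PARTICIPANTS = [ParticipantRecord(participant_id="hc-01", group="HC")]


def _kg_for(registry, specs):
    """Build a kg from (pk, duration, device_steps) activity specs."""
    activities, observations = [], []
    for pk, duration, steps in specs:
        act, obs = make_activity(registry, pk, "hc-01", at(0), duration, steps)
        activities.append(act)
        observations.extend(obs)
    devices = list(registry)
    kg = to_rdf(activities, observations, PARTICIPANTS, devices, build_ontology())
    return kg, activities


def _steps(n, duration=1800.0):
    """n door steps on neutral devices, evenly spread."""
    pool = ["Drawer 1", "Drawer 2", "Cabinet (Utensils)"]
    return [
        (pool[i % 3], round((i + 1) * duration / (n + 2), 3)) for i in range(n)
    ]


class TestTooLongDuration:
    def test_fires_above_threshold_with_duration_rate(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 2400.0, [("Cooker", 60.0)])])
        (rec,) = rule_too_long_duration(kg, rule_config)
        assert rec.type == "TooLongDuration"
        assert rec.rate == 2400.0
        assert rec.patient_id == "hc-01"
        assert rec.date == at(0)

    def test_boundary_is_strict(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 2100.0, [("Cooker", 60.0)])])
        assert rule_too_long_duration(kg, rule_config) == []

    def test_filters_among_mixed_durations(self, registry, rule_config):
        kg, _ = _kg_for(
            registry,
            [
                ("a1", 1800.0, [("Cooker", 60.0)]),
                ("a2", 2100.0, [("Cooker", 60.0)]),
                ("a3", 2101.0, [("Cooker", 60.0)]),
            ],
        )
        recs = rule_too_long_duration(kg, rule_config)
        assert [r.activity_pk for r in recs] == ["a3"]

    def test_other_activity_names_ignored(self, registry, rule_config):
        activities, observations = [], []
        act, obs = make_activity(
            registry, "a1", "hc-01", at(0), 3000.0, [("Toaster", 60.0)],
            name="Cold Meal Preparation",
        )
        kg = to_rdf([act], obs, PARTICIPANTS, list(registry), build_ontology())
        assert rule_too_long_duration(kg, rule_config) == []

    def test_raising_threshold_never_adds_problems(self, registry):
        kg, _ = _kg_for(
            registry,
            [(f"a{i}", 1500.0 + i * 300, [("Cooker", 60.0)]) for i in range(6)],
        )
        counts = [
            len(rule_too_long_duration(kg, RuleConfig(duration_threshold_s=t)))
            for t in (1500.0, 2100.0, 2700.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestStepCountRules:
    def test_extra_steps_fires_with_count_rate(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 1800.0, _steps(24) + [("Cooker", 900.0)])])
        (rec,) = rule_extra_steps(kg, rule_config)
        assert (rec.type, rec.rate) == ("ExtraSteps", 26)  # 24 doors + cooker + motion

    def test_exactly_twenty_does_not_fire(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 1800.0, _steps(18) + [("Cooker", 900.0)])])
        assert rule_extra_steps(kg, rule_config) == []

    def test_missing_steps_fires_below_ten(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 1800.0, _steps(5) + [("Cooker", 900.0)])])
        (rec,) = rule_missing_steps(kg, rule_config)
        assert (rec.type, rec.rate) == ("MissingSteps", 7)

    def test_exactly_ten_does_not_fire(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 1800.0, _steps(8) + [("Cooker", 900.0)])])
        assert rule_missing_steps(kg, rule_config) == []

    def test_never_both_extra_and_missing(self, registry, rule_config):
        rng = np.random.default_rng(3)
        for n in rng.integers(1, 30, size=10):
            kg, _ = _kg_for(
                registry, [("a1", 1800.0, _steps(int(n)) + [("Cooker", 900.0)])]
            )
            extra = rule_extra_steps(kg, rule_config)
            missing = rule_missing_steps(kg, rule_config)
            assert not (extra and missing)

    def test_lowering_missing_threshold_never_adds_problems(self, registry):
        kg, _ = _kg_for(
            registry,
            [(f"a{i}", 1800.0, _steps(i + 2) + [("Cooker", 900.0)]) for i in range(8)],
        )
        counts = [
            len(rule_missing_steps(kg, RuleConfig(missing_steps_threshold=t)))
            for t in (10, 7, 4)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDivergence:
    CONFORMANT = [("Cabinet (Food)", 60.0), ("Cooker", 600.0), ("Fridge Door1", 1500.0)]

    def test_correct_order_does_not_fire(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 1800.0, self.CONFORMANT)])
        assert rule_divergence(kg, rule_config) == []

    def test_permuted_order_fires(self, registry, rule_config):
        steps = [("Fridge Door1", 60.0), ("Cabinet (Food)", 600.0), ("Cooker", 1500.0)]
        kg, _ = _kg_for(registry, [("a1", 1800.0, steps)])
        (rec,) = rule_divergence(kg, rule_config)
        assert rec.type == "DivergenceFromProtocol"
        assert rec.activity_pk == "a1"
        assert rec.rate is None

    def test_late_duplicate_cabinet_fires(self, registry, rule_config):
        """A second cabinet opening after the cooker forms a wrong combination."""
        steps = self.CONFORMANT + [("Cabinet (Food)", 1200.0)]
        kg, _ = _kg_for(registry, [("a1", 1800.0, steps)])
        assert len(rule_divergence(kg, rule_config)) == 1

    def test_missing_protocol_device_not_applicable(self, registry, rule_config):
        steps = [("Cabinet (Food)", 60.0), ("Fridge Door1", 1500.0)]  # no cooker
        kg, _ = _kg_for(registry, [("a1", 1800.0, steps)])
        assert rule_divergence(kg, rule_config) == []


class TestRunRules:
    def test_empty_instance_graph(self, registry, rule_config):
        kg = to_rdf([], [], [], [], build_ontology())
        before = len(kg)
        kg, problems = run_rules(kg, rule_config)
        assert problems == []
        assert len(kg) == before

    def test_one_activity_two_problems_distinct_iris(self, registry, rule_config):
        steps = _steps(24, duration=2400.0) + [("Cooker", 1200.0)]
        kg, _ = _kg_for(registry, [("a1", 2400.0, steps)])
        kg, problems = run_rules(kg, rule_config)
        assert {p.type for p in problems} == {"TooLongDuration", "ExtraSteps"}
        assert len({p.problem_iri for p in problems}) == 2

    def test_rerun_is_idempotent(self, registry, rule_config):
        kg, _ = _kg_for(registry, [("a1", 2400.0, [("Cooker", 60.0)])])
        kg, first = run_rules(kg, rule_config)
        size = len(kg)
        kg, second = run_rules(kg, rule_config)
        assert len(kg) == size
        assert first == second

    def test_enrichment_matches_emitted_records(self, registry, rule_config):
        steps = [("Fridge Door1", 60.0), ("Cooker", 600.0), ("Cabinet (Food)", 1500.0)]
        kg, _ = _kg_for(registry, [("a1", 2400.0, steps)])
        kg, problems = run_rules(kg, rule_config)
        closure = kg.instances_of(ADL.Problem)
        assert {p.problem_iri for p in problems} == {str(i) for i in closure}


class TestOracleEquivalence:
    def test_oracle_reproduces_rule_examples(self, registry, rule_config):
        activities = []
        observations = []
        for pk, dur, steps in [
            ("a1", 2400.0, [("Cooker", 60.0)]),
            ("a2", 2100.0, [("Cooker", 60.0)]),
            ("a3", 1800.0, _steps(24) + [("Cooker", 900.0)]),
            ("a4", 1800.0, [("Fridge Door1", 60.0), ("Cooker", 600.0),
                            ("Cabinet (Food)", 1500.0)]),
        ]:
            act, obs = make_activity(registry, pk, "hc-01", at(0), dur, steps)
            activities.append(act)
            observations.extend(obs)
        records = brute_force_oracle(activities, rule_config, list(registry))
        by_pk = {}
        for r in records:
            by_pk.setdefault(r.activity_pk, set()).add(r.type)
        # a1/a2/a4 have few observations, so MissingSteps also applies
        assert by_pk == {
            "a1": {"TooLongDuration", "MissingSteps"},
            "a2": {"MissingSteps"},
            "a3": {"ExtraSteps"},
            "a4": {"MissingSteps", "DivergenceFromProtocol"},
        }

    def test_empty_input(self, rule_config):
        assert brute_force_oracle([], rule_config, []) == []

    def test_engine_matches_oracle_on_random_graphs(self, registry, rule_config):
        """SPARQL rule engine == direct brute force, 30 random graphs."""
        schema = build_ontology()
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            activities, observations, participants = random_activity_set(rng, registry)
            kg = to_rdf(activities, observations, participants, list(registry), schema)
            _, engine = run_rules(kg, rule_config)
            oracle = brute_force_oracle(activities, rule_config, list(registry))
            key = lambda r: (r.problem_iri, r.type, r.patient_id, r.date, r.rate,
                             r.activity_pk)
            assert sorted(map(key, engine)) == sorted(map(key, oracle)), f"seed {seed}"
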