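# Methods

## Raw data model and segmentation

Two raw time series are ingested. **Signal** devices (motion, door/drawer/
cabinet, panic) report state transitions as `(old_value, new_value)` pairs
of booleans: a 0→1 transition opens an interval, the next 1→0 closes it.
Readings with `old_value == new_value` carry no state change and are
dropped; a repeated 0→1 while an interval is open is ignored with a
warning (the pairing rule assumes alternation). An interval never closed
by the stream is, by default, closed at the stream end and flagged
`terminated=false` (policy `close_at_stream_end`); the alternative policy
drops it. **Consumption** devices (wall plugs) report instantaneous
wattage. An appliance is *in use* while its draw is at or above
`consumption_threshold_watts` (default **5 W**); idle is strictly below.
The boundary is resolved as ≥ so that "below the threshold" is literally
the off condition; a one-reading sweep at 4.9/5.0/5.1 W pins this down in
the tests. A consumption event opens at the first in-use reading and ends
at the timestamp of the first subsequent idle reading; every sub-threshold
dip closes an event (no debounce interval is applied — resumption after a
dip starts a new event).

Validity normalization handles the classic false negative of contact
sensors (a cabinet that never quite closed): signal events longer than
`max_plausible_signal_duration_s` (default 7200 s, comfortably above any
single task session) are truncated to that duration and flagged
unterminated.

Timestamps are ISO 8601 UTC at millisecond precision; durations are plain
decimal seconds, because the problem rules compare durations numerically.

A note on an invariant one might expect: the *number* of consumption
events is **not** monotone in the threshold — raising it can split one
excursion at an interior dip. The monotone quantity is the total in-use
time, and that is what the property test asserts (count monotonicity holds
and is tested on unimodal excursions).

## Activity composition

Each event becomes an `Observation` carrying the feature of interest
implied by its device kind (motion → `MotionFeature`, door →
`DoorFeature`, panic → `PanicFeature`, wall plug → `ConsumptionFeature`).
Composition into activities is template-driven rather than manual: a
`ProtocolTemplate` names the task, its room, its member devices, the
trigger devices that distinguish it (cooker → hot meal; kettle → hot
beverage; toaster → cold meal), and a chaining gap `max_gap_s` (default
**900 s**; no published value exists, so it was set well below the 2100 s
normal-duration bound so that one task cannot absorb the next).
Observations on member devices — plus motion observations in the
template's room, which join but never trigger — are chained while
consecutive starts are within the gap; a chain with at least one trigger
observation becomes an `ActivityRecord` spanning the hull of its
observations. Chains from different templates competing for observations
are resolved earliest-first (ties by template order), then re-validated,
so each observation belongs to at most one activity and the result is
deterministic. Single occupancy is assumed throughout: composition is per
participant.

## Ontology and knowledge graph

The ADL Recognition Ontology declares `Device`, `Sensor` (with
`MotionSensor`, `DoorSensor`, `PanicButton`, `WallPlug`), `Observation`,
`Activity`, `FeatureOfInterest` (4 subclasses), `ObservableProperty`,
`Patient` and `Problem` with exactly four subclasses (`TooLongDuration`,
`DivergenceFromProtocol`, `ExtraSteps`, `MissingSteps`). The
sensor-centric classes are aligned to the public SSN/SOSA IRIs by
`owl:equivalentClass` / `rdfs:subClassOf` annotations; nothing is fetched
at run time. The store is an embedded rdflib graph; reasoning is limited
to subclass closure (property-path queries) and conformance checks.

Instance conversion mints deterministic IRIs — `…/activity/{pk}`,
`…/observation/{id}`, `…/patient/{id}`, `…/device/{slug(name)}` — so two
runs over identical inputs yield identical triple sets. Each activity
carries its type, `activity_pk`, `activity_start`, `activity_end`,
`activity_name`, an `activity_duration` in xsd:decimal seconds, one
`refersToUser` and one `consistsOf` edge per observation; each observation
its type, `observation_start_time` and `refersToDevice`; each device a
sensor-class type and `device_name`; each participant a `Patient` type.
Durations are materialized as decimal seconds rather than `xsd:duration`
because dateTime subtraction and duration ordering are not portable
SPARQL 1.1; the comparison semantics are identical and directly testable.
An observation's feature of interest is derivable from its device's sensor
class rather than asserted per observation; the conformance checker
reports observations for which it cannot be resolved, activities missing
required properties, problems without a patient, and undeclared
predicates.

## Problem rules

The four rules ship as SPARQL 1.1 CONSTRUCT templates (`queries/*.rq`)
parameterized by activity name, thresholds and the three protocol device
names, loaded and filled at run time:

* **TooLongDuration** — `activity_duration > 2100` (strict; 2100 s exactly
  does not fire). Rate = duration in seconds.
* **ExtraSteps** — `COUNT(DISTINCT observation) > 20` via a sub-SELECT
  with GROUP BY. Rate = the count.
* **MissingSteps** — the same count `< 10`. The two step rules are
  mutually exclusive by construction.
* **DivergenceFromProtocol** — applicable only to activities containing at
  least one observation on each protocol device (food cabinet, cooker,
  fridge door); fires iff some combination of their start times violates
  t₁ < t₂ < t₃ (strict comparisons; equal timestamps count as violations).

Problem IRIs are minted inside the query as
`IRI(CONCAT(base, rule, ENCODE_FOR_URI(activity_pk)))`, which makes rule
execution idempotent: re-running on an enriched graph reconstructs the
same triples into a set. Problem dates equal the activity start.

A `brute_force_oracle` implements all four rules as direct loops over
activity records (the divergence check enumerates every device-event
combination). It shares no code with the SPARQL path and exists solely so
the engine can be verified against an independent implementation; the test
suite asserts set-equality of the two outputs over 100+ randomized seeded
graphs whose durations and observation counts straddle every threshold.

The shipped divergence query covers the canonical three-device protocol;
configuring a different protocol length raises an error rather than
silently degrading. Rules are parameterized per activity name and default
to "Hot Meal Preparation", the only task with a published instantiation.

## Cohort simulator

`CohortSpec` encodes the study conditions: 13 HC / 14 SCD / 13 MCI
participants, one hot-meal session each on consecutive days. Durations are
truncated normal (floor 300 s) with group means **1782.36 / 2179.81 /
2399 s**; step counts are rounded normal with group means **15.72 / 15.63 /
18.37**; divergence is injected with probability **0.81 / 0.81 / 1.0** per
group. The spreads (duration sd 400 s, step sd 4) are simulator choices —
only the means are published — and are config knobs; no test depends on
their exact values, only on means and orderings. A session plan's
`step_count` counts all observations of the resulting activity including
the spanning kitchen-motion observation, so the generator emits
`step_count − 1` device events; the step floor is 4 so the three protocol
devices are always representable and divergence can be injected or
withheld deterministically. Divergent sessions swap the fridge event
before the cabinet event — the minimal permutation the order rule
detects; conformant sessions place exactly one event per protocol device
in the prescribed order, so no wrong combination can arise.

Emitted streams encode each plan exactly: kitchen motion 0→1/1→0 spanning
the session, a door open/close pair (or a cooker wattage excursion of
800–1500 W bounded by idle readings) per device step, idle wall-plug noise
below 5 W, and an occasional no-op panic press outside the session. Device
steps are spaced by `min(duration / step_count, 850) s` — always inside
the 900 s chaining gap — and end strictly before the motion interval does,
so the recovered activity duration equals the planned duration to the
millisecond. This is what makes the full-pipeline round-trip test exact:
for a 40-participant cohort, recovered durations, observation counts and
divergence flags equal the ground truth record for record.

What the simulator deliberately does not model: appliance load curves
(only the ≥ 5 W classification matters downstream), overnight stays,
multi-occupancy, sensor dropout or clock skew, and correlated step/
duration distributions. Passing round-trip tests therefore demonstrate
pipeline correctness under clean single-occupant streams, not robustness
to real-world sensor noise.

## Reporting

Group summaries report, per problem type, the percentage of participants
with at least one problem of that type. The denominator is the number of
participants in the group with at least one activity of the target name —
not the group size — since a participant who never performed the task
cannot be flagged; with the default simulator every participant
participates, so the two coincide. Participants with several problems of
one type count once. Percentages are rounded to two decimals. The
dashboard export is a pure function producing byte-stable JSON with three
sections (event log, activity log, problems over time); rendering is out
of scope.

## Known limitations and observed behavior

* The per-seed stochastic ordering of TooLongDuration rates (HC ≤ SCD ≤
  MCI) is not near-certain at the default cohort size: with 13–14
  participants per group and sd 400 s, the SCD and MCI flag probabilities
  (≈0.58 and ≈0.77) overlap enough that the sample ordering inverts in
  roughly one seed in six. The corresponding acceptance test documents
  this honestly; pooled rates over many seeds order correctly.
* `MissingSteps` can fire in simulation (step counts < 10 are ~1.5σ below
  the HC/SCD means), whereas small pilot cohorts may show none.
* The divergence rule follows the applicability condition of the order
  query: an activity missing a protocol device entirely is not counted as
  divergent.
* One activity per participant by default; longitudinal monitoring would
  simply add sessions.
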