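# adlgraph

Semantic detection of problems in **activities of daily living (ADLs)**
monitored through smart-home sensors.

Clinicians assessing people across the dementia spectrum (healthy controls,
subjective cognitive decline, mild cognitive impairment — HC / SCD / MCI)
look for deviations from the normal execution of instrumental ADLs such as
preparing a hot meal: taking too long, taking too many or too few steps, or
departing from the prescribed order of steps. `adlgraph` implements a full
pipeline that turns raw smart-home sensor streams into an RDF knowledge
graph and detects such problems with explicit, inspectable SPARQL rules:

1. **Sensor ingestion** — raw *Signal* readings (boolean 0→1 / 1→0
   transitions from motion, door/drawer/cabinet and panic sensors) are
   paired into intervals; *Consumption* readings (wall-plug wattage) are
   segmented into events wherever the draw is ≥ 5 W (idle is < 5 W).
2. **Activity composition** — events become *Observations* with a feature
   of interest, and protocol templates chain them into named *Activities*
   (e.g., "Hot Meal Preparation", triggered by the cooker) whenever
   consecutive observation starts are within a 15-minute gap.
3. **Knowledge graph** — everything is converted to RDF under an
   SSN/SOSA-derived *ADL Recognition Ontology* (classes `Sensor`,
   `Observation`, `Activity`, `FeatureOfInterest`, `Patient`, `Problem`
   with exactly four subclasses), hosted in an embedded rdflib store.
4. **Problem rules** — four SPARQL CONSTRUCT queries enrich the graph with
   `Problem` instances:

   | rule | condition |
   |---|---|
   | `TooLongDuration` | activity duration > 2100 s (35 min) |
   | `ExtraSteps` | distinct observations > 20 |
   | `MissingSteps` | distinct observations < 10 |
   | `DivergenceFromProtocol` | some (cabinet, cooker, fridge) combination violates t₁ < t₂ < t₃ |

5. **Reporting** — per-group percentages of flagged participants, average
   durations/step counts, and a dashboard-ready JSON bundle.

Because no sensor dataset is distributable, the package ships a **seeded
cohort simulator** that emulates the study conditions (13 HC / 14 SCD /
13 MCI participants; group-mean durations 1782.36 / 2179.81 / 2399 s;
group-mean step counts 15.72 / 15.63 / 18.37; divergence probabilities
0.81 / 0.81 / 1.0) and emits raw Signal/Consumption streams together with
their ground-truth plans, so the whole pipeline is testable end to end.

## Worked example

```bash
adlgraph demo --seed 1 --out demo_out
```

runs simulate → ingest → build-activities → build-kg → detect → report and
writes `summary.csv`, `problems.json`, `graph.ttl` and `dashboard.json`.
With seed 1 the summary table is:

```
group,n_participants,n_with_activity,too_long_pct,divergence_pct,extra_steps_pct,missing_steps_pct,avg_duration_s,avg_steps
HC,13,13,38.46,76.92,15.38,7.69,1930.36,15.85
SCD,14,14,50.00,92.86,0.00,0.00,2078.23,16.14
MCI,13,13,92.31,100.00,15.38,0.00,2518.36,17.31
```

Reading: every simulated participant performed one hot-meal session; 38% of
healthy controls but 92% of MCI participants exceeded the 35-minute
duration limit, and protocol divergences dominate everywhere — the expected
gradient across cognitive-status groups. (`avg_steps` counts all
observations of an activity, including the room-presence observation.)

The same pipeline is available stage by stage (`adlgraph simulate`,
`ingest`, `build-activities`, `build-kg`, `detect`, `report`) with files
between stages, or programmatically:

```python
from adlgraph import CohortSpec, run_cohort

result = run_cohort(CohortSpec(seed=1))
print(len(result.activities), "activities,", len(result.problems), "problems")
for s in result.summaries:
    print(s.group, s.problem_pct)
```

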