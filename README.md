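# rx-pathways

Derive depression care pathways — treatment sequences, response,
remission, relapse, switching, combination, augmentation, resumption,
treatment failure and treatment-resistant depression (TRD) status —
from raw primary-care antidepressant prescription records.

## Who this is for

Pharmacoepidemiologists and health-data scientists who have
prescription-level EHR extracts (patient id, drug, issue date, dose,
supply days) plus coded clinical events, and who want reproducible,
rule-based treatment outcomes in the absence of symptom-scale data.
Because the real linked primary/secondary-care warehouses this kind of
analysis runs on are access-restricted, the package ships a fully
synthetic cohort generator with per-patient ground-truth labels, so
every rule is testable end to end on any machine.

## The model

All outcomes are operational rules on **treatment sequences**. Each
prescription covers `[issue_date, issue_date + supply_days)` (default
supply 30 days); same-drug coverage separated by ≤ 60 days is bridged;
a *sequence* is a maximal period with a constant set of concurrently
covered antidepressants (the regimen), dose changes excepted. Then,
with durations in days:

| outcome | rule |
|---|---|
| response | sequence sustained ≥ 90 d (dose changes allowed) |
| remission | response ≥ 180 d, **or** ≥ 90 d then ≥ 60 antidepressant-free days |
| relapse | new sequence starting 60–180 d (inclusive) after a responding sequence |
| switch | ≥ 1 drug stopped and ≥ 1 introduced within the switch gap window |
| combination | an antidepressant added, enlarged regimen lasting ≥ 45 d |
| augmentation | lithium / antipsychotic / thyroxine / T3 / anticonvulsant overlapping ≥ 45 d |
| resumption | restart of a previously used regimen outside the relapse window |
| treatment failure | no response, or followed by switch/combination, or augmented |

A patient is **TRD** when one depressive episode (episodes close on
remission or a > 180-day treatment-free gap) contains ≥ 2 failed lines
with different regimens, each an adequate trial (≥ 42 d and, where dose
data exist, at or above the minimum effective daily dose). Everyone
else in the cohort is MDD. Group contrasts use the Pearson χ² test
(1 d.f.) for proportions and the Wilcoxon rank-sum test with
continuity correction for numeric measures, both implemented from
first principles.

## Worked example

```bash
rx-pathways run --simulate --seed 7 --n-patients 500 --out demo_run
```

prints the stage row counts:

```json
{
  "prescriptions": 3339,
  "prescriptions_rejected": 0,
  "events": 933,
  "events_rejected": 0,
  "patients": 500,
  "eligible": 481,
  "pathway_events": 1707,
  "classified": 481
}
```

481 of 500 simulated patients meet the eligibility rules (adult,
depression code, in-window antidepressant, no exclusion diagnosis); the
classifier emits 1707 pathway events over them. `demo_run/` then holds
the cohort, per-event and per-patient tables, group summaries, and a
manifest (seed, config hash, input checksums) sufficient to reproduce
every output byte-for-byte. The suppressed count table
(`counts_suppressed.csv`) applies the warehouse disclosure rule —
counts of 0–4 render as `<5`:

```text
measure,MDD,TRD,TRD3+,TRD4+,MHS
n_patients,443,38,14,5,93
n_response,193,20,9,<5,41
n_relapse,46,8,<5,<5,15
n_remission,159,16,5,<5,35
```

Comparing prescription counts between groups:

```bash
rx-pathways compare --run-dir demo_run --metric n_prescriptions --groups MDD,TRD
```

```json
{
  "statistic": 3445.0,
  "p_value": 1.237477331475517e-09,
  "method": "Wilcoxon rank-sum with continuity correction"
}
```

TRD patients receive significantly more prescriptions than MDD
patients, as expected from trajectories forced through multiple failed
lines. The same calls are available as library functions
(`rx_pathways.run_pipeline`, `classify_cohort`, `wilcoxon_rank_sum_cc`,
…) on pandas DataFrames.

## Layout

- `src/rx_pathways/io.py` — readers, writers, code dictionaries
- `src/rx_pathways/cohort.py` — eligibility, exclusions, index dates
- `src/rx_pathways/sequences.py` — coverage intervals and sequences
- `src/rx_pathways/classify.py` — outcome rules and MDD/TRD status
- `src/rx_pathways/metrics.py` — per-patient/group summaries, suppression
- `src/rx_pathways/stats.py` — χ² (1 d.f.) and Wilcoxon rank-sum
- `src/rx_pathways/simulate.py` — label-first generator, archetypes
- `src/rx_pathways/cli.py` — `rx-pathways` subcommands
- `docs/methods.md` — methods note: assumptions, parameters, limitations
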