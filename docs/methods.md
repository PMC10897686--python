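# Methods

## Problem and approach

In UK primary care, depression outcomes are rarely recorded with
symptom scales at the scale and completeness needed for cohort
analysis. This package derives treatment outcomes purely from the
*dynamics of prescribing*: when antidepressants were issued, for how
long, whether the drug set changed, and what was added alongside. The
cost of this approach is that every outcome is an operational proxy —
a "response" is a sustained prescription, not a measured improvement —
and the package is explicit about each rule so that the proxies are
auditable and adjustable.

## From scripts to sequences

Dates are calendar dates; all interval arithmetic is in whole days on
half-open intervals `[start, end)`. Each issued script covers
`[issue_date, issue_date + supply_days)`; a missing supply quantity is
imputed as 30 days, the typical script length. Per drug, consecutive
coverage separated by at most `same_regimen_gap_tolerance_days`
(default 60) is bridged into one continuous exposure: short adherence
lapses and late refills must not fragment treatment. Overlapping
same-drug scripts extend coverage to the latest end without stacking
supply, since early refills are common and stacking inflates duration.

The patient's timeline is then partitioned at every date where the set
of concurrently covered antidepressant ingredients changes; each
maximal constant-regimen span is one *treatment sequence*. On a change
date the new regimen owns the day (half-open convention). Dose changes
are traced but never split a sequence; dose comparisons use exact
equality, with a missing dose equal to missing and unequal to any
number.

The 60-day bridging tolerance is an inference, not a stated parameter
of the operational definitions we implement: the remission rule treats
60 antidepressant-free days as a discontinuation, so a gap short
enough to block remission is also treated as too short to fragment a
sequence. It is configurable, and analyses sensitive to it should
sweep it.

## Outcome rules

* **Response**: sequence length ≥ `response_min_days` (90). Dose
  changes are explicitly permitted; regimen constancy is guaranteed by
  construction.
* **Remission**: response of ≥ `remission_response_days` (180), or a
  ≥ 90-day sequence with no antidepressant prescription issued in the
  `remission_gap_days` (60) after its end. The gap clause is applied
  only when the look-forward window closes before the end of the study
  window; otherwise every patient still on treatment at the censoring
  date would "remit". This censoring guard is our addition; the source
  definitions are silent on it.
* **Relapse**: a sequence starting 60–180 days (both endpoints
  inclusive; the stated range is ambiguous and this reading is
  configurable) after the end of a responding sequence. Note a
  structural consequence: a relapse gap of ≥ 60 treatment-free days
  itself satisfies the remission gap clause, so relapse presupposes
  remission under these rules — the pair reads as "recovered, then
  restarted treatment".
* **Switch**: at least one drug stopped and at least one introduced,
  with the between-sequence gap inside
  `[switch_gap_min_days, switch_gap_max_days]`. The 60–180-day window
  of the written definition exists to tolerate prescribing delays; we
  default the lower bound to 0 because an immediate replacement is
  unambiguously a switch, and expose the literal behaviour via
  `switch_gap_min_days=60`.
* **Combination**: the next regimen is a strict superset of the
  previous and lasts ≥ `combination_min_days` (45).
* **Augmentation**: merged coverage of lithium, an antipsychotic,
  thyroxine, tri-iodothyronine or an anticonvulsant overlaps a
  sequence for ≥ `augmentation_min_days` (45). An agent spanning two
  sequences long enough augments both.
* **Resumption**: restart of a previously used regimen after a gap
  above the bridging tolerance, excluding restarts that the relapse
  rule claims.
* **Transition precedence** when several rules could label one
  boundary: combination > switch > resumption — a superset regimen is
  more specific than a replacement, which is more specific than a
  repeat.
* **Treatment failure**: a sequence with no response, or followed by a
  switch or combination, or augmented. Response and failure are not
  mutually exclusive (a responding sequence later switched away from is
  both); both tallies are emitted so either reading of aggregate tables
  can be reproduced.

## Episodes, lines and TRD

An *episode* is a run of treatment not interrupted by a remission or
by a treatment-free gap longer than `episode_gap_days` (180, strict).
*Lines of therapy* count, within an episode, the distinct regimens
initiated by the episode's first sequence or via switch/combination;
resumptions and regimen shrinkage do not open lines. The patient-level
line count is the maximum over episodes.

**TRD** requires, within a single episode, at least two failed lines
with different regimens, each an *adequate trial*: duration ≥
`adequate_line_min_days` and, where both a recorded dose and a
dictionary minimum effective dose exist, a maximum daily dose at or
above the minimum. The written definition says only "adequate dose and
duration"; 42 days (six weeks) matches the guideline horizon for
reviewing an ineffective antidepressant and is configurable. Unknown
doses never disqualify a trial, because dose recording is patchy in
source data and a missing value is not evidence of underdosing.

Cohort eligibility: adults (≥ 18 at the index date — the first
in-window antidepressant script, which anchors all person-time), at
least one coded depression diagnosis at any time up to the end of the
study window (the code may postdate the first script), and no
bipolar/dementia/mania/psychosis/schizophrenia-spectrum code from the
exclusion look-back (2010) onwards. Presence in the demographics table
stands in for GP registration; registration intervals are not
modelled.

## Statistics

Group contrasts use the Pearson χ² test (1 d.f., no Yates correction
by default; the correction is available by flag) and the two-sided
Wilcoxon rank-sum test under the normal approximation with midranks,
tie-corrected variance and a 0.5 continuity correction. Both are
implemented from their definitions; scipy supplies only the χ² and
normal distribution functions. An exact-enumeration rank-sum p-value
is provided for small samples as an internal cross-check. Day counts
convert to months at 30.44 days/month. All emitted count tables apply
small-cell suppression: integers 0–4 render as `<5`.

## The synthetic cohort generator

The generator is *label-first*: it samples each patient's intended
pathway as a plan — an ordered list of constant-regimen spells with
gaps, durations and optional augmentation — and then emits the raw
~30-day scripts realising the plan exactly. Ground truth is computed
from the plan by a small spell-level rule evaluator that shares no
code with the analysis pipeline. Free dynamics simulated forward and
labelled post hoc would be more naturalistic but would make the truth
labels as fallible as the classifier under test; label-first
generation keeps them exact.

Default conditions (all configurable in `GeneratorConfig`): 8% of
eligible patients are constructed as TRD (two to four failed adequate
distinct lines in one episode, with third/fourth lines at
probabilities 0.33/0.28 conditional on the previous); four drugs —
citalopram, sertraline, fluoxetine, mirtazapine — carry ~83% of the
prescription mass; non-TRD patients respond with probability 0.45 and
remit given response with probability 0.8; relapse conditional on
remission is 0.3 (non-TRD-like) and 0.5 (TRD-like); secondary
mental-health contact occurs for 21%/54% of MDD/TRD patients with a
truncated-normal delay of mean 40 and s.d. 32 months after the first
depression code; comorbidity prevalences (anxiety 0.29, asthma 0.15,
alcohol/substance misuse 0.10, diabetes 0.08) rise by ×1.6 in TRD;
suicidality codes occur for ~6.5% of patients. Refill gaps are drawn
from a mixture (mostly 0–10 days, occasionally 30–58) to exercise the
coverage bridge; ~5% of patients are made ineligible (minor, exclusion
diagnosis, or missing depression code) to exercise cohort
construction. Identical configuration and seed give byte-identical
output files.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: free-running prescribing over many years
(generated patients average ~6.5 scripts, far below the ~20+ seen in
long real-world follow-up, because trajectories are planned at
label-bearing scale), coding errors and duplicate records, partially
observed trajectories truncated mid-rule (plans are fitted inside the
study window with the remission look-forward observable), realistic
clinical vocabularies, dose inadequacy, secondary-care prescribing
gaps, and any correlation structure between comorbidities and
outcomes beyond group membership.

## Verification design

* Twenty hand-built archetype patients place every threshold on both
  sides (89/90, 179/180, 59/60, 59/60–180/181, 44/45 days); their
  expected event counts and classifications are asserted exactly.
* The sequence engine is checked against a brute-force day-by-day
  regimen scan, and the classifier against an exhaustive re-statement
  of the rules, on hundreds of random small patients.
* A 5000-patient generated cohort must recover group and line labels
  for every patient and reproduce the configured rates within three
  binomial standard errors (problem size chosen to keep the default
  suite fast while leaving Monte-Carlo bands tight).
* The statistical tests reproduce closed-form values and a frozen
  independently generated reference file to 1e-8, and the Wilcoxon
  type-I error is checked over 2000 null replicates.

## Known limitations

Prescriptions are assumed dispensed and consumed as written. The index
rule ignores pre-window prescribing, so left-censored histories can
misclassify the first in-window sequence as a fresh start. The TRD
definition is sensitive to the adequacy threshold and bridging
tolerance; both default values are editorial choices documented above.
Small real-world corner cases (e.g. a regimen shrinking by one drug)
produce sequences that open no new line, so a TRD patient can in
principle carry a line count below their failed-line count. No
multiplicity adjustment is applied to group comparisons, and nothing
here supports causal interpretation.
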