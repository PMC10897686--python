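"""Label-first synthetic primary-care cohort generator.

The generator writes each patient's trajectory top-down from an intended
pathway (a *plan*: an ordered list of constant-regimen spells with gaps,
durations and optional augmentation), then emits the raw prescription
and coded-event streams that realise the plan. Because the plan is
constructed first, every patient carries unambiguous ground-truth
labels, derived at spell level by a small independent rule evaluator
(`plan_truth`) that never touches the analysis pipeline's coverage or
sequence code.

What the streams emulate: prescribing dominated by four drugs
(citalopram, sertraline, fluoxetine, mirtazapine, roughly 83% of
scripts), ~30-day scripts with adherence gaps (mostly 0-10 days, with
occasional 30-58 day lapses that exercise the coverage merge tolerance),
a small minority (~8%) progressing through two or more failed adequate
treatment lines within one episode, depression/exclusion/comorbidity/
suicidality codes, and delayed secondary mental-health contact (mean
around 40 months after diagnosis). Calendar realism (weekday patterns,
holidays) and realistic clinical vocabularies are deliberately out of
scope; dates are uniform over the study window subject to the trajectory
fitting inside it.
"""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import CodeDictionary, default_code_dictionary

DEFAULT_DRUG_WEIGHTS = {
    "citalopram": 0.30,
    "sertraline": 0.22,
    "fluoxetine": 0.17,
    "mirtazapine": 0.14,
    "venlafaxine": 0.05,
    "amitriptyline": 0.04,
    "paroxetine": 0.03,
    "escitalopram": 0.03,
    "duloxetine": 0.01,
    "trazodone": 0.01,
}

DEFAULT_COMORBIDITY_PREVALENCE = {
    "CMB-ANX": 0.29,
    "CMB-AST": 0.15,
    "CMB-ALC": 0.10,
    "CMB-DIA": 0.08,
}

AGENT_INGREDIENTS = ("lithium", "quetiapine", "levothyroxine", "liothyronine", "lamotrigine")


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Probabilities are per-patient unless noted. ``relapse_prob_*`` is the
    probability of relapse conditional on remission (a relapse here
    presupposes recovery: the rules place it 60-180 days after a
    responding sequence, a gap that itself satisfies the remission
    discontinuation clause).
    """

    n_patients: int = 1000
    trd_proportion: float = 0.08
    response_prob: float = 0.45  # non-TRD: any responding line
    trd_response_prob: float = 0.60  # TRD: responds after the failed lines
    remission_given_response: float = 0.80
    relapse_prob_mdd: float = 0.30
    relapse_prob_trd: float = 0.50
    trd_3plus_prob: float = 0.33  # third line, conditional on TRD
    trd_4plus_prob: float = 0.28  # fourth line, conditional on a third
    combination_line_prob: float = 0.25  # failed line added as combination, else switch
    mdd_prefailure_prob: float = 0.30  # remitting non-TRD: one inadequate-era... adequate failed first line
    mdd_augmentation_prob: float = 0.04
    trd_augmentation_prob: float = 0.35
    drug_weights: tuple[tuple[str, float], ...] = tuple(DEFAULT_DRUG_WEIGHTS.items())
    long_gap_prob: float = 0.15  # adherence lapse of 30-58 days between refills
    comorbidity_prevalence: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_COMORBIDITY_PREVALENCE.items()
    )
    trd_comorbidity_multiplier: float = 1.6
    suicidality_rate: float = 0.065
    mhs_contact_prob_mdd: float = 0.21
    mhs_contact_prob_trd: float = 0.54
    mhs_delay_mean_months: float = 40.0
    mhs_delay_sd_months: float = 32.0
    depression_after_script_prob: float = 0.10
    missing_dose_prob: float = 0.10
    missing_supply_prob: float = 0.05
    other_med_prob: float = 0.10
    ineligible_fraction: float = 0.05
    rng_seed: int = 0

    def __post_init__(self):
        probs = {
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self)
            if f.name.endswith(("_prob", "_proportion", "_rate", "_fraction"))
        }
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        weights = dict(self.drug_weights)
        total = sum(weights.values())
        if total <= 0 or any(w < 0 for w in weights.values()):
            raise ValueError("drug weights must be nonnegative with positive sum")
        if self.trd_proportion > 0 and len(weights) < 3:
            raise ValueError("treatment resistance needs at least three distinct drugs")
        if self.trd_proportion > 0 and self.response_prob >= 1.0:
            raise ValueError(
                "infeasible: cannot carry failed adequate lines when every line responds"
            )
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")


@dataclasses.dataclass
class Spell:
    """One planned constant-regimen treatment period."""

    gap_before: int  # days since end of previous spell (ignored for the first)
    regimen: frozenset[str]
    duration: int
    augmented: str | None = None  # augmentation agent ingredient


@dataclasses.dataclass
class PlanTruth:
    group: str
    lines: int
    responded: bool
    remitted: bool
    relapsed: bool
    n_resumptions: int
    n_failures: int


def plan_truth(plan: list[Spell], cfg: StudyConfig) -> PlanTruth:
    """Apply the outcome definitions directly to a spell plan.

    This is the generator's ground-truth bookkeeping: a spell-level
    re-statement of the rules that never sees prescriptions, coverage
    intervals or the analysis classifier. It presumes what the emitter
    guarantees — each spell realises exactly one treatment sequence and
    the trailing remission window is observable.
    """
    n = len(plan)
    durations = [s.duration for s in plan]
    gaps = [plan[i].gap_before for i in range(1, n)]  # gap between spell i-1 and i
    responded = [d >= cfg.response_min_days for d in durations]
    low, high = cfg.relapse_window_days

    remitted = []
    for i in range(n):
        if not responded[i]:
            remitted.append(False)
        elif durations[i] >= cfg.remission_response_days:
            remitted.append(True)
        else:
            gap_next = gaps[i] if i < n - 1 else None
            remitted.append(gap_next is None or gap_next >= cfg.remission_gap_days)

    relapses = [
        responded[i] and low <= gaps[i] <= high for i in range(n - 1)
    ]  # relapse anchored at spell i+1

    transitions: list[str] = []
    seen: set[frozenset[str]] = set()
    for i in range(1, n):
        prev, nxt = plan[i - 1], plan[i]
        gap = gaps[i - 1]
        seen.add(prev.regimen)
        if nxt.regimen > prev.regimen and nxt.duration >= cfg.combination_min_days:
            transitions.append("combination")
        elif (
            (prev.regimen - nxt.regimen)
            and (nxt.regimen - prev.regimen)
            and cfg.switch_gap_min_days <= gap <= cfg.switch_gap_max_days
        ):
            transitions.append("switch")
        elif (
            nxt.regimen in seen
            and gap > cfg.same_regimen_gap_tolerance_days
            and not (responded[i - 1] and low <= gap <= high)
        ):
            transitions.append("resumption")
        else:
            transitions.append("none")

    failed = []
    for i in range(n):
        fail = not responded[i]
        if i < n - 1 and transitions[i] in ("switch", "combination"):
            fail = True
        if plan[i].augmented:
            fail = True
        failed.append(fail)

    # episodes close on remission or on a gap above the episode threshold
    episode_bounds = []
    start = 0
    for i in range(n):
        close = remitted[i] or (i < n - 1 and gaps[i] > cfg.episode_gap_days) or i == n - 1
        if close:
            episode_bounds.append((start, i + 1))
            start = i + 1
    is_trd = False
    lines = 0
    for lo, hi in episode_bounds:
        initiated = {plan[lo].regimen}
        for i in range(lo + 1, hi):
            if transitions[i - 1] in ("switch", "combination"):
                initiated.add(plan[i].regimen)
        lines = max(lines, len(initiated))
        distinct_failed = {
            plan[i].regimen
            for i in range(lo, hi)
            if failed[i] and plan[i].duration >= cfg.adequate_line_min_days
        }
        if len(distinct_failed) >= 2:
            is_trd = True

    return PlanTruth(
        group="TRD" if is_trd else "MDD",
        lines=max(lines, 1),
        responded=any(responded),
        remitted=any(remitted),
        relapsed=any(relapses),
        n_resumptions=sum(t == "resumption" for t in transitions),
        n_failures=sum(failed),
    )


class _Emitter:
    """Accumulates raw CSV rows for one cohort."""

    def __init__(self, dictionary: CodeDictionary, gc: GeneratorConfig, rng: np.random.Generator):
        self.dictionary = dictionary
        self.gc = gc
        self.rng = rng
        self.code_of = {e.ingredient: e.code for e in dictionary.drugs.values()}
        self.min_dose = {
            e.ingredient: e.min_daily_dose
            for e in dictionary.drugs.values()
            if e.min_daily_dose is not None
        }
        self.rx_rows: list[tuple] = []
        self.ev_rows: list[tuple] = []
        self.script_counts: dict[str, int] = {}

    def script(self, pid: str, ingredient: str, when: date, supply: int, dose: float | None):
        code = self.code_of[ingredient]
        dose_s = "" if dose is None else f"{dose:g}"
        supply_s = (
            ""
            if supply == 30 and self.rng.random() < self.gc.missing_supply_prob
            else str(supply)
        )
        self.rx_rows.append((pid, code, when.isoformat(), dose_s, supply_s))
        if self.dictionary.drugs[code].role == "antidepressant":
            self.script_counts[pid] = self.script_counts.get(pid, 0) + 1

    def event(self, pid: str, code: str, when: date):
        system = self.dictionary.clinical[code].code_system
        self.ev_rows.append((pid, code, system, when.isoformat()))

    def spell_scripts(self, pid: str, ingredient: str, start: date, duration: int):
        """Emit ~30-day scripts realising coverage exactly [start, start+duration)."""
        rng = self.rng
        dose = None
        if rng.random() >= self.gc.missing_dose_prob:
            base = self.min_dose.get(ingredient, 20.0)
            dose = base * (2.0 if rng.random() < 0.3 else 1.0)
        end = start + timedelta(days=duration)
        if duration <= 30:
            self.script(pid, ingredient, start, duration, dose)
            return
        issues = [start]
        cur = start
        while True:
            if rng.random() < self.gc.long_gap_prob:
                step = int(rng.integers(60, 89))  # coverage gap 30-58d, inside tolerance
            else:
                step = int(rng.integers(25, 41))
            nxt = cur + timedelta(days=step)
            if (nxt + timedelta(days=30)) >= end:
                break
            issues.append(nxt)
            cur = nxt
        final = end - timedelta(days=30)
        if final > cur:
            issues.append(final)
        change_at = len(issues) // 2 if (len(issues) > 1 and rng.random() < 0.2) else None
        for i, when in enumerate(issues):
            d = dose
            if change_at is not None and i >= change_at and dose is not None:
                d = dose * 2
            self.script(pid, ingredient, when, 30, d)


def _sample_drugs(rng: np.random.Generator, weights: dict[str, float], k: int) -> list[str]:
    names = list(weights)
    p = np.asarray([weights[n] for n in names], dtype=float)
    p = p / p.sum()
    return [names[i] for i in rng.choice(len(names), size=k, replace=False, p=p)]


def _build_plan(gc: GeneratorConfig, study: StudyConfig, rng: np.random.Generator, intended_trd: bool) -> list[Spell]:
    """Sample a spell plan realising the intended group label."""
    weights = dict(gc.drug_weights)
    u = lambda lo, hi: int(rng.integers(lo, hi + 1))
    plan: list[Spell] = []

    if intended_trd:
        n_failed = 2
        if rng.random() < gc.trd_3plus_prob:
            n_failed = 3
            if rng.random() < gc.trd_4plus_prob:
                n_failed = 4
        drugs = _sample_drugs(rng, weights, n_failed + 1)
        regimen = frozenset({drugs[0]})
        plan.append(Spell(0, regimen, u(45, 89)))
        for k in range(1, n_failed):
            if rng.random() < gc.combination_line_prob:
                regimen = regimen | {drugs[k]}
                plan.append(Spell(0, regimen, u(45, 89)))
            else:
                regimen = frozenset({drugs[k]})
                plan.append(Spell(u(0, 50), regimen, u(45, 89)))
        if rng.random() < gc.trd_response_prob:
            first = frozenset({drugs[0]})
            if rng.random() < gc.remission_given_response:
                duration = u(90, 400)
                plan.append(Spell(u(61, 180), first, duration))
                if rng.random() < gc.relapse_prob_trd:
                    plan.append(Spell(u(61, 180), first, u(30, 89)))
            else:
                plan.append(Spell(u(61, 180), first, u(90, 179)))
                plan.append(Spell(u(1, 59), frozenset({drugs[n_failed]}), u(20, 41)))
        if rng.random() < gc.trd_augmentation_prob:
            plan[0].augmented = AGENT_INGREDIENTS[int(rng.integers(0, len(AGENT_INGREDIENTS)))]
        return plan

    # non-TRD pathways
    if rng.random() < gc.response_prob:
        drugs = _sample_drugs(rng, weights, 3)
        if rng.random() < gc.remission_given_response:
            respond_drug = drugs[0]
            if rng.random() < gc.mdd_prefailure_prob:
                plan.append(Spell(0, frozenset({drugs[1]}), u(42, 89)))
                respond_drug = drugs[0]
                gap = u(0, 40)
            else:
                gap = 0
            remission_long = rng.random() < 0.5
            duration = u(180, 500) if remission_long else u(90, 179)
            plan.append(Spell(gap, frozenset({respond_drug}), duration))
            if rng.random() < gc.relapse_prob_mdd:
                plan.append(Spell(u(61, 180), frozenset({respond_drug}), u(30, 89)))
        else:
            # responds but does not remit: a quick switch interrupts the
            # post-response gap; the tail trial is deliberately inadequate
            plan.append(Spell(0, frozenset({drugs[0]}), u(90, 179)))
            plan.append(Spell(u(1, 59), frozenset({drugs[1]}), u(20, 41)))
    else:
        drug = _sample_drugs(rng, weights, 1)[0]
        n_spells = 1 + int(rng.poisson(1.2))
        first_duration = u(20, 89)
        augment = rng.random() < gc.mdd_augmentation_prob
        if augment:
            first_duration = max(first_duration, 46)
        plan.append(Spell(0, frozenset({drug}), first_duration))
        for _ in range(n_spells - 1):
            plan.append(Spell(u(61, 400), frozenset({drug}), u(20, 89)))
        if augment:
            plan[0].augmented = AGENT_INGREDIENTS[int(rng.integers(0, len(AGENT_INGREDIENTS)))]
    return plan


def _plan_span(plan: list[Spell]) -> int:
    span = 0
    for i, spell in enumerate(plan):
        if i:
            span += spell.gap_before
        span += spell.duration
    return span


@dataclasses.dataclass
class SyntheticCohort:
    prescriptions: pd.DataFrame  # raw reader-format columns
    events: pd.DataFrame
    demographics: pd.DataFrame
    truth: pd.DataFrame
    config: GeneratorConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (
            ("prescriptions", self.prescriptions),
            ("events", self.events),
            ("demographics", self.demographics),
            ("truth", self.truth),
        ):
            path = out / f"{name}.csv"
            frame.to_csv(path, index=False)
            paths[name] = path
        return paths


def generate_cohort(
    gc: GeneratorConfig, study: StudyConfig | None = None
) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort under the given conditions.

    Each intended-eligible patient gets a spell plan fitted inside the
    study window with a trailing margin so every remission look-forward
    is observable; plans are emitted as raw ~30-day scripts. A small
    fraction of patients is made ineligible (minor, exclusion diagnosis,
    or no depression code) to exercise cohort construction. The truth
    table carries the plan-level labels.
    """
    study = study or StudyConfig()
    rng = np.random.default_rng(gc.rng_seed)
    dictionary = default_code_dictionary()
    emit = _Emitter(dictionary, gc, rng)
    window_days = (study.study_end - study.study_start).days
    margin = study.remission_gap_days + 1

    truth_rows = []
    demo_rows = []
    for idx in range(gc.n_patients):
        pid = f"P{idx:06d}"
        ineligible_reason = None
        if rng.random() < gc.ineligible_fraction:
            ineligible_reason = ("under_18", "exclusion_code", "no_depression_code")[
                int(rng.integers(0, 3))
            ]
        intended_trd = ineligible_reason is None and rng.random() < gc.trd_proportion

        if ineligible_reason is None:
            plan = _build_plan(gc, study, rng, intended_trd)
        else:
            drug = _sample_drugs(rng, dict(gc.drug_weights), 1)[0]
            plan = [Spell(0, frozenset({drug}), int(rng.integers(30, 120)))]

        # trim over-long plans from the tail, never below the label-bearing core
        min_spells = 2 if intended_trd else 1
        while _plan_span(plan) + margin > window_days and len(plan) > min_spells:
            plan.pop()
        span = _plan_span(plan) + margin
        latest_offset = max(0, window_days - span)
        index_date = study.study_start + timedelta(days=int(rng.integers(0, latest_offset + 1)))

        truth = plan_truth(plan, study)
        if ineligible_reason is None and (truth.group == "TRD") != intended_trd:
            raise RuntimeError(f"generator plan for {pid} does not realise its label")

        # prescriptions
        cursor = index_date
        for i, spell in enumerate(plan):
            if i:
                cursor = cursor + timedelta(days=spell.gap_before)
            for ingredient in sorted(spell.regimen):
                emit.spell_scripts(pid, ingredient, cursor, spell.duration)
            if spell.augmented:
                overlap = min(spell.duration, int(rng.integers(45, 61)))
                offset = int(rng.integers(0, spell.duration - overlap + 1))
                emit.spell_scripts(
                    pid, spell.augmented, cursor + timedelta(days=offset), overlap
                )
            cursor = cursor + timedelta(days=spell.duration)
        if rng.random() < gc.other_med_prob:
            when = study.study_start + timedelta(days=int(rng.integers(0, window_days)))
            emit.rx_rows.append((pid, "OT-PCM", when.isoformat(), "", "30"))

        # demographics: adults except the under-18 ineligibles
        if ineligible_reason == "under_18":
            birth = index_date - timedelta(days=int(17 * 365.25))
        else:
            birth = index_date - timedelta(days=int(rng.integers(19, 80) * 365.25))
        gender = "F" if rng.random() < 0.66 else "M"
        demo_rows.append((pid, birth.isoformat(), gender))

        # depression code (usually before index, sometimes after the first script)
        depression_date = None
        if ineligible_reason != "no_depression_code":
            code = ("DEP01", "DEP02", "F32", "F33")[int(rng.integers(0, 4))]
            if rng.random() < gc.depression_after_script_prob:
                depression_date = index_date + timedelta(days=int(rng.integers(1, 61)))
            else:
                depression_date = index_date - timedelta(days=int(rng.integers(30, 1500)))
            depression_date = min(depression_date, study.study_end)
            emit.event(pid, code, depression_date)
        if ineligible_reason == "exclusion_code":
            emit.event(
                pid,
                ("EXC-BIP", "EXC-PSY", "F20")[int(rng.integers(0, 3))],
                study.exclusion_lookback_start + timedelta(days=int(rng.integers(0, 2000))),
            )

        # comorbidities, suicidality, mental-health-service contact
        multiplier = gc.trd_comorbidity_multiplier if intended_trd else 1.0
        for code, prevalence in gc.comorbidity_prevalence:
            if rng.random() < min(prevalence * multiplier, 0.95):
                when = study.study_start + timedelta(days=int(rng.integers(0, window_days)))
                emit.event(pid, code, when)
        suicid_p = min(gc.suicidality_rate * (1.5 if intended_trd else 1.0), 1.0)
        if rng.random() < suicid_p:
            for _ in range(1 + int(rng.poisson(0.4))):
                when = study.study_start + timedelta(days=int(rng.integers(0, window_days)))
                emit.event(
                    pid, ("SUI-ID", "SUI-AT", "SUI-SH")[int(rng.integers(0, 3))], when
                )
        mhs_contact = False
        if ineligible_reason is None and depression_date is not None:
            p_contact = gc.mhs_contact_prob_trd if intended_trd else gc.mhs_contact_prob_mdd
            if rng.random() < p_contact:
                months = -1.0
                while months <= 0.5:
                    months = rng.normal(gc.mhs_delay_mean_months, gc.mhs_delay_sd_months)
                when = depression_date + timedelta(days=int(months * study.month_length_days))
                if when <= study.study_end:
                    mhs_contact = True
                    emit.event(
                        pid, ("MHS-REF", "MHS-CON", "MHS-AE")[int(rng.integers(0, 3))], when
                    )

        truth_rows.append(
            {
                "patient_id": pid,
                "eligible": ineligible_reason is None,
                "ineligible_reason": ineligible_reason or "",
                "true_group": truth.group if ineligible_reason is None else "",
                "true_lines": truth.lines if ineligible_reason is None else 0,
                "true_response": truth.responded,
                "true_remission": truth.remitted,
                "true_relapse": truth.relapsed,
                "true_n_resumptions": truth.n_resumptions,
                "true_n_failures": truth.n_failures,
                "true_mhs_contact": mhs_contact,
                "true_n_scripts": emit.script_counts.get(pid, 0),
                "index_date": index_date.isoformat(),
            }
        )

    prescriptions = pd.DataFrame(
        emit.rx_rows, columns=["patient_id", "drug_code", "issue_date", "daily_dose", "supply_days"]
    ).sort_values(["patient_id", "issue_date", "drug_code"], kind="stable", ignore_index=True)
    events = pd.DataFrame(
        emit.ev_rows, columns=["patient_id", "code", "code_system", "event_date"]
    ).sort_values(["patient_id", "event_date", "code"], kind="stable", ignore_index=True)
    demographics = pd.DataFrame(demo_rows, columns=["patient_id", "birth_date", "gender"])
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(prescriptions, events, demographics, truth, gc)


# ---------------------------------------------------------------------------
# archetype fixtures: one hand-built patient per rule boundary


def spell_script_rows(
    pid: str, ingredient: str, start: date, duration: int, dose: float | None = None
) -> list[tuple]:
    """Raw prescription rows covering exactly [start, start + duration)
    with 30-day scripts (deterministic; used by archetypes and tests)."""
    code = {e.ingredient: e.code for e in default_code_dictionary().drugs.values()}[ingredient]
    dose_s = "" if dose is None else f"{dose:g}"
    rows = []
    if duration <= 30:
        return [(pid, code, start.isoformat(), dose_s, str(duration))]
    cur = start
    end = start + timedelta(days=duration)
    while cur + timedelta(days=30) < end:
        rows.append((pid, code, cur.isoformat(), dose_s, "30"))
        cur += timedelta(days=30)
    rows.append((pid, code, (end - timedelta(days=30)).isoformat(), dose_s, "30"))
    return rows


def _archetype_patients() -> list[dict]:
    """Each entry: patient definition plus the exact labels the rules must emit.

    Spans are day offsets from the patient's index date; every boundary
    named in the outcome definitions appears on both sides.
    """
    A, B, C = "citalopram", "sertraline", "mirtazapine"
    return [
        dict(name="response_90d", spells=[(A, 0, 90)],
             expect=dict(response=1, remission=1, relapse=0, switch=0, combination=0,
                         augmentation=0, resumption=0, treatment_failure=0,
                         group="MDD", lines=1)),
        dict(name="response_89d", spells=[(A, 0, 89)],
             expect=dict(response=0, remission=0, relapse=0, switch=0, combination=0,
                         augmentation=0, resumption=0, treatment_failure=1,
                         group="MDD", lines=1)),
        dict(name="remission_duration_180", spells=[(A, 0, 180), (B, 190, 30)],
             expect=dict(response=1, remission=1, relapse=0, switch=1, combination=0,
                         augmentation=0, resumption=0, treatment_failure=2,
                         group="MDD", lines=1)),
        dict(name="remission_duration_179", spells=[(A, 0, 179), (B, 189, 30)],
             expect=dict(response=1, remission=0, relapse=0, switch=1, combination=0,
                         augmentation=0, resumption=0, treatment_failure=2,
                         group="MDD", lines=2)),
        dict(name="remission_gap_60", spells=[(A, 0, 100), (B, 160, 30)],
             expect=dict(response=1, remission=1, relapse=1, switch=1, combination=0,
                         augmentation=0, resumption=0, treatment_failure=2,
                         group="MDD", lines=1)),
        dict(name="remission_gap_59", spells=[(A, 0, 100), (B, 159, 30)],
             expect=dict(response=1, remission=0, relapse=0, switch=1, combination=0,
                         augmentation=0, resumption=0, treatment_failure=2,
                         group="MDD", lines=2)),
        dict(name="relapse_at_60", spells=[(A, 0, 90), (B, 150, 30)],
             expect=dict(relapse=1, switch=1, response=1, remission=1)),
        dict(name="relapse_at_180", spells=[(A, 0, 90), (B, 270, 30)],
             expect=dict(relapse=1, switch=1, response=1, remission=1)),
        dict(name="no_relapse_59", spells=[(A, 0, 90), (B, 149, 30)],
             expect=dict(relapse=0, switch=1, response=1, remission=0)),
        dict(name="no_relapse_181", spells=[(A, 0, 90), (B, 271, 30)],
             expect=dict(relapse=0, switch=0, response=1, remission=1, resumption=0)),
        dict(name="relapse_same_drug_61", spells=[(A, 0, 90), (A, 151, 40)],
             expect=dict(relapse=1, switch=0, resumption=0, response=1, remission=1,
                         group="MDD", lines=1)),
        dict(name="combination_45", spells=[(A, 0, 60), (A, 60, 45), (B, 60, 45)],
             expect=dict(combination=1, switch=0, response=0, treatment_failure=2,
                         group="TRD", lines=2)),
        dict(name="combination_44", spells=[(A, 0, 60), (A, 60, 44), (B, 60, 44)],
             expect=dict(combination=0, switch=0, response=0, treatment_failure=2,
                         group="TRD", lines=1)),
        dict(name="augmentation_45", spells=[(A, 0, 120), ("lithium", 10, 45)],
             expect=dict(augmentation=1, response=1, remission=1, treatment_failure=1,
                         group="MDD", lines=1)),
        dict(name="augmentation_44", spells=[(A, 0, 120), ("lithium", 10, 44)],
             expect=dict(augmentation=0, response=1, remission=1, treatment_failure=0,
                         group="MDD", lines=1)),
        dict(name="trd_two_lines", spells=[(A, 0, 60), (B, 70, 60)],
             expect=dict(switch=1, response=0, treatment_failure=2, group="TRD", lines=2)),
        dict(name="episode_break_not_trd", spells=[(A, 0, 60), (B, 260, 60)],
             expect=dict(switch=0, response=0, treatment_failure=2, group="MDD", lines=1)),
        dict(name="immediate_switch", spells=[(A, 0, 50), (B, 50, 90)],
             expect=dict(switch=1, response=1, remission=1, treatment_failure=1,
                         group="MDD", lines=2)),
        dict(name="resumption", spells=[(A, 0, 60), (A, 160, 60)],
             expect=dict(resumption=1, switch=0, relapse=0, response=0,
                         treatment_failure=2, group="MDD", lines=1)),
        dict(name="trd_three_lines", spells=[(A, 0, 60), (B, 70, 60), (C, 140, 60)],
             expect=dict(switch=2, treatment_failure=3, group="TRD", lines=3)),
    ]


def generate_archetypes(index_date: date = date(2016, 1, 1)) -> SyntheticCohort:
    """Hand-constructed boundary patients with exact expected labels.

    ``spells`` are (ingredient, start offset, duration) triples; lithium
    rows exercise augmentation. The truth table carries, per patient,
    the expected count of every event type plus group and line count
    (missing expectations mean "unchecked" and are stored as -1).
    """
    rx_rows: list[tuple] = []
    ev_rows: list[tuple] = []
    demo_rows: list[tuple] = []
    truth_rows: list[dict] = []
    event_types = (
        "response", "remission", "relapse", "switch", "combination",
        "augmentation", "resumption", "treatment_failure",
    )
    for arch in _archetype_patients():
        pid = arch["name"]
        for ingredient, offset, duration in arch["spells"]:
            rx_rows.extend(
                spell_script_rows(pid, ingredient, index_date + timedelta(days=offset), duration)
            )
        ev_rows.append((pid, "DEP01", "read_v2", (index_date - timedelta(days=100)).isoformat()))
        demo_rows.append((pid, "1980-05-15", "F"))
        expect = arch["expect"]
        truth_rows.append(
            {
                "patient_id": pid,
                "eligible": True,
                "true_group": expect.get("group", ""),
                "true_lines": expect.get("lines", -1),
                **{f"n_{t}": expect.get(t, -1) for t in event_types},
            }
        )
    prescriptions = pd.DataFrame(
        rx_rows, columns=["patient_id", "drug_code", "issue_date", "daily_dose", "supply_days"]
    )
    events = pd.DataFrame(ev_rows, columns=["patient_id", "code", "code_system", "event_date"])
    demographics = pd.DataFrame(demo_rows, columns=["patient_id", "birth_date", "gender"])
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(prescriptions, events, demographics, truth, GeneratorConfig(n_patients=len(truth_rows)))


# ---------------------------------------------------------------------------
# parameter recovery


def recover_parameters(
    gc: GeneratorConfig,
    truth: pd.DataFrame,
    classes: pd.DataFrame,
    metrics: pd.DataFrame,
) -> pd.DataFrame:
    """Compare pipeline estimates against the configured generator values.

    Rows: TRD proportion, response rate by group, relapse rate among
    remitters by group, and mean antidepressant scripts per patient
    (against the generator-side emitted mean). Each row reports the
    estimate, the reference value, the absolute error, the standard
    error on the relevant denominator, and whether the estimate sits
    within three standard errors.
    """
    eligible = truth[truth["eligible"]].copy()
    if set(eligible["patient_id"]) != set(classes["patient_id"]):
        raise ValueError("classified patients do not match the generated eligible cohort")
    merged = classes.merge(eligible, on="patient_id", validate="one_to_one")
    merged = merged.merge(metrics, on="patient_id", validate="one_to_one")
    n = len(merged)

    rows = []

    def binomial_row(name, estimate, configured, denom):
        se = float(np.sqrt(configured * (1 - configured) / denom)) if denom else np.nan
        err = abs(estimate - configured)
        rows.append(
            {
                "parameter": name,
                "configured": configured,
                "estimated": estimate,
                "n": denom,
                "abs_error": err,
                "se": se,
                "within_3se": bool(denom) and err <= 3 * se,
            }
        )

    binomial_row("trd_proportion", float((merged["group"] == "TRD").mean()), gc.trd_proportion, n)
    for group, p_resp, p_rel in (
        ("MDD", gc.response_prob, gc.relapse_prob_mdd),
        ("TRD", gc.trd_response_prob, gc.relapse_prob_trd),
    ):
        sub = merged[merged["group"] == group]
        if len(sub):
            binomial_row(
                f"response_rate_{group.lower()}",
                float((sub["n_responses"] >= 1).mean()),
                p_resp,
                len(sub),
            )
        remitted = sub[sub["remission_flag"].astype(bool)]
        if len(remitted):
            binomial_row(
                f"relapse_given_remission_{group.lower()}",
                float((remitted["n_relapses"] >= 1).mean()),
                p_rel,
                len(remitted),
            )

    emitted = eligible["true_n_scripts"].astype(float)
    measured = merged["n_prescriptions"].astype(float)
    se = float(emitted.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    err = abs(float(measured.mean()) - float(emitted.mean()))
    rows.append(
        {
            "parameter": "mean_scripts_per_patient",
            "configured": float(emitted.mean()),
            "estimated": float(measured.mean()),
            "n": n,
            "abs_error": err,
            "se": se,
            "within_3se": err <= 3 * se if se == se else False,
        }
    )

    agree_group = merged["group"] == merged["true_group"]
    agree_lines = merged["lines_of_therapy"] == merged["true_lines"]
    for name, series in (("group_agreement", agree_group), ("line_agreement", agree_lines)):
        rows.append(
            {
                "parameter": name,
                "configured": 1.0,
                "estimated": float(series.mean()),
                "n": n,
                "abs_error": 1.0 - float(series.mean()),
                "se": 0.0,
                "within_3se": bool(series.all()),
            }
        )
    return pd.DataFrame(rows)
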