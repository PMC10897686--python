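"""Outcome rules over treatment sequences and MDD/TRD classification.

The eight pathway outcomes are operational rules on the sequence
timeline, using prescription coverage only (no symptom scales):

* response — a sequence sustained for >= 90 days; dose changes are
  permitted, regimen constancy is guaranteed by sequence construction.
* remission — a response lasting >= 180 days, or a >= 90-day sequence
  followed by >= 60 antidepressant-free days.
* relapse — a new sequence starting 60-180 days (inclusive) after the
  end of a sequence that had resulted in a response.
* switch — at least one antidepressant stopped and at least one
  replacement introduced within the switch gap window.
* combination — an antidepressant added to the previous regimen, the
  enlarged regimen lasting >= 45 days.
* augmentation — lithium, an antipsychotic, thyroxine,
  tri-iodothyronine or an anticonvulsant covering a sequence for
  >= 45 days (attached during sequence construction).
* resumption — restart of a previously used regimen outside the relapse
  window, after a gap too long to be bridged into the same sequence.
* treatment failure — a sequence with no response, or followed by a
  switch or combination, or augmented.

A patient is treatment-resistant (TRD) when a single depressive episode
contains at least two failed lines with different regimens, each an
adequate trial (long enough, and at an effective dose where dose data
exist). An episode is closed by a remission or by a treatment-free gap
longer than the episode threshold; failed-line counting restarts in the
next episode. Everyone else in the cohort is MDD.
"""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta

import pandas as pd

from .config import StudyConfig
from .io import CodeDictionary
from .sequences import TreatmentSequence, build_patient_sequences

EVENT_TYPES = (
    "response",
    "remission",
    "relapse",
    "switch",
    "combination",
    "augmentation",
    "resumption",
    "treatment_failure",
)

TRANSITION_TYPES = ("switch", "combination", "resumption", "continuation_boundary", "none")


@dataclasses.dataclass
class PathwayEvent:
    patient_id: str
    event_type: str
    sequence_ordinal: int
    event_date: date
    related_ordinal: int | None = None
    rule_trace: str = ""


@dataclasses.dataclass
class PatientClassification:
    patient_id: str
    group: str  # MDD | TRD
    lines_of_therapy: int
    failure_count: int
    trd_2_lines: bool = False
    trd_3plus_lines: bool = False
    trd_4plus_lines: bool = False
    mhs_contact: bool = False


def detect_response(seq: TreatmentSequence, cfg: StudyConfig) -> bool:
    """True iff the sequence lasted at least the response threshold."""
    return seq.days >= cfg.response_min_days


def detect_remission(
    sequences: list[TreatmentSequence],
    ad_issue_dates: list[date],
    cfg: StudyConfig,
) -> list[PathwayEvent]:
    """Remission events: long response, or response then discontinuation.

    The discontinuation clause requires an antidepressant-free window of
    ``remission_gap_days`` after the sequence end with no prescription
    issued inside it; the window must be fully observable before the end
    of the study, otherwise still-ongoing patients would remit by
    censoring.
    """
    events = []
    issue_dates = sorted(ad_issue_dates)
    for seq in sequences:
        if not detect_response(seq, cfg):
            continue
        if seq.days >= cfg.remission_response_days:
            when = min(seq.start + timedelta(days=cfg.remission_response_days), cfg.study_end)
            events.append(
                PathwayEvent(
                    seq.patient_id,
                    "remission",
                    seq.ordinal,
                    when,
                    rule_trace=f"sequence sustained {seq.days}d >= {cfg.remission_response_days}d",
                )
            )
            continue
        window_end = seq.end + timedelta(days=cfg.remission_gap_days)
        if window_end > cfg.study_end_exclusive:
            continue  # gap window censored by study end
        blocked = any(seq.end <= d < window_end for d in issue_dates)
        if not blocked:
            events.append(
                PathwayEvent(
                    seq.patient_id,
                    "remission",
                    seq.ordinal,
                    min(seq.end, cfg.study_end),
                    rule_trace=(
                        f"response of {seq.days}d then no antidepressant prescription "
                        f"in the {cfg.remission_gap_days}d after sequence end"
                    ),
                )
            )
    return events


def detect_relapse(
    sequences: list[TreatmentSequence], cfg: StudyConfig
) -> list[PathwayEvent]:
    """A sequence starting 60-180 days (inclusive) after a responding one."""
    low, high = cfg.relapse_window_days
    events = []
    for prev, nxt in zip(sequences[:-1], sequences[1:]):
        if not detect_response(prev, cfg):
            continue
        gap = (nxt.start - prev.end).days
        if low <= gap <= high:
            events.append(
                PathwayEvent(
                    prev.patient_id,
                    "relapse",
                    nxt.ordinal,
                    min(nxt.start, cfg.study_end),
                    related_ordinal=prev.ordinal,
                    rule_trace=(
                        f"new sequence {gap}d after end of responding sequence "
                        f"{prev.ordinal} (window {low}-{high}d inclusive)"
                    ),
                )
            )
    return events


def classify_transition(
    prev: TreatmentSequence,
    nxt: TreatmentSequence,
    cfg: StudyConfig,
    earlier_regimens: set[frozenset[str]] | None = None,
    prev_responded: bool | None = None,
) -> str:
    """Classify the boundary between two consecutive sequences.

    Precedence: combination > switch > resumption (a superset regimen is
    more specific than a replacement). ``earlier_regimens`` holds the
    regimens of all sequences before ``nxt``; when omitted only
    ``prev.regimen`` is known. A restart in the relapse window after a
    response is left to the relapse rule, not called a resumption.
    """
    gap = (nxt.start - prev.end).days
    if gap < 0:
        raise ValueError(
            f"overlapping sequences {prev.ordinal} and {nxt.ordinal} "
            f"for patient {prev.patient_id}"
        )
    if nxt.regimen > prev.regimen and nxt.days >= cfg.combination_min_days:
        return "combination"
    stopped = prev.regimen - nxt.regimen
    introduced = nxt.regimen - prev.regimen
    if stopped and introduced and cfg.switch_gap_min_days <= gap <= cfg.switch_gap_max_days:
        return "switch"
    seen = set(earlier_regimens) if earlier_regimens is not None else set()
    seen.add(prev.regimen)
    if prev_responded is None:
        prev_responded = detect_response(prev, cfg)
    low, high = cfg.relapse_window_days
    in_relapse_window = prev_responded and low <= gap <= high
    if (
        nxt.regimen in seen
        and gap > cfg.same_regimen_gap_tolerance_days
        and not in_relapse_window
    ):
        return "resumption"
    return "continuation_boundary" if gap == 0 else "none"


def detect_treatment_failure(
    sequences: list[TreatmentSequence],
    transitions: list[str],
    cfg: StudyConfig,
) -> list[PathwayEvent]:
    """A sequence fails on lack of response, a following switch or
    combination, or an attached augmentation. ``transitions[i]`` labels
    the boundary between sequence i and i+1."""
    events = []
    for i, seq in enumerate(sequences):
        clauses = []
        if not detect_response(seq, cfg):
            clauses.append("no response")
        if i < len(transitions) and transitions[i] in ("switch", "combination"):
            clauses.append(f"followed by {transitions[i]}")
        if seq.augmentations:
            clauses.append("augmented")
        if clauses:
            events.append(
                PathwayEvent(
                    seq.patient_id,
                    "treatment_failure",
                    seq.ordinal,
                    min(seq.end, cfg.study_end),
                    rule_trace="; ".join(clauses),
                )
            )
    return events


def _episode_slices(
    sequences: list[TreatmentSequence],
    remission_ordinals: set[int],
    cfg: StudyConfig,
) -> list[list[TreatmentSequence]]:
    """Split the sequence list into depressive episodes.

    An episode closes after sequence i when the treatment-free gap to
    sequence i+1 exceeds the episode threshold, or when sequence i ended
    in remission.
    """
    episodes: list[list[TreatmentSequence]] = []
    current: list[TreatmentSequence] = []
    for i, seq in enumerate(sequences):
        current.append(seq)
        close = False
        if seq.ordinal in remission_ordinals:
            close = True
        if i + 1 < len(sequences):
            gap = (sequences[i + 1].start - seq.end).days
            if gap > cfg.episode_gap_days:
                close = True
        else:
            close = True
        if close:
            episodes.append(current)
            current = []
    if current:
        episodes.append(current)
    return episodes


def count_lines(
    episode: list[TreatmentSequence], transitions_by_ordinal: dict[int, str]
) -> int:
    """Distinct regimens initiated by the episode's first sequence or via
    switch/combination; resumptions and regimen drops do not add lines."""
    initiated: set[frozenset[str]] = set()
    for i, seq in enumerate(episode):
        if i == 0 or transitions_by_ordinal.get(seq.ordinal) in ("switch", "combination"):
            initiated.add(seq.regimen)
    return len(initiated)


def _line_is_adequate(
    seq: TreatmentSequence, dictionary: CodeDictionary, cfg: StudyConfig
) -> bool:
    """Adequate trial: long enough, and at an effective dose wherever both
    a recorded dose and a dictionary minimum exist (unknown dose passes)."""
    if seq.days < cfg.adequate_line_min_days:
        return False
    for ingredient in seq.regimen:
        minimum = dictionary.min_daily_dose(ingredient)
        recorded = [d for d in seq.doses.get(ingredient, ()) if d is not None]
        if minimum is not None and recorded and max(recorded) < minimum:
            return False
    return True


def classify_patient(
    sequences: list[TreatmentSequence],
    ad_issue_dates: list[date],
    cfg: StudyConfig,
    dictionary: CodeDictionary,
    mhs_contact: bool = False,
) -> tuple[list[PathwayEvent], PatientClassification]:
    """Run all outcome rules for one cohort patient.

    Returns the full event list and the patient's classification. TRD
    requires, within one episode, two or more failed adequate lines with
    different regimens.
    """
    if not sequences:
        raise ValueError("classify_patient requires at least one treatment sequence")
    patient_id = sequences[0].patient_id
    events: list[PathwayEvent] = []

    responded = {s.ordinal for s in sequences if detect_response(s, cfg)}
    for seq in sequences:
        if seq.ordinal in responded:
            events.append(
                PathwayEvent(
                    patient_id,
                    "response",
                    seq.ordinal,
                    min(seq.start + timedelta(days=cfg.response_min_days), cfg.study_end),
                    rule_trace=f"sequence sustained {seq.days}d >= {cfg.response_min_days}d",
                )
            )

    remissions = detect_remission(sequences, ad_issue_dates, cfg)
    events.extend(remissions)
    events.extend(detect_relapse(sequences, cfg))

    transitions: list[str] = []
    seen: set[frozenset[str]] = set()
    for prev, nxt in zip(sequences[:-1], sequences[1:]):
        kind = classify_transition(
            prev, nxt, cfg, earlier_regimens=seen, prev_responded=prev.ordinal in responded
        )
        seen.add(prev.regimen)
        transitions.append(kind)
        nxt.preceded_by = kind
        if kind in ("switch", "combination", "resumption"):
            events.append(
                PathwayEvent(
                    patient_id,
                    kind,
                    nxt.ordinal,
                    min(nxt.start, cfg.study_end),
                    related_ordinal=prev.ordinal,
                    rule_trace=(
                        f"regimen {'+'.join(sorted(prev.regimen))} -> "
                        f"{'+'.join(sorted(nxt.regimen))}, "
                        f"gap {(nxt.start - prev.end).days}d"
                    ),
                )
            )

    for seq in sequences:
        for aug in seq.augmentations:
            events.append(
                PathwayEvent(
                    patient_id,
                    "augmentation",
                    seq.ordinal,
                    min(aug.start, cfg.study_end),
                    rule_trace=(
                        f"{aug.agent_class} ({aug.ingredient}) overlapping "
                        f"{aug.days}d >= {cfg.augmentation_min_days}d"
                    ),
                )
            )

    failures = detect_treatment_failure(sequences, transitions, cfg)
    events.extend(failures)
    failed_ordinals = {e.sequence_ordinal for e in failures}

    remission_ordinals = {e.sequence_ordinal for e in remissions}
    episodes = _episode_slices(sequences, remission_ordinals, cfg)
    transitions_by_ordinal = {
        nxt.ordinal: kind for nxt, kind in zip(sequences[1:], transitions)
    }

    is_trd = False
    lines_of_therapy = 0
    for episode in episodes:
        lines = count_lines(episode, transitions_by_ordinal)
        lines_of_therapy = max(lines_of_therapy, lines)
        failed_adequate_regimens = {
            s.regimen
            for s in episode
            if s.ordinal in failed_ordinals and _line_is_adequate(s, dictionary, cfg)
        }
        if len(failed_adequate_regimens) >= 2:
            is_trd = True

    classification = PatientClassification(
        patient_id=patient_id,
        group="TRD" if is_trd else "MDD",
        lines_of_therapy=max(lines_of_therapy, 1),
        failure_count=len(failed_ordinals),
        mhs_contact=mhs_contact,
    )
    if is_trd:
        classification.trd_2_lines = classification.lines_of_therapy == 2
        classification.trd_3plus_lines = classification.lines_of_therapy >= 3
        classification.trd_4plus_lines = classification.lines_of_therapy >= 4
    events.sort(key=lambda e: (e.event_date, e.sequence_ordinal, EVENT_TYPES.index(e.event_type)))
    return events, classification


def classify_cohort(
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    cfg: StudyConfig,
    dictionary: CodeDictionary,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every eligible cohort patient.

    Only prescriptions issued within the study window enter sequence
    construction (the index rule anchors all person-time at the first
    in-window script). Returns ``(events_frame, classes_frame)``.
    """
    eligible = cohort[cohort["eligible"]]
    in_window = prescriptions[
        (prescriptions["issue_date"] >= cfg.study_start)
        & (prescriptions["issue_date"] <= cfg.study_end)
    ]
    rx_by_pt = dict(tuple(in_window.groupby("patient_id", sort=False)))
    mhs_ids = set(
        events.loc[events["category"].isin(["mhs_referral", "mhs_contact"]), "patient_id"]
    )

    event_rows = []
    class_rows = []
    for pid in eligible["patient_id"]:
        scripts = rx_by_pt.get(pid)
        if scripts is None:
            continue  # eligibility guarantees an in-window script; defensive
        sequences = build_patient_sequences(scripts, cfg)
        if not sequences:
            continue
        ad_dates = list(
            scripts.loc[scripts["drug_role"] == "antidepressant", "issue_date"]
        )
        pt_events, classification = classify_patient(
            sequences, ad_dates, cfg, dictionary, mhs_contact=pid in mhs_ids
        )
        for ev in pt_events:
            event_rows.append(dataclasses.asdict(ev))
        class_rows.append(dataclasses.asdict(classification))

    events_frame = pd.DataFrame(
        event_rows,
        columns=[
            "patient_id",
            "event_type",
            "sequence_ordinal",
            "event_date",
            "related_ordinal",
            "rule_trace",
        ],
    )
    classes_frame = pd.DataFrame(
        class_rows,
        columns=[
            "patient_id",
            "group",
            "lines_of_therapy",
            "failure_count",
            "trd_2_lines",
            "trd_3plus_lines",
            "trd_4plus_lines",
            "mhs_contact",
        ],
    )
    return events_frame, classes_frame
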