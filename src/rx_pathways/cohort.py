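"""Eligibility, exclusion and index-date rules producing the analysable cohort.

A patient enters the cohort when all of the following hold: they appear
in the demographics table (standing in for GP registration), they are an
adult (18 or older at the index date), they carry at least one coded
depression diagnosis recorded any time up to the end of the study (the
code may postdate the first prescription), they received at least one
antidepressant prescription inside the study window (the earliest such
script is the index date), and they have no exclusion diagnosis
(bipolar, dementia, mania, psychosis, schizophrenia spectrum) recorded
on or after the exclusion look-back start.
"""

from __future__ import annotations

import dataclasses
from datetime import date

import pandas as pd

from .config import StudyConfig

EXCLUSION_REASONS = (
    "not_registered",
    "under_18",
    "no_depression_code",
    "no_antidepressant_in_window",
    "exclusion_code",
)


@dataclasses.dataclass
class CohortEntry:
    patient_id: str
    index_date: date | None
    eligible: bool
    exclusion_reasons: list[str]


def compute_index_date(scripts: pd.DataFrame, cfg: StudyConfig) -> date | None:
    """Earliest antidepressant issue date within the study window, else None."""
    if scripts.empty:
        return None
    ad = scripts[
        (scripts["drug_role"] == "antidepressant")
        & (scripts["issue_date"] >= cfg.study_start)
        & (scripts["issue_date"] <= cfg.study_end)
    ]
    if ad.empty:
        return None
    return ad["issue_date"].min()


def check_exclusions(events: pd.DataFrame, cfg: StudyConfig) -> list[str]:
    """['exclusion_code'] iff an exclusion-category diagnosis falls on/after
    the look-back start; earlier exclusion codes are disregarded."""
    if events.empty:
        return []
    hits = events[
        (events["category"] == "exclusion")
        & (events["event_date"] >= cfg.exclusion_lookback_start)
    ]
    return ["exclusion_code"] if not hits.empty else []


def _age_at(birth: date, when: date) -> int:
    return when.year - birth.year - ((when.month, when.day) < (birth.month, birth.day))


def build_cohort(
    prescriptions: pd.DataFrame,
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    cfg: StudyConfig,
) -> pd.DataFrame:
    """One row per patient seen anywhere in the inputs, with eligibility.

    Columns: ``patient_id, index_date, eligible, exclusion_reasons``
    (reasons ';'-joined, empty iff eligible). Patients missing a birth
    date are ineligible with an unresolved ``under_18`` flag, since
    adulthood cannot be confirmed.
    """
    ids = (
        set(prescriptions["patient_id"])
        | set(events["patient_id"])
        | set(demographics["patient_id"])
    )
    birth = demographics.set_index("patient_id")["birth_date"]
    rx_by_pt = dict(tuple(prescriptions.groupby("patient_id", sort=False)))
    ev_by_pt = dict(tuple(events.groupby("patient_id", sort=False)))
    empty_rx = prescriptions.iloc[0:0]
    empty_ev = events.iloc[0:0]

    rows = []
    for pid in sorted(ids):
        scripts = rx_by_pt.get(pid, empty_rx)
        evs = ev_by_pt.get(pid, empty_ev)
        reasons: list[str] = []
        index_date = compute_index_date(scripts, cfg)
        if index_date is None:
            reasons.append("no_antidepressant_in_window")
        if pid not in birth.index:
            reasons.append("not_registered")
        else:
            dob = birth.loc[pid]
            if not isinstance(dob, date):
                # unknown date of birth: adulthood unresolved
                reasons.append("under_18")
            elif index_date is not None and _age_at(dob, index_date) < 18:
                reasons.append("under_18")
        depression = evs[
            (evs["category"] == "depression") & (evs["event_date"] <= cfg.study_end)
        ]
        if depression.empty:
            reasons.append("no_depression_code")
        reasons.extend(check_exclusions(evs, cfg))
        rows.append(
            {
                "patient_id": pid,
                "index_date": index_date,
                "eligible": not reasons,
                "exclusion_reasons": ";".join(reasons),
            }
        )
    out = pd.DataFrame(rows, columns=["patient_id", "index_date", "eligible", "exclusion_reasons"])
    return out
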