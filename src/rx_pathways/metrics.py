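"""Per-patient and per-group summary measures with disclosure control.

Day counts are converted to months with a fixed 30.44-day month. Group
summaries cover the MDD group, the TRD group, the TRD subgroups with
three-or-more and four-or-more lines of therapy, and the subgroup in
contact with secondary mental health services (which overlaps both MDD
and TRD — it is not a partition). All emitted count cells obey the
warehouse suppression rule: integers 0-4 render as ``"<5"``.
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

from .config import StudyConfig

log = logging.getLogger(__name__)

GROUPS = ("MDD", "TRD", "TRD3+", "TRD4+", "MHS")

METRIC_COLUMNS = [
    "patient_id",
    "months_in_study",
    "duration_of_depression_months",
    "time_to_mhs_contact_months",
    "n_prescriptions",
    "n_resumptions",
    "n_combination_prescriptions",
    "n_augmentation_prescriptions",
    "n_responses",
    "n_relapses",
    "remission_flag",
    "suicidality_record_count",
]


def time_to_first_mhs_contact(
    patient_events: pd.DataFrame, cfg: StudyConfig
) -> float | None:
    """Months from the earliest depression code to the first referral code
    or recorded mental-health-service contact (any route counts; a
    referral is not required). None when no contact is recorded. A
    contact predating the depression code yields a negative duration,
    kept as-is with a warning as a data-quality signal."""
    dep = patient_events.loc[patient_events["category"] == "depression", "event_date"]
    if dep.empty:
        return None
    contact = patient_events.loc[
        patient_events["category"].isin(["mhs_referral", "mhs_contact"]), "event_date"
    ]
    if contact.empty:
        return None
    days = (contact.min() - dep.min()).days
    if days < 0:
        log.warning(
            "patient %s: mental-health contact precedes first depression code by %dd",
            patient_events["patient_id"].iloc[0],
            -days,
        )
    return days / cfg.month_length_days


def compute_patient_metrics(
    prescriptions: pd.DataFrame,
    clinical_events: pd.DataFrame,
    pathway_events: pd.DataFrame,
    cohort: pd.DataFrame,
    cfg: StudyConfig,
) -> pd.DataFrame:
    """One row of summary measures per classified patient.

    ``duration_of_depression_months`` runs from the earliest depression
    code to the first response, or to the study end when no response
    occurred. Prescription counts cover in-window antidepressant scripts;
    resumption/combination/augmentation counts tally classified events.
    """
    eligible = cohort[cohort["eligible"]]
    rx = prescriptions[
        (prescriptions["drug_role"] == "antidepressant")
        & (prescriptions["issue_date"] >= cfg.study_start)
        & (prescriptions["issue_date"] <= cfg.study_end)
    ]
    rx_counts = rx.groupby("patient_id").size()
    ev_by_pt = dict(tuple(clinical_events.groupby("patient_id", sort=False)))
    pw_by_pt = dict(tuple(pathway_events.groupby("patient_id", sort=False)))
    empty_ev = clinical_events.iloc[0:0]
    empty_pw = pathway_events.iloc[0:0]

    rows = []
    for entry in eligible.itertuples(index=False):
        pid = entry.patient_id
        index_date: date = entry.index_date
        evs = ev_by_pt.get(pid, empty_ev)
        pws = pw_by_pt.get(pid, empty_pw)
        type_counts = pws["event_type"].value_counts()

        dep_dates = evs.loc[evs["category"] == "depression", "event_date"]
        responses = pws.loc[pws["event_type"] == "response", "event_date"]
        if dep_dates.empty:
            duration_dep = np.nan
        else:
            until = responses.min() if not responses.empty else cfg.study_end
            duration_dep = (until - dep_dates.min()).days / cfg.month_length_days

        rows.append(
            {
                "patient_id": pid,
                "months_in_study": (cfg.study_end - index_date).days / cfg.month_length_days,
                "duration_of_depression_months": duration_dep,
                "time_to_mhs_contact_months": time_to_first_mhs_contact(evs, cfg)
                if not evs.empty
                else None,
                "n_prescriptions": int(rx_counts.get(pid, 0)),
                "n_resumptions": int(type_counts.get("resumption", 0)),
                "n_combination_prescriptions": int(type_counts.get("combination", 0)),
                "n_augmentation_prescriptions": int(type_counts.get("augmentation", 0)),
                "n_responses": int(type_counts.get("response", 0)),
                "n_relapses": int(type_counts.get("relapse", 0)),
                "remission_flag": bool(type_counts.get("remission", 0)),
                "suicidality_record_count": int((evs["category"] == "suicidality").sum()),
            }
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def suppress_small_counts(table: pd.DataFrame, cfg: StudyConfig | None = None) -> pd.DataFrame:
    """Render every integer count cell in [0, ceiling) as ``"<{ceiling}"``.

    Non-count cells (floats with fractional part, strings, missing) pass
    through unchanged; a negative count is a hard error. Idempotent.
    """
    ceiling = cfg.suppression_ceiling if cfg is not None else 5
    marker = f"<{ceiling}"

    def _cell(value):
        if isinstance(value, str) or value is None:
            return value
        if isinstance(value, (bool, np.bool_)):
            value = int(value)
        if isinstance(value, (int, np.integer)) or (
            isinstance(value, (float, np.floating)) and float(value).is_integer()
        ):
            iv = int(value)
            if iv < 0:
                raise ValueError(f"negative count {iv} in table under suppression")
            return marker if iv < ceiling else str(iv)
        return value

    return table.map(_cell)


def _group_masks(classes: pd.DataFrame) -> dict[str, pd.Series]:
    return {
        "MDD": classes["group"] == "MDD",
        "TRD": classes["group"] == "TRD",
        "TRD3+": classes["trd_3plus_lines"].astype(bool),
        "TRD4+": classes["trd_4plus_lines"].astype(bool),
        "MHS": classes["mhs_contact"].astype(bool),
    }


def summarize_groups(
    metrics: pd.DataFrame, classes: pd.DataFrame, cfg: StudyConfig
) -> dict[str, pd.DataFrame]:
    """Group summary tables shaped like the study's outcome tables.

    Returns ``{"summary": ..., "rates": ..., "counts": ...}``:
    ``summary`` holds n/mean/s.d./median/range per numeric measure and
    group; ``rates`` holds outcome percentages per group; ``counts`` is
    the suppressed patient-count table. Empty groups produce suppressed
    or missing cells, never a division by zero.
    """
    merged = metrics.merge(classes, on="patient_id", validate="one_to_one")
    masks = _group_masks(merged)

    numeric = [
        "months_in_study",
        "duration_of_depression_months",
        "time_to_mhs_contact_months",
        "n_prescriptions",
        "n_resumptions",
        "n_combination_prescriptions",
        "n_augmentation_prescriptions",
        "n_responses",
        "n_relapses",
        "suicidality_record_count",
    ]
    summary_rows = []
    for measure in numeric:
        for stat in ("n", "mean", "sd", "median", "min", "max"):
            row = {"measure": measure, "statistic": stat}
            for name, mask in masks.items():
                values = merged.loc[mask, measure].dropna().astype(float)
                if values.empty:
                    row[name] = np.nan
                elif stat == "n":
                    row[name] = float(len(values))
                elif stat == "sd":
                    row[name] = float(values.std(ddof=1)) if len(values) > 1 else 0.0
                else:
                    row[name] = float(getattr(values, stat)())
            summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    rate_rows = []
    outcome_flags = {
        "response": merged["n_responses"] >= 1,
        "relapse": merged["n_relapses"] >= 1,
        "remission": merged["remission_flag"].astype(bool),
        "resumption": merged["n_resumptions"] >= 1,
        "augmentation": merged["n_augmentation_prescriptions"] >= 1,
        "combination": merged["n_combination_prescriptions"] >= 1,
        "suicidality_recorded": merged["suicidality_record_count"] >= 1,
    }
    for outcome, flag in outcome_flags.items():
        row = {"outcome": outcome}
        for name, mask in masks.items():
            denom = int(mask.sum())
            row[name] = 100.0 * float((flag & mask).sum()) / denom if denom else np.nan
        rate_rows.append(row)
    rates = pd.DataFrame(rate_rows)

    count_rows = [{"measure": "n_patients", **{g: int(m.sum()) for g, m in masks.items()}}]
    for outcome, flag in outcome_flags.items():
        count_rows.append(
            {"measure": f"n_{outcome}", **{g: int((flag & m).sum()) for g, m in masks.items()}}
        )
    counts = suppress_small_counts(pd.DataFrame(count_rows), cfg)

    total = len(merged)
    for name in ("MDD", "TRD"):
        assert int(masks[name].sum()) <= total
    assert int(masks["MDD"].sum()) + int(masks["TRD"].sum()) == total
    return {"summary": summary, "rates": rates, "counts": counts}
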