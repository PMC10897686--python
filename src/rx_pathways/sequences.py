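"""Drug coverage intervals and constant-regimen treatment sequences.

Each issued script covers ``[issue_date, issue_date + supply_days)``.
Same-ingredient coverage separated by a gap no longer than the
same-regimen tolerance is bridged (short adherence lapses and late
refills must not fragment exposure); overlapping same-ingredient scripts
extend coverage to the latest end without stacking supply. The patient's
timeline is then partitioned at every date where the set of concurrently
covered antidepressant ingredients (the regimen) changes; each maximal
constant-regimen span is one treatment sequence. Dose changes are
recorded but never split a sequence.

All intervals are half-open ``[start, end)`` in whole days; on a regimen
change the new regimen owns the change date.
"""

from __future__ import annotations

import dataclasses
from datetime import date, timedelta

import pandas as pd

from .config import StudyConfig

_MISSING = object()  # sentinel: missing dose equals missing, differs from any number


def _dose_key(value):
    if value is None or (isinstance(value, float) and value != value):
        return _MISSING
    return float(value)


@dataclasses.dataclass
class CoverageInterval:
    """Merged exposure window for one patient and one ingredient."""

    patient_id: str
    ingredient: str
    start: date
    end: date  # half-open
    dose_trace: list[tuple[date, object]] = dataclasses.field(default_factory=list)
    agent_class: str | None = None  # populated for augmentation agents

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclasses.dataclass
class Augmentation:
    agent_class: str
    ingredient: str
    start: date
    end: date

    @property
    def days(self) -> int:
        return (self.end - self.start).days


@dataclasses.dataclass
class TreatmentSequence:
    """Maximal span with a constant set of antidepressant ingredients."""

    patient_id: str
    regimen: frozenset[str]
    start: date
    end: date  # half-open
    ordinal: int = 0
    dose_changes: int = 0
    doses: dict[str, tuple] = dataclasses.field(default_factory=dict)
    augmentations: list[Augmentation] = dataclasses.field(default_factory=list)
    preceded_by: str | None = None  # transition type filled by the classifier

    @property
    def days(self) -> int:
        return (self.end - self.start).days


def expand_and_merge_coverage(
    scripts: pd.DataFrame, cfg: StudyConfig
) -> list[CoverageInterval]:
    """Build merged per-ingredient coverage for one patient's scripts.

    ``scripts`` carries one drug role (antidepressants, or augmentation
    agents when building augmentation coverage). Gaps up to
    ``cfg.same_regimen_gap_tolerance_days`` between consecutive
    same-ingredient scripts are bridged; overlaps never stack.
    """
    intervals: list[CoverageInterval] = []
    if scripts.empty:
        return intervals
    if scripts["patient_id"].nunique() > 1:
        raise ValueError("expand_and_merge_coverage expects a single patient's scripts")
    tol = cfg.same_regimen_gap_tolerance_days
    for ingredient, group in scripts.groupby("ingredient", sort=True):
        group = group.sort_values(["issue_date"], kind="stable")
        current: CoverageInterval | None = None
        for row in group.itertuples(index=False):
            start = row.issue_date
            end = start + timedelta(days=int(row.supply_days))
            dose = _dose_key(row.daily_dose)
            agent = getattr(row, "agent_class", None)
            if current is not None and (start - current.end).days <= tol:
                if end > current.end:
                    current.end = end
                current.dose_trace.append((start, dose))
            else:
                if current is not None:
                    intervals.append(current)
                current = CoverageInterval(
                    patient_id=row.patient_id,
                    ingredient=ingredient,
                    start=start,
                    end=end,
                    dose_trace=[(start, dose)],
                    agent_class=agent if isinstance(agent, str) else None,
                )
        intervals.append(current)
    intervals.sort(key=lambda iv: (iv.start, iv.ingredient))
    return intervals


def _doses_in_span(interval: CoverageInterval, start: date, end: date) -> list:
    """Dose values prevailing over ``[start, end)``: the latest value at or
    before span start plus every change inside the span."""
    prevailing = None
    inside = []
    for when, value in interval.dose_trace:
        if when <= start:
            prevailing = value
        elif when < end:
            inside.append(value)
    values = inside if prevailing is None else [prevailing, *inside]
    return values


def derive_sequences(
    coverage: list[CoverageInterval], cfg: StudyConfig
) -> list[TreatmentSequence]:
    """Partition merged coverage into maximal constant-regimen sequences.

    Change points are the starts and ends of coverage intervals; spans
    with an empty regimen separate sequences. Dose-change counting sums,
    over the ingredients of the regimen, the number of distinct dose
    values observed within the span minus one (a missing dose is its own
    value: equal to missing, different from any number).
    """
    if not coverage:
        return []
    patient_id = coverage[0].patient_id
    bounds = sorted({iv.start for iv in coverage} | {iv.end for iv in coverage})
    segments: list[tuple[date, date, frozenset[str]]] = []
    for left, right in zip(bounds[:-1], bounds[1:]):
        regimen = frozenset(
            iv.ingredient for iv in coverage if iv.start <= left and iv.end >= right
        )
        if regimen:
            segments.append((left, right, regimen))

    sequences: list[TreatmentSequence] = []
    for left, right, regimen in segments:
        if (
            sequences
            and sequences[-1].regimen == regimen
            and sequences[-1].end == left
        ):
            sequences[-1].end = right
        else:
            sequences.append(
                TreatmentSequence(patient_id=patient_id, regimen=regimen, start=left, end=right)
            )

    by_ingredient: dict[str, list[CoverageInterval]] = {}
    for iv in coverage:
        by_ingredient.setdefault(iv.ingredient, []).append(iv)
    for ordinal, seq in enumerate(sequences, start=1):
        seq.ordinal = ordinal
        changes = 0
        for ingredient in sorted(seq.regimen):
            values: list = []
            for iv in by_ingredient[ingredient]:
                if iv.start < seq.end and iv.end > seq.start:
                    values.extend(_doses_in_span(iv, seq.start, seq.end))
            distinct = {v if v is _MISSING else float(v) for v in values}
            seq.doses[ingredient] = tuple(
                sorted((v for v in distinct if v is not _MISSING))
            ) + ((None,) if _MISSING in distinct else ())
            if distinct:
                changes += len(distinct) - 1
        seq.dose_changes = changes
    return sequences


def attach_augmentations(
    sequences: list[TreatmentSequence],
    agent_coverage: list[CoverageInterval],
    cfg: StudyConfig,
) -> list[TreatmentSequence]:
    """Attach augmentation agents overlapping a sequence long enough.

    An agent (lithium, an antipsychotic, thyroxine, tri-iodothyronine or
    an anticonvulsant) augments a sequence iff its merged coverage
    overlaps the sequence for at least ``cfg.augmentation_min_days``.
    An agent spanning several sequences can augment each of them.
    """
    for seq in sequences:
        for iv in agent_coverage:
            left = max(seq.start, iv.start)
            right = min(seq.end, iv.end)
            if (right - left).days >= cfg.augmentation_min_days:
                seq.augmentations.append(
                    Augmentation(
                        agent_class=iv.agent_class or "unknown",
                        ingredient=iv.ingredient,
                        start=left,
                        end=right,
                    )
                )
    return sequences


def build_patient_sequences(
    scripts: pd.DataFrame, cfg: StudyConfig
) -> list[TreatmentSequence]:
    """Full per-patient path: scripts -> coverage -> sequences -> augmentations."""
    ad = scripts[scripts["drug_role"] == "antidepressant"]
    coverage = expand_and_merge_coverage(ad, cfg)
    sequences = derive_sequences(coverage, cfg)
    ag = scripts[scripts["drug_role"] == "augmentation_agent"]
    if not ag.empty:
        agent_coverage = expand_and_merge_coverage(ag, cfg)
        attach_augmentations(sequences, agent_coverage, cfg)
    return sequences


def sequences_frame(sequences: list[TreatmentSequence]) -> pd.DataFrame:
    """Audit table: one row per sequence, regimen '+'-joined."""
    rows = [
        {
            "patient_id": s.patient_id,
            "regimen": "+".join(sorted(s.regimen)),
            "start": s.start,
            "end": s.end,
            "ordinal": s.ordinal,
            "days": s.days,
            "dose_changes": s.dose_changes,
            "n_augmentations": len(s.augmentations),
        }
        for s in sequences
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "regimen",
            "start",
            "end",
            "ordinal",
            "days",
            "dose_changes",
            "n_augmentations",
        ],
    )
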