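"""Study configuration: windows, thresholds and calendar bounds.

Every day-count threshold used by the pathway rules lives here, so a
single object documents the operational definitions and makes them
adjustable without touching rule code. Interval arithmetic throughout
the package is in integer days on half-open intervals ``[start, end)``.
"""

from __future__ import annotations

import dataclasses
from datetime import date
from pathlib import Path

import yaml


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return date.fromisoformat(str(value))


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    """Parameters of the pathway-derivation rules.

    Attributes
    ----------
    study_start, study_end:
        Inclusive calendar bounds of the observation window. The index
        date (first antidepressant prescription) must fall inside them.
    exclusion_lookback_start:
        Exclusion diagnoses (bipolar, dementia, mania, psychosis,
        schizophrenia spectrum) recorded on/after this date make a
        patient ineligible.
    default_supply_days:
        Supply imputed for a prescription with no recorded quantity;
        30 days is the typical script length in UK primary care.
    response_min_days:
        Minimum length of a constant-regimen sequence to count as a
        treatment response (dose changes permitted).
    remission_response_days:
        Sequence length that by itself indicates remission.
    remission_gap_days:
        Length of the antidepressant-free look-forward after a
        responding sequence that indicates remission by discontinuation.
    relapse_window_days:
        ``(low, high)`` inclusive gap window, in days after the end of a
        responding sequence, within which a new sequence is a relapse.
    switch_gap_min_days, switch_gap_max_days:
        Gap window for classifying a regimen replacement as a switch.
        The operational definition allows 60-180 days of delay; the
        default lower bound of 0 additionally treats immediate
        replacements as switches (set to 60 for the literal window).
    combination_min_days:
        Minimum duration of the enlarged regimen for a combination.
    augmentation_min_days:
        Minimum overlap of an augmentation agent with a sequence.
    adequate_line_min_days:
        Minimum duration for a failed line to count as an adequate
        trial when deciding treatment resistance (6 weeks by default,
        the guideline review horizon).
    same_regimen_gap_tolerance_days:
        Same-drug prescription gaps up to this length are bridged when
        building coverage, so short adherence lapses do not fragment a
        sequence.
    episode_gap_days:
        A treatment-free gap strictly longer than this closes a
        depressive episode; failed-line counting for treatment
        resistance restarts in the next episode.
    month_length_days:
        Divisor for day-to-month conversions in reported metrics.
    suppression_ceiling:
        Counts strictly below this render as ``"<5"`` in aggregate
        tables (statistical disclosure control).
    """

    study_start: date = date(2015, 1, 1)
    study_end: date = date(2020, 12, 31)
    exclusion_lookback_start: date = date(2010, 1, 1)
    default_supply_days: int = 30
    response_min_days: int = 90
    remission_response_days: int = 180
    remission_gap_days: int = 60
    relapse_window_days: tuple[int, int] = (60, 180)
    switch_gap_min_days: int = 0
    switch_gap_max_days: int = 180
    combination_min_days: int = 45
    augmentation_min_days: int = 45
    adequate_line_min_days: int = 42
    same_regimen_gap_tolerance_days: int = 60
    episode_gap_days: int = 180
    month_length_days: float = 30.44
    suppression_ceiling: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "study_start", _parse_date(self.study_start))
        object.__setattr__(self, "study_end", _parse_date(self.study_end))
        object.__setattr__(
            self, "exclusion_lookback_start", _parse_date(self.exclusion_lookback_start)
        )
        if isinstance(self.relapse_window_days, list):
            object.__setattr__(self, "relapse_window_days", tuple(self.relapse_window_days))
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        low, high = self.relapse_window_days
        if not 0 < low < high:
            raise ValueError("relapse window must satisfy 0 < low < high")
        for name in (
            "default_supply_days",
            "response_min_days",
            "remission_response_days",
            "remission_gap_days",
            "combination_min_days",
            "augmentation_min_days",
            "adequate_line_min_days",
            "same_regimen_gap_tolerance_days",
            "episode_gap_days",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.switch_gap_min_days < 0 or self.switch_gap_max_days <= self.switch_gap_min_days:
            raise ValueError("switch gap window must satisfy 0 <= min < max")
        if self.month_length_days <= 0:
            raise ValueError("month_length_days must be positive")

    @property
    def study_end_exclusive(self) -> date:
        """First day after the study window (half-open convention)."""
        from datetime import timedelta

        return self.study_end + timedelta(days=1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        """Load a config from a YAML mapping; missing keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("study_start", "study_end", "exclusion_lookback_start"):
            out[key] = out[key].isoformat()
        out["relapse_window_days"] = list(self.relapse_window_days)
        return out
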