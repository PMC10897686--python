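"""Readers, writers and code dictionaries for primary-care style records.

Inputs are plain delimited text (comma, UTF-8, header row): one table of
antidepressant / augmentation prescriptions, one of coded clinical
events, one of demographics. A code dictionary — itself a CSV, shipped
with defaults but fully user-replaceable — maps raw drug and clinical
codes onto the canonical ingredients and event categories the pathway
rules operate on.

Prescriptions and clinical events are held as pandas DataFrames with
normalised column types; reject/unknown-code counts from a read are
attached to ``DataFrame.attrs`` so no row is dropped silently.
"""

from __future__ import annotations

import dataclasses
import logging
from datetime import date
from importlib import resources
from pathlib import Path

import pandas as pd

from .config import StudyConfig

log = logging.getLogger(__name__)

DRUG_ROLES = frozenset({"antidepressant", "augmentation_agent", "other"})
AUGMENTATION_CLASSES = frozenset(
    {"lithium", "antipsychotic", "thyroxine", "tri_iodothyronine", "anticonvulsant"}
)
CLINICAL_CATEGORIES = frozenset(
    {
        "depression",
        "exclusion",
        "comorbidity",
        "suicidality",
        "mhs_referral",
        "mhs_contact",
        "assessment",
    }
)
CODE_SYSTEMS = frozenset({"read_v2", "icd10"})

PRESCRIPTION_COLUMNS = [
    "patient_id",
    "drug_code",
    "ingredient",
    "drug_role",
    "agent_class",
    "issue_date",
    "daily_dose",
    "supply_days",
]
EVENT_COLUMNS = ["patient_id", "code", "code_system", "category", "event_date"]


@dataclasses.dataclass(frozen=True)
class DrugEntry:
    """Dictionary entry for a prescribable drug code."""

    code: str
    ingredient: str
    role: str  # antidepressant | augmentation_agent | other
    agent_class: str | None = None  # set for augmentation agents
    min_daily_dose: float | None = None  # minimum effective daily dose, dictionary units


@dataclasses.dataclass(frozen=True)
class ClinicalEntry:
    """Dictionary entry for a coded clinical event."""

    code: str
    label: str
    category: str
    code_system: str


class CodeDictionary:
    """Raw code -> ingredient/category lookup for drugs and clinical events.

    The dictionary is the single source of truth for which drugs are
    antidepressants, which are augmentation agents (and of which class),
    and which clinical codes mean depression, an exclusion diagnosis, a
    comorbidity, suicidality, or mental-health-service referral/contact.
    No raw code may carry two meanings.
    """

    def __init__(self, drugs: list[DrugEntry], clinical: list[ClinicalEntry]):
        self.drugs: dict[str, DrugEntry] = {}
        self.clinical: dict[str, ClinicalEntry] = {}
        for entry in drugs:
            prev = self.drugs.get(entry.code)
            if prev is not None and prev != entry:
                raise ValueError(f"code {entry.code!r} has conflicting drug mappings")
            if entry.code in self.clinical:
                raise ValueError(f"code {entry.code!r} mapped as both drug and clinical code")
            self.drugs[entry.code] = entry
        for entry in clinical:
            prev = self.clinical.get(entry.code)
            if prev is not None and prev != entry:
                raise ValueError(f"code {entry.code!r} has conflicting clinical mappings")
            if entry.code in self.drugs:
                raise ValueError(f"code {entry.code!r} mapped as both drug and clinical code")
            self.clinical[entry.code] = entry

    def drug_role(self, code: str) -> str:
        entry = self.drugs.get(code)
        return entry.role if entry is not None else "other"

    def ingredient(self, code: str) -> str | None:
        entry = self.drugs.get(code)
        return entry.ingredient if entry is not None else None

    def min_daily_dose(self, ingredient: str) -> float | None:
        """Minimum effective daily dose for an antidepressant ingredient."""
        for entry in self.drugs.values():
            if entry.ingredient == ingredient and entry.min_daily_dose is not None:
                return entry.min_daily_dose
        return None

    def category(self, code: str) -> str:
        entry = self.clinical.get(code)
        return entry.category if entry is not None else "other"

    @property
    def antidepressants(self) -> set[str]:
        return {e.ingredient for e in self.drugs.values() if e.role == "antidepressant"}


def load_code_dictionary(path: str | Path) -> CodeDictionary:
    """Load a combined drug + clinical code dictionary from CSV.

    Expected columns: ``code, name, category, agent_class, min_daily_dose,
    code_system``. ``category`` is either a drug role (``antidepressant``,
    ``augmentation_agent``, ``other``) or a clinical event category.
    ``agent_class`` and ``min_daily_dose`` apply to drug rows only;
    ``code_system`` to clinical rows only.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"code", "name", "category"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"code dictionary {path} missing columns: {sorted(missing)}")
    if frame.empty:
        log.warning("code dictionary %s is empty", path)
        return CodeDictionary([], [])

    drugs: list[DrugEntry] = []
    clinical: list[ClinicalEntry] = []
    for row in frame.itertuples(index=False):
        code = row.code.strip()
        category = row.category.strip()
        if not code:
            raise ValueError(f"code dictionary {path}: blank code for name {row.name!r}")
        if category in DRUG_ROLES:
            agent_class = getattr(row, "agent_class", "") or None
            if category == "augmentation_agent":
                if agent_class not in AUGMENTATION_CLASSES:
                    raise ValueError(
                        f"augmentation agent {code!r} has unknown class {agent_class!r}"
                    )
            elif agent_class:
                raise ValueError(f"drug {code!r}: agent_class only valid for augmentation agents")
            raw_dose = getattr(row, "min_daily_dose", "")
            dose = float(raw_dose) if raw_dose else None
            drugs.append(DrugEntry(code, row.name.strip(), category, agent_class, dose))
        elif category in CLINICAL_CATEGORIES:
            system = getattr(row, "code_system", "") or "read_v2"
            if system not in CODE_SYSTEMS:
                raise ValueError(f"clinical code {code!r} has unknown code_system {system!r}")
            clinical.append(ClinicalEntry(code, row.name.strip(), category, system))
        else:
            raise ValueError(f"code {code!r} has unknown category {category!r}")
    return CodeDictionary(drugs, clinical)


def default_code_dictionary() -> CodeDictionary:
    """The bundled sample dictionary (small, synthetic code values)."""
    with resources.as_file(
        resources.files("rx_pathways").joinpath("data/default_codes.csv")
    ) as path:
        return load_code_dictionary(path)


def _parse_dates(series: pd.Series) -> pd.Series:
    return pd.to_datetime(series, format="%Y-%m-%d", errors="coerce").dt.date


def read_prescriptions(
    path: str | Path, dictionary: CodeDictionary, cfg: StudyConfig
) -> pd.DataFrame:
    """Read a prescription table and resolve drug codes.

    Required columns: ``patient_id, drug_code, issue_date, daily_dose,
    supply_days``. Rows with an unparseable date or blank patient id are
    rejected (counted in ``result.attrs['n_rejected']``, logged with row
    numbers); a missing supply defaults to ``cfg.default_supply_days``;
    codes absent from the dictionary keep role ``other``. Output is
    sorted by (patient_id, issue_date, drug_code).
    """
    frame = pd.read_csv(path, dtype={"patient_id": str, "drug_code": str})
    required = {"patient_id", "drug_code", "issue_date"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"prescriptions file {path} missing columns: {sorted(missing)}")

    parsed = _parse_dates(frame["issue_date"].astype(str))
    blank_id = frame["patient_id"].isna() | (frame["patient_id"].astype(str).str.strip() == "")
    bad = parsed.isna() | blank_id
    for idx in frame.index[bad]:
        log.warning("prescriptions %s row %d rejected (bad date or patient id)", path, idx + 2)
    out = frame.loc[~bad].copy()
    out["issue_date"] = parsed[~bad]
    out["patient_id"] = out["patient_id"].astype(str)
    out["drug_code"] = out["drug_code"].astype(str)

    if "daily_dose" in out.columns:
        out["daily_dose"] = pd.to_numeric(out["daily_dose"], errors="coerce")
    else:
        out["daily_dose"] = float("nan")
    if "supply_days" in out.columns:
        supply = pd.to_numeric(out["supply_days"], errors="coerce")
    else:
        supply = pd.Series(float("nan"), index=out.index)
    n_defaulted = int(supply.isna().sum())
    supply = supply.fillna(cfg.default_supply_days).astype(int)
    if (supply < 1).any():
        raise ValueError(f"prescriptions file {path}: supply_days must be >= 1")
    out["supply_days"] = supply

    out["ingredient"] = out["drug_code"].map(
        lambda c: dictionary.ingredient(c) or c
    )
    out["drug_role"] = out["drug_code"].map(dictionary.drug_role)
    out["agent_class"] = out["drug_code"].map(
        lambda c: (dictionary.drugs.get(c).agent_class if c in dictionary.drugs else None)
    )
    n_unknown = int((~out["drug_code"].isin(dictionary.drugs.keys())).sum())
    if n_unknown:
        log.warning("prescriptions %s: %d scripts with codes outside dictionary", path, n_unknown)

    out = out[PRESCRIPTION_COLUMNS].sort_values(
        ["patient_id", "issue_date", "drug_code"], kind="stable"
    )
    out = out.reset_index(drop=True)
    out.attrs["n_rejected"] = int(bad.sum())
    out.attrs["n_supply_defaulted"] = n_defaulted
    out.attrs["n_unknown_codes"] = n_unknown
    return out


def read_clinical_events(path: str | Path, dictionary: CodeDictionary) -> pd.DataFrame:
    """Read a coded clinical event table and assign categories.

    Required columns: ``patient_id, code, code_system, event_date``.
    Unknown codes keep category ``other`` with a warning; rows with an
    invalid code system or unparseable date are rejected and counted.
    """
    frame = pd.read_csv(path, dtype=str)
    required = {"patient_id", "code", "code_system", "event_date"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"events file {path} missing columns: {sorted(missing)}")
    if frame.empty:
        out = pd.DataFrame(columns=EVENT_COLUMNS)
        out.attrs["n_rejected"] = 0
        return out

    parsed = _parse_dates(frame["event_date"].astype(str))
    bad_system = ~frame["code_system"].isin(CODE_SYSTEMS)
    blank_id = frame["patient_id"].isna() | (frame["patient_id"].astype(str).str.strip() == "")
    bad = parsed.isna() | bad_system | blank_id
    for idx in frame.index[bad]:
        log.warning("events %s row %d rejected (bad date, id or code_system)", path, idx + 2)
    out = frame.loc[~bad].copy()
    out["event_date"] = parsed[~bad]
    out["patient_id"] = out["patient_id"].astype(str)
    out["code"] = out["code"].astype(str)
    out["category"] = out["code"].map(dictionary.category)
    n_unknown = int((out["category"] == "other").sum())
    if n_unknown:
        log.warning("events %s: %d events with codes outside dictionary", path, n_unknown)

    out = out[EVENT_COLUMNS].sort_values(["patient_id", "event_date", "code"], kind="stable")
    out = out.reset_index(drop=True)
    out.attrs["n_rejected"] = int(bad.sum())
    out.attrs["n_unknown_codes"] = n_unknown
    return out


def read_demographics(path: str | Path) -> pd.DataFrame:
    """Read demographics: ``patient_id, birth_date`` (+ optional columns).

    A patient's presence in this table stands in for GP registration.
    An unparseable birth date is kept as missing (age then unresolved).
    """
    frame = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "birth_date"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"demographics file {path} missing columns: {sorted(missing)}")
    frame = frame.copy()
    frame["patient_id"] = frame["patient_id"].astype(str)
    frame["birth_date"] = _parse_dates(frame["birth_date"].astype(str))
    if frame["patient_id"].duplicated().any():
        raise ValueError(f"demographics file {path} has duplicate patient ids")
    return frame.reset_index(drop=True)


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV with ISO dates; round-trips through the readers."""
    out = frame.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, date)).any():
            out[col] = out[col].map(lambda v: v.isoformat() if isinstance(v, date) else "")
    out.to_csv(path, index=False)
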