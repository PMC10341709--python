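"""Patient-level cohort data model and CSV round-trip.

A cohort is a flat CSV (comma-separated, UTF-8, dot decimal, header row,
empty cell = missing) with one row per patient.  Each row carries the
lumbar-puncture analyte panel (CSF/serum CXCL13 in pg/mL, CSF/serum albumin
in any consistent unit pair, CSF total nucleated cell count per µL) and the
longitudinal outcome panel (CDMS conversion, attack and MRI counts,
follow-up years).  Records are validated on read; nothing is silently
coerced.
"""

from __future__ import annotations

import enum
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator


class Diagnosis(str, enum.Enum):
    CIS = "CIS"
    RIS = "RIS"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    #: accepted in data, excluded from sex-stratified summaries
    OTHER = "other"


class CohortValidationError(ValueError):
    """A row failed validation; the message names the row and column."""


class AnalytePanel(BaseModel):
    """Lumbar-puncture and serum analyte measurements for one patient.

    Concentrations must be strictly positive when present.  The two albumin
    measurements are only ever used as a ratio (the albumin quotient), so any
    unit is accepted as long as CSF and serum use the same one; the unit tags
    must match and both albumin values must be present or absent together.
    """

    model_config = ConfigDict(frozen=True)

    csf_cxcl13: float = Field(gt=0, description="CSF CXCL13, pg/mL")
    serum_cxcl13: Optional[float] = Field(default=None, gt=0, description="serum CXCL13, pg/mL")
    csf_albumin: Optional[float] = Field(default=None, gt=0)
    serum_albumin: Optional[float] = Field(default=None, gt=0)
    csf_albumin_unit: str = "mg/dL"
    serum_albumin_unit: str = "mg/dL"
    tnc: Optional[float] = Field(default=None, ge=0, description="CSF total nucleated cells per µL")

    @model_validator(mode="after")
    def _albumin_pair(self) -> "AnalytePanel":
        if (self.csf_albumin is None) != (self.serum_albumin is None):
            raise ValueError("csf_albumin and serum_albumin must be both present or both absent")
        if self.csf_albumin is not None and self.csf_albumin_unit != self.serum_albumin_unit:
            raise ValueError(
                f"albumin unit mismatch: csf={self.csf_albumin_unit!r} serum={self.serum_albumin_unit!r}"
            )
        return self


class OutcomePanel(BaseModel):
    """Longitudinal MS-activity outcomes over the follow-up window."""

    model_config = ConfigDict(frozen=True)

    converted_cdms: bool
    ocb_positive: bool
    n_attacks: int = Field(ge=0)
    n_mris: int = Field(ge=0)
    n_mris_with_new_lesions: int = Field(ge=0)
    n_new_or_enhancing_lesions: int = Field(ge=0)
    followup_years: float = Field(gt=0)

    @model_validator(mode="after")
    def _mri_counts(self) -> "OutcomePanel":
        if self.n_mris_with_new_lesions > self.n_mris:
            raise ValueError(
                f"n_mris_with_new_lesions={self.n_mris_with_new_lesions} exceeds n_mris={self.n_mris}"
            )
        return self


class PatientRecord(BaseModel):
    """One CIS/RIS subject: demographics, analytes and outcomes.

    ``diagnosis`` is consumed as given (clinical adjudication is out of
    scope).  ``study_eligible`` marks subjects meeting the study's follow-up
    requirement of at least five years.
    """

    model_config = ConfigDict(frozen=True)

    patient_id: str = Field(min_length=1)
    diagnosis: Diagnosis
    age: float = Field(gt=0)
    sex: Sex
    analytes: AnalytePanel
    outcomes: OutcomePanel
    treatment: str = "none"
    study_eligible: bool = True

    @model_validator(mode="after")
    def _eligibility(self) -> "PatientRecord":
        if self.study_eligible and self.outcomes.followup_years < 5:
            raise ValueError(
                f"study-eligible record has followup_years={self.outcomes.followup_years} < 5"
            )
        return self


#: CSV column order; every column maps 1:1 onto a model field.
COLUMNS: tuple[str, ...] = (
    "patient_id",
    "diagnosis",
    "age",
    "sex",
    "treatment",
    "study_eligible",
    "csf_cxcl13",
    "serum_cxcl13",
    "csf_albumin",
    "serum_albumin",
    "csf_albumin_unit",
    "serum_albumin_unit",
    "tnc",
    "converted_cdms",
    "ocb_positive",
    "n_attacks",
    "n_mris",
    "n_mris_with_new_lesions",
    "n_new_or_enhancing_lesions",
    "followup_years",
)

_ANALYTE_COLS = (
    "csf_cxcl13",
    "serum_cxcl13",
    "csf_albumin",
    "serum_albumin",
    "csf_albumin_unit",
    "serum_albumin_unit",
    "tnc",
)
_OUTCOME_COLS = (
    "converted_cdms",
    "ocb_positive",
    "n_attacks",
    "n_mris",
    "n_mris_with_new_lesions",
    "n_new_or_enhancing_lesions",
    "followup_years",
)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean: {raw!r}")


def _parse_float(raw: str) -> float:
    value = float(raw)
    if not math.isfinite(value):
        raise ValueError(f"non-finite value: {raw!r}")
    return value


def _parse_int(raw: str) -> int:
    return int(raw.strip())


def _cell(row: pd.Series, column: str) -> Optional[str]:
    raw = row.get(column, "")
    if raw is None:
        return None
    raw = str(raw).strip()
    return raw or None


def _record_from_row(row: pd.Series, row_label: int) -> PatientRecord:
    def require(column: str) -> str:
        raw = _cell(row, column)
        if raw is None:
            raise CohortValidationError(f"row {row_label}, column {column!r}: missing required value")
        return raw

    def parse(column: str, parser, required: bool = True):
        raw = require(column) if required else _cell(row, column)
        if raw is None:
            return None
        try:
            return parser(raw)
        except (ValueError, TypeError) as exc:
            raise CohortValidationError(f"row {row_label}, column {column!r}: {exc}") from exc

    analyte_kwargs = {
        "csf_cxcl13": parse("csf_cxcl13", _parse_float),
        "serum_cxcl13": parse("serum_cxcl13", _parse_float, required=False),
        "csf_albumin": parse("csf_albumin", _parse_float, required=False),
        "serum_albumin": parse("serum_albumin", _parse_float, required=False),
        "tnc": parse("tnc", _parse_float, required=False),
    }
    for unit_col in ("csf_albumin_unit", "serum_albumin_unit"):
        raw = _cell(row, unit_col)
        if raw is not None:
            analyte_kwargs[unit_col] = raw
    outcome_kwargs = {
        "converted_cdms": parse("converted_cdms", _parse_bool),
        "ocb_positive": parse("ocb_positive", _parse_bool),
        "n_attacks": parse("n_attacks", _parse_int),
        "n_mris": parse("n_mris", _parse_int),
        "n_mris_with_new_lesions": parse("n_mris_with_new_lesions", _parse_int),
        "n_new_or_enhancing_lesions": parse("n_new_or_enhancing_lesions", _parse_int),
        "followup_years": parse("followup_years", _parse_float),
    }
    try:
        return PatientRecord(
            patient_id=require("patient_id"),
            diagnosis=require("diagnosis"),
            age=parse("age", _parse_float),
            sex=require("sex"),
            treatment=_cell(row, "treatment") or "none",
            study_eligible=parse("study_eligible", _parse_bool),
            analytes=AnalytePanel(**analyte_kwargs),
            outcomes=OutcomePanel(**outcome_kwargs),
        )
    except CohortValidationError:
        raise
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(f"row {row_label}: {exc}") from exc


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV, one :class:`PatientRecord` per row.

    Empty cells encode missing values (never zero).  Raises
    :class:`CohortValidationError` naming the offending row and column on any
    malformed cell, invariant violation or duplicate ``patient_id``.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns and c not in (
        "csf_albumin_unit", "serum_albumin_unit", "treatment")]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    records = []
    seen: set[str] = set()
    for i, (_, row) in enumerate(frame.iterrows()):
        record = _record_from_row(row, row_label=i + 2)  # +2: header + 1-based
        if record.patient_id in seen:
            raise CohortValidationError(
                f"row {i + 2}, column 'patient_id': duplicate id {record.patient_id!r}"
            )
        seen.add(record.patient_id)
        records.append(record)
    return records


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable representation
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten records into a string DataFrame in the canonical column order."""
    rows = []
    for rec in records:
        flat = {
            "patient_id": rec.patient_id,
            "diagnosis": rec.diagnosis,
            "age": rec.age,
            "sex": rec.sex,
            "treatment": rec.treatment,
            "study_eligible": rec.study_eligible,
        }
        flat.update({c: getattr(rec.analytes, c) for c in _ANALYTE_COLS})
        flat.update({c: getattr(rec.outcomes, c) for c in _OUTCOME_COLS})
        rows.append({c: _format_cell(flat[c]) for c in COLUMNS})
    return pd.DataFrame(rows, columns=list(COLUMNS), dtype=str)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records to CSV such that ``read_cohort`` restores them exactly.

    Floats are written in their shortest round-trippable form; missing values
    become empty cells.  An empty collection yields a header-only file.
    """
    records_to_frame(records).to_csv(path, index=False)
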