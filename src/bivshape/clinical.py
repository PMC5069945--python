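"""Clinical diagnostic tables: 2010 Task Force Criteria bookkeeping.

ARVC diagnosis under the 2010 Task Force Criteria (TFC) is a count-based
rule over major and minor criteria: definite (2 major, or 1 major + 2
minor, or 4 minor), borderline (1 major + 1 minor, or 3 minor) and
possible (1 major, or 2 minor).  This module parses per-patient index
tables (diagnosis category, criteria counts, binary event/finding
flags), applies the category rule, computes Dubois body surface area,
and tallies cohort summaries.

A reference table for a 27-patient ARVC cohort is bundled
(``data/arvc_reference_cohort.csv``); its transcription is validated
against independently reported cohort totals rather than trusted
blindly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SchemaError, ValidationError

#: Canonical column names of the diagnostic table.
REQUIRED_COLUMNS = (
    "arvc_diagnosis",
    "tfc_major",
    "tfc_minor",
    "cmr_major",
    "cmr_minor",
    "vt_vf",
    "icd",
    "cardiac_arrest",
    "syncope",
    "ecg_major",
    "sa_ecg",
    "fat",
    "fibrosis",
)
FLAG_COLUMNS = (
    "cmr_major",
    "cmr_minor",
    "vt_vf",
    "icd",
    "cardiac_arrest",
    "syncope",
    "ecg_major",
    "sa_ecg",
    "fat",
    "fibrosis",
)
COUNT_COLUMNS = ("tfc_major", "tfc_minor")

#: Accepted header aliases (lower-cased, stripped of spaces/punctuation).
_ALIASES = {
    "arvcdiagnosis": "arvc_diagnosis",
    "diagnosis": "arvc_diagnosis",
    "major": "tfc_major",
    "tfcmajor": "tfc_major",
    "nomajor": "tfc_major",
    "minor": "tfc_minor",
    "tfcminor": "tfc_minor",
    "nominor": "tfc_minor",
    "cmrmajor": "cmr_major",
    "cmrminor": "cmr_minor",
    "vtvf": "vt_vf",
    "icd": "icd",
    "cardiacarrest": "cardiac_arrest",
    "arrest": "cardiac_arrest",
    "syncope": "syncope",
    "ecgmajor": "ecg_major",
    "saecg": "sa_ecg",
    "fat": "fat",
    "fibrosis": "fibrosis",
    "subjectid": "subject_id",
}


@dataclass
class ClinicalTable:
    """Validated per-patient diagnostic indices plus a parse report."""

    records: pd.DataFrame
    parse_report: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _canonical(name: str) -> str:
    key = "".join(ch for ch in name.lower() if ch.isalnum())
    return _ALIASES.get(key, name.strip().lower().replace(" ", "_").replace("/", "_"))


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read and validate a diagnostic-index CSV.

    Headers are matched case-insensitively with common aliases
    (``VT/VF`` -> ``vt_vf``); separators are sniffed.  Flag columns
    must be strictly 0/1; criteria counts must be nonnegative integers.
    Counts outside the reference ranges (major > 5, minor > 2) are
    reported as warnings, not errors, since other cohorts may exceed
    them.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise SchemaError(f"{path} is empty or not delimited text") from exc
    df = df.rename(columns={c: _canonical(c) for c in df.columns})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    report: list[str] = []
    for col in FLAG_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not set(np.unique(vals)).issubset({0, 1}):
            raise ValidationError(f"non-binary value in flag column {col!r}")
        df[col] = vals.astype(np.int64)
    for col in COUNT_COLUMNS + ("arvc_diagnosis",):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals < 0).any() or (vals % 1 != 0).any():
            raise ValidationError(f"column {col!r} must hold nonnegative integers")
        df[col] = vals.astype(np.int64)
    if (df["tfc_major"] > 5).any() or (df["tfc_minor"] > 2).any():
        msg = "criteria counts exceed reference ranges (major <= 5, minor <= 2)"
        warnings.warn(msg, stacklevel=2)
        report.append(msg)
    return ClinicalTable(records=df, parse_report=report)


def load_reference_table() -> ClinicalTable:
    """The bundled 27-patient ARVC reference diagnostic table."""
    with resources.as_file(
        resources.files("bivshape.data") / "arvc_reference_cohort.csv"
    ) as p:
        return read_clinical_table(p)


def tally(table: ClinicalTable | pd.DataFrame, column: str) -> int:
    """Number of records with flag = 1 (binary columns) or value > 0."""
    df = table.records if isinstance(table, ClinicalTable) else table
    if column not in df.columns:
        raise InvalidArgumentError(f"unknown column {column!r}")
    return int((df[column] == 1).sum()) if column in FLAG_COLUMNS else int(
        (df[column] > 0).sum()
    )


def column_range(table: ClinicalTable | pd.DataFrame, column: str) -> tuple[int, int]:
    """(min, max) of a count column across the cohort."""
    df = table.records if isinstance(table, ClinicalTable) else table
    if column not in df.columns:
        raise InvalidArgumentError(f"unknown column {column!r}")
    if len(df) == 0:
        raise InvalidArgumentError("empty table has no range")
    return int(df[column].min()), int(df[column].max())


def bsa_dubois(weight: float, height: float) -> float:
    """Dubois body surface area (m^2) from weight (kg) and height (cm).

    BSA = 0.007184 * weight^0.425 * height^0.725.
    """
    if weight <= 0 or height <= 0:
        raise InvalidArgumentError("weight and height must be positive")
    return 0.007184 * weight**0.425 * height**0.725


def tfc_category(n_major: int, n_minor: int) -> str:
    """Task Force diagnostic category from criteria counts.

    Thresholds are minima (e.g. 3 major still qualifies as definite).
    The rule's "minor criteria from different categories" qualifier is
    not checkable from counts alone and is assumed satisfied.
    """
    if n_major < 0 or n_minor < 0:
        raise InvalidArgumentError("criteria counts must be nonnegative")
    if n_major >= 2 or (n_major >= 1 and n_minor >= 2) or n_minor >= 4:
        return "definite"
    if (n_major >= 1 and n_minor >= 1) or n_minor >= 3:
        return "borderline"
    if n_major >= 1 or n_minor >= 2:
        return "possible"
    return "none"


_CATEGORY_CODE = {"definite": 3, "borderline": 2, "possible": 1, "none": 0}


def check_diagnosis_consistency(table: ClinicalTable | pd.DataFrame) -> list[int]:
    """Row indices where the count rule disagrees with the diagnosis column.

    Disagreements are possible only through the "different categories"
    qualifier the counts cannot encode; they are listed for review, not
    silently accepted.
    """
    df = table.records if isinstance(table, ClinicalTable) else table
    bad = []
    for i, row in df.iterrows():
        derived = _CATEGORY_CODE[tfc_category(row["tfc_major"], row["tfc_minor"])]
        if derived != row["arvc_diagnosis"]:
            bad.append(int(i))
    return bad
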