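"""Patient-level data model for ICU admissions with cirrhosis.

A :class:`PatientRecord` holds the first-available admission values used by
the severity-score panel and by the outcome analyses: demographics, admission
biochemistry and physiology, ordinal ascites / hepatic-encephalopathy grades,
and the ICU outcome. Any clinical field may be missing (``None``); the ICU
outcome never is. A :class:`Cohort` is an ordered collection of records with
a label (e.g. ``"glasgow"``) and free-text provenance.

I/O is plain CSV (UTF-8, ``.`` decimal separator) with one header row.
Column names and units can be remapped through a schema (dict or YAML file);
unparseable numeric cells are treated as missing and are never imputed at
read time.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "PatientRecord",
    "Cohort",
    "FieldSummary",
    "CohortError",
    "read_cohort",
    "write_cohort",
    "load_schema",
    "exclude_incomplete",
    "summarize_field",
]

SEX_LEVELS = ("male", "female")
ASCITES_LEVELS = ("none", "mild", "severe")
OUTCOME_LEVELS = ("survived", "died")
ENCEPHALOPATHY_GRADES = (0, 1, 2, 3, 4)

#: fields holding real-valued measurements, with their canonical units
NUMERIC_FIELDS: dict[str, str] = {
    "age": "years",
    "sodium": "mmol/L",
    "potassium": "mmol/L",
    "urea": "mmol/L",
    "lactate": "mmol/L",
    "creatinine": "umol/L",
    "wcc": "1e9/L",
    "bilirubin": "umol/L",
    "pt_ratio": "ratio",
    "albumin": "g/L",
    "platelets": "1e9/L",
    "pao2": "kPa",
    "pf_ratio": "kPa",
    "gcs": "points",
    "map": "mmHg",
    "noradrenaline_dose": "ug/kg/min",
}

CATEGORICAL_FIELDS = (
    "sex",
    "ascites",
    "encephalopathy",
    "alcoholic_aetiology",
    "icu_outcome",
    "hospital_outcome",
)

ALL_FIELDS = ("patient_id",) + tuple(NUMERIC_FIELDS) + CATEGORICAL_FIELDS

#: multiplicative factors converting a declared unit into the canonical unit
KPA_PER_MMHG = 1.0 / 7.50062
UNIT_CONVERSIONS: dict[tuple[str, str], float] = {
    ("urea", "umol/L"): 1e-3,  # tables sometimes mislabel urea as umol/L
    ("bilirubin", "mg/dL"): 17.1,
    ("creatinine", "mg/dL"): 88.4,
    ("pao2", "mmHg"): KPA_PER_MMHG,
    ("pf_ratio", "mmHg"): KPA_PER_MMHG,
}


class CohortError(ValueError):
    """Raised for malformed cohort files or invalid records."""


@dataclass
class PatientRecord:
    """One ICU admission. ``None`` marks a missing clinical value."""

    patient_id: str
    age: float | None = None
    sex: str | None = None
    sodium: float | None = None
    potassium: float | None = None
    urea: float | None = None
    lactate: float | None = None
    creatinine: float | None = None
    wcc: float | None = None
    bilirubin: float | None = None
    pt_ratio: float | None = None
    albumin: float | None = None
    platelets: float | None = None
    pao2: float | None = None
    pf_ratio: float | None = None
    gcs: int | None = None
    map: float | None = None
    noradrenaline_dose: float | None = None
    ascites: str | None = None
    encephalopathy: int | None = None
    alcoholic_aetiology: bool | None = None
    icu_outcome: str | None = None
    hospital_outcome: str | None = None

    def validate(self) -> None:
        """Check record-level invariants; raise :class:`CohortError` on failure."""
        pid = self.patient_id
        if self.icu_outcome not in OUTCOME_LEVELS:
            raise CohortError(f"record {pid!r}: icu_outcome must be one of "
                              f"{OUTCOME_LEVELS}, got {self.icu_outcome!r}")
        if self.age is not None and self.age < 18:
            raise CohortError(f"record {pid!r}: age {self.age} below adult "
                              "inclusion threshold of 18")
        # concentrations / ratios are strictly positive when present;
        # noradrenaline dose may legitimately be zero (no vasopressor)
        for name in ("sodium", "potassium", "urea", "lactate", "creatinine",
                     "wcc", "bilirubin", "pt_ratio", "albumin", "platelets",
                     "pao2", "pf_ratio"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise CohortError(f"record {pid!r}: {name} must be > 0, got {v}")
        if self.noradrenaline_dose is not None and self.noradrenaline_dose < 0:
            raise CohortError(f"record {pid!r}: noradrenaline_dose must be >= 0")
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise CohortError(f"record {pid!r}: gcs {self.gcs} outside [3, 15]")
        if (self.pao2 is not None and self.pf_ratio is not None
                and self.pf_ratio > self.pao2 / 0.21 * 1.005):
            raise CohortError(
                f"record {pid!r}: pf_ratio {self.pf_ratio} exceeds pao2 on "
                f"room air ({self.pao2 / 0.21:.1f})")
        for name, levels in (("sex", SEX_LEVELS), ("ascites", ASCITES_LEVELS),
                             ("hospital_outcome", OUTCOME_LEVELS)):
            v = getattr(self, name)
            if v is not None and v not in levels:
                raise CohortError(f"record {pid!r}: {name}={v!r} not in {levels}")
        if (self.encephalopathy is not None
                and self.encephalopathy not in ENCEPHALOPATHY_GRADES):
            raise CohortError(f"record {pid!r}: encephalopathy grade "
                              f"{self.encephalopathy!r} outside 0-4")

    def is_missing(self, field: str) -> bool:
        return getattr(self, field) is None


@dataclass
class Cohort:
    """An ordered, labelled collection of patient records."""

    label: str
    records: list[PatientRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            return
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"cohort {self.label!r}: duplicate patient ids {dup}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        return pd.DataFrame(rows, columns=list(ALL_FIELDS))

    def values(self, field: str, *, dropna: bool = False) -> list:
        vals = [getattr(r, field) for r in self.records]
        if dropna:
            vals = [v for v in vals if v is not None]
        return vals


# ---------------------------------------------------------------------------
# schema handling and CSV I/O

def load_schema(path: str | Path) -> dict:
    """Load a YAML/JSON column-mapping schema.

    The schema maps record fields to file columns and optionally declares the
    unit a column is expressed in::

        columns: {lactate: "Lactate (mmol/l)", icu_outcome: outcome}
        units: {urea: umol/L}
    """
    with open(path, "r", encoding="utf-8") as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, Mapping):
        raise CohortError(f"schema file {path} must contain a mapping")
    return dict(schema)


def _parse_bool(raw: str, row: int) -> bool:
    low = raw.strip().lower()
    if low in ("true", "1", "yes", "y"):
        return True
    if low in ("false", "0", "no", "n"):
        return False
    raise CohortError(f"row {row}: unknown boolean value {raw!r}")


def _parse_categorical(field: str, raw: object, row: int):
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    text = str(raw).strip()
    if text == "":
        return None
    if field == "alcoholic_aetiology":
        return _parse_bool(text, row)
    if field == "encephalopathy":
        try:
            grade = int(float(text))
        except ValueError:
            raise CohortError(f"row {row}: encephalopathy grade {text!r} "
                              "is not an integer 0-4") from None
        if grade not in ENCEPHALOPATHY_GRADES:
            raise CohortError(f"row {row}: encephalopathy grade {grade} outside 0-4")
        return grade
    low = text.lower()
    levels = {"sex": SEX_LEVELS, "ascites": ASCITES_LEVELS,
              "icu_outcome": OUTCOME_LEVELS, "hospital_outcome": OUTCOME_LEVELS}[field]
    if low in levels:
        return low
    raise CohortError(f"row {row}: unknown level {text!r} for field {field!r}")


def read_cohort(path: str | Path, schema: Mapping | None = None,
                label: str | None = None) -> Cohort:
    """Read a delimited cohort file into a :class:`Cohort`.

    Unparseable numeric cells become missing values; a missing ICU-outcome
    column (or blank outcome cell) is a hard error, as records without an
    outcome are not analysable.
    """
    schema = dict(schema or {})
    colmap: dict[str, str] = {f: f for f in ALL_FIELDS}
    colmap.update(schema.get("columns", {}))
    units: dict[str, str] = dict(schema.get("units", {}))

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if colmap["icu_outcome"] not in df.columns:
        raise CohortError(f"{path}: required outcome column "
                          f"{colmap['icu_outcome']!r} is absent")

    records: list[PatientRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        kwargs: dict = {}
        pid_col = colmap["patient_id"]
        kwargs["patient_id"] = (str(rowd[pid_col]).strip()
                                if pid_col in df.columns and str(rowd[pid_col]).strip()
                                else f"row{idx}")
        for f, canonical_unit in NUMERIC_FIELDS.items():
            col = colmap.get(f, f)
            if col not in df.columns:
                continue
            text = str(rowd[col]).strip()
            try:
                value = float(text)  # full-precision, round-trip parse
            except ValueError:
                value = math.nan
            if text == "" or math.isnan(value):
                kwargs[f] = None
                continue
            declared = units.get(f, canonical_unit)
            if declared != canonical_unit:
                try:
                    value *= UNIT_CONVERSIONS[(f, declared)]
                except KeyError:
                    raise CohortError(
                        f"no conversion from unit {declared!r} to "
                        f"{canonical_unit!r} for field {f!r}") from None
            kwargs[f] = int(round(value)) if f == "gcs" else value
        for f in CATEGORICAL_FIELDS:
            col = colmap.get(f, f)
            if col in df.columns:
                kwargs[f] = _parse_categorical(f, rowd[col], idx)
        if kwargs.get("icu_outcome") is None:
            raise CohortError(f"{path}: row {idx}: blank ICU outcome")
        rec = PatientRecord(**kwargs)
        rec.validate()
        records.append(rec)
    return Cohort(label=label or Path(path).stem, records=records,
                  provenance=f"read from {path}")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as canonical CSV (blank cells for missing values)."""
    df = cohort.to_dataframe()
    df["alcoholic_aetiology"] = df["alcoholic_aetiology"].map(
        {True: "true", False: "false"})
    # repr round-trips float64 exactly; pandas' default formatting does not
    for col in NUMERIC_FIELDS:
        if col == "gcs":
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else str(int(v)))
        else:
            df[col] = df[col].map(
                lambda v: "" if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# exclusion and summaries

def exclude_incomplete(cohort: Cohort, required_fields: Sequence[str]
                       ) -> tuple[Cohort, list[str]]:
    """Complete-case filter: keep records with all *required_fields* present.

    Returns the retained cohort (order preserved) and the ids of the removed
    records; the two outputs partition the input.
    """
    if not required_fields:
        raise ValueError("required_fields must be non-empty")
    for f in required_fields:
        if f not in ALL_FIELDS:
            raise ValueError(f"unknown field {f!r}")
    kept, dropped = [], []
    for rec in cohort:
        if any(rec.is_missing(f) for f in required_fields):
            dropped.append(rec.patient_id)
        else:
            kept.append(rec)
    return Cohort(label=cohort.label, records=kept,
                  provenance=cohort.provenance), dropped


@dataclass
class FieldSummary:
    """Descriptive summary of one field over a cohort."""

    field: str
    kind: str  # mean_range | median_iqr | count_percent
    n: int  # non-missing values used
    available: bool
    stats: dict = dc_field(default_factory=dict)

    def formatted(self) -> str:
        if not self.available:
            return "NA"
        s = self.stats
        if self.kind == "mean_range":
            return f"{s['mean']:.1f} ({s['min']:.1f}-{s['max']:.1f})"
        if self.kind == "median_iqr":
            return f"{s['median']:.1f} ({s['q25']:.1f}-{s['q75']:.1f})"
        return f"{s['count']} ({s['percent']:.1f} %)"


def summarize_field(cohort: Cohort, field: str, kind: str,
                    level: object | Sequence | None = None) -> FieldSummary:
    """Summarize one field as mean (range), median (IQR) or n (%).

    Quartiles use linear interpolation between closest ranks. For
    ``count_percent``, *level* names the level(s) counted (e.g. ``"male"`` or
    ``("mild", "severe")`` for "any ascites") and the percentage denominator
    is the full cohort size, matching tables whose per-row n varies with
    missingness elsewhere.
    """
    if field not in ALL_FIELDS:
        raise ValueError(f"unknown field {field!r}")
    values = cohort.values(field, dropna=True)
    if kind == "count_percent":
        if level is None:
            raise ValueError("count_percent requires a level to count")
        levels = (level,) if isinstance(level, (str, int, bool)) else tuple(level)
        count = sum(1 for v in values if v in levels)
        denom = len(cohort)
        return FieldSummary(field, kind, n=len(values), available=denom > 0,
                            stats={"count": count,
                                   "percent": 100.0 * count / denom if denom else math.nan})
    if not values:
        return FieldSummary(field, kind, n=0, available=False)
    import numpy as np

    arr = np.asarray(values, dtype=float)
    if kind == "mean_range":
        stats = {"mean": float(arr.mean()), "min": float(arr.min()),
                 "max": float(arr.max())}
    elif kind == "median_iqr":
        q25, med, q75 = np.percentile(arr, [25, 50, 75], method="linear")
        stats = {"median": float(med), "q25": float(q25), "q75": float(q75)}
    else:
        raise ValueError(f"unknown summary kind {kind!r}")
    return FieldSummary(field, kind, n=len(values), available=True, stats=stats)
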