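"""Severity-score panel for critically ill cirrhosis patients.

Two scores are fixed in code because they are the package's raison d'etre:

* **CTP** (Child-Turcotte-Pugh): five components (bilirubin, albumin,
  INR/PT ratio, ascites grade, encephalopathy grade), each awarded 1-3
  points, total 5-15.
* **CTP+L**: the CTP total plus the raw arterial lactate in mmol/L — a
  bedside-computable modification that injects the admission lactate's
  prognostic signal into the familiar categorical score.

The rest of the panel (MELD, UKELD, SOFA, CLIF-SOFA, APACHE II, RFH) is
driven by declarative :class:`ScoreDefinition` documents shipped as YAML
under ``liverscore/definitions``; they are either band-sum tables or
log-linear predictors with per-component unit conversion and clamping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import pandas as pd
import yaml

from .cohort import (
    ALL_FIELDS,
    KPA_PER_MMHG,
    Cohort,
    PatientRecord,
)

__all__ = [
    "ScoreDefinition",
    "ScoreDefinitionError",
    "MissingComponent",
    "ctp_component_points",
    "compute_ctp",
    "compute_ctp_plus_l",
    "compute_defined_score",
    "compute_panel",
    "load_definition",
    "builtin_definitions",
    "organ_failure_count",
    "DEFAULT_ORGAN_FAILURE_CRITERIA",
    "ENCEPHALOPATHY_MODES",
]

ENCEPHALOPATHY_MODES = ("observed", "presumed_2", "excluded")

CTP_COMPONENTS = ("bilirubin", "albumin", "inr", "ascites", "encephalopathy")


class ScoreDefinitionError(ValueError):
    """Raised for structurally invalid score definitions."""


class MissingComponent(Exception):
    """Signal that a required score input is absent from the record."""

    def __init__(self, component: str):
        self.component = component
        super().__init__(component)


# ---------------------------------------------------------------------------
# CTP and CTP + L

def ctp_component_points(component: str, value) -> int:
    """Points (1-3) for one CTP component.

    Band closures at the printed edges: bilirubin band 2 is [34, 50] umol/L,
    albumin band 2 is [28, 35] g/L, and INR band 2 is the half-open
    (1.70, 2.30], so a PT ratio of exactly 1.70 scores 1 point.
    """
    if value is None:
        raise MissingComponent(component)
    if component == "bilirubin":
        return 1 if value < 34 else (2 if value <= 50 else 3)
    if component == "albumin":
        return 1 if value > 35 else (2 if value >= 28 else 3)
    if component == "inr":
        return 1 if value <= 1.70 else (2 if value <= 2.30 else 3)
    if component == "ascites":
        try:
            return {"none": 1, "mild": 2, "severe": 3}[value]
        except KeyError:
            raise ValueError(f"unknown ascites grade {value!r}") from None
    if component == "encephalopathy":
        if value not in (0, 1, 2, 3, 4):
            raise ValueError(f"unknown encephalopathy grade {value!r}")
        return 1 if value == 0 else (2 if value <= 2 else 3)
    raise ValueError(f"unknown CTP component {component!r}")


def compute_ctp(record: PatientRecord,
                encephalopathy_mode: str = "observed") -> int | None:
    """Child-Turcotte-Pugh total.

    ``encephalopathy_mode`` handles cohorts without reliable pre-intubation
    encephalopathy grades: ``observed`` uses the recorded grade,
    ``presumed_2`` awards 2 points regardless of the record, ``excluded``
    sums only the other four components (range 4-12).

    Returns ``None`` when any required component is missing.
    """
    if encephalopathy_mode not in ENCEPHALOPATHY_MODES:
        raise ValueError(f"unknown encephalopathy_mode {encephalopathy_mode!r}")
    try:
        total = (ctp_component_points("bilirubin", record.bilirubin)
                 + ctp_component_points("albumin", record.albumin)
                 + ctp_component_points("inr", record.pt_ratio)
                 + ctp_component_points("ascites", record.ascites))
        if encephalopathy_mode == "observed":
            total += ctp_component_points("encephalopathy", record.encephalopathy)
        elif encephalopathy_mode == "presumed_2":
            total += 2
    except MissingComponent:
        return None
    return total


def compute_ctp_plus_l(record: PatientRecord,
                       encephalopathy_mode: str = "observed") -> float | None:
    """CTP plus the raw arterial lactate (mmol/L, unbanded, unrounded)."""
    ctp = compute_ctp(record, encephalopathy_mode)
    if ctp is None or record.lactate is None:
        return None
    return ctp + record.lactate


# ---------------------------------------------------------------------------
# declarative score definitions

@dataclass
class Component:
    """One input of a declarative score."""

    kind: str  # band | categorical | derived | linear
    field: str | None = None
    rule: str | None = None
    unit: str | None = None
    edges: list[float] | None = None
    points: list[float] | None = None
    right_closed: bool = False
    mapping: dict | None = None
    transform: str = "identity"  # identity | log
    coefficient: float = 0.0
    floor: float | None = None
    cap: float | None = None
    normal_if_missing: bool = False
    params: dict = dc_field(default_factory=dict)


@dataclass
class ScoreDefinition:
    """Declarative banding table or linear predictor defining one score."""

    name: str
    kind: str  # band_sum | linear_predictor
    components: list[Component]
    intercept: float = 0.0
    constant: float = 0.0
    bounds: tuple[float, float] | None = None
    source: str = ""
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("band_sum", "linear_predictor"):
            raise ScoreDefinitionError(f"{self.name}: unknown kind {self.kind!r}")
        if not self.components:
            raise ScoreDefinitionError(f"{self.name}: no components")
        for c in self.components:
            if c.field is None and c.rule is None:
                raise ScoreDefinitionError(f"{self.name}: component without "
                                           "field or rule")
            if c.field is not None and c.field not in ALL_FIELDS:
                raise ScoreDefinitionError(
                    f"{self.name}: component names unknown field {c.field!r}")
            if c.rule is not None and c.rule not in DERIVED_RULES:
                raise ScoreDefinitionError(
                    f"{self.name}: unknown derived rule {c.rule!r}")
            if self.kind == "band_sum" and c.kind == "band":
                if c.edges is None or c.points is None:
                    raise ScoreDefinitionError(
                        f"{self.name}/{c.field}: band component needs edges+points")
                if any(b <= a for a, b in zip(c.edges, c.edges[1:])):
                    raise ScoreDefinitionError(
                        f"{self.name}/{c.field}: band edges must be strictly "
                        "increasing")
                if len(c.points) != len(c.edges) + 1:
                    raise ScoreDefinitionError(
                        f"{self.name}/{c.field}: need len(edges)+1 points")
                if any(p < 0 or p != int(p) for p in c.points):
                    raise ScoreDefinitionError(
                        f"{self.name}/{c.field}: band points must be "
                        "non-negative integers")


# unit conversions applied inside definitions (canonical unit -> declared)
_DEF_UNIT_FACTORS: dict[tuple[str, str], float] = {
    ("bilirubin", "mg/dL"): 1 / 17.1,
    ("creatinine", "mg/dL"): 1 / 88.4,
    ("pf_ratio", "mmHg"): 1 / KPA_PER_MMHG,
    ("pao2", "mmHg"): 1 / KPA_PER_MMHG,
    ("urea", "mg/dL"): 2.8,  # BUN equivalent
}


def _component_value(record: PatientRecord, comp: Component):
    if comp.rule is not None:
        return DERIVED_RULES[comp.rule](record, comp.params)
    value = getattr(record, comp.field)
    if value is None:
        return None
    if comp.unit is not None:
        key = (comp.field, comp.unit)
        if key in _DEF_UNIT_FACTORS:
            value = value * _DEF_UNIT_FACTORS[key]
        elif comp.unit != "canonical":
            raise ScoreDefinitionError(
                f"no conversion to unit {comp.unit!r} for field {comp.field!r}")
    return value


def _band_points(comp: Component, value: float) -> float:
    """Points for *value* in an edge-partitioned band table.

    ``right_closed=False`` (default) means bands are ``(-inf, e1), [e1, e2),
    ..., [ek, inf)``; ``right_closed=True`` closes bands on the right instead.
    """
    import bisect

    if comp.right_closed:
        return comp.points[bisect.bisect_left(comp.edges, value)]
    return comp.points[bisect.bisect_right(comp.edges, value)]


def compute_defined_score(record: PatientRecord,
                          definition: ScoreDefinition) -> float | None:
    """Evaluate one declarative score for one record.

    Band-sum scores add per-component band points (plus any fixed constant,
    e.g. chronic-health points); linear predictors compute
    ``intercept + sum(coef * transform(value))`` with unit conversion,
    floor/cap clamping and optional natural-log transform. Components marked
    ``normal_if_missing`` contribute their zero-point band (or zero term)
    when absent; otherwise a missing component makes the whole score missing.
    """
    total = definition.constant if definition.kind == "band_sum" else definition.intercept
    for comp in definition.components:
        value = _component_value(record, comp)
        if value is None:
            if comp.normal_if_missing:
                continue
            return None
        if definition.kind == "band_sum":
            if comp.kind == "categorical":
                try:
                    total += comp.mapping[value]
                except KeyError:
                    raise ValueError(
                        f"{definition.name}: record {record.patient_id!r} has "
                        f"unmapped level {value!r} for {comp.field}") from None
            elif comp.kind == "derived":
                total += value
            else:
                total += _band_points(comp, value)
        else:
            if comp.floor is not None:
                value = max(value, comp.floor)
            if comp.cap is not None:
                value = min(value, comp.cap)
            if comp.transform == "log":
                if value <= 0:
                    raise ValueError(
                        f"{definition.name}: log of non-positive "
                        f"{comp.field or comp.rule}={value} for record "
                        f"{record.patient_id!r}")
                value = math.log(value)
            elif comp.transform != "identity":
                raise ScoreDefinitionError(
                    f"unknown transform {comp.transform!r}")
            total += comp.coefficient * value
    if definition.bounds is not None:
        lo, hi = definition.bounds
        total = min(max(total, lo), hi)
    return total


# ---------------------------------------------------------------------------
# derived inputs (multi-variable rules that a band table cannot express)

DEFAULT_ORGAN_FAILURE_CRITERIA: dict[str, dict] = {
    "respiratory": {"field": "pf_ratio", "op": "lt", "threshold": 26.7},
    "cardiovascular_map": {"field": "map", "op": "lt", "threshold": 70.0},
    "cardiovascular_vasopressor": {"field": "noradrenaline_dose", "op": "gt",
                                   "threshold": 0.0},
    "renal": {"field": "creatinine", "op": "gt", "threshold": 170.0},
    "cerebral": {"field": "gcs", "op": "lt", "threshold": 13},
    "coagulation": {"field": "platelets", "op": "lt", "threshold": 50.0},
    "liver": {"field": "bilirubin", "op": "gt", "threshold": 204.0},
}

_ORGAN_SYSTEMS = ("respiratory", "cardiovascular", "renal", "cerebral",
                  "coagulation", "liver")


def organ_failure_count(record: PatientRecord,
                        criteria: Mapping[str, Mapping] | None = None) -> int:
    """Number of failing organ systems (0-6) under configurable criteria.

    A criterion whose input is missing counts as not failing; systems with
    several criteria (e.g. cardiovascular: hypotension or vasopressor use)
    fail when any criterion fires.
    """
    criteria = criteria or DEFAULT_ORGAN_FAILURE_CRITERIA
    failing: set[str] = set()
    for name, crit in criteria.items():
        value = getattr(record, crit["field"])
        if value is None:
            continue
        op, thr = crit["op"], crit["threshold"]
        fired = value < thr if op == "lt" else value > thr
        if fired:
            failing.add(name.split("_")[0])
    return len(failing & set(_ORGAN_SYSTEMS))


def _rule_organ_failures(record: PatientRecord, params: Mapping) -> int | None:
    return organ_failure_count(record, params.get("criteria"))


def _rule_sofa_cardiovascular(record: PatientRecord, params: Mapping) -> int | None:
    """Cardiovascular points 0-4 from MAP and noradrenaline dose.

    Dopamine/dobutamine doses are not collected, so the 1-2 point vasoactive
    bands collapse onto the MAP criterion.
    """
    nor = record.noradrenaline_dose
    if nor is not None and nor > 0:
        return 4 if nor > 0.1 else 3
    if record.map is None:
        return None if nor is None else 0
    return 1 if record.map < 70 else 0


def _rule_clif_cerebral(record: PatientRecord, params: Mapping) -> int | None:
    """Cerebral points: the West Haven grade itself (0-4), falling back to a
    GCS banding when no pre-intubation encephalopathy grade was recorded."""
    if record.encephalopathy is not None:
        return record.encephalopathy
    g = record.gcs
    if g is None:
        return None
    if g == 15:
        return 0
    if g >= 13:
        return 1
    if g >= 10:
        return 2
    if g >= 6:
        return 3
    return 4


DERIVED_RULES: dict[str, Callable[[PatientRecord, Mapping], object]] = {
    "organ_failure_count": _rule_organ_failures,
    "sofa_cardiovascular": _rule_sofa_cardiovascular,
    "clif_cerebral": _rule_clif_cerebral,
}


# ---------------------------------------------------------------------------
# definition loading and the panel

def _parse_definition(doc: Mapping) -> ScoreDefinition:
    comps = []
    for c in doc.get("components", []):
        c = dict(c)
        if "edges" in c:
            c.setdefault("kind", "band")
            c["edges"] = [float(e) for e in c["edges"]]
            c["points"] = [float(p) for p in c["points"]]
        elif "mapping" in c:
            c.setdefault("kind", "categorical")
        elif "rule" in c:
            c.setdefault("kind", "derived")
        else:
            c.setdefault("kind", "linear")
        comps.append(Component(**c))
    bounds = doc.get("bounds")
    return ScoreDefinition(
        name=doc["name"], kind=doc["kind"], components=comps,
        intercept=float(doc.get("intercept", 0.0)),
        constant=float(doc.get("constant", 0.0)),
        bounds=tuple(bounds) if bounds else None,
        source=doc.get("source", ""),
        provisional=bool(doc.get("provisional", False)))


def load_definition(path: str | Path) -> ScoreDefinition:
    """Load and validate a YAML score definition."""
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_definition(yaml.safe_load(fh))


def builtin_definitions() -> dict[str, ScoreDefinition]:
    """The shipped definition set: MELD, UKELD, SOFA, CLIF-SOFA, APACHE II, RFH."""
    defs: dict[str, ScoreDefinition] = {}
    pkg = resources.files("liverscore") / "definitions"
    for entry in sorted(pkg.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            d = _parse_definition(yaml.safe_load(entry.read_text(encoding="utf-8")))
            defs[d.name] = d
    return defs


PANEL_SCORES = ("CTP", "CTP+L", "MELD", "UKELD", "SOFA", "CLIF-SOFA",
                "APACHE II", "RFH")


def compute_panel(cohort: Cohort,
                  definitions: Mapping[str, ScoreDefinition] | None = None,
                  encephalopathy_mode: str = "observed") -> pd.DataFrame:
    """Score every record with CTP, CTP+L and all supplied definitions.

    Returns a DataFrame indexed by ``patient_id`` with one column per score;
    missing inputs yield NaN for the affected score only. Output is a pure
    function of the records and is insensitive to record order.
    """
    definitions = builtin_definitions() if definitions is None else definitions
    rows = {}
    for rec in cohort:
        row = {
            "CTP": compute_ctp(rec, encephalopathy_mode),
            "CTP+L": compute_ctp_plus_l(rec, encephalopathy_mode),
        }
        for name, d in definitions.items():
            row[name] = compute_defined_score(rec, d)
        rows[rec.patient_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.index.name = "patient_id"
    cols = ["CTP", "CTP+L"] + list(definitions)
    return df[cols]
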