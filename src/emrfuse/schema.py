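"""Cohort data model: feature schema, record validation, imputation and scaling.

A cohort is a list of :class:`PatientRecord` plus a :class:`FeatureSchema`
describing 11 structured fields (categorical + numeric), 2 free-text units and
a binary label. Missing values are carried as the explicit :data:`MISSING`
sentinel; imputation fills them while recording a per-field status marker so
the original testing status stays recoverable.
"""

from __future__ import annotations


from collections import Counter
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd


class _Missing:
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self):
        return "MISSING"

    def __bool__(self):
        return False


#: Sentinel for an untested / unrecorded value; distinguishable from any legal value.
MISSING = _Missing()

MEASURED = "measured"
IMPUTED_BASELINE = "imputed_baseline"
IMPUTED_MEAN = "imputed_mean"
IMPUTED_MODE = "imputed_mode"

#: Clinically informed fallback for C-reactive protein in afebrile patients (mg/L).
CRP_BASELINE = 3.5


class SchemaError(ValueError):
    """Record/schema mismatch: unknown field, bad category set, etc."""


class ConfigurationError(ValueError):
    """Missing statistics or invalid configuration for an operation."""


@dataclass(frozen=True)
class CategoricalField:
    name: str
    categories: tuple[str, ...]

    def __post_init__(self):
        if len(self.categories) < 2:
            raise SchemaError(f"field {self.name!r}: cardinality must be >= 2")
        if len(set(self.categories)) != len(self.categories):
            raise SchemaError(f"field {self.name!r}: duplicate category labels")

    @property
    def cardinality(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class NumericField:
    name: str
    units: str
    valid_range: tuple[float, float]

    def __post_init__(self):
        lo, hi = self.valid_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise SchemaError(f"field {self.name!r}: range must be finite with low < high")


@dataclass(frozen=True)
class Violation:
    field: str
    kind: str  # "range" | "unknown_category" | "constraint"
    message: str


# A logical-relationship hook: returns a Violation or None for a record.
ConstraintHook = Callable[["PatientRecord"], Violation | None]


def _fever_crp_consistency(record: "PatientRecord") -> Violation | None:
    # advisory demonstration constraint: febrile patients are expected to have CRP tested
    if record.values.get("fever") == "yes" and record.values.get("crp") is MISSING:
        return Violation("crp", "constraint", "febrile patient without a CRP measurement")
    return None


@dataclass(frozen=True)
class FeatureSchema:
    categorical_fields: tuple[CategoricalField, ...]
    numeric_fields: tuple[NumericField, ...]
    text_units: tuple[str, ...]
    label_name: str = "label"
    constraints: tuple[ConstraintHook, ...] = ()

    @property
    def structured_field_names(self) -> list[str]:
        return [f.name for f in self.categorical_fields] + [f.name for f in self.numeric_fields]

    @property
    def n_structured_fields(self) -> int:
        return len(self.categorical_fields) + len(self.numeric_fields)

    @property
    def cardinalities(self) -> list[int]:
        return [f.cardinality for f in self.categorical_fields]

    def categorical(self, name: str) -> CategoricalField:
        for f in self.categorical_fields:
            if f.name == name:
                return f
        raise SchemaError(f"unknown categorical field {name!r}")

    def numeric(self, name: str) -> NumericField:
        for f in self.numeric_fields:
            if f.name == name:
                return f
        raise SchemaError(f"unknown numeric field {name!r}")

    @staticmethod
    def default() -> "FeatureSchema":
        """Stand-in schema: 2 categorical + 9 numeric = 11 structured fields, 2 text units."""
        return FeatureSchema(
            categorical_fields=(
                CategoricalField("sex", ("female", "male")),
                CategoricalField("fever", ("no", "yes")),
            ),
            numeric_fields=(
                NumericField("age", "years", (35.0, 91.0)),
                NumericField("crp", "mg/L", (0.0, 300.0)),
                NumericField("ph", "pH", (6.8, 7.8)),
                NumericField("pao2", "mmHg", (30.0, 150.0)),
                NumericField("paco2", "mmHg", (15.0, 130.0)),
                NumericField("hco3", "mmol/L", (5.0, 50.0)),
                NumericField("wbc", "1e9/L", (1.0, 50.0)),
                NumericField("neut_pct", "%", (10.0, 100.0)),
                NumericField("hgb", "g/L", (40.0, 220.0)),
            ),
            text_units=("ct_report", "history"),
            constraints=(_fever_crp_consistency,),
        )


@dataclass
class PatientRecord:
    id: str
    values: dict  # field name -> category string | float | MISSING
    text: dict  # text unit name -> str
    label: int
    imputation_status: dict = field(default_factory=dict)  # field name -> status marker

    def __post_init__(self):
        for name in self.values:
            self.imputation_status.setdefault(name, MEASURED)

    @property
    def fever_flag(self) -> bool:
        return self.values.get("fever") == "yes"

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            id=self.id,
            values=dict(self.values),
            text=dict(self.text),
            label=self.label,
            imputation_status=dict(self.imputation_status),
        )


@dataclass
class Cohort:
    records: list[PatientRecord]
    schema: FeatureSchema

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def subset(self, indices) -> "Cohort":
        return Cohort([self.records[i] for i in indices], self.schema)

    # -- CSV round-trip ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"patient_id": r.id}
            for name in self.schema.structured_field_names:
                v = r.values.get(name, MISSING)
                row[name] = "" if v is MISSING else v
            for unit in self.schema.text_units:
                row[unit] = r.text.get(unit, "")
            row[self.schema.label_name] = int(r.label)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def from_frame(frame: pd.DataFrame, schema: FeatureSchema) -> "Cohort":
        records = []
        cat_names = {f.name for f in schema.categorical_fields}
        for _, row in frame.iterrows():
            values: dict = {}
            for name in schema.structured_field_names:
                raw = row[name]
                if pd.isna(raw) or raw == "":
                    values[name] = MISSING
                elif name in cat_names:
                    values[name] = str(raw)
                else:
                    values[name] = float(raw)
            text = {u: ("" if pd.isna(row[u]) else str(row[u])) for u in schema.text_units}
            records.append(
                PatientRecord(
                    id=str(row["patient_id"]),
                    values=values,
                    text=text,
                    label=int(row[schema.label_name]),
                )
            )
        return Cohort(records, schema)

    @staticmethod
    def read_csv(path, schema: FeatureSchema) -> "Cohort":
        return Cohort.from_frame(pd.read_csv(path, keep_default_na=False), schema)

    def imputation_log(self) -> pd.DataFrame:
        rows = [
            {"patient_id": r.id, "field": name, "status": status}
            for r in self.records
            for name, status in sorted(r.imputation_status.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def validate_record(record: PatientRecord, schema: FeatureSchema) -> list[Violation]:
    """Return every range violation, unknown category and failed constraint.

    Missing values are not violations; unknown field names raise
    :class:`SchemaError`.
    """
    known = set(schema.structured_field_names)
    unknown = set(record.values) - known
    if unknown:
        raise SchemaError(f"record {record.id!r} has unknown fields: {sorted(unknown)}")

    violations: list[Violation] = []
    for f in schema.categorical_fields:
        v = record.values.get(f.name, MISSING)
        if v is not MISSING and v not in f.categories:
            violations.append(
                Violation(f.name, "unknown_category", f"{v!r} not in {f.categories}")
            )
    for f in schema.numeric_fields:
        v = record.values.get(f.name, MISSING)
        if v is not MISSING:
            lo, hi = f.valid_range
            if not (lo <= float(v) <= hi):
                violations.append(
                    Violation(f.name, "range", f"{v} outside [{lo}, {hi}] {f.units}")
                )
    for hook in schema.constraints:
        hit = hook(record)
        if hit is not None:
            violations.append(hit)
    return violations


def winsorize_record(
    record: PatientRecord, schema: FeatureSchema
) -> tuple[PatientRecord, list[tuple[str, float, float]]]:
    """Clamp out-of-range numeric values to the schema range; log each action."""
    out = record.copy()
    log: list[tuple[str, float, float]] = []
    for f in schema.numeric_fields:
        v = out.values.get(f.name, MISSING)
        if v is MISSING:
            continue
        lo, hi = f.valid_range
        clipped = min(max(float(v), lo), hi)
        if clipped != float(v):
            log.append((f.name, float(v), clipped))
            out.values[f.name] = clipped
    return out, log


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldStatistics:
    """Training-split means (numeric) and modes (categorical) for imputation."""

    means: dict
    modes: dict

    @staticmethod
    def fit(records: list[PatientRecord], schema: FeatureSchema) -> "FieldStatistics":
        if not records:
            raise ConfigurationError("cannot fit field statistics on an empty split")
        means = {}
        for f in schema.numeric_fields:
            vals = [r.values[f.name] for r in records if r.values.get(f.name) is not MISSING]
            if vals:
                means[f.name] = float(np.mean(vals))
        modes = {}
        for f in schema.categorical_fields:
            vals = [r.values[f.name] for r in records if r.values.get(f.name) is not MISSING]
            if vals:
                counts = Counter(vals)
                top = max(counts.values())
                # deterministic tie-break: schema category order
                modes[f.name] = next(c for c in f.categories if counts.get(c, 0) == top)
        return FieldStatistics(means=means, modes=modes)


def impute_record(
    record: PatientRecord, stats: FieldStatistics, schema: FeatureSchema
) -> PatientRecord:
    """Fill missing values, tagging each fill with its imputation status.

    Afebrile patients with no CRP result get the clinical baseline value;
    every other missing numeric gets the training mean and every missing
    categorical the training mode. Measured values are never touched.
    """
    out = record.copy()
    for f in schema.numeric_fields:
        if out.values.get(f.name, MISSING) is not MISSING:
            continue
        if f.name == "crp" and not record.fever_flag:
            out.values["crp"] = CRP_BASELINE
            out.imputation_status["crp"] = IMPUTED_BASELINE
            continue
        if f.name not in stats.means:
            raise ConfigurationError(f"no training mean available for field {f.name!r}")
        out.values[f.name] = stats.means[f.name]
        out.imputation_status[f.name] = IMPUTED_MEAN
    for f in schema.categorical_fields:
        if out.values.get(f.name, MISSING) is not MISSING:
            continue
        if f.name not in stats.modes:
            raise ConfigurationError(f"no training mode available for field {f.name!r}")
        out.values[f.name] = stats.modes[f.name]
        out.imputation_status[f.name] = IMPUTED_MODE
    return out


def impute_cohort(cohort: Cohort, stats: FieldStatistics) -> Cohort:
    return Cohort([impute_record(r, stats, cohort.schema) for r in cohort], cohort.schema)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Per-field z-score parameters fitted on the training split only.

    Uses the population standard deviation; sd = 0 fields transform to 0.
    """

    means: dict
    sds: dict
    field_names: list[str]

    @staticmethod
    def fit(records: list[PatientRecord], schema: FeatureSchema) -> "Standardizer":
        if not records:
            raise ConfigurationError("cannot fit a standardizer on an empty split")
        means, sds = {}, {}
        for f in schema.numeric_fields:
            if any(r.values.get(f.name, MISSING) is MISSING for r in records):
                raise ConfigurationError(f"field {f.name!r} still has missing values; impute first")
            vals = np.array([float(r.values[f.name]) for r in records])
            means[f.name] = float(vals.mean())
            sds[f.name] = float(vals.std())  # population sd
        return Standardizer(means=means, sds=sds, field_names=[f.name for f in schema.numeric_fields])

    def transform_value(self, name: str, value: float) -> float:
        sd = self.sds[name]
        if sd == 0.0:
            return 0.0
        return (float(value) - self.means[name]) / sd

    def inverse_value(self, name: str, z: float) -> float:
        return z * self.sds[name] + self.means[name]

    def transform_record(self, record: PatientRecord) -> np.ndarray:
        return np.array([self.transform_value(n, record.values[n]) for n in self.field_names])


def encode_binary(
    record: PatientRecord, schema: FeatureSchema, standardizer: Standardizer
) -> np.ndarray:
    """One-hot categorical bits + standardized numerics (baseline-model encoding)."""
    parts = []
    for f in schema.categorical_fields:
        v = record.values.get(f.name, MISSING)
        if v is MISSING or v not in f.categories:
            raise SchemaError(f"field {f.name!r}: cannot one-hot encode {v!r}")
        bits = np.zeros(f.cardinality)
        bits[f.categories.index(v)] = 1.0
        parts.append(bits)
    parts.append(standardizer.transform_record(record))
    return np.concatenate(parts)
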