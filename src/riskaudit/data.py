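"""Patient-level tabular data: schema declaration, validation, CSV ingestion.

The containers here are deliberately thin: a :class:`DatasetSchema` names the
binary outcome column and declares each predictor's kind (continuous, boolean
or nominal), and a :class:`PatientTable` holds the validated column arrays.
Continuous features may contain missing values (NaN in memory, empty fields on
disk); the outcome must be complete and binary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

FEATURE_KINDS = ("continuous", "boolean", "nominal")


class SchemaError(ValueError):
    """The file or frame does not match the declared schema."""


class ValidationError(ValueError):
    """The data violate a container invariant (e.g. non-binary outcome)."""


@dataclass(frozen=True)
class FeatureSpec:
    """One predictor column: name, kind and free-text units."""

    name: str
    kind: str = "continuous"
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(
                f"feature {self.name!r}: kind must be one of {FEATURE_KINDS}, got {self.kind!r}"
            )


@dataclass(frozen=True)
class DatasetSchema:
    """Outcome column name plus an ordered list of feature specs.

    Invariants: the outcome is not among the features, feature names are
    unique, and there is at least one feature.
    """

    outcome_name: str
    features: tuple[FeatureSpec, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(names) == 0:
            raise ValidationError("schema needs at least one feature")
        if len(set(names)) != len(names):
            raise ValidationError("feature names must be unique")
        if self.outcome_name in names:
            raise ValidationError("outcome column cannot also be a feature")

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    def kind_of(self, name: str) -> str:
        for f in self.features:
            if f.name == name:
                return f.kind
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "outcome_name": self.outcome_name,
            "features": [
                {"name": f.name, "kind": f.kind, "units": f.units} for f in self.features
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatasetSchema":
        feats = tuple(
            FeatureSpec(f["name"], f.get("kind", "continuous"), f.get("units", ""))
            for f in d["features"]
        )
        return cls(outcome_name=d["outcome_name"], features=feats)

    @classmethod
    def infer(cls, df: pd.DataFrame, outcome_name: str) -> "DatasetSchema":
        """Guess feature kinds from a dataframe.

        Numeric columns whose non-missing values are a subset of {0, 1} are
        boolean, other numeric columns continuous, everything else nominal.
        """
        if outcome_name not in df.columns:
            raise SchemaError(f"outcome column {outcome_name!r} not in dataframe")
        feats = []
        for col in df.columns:
            if col == outcome_name:
                continue
            s = df[col]
            if pd.api.types.is_numeric_dtype(s):
                vals = s.dropna().unique()
                kind = "boolean" if len(vals) and set(np.unique(vals)) <= {0, 1} else "continuous"
            else:
                kind = "nominal"
            feats.append(FeatureSpec(col, kind))
        return cls(outcome_name=outcome_name, features=tuple(feats))


@dataclass
class PatientTable:
    """Validated per-patient arrays: binary outcome plus feature columns.

    ``features`` maps each schema feature to a length-``n`` array: float
    (NaN = missing) for continuous and boolean features, object (strings) for
    nominal ones.
    """

    schema: DatasetSchema
    outcome: np.ndarray
    features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = np.asarray(self.outcome)
        if y.ndim != 1 or y.size < 1:
            raise ValidationError("outcome must be a non-empty 1-d vector")
        yf = y.astype(float, copy=False)
        if np.isnan(yf).any():
            raise ValidationError("outcome contains missing values")
        if not np.isin(yf, (0.0, 1.0)).all():
            bad = np.unique(yf[~np.isin(yf, (0.0, 1.0))])
            raise ValidationError(f"outcome must be binary 0/1; found values {bad.tolist()}")
        self.outcome = yf.astype(np.int8)
        n = self.outcome.size
        for spec in self.schema.features:
            if spec.name not in self.features:
                raise SchemaError(f"feature column {spec.name!r} missing from table")
            col = np.asarray(self.features[spec.name])
            if col.shape != (n,):
                raise ValidationError(f"feature {spec.name!r} has wrong length")
            if spec.kind in ("continuous", "boolean"):
                col = col.astype(float)
                if spec.kind == "boolean":
                    finite = col[~np.isnan(col)]
                    if not np.isin(finite, (0.0, 1.0)).all():
                        raise ValidationError(
                            f"boolean feature {spec.name!r} has values outside {{0,1}}"
                        )
            else:
                col = np.asarray(col, dtype=object)
            self.features[spec.name] = col

    @property
    def n(self) -> int:
        return int(self.outcome.size)

    def to_dataframe(self) -> pd.DataFrame:
        data = {self.schema.outcome_name: self.outcome.astype(int)}
        for spec in self.schema.features:
            data[spec.name] = self.features[spec.name]
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: DatasetSchema) -> "PatientTable":
        if schema.outcome_name not in df.columns:
            raise SchemaError(f"outcome column {schema.outcome_name!r} not found")
        missing = [f.name for f in schema.features if f.name not in df.columns]
        if missing:
            raise SchemaError(f"feature columns missing from data: {missing}")
        declared = set(schema.feature_names) | {schema.outcome_name}
        extra = [c for c in df.columns if c not in declared]
        if extra:
            warnings.warn(f"ignoring undeclared columns: {extra}", stacklevel=2)
        y = df[schema.outcome_name].to_numpy()
        feats = {f.name: df[f.name].to_numpy() for f in schema.features}
        return cls(schema=schema, outcome=y, features=feats)


def read_patient_table(path, schema: DatasetSchema) -> PatientTable:
    """Read a comma-separated patient table (UTF-8, header row) against *schema*.

    Missing continuous values are empty fields on disk and NaN in memory.
    Undeclared columns are ignored with a warning; a missing outcome column or
    non-binary outcome raises.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty input file: {path}") from exc
    if len(df) == 0:
        raise ValidationError(f"input file has a header but no rows: {path}")
    return PatientTable.from_dataframe(df, schema)


def write_patient_table(table: PatientTable, path) -> None:
    """Inverse of :func:`read_patient_table` (CSV, empty field = missing)."""
    table.to_dataframe().to_csv(path, index=False)
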