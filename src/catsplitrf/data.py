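"""Tabular data handling: column schemas and the internal training container.

A dataset is a pandas DataFrame plus a schema mapping each column to a role:

* ``numeric`` — continuous predictor,
* ``ordinal`` — ordered categorical predictor (split at half-integer ranks),
* ``nominal`` — unordered categorical predictor,
* ``outcome_regression`` / ``outcome_classification`` — single outcome column,
* ``outcome_time`` + ``outcome_status`` — survival outcome pair.

Schemas are stored as flat YAML mappings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .nominal import NominalVar, SurvivalOutcome

__all__ = ["Predictor", "TrainingData", "load_schema", "save_schema", "from_dataframe"]

PREDICTOR_ROLES = {"numeric", "ordinal", "nominal"}
OUTCOME_ROLES = {"outcome_regression", "outcome_classification", "outcome_time", "outcome_status"}


@dataclass(frozen=True)
class Predictor:
    """One predictor column in training representation.

    ``numeric``: ``values`` holds floats.  ``ordinal``: ``values`` holds rank
    codes and ``levels`` the sorted distinct raw values.  ``nominal``:
    ``var`` holds the integer-coded :class:`NominalVar`.
    """

    name: str
    kind: str
    values: np.ndarray | None = None
    levels: np.ndarray | None = None
    var: NominalVar | None = None

    @property
    def k(self) -> int:
        return self.var.k if self.var is not None else 0


@dataclass(frozen=True)
class TrainingData:
    """Predictors plus one outcome, validated against a schema."""

    predictors: tuple[Predictor, ...]
    outcome_type: str  # regression | classification | survival
    y: np.ndarray | None = None
    classes: np.ndarray | None = None  # original class labels, sorted
    surv: SurvivalOutcome | None = None

    @property
    def n(self) -> int:
        if self.surv is not None:
            return len(self.surv)
        return self.y.size

    @property
    def p(self) -> int:
        return len(self.predictors)

    @property
    def n_classes(self) -> int:
        return self.classes.size if self.classes is not None else 0


def load_schema(path: str | Path) -> dict[str, str]:
    with open(path) as fh:
        schema = yaml.safe_load(fh)
    if not isinstance(schema, dict):
        raise ValueError("schema must be a mapping of column -> role")
    return {str(k): str(v) for k, v in schema.items()}


def save_schema(schema: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(schema), fh, sort_keys=False)


def _outcome_from(df: pd.DataFrame, schema: dict[str, str]):
    roles = {role: col for col, role in schema.items() if role in OUTCOME_ROLES}
    if "outcome_time" in roles or "outcome_status" in roles:
        if not ("outcome_time" in roles and "outcome_status" in roles):
            raise ValueError("survival outcomes need both outcome_time and outcome_status")
        surv = SurvivalOutcome(
            time=df[roles["outcome_time"]].to_numpy(dtype=np.float64),
            status=df[roles["outcome_status"]].to_numpy(dtype=np.int64),
        )
        return "survival", None, None, surv
    if "outcome_regression" in roles:
        y = df[roles["outcome_regression"]].to_numpy(dtype=np.float64)
        return "regression", y, None, None
    if "outcome_classification" in roles:
        raw = df[roles["outcome_classification"]].to_numpy()
        classes, y = np.unique(raw, return_inverse=True)
        return "classification", y.astype(np.int64), classes, None
    raise ValueError("schema declares no outcome column")


def from_dataframe(
    df: pd.DataFrame,
    schema: dict[str, str],
    nominal_labels: dict[str, tuple[str, ...]] | None = None,
) -> TrainingData:
    """Convert a DataFrame to the internal training representation.

    ``nominal_labels`` pins the category label sets (label-sorted order) of
    nominal columns; used to align validation data with training categories.
    """
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"schema columns missing from data: {missing}")
    predictors = []
    for col, role in schema.items():
        if role in OUTCOME_ROLES:
            continue
        if role == "numeric":
            predictors.append(Predictor(col, "numeric", values=df[col].to_numpy(dtype=np.float64)))
        elif role == "ordinal":
            raw = df[col].to_numpy(dtype=np.float64)
            levels = np.unique(raw)
            ranks = np.searchsorted(levels, raw).astype(np.float64)
            predictors.append(Predictor(col, "ordinal", values=ranks, levels=levels))
        elif role == "nominal":
            labels = None if nominal_labels is None else nominal_labels.get(col)
            predictors.append(
                Predictor(col, "nominal", var=NominalVar.from_values(df[col].to_numpy(), labels))
            )
        else:
            raise ValueError(f"unknown role {role!r} for column {col!r}")
    outcome_type, y, classes, surv = _outcome_from(df, schema)
    return TrainingData(
        predictors=tuple(predictors),
        outcome_type=outcome_type,
        y=y,
        classes=classes,
        surv=surv,
    )
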