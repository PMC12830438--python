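"""CSV table schemas, validation, and round-trip I/O.

Conventions enforced here once: 0-based ``trial_index``, angles in the
half-open interval [0, 360), RTs as positive floating-point milliseconds.
Hard violations (missing columns, duplicate trial keys, out-of-range
values) abort with row numbers; soft issues (missing covariates) warn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: dict  # column -> dtype kind: 'str' | 'int' | 'float'
    key: tuple = ()  # columns forming the uniqueness key
    optional: tuple = ()  # columns allowed to hold NaN
    checks: tuple = field(default_factory=tuple)  # (label, fn(df) -> bool mask of bad rows)


def _angle_check(col):
    return (f"{col} in [0,360)",
            lambda df: (df[col] < 0) | (df[col] >= 360) | ~np.isfinite(df[col]))


SCHEMAS = {
    "di_trials": TableSchema(
        name="di_trials",
        columns={"participant_id": "str", "session": "int", "trial_index": "int",
                 "target_id": "int", "posttarget_id": "int", "response_id": "int"},
        key=("participant_id", "session", "trial_index"),
        checks=(("target != posttarget", lambda df: df["target_id"] == df["posttarget_id"]),),
    ),
    "ab_trials": TableSchema(
        name="ab_trials",
        columns={"participant_id": "str", "session": "int", "trial_index": "int",
                 "trial_type": "str", "lag": "float", "t1_id": "float",
                 "t1_response": "float", "t2_id": "float", "t2_response": "float",
                 "target_id": "float", "posttarget_id": "float", "response_id": "float"},
        key=("participant_id", "session", "trial_index"),
        optional=("lag", "t1_id", "t1_response", "t2_id", "t2_response",
                  "target_id", "posttarget_id", "response_id"),
        checks=(
            ("lag in {3,7} on two-target rows",
             lambda df: (df["trial_type"] == "dual") & ~df["lag"].isin([3.0, 7.0])),
        ),
    ),
    "time_trials": TableSchema(
        name="time_trials",
        columns={"participant_id": "str", "trial_index": "int",
                 "cue_angle_deg": "float", "response_angle_deg": "float"},
        key=("participant_id", "trial_index"),
        checks=(_angle_check("cue_angle_deg"), _angle_check("response_angle_deg")),
    ),
    "rt_trials": TableSchema(
        name="rt_trials",
        columns={"participant_id": "str", "task": "str", "condition": "str",
                 "trial_index": "int", "rt_ms": "float", "correct": "int"},
        key=("participant_id", "task", "trial_index"),
        checks=(("rt_ms > 0", lambda df: ~(df["rt_ms"] > 0)),
                ("correct in {0,1}", lambda df: ~df["correct"].isin([0, 1]))),
    ),
    "covariates": TableSchema(
        name="covariates",
        columns={"participant_id": "str", "age": "float", "order_group": "str",
                 "reading_swe": "float", "reading_pde": "float"},
        key=("participant_id",),
        optional=("age", "reading_swe", "reading_pde"),
    ),
}


def validate(df: pd.DataFrame, schema: TableSchema | str) -> pd.DataFrame:
    """Type-coerce and invariant-check a table against a schema.

    Returns the coerced copy; raises ValidationError naming offending rows
    for hard violations, warns for missing optional values.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    missing = set(schema.columns) - set(df.columns)
    if missing:
        raise ValidationError(f"{schema.name}: missing required column(s) {sorted(missing)}")
    out = df.copy()
    for col, kind in schema.columns.items():
        try:
            if kind == "str":
                out[col] = out[col].astype(str)
            elif kind == "int":
                out[col] = pd.to_numeric(out[col], errors="raise").astype(np.int64)
            else:
                out[col] = pd.to_numeric(out[col], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{schema.name}: column {col!r} failed {kind} coercion: {exc}")

    required = [c for c in schema.columns if c not in schema.optional]
    na_rows = out.index[out[required].isna().any(axis=1)]
    if len(na_rows):
        raise ValidationError(f"{schema.name}: missing values in required columns, rows {na_rows.tolist()[:10]}")
    opt_na = int(out[list(schema.optional)].isna().sum().sum()) if schema.optional else 0
    if schema.name == "covariates" and opt_na:
        warnings.warn(f"{schema.name}: {opt_na} missing covariate value(s); rows flagged, not dropped")

    if schema.key:
        dup = out.duplicated(subset=list(schema.key), keep=False)
        if dup.any():
            raise ValidationError(
                f"{schema.name}: duplicate {schema.key} on rows {out.index[dup].tolist()[:10]}"
            )
    if (out["participant_id"].str.len() == 0).any() if "participant_id" in out else False:
        raise ValidationError(f"{schema.name}: empty participant_id")

    for label, fn in schema.checks:
        bad = fn(out)
        bad = bad.fillna(False) if hasattr(bad, "fillna") else bad
        if np.asarray(bad).any():
            rows = out.index[np.asarray(bad)].tolist()[:10]
            raise ValidationError(f"{schema.name}: violated '{label}' on rows {rows}")
    return out


def read_validate(path, schema: TableSchema | str) -> pd.DataFrame:
    """Read a delimiter-separated table with header and validate it."""
    df = pd.read_csv(path)
    return validate(df, schema)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a schema table as CSV (lossless round-trip with read_validate)."""
    df.to_csv(path, index=False)
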