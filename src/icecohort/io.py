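"""Reading and validating the four analysis input files.

All inputs are plain CSV: persons (one row per background-population
person), hospital contacts, death records and survey responses.  Schema
violations are reported with file, row and column so a failing pipeline
stage names the offending record.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["SchemaError", "read_persons", "read_contacts", "read_deaths", "read_survey"]

PERSON_COLUMNS = ("person_id", "sex", "birth_date")
CONTACT_COLUMNS = ("person_id", "date", "main_dx", "sub_dx", "reason_suicide_attempt")
DEATH_COLUMNS = ("person_id", "date", "cause", "manner")
SURVEY_COLUMNS = (
    "person_id", "completion_date",
    "ideation_ever", "ideation_year", "plans_ever", "plans_year",
    "attempt_ever", "attempt_year",
)


class SchemaError(ValueError):
    """An input file violates its schema; message carries file/row/column."""


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _require_values(df: pd.DataFrame, column: str, path) -> None:
    null = df[column].isna() | (df[column].astype(str).str.strip() == "")
    if null.any():
        row = int(null.idxmax())
        raise SchemaError(f"{path}: row {row}: column {column!r} is empty")


def _parse_dates(df: pd.DataFrame, column: str, path, allow_missing=False) -> None:
    parsed = pd.to_datetime(df[column], errors="coerce", format="ISO8601")
    bad = parsed.isna() & df[column].notna() & (df[column].astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"{path}: row {row}: column {column!r} is not an ISO-8601 date "
            f"({df.loc[row, column]!r})"
        )
    if not allow_missing and parsed.isna().any():
        row = int(parsed.isna().idxmax())
        raise SchemaError(f"{path}: row {row}: column {column!r} missing")
    df[column] = parsed


def read_persons(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    _require_columns(df, PERSON_COLUMNS, path)
    _require_values(df, "person_id", path)
    _parse_dates(df, "birth_date", path)
    if df["person_id"].duplicated().any():
        row = int(df["person_id"].duplicated().idxmax())
        raise SchemaError(f"{path}: row {row}: duplicate person_id")
    return df


def read_contacts(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "main_dx": str, "sub_dx": str})
    _require_columns(df, CONTACT_COLUMNS, path)
    _require_values(df, "person_id", path)
    _require_values(df, "main_dx", path)
    _parse_dates(df, "date", path)
    df["sub_dx"] = df["sub_dx"].fillna("")
    df["reason_suicide_attempt"] = (
        df["reason_suicide_attempt"].fillna(0).astype(int).astype(bool)
    )
    return df


def read_deaths(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "cause": str, "manner": str})
    _require_columns(df, DEATH_COLUMNS, path)
    _require_values(df, "person_id", path)
    _parse_dates(df, "date", path)
    if df["person_id"].duplicated().any():
        row = int(df["person_id"].duplicated().idxmax())
        raise SchemaError(f"{path}: row {row}: multiple death records for one person")
    return df


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    _require_columns(df, SURVEY_COLUMNS, path)
    _require_values(df, "person_id", path)
    _parse_dates(df, "completion_date", path)
    valid = {"Y", "N", "DK", "NA"}
    for col in SURVEY_COLUMNS[2:]:
        vals = df[col].fillna("NA").astype(str).str.strip().str.upper()
        bad = ~vals.isin(valid)
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: row {row}: column {col!r} has invalid answer "
                f"{df.loc[row, col]!r}"
            )
        df[col] = vals
    if df["person_id"].duplicated().any():
        row = int(df["person_id"].duplicated().idxmax())
        raise SchemaError(f"{path}: row {row}: duplicate survey response")
    return df
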