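"""Survey CSV dialect and report serialization.

The survey table is a flat CSV with a strict, documented header:

    id, time_minutes, gender, age,
    q1_f1..q1_f10, q2_f1..q2_f10, q3_f1..q3_f10, q4_f1..q4_f10,
    gdt_1..gdt_4, irrelevant_flag

Empty text fields are preserved as empty strings (never NaN).  Clean
datasets are one row per respondent with the space-joined deduplicated word
sequence per question.  All JSON outputs carry a ``format_version`` field.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

__all__ = [
    "survey_columns",
    "read_survey",
    "write_survey",
    "write_clean_dataset",
    "read_clean_dataset",
    "write_report",
]

FORMAT_VERSION = 1


def survey_columns(n_questions: int = 4, fields_per_question: int = 10) -> list[str]:
    cols = ["id", "time_minutes", "gender", "age"]
    for q in range(1, n_questions + 1):
        cols += [f"q{q}_f{f}" for f in range(1, fields_per_question + 1)]
    cols += [f"gdt_{i}" for i in range(1, 5)]
    cols.append("irrelevant_flag")
    return cols


def write_survey(records: pd.DataFrame, path) -> None:
    expected = survey_columns()
    missing = [c for c in expected if c not in records.columns]
    if missing:
        raise ValueError(f"survey table missing columns: {missing}")
    records[expected].to_csv(path, index=False)


def read_survey(path, n_questions: int = 4, fields_per_question: int = 10) -> pd.DataFrame:
    """Read and validate a raw survey CSV; header must match exactly."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = survey_columns(n_questions, fields_per_question)
    if list(df.columns) != expected:
        missing = sorted(set(expected) - set(df.columns))
        extra = sorted(set(df.columns) - set(expected))
        raise ValueError(
            f"survey header mismatch: missing columns {missing}, unexpected columns {extra}"
        )
    df["time_minutes"] = pd.to_numeric(df["time_minutes"], errors="raise")
    df["age"] = pd.to_numeric(df["age"], errors="raise")
    for i in range(1, 5):
        col = f"gdt_{i}"
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round())
        if bad.any():
            rows = df.loc[bad, "id"].tolist()
            raise ValueError(f"non-integer GDT item {col} in rows with id {rows}")
        df[col] = vals.astype(int)
    df["irrelevant_flag"] = df["irrelevant_flag"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if df["irrelevant_flag"].isna().any():
        raise ValueError("irrelevant_flag must be boolean")
    return df


def write_clean_dataset(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, index=False)


def read_clean_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    for q in (1, 2, 3, 4):
        df[f"q{q}"] = df[f"q{q}"].astype(str)
        if f"q{q}_n_words" in df.columns:
            df[f"q{q}_n_words"] = pd.to_numeric(df[f"q{q}_n_words"]).astype(int)
    for i in range(1, 5):
        df[f"gdt_{i}"] = pd.to_numeric(df[f"gdt_{i}"]).astype(int)
    return df


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report: dict, path) -> None:
    payload = {"format_version": FORMAT_VERSION}
    payload.update(_jsonable(report))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
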