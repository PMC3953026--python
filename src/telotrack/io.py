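"""CSV dialects shared by the generator, the pipeline, and the CLI.

One row per well / per examination record / per registry event; ISO-8601
dates; explicit ``missing`` tokens rather than empty cells.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MISSING_TOKEN = "missing"

PLATE_COLUMNS = ["plate_id", "sample_id", "role", "assay", "ct", "primer_dimer"]
EXAM_COLUMNS = [
    "participant_id", "exam_id", "exam_date", "age", "sex", "current_smoking",
    "tobacco_g_day", "weight_kg", "height_m", "bmi", "alcohol_g_week",
    "exercise_h_week", "tl_bp",
]
REGISTRY_COLUMNS = ["participant_id", "event_date", "event_type", "icd_version", "icd_code"]


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep=MISSING_TOKEN)


def _read(path: str | Path, required: list[str], date_cols: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    df = pd.read_csv(path, na_values=[MISSING_TOKEN], keep_default_na=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path} missing required columns: {missing}")
    for col in date_cols:
        df[col] = pd.to_datetime(df[col])
    return df


def read_plates(path: str | Path) -> pd.DataFrame:
    df = _read(path, PLATE_COLUMNS)
    df["primer_dimer"] = df["primer_dimer"].astype(bool)
    return df


def read_exams(path: str | Path) -> pd.DataFrame:
    return _read(path, EXAM_COLUMNS, date_cols=("exam_date",))


def read_registry(path: str | Path) -> pd.DataFrame:
    df = _read(path, REGISTRY_COLUMNS, date_cols=("event_date",))
    df["icd_version"] = df["icd_version"].fillna("")
    df["icd_code"] = df["icd_code"].fillna("")
    return df
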