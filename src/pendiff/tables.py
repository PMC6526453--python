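"""CSV dialects for stroke logs, trials, schedules, cohort truths and fits.

All files are UTF-8 with a header row, '.' decimal separator and ``NA`` for
missing values. Writing then reading any table is the identity on its
records.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DataError

__all__ = [
    "read_strokes", "write_strokes",
    "read_trials", "write_trials",
    "read_schedule", "write_schedule",
    "read_truth", "write_truth",
    "read_fits", "write_fits",
]

_NA = "NA"

# column -> ("int" | "float" | "str" | "bool"), nullable flag
_SCHEMAS = {
    "strokes": {
        "participant_id": ("str", False),
        "session": ("int", False),
        "page": ("int", False),
        "slot": ("int", False),
        "checkbox": ("str", False),
        "pen_down_s": ("float", False),
        "pen_up_s": ("float", False),
    },
    "trials": {
        "participant_id": ("str", False),
        "session": ("int", False),
        "page": ("int", False),
        "slot": ("int", False),
        "condition": ("str", False),
        "is_reference": ("bool", False),
        "is_practice": ("bool", False),
        "response": ("str", True),
        "rt_s": ("float", True),
    },
    "schedule": {
        "stimulus_id": ("int", False),
        "text": ("str", False),
        "condition": ("str", False),
        "frequency_class": ("str", False),
        "session": ("int", False),
        "page": ("int", False),
        "slot": ("int", False),
        "is_reference": ("bool", False),
    },
}


def _read(path, schema_name: str) -> pd.DataFrame:
    schema = _SCHEMAS[schema_name]
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    except Exception as exc:  # malformed CSV structure
        raise DataError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = set(schema) - set(raw.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    out = pd.DataFrame(index=raw.index)
    for col, (kind, nullable) in schema.items():
        s = raw[col]
        is_na = s.eq(_NA) | s.eq("")
        if is_na.any() and not nullable:
            line = int(is_na.idxmax()) + 2  # +1 header, +1 one-based
            raise DataError(f"{path}:{line}: missing value in column '{col}'")
        if kind in ("int", "float"):
            conv = pd.to_numeric(s.where(~is_na), errors="coerce")
            bad = conv.isna() & ~is_na
            if bad.any():
                line = int(bad.idxmax()) + 2
                raise DataError(
                    f"{path}:{line}: non-numeric value {s[bad.idxmax()]!r} "
                    f"in column '{col}'"
                )
            out[col] = conv.astype(float) if kind == "float" else conv.astype("int64")
        elif kind == "bool":
            ok = s.isin(["0", "1"])
            if not ok.all():
                line = int((~ok).idxmax()) + 2
                raise DataError(f"{path}:{line}: column '{col}' must be 0 or 1")
            out[col] = s.eq("1")
        else:
            out[col] = s.where(~is_na)
    return out


def _write(df: pd.DataFrame, path, schema_name: str) -> None:
    schema = _SCHEMAS[schema_name]
    out = pd.DataFrame(index=df.index)
    for col, (kind, _) in schema.items():
        if kind == "bool":
            out[col] = df[col].astype(bool).astype(int)
        else:
            out[col] = df[col]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, na_rep=_NA, encoding="utf-8")


def read_strokes(path) -> pd.DataFrame:
    return _read(path, "strokes")


def write_strokes(df: pd.DataFrame, path) -> None:
    _write(df, path, "strokes")


def read_trials(path) -> pd.DataFrame:
    df = _read(path, "trials")
    df["correct"] = np.where(
        df["response"].notna(), df["response"] == df["condition"], np.nan
    )
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    _write(df, path, "trials")


def read_schedule(path) -> pd.DataFrame:
    return _read(path, "schedule")


def write_schedule(df: pd.DataFrame, path) -> None:
    _write(df, path, "schedule")


def read_truth(path) -> pd.DataFrame:
    """Per-participant true parameters and covariates (free-form columns)."""
    return pd.read_csv(path, na_values=[_NA], keep_default_na=False, encoding="utf-8")


def write_truth(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep=_NA, encoding="utf-8")


def read_fits(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=[_NA], keep_default_na=False, encoding="utf-8")
    if "converged" in df.columns:
        df["converged"] = df["converged"].astype(bool)
    return df


def write_fits(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep=_NA, encoding="utf-8")
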