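"""Reading and writing the flat record schema and YAML configuration."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simulate import RECORD_COLUMNS

DATE_COLUMNS = ("birth_date", "pension_start_date", "pension_end_date", "death_date")


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Write records as UTF-8 CSV (RFC 4180), empty string for missing dates.

    Output is byte-deterministic for a given frame: dates are ISO-8601,
    ``retirement_age_years`` and ``initial_pension_eur_month`` carry two
    decimals.
    """
    out = df.copy()
    for col in DATE_COLUMNS:
        if col in out:
            dt = pd.to_datetime(out[col])
            out[col] = dt.dt.strftime("%Y-%m-%d").fillna("")
    for col in ("retirement_age_years", "initial_pension_eur_month"):
        if col in out:
            out[col] = out[col].map(lambda v: f"{v:.2f}")
    cols = [c for c in RECORD_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a record CSV; empty date fields become NaT, bad dates stay NaT."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in DATE_COLUMNS:
        if col in df:
            df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    for col in ("retirement_age_years", "initial_pension_eur_month"):
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
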