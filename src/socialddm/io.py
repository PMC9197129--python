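"""Delimited-text serialization of trial tables and fit tables.

All tables are UTF-8 tab-separated files with a header row, '.' decimal
separator, and 0-based trial indices.  The trial-table schema is the one
:mod:`socialddm.fitting` consumes (see ``TRIAL_COLUMNS``).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .fitting import TRIAL_COLUMNS

__all__ = ["write_trials", "read_trials", "write_table", "read_table"]

_REQUIRED = set(TRIAL_COLUMNS)


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as TSV (schema-checked)."""
    missing = _REQUIRED - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, sep="\t")
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"{path}: not a trial table; missing columns {sorted(missing)}")
    df["censored"] = df["censored"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table (fits, summaries, reports) as TSV."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
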