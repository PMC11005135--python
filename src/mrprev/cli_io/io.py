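"""Typed CSV reading and writing with schema checks.

Tables are UTF-8, comma-delimited, header row, empty fields for missing
values (RFC-4180 quoting via pandas).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "read_table",
    "write_table",
    "OUTCOME_SURVEY_SCHEMA",
    "SMOKING_SURVEY_SCHEMA",
    "POPULATION_SCHEMA",
    "GOLD_SCHEMA",
    "TRUTH_SCHEMA",
]

_CELL_COLS = {
    "sex": "string",
    "age_group": "string",
    "race_eth": "string",
    "ses": "string",
}

OUTCOME_SURVEY_SCHEMA: Mapping[str, str] = {
    "domain": "int64",
    "wave": "int64",
    **_CELL_COLS,
    "outcome": "int64",
    "weight": "float64",
    "labor_force_rate": "float64",
}

SMOKING_SURVEY_SCHEMA: Mapping[str, str] = {
    "domain": "int64",
    "wave": "int64",
    **_CELL_COLS,
    "smoker": "int64",
    "weight": "float64",
    "labor_force_rate": "float64",
}

POPULATION_SCHEMA: Mapping[str, str] = {
    "domain": "int64",
    "wave": "int64",
    **_CELL_COLS,
    "population": "int64",
}

GOLD_SCHEMA: Mapping[str, str] = {
    "domain": "int64",
    "wave": "int64",
    "subgroup": "string",
    "estimate": "float64",
    "variance": "float64",
    "n": "int64",
}

TRUTH_SCHEMA: Mapping[str, str] = {
    "domain": "int64",
    "wave": "int64",
    **_CELL_COLS,
    "population": "int64",
    "pi_true": "float64",
    "p_smoke": "float64",
    "n_true": "float64",
}


def read_table(path: str | Path, schema: Mapping[str, str]) -> pd.DataFrame:
    """Read a CSV whose header must match ``schema`` exactly."""
    path = Path(path)
    header = pd.read_csv(path, nrows=0).columns.tolist()
    missing = [c for c in schema if c not in header]
    extra = [c for c in header if c not in schema]
    if missing or extra:
        raise ValueError(
            f"{path.name}: schema mismatch; missing columns {missing}, "
            f"unexpected columns {extra}"
        )
    df = pd.read_csv(path, dtype=dict(schema))
    # plain python strings downstream
    for col, dt in schema.items():
        if dt == "string":
            df[col] = df[col].astype(object)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a CSV round-trip-stable to 17 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")
    return path
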