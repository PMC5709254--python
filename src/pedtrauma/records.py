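"""ED visit record schema and delimited-file round trip.

A visit table is a pandas ``DataFrame`` with one row per ED visit. Multi-value
code fields (up to 4 external-cause E-codes, up to 15 ICD-9-CM diagnosis
codes) are stored pipe-delimited inside a single cell, which keeps the table
rectangular and round-trips losslessly through CSV.
"""
from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

REGIONS = ("Northeast", "Midwest", "South", "West")

#: required columns for a visit table
CORE_COLUMNS = [
    "visit_id", "year", "age", "female", "stratum_id", "cluster_id",
    "weight", "ecodes", "dx_codes", "died", "trauma_level12", "region",
]

MAX_ECODES = 4
MAX_DX = 15


def split_codes(cell) -> list[str]:
    """Split a pipe-delimited code cell into a list ('' -> [])."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return []
    return str(cell).split("|")


def join_codes(codes) -> str:
    return "|".join(codes)


def validate_records(df: pd.DataFrame) -> pd.DataFrame:
    """Check the visit-table contract; returns the frame unchanged.

    Raises ``ValueError`` on a missing column, an age outside 0-19, a
    non-positive weight, a death without any diagnosis code, or an unknown
    census region.
    """
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"visit table missing columns: {missing}")
    if len(df) == 0:
        return df
    age = df["age"].to_numpy()
    if (age < 0).any() or (age > 19).any():
        raise ValueError("age outside the pediatric range 0-19")
    if (df["weight"].to_numpy() <= 0).any():
        raise ValueError("survey weights must be strictly positive")
    bad_region = set(df["region"].unique()) - set(REGIONS)
    if bad_region:
        raise ValueError(f"unknown region values: {sorted(bad_region)}")
    died = df["died"].to_numpy().astype(bool)
    has_dx = df["dx_codes"].fillna("").astype(str).str.len() > 0
    if (died & ~has_dx.to_numpy()).any():
        raise ValueError("death recorded on a visit without diagnosis codes")
    return df


def write_records(df: pd.DataFrame, path, config=None) -> None:
    """Write a visit table as CSV; optionally drop a ``<path>.yaml`` sidecar
    holding the generating configuration."""
    path = pathlib.Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        from .synthetic import config_to_dict  # local import, avoids cycle

        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def read_records(path) -> pd.DataFrame:
    """Read a visit table written by :func:`write_records`."""
    df = pd.read_csv(path, dtype={"ecodes": str, "dx_codes": str, "region": str})
    for col in ("ecodes", "dx_codes"):
        df[col] = df[col].fillna("")
    return validate_records(df)
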