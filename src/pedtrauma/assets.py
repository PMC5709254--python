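"""Packaged lookup tables.

All classification steps (E-code mechanism, Barell matrix cells, TBI types)
run against small editable CSV assets shipped with the package, so that the
code lists can be audited or swapped without touching code.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml


def _asset_path(name: str):
    return resources.files("pedtrauma.data").joinpath(name)


@lru_cache(maxsize=None)
def load_ecode_classes() -> pd.DataFrame:
    """E-code -> mechanism category (pedestrian/bicyclist/excluded_*) table.

    The ``group`` column distinguishes traffic (E810-E819), non-traffic
    (E820-E825) and pedal-cycle (E826) code blocks for sensitivity counts.
    """
    with _asset_path("ecode_classes.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)


@lru_cache(maxsize=None)
def ecode_category_map() -> dict[str, str]:
    df = load_ecode_classes()
    return dict(zip(df["code"], df["category"]))


@lru_cache(maxsize=None)
def ecode_group_map() -> dict[str, str]:
    df = load_ecode_classes()
    return dict(zip(df["code"], df["group"]))


@lru_cache(maxsize=None)
def load_barell_cells() -> pd.DataFrame:
    with _asset_path("barell_cells.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)


@lru_cache(maxsize=None)
def barell_cell_map() -> dict[str, tuple[str, str]]:
    df = load_barell_cells()
    return {c: (r, n) for c, r, n in zip(df["code"], df["body_region"], df["nature"])}


@lru_cache(maxsize=None)
def load_tbi_types() -> pd.DataFrame:
    with _asset_path("tbi_types.csv").open() as fh:
        return pd.read_csv(fh, dtype=str)


@lru_cache(maxsize=None)
def tbi_type_map() -> dict[str, str]:
    df = load_tbi_types()
    return dict(zip(df["code"], df["tbi_type"]))


@lru_cache(maxsize=None)
def load_denominators() -> pd.DataFrame:
    """Annual denominators: US 0-19 population, total ED discharges (where
    published), and highway vehicle-miles traveled (millions)."""
    with _asset_path("denominators.csv").open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def load_published_estimates() -> dict:
    """Published national survey estimates (annual counts with SEs, period
    totals, TBI-grade table, interaction risk quartet) used as reference
    inputs for worked examples and arithmetic checks."""
    with _asset_path("published_estimates.yaml").open() as fh:
        return yaml.safe_load(fh)
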